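"""Bootstrap-NMF extraction of composite sequence+structure signatures.

The samples x 192 dual-block count matrix is repeatedly perturbed by
per-sample multinomial bootstrap and factorized with Lee-Seung
multiplicative-update NMF (squared Frobenius objective) over a range of
component numbers k.  A hierarchical pass removes samples that are
already well reconstructed (cosine above a threshold) between rounds so
rarer processes can surface.  Pooled candidate signatures are then:

* matched against a reference catalog of 96-channel trinucleotide
  signatures (cosine on the trinucleotide half only); per catalog entry
  the best-matching candidate is kept when its cosine exceeds 0.85 and
  named after every catalog entry it resembles ("L" suffix for
  0.85 <= cosine < 0.95, none for >= 0.95);
* clustered per-k with a CLARA-style k-medoids (PAM on repeated 10%
  subsamples, Euclidean distance on standardized profiles); the
  clustering whose medoids agree most with the catalog is kept and
  medoids dissimilar from every catalog entry (cosine < 0.8) become
  novel structural signatures SBS-SS1, SBS-SS2, ... ordered by total
  exposure.

Exposures are the NMF score (H) rows of the contributing run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import feature_labels, seq_feature_labels

logger = logging.getLogger(__name__)

MATCH_THRESHOLD = 0.85   # minimum cosine to call a candidate "known"
CLOSE_THRESHOLD = 0.95   # at or above: no "L" (like) suffix
RECONSTRUCTION_THRESHOLD = 0.97  # hierarchical sample-removal cosine
NOVELTY_THRESHOLD = 0.80  # below: a medoid is a novel signature


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u.v / (|u||v|); errors on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


# ---------------------------------------------------------------------------
# reference catalog


@dataclass
class SignatureCatalog:
    """Named 96-channel trinucleotide reference profiles, each summing to 1."""

    profiles: pd.DataFrame  # 96 rows (context labels) x signatures

    def __post_init__(self):
        if self.profiles.shape[0] != 96:
            raise ValueError("catalog profiles must have 96 rows")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("catalog profiles must be non-negative")
        totals = self.profiles.sum(axis=0)
        self.profiles = self.profiles / totals

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.profiles.columns]

    def profile(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy()

    def matrix(self) -> np.ndarray:
        return self.profiles.to_numpy().T  # signatures x 96

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        expected = seq_feature_labels()
        if list(df.index) != expected:
            df = df.reindex(expected)
            if df.isna().any().any():
                raise ValueError(
                    f"catalog {path} does not cover the 96 canonical contexts"
                )
        return cls(profiles=df)

    def to_tsv(self, path: str | Path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="context")


# ---------------------------------------------------------------------------
# bootstrap and NMF


def bootstrap_spectrum(
    matrix: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-sample multinomial resampling of a samples x features count matrix.

    Each row is redrawn at its own total, preserving row sums exactly;
    zero-sum rows pass through unchanged with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = np.asarray(matrix)
    if (M < 0).any():
        raise ValueError("bootstrap requires a non-negative count matrix")
    out = np.empty_like(M, dtype=np.int64)
    for i, row in enumerate(M):
        total = int(row.sum())
        if total == 0:
            logger.warning("bootstrap: sample row %d has zero total", i)
            out[i] = 0
        else:
            out[i] = rng.multinomial(total, row / row.sum())
    return out


@dataclass
class NMFRun:
    """One NMF factorization V ~ W H with provenance.

    W columns are L1-normalized signature profiles (features x k); the
    absorbed scales live in H (k x samples), whose rows are exposures.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    bootstrap: int
    round: int
    sample_ids: list[str]
    objective: float
    converged: bool
    n_iter: int
    objective_trace: np.ndarray | None = None


def nmf_multiplicative(
    V: np.ndarray,
    k: int,
    *,
    seed: int | np.random.Generator = 0,
    max_iter: int = 10000,
    tol: float = 1e-9,
    track_objective: bool = False,
    check_every: int = 10,
) -> NMFRun:
    """Lee-Seung multiplicative-update NMF minimizing ||V - WH||_F^2.

    W and H start uniform-random in (0, 1] from the given seed; iteration
    stops at ``max_iter`` or when the relative objective decrease over a
    check interval falls below ``tol``.  With ``track_objective`` the full
    per-iteration objective sequence is recorded (it is non-increasing).
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF requires a non-negative matrix")
    f, n = V.shape
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(f, n):
        raise ValueError(f"k={k} must be below min(dim)={min(f, n)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = 1e-12
    W = 1.0 - rng.random((f, k))  # uniform in (0, 1]
    H = 1.0 - rng.random((k, n))
    norm_v = float((V ** 2).sum())

    def objective() -> float:
        return float(((V - W @ H) ** 2).sum())

    trace = [objective()] if track_objective else []
    prev = trace[0] if trace else objective()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        if track_objective:
            trace.append(objective())
        if it % check_every == 0 or it == max_iter:
            cur = trace[-1] if track_objective else objective()
            denom = max(prev, eps * norm_v, eps)
            if prev - cur >= 0 and (prev - cur) / denom < tol:
                converged = True
                break
            prev = cur
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return NMFRun(
        W=W, H=H, k=k, bootstrap=-1, round=-1,
        sample_ids=[f"s{i}" for i in range(n)],
        objective=objective(), converged=converged, n_iter=it,
        objective_trace=np.asarray(trace) if track_objective else None,
    )


def reconstruction_cosines(run: NMFRun, V_original: np.ndarray) -> np.ndarray:
    """Per-sample cosine between reconstruction and the original spectrum."""
    R = run.W @ run.H
    num = (R * V_original).sum(axis=0)
    den = np.linalg.norm(R, axis=0) * np.linalg.norm(V_original, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(den > 0, num / den, 0.0)
    return cos


def hierarchical_extract(
    matrix: pd.DataFrame | np.ndarray,
    k_range: Sequence[int],
    *,
    n_boot: int = 300,
    recon_cos: float = RECONSTRUCTION_THRESHOLD,
    max_rounds: int = 3,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-9,
) -> list[NMFRun]:
    """Bootstrap-NMF pool over k, with hierarchical sample removal.

    Each round fits ``n_boot`` bootstrap replicates at every k on the
    currently active samples.  A sample whose original spectrum is
    reconstructed above ``recon_cos`` by any run of the round is removed
    before the next round (at most ``max_rounds`` rounds).  Every run is
    kept in the returned pool with (bootstrap, k, round) provenance.
    """
    if isinstance(matrix, pd.DataFrame):
        sample_ids = [str(i) for i in matrix.index]
        M = matrix.to_numpy(dtype=float)
    else:
        M = np.asarray(matrix, dtype=float)
        sample_ids = [f"s{i}" for i in range(M.shape[0])]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    if M.shape[0] < max(k_range) + 1:
        raise ValueError(
            f"need at least max(k_range)+1={max(k_range) + 1} samples, "
            f"got {M.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    active = list(range(M.shape[0]))
    pool: list[NMFRun] = []
    for round_idx in range(1, max_rounds + 1):
        usable_k = [k for k in k_range if k < len(active)]
        if not usable_k or len(active) < 2:
            logger.info("hierarchical extraction stopped before round %d: "
                        "%d active samples", round_idx, len(active))
            break
        V_orig = M[active].T  # features x active samples
        round_runs: list[NMFRun] = []
        for b in range(n_boot):
            Vb = bootstrap_spectrum(M[active], rng).T.astype(float)
            for k in usable_k:
                run = nmf_multiplicative(
                    Vb, k, seed=rng, max_iter=max_iter, tol=tol
                )
                run.bootstrap = b
                run.round = round_idx
                run.sample_ids = [sample_ids[i] for i in active]
                round_runs.append(run)
        pool.extend(round_runs)
        best_cos = np.zeros(len(active))
        for run in round_runs:
            best_cos = np.maximum(best_cos, reconstruction_cosines(run, V_orig))
        keep = [s for s, c in zip(active, best_cos) if c <= recon_cos]
        removed = len(active) - len(keep)
        logger.info("round %d: %d/%d samples well-reconstructed and removed",
                    round_idx, removed, len(active))
        active = keep
        if not active:
            break
    return pool


# ---------------------------------------------------------------------------
# matching and naming


@dataclass
class ExtractedSignature:
    """A 192-component signature with catalog matches and exposures."""

    profile: np.ndarray
    name: str
    primary_match: tuple[str, float] | None
    secondary_matches: list[tuple[str, float]] = field(default_factory=list)
    exposures: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def trinucleotide_half(self) -> np.ndarray:
        return self.profile[:96]

    @property
    def structural_half(self) -> np.ndarray:
        return self.profile[96:]

    @property
    def total_exposure(self) -> float:
        return float(sum(self.exposures.values()))


def name_signature(similarities: dict[str, float]) -> str:
    """Signature name from its catalog cosine map.

    The primary (arg-max) match is written in full with an "L" suffix when
    its cosine is below 0.95; every further catalog entry at cosine >= 0.85
    is appended after "/" in decreasing-cosine order with the shared "SBS"
    prefix elided, each under the same L rule.  Requires at least one
    cosine >= 0.85.
    """
    hits = sorted(
        ((n, c) for n, c in similarities.items() if c >= MATCH_THRESHOLD),
        key=lambda nc: (-nc[1], nc[0]),
    )
    if not hits:
        raise ValueError("no catalog match at cosine >= 0.85; novel signature")
    parts = []
    for i, (cat_name, cos) in enumerate(hits):
        label = cat_name if i == 0 else (
            cat_name[3:] if cat_name.startswith("SBS") else cat_name
        )
        if cos < CLOSE_THRESHOLD:
            label += "L"
        parts.append(label)
    return "/".join(parts)


def _candidate_table(pool: Iterable[NMFRun]):
    """Flatten a pool into per-component candidates with provenance."""
    cands = []
    for run_idx, run in enumerate(pool):
        for j in range(run.k):
            profile = run.W[:, j]
            if profile[:96].sum() == 0:
                continue
            cands.append({
                "profile": profile,
                "exposures": dict(zip(run.sample_ids, run.H[j])),
                "provenance": {"run": run_idx, "component": j,
                               "bootstrap": run.bootstrap, "k": run.k,
                               "round": run.round},
            })
    return cands


def _catalog_cosines(trinuc: np.ndarray, catalog: SignatureCatalog) -> np.ndarray:
    """Cosines of candidate trinucleotide halves (m x 96) vs catalog entries."""
    C = np.atleast_2d(np.asarray(trinuc, dtype=float))
    S = catalog.matrix()
    Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
    Sn = S / np.linalg.norm(S, axis=1, keepdims=True)
    return Cn @ Sn.T


def select_known(
    pool: Sequence[NMFRun],
    catalog: SignatureCatalog,
    threshold: float = MATCH_THRESHOLD,
) -> list[ExtractedSignature]:
    """Best-matching pooled candidate per catalog signature (cosine > 0.85).

    Matching uses only the trinucleotide half of each candidate.  When
    several catalog entries select the same candidate it is reported once;
    its name already encodes every match at cosine >= 0.85.
    """
    cands = _candidate_table(pool)
    if not cands:
        return []
    cos = _catalog_cosines(np.stack([c["profile"][:96] for c in cands]), catalog)
    chosen: dict[int, ExtractedSignature] = {}
    for s_idx, cat_name in enumerate(catalog.names):
        best = int(np.argmax(cos[:, s_idx]))
        if cos[best, s_idx] <= threshold:
            continue
        if best in chosen:
            continue
        sims = dict(zip(catalog.names, cos[best]))
        hits = sorted(((n, c) for n, c in sims.items() if c >= threshold),
                      key=lambda nc: (-nc[1], nc[0]))
        chosen[best] = ExtractedSignature(
            profile=cands[best]["profile"].copy(),
            name=name_signature(sims),
            primary_match=hits[0],
            secondary_matches=hits[1:],
            exposures=cands[best]["exposures"],
            provenance=cands[best]["provenance"],
        )
    return sorted(chosen.values(), key=lambda s: s.name)


# ---------------------------------------------------------------------------
# CLARA-style k-medoids for novel-signature discovery


def _pam(D: np.ndarray, k: int, rng: np.random.Generator,
         max_swaps: int = 200) -> np.ndarray:
    """PAM (build + swap) on a precomputed distance matrix; medoid indices."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]  # BUILD: most central first
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    cost = D[:, medoids].min(axis=1).sum()
    for _ in range(max_swaps):  # SWAP until no improvement
        improved = False
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            trial = medoids.copy()
            costs = np.empty(len(non_medoids))
            for t, h in enumerate(non_medoids):
                trial[mi] = h
                costs[t] = D[:, trial].min(axis=1).sum()
            best = int(np.argmin(costs))
            if costs[best] < cost - 1e-12:
                medoids[mi] = non_medoids[best]
                medoids.sort()
                cost = costs[best]
                improved = True
        if not improved:
            break
    return medoids


def clara_medoids(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    *,
    subsample_frac: float = 0.10,
    n_subsamples: int = 5,
) -> np.ndarray:
    """CLARA-style k-medoids: PAM on repeated subsamples, best by full cost.

    Each subsample holds max(ceil(frac*n), 2k, k+2) points; medoids from
    the subsample PAM are scored by the total Euclidean distance of all
    points to their nearest medoid, and the best medoid set (full-data
    indices) is returned.
    """
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} needs more than k points (n={n})")
    size = min(n, max(int(np.ceil(subsample_frac * n)), 2 * k, k + 2))
    best_cost, best_medoids = np.inf, None
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=size, replace=False)
        sub = X[idx]
        D = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
        med_local = _pam(D, k, rng)
        med = idx[med_local]
        dist_full = np.linalg.norm(X[:, None, :] - X[med][None, :, :], axis=2)
        cost = dist_full.min(axis=1).sum()
        if cost < best_cost:
            best_cost, best_medoids = cost, np.sort(med)
    return best_medoids


def discover_novel(
    pool: Sequence[NMFRun],
    catalog: SignatureCatalog,
    *,
    cluster_k_range: Sequence[int] = range(2, 41),
    subsample_frac: float = 0.10,
    n_subsamples: int = 5,
    novelty_threshold: float = NOVELTY_THRESHOLD,
    known_threshold: float = MATCH_THRESHOLD,
    dedupe_cos: float = CLOSE_THRESHOLD,
    seed: int = 0,
) -> list[ExtractedSignature]:
    """Novel signatures: cluster candidates per k, keep catalog-dissimilar medoids.

    For each batch (all pooled runs at one k) the standardized candidate
    profiles are clustered for every cluster count in ``cluster_k_range``;
    the clustering maximizing the number of medoids that resemble a
    catalog entry (cosine > 0.85 on the trinucleotide half) is kept, and
    its medoids with maximum catalog cosine < 0.8 are pooled across
    batches, de-duplicated at cosine > 0.95 (keeping the higher total
    exposure), and named SBS-SS1, SBS-SS2, ... by decreasing total
    exposure.
    """
    rng = np.random.default_rng(seed)
    cands = _candidate_table(pool)
    if len(cands) < 3:
        return []
    by_k: dict[int, list[int]] = {}
    for i, c in enumerate(cands):
        by_k.setdefault(c["provenance"]["k"], []).append(i)
    all_profiles = np.stack([c["profile"] for c in cands])
    cos_catalog = _catalog_cosines(all_profiles[:, :96], catalog)
    max_cat = cos_catalog.max(axis=1)
    novel_idx: list[int] = []
    for k_batch in sorted(by_k):
        idx = np.array(by_k[k_batch])
        if len(idx) < 3:
            continue
        X = all_profiles[idx]
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        best = None  # (n_known, -kc, medoid indices into cands)
        for kc in cluster_k_range:
            if kc >= len(idx):
                break
            medoids_local = clara_medoids(
                Xs, kc, rng, subsample_frac=subsample_frac,
                n_subsamples=n_subsamples,
            )
            med = idx[medoids_local]
            n_known = int((max_cat[med] > known_threshold).sum())
            key = (n_known, -kc)
            if best is None or key > best[0]:
                best = (key, med)
        if best is None:
            continue
        novel_idx.extend(int(m) for m in best[1]
                         if max_cat[m] < novelty_threshold)
    # de-duplicate across batches at high cosine, keep larger total exposure
    def total_exposure(i: int) -> float:
        return float(sum(cands[i]["exposures"].values()))

    kept: list[int] = []
    for i in sorted(set(novel_idx), key=lambda i: -total_exposure(i)):
        if all(
            cosine_similarity(all_profiles[i], all_profiles[j]) <= dedupe_cos
            for j in kept
        ):
            kept.append(i)
    out = []
    for rank, i in enumerate(kept, start=1):
        out.append(ExtractedSignature(
            profile=all_profiles[i].copy(),
            name=f"SBS-SS{rank}",
            primary_match=None,
            secondary_matches=[],
            exposures=cands[i]["exposures"],
            provenance=cands[i]["provenance"],
        ))
    return out


# ---------------------------------------------------------------------------
# output


def write_signatures(
    signatures: Sequence[ExtractedSignature],
    out_dir: str | Path,
) -> None:
    """Write signature profiles TSV, exposures TSVs and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not signatures:
        (out / "signatures.json").write_text("[]")
        return
    prof = pd.DataFrame(
        {s.name: s.profile for s in signatures}, index=feature_labels()
    )
    prof.to_csv(out / "signatures.tsv", sep="\t", index_label="feature")
    samples = sorted({sid for s in signatures for sid in s.exposures})
    expo = pd.DataFrame(
        {s.name: [s.exposures.get(sid, 0.0) for sid in samples]
         for s in signatures},
        index=samples,
    )
    expo.to_csv(out / "exposures.tsv", sep="\t", index_label="sample_id")
    norm = expo.div(expo.sum(axis=1).replace(0, 1.0), axis=0)
    norm.to_csv(out / "exposures_normalized.tsv", sep="\t",
                index_label="sample_id")
    meta = [{
        "name": s.name,
        "primary_match": list(s.primary_match) if s.primary_match else None,
        "secondary_matches": [list(m) for m in s.secondary_matches],
        "provenance": s.provenance,
        "total_exposure": s.total_exposure,
    } for s in signatures]
    (out / "signatures.json").write_text(json.dumps(meta, indent=2))
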