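"""Per-sample Poisson regression of k-mer mutation counts.

Each strand-collapsed k-mer occurring in the genome is one observation:
its pooled mutation count y (all alternate alleles at that k-mer, C-site
types pooled and T-site types pooled via the central-base feature) is
modelled as

    log E[y] = log D + beta_0 + beta_1 x_1 + ... + beta_p x_p,

where D is the genome-wide opportunity count of the k-mer (an offset) and
the x_j encode either the flanking nucleotides (sequence representations
"3nt-seq", "5nt-seq") or the L/M/H-binned shape descriptors of the k-mer
(structural representations "5nt-str", "7nt-str").  Model fit is
summarized by McFadden's pseudo-R^2 = 1 - l/l0 against the
intercept-plus-offset null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .shape import (
    BinningSpec,
    HEPTAMER_DESCRIPTORS,
    PENTAMER_DESCRIPTORS,
    ShapeTable,
    descriptor_param_type,
    profile_kmer,
)

REPRESENTATIONS = ("3nt-seq", "5nt-seq", "5nt-str", "7nt-str")

_REP_K = {"3nt-seq": 3, "5nt-seq": 5, "5nt-str": 5, "7nt-str": 7}

#: reference levels dropped from the dummy coding
REF_BASE = "A"      # flanking nucleotides
REF_CENTER = "C"    # central pyrimidine
REF_BIN = "M"       # binned shape descriptors


class CollinearityError(ValueError):
    """Design matrix is rank-deficient after dropping reference levels."""


def representation_k(representation: str) -> int:
    try:
        return _REP_K[representation]
    except KeyError:
        raise ValueError(
            f"unknown representation {representation!r}; choose from "
            f"{REPRESENTATIONS}"
        ) from None


def _seq_features(kmer: str) -> dict[str, str]:
    k = len(kmer)
    half = k // 2
    feats = {}
    for i, base in enumerate(kmer):
        pos = i - half
        if pos == 0:
            feats["center"] = base
        else:
            feats[f"pos{pos:+d}"] = base
    return feats


def build_regression_table(
    contexts,
    opportunities,
    representation: str,
    shape: tuple[ShapeTable, BinningSpec] | None = None,
) -> pd.DataFrame:
    """One row per genome k-mer: kmer, y, D and categorical features.

    ``contexts`` are the oriented contexts of one sample at the matching k;
    every k-mer present in the opportunity table appears as a row, so
    zero-count k-mers retain their opportunity information.
    """
    k = representation_k(representation)
    if opportunities.k != k:
        raise ValueError(
            f"representation {representation} needs k={k} opportunities, "
            f"got k={opportunities.k}"
        )
    counts: dict[str, int] = {}
    for ctx in contexts:
        if ctx.k != k:
            raise ValueError(f"context {ctx.kmer!r} has k={ctx.k}, expected {k}")
        if ctx.kmer not in opportunities.counts:
            raise ValueError(
                f"context k-mer {ctx.kmer!r} absent from the genome "
                "opportunity table; catalog and genome disagree"
            )
        counts[ctx.kmer] = counts.get(ctx.kmer, 0) + 1
    structural = representation.endswith("str")
    if structural and shape is None:
        raise ValueError("structural representations need shape=(table, spec)")
    rows = []
    for kmer in sorted(opportunities.counts):
        row: dict[str, object] = {
            "kmer": kmer,
            "y": counts.get(kmer, 0),
            "D": opportunities.counts[kmer],
        }
        if structural:
            table, spec = shape
            profile = profile_kmer(kmer, table)
            for name, value in profile.descriptors.items():
                row[name] = spec.bin_value(descriptor_param_type(name), value)
        else:
            row.update(_seq_features(kmer))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["representation"] = representation
    expected = (PENTAMER_DESCRIPTORS if representation == "5nt-str"
                else HEPTAMER_DESCRIPTORS if representation == "7nt-str" else None)
    if expected is not None:
        assert [c for c in df.columns if c not in ("kmer", "y", "D")] == list(expected)
    return df


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("kmer", "y", "D")]


def design_matrix(
    table: pd.DataFrame, coding: str = "reference"
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Dummy-coded design (without intercept) and the dropped reference levels.

    ``coding='reference'`` drops one reference level per feature
    (A for flanks, C for the center, M for binned descriptors);
    ``coding='sum'`` uses sum-to-zero contrasts against the same level.
    Constant (all-zero) dummy columns, arising when a level is absent from
    the genome, are removed.
    """
    cols = {}
    dropped = []
    for feat in _feature_columns(table):
        values = table[feat].astype(str)
        levels = sorted(values.unique())
        if feat == "center":
            ref = REF_CENTER if REF_CENTER in levels else levels[0]
        elif feat.startswith("pos"):
            ref = REF_BASE if REF_BASE in levels else levels[0]
        else:
            ref = REF_BIN if REF_BIN in levels else levels[0]
        dropped.append((feat, ref))
        for level in levels:
            if level == ref:
                continue
            ind = (values == level).to_numpy(dtype=float)
            if coding == "sum":
                ind = ind - (values == ref).to_numpy(dtype=float)
            if np.ptp(ind) == 0:
                continue  # level absent (or only level observed)
            cols[f"{feat}[{level}]"] = ind
    X = pd.DataFrame(cols, index=table.index)
    return X, dropped


@dataclass
class PoissonFit:
    """Fitted coefficients, likelihoods and McFadden pseudo-R^2."""

    coefficients: pd.DataFrame  # feature, level, estimate, se, ci_lo, ci_hi
    loglik: float
    loglik_null: float
    representation: str
    n_obs: int
    n_mutations: int
    coding: str = "reference"
    converged: bool = True
    reference_levels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pseudo_r2(self) -> float:
        return mcfadden_pr2(self)

    def coef(self, feature: str, level: str) -> float:
        df = self.coefficients
        row = df[(df["feature"] == feature) & (df["level"] == level)]
        if row.empty:
            raise KeyError(f"no coefficient for {feature}[{level}]")
        return float(row["estimate"].iloc[0])

    def summary_json(self, path: str | Path | None = None) -> str:
        payload = {
            "representation": self.representation,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "pseudo_r2": self.pseudo_r2,
            "n_obs": self.n_obs,
            "n_mutations": self.n_mutations,
            "coding": self.coding,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def coefficients_tsv(self, path: str | Path) -> None:
        self.coefficients.to_csv(path, sep="\t", index=False)


def poisson_loglik(
    y: np.ndarray, mu: np.ndarray
) -> float:
    """Exact Poisson log-likelihood sum log pmf(y; mu)."""
    from scipy.special import gammaln

    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(np.sum(term - mu - gammaln(y + 1)))


def fit_poisson(
    table: pd.DataFrame,
    coding: str = "reference",
    alpha: float = 0.05,
) -> PoissonFit:
    """Maximum-likelihood Poisson fit with offset log D.

    IRLS via statsmodels GLM (max 100 iterations, log-likelihood tolerance
    1e-10), Wald confidence intervals.  Reference levels are reported with
    estimate 0.  Raises :class:`CollinearityError` naming redundant columns
    when the design is rank-deficient.
    """
    y = table["y"].to_numpy(dtype=float)
    if not (y > 0).any():
        raise ValueError("all mutation counts are zero; nothing to fit")
    D = table["D"].to_numpy(dtype=float)
    if ((y > 0) & (D <= 0)).any():
        raise ValueError("positive count with zero opportunity")
    offset = np.log(D)
    X, ref_levels = design_matrix(table, coding=coding)
    Xc = sm.add_constant(X, prepend=True, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the columns whose removal restores full rank
        _, R = np.linalg.qr(Xc.to_numpy())
        bad = [Xc.columns[j] for j in range(Xc.shape[1])
               if abs(R[j, j]) < 1e-8]
        raise CollinearityError(f"collinear design columns: {bad}")
    model = sm.GLM(y, Xc, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=100, tol=1e-10)
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson(),
                  offset=offset).fit(maxiter=100, tol=1e-10)
    ci = res.conf_int(alpha=alpha)
    rows = [{
        "feature": "intercept", "level": "",
        "estimate": float(res.params.iloc[0]),
        "se": float(res.bse.iloc[0]),
        "ci_lo": float(ci.iloc[0, 0]), "ci_hi": float(ci.iloc[0, 1]),
    }]
    for name in X.columns:
        feat, level = name[:-1].split("[", 1)
        i = list(Xc.columns).index(name)
        rows.append({
            "feature": feat, "level": level,
            "estimate": float(res.params.iloc[i]),
            "se": float(res.bse.iloc[i]),
            "ci_lo": float(ci.iloc[i, 0]), "ci_hi": float(ci.iloc[i, 1]),
        })
    for feat, ref in ref_levels:
        rows.append({"feature": feat, "level": ref, "estimate": 0.0,
                     "se": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
    return PoissonFit(
        coefficients=pd.DataFrame(rows),
        loglik=float(res.llf),
        loglik_null=float(null.llf),
        representation=str(table.attrs.get("representation", "?")),
        n_obs=len(table),
        n_mutations=int(table["y"].sum()),
        coding=coding,
        converged=bool(res.converged),
        reference_levels=ref_levels,
    )


def mcfadden_pr2(fit: PoissonFit) -> float:
    """McFadden pseudo-R^2 = 1 - l / l0 (0 for the null model itself)."""
    if fit.loglik_null == 0:
        raise ValueError("degenerate null log-likelihood of 0")
    return 1.0 - fit.loglik / fit.loglik_null
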