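"""Joint PCA of the dual-block spectrum matrix with block attribution.

Principal components are computed by thin SVD of the column-centered
(optionally unit-scaled) samples x 192 matrix.  Because loadings are unit
vectors, the variance explained by PC k splits exactly across any
partition of the columns as ve_k * sum_j loading_jk^2 per block, which
quantifies how much of each component is carried by the trinucleotide
block versus the structural block.  The broken-stick distribution
g_k = (1/p) sum_{i=k}^p 1/i serves as a null baseline for component
retention; following common practice for scree baselines, half of g_k is
also reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class PCADecomposition:
    """Loadings (p x n_pc, orthonormal columns), scores, and variance shares."""

    loadings: np.ndarray
    scores: np.ndarray
    variance_explained: np.ndarray
    column_labels: list[str]
    sample_ids: list[str]
    centered: bool = True
    scaled: bool = False

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Centered-data reconstruction from all retained PCs."""
        return self.scores @ self.loadings.T

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_pc)]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_pc)]
        return pd.DataFrame(self.loadings, index=self.column_labels, columns=cols)


def run_pca(
    matrix: pd.DataFrame | np.ndarray,
    *,
    center: bool = True,
    scale: bool = False,
) -> PCADecomposition:
    """SVD-based PCA of a samples x features matrix.

    Column signs are fixed by forcing the largest-magnitude entry of each
    loading vector positive, making the decomposition reproducible.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(c) for c in matrix.columns]
        samples = [str(i) for i in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [f"f{j}" for j in range(X.shape[1])]
        samples = [f"s{i}" for i in range(X.shape[0])]
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    scale_ref = float(np.linalg.norm(np.asarray(matrix, dtype=float)
                                     if not isinstance(matrix, pd.DataFrame)
                                     else matrix.to_numpy(dtype=float)))
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|entry| of each loading positive
    flip = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    total = float((s ** 2).sum())
    # a centered matrix that is numerically zero carries no variance at all
    if np.sqrt(total) <= 1e-10 * max(scale_ref, 1.0):
        ve = np.zeros_like(s)
    else:
        ve = (s ** 2) / total
    return PCADecomposition(
        loadings=Vt.T,
        scores=U * s,
        variance_explained=ve,
        column_labels=labels,
        sample_ids=samples,
        centered=center,
        scaled=scale,
    )


def block_contributions(
    pca: PCADecomposition,
    blocks: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Per-PC variance share of each column block.

    ``blocks`` must partition the column indices; the returned frame has
    one row per PC with one column per block plus ``variance_explained``,
    and each row's block shares sum to that PC's variance explained.
    """
    p = pca.loadings.shape[0]
    seen = np.zeros(p, dtype=int)
    for idx in blocks.values():
        seen[list(idx)] += 1
    if not (seen == 1).all():
        raise ValueError("blocks do not partition the columns")
    rows = {}
    for name, idx in blocks.items():
        idx = np.asarray(list(idx))
        rows[name] = pca.variance_explained * (pca.loadings[idx, :] ** 2).sum(axis=0)
    df = pd.DataFrame(rows, index=[f"PC{i+1}" for i in range(pca.n_pc)])
    df["variance_explained"] = pca.variance_explained
    return df


def dual_block_contributions(pca: PCADecomposition) -> pd.DataFrame:
    """Sequence/structure split for the canonical 192-column matrix."""
    if pca.loadings.shape[0] != 192:
        raise ValueError("expected the 192-column dual-block matrix")
    return block_contributions(pca, {"seq": range(96), "struct": range(96, 192)})


def broken_stick(p: int) -> pd.DataFrame:
    """Broken-stick expected variance fractions g_k and their halves."""
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    g = np.cumsum(inv[::-1])[::-1] / p  # g_k = (1/p) sum_{i=k}^p 1/i
    return pd.DataFrame(
        {"broken_stick": g, "half_broken_stick": g / 2},
        index=[f"PC{k}" for k in range(1, p + 1)],
    )


def write_pca_outputs(
    pca: PCADecomposition,
    out_dir: str | Path,
    blocks: Mapping[str, Sequence[int]] | None = None,
) -> None:
    """Write loadings/scores/scree TSVs and a JSON block-attribution summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pca.loadings_frame().to_csv(out / "loadings.tsv", sep="\t",
                                index_label="feature")
    pca.scores_frame().to_csv(out / "scores.tsv", sep="\t",
                              index_label="sample_id")
    bs = broken_stick(pca.n_pc)
    scree = pd.DataFrame({"variance_explained": pca.variance_explained},
                         index=bs.index).join(bs)
    if blocks is None and pca.loadings.shape[0] == 192:
        blocks = {"seq": range(96), "struct": range(96, 192)}
    summary = {"n_pc": pca.n_pc, "scaled": pca.scaled}
    if blocks is not None:
        contrib = block_contributions(pca, blocks)
        scree = scree.join(contrib.drop(columns="variance_explained"))
        summary["block_contributions"] = {
            c: contrib[c].tolist() for c in contrib.columns
        }
    scree.to_csv(out / "scree.tsv", sep="\t", index_label="pc")
    summary["variance_explained"] = pca.variance_explained.tolist()
    summary["broken_stick"] = bs["broken_stick"].tolist()
    (out / "pca_summary.json").write_text(json.dumps(summary, indent=2))
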