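"""Seeded generators for genomes, shape tables, signatures and catalogs.

Every stage of the framework is testable without external downloads:

* random i.i.d. genomes at a chosen GC content;
* a physically plausible synthetic pentamer shape table (uniform values
  within literature-scale ranges per parameter type), optionally
  post-adjusted so the energetically forbidden bin combinations never
  occur at the matching central base;
* sparse ground-truth trinucleotide signatures with low mutual cosine;
* mutation catalogs sampled from signature mixtures (per-sample Dirichlet
  exposures), placed at uniformly random genome positions carrying the
  drawn strand-collapsed trinucleotide context -- the structural half of
  a simulated signature therefore arises from the genome and shape table
  exactly as in real data;
* Poisson counts generated from a known coefficient vector over a
  regression design, for parameter-recovery checks.

All functions are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contexts import BASES, MUTATION_TYPES, GenomeView, MutationRecord, revcomp
from .mutability import design_matrix
from .shape import (
    SHAPE_COLUMNS,
    ShapeTable,
    STEP_PARAMS,
    fit_binning,
    _all_pentamers,
)

logger = logging.getLogger(__name__)

#: value ranges per parameter type (degrees or angstroms); fixture-scale
#: stand-ins with literature-plausible magnitudes for the four focal
#: parameters and zero-centered spreads for the rest.
DEFAULT_SHAPE_RANGES: dict[str, tuple[float, float]] = {
    "mgw": (2.8, 6.2),
    "prop": (-25.0, 5.0),
    "tw": (20.0, 40.0),
    "ro": (-10.0, 12.0),
    "open": (-6.0, 6.0),
    "buck": (-14.0, 14.0),
    "stre": (-0.6, 0.6),
    "stag": (-0.6, 0.6),
    "shea": (-0.6, 0.6),
    "ti": (-5.0, 5.0),
    "sl": (-1.2, 1.2),
    "ri": (-0.4, 0.4),
    "sh": (-0.6, 0.6),
}


def make_genome(
    length: int,
    gc: float = 0.41,
    seed: int = 0,
    *,
    name: str = "chr1",
    path=None,
) -> dict[str, str]:
    """Single-contig i.i.d. random genome at the requested GC fraction."""
    if length < 7:
        raise ValueError("genome length must be at least 7")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    genome = {name: seq}
    if path is not None:
        from .contexts import write_fasta

        write_fasta(genome, path)
    return genome


def _column_param_type(col: str) -> str:
    return col.split("_")[0] if "_" in col else col


def make_shape_table(
    seed: int = 0,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    *,
    honor_forbidden: bool = True,
) -> ShapeTable:
    """Synthetic complete pentamer shape table, uniform within ranges.

    With ``honor_forbidden`` the four unsampled combinations are enforced:
    C-centered pentamers never bin prop0 as L nor ro-1 as H, T-centered
    never prop0 as H nor tw+1 as L.  Values are adjusted iteratively
    against the table's own fitted binning until no violation remains.
    """
    ranges = dict(DEFAULT_SHAPE_RANGES, **(ranges or {}))
    for ptype, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid range for {ptype}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    pentamers = _all_pentamers()
    data = {"pentamer": pentamers}
    for col in SHAPE_COLUMNS:
        lo, hi = ranges[_column_param_type(col)]
        data[col] = rng.uniform(lo, hi, size=len(pentamers))
    df = pd.DataFrame(data)
    table = ShapeTable.from_frame(df)
    if not honor_forbidden:
        return table
    central = np.array([p[2] for p in sorted(table.index, key=table.index.get)])
    # (column, affected central base, forbidden bin code)
    constraints = [
        ("prop", "C", 0),     # prop0 L forbidden at C sites
        ("ro_pre", "C", 2),   # ro-1 H forbidden at C sites
        ("prop", "T", 2),     # prop0 H forbidden at T sites
        ("tw_post", "T", 0),  # tw+1 L forbidden at T sites
    ]
    margin = 0.02
    for _ in range(50):
        spec = fit_binning(table)
        dirty = False
        for col, base, bad_bin in constraints:
            ptype = _column_param_type(col)
            j = SHAPE_COLUMNS.index(col)
            codes = spec.bin_codes(ptype, table.values[:, j])
            viol = (central == base) & (codes == bad_bin)
            if not viol.any():
                continue
            dirty = True
            lo, hi = spec.ranges[ptype]
            span = hi - lo
            # resample strictly inside the allowed normalized interval
            if bad_bin == 0:
                u = rng.uniform(1 / 3 + margin, 1.0 - margin, size=viol.sum())
            else:
                u = rng.uniform(margin, 2 / 3 - margin, size=viol.sum())
            table.values[viol, j] = lo + u * span
        if not dirty:
            return table
    raise RuntimeError("forbidden-context adjustment did not converge")


def make_signatures(
    n: int,
    seed: int = 0,
    *,
    n_active: tuple[int, int] = (6, 12),
    max_pairwise_cos: float = 0.25,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sparse random 96-channel trinucleotide profiles with low mutual cosine.

    Each profile concentrates exponential weights on a small random subset
    of contexts; draws are rejected until all pairwise cosines fall below
    ``max_pairwise_cos``.  Returns a 96 x n frame (columns sum to 1).
    """
    from .spectra import seq_feature_labels

    rng = np.random.default_rng(seed)
    profiles: list[np.ndarray] = []
    attempts = 0
    while len(profiles) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("cannot draw signatures this dissimilar")
        k_active = rng.integers(n_active[0], n_active[1] + 1)
        support = rng.choice(96, size=k_active, replace=False)
        prof = np.zeros(96)
        prof[support] = rng.exponential(1.0, size=k_active)
        prof /= prof.sum()
        u = prof / np.linalg.norm(prof)
        if all(float(u @ (q / np.linalg.norm(q))) < max_pairwise_cos
               for q in profiles):
            profiles.append(prof)
    if names is None:
        names = [f"GT{i + 1}" for i in range(n)]
    return pd.DataFrame(np.column_stack(profiles),
                        index=seq_feature_labels(), columns=list(names))


def make_exposures(
    n_samples: int, n_signatures: int, seed: int = 0, concentration: float = 1.0
) -> np.ndarray:
    """Per-sample Dirichlet signature mixture weights (rows sum to 1)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n_signatures, concentration), size=n_samples)


def _context_position_index(view: GenomeView, pad: int = 3):
    """Map strand-collapsed trimer -> (chrom, 0-based center) arrays.

    Centers within ``pad`` of a contig end are excluded so that k=7
    windows are always available downstream.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom in view.contigs():
        seq = view.seq(chrom)
        for center in range(pad, len(seq) - pad):
            tri = seq[center - 1 : center + 2]
            if any(b not in BASES for b in tri):
                continue
            if tri[1] in "AG":
                tri = revcomp(tri)
            index.setdefault(tri, []).append((chrom, center))
    return {k: v for k, v in index.items()}


def simulate_catalog(
    genome,
    signatures: pd.DataFrame,
    exposures: np.ndarray,
    n_mut: int,
    seed: int = 0,
    *,
    sample_prefix: str = "S",
) -> list[MutationRecord]:
    """Mutation catalog sampled from a signature mixture over a genome.

    For each of ``n_mut`` mutations per sample, a signature is drawn by
    exposure, a trinucleotide context and alternate allele by the
    signature profile, and a uniformly random genome position carrying
    that strand-collapsed context; ref/alt are emitted on the genomic
    strand.  Raises if a needed context is absent from the genome.
    """
    from .spectra import seq_feature_labels

    view = genome if isinstance(genome, GenomeView) else GenomeView(genome)
    rng = np.random.default_rng(seed)
    labels = seq_feature_labels()
    if list(signatures.index) != labels:
        raise ValueError("signatures must be indexed by the 96 canonical "
                         "trinucleotide context labels")
    S = signatures.to_numpy(dtype=float)
    S = S / S.sum(axis=0)
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape[1] != S.shape[1]:
        raise ValueError("exposures and signatures disagree on signature count")
    index = _context_position_index(view)
    comp = dict(zip("ACGT", "TGCA"))
    records: list[MutationRecord] = []
    for s_idx, expo in enumerate(exposures):
        sample_id = f"{sample_prefix}{s_idx + 1}"
        sig_draws = rng.choice(S.shape[1], size=n_mut, p=expo / expo.sum())
        for g in sig_draws:
            feat = int(rng.choice(96, p=S[:, g]))
            label = labels[feat]  # e.g. "A[C>T]G"
            f5, rest = label.split("[")
            mt, f3 = rest.split("]")
            central, alt = mt[0], mt[2]
            tri = f5 + central + f3
            positions = index.get(tri)
            if not positions:
                raise ValueError(f"context {tri} absent from genome; cannot "
                                 f"place a {label} mutation")
            chrom, center = positions[int(rng.integers(len(positions)))]
            ref = view.seq(chrom)[center]
            if ref in "CT":
                rec_alt = alt
            else:
                rec_alt = comp[alt]
            records.append(MutationRecord(sample_id, chrom, center + 1, ref,
                                          rec_alt))
    return records


def write_catalog_tsv(records: Sequence[MutationRecord], path) -> None:
    """Write a mutation catalog in the package's TSV dialect."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\n")


def write_catalog_vcf(records: Sequence[MutationRecord], path,
                      contig_lengths: Mapping[str, int]) -> None:
    """Write a minimal single-column VCF (sample id in the SAMPLE info tag)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,'
                 'Description="Sample attribution">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
                     f"SAMPLE={r.sample_id}\n")


def simulate_poisson_counts(
    regression_table: pd.DataFrame,
    beta: Mapping[str, float],
    seed: int = 0,
    coding: str = "reference",
) -> np.ndarray:
    """Poisson counts y_kmer ~ Poisson(D * exp(X beta)) over a design table.

    ``beta`` maps design column names (e.g. "pos+1[G]") to coefficients,
    plus "intercept"; unnamed columns default to 0, and a name absent from
    the design raises.
    """
    rng = np.random.default_rng(seed)
    X, _ = design_matrix(regression_table, coding=coding)
    unknown = [k for k in beta if k != "intercept" and k not in X.columns]
    if unknown:
        raise ValueError(f"beta names not in the design: {unknown}")
    eta = np.full(len(X), float(beta.get("intercept", 0.0)))
    for name, value in beta.items():
        if name == "intercept":
            continue
        eta += value * X[name].to_numpy()
    D = regression_table["D"].to_numpy(dtype=float)
    mu = D * np.exp(eta)
    return rng.poisson(mu)
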