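"""Dual-block mutation spectra: 96 trinucleotide + 96 structural contexts.

The sequence block is the standard 96-channel trinucleotide spectrum
(6 pyrimidine-centered mutation types x 16 flank pairs).  The structural
block discretizes six focal shape descriptors of the mutated pentamer
(mgw0, prop0, ro-1, ro+1, tw-1, tw+1) into L/M/H bins per mutation type:
6 x 3 x 6 = 108 raw contexts, of which 12 combinations are energetically
unsampled at the given central base (prop0 L and ro-1 H at C sites,
prop0 H and tw+1 L at T sites) and are removed, leaving 96.  Each mutation
contributes one count per focal descriptor, so the raw structural block of
a sample sums to six times its mutation count; it is then multinomially
resampled to match the sequence-block total so that the two blocks carry
equal counting noise in joint factorizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import BASES, MUTATION_TYPES, OrientedContext, count_opportunities
from .shape import SHAPE_COLUMNS, BinningSpec, ShapeTable, BIN_LABELS

logger = logging.getLogger(__name__)

#: focal structural descriptors used for the spectrum block, in canonical order
FOCAL_DESCRIPTORS = ("mgw0", "prop0", "ro-1", "ro+1", "tw-1", "tw+1")

# (shape-table column, parameter type) backing each focal descriptor
_FOCAL_SOURCE = {
    "mgw0": ("mgw", "mgw"),
    "prop0": ("prop", "prop"),
    "ro-1": ("ro_pre", "ro"),
    "ro+1": ("ro_post", "ro"),
    "tw-1": ("tw_pre", "tw"),
    "tw+1": ("tw_post", "tw"),
}


def seq_feature_labels() -> list[str]:
    """The 96 trinucleotide context labels, e.g. 'A[C>A]A'.

    Ordered by mutation type (C>A .. T>G), then 5' flank, then 3' flank.
    """
    return [
        f"{f5}[{mt}]{f3}"
        for mt in MUTATION_TYPES
        for f5 in BASES
        for f3 in BASES
    ]


def raw_struct_feature_labels() -> list[str]:
    """All 108 (mutation type, descriptor, bin) labels before removal."""
    return [
        f"{mt}:{d}:{b}"
        for mt in MUTATION_TYPES
        for d in FOCAL_DESCRIPTORS
        for b in BIN_LABELS
    ]


def forbidden_contexts() -> list[tuple[str, str, str]]:
    """The 12 unsampled (descriptor, bin, mutation type) combinations."""
    out = []
    for mt in MUTATION_TYPES:
        if mt.startswith("C"):
            out.append(("prop0", "L", mt))
            out.append(("ro-1", "H", mt))
        else:
            out.append(("prop0", "H", mt))
            out.append(("tw+1", "L", mt))
    return out


def struct_feature_labels() -> list[str]:
    """The 96 structural context labels (108 minus the 12 forbidden)."""
    forbidden = {f"{mt}:{d}:{b}" for d, b, mt in forbidden_contexts()}
    return [lab for lab in raw_struct_feature_labels() if lab not in forbidden]


def feature_labels() -> list[str]:
    """All 192 column labels: 96 sequence then 96 structural."""
    return seq_feature_labels() + struct_feature_labels()


_SEQ_INDEX = {lab: i for i, lab in enumerate(seq_feature_labels())}
_RAW_STRUCT_LABELS = raw_struct_feature_labels()
_STRUCT_LABELS = struct_feature_labels()
_KEPT_RAW_IDX = np.array(
    [i for i, lab in enumerate(_RAW_STRUCT_LABELS) if lab in set(_STRUCT_LABELS)]
)
_MT_INDEX = {mt: i for i, mt in enumerate(MUTATION_TYPES)}


def seq_spectrum(contexts: Iterable[OrientedContext]) -> np.ndarray:
    """96-channel trinucleotide spectrum of a context list (k >= 3)."""
    vec = np.zeros(96, dtype=np.int64)
    for ctx in contexts:
        tri = ctx.trimer
        if len(tri) != 3:
            raise ValueError(f"need k >= 3 contexts, got {ctx.kmer!r}")
        vec[_SEQ_INDEX[f"{tri[0]}[{ctx.mutation_type}]{tri[2]}"]] += 1
    return vec


def focal_bin_codes(
    pentamers: Sequence[str], table: ShapeTable, spec: BinningSpec
) -> np.ndarray:
    """(n, 6) integer bin codes (0=L,1=M,2=H) of the six focal descriptors."""
    rows = np.fromiter((table.index[p] for p in pentamers), dtype=np.int64,
                       count=len(pentamers))
    codes = np.empty((len(pentamers), len(FOCAL_DESCRIPTORS)), dtype=np.int8)
    for j, desc in enumerate(FOCAL_DESCRIPTORS):
        col, ptype = _FOCAL_SOURCE[desc]
        vals = table.values[rows, SHAPE_COLUMNS.index(col)]
        codes[:, j] = spec.bin_codes(ptype, vals)
    return codes


def struct_spectrum(
    contexts: Sequence[OrientedContext],
    table: ShapeTable,
    spec: BinningSpec,
) -> tuple[np.ndarray, int]:
    """96-channel structural spectrum of pentamer contexts.

    Each mutation adds one count to each of its six (descriptor, bin,
    mutation type) slots; counts that land on a forbidden slot are dropped.
    Returns (spectrum, n_dropped).
    """
    if any(ctx.k != 5 for ctx in contexts):
        raise ValueError("structural spectrum requires k=5 contexts")
    mt_idx = np.fromiter((_MT_INDEX[c.mutation_type] for c in contexts),
                         dtype=np.int64, count=len(contexts))
    codes = focal_bin_codes([c.kmer for c in contexts], table, spec)
    return struct_spectrum_from_bins(mt_idx, codes)


def struct_spectrum_from_bins(
    mt_idx: np.ndarray, bin_codes: np.ndarray
) -> tuple[np.ndarray, int]:
    """Structural spectrum from precomputed (n,) type indices and (n, 6) bins."""
    n = len(mt_idx)
    raw = np.zeros(108, dtype=np.int64)
    if n:
        # raw slot = mt*18 + descriptor*3 + bin
        desc_offsets = np.arange(6) * 3
        slots = (mt_idx[:, None] * 18 + desc_offsets[None, :] + bin_codes).ravel()
        raw += np.bincount(slots, minlength=108)
    kept = raw[_KEPT_RAW_IDX]
    dropped = int(raw.sum() - kept.sum())
    if dropped:
        logger.info("dropped %d structural counts on forbidden contexts", dropped)
    return kept, dropped


@dataclass
class SampleSpectrum:
    """Per-sample dual-block counts; ``struct_counts`` is total-matched."""

    sample_id: str
    seq_counts: np.ndarray
    struct_counts: np.ndarray
    raw_struct_counts: np.ndarray
    dropped_forbidden: int = 0

    def combined(self) -> np.ndarray:
        return np.concatenate([self.seq_counts, self.struct_counts])


def match_block_totals(
    spectrum: SampleSpectrum,
    seed: int | np.random.Generator,
    *,
    bootstrap_both: bool = False,
) -> SampleSpectrum:
    """Resample the structural block to the sequence-block total.

    The structural counts are drawn from a multinomial with n equal to the
    sequence-block sum and probabilities proportional to the raw structural
    counts, equalizing counting noise between the blocks.  With
    ``bootstrap_both`` the sequence block is also multinomially resampled
    at its own total.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_seq = int(spectrum.seq_counts.sum())
    raw = spectrum.raw_struct_counts
    total_raw = raw.sum()
    if total_raw <= 0:
        if n_seq > 0:
            raise ValueError(
                f"sample {spectrum.sample_id}: zero structural counts with "
                f"{n_seq} sequence counts; cannot match totals"
            )
        struct = np.zeros_like(raw)
    else:
        struct = rng.multinomial(n_seq, raw / total_raw)
    seq = spectrum.seq_counts
    if bootstrap_both and n_seq > 0:
        seq = rng.multinomial(n_seq, seq / n_seq)
    return SampleSpectrum(
        sample_id=spectrum.sample_id,
        seq_counts=seq,
        struct_counts=struct,
        raw_struct_counts=raw.copy(),
        dropped_forbidden=spectrum.dropped_forbidden,
    )


def build_sample_spectra(
    genome,
    records,
    table: ShapeTable,
    spec: BinningSpec,
    seed: int,
    *,
    match_totals: bool = True,
    skip_mismatch: bool = False,
) -> list[SampleSpectrum]:
    """Per-sample dual-block spectra from a mutation catalog.

    Contexts are extracted once at k=5 (the trinucleotide is its middle
    trimer), so a mutation enters both blocks or neither.  Samples are
    processed in sorted id order; matching seeds derive from ``seed``.
    """
    from .contexts import GenomeView, extract_contexts

    view = genome if isinstance(genome, GenomeView) else GenomeView(genome)
    by_sample: dict[str, list] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    rng = np.random.default_rng(seed)
    out = []
    for sample_id in sorted(by_sample):
        contexts, _ = extract_contexts(view, by_sample[sample_id], 5,
                                       skip_mismatch=skip_mismatch)
        seq = seq_spectrum(contexts)
        struct_raw, dropped = struct_spectrum(contexts, table, spec)
        spectrum = SampleSpectrum(sample_id, seq, struct_raw.copy(), struct_raw,
                                  dropped)
        if match_totals:
            spectrum = match_block_totals(spectrum, rng)
        out.append(spectrum)
    return out


def spectra_to_frame(spectra: Sequence[SampleSpectrum]) -> pd.DataFrame:
    """Samples x 192 count matrix with canonical column labels."""
    data = np.stack([s.combined() for s in spectra])
    return pd.DataFrame(data, index=[s.sample_id for s in spectra],
                        columns=feature_labels())


def write_spectra(spectra_or_frame, path: str | Path) -> None:
    df = (spectra_or_frame if isinstance(spectra_or_frame, pd.DataFrame)
          else spectra_to_frame(spectra_or_frame))
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_spectra(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    expected = feature_labels()
    if list(df.columns) != expected:
        raise ValueError(f"spectrum matrix {path} does not carry the canonical "
                         "192 feature labels in order")
    return df


@dataclass
class OpportunitySpectra:
    """Genome-wide nucleotides-at-risk, stratified like the two blocks.

    ``struct_forbidden`` tallies pentamer opportunity mass falling on
    forbidden slots (counted but excluded from the 96-channel block).
    """

    seq_counts: np.ndarray  # 96
    struct_counts: np.ndarray  # 96
    struct_forbidden: dict[str, int]

    def seq_normalized(self) -> np.ndarray:
        return self.seq_counts / self.seq_counts.sum()

    def struct_normalized(self) -> np.ndarray:
        return self.struct_counts / self.struct_counts.sum()


def feature_opportunities(
    genome, table: ShapeTable, spec: BinningSpec
) -> OpportunitySpectra:
    """Nucleotides-at-risk per trinucleotide and per structural context.

    The sequence part expands the strand-collapsed trimer occurrence table
    over the three mutation types of each central base; the structural part
    bins every genome pentamer and accumulates its occurrence into the six
    focal (descriptor, bin) slots of each applicable mutation type.
    """
    tri = count_opportunities(genome, 3)
    seq = np.zeros(96, dtype=np.int64)
    for kmer, n in tri.counts.items():
        central = kmer[1]
        for mt in MUTATION_TYPES:
            if mt[0] == central:
                seq[_SEQ_INDEX[f"{kmer[0]}[{mt}]{kmer[2]}"]] += n
    pent = count_opportunities(genome, 5)
    pentamers = list(pent.counts)
    weights = np.fromiter((pent.counts[p] for p in pentamers), dtype=np.int64)
    codes = focal_bin_codes(pentamers, table, spec)
    raw = np.zeros(108, dtype=np.int64)
    desc_offsets = np.arange(6) * 3
    for mt, mt_i in _MT_INDEX.items():
        mask = np.array([p[2] == mt[0] for p in pentamers])
        if not mask.any():
            continue
        slots = (mt_i * 18 + desc_offsets[None, :] + codes[mask]).ravel()
        raw += np.bincount(slots, weights=np.repeat(weights[mask], 6),
                           minlength=108).astype(np.int64)
    kept = raw[_KEPT_RAW_IDX]
    forbidden_mask = np.ones(108, dtype=bool)
    forbidden_mask[_KEPT_RAW_IDX] = False
    forbidden = {
        _RAW_STRUCT_LABELS[i]: int(raw[i])
        for i in np.flatnonzero(forbidden_mask)
    }
    return OpportunitySpectra(seq_counts=seq, struct_counts=kept,
                              struct_forbidden=forbidden)
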