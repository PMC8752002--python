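"""Genome and mutation-catalog I/O, strand-collapsed k-mer contexts.

Somatic single-nucleotide variants are read from VCF or a simple TSV
dialect, oriented so that the mutated base is a pyrimidine (C or T; the
purine-strand record is reverse-complemented), and annotated with their
k-mer neighborhood (k in {3, 5, 7}).  Genome-wide k-mer occurrence counts
under the same strand collapse provide the mutational-opportunity
denominator D used downstream as a regression offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
MUTATION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMP)[::-1]


class RefMismatchError(ValueError):
    """Genome base at a mutation position disagrees with the record's ref."""


class FormatError(ValueError):
    """Unparseable mutation file."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV attributed to a sample; ``pos`` is 1-based."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(
                f"non-ACGT allele {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class OrientedContext:
    """Pyrimidine-oriented k-mer neighborhood of one mutation.

    ``kmer`` is the genomic window, reverse-complemented when the mutated
    base was a purine (``rc_applied``), so the central base is C or T and
    ``mutation_type`` is one of the six canonical substitution classes.
    """

    kmer: str
    central: str
    mutation_type: str
    rc_applied: bool

    @property
    def k(self) -> int:
        return len(self.kmer)

    @property
    def trimer(self) -> str:
        mid = (len(self.kmer) - 1) // 2
        return self.kmer[mid - 1 : mid + 2]


@dataclass
class OpportunityTable:
    """Genome occurrence of each strand-collapsed k-mer (offset symbol D)."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tcount\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OpportunityTable":
        df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "count": int})
        if df.empty:
            raise FormatError(f"empty opportunity table: {path}")
        k = len(df["kmer"].iloc[0])
        return cls(k=k, counts=dict(zip(df["kmer"], df["count"])))


# ---------------------------------------------------------------------------
# mutation catalogs


def _read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    names = ["sample", "chrom", "pos", "ref", "alt"]
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, names=names, dtype=str,
                         comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse mutation TSV {path}: {exc}") from exc
    if df.empty:
        return []
    # optional header row: detect a non-numeric pos in the first line
    first = str(df["pos"].iloc[0])
    if not first.lstrip("-").isdigit():
        df = df.iloc[1:]
    if df.empty:
        return []
    records = []
    skipped = 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skipped += 1
            continue
        try:
            pos = int(row.pos)
        except ValueError as exc:
            raise FormatError(f"non-integer position {row.pos!r} in {path}") from exc
        records.append(MutationRecord(str(row.sample), str(row.chrom), pos, ref, alt))
    if skipped:
        logger.info("skipped %d non-SNV rows in %s", skipped, path)
    return records


def _read_mutations_vcf(path: str | Path) -> list[MutationRecord]:
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    vcf_samples = list(vcf.header.samples)
    default_sample = vcf_samples[0] if len(vcf_samples) == 1 else Path(path).stem
    records: list[MutationRecord] = []
    skipped = 0
    for rec in vcf:
        ref = (rec.ref or "").upper()
        for alt in rec.alts or ():
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skipped += 1  # indel / symbolic / non-SNV allele
                continue
            if len(vcf_samples) > 1:
                carriers = [
                    s for s in vcf_samples
                    if any(a not in (0, None) for a in (rec.samples[s].get("GT") or ()))
                ]
                if not carriers:
                    raise FormatError(
                        f"multi-sample VCF record {rec.chrom}:{rec.pos} "
                        f"{ref}>{alt} has no genotyped carrier sample"
                    )
            else:
                carriers = [default_sample]
            for sample in carriers:
                records.append(
                    MutationRecord(sample, rec.chrom, int(rec.pos), ref, alt)
                )
    if skipped:
        logger.info("skipped %d non-SNV VCF alleles in %s", skipped, path)
    return records


def read_mutations(path: str | Path, format: str | None = None) -> list[MutationRecord]:
    """Read a somatic SNV catalog from VCF or whitespace-delimited TSV.

    The TSV dialect has columns sample, chrom, pos (1-based), ref, alt and
    an optional header.  Multi-allelic VCF records are expanded to one
    record per alternate allele; indels and other non-SNV alleles are
    skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf", ".gz"} else "tsv"
    if format == "vcf":
        return _read_mutations_vcf(path)
    if format == "tsv":
        return _read_mutations_tsv(path)
    raise ValueError(f"unknown mutation format {format!r}")


# ---------------------------------------------------------------------------
# genome access


def _contig(genome, chrom: str) -> str:
    """Fetch a whole contig as an uppercase string from dict-like genomes."""
    seq = genome[chrom]
    if not isinstance(seq, str):
        seq = str(seq)  # pyfaidx FastaRecord
    return seq.upper()


class GenomeView:
    """Uppercase in-memory view over a genome (dict of strings or pyfaidx.Fasta).

    Contigs are cached as plain strings; per-mutation window extraction is a
    slice, which keeps large catalogs cheap.
    """

    def __init__(self, genome):
        if isinstance(genome, (str, Path)):
            import pyfaidx

            genome = pyfaidx.Fasta(str(genome))
        self._source = genome
        self._cache: dict[str, str] = {}

    def contigs(self) -> list[str]:
        keys = getattr(self._source, "keys", None)
        return list(keys()) if callable(keys) else list(self._source)

    def seq(self, chrom: str) -> str:
        if chrom not in self._cache:
            self._cache[chrom] = _contig(self._source, chrom)
        return self._cache[chrom]


def _orient(window: str, ref: str, alt: str) -> OrientedContext:
    if ref in PYRIMIDINES:
        return OrientedContext(window, ref, f"{ref}>{alt}", rc_applied=False)
    rc = revcomp(window)
    cref = ref.translate(_COMP)
    calt = alt.translate(_COMP)
    return OrientedContext(rc, cref, f"{cref}>{calt}", rc_applied=True)


def extract_context(
    genome, record: MutationRecord, k: int, *, skip_mismatch: bool = False
) -> OrientedContext | None:
    """Pyrimidine-oriented k-mer around one mutation, or None if unusable.

    Returns None (logged) when the window runs off the contig or contains a
    non-ACGT base.  A disagreement between the genome base and ``record.ref``
    raises :class:`RefMismatchError` unless ``skip_mismatch``.
    """
    if k not in (3, 5, 7):
        raise ValueError(f"k must be 3, 5 or 7, got {k}")
    view = genome if isinstance(genome, GenomeView) else GenomeView(genome)
    seq = view.seq(record.chrom)
    half = (k - 1) // 2
    center = record.pos - 1  # to 0-based
    if center < 0 or center >= len(seq):
        raise ValueError(f"position {record.chrom}:{record.pos} outside contig")
    genome_base = seq[center]
    if genome_base != record.ref:
        msg = (f"ref mismatch at {record.chrom}:{record.pos}: "
               f"genome {genome_base}, record {record.ref}")
        if skip_mismatch:
            logger.warning(msg)
            return None
        raise RefMismatchError(msg)
    lo, hi = center - half, center + half + 1
    if lo < 0 or hi > len(seq):
        logger.info("skipping %s:%d: %d-mer window off contig end",
                    record.chrom, record.pos, k)
        return None
    window = seq[lo:hi]
    if any(b not in BASES for b in window):
        logger.info("skipping %s:%d: non-ACGT base in window %s",
                    record.chrom, record.pos, window)
        return None
    return _orient(window, record.ref, record.alt)


def extract_contexts(
    genome,
    records: Iterable[MutationRecord],
    k: int,
    *,
    skip_mismatch: bool = False,
) -> tuple[list[OrientedContext], dict[str, int]]:
    """Vector version of :func:`extract_context`; returns (contexts, skip tally)."""
    view = genome if isinstance(genome, GenomeView) else GenomeView(genome)
    out: list[OrientedContext] = []
    skipped = {"window": 0, "mismatch": 0}
    for rec in records:
        try:
            ctx = extract_context(view, rec, k, skip_mismatch=skip_mismatch)
        except RefMismatchError:
            raise
        if ctx is None:
            key = "mismatch" if view.seq(rec.chrom)[rec.pos - 1] != rec.ref else "window"
            skipped[key] += 1
        else:
            out.append(ctx)
    return out, skipped


# ---------------------------------------------------------------------------
# opportunity counting


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_from_code(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def count_opportunities(genome, k: int) -> OpportunityTable:
    """Count every N-free k-mer window genome-wide under strand collapse.

    Windows whose central base is a purine are reverse-complemented before
    counting, so every key has a C or T center.
    """
    if k % 2 != 1 or k < 1:
        raise ValueError(f"k must be odd positive, got {k}")
    view = genome if isinstance(genome, GenomeView) else GenomeView(genome)
    half = k // 2
    totals = np.zeros(4 ** k, dtype=np.int64)
    for chrom in view.contigs():
        codes = _codes(view.seq(chrom))
        if len(codes) < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (win < 4).all(axis=1)
        win = win[valid].astype(np.int64)
        if win.size == 0:
            continue
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        fwd = win @ powers
        rc = (3 - win[:, ::-1]) @ powers
        purine = (win[:, half] == 0) | (win[:, half] == 2)  # A or G center
        collapsed = np.where(purine, rc, fwd)
        totals += np.bincount(collapsed, minlength=4 ** k)
    counts = {
        _kmer_from_code(code, k): int(n)
        for code, n in enumerate(totals)
        if n > 0
    }
    return OpportunityTable(k=k, counts=counts)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write contigs to a FASTA file with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
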