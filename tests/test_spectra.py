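"""Dual-block spectrum construction, forbidden contexts and total matching."""

import numpy as np
import pytest

from shapesig import (
    MutationRecord,
    SampleSpectrum,
    build_sample_spectra,
    extract_contexts,
    feature_labels,
    feature_opportunities,
    forbidden_contexts,
    match_block_totals,
    read_spectra,
    revcomp,
    seq_feature_labels,
    seq_spectrum,
    spectra_to_frame,
    struct_feature_labels,
    struct_spectrum,
    write_spectra,
)
from shapesig.contexts import OrientedContext
from shapesig.spectra import raw_struct_feature_labels


def test_feature_space_sizes():
    assert len(seq_feature_labels()) == 96
    assert len(raw_struct_feature_labels()) == 108
    assert len(forbidden_contexts()) == 12
    assert len(struct_feature_labels()) == 96
    assert len(feature_labels()) == 192


def test_forbidden_rule_content():
    forb = forbidden_contexts()
    assert ("prop0", "L", "C>T") in forb
    assert ("prop0", "L", "T>A") not in forb
    assert ("ro-1", "H", "C>A") in forb
    assert ("prop0", "H", "T>C") in forb
    assert ("tw+1", "L", "T>G") in forb
    # exclusion applies to all three mutation types of the central base
    assert sum(1 for d, b, mt in forb if (d, b) == ("prop0", "L")) == 3


def test_seq_spectrum_placement_and_linearity():
    ctx = OrientedContext("ACG", "C", "C>T", False)
    vec = seq_spectrum([ctx])
    assert vec.sum() == 1
    assert vec[seq_feature_labels().index("A[C>T]G")] == 1
    assert seq_spectrum([]).sum() == 0
    assert (seq_spectrum([ctx, ctx]) == 2 * vec).all()


def test_seq_spectrum_accepts_wider_kmers():
    ctx = OrientedContext("TACGT", "C", "C>A", False)
    vec = seq_spectrum([ctx])
    assert vec[seq_feature_labels().index("A[C>A]G")] == 1


def test_struct_spectrum_six_counts_per_mutation(shape_table, binning,
                                                 genome, small_catalog):
    _, _, records = small_catalog
    ctxs, _ = extract_contexts(genome, records, 5)
    vec, dropped = struct_spectrum(ctxs, shape_table, binning)
    # the fixture table honors the forbidden combinations by construction
    assert dropped == 0
    assert vec.sum() == 6 * len(ctxs)


def test_struct_spectrum_drops_forbidden(free_shape_table, genome,
                                         small_catalog):
    from shapesig import fit_binning

    _, _, records = small_catalog
    spec = fit_binning(free_shape_table)
    ctxs, _ = extract_contexts(genome, records, 5)
    vec, dropped = struct_spectrum(ctxs, free_shape_table, spec)
    assert dropped > 0  # unconstrained table hits forbidden slots
    assert vec.sum() + dropped == 6 * len(ctxs)


def test_match_block_totals_constraint_and_determinism(rng):
    raw = rng.integers(0, 50, size=96)
    raw[0] += 1  # ensure nonzero
    spectrum = SampleSpectrum("S1", seq_counts=np.full(96, 2),
                              struct_counts=raw.copy(),
                              raw_struct_counts=raw)
    out1 = match_block_totals(spectrum, seed=7)
    out2 = match_block_totals(spectrum, seed=7)
    assert out1.struct_counts.sum() == out1.seq_counts.sum() == 192
    assert (out1.struct_counts == out2.struct_counts).all()
    assert (out1.raw_struct_counts == raw).all()


def test_match_block_totals_zero_struct_errors():
    spectrum = SampleSpectrum("S1", seq_counts=np.ones(96, dtype=int),
                              struct_counts=np.zeros(96, dtype=int),
                              raw_struct_counts=np.zeros(96, dtype=int))
    with pytest.raises(ValueError, match="zero structural"):
        match_block_totals(spectrum, seed=0)


def test_match_block_totals_multinomial_expectation(rng):
    """Mean resampled count per slot matches n * p within 3 standard errors."""
    raw = np.zeros(96, dtype=int)
    raw[:4] = [600, 200, 150, 50]
    spectrum = SampleSpectrum("S1", seq_counts=np.full(96, 0),
                              struct_counts=raw.copy(),
                              raw_struct_counts=raw)
    spectrum.seq_counts[0] = 100
    n_rep = 1000
    sums = np.zeros(96)
    for i in range(n_rep):
        sums += match_block_totals(spectrum, seed=1000 + i).struct_counts
    mean = sums / n_rep
    p = raw / raw.sum()
    se = np.sqrt(100 * p * (1 - p) / n_rep)
    ok = np.abs(mean - 100 * p) <= 3 * np.maximum(se, 1e-9)
    assert ok[:4].all() and (mean[4:] == 0).all()


def test_build_sample_spectra_strand_symmetry(genome, shape_table, binning,
                                              small_catalog):
    """Spectra from a catalog and its reverse-complemented mirror agree."""
    _, _, records = small_catalog
    seq = genome["chr1"]
    comp = dict(zip("ACGT", "TGCA"))
    mirror_genome = {"chr1": revcomp(seq)}
    mirrored = [
        MutationRecord(r.sample_id, r.chrom, len(seq) - r.pos + 1,
                       comp[r.ref], comp[r.alt])
        for r in records
    ]
    fwd = build_sample_spectra(genome, records, shape_table, binning, seed=3)
    rev = build_sample_spectra(mirror_genome, mirrored, shape_table, binning,
                               seed=3)
    for a, b in zip(fwd, rev):
        assert a.sample_id == b.sample_id
        assert (a.seq_counts == b.seq_counts).all()
        assert (a.raw_struct_counts == b.raw_struct_counts).all()
        assert (a.struct_counts == b.struct_counts).all()  # same seed stream


def test_spectra_matrix_tsv_roundtrip(genome, shape_table, binning,
                                      small_catalog, tmp_path):
    _, _, records = small_catalog
    spectra = build_sample_spectra(genome, records, shape_table, binning,
                                   seed=4)
    df = spectra_to_frame(spectra)
    assert list(df.columns) == feature_labels()
    assert (df.iloc[:, :96].sum(axis=1) == df.iloc[:, 96:].sum(axis=1)).all()
    path = tmp_path / "spectra.tsv"
    write_spectra(df, path)
    back = read_spectra(path)
    assert (back == df).all().all() and list(back.index) == list(df.index)


def test_feature_opportunities_degenerate_genome(shape_table, binning):
    opp = feature_opportunities({"c": "AAAAAAAA"}, shape_table, binning)
    labels = seq_feature_labels()
    nonzero = {labels[i] for i in np.flatnonzero(opp.seq_counts)}
    assert nonzero == {"T[T>A]T", "T[T>C]T", "T[T>G]T"}
    assert opp.seq_normalized().sum() == pytest.approx(1.0)
    assert opp.struct_normalized().sum() == pytest.approx(1.0)


def test_feature_opportunities_forbidden_flagged(genome, free_shape_table):
    from shapesig import fit_binning

    spec = fit_binning(free_shape_table)
    opp = feature_opportunities(genome, free_shape_table, spec)
    assert len(opp.struct_forbidden) == 12
    assert sum(opp.struct_forbidden.values()) > 0
    # honoring table puts zero mass on forbidden slots
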