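"""Shape-table lookup, heptamer profiling and L/M/H discretization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shapesig import (
    BinningSpec,
    ShapeTable,
    bin_profile,
    fit_binning,
    load_shape_table,
    profile_kmer,
    write_shape_table,
)
from shapesig.shape import (
    HEPTAMER_DESCRIPTORS,
    PENTAMER_DESCRIPTORS,
    SHAPE_COLUMNS,
    ShapeTableError,
    descriptor_param_type,
)

KMER5 = st.text(alphabet="ACGT", min_size=5, max_size=5)
KMER7 = st.text(alphabet="ACGT", min_size=7, max_size=7)


def test_table_lookup_identity(shape_table):
    df = shape_table.to_frame()
    row = df[df["pentamer"] == "AACGT"].iloc[0]
    assert np.allclose(shape_table.row("AACGT"),
                       row[list(SHAPE_COLUMNS)].to_numpy(dtype=float))


def test_table_completeness_checks(shape_table):
    df = shape_table.to_frame()
    with pytest.raises(ShapeTableError, match="missing"):
        ShapeTable.from_frame(df.iloc[1:])  # 1023 rows
    dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    with pytest.raises(ShapeTableError, match="duplicated"):
        ShapeTable.from_frame(dup)


def test_table_tsv_roundtrip_and_nonnumeric(shape_table, tmp_path):
    path = tmp_path / "table.tsv"
    write_shape_table(shape_table, path)
    back = load_shape_table(path)
    assert back.index == shape_table.index
    assert np.allclose(back.values, shape_table.values, atol=1e-6)
    bad = path.read_text().replace("\t", "\t", 1).splitlines()
    bad[1] = bad[1].rsplit("\t", 1)[0] + "\tnot_a_number"
    bad_path = tmp_path / "bad.tsv"
    bad_path.write_text("\n".join(bad) + "\n")
    with pytest.raises(ShapeTableError, match="non-numeric"):
        load_shape_table(bad_path)


@settings(max_examples=25, derandomize=True)
@given(kmer=KMER5)
def test_pentamer_profile_has_19_descriptors(kmer, shape_table):
    profile = profile_kmer(kmer, shape_table)
    assert len(profile) == 19
    assert list(profile.descriptors) == list(PENTAMER_DESCRIPTORS)


@settings(max_examples=25, derandomize=True)
@given(kmer=KMER7)
def test_heptamer_profile_has_45_descriptors(kmer, shape_table):
    profile = profile_kmer(kmer, shape_table)
    assert len(profile) == 45
    assert list(profile.descriptors) == list(HEPTAMER_DESCRIPTORS)


def test_step_averaging_rule(shape_table):
    """Interior heptamer steps are the mean of the two covering pentamers."""
    kmer = "ACGTACG"
    w = {p: shape_table.row(kmer[i : i + 5]) for i, p in enumerate((-1, 0, 1))}
    col = SHAPE_COLUMNS.index
    profile = profile_kmer(kmer, shape_table).descriptors
    assert profile["tw+1"] == pytest.approx(
        0.5 * (w[0][col("tw_post")] + w[1][col("tw_pre")])
    )
    assert profile["tw-1"] == pytest.approx(
        0.5 * (w[-1][col("tw_post")] + w[0][col("tw_pre")])
    )
    # exterior steps come from their single covering window
    assert profile["ro-2"] == w[-1][col("ro_pre")]
    assert profile["ro+2"] == w[1][col("ro_post")]


@settings(max_examples=20, derandomize=True)
@given(kmer=KMER7)
def test_heptamer_center_consistent_with_pentamer(kmer, shape_table):
    """Central-position descriptors of a 7-mer equal the middle 5-mer's,
    and the two averaged steps lie between their contributing values."""
    p7 = profile_kmer(kmer, shape_table).descriptors
    p5 = profile_kmer(kmer[1:6], shape_table).descriptors
    for name, value in p5.items():
        if name.endswith(("-1", "+1")) and descriptor_param_type(name) in (
            "tw", "ro", "ti", "sl", "ri", "sh"
        ):
            side = "pre" if name.endswith("-1") else "post"
            col = SHAPE_COLUMNS.index
            own = shape_table.row(kmer[1:6])[
                col(f"{descriptor_param_type(name)}_{side}")
            ]
            neighbor = shape_table.row(kmer[:5] if side == "pre" else kmer[2:7])
            other = neighbor[
                col(f"{descriptor_param_type(name)}"
                    f"_{'post' if side == 'pre' else 'pre'}")
            ]
            lo, hi = min(own, other), max(own, other)
            assert lo - 1e-12 <= p7[name] <= hi + 1e-12
        else:
            assert p7[name] == pytest.approx(value)


def test_binning_edges():
    spec = BinningSpec(ranges={"tw": (20.0, 40.0)})
    assert spec.bin_value("tw", 30.0) == "M"
    assert spec.bin_value("tw", 20.0) == "L"
    assert spec.bin_value("tw", 40.0) == "H"  # closed top bin
    assert spec.bin_value("tw", 20.0 + 20.0 / 3) == "M"  # v'=1/3 half-open
    # out-of-range values clamp to the nearest bin
    assert spec.bin_value("tw", 10.0) == "L"
    assert spec.bin_value("tw", 50.0) == "H"


def test_fit_binning_pools_step_columns(shape_table):
    spec = fit_binning(shape_table)
    pooled = np.concatenate([shape_table.column("tw_pre"),
                             shape_table.column("tw_post")])
    assert spec.ranges["tw"] == (pooled.min(), pooled.max())


def test_fit_binning_rejects_constant_parameter(shape_table):
    df = shape_table.to_frame()
    df["mgw"] = 5.0
    with pytest.raises(ShapeTableError, match="constant"):
        fit_binning(ShapeTable.from_frame(df))


def test_bin_profile_cardinality_and_idempotence(shape_table, binning):
    profile = profile_kmer("ACGTA", shape_table)
    bins = bin_profile(profile, binning)
    assert len(bins) == 19
    assert set(bins.values()) <= {"L", "M", "H"}
    assert bin_profile(profile, binning) == bins


def test_binning_spec_json_roundtrip(binning, tmp_path):
    path = tmp_path / "spec.json"
    binning.to_json(path)
    back = BinningSpec.from_json(path)
    assert back.ranges == binning.ranges and back.mode == binning.mode
    vals = np.linspace(*binning.ranges["mgw"], 37)
    assert (back.bin_codes("mgw", vals) == binning.bin_codes("mgw", vals)).all()


def test_tertile_binning_balances_mass(shape_table):
    spec = fit_binning(shape_table, mode="tertile")
    codes = spec.bin_codes("mgw", shape_table.column("mgw"))
    counts = np.bincount(codes, minlength=3)
    assert counts.min() > 0.25 * len(codes)  # roughly equal thirds
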