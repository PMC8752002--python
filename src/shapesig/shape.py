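"""Pentamer-resolved DNA shape descriptors and L/M/H discretization.

The local conformation of double-stranded B-DNA is well approximated by a
function of the pentamer sequence centered on a base pair.  A shape table
maps each of the 4^5 = 1024 pentamers to 19 descriptors: minor groove
width at the center (mgw0), six intra-base-pair parameters (propeller,
opening, buckle in degrees; stretch, stagger, shear in angstroms), and six
inter-base-pair step parameters (twist, roll, tilt in degrees; slide,
rise, shift in angstroms) for the step preceding and the step following
the center (12 step values).  A 7-mer is profiled by sliding the pentamer
window over its three central positions, giving 45 descriptors
(3 mgw + 18 bp + 24 step); the two interior steps covered by two windows
take the mean of the two covering values.

Each parameter type is min-max normalized over the table and discretized
into three equal-width bins, low / medium / high.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BP_PARAMS = ("prop", "open", "buck", "stre", "stag", "shea")
STEP_PARAMS = ("tw", "ro", "ti", "sl", "ri", "sh")
PARAM_TYPES = ("mgw",) + BP_PARAMS + STEP_PARAMS

#: TSV columns of a shape table, after the pentamer key column.
SHAPE_COLUMNS = (
    ("mgw",)
    + BP_PARAMS
    + tuple(f"{p}_{side}" for p in STEP_PARAMS for side in ("pre", "post"))
)

BIN_LABELS = ("L", "M", "H")

#: descriptor order for a pentamer profile (19 values)
PENTAMER_DESCRIPTORS = (
    ("mgw0",)
    + tuple(f"{p}0" for p in BP_PARAMS)
    + tuple(f"{p}{s}" for p in STEP_PARAMS for s in ("-1", "+1"))
)

#: descriptor order for a heptamer profile (45 values)
HEPTAMER_DESCRIPTORS = (
    ("mgw-1", "mgw0", "mgw+1")
    + tuple(f"{p}{s}" for p in BP_PARAMS for s in ("-1", "0", "+1"))
    + tuple(f"{p}{s}" for p in STEP_PARAMS for s in ("-2", "-1", "+1", "+2"))
)


def descriptor_param_type(name: str) -> str:
    """Parameter type of a descriptor name, e.g. 'tw+1' -> 'tw'."""
    stem = name.rstrip("+-0123456789")
    if stem not in PARAM_TYPES:
        raise KeyError(f"unknown descriptor {name!r}")
    return stem


def _all_pentamers() -> list[str]:
    from itertools import product

    return ["".join(p) for p in product("ACGT", repeat=5)]


class ShapeTableError(ValueError):
    """Malformed pentamer shape table."""


@dataclass
class ShapeTable:
    """Complete pentamer -> 19-descriptor lookup, vectorized for batch use."""

    values: np.ndarray  # (1024, 19) in SHAPE_COLUMNS order
    index: dict[str, int]  # pentamer -> row

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ShapeTable":
        if "pentamer" not in df.columns:
            raise ShapeTableError("shape table needs a 'pentamer' column")
        missing_cols = [c for c in SHAPE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ShapeTableError(f"missing value columns: {missing_cols}")
        pentamers = df["pentamer"].astype(str).str.upper()
        dup = pentamers[pentamers.duplicated()].tolist()
        if dup:
            raise ShapeTableError(f"duplicated pentamers: {sorted(set(dup))[:10]}")
        present = set(pentamers)
        absent = [p for p in _all_pentamers() if p not in present]
        if absent:
            raise ShapeTableError(
                f"incomplete table: {len(absent)} pentamers missing, "
                f"e.g. {absent[:10]}"
            )
        vals = df[list(SHAPE_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = df.loc[~np.isfinite(vals).all(axis=1), "pentamer"].tolist()
            raise ShapeTableError(f"non-finite values for pentamers {bad[:10]}")
        order = np.argsort(pentamers.to_numpy())
        vals = vals[order]
        idx = {p: i for i, p in enumerate(pentamers.to_numpy()[order])}
        return cls(values=vals, index=idx)

    def to_frame(self) -> pd.DataFrame:
        pent = sorted(self.index, key=self.index.get)
        df = pd.DataFrame(self.values, columns=list(SHAPE_COLUMNS))
        df.insert(0, "pentamer", pent)
        return df

    def row(self, pentamer: str) -> np.ndarray:
        try:
            return self.values[self.index[pentamer]]
        except KeyError:
            raise KeyError(f"not a pentamer over ACGT: {pentamer!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, SHAPE_COLUMNS.index(name)]


def load_shape_table(path: str | Path) -> ShapeTable:
    """Load a pentamer shape table from TSV (columns per SHAPE_COLUMNS)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ShapeTableError(f"cannot parse shape table {path}: {exc}") from exc
    for col in SHAPE_COLUMNS:
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ShapeTableError(
                f"non-numeric value in column {col}, row(s) {bad.index[:5].tolist()}"
            )
    return ShapeTable.from_frame(df)


def write_shape_table(table: ShapeTable | pd.DataFrame, path: str | Path) -> None:
    df = table.to_frame() if isinstance(table, ShapeTable) else table
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass(frozen=True)
class ShapeProfile:
    """Ordered descriptor vector of one oriented k-mer (19 or 45 values)."""

    k: int
    descriptors: dict[str, float]

    def __len__(self) -> int:
        return len(self.descriptors)

    def values(self) -> np.ndarray:
        return np.fromiter(self.descriptors.values(), dtype=float)


# index plumbing for the 5-mer profile: descriptor -> SHAPE_COLUMNS position
_PENT_SRC = [
    SHAPE_COLUMNS.index("mgw"),
    *[SHAPE_COLUMNS.index(p) for p in BP_PARAMS],
    *[SHAPE_COLUMNS.index(f"{p}_{side}")
      for p in STEP_PARAMS for side in ("pre", "post")],
]


def _pentamer_profile_values(table: ShapeTable, pentamer: str) -> np.ndarray:
    return table.row(pentamer)[_PENT_SRC]


def profile_kmer(kmer: str, table: ShapeTable) -> ShapeProfile:
    """Shape profile of an oriented 5-mer (19 descriptors) or 7-mer (45).

    For a 7-mer, each of the three central positions is profiled from the
    pentamer window centered on it; the two steps covered by two windows
    ((-1,0) and (0,+1)) take the arithmetic mean of the two window values.
    """
    kmer = kmer.upper()
    if any(b not in "ACGT" for b in kmer):
        raise ValueError(f"k-mer must be over ACGT: {kmer!r}")
    if len(kmer) == 5:
        vals = _pentamer_profile_values(table, kmer)
        return ShapeProfile(5, dict(zip(PENTAMER_DESCRIPTORS, vals)))
    if len(kmer) != 7:
        raise ValueError(f"k must be 5 or 7, got {len(kmer)}")
    w = {p: table.row(kmer[i : i + 5]) for i, p in enumerate((-1, 0, +1))}
    col = SHAPE_COLUMNS.index
    out: dict[str, float] = {}
    for pos in (-1, 0, +1):
        out[f"mgw{pos:+d}".replace("+0", "0")] = w[pos][col("mgw")]
    for p in BP_PARAMS:
        for pos in (-1, 0, +1):
            out[f"{p}{pos:+d}".replace("+0", "0")] = w[pos][col(p)]
    for p in STEP_PARAMS:
        pre, post = col(f"{p}_pre"), col(f"{p}_post")
        out[f"{p}-2"] = w[-1][pre]
        out[f"{p}-1"] = 0.5 * (w[-1][post] + w[0][pre])
        out[f"{p}+1"] = 0.5 * (w[0][post] + w[+1][pre])
        out[f"{p}+2"] = w[+1][post]
    ordered = {name: out[name] for name in HEPTAMER_DESCRIPTORS}
    return ShapeProfile(7, ordered)


@dataclass
class BinningSpec:
    """Per-parameter-type min/max and the equal-width L/M/H bin rule.

    Normalized value v' = (v - min) / (max - min); bins are
    L = [0, 1/3), M = [1/3, 2/3), H = [2/3, 1].  Values outside the table
    range are clamped to the nearest bin.  An equal-frequency variant
    ("tertile") stores explicit edges instead.
    """

    ranges: dict[str, tuple[float, float]]
    mode: str = "equal_width"
    edges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def bin_value(self, param_type: str, value: float) -> str:
        if self.mode == "equal_width":
            lo, hi = self.ranges[param_type]
            v = (value - lo) / (hi - lo)
            v = min(max(v, 0.0), 1.0)
            if v < 1 / 3:
                return "L"
            if v < 2 / 3:
                return "M"
            return "H"
        e1, e2 = self.edges[param_type]
        if value < e1:
            return "L"
        if value < e2:
            return "M"
        return "H"

    def bin_codes(self, param_type: str, values: np.ndarray) -> np.ndarray:
        """Vectorized binning to integer codes 0=L, 1=M, 2=H."""
        values = np.asarray(values, dtype=float)
        if self.mode == "equal_width":
            lo, hi = self.ranges[param_type]
            v = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
            return np.where(v < 1 / 3, 0, np.where(v < 2 / 3, 1, 2)).astype(np.int8)
        e1, e2 = self.edges[param_type]
        return np.where(values < e1, 0, np.where(values < e2, 1, 2)).astype(np.int8)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "edges": {k: list(v) for k, v in self.edges.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BinningSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            ranges={k: tuple(v) for k, v in payload["ranges"].items()},
            mode=payload.get("mode", "equal_width"),
            edges={k: tuple(v) for k, v in payload.get("edges", {}).items()},
        )


def _type_columns(param_type: str) -> list[str]:
    if param_type in STEP_PARAMS:
        return [f"{param_type}_pre", f"{param_type}_post"]
    return [param_type]


def fit_binning(table: ShapeTable, mode: str = "equal_width") -> BinningSpec:
    """Fit the L/M/H discretization from a complete shape table.

    Min/max (or tertile edges) are taken per parameter type over all 1024
    table values; for step parameters both the preceding- and
    following-step columns are pooled.
    """
    ranges: dict[str, tuple[float, float]] = {}
    edges: dict[str, tuple[float, float]] = {}
    for ptype in PARAM_TYPES:
        vals = np.concatenate([table.column(c) for c in _type_columns(ptype)])
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            raise ShapeTableError(f"parameter {ptype!r} is constant ({lo}); "
                                  "cannot bin")
        ranges[ptype] = (lo, hi)
        if mode == "tertile":
            e1, e2 = np.quantile(vals, [1 / 3, 2 / 3])
            edges[ptype] = (float(e1), float(e2))
    return BinningSpec(ranges=ranges, mode=mode, edges=edges)


def bin_profile(profile: ShapeProfile, spec: BinningSpec) -> dict[str, str]:
    """Discretize every descriptor of a profile into L/M/H labels."""
    return {
        name: spec.bin_value(descriptor_param_type(name), value)
        for name, value in profile.descriptors.items()
    }
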