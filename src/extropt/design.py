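"""Box-Behnken designs and coded/actual factor transforms.

A Box-Behnken design (BBD) is a three-level second-order design whose edge
runs place every factor pair at the four (+/-1, +/-1) combinations while all
remaining factors sit at their centre, plus replicated all-centre runs.  For
k = 4 factors that is 6 pairs x 4 = 24 edge runs; the study this package
models used 6 centre replicates, i.e. 30 runs in total.

Factors live in two bases: *actual* units (W, degC, mL/g, min) and *coded*
units, the affine rescaling in which low/centre/high map to -1/0/+1.  All
polynomial modelling downstream happens in coded units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "PAPER_FACTORS",
    "RESPONSE_COLUMN",
    "build_bbd",
    "code",
    "decode",
    "read_design",
    "write_design",
    "load_table1",
]

RESPONSE_COLUMN = "yield_pct"


class DesignError(ValueError):
    """Invalid design construction or inconsistent design table."""


class DesignParseError(DesignError):
    """Malformed design CSV."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its actual-unit range.

    ``low`` and ``high`` are the actual values at coded -1 and +1.
    """

    name: str
    units: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise DesignError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def step(self) -> float:
        return 0.5 * (self.high - self.low)


#: The four ultrasound-assisted aqueous two-phase extraction factors:
#: ultrasound power, extraction temperature, liquid-to-solid ratio,
#: extraction time, with the ranges used in the 30-run study design.
PAPER_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("X1_power_W", "W", 200.0, 400.0),
    FactorSpec("X2_temp_C", "degC", 50.0, 70.0),
    FactorSpec("X3_ratio_mL_per_g", "mL/g", 15.0, 25.0),
    FactorSpec("X4_time_min", "min", 20.0, 40.0),
)


def code(actual: np.ndarray, factors: Sequence[FactorSpec]) -> np.ndarray:
    """Map actual factor values to coded units, (x - center) / step.

    Works on a single point (length k) or a matrix (n x k).  Values outside
    [-1, 1] are legal (extrapolation) and returned as-is.
    """
    actual = np.asarray(actual, dtype=float)
    center = np.array([f.center for f in factors])
    step = np.array([f.step for f in factors])
    if actual.shape[-1] != len(factors):
        raise DesignError(
            f"expected {len(factors)} factor values, got shape {actual.shape}"
        )
    return (actual - center) / step


def decode(coded: np.ndarray, factors: Sequence[FactorSpec]) -> np.ndarray:
    """Inverse of :func:`code`: coded -> actual units."""
    coded = np.asarray(coded, dtype=float)
    center = np.array([f.center for f in factors])
    step = np.array([f.step for f in factors])
    if coded.shape[-1] != len(factors):
        raise DesignError(
            f"expected {len(factors)} coded values, got shape {coded.shape}"
        )
    return center + coded * step


@dataclass
class DesignTable:
    """A design-of-experiments table: factors plus per-run values.

    ``frame`` holds one row per run with columns ``run``, one actual-unit
    column per factor (named after the factor), and the response column
    (NaN where not yet measured).  Coded values are derived on demand so the
    two bases can never drift apart.
    """

    factors: tuple[FactorSpec, ...]
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        required = ["run", *[f.name for f in self.factors], RESPONSE_COLUMN]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        self.frame = self.frame.loc[:, required].reset_index(drop=True)

    # -- views -------------------------------------------------------------
    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def actual(self) -> np.ndarray:
        return self.frame[[f.name for f in self.factors]].to_numpy(float)

    @property
    def coded(self) -> np.ndarray:
        return code(self.actual, self.factors)

    @property
    def response(self) -> np.ndarray:
        return self.frame[RESPONSE_COLUMN].to_numpy(float)

    @property
    def has_responses(self) -> bool:
        return bool(np.isfinite(self.response).all())

    # -- checks ------------------------------------------------------------
    def validate_bbd(self, atol: float = 1e-9) -> None:
        """Raise unless the coded rows form a valid BBD (edges + centres)."""
        c = self.coded
        center_mask = np.all(np.abs(c) <= atol, axis=1)
        edges = c[~center_mask]
        if center_mask.sum() < 1:
            raise DesignError("BBD requires at least one centre run")
        on_grid = np.isin(np.round(edges, 9), (-1.0, 0.0, 1.0)).all()
        if not on_grid:
            raise DesignError("edge runs must have coded entries in {-1, 0, +1}")
        nonzero = (np.abs(edges) > atol).sum(axis=1)
        if not np.all(nonzero == 2):
            raise DesignError("each BBD edge run must have exactly two nonzero coded entries")
        if self.k == 4 and len(edges) != 24:
            raise DesignError(f"k=4 BBD needs 24 edge runs, found {len(edges)}")
        col_sums = c.sum(axis=0)
        if not np.allclose(col_sums, 0.0, atol=1e-8):
            raise DesignError(f"coded columns must sum to zero, got {col_sums}")


def build_bbd(factors: Sequence[FactorSpec], n_center: int) -> DesignTable:
    """Construct a Box-Behnken design.

    Edge runs are emitted in factor-pair lexicographic order — (1,2), (1,3),
    ... — with centre replicates last.  The physical experiment would be run
    in randomised order, but run order does not enter any model fit, so the
    deterministic ordering is kept for reproducibility.  Responses are NaN.
    """
    factors = tuple(factors)
    k = len(factors)
    if k < 3:
        raise DesignError(f"a Box-Behnken design needs at least 3 factors, got {k}")
    if n_center < 1:
        raise DesignError("n_center must be >= 1")
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            v = np.zeros(k)
            v[i], v[j] = si, sj
            rows.append(v)
    rows.extend(np.zeros(k) for _ in range(n_center))
    coded = np.vstack(rows)
    actual = decode(coded, factors)
    frame = pd.DataFrame(actual, columns=[f.name for f in factors])
    frame.insert(0, "run", np.arange(1, len(frame) + 1))
    frame[RESPONSE_COLUMN] = np.nan
    return DesignTable(factors, frame)


def write_design(table: DesignTable, path) -> None:
    """Write a design table as CSV (comma, dot decimal, UTF-8 header)."""
    out = table.frame.copy()
    out.to_csv(path, index=False)


def read_design(path, factors: Sequence[FactorSpec] | None = None) -> DesignTable:
    """Read a design CSV.

    The header must name the factor columns and the response column
    (missing responses may be empty cells).  When ``factors`` is omitted,
    each factor's low/high is inferred from the column extremes — exact for
    any design that exercises its full range, as a BBD does.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DesignParseError(f"cannot parse design CSV {path}: {exc}") from exc
    if frame.empty and len(frame.columns) == 0:
        raise DesignParseError(f"design CSV {path} is empty")
    if factors is None:
        names = [c for c in frame.columns if c not in ("run", RESPONSE_COLUMN)]
        if not names:
            raise DesignParseError(f"design CSV {path} has no factor columns")
        factors = tuple(
            FactorSpec(name, "", float(frame[name].min()), float(frame[name].max()))
            for name in names
        )
    for f in factors:
        if f.name not in frame.columns:
            raise DesignParseError(f"design CSV {path} missing factor column {f.name!r}")
    if RESPONSE_COLUMN not in frame.columns:
        raise DesignParseError(f"design CSV {path} missing column {RESPONSE_COLUMN!r}")
    if "run" not in frame.columns:
        frame.insert(0, "run", np.arange(1, len(frame) + 1))
    for colname in [f.name for f in factors]:
        col = pd.to_numeric(frame[colname], errors="coerce")
        if col.isna().any():
            bad = int(frame.index[col.isna()][0]) + 2  # header is line 1
            raise DesignParseError(
                f"non-numeric value in column {colname!r} near line {bad} of {path}"
            )
        frame[colname] = col
    frame[RESPONSE_COLUMN] = pd.to_numeric(frame[RESPONSE_COLUMN], errors="coerce")
    return DesignTable(tuple(factors), frame)


def load_table1() -> DesignTable:
    """The packaged 30-run extraction study design with measured yields."""
    with resources.as_file(
        resources.files("extropt.data").joinpath("table1.csv")
    ) as p:
        return read_design(p, PAPER_FACTORS)
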