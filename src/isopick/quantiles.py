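"""Mass-window quantile tables of isotope abundance ratios.

To validate an observed isotope cluster one needs to know which
monoisotopic-to-i-th-isotope abundance ratios are chemically plausible
for a substance of a given mass.  This module derives that prior from a
compound database (a list of molecular formulas): for every compound
the theoretical isotope cluster is computed and the ratio of the
monoisotopic peak to the 1st..5th isotope peak recorded; compounds are
then grouped into consecutive exact-mass windows and per-window
p-quantiles of the ratios are tabulated.  A pair of quantiles (e.g.
p = 0.005 and 0.995) forms the 99% confidence interval used by cluster
validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pattern import (
    FormulaError,
    MolecularFormula,
    exact_mass,
    formula_to_string,
    parse_formula,
    theoretical_pattern,
)

logger = logging.getLogger(__name__)

__all__ = [
    "P_GRID",
    "WINDOW_SIZES",
    "CompoundRecord",
    "QuantileTable",
    "compound_ratios",
    "build_quantile_table",
    "build_quantile_tables",
    "lookup_interval",
]

#: default probability grid (23 values, symmetric pairs plus the median)
P_GRID: tuple[float, ...] = (
    5.0e-6, 1.0e-5, 5.0e-5, 1.0e-4, 5.0e-4, 0.001, 0.005, 0.01, 0.025,
    0.05, 0.1, 0.5, 0.9, 0.95, 0.975, 0.99, 0.995, 0.999, 0.9995,
    0.9999, 0.99995, 0.99999, 0.999995,
)

#: supported mass window sizes in dalton
WINDOW_SIZES: tuple[int, ...] = (10, 25, 50, 100, 250)

MAX_ISOTOPE = 5


@dataclass
class CompoundRecord:
    """Exact mass and isotope abundance ratios of one database compound."""

    formula: MolecularFormula
    exact_mass: float
    #: isotope index (1..5) -> ratio monoisotopic/i-th peak; absent peaks omitted
    ratios: dict[int, float] = field(default_factory=dict)
    #: isotope index (0..5) -> relative intensity (percent of max)
    intensities: dict[int, float] = field(default_factory=dict)

    def pair_ratio(self, i: int, j: int) -> float | None:
        """Abundance ratio of the i-th to the j-th isotope peak (i < j)."""
        a, b = self.intensities.get(i), self.intensities.get(j)
        if a is None or b is None or b <= 0:
            return None
        return a / b


def compound_ratios(
    formulas: list[MolecularFormula | str],
    resolution: float = 10000.0,
) -> list[CompoundRecord]:
    """Compute exact masses and isotope ratios for a compound list.

    Formula strings are parsed; unparseable entries are skipped with a
    warning.  Patterns are computed at full depth (no intensity pruning)
    so that very large ratios of weak high isotopes are preserved.
    """
    if not formulas:
        raise ValueError("empty formula list")
    records: list[CompoundRecord] = []
    skipped = 0
    for item in formulas:
        try:
            formula = parse_formula(item) if isinstance(item, str) else dict(item)
            if not formula:
                raise FormulaError("empty formula")
            pat = theoretical_pattern(
                formula, resolution, prune_threshold=0.0, max_isotopes=MAX_ISOTOPE
            )
        except FormulaError as exc:
            skipped += 1
            logger.warning("skipping formula %r: %s", item, exc)
            continue
        intensities: dict[int, float] = {}
        for idx, inten in zip(pat.isotope_indices(), pat.intensities):
            intensities[int(idx)] = intensities.get(int(idx), 0.0) + float(inten)
        ratios = {}
        for i in range(1, MAX_ISOTOPE + 1):
            if intensities.get(i, 0.0) > 0 and 0 in intensities:
                ratios[i] = intensities[0] / intensities[i]
        records.append(
            CompoundRecord(
                formula=formula,
                exact_mass=exact_mass(formula),
                ratios=ratios,
                intensities=intensities,
            )
        )
    if skipped:
        logger.warning("skipped %d of %d formulas", skipped, len(formulas))
    if not records:
        raise ValueError("no parseable formula in input")
    return records


@dataclass
class QuantileTable:
    """p-quantiles of mono/i-th isotope ratios per consecutive mass window.

    Window k covers the half-open interval [k*w, (k+1)*w).  ``matrix``
    has one row per p in ``p_grid`` (ascending) and one column per
    window; empty windows hold NaN.
    """

    source_name: str
    window_size: float
    isotope_index: int
    p_grid: tuple[float, ...]
    matrix: np.ndarray
    window_count: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.p_grid), self.window_count):
            raise ValueError("matrix shape does not match p_grid/window_count")

    def window_of(self, mass: float) -> int:
        if mass <= 0:
            raise ValueError("mass must be positive")
        return int(mass // self.window_size)

    def populated_windows(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.matrix).all(axis=0))

    def quantile(self, mass: float, p: float) -> float:
        """Ratio quantile at probability p for the window containing mass."""
        try:
            row = self.p_grid.index(p)
        except ValueError:
            raise ValueError(f"p={p} not in the table's p_grid") from None
        k = self.window_of(mass)
        populated = self.populated_windows()
        if populated.size == 0:
            raise ValueError("quantile table has no populated windows")
        if k not in populated:
            # clamp beyond the last populated window, else nearest populated
            nearest = int(populated[np.argmin(np.abs(populated - k))])
            logger.warning(
                "mass %.3f falls in empty window %d; using window %d", mass, k, nearest
            )
            k = nearest
        return float(self.matrix[row, k])

    # ---- serialization ----

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    def to_dict(self) -> dict:
        return {
            "source_name": self.source_name,
            "window_size": self.window_size,
            "isotope_index": self.isotope_index,
            "p_grid": list(self.p_grid),
            "window_count": self.window_count,
            "matrix": [
                [None if np.isnan(v) else v for v in row] for row in self.matrix
            ],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "QuantileTable":
        matrix = np.array(
            [[np.nan if v is None else v for v in row] for row in obj["matrix"]],
            dtype=float,
        )
        return cls(
            source_name=obj["source_name"],
            window_size=obj["window_size"],
            isotope_index=obj["isotope_index"],
            p_grid=tuple(obj["p_grid"]),
            matrix=matrix,
            window_count=obj["window_count"],
        )

    @classmethod
    def from_json(cls, path) -> "QuantileTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_csv(self, path) -> None:
        cols = [k * self.window_size for k in range(self.window_count)]
        pd.DataFrame(self.matrix, index=list(self.p_grid), columns=cols).to_csv(
            path, index_label="p"
        )

    @classmethod
    def from_csv(cls, path, source_name: str, isotope_index: int) -> "QuantileTable":
        df = pd.read_csv(path, index_col="p")
        starts = df.columns.astype(float)
        window_size = float(starts[1] - starts[0]) if len(starts) > 1 else float("nan")
        return cls(
            source_name=source_name,
            window_size=window_size,
            isotope_index=isotope_index,
            p_grid=tuple(df.index),
            matrix=df.to_numpy(),
            window_count=df.shape[1],
        )


def build_quantile_table(
    records: list[CompoundRecord],
    window_size: float = 50.0,
    isotope_index: int = 1,
    p_grid: tuple[float, ...] = P_GRID,
    source_name: str = "custom",
    pair: tuple[int, int] | None = None,
) -> QuantileTable:
    """Tabulate per-mass-window p-quantiles of isotope abundance ratios.

    By default the ratio is monoisotopic / ``isotope_index``-th peak;
    passing ``pair=(i, j)`` tabulates the i-th/j-th peak ratio instead.
    Quantiles are the linearly interpolated empirical order statistics;
    extreme p on small windows degenerate to the window min/max.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if not 1 <= isotope_index <= MAX_ISOTOPE:
        raise ValueError("isotope_index must be in 1..5")
    p_grid = tuple(sorted(p_grid))
    masses: list[float] = []
    values: list[float] = []
    for rec in records:
        if pair is not None:
            ratio = rec.pair_ratio(*pair)
        else:
            ratio = rec.ratios.get(isotope_index)
        if ratio is None:
            continue
        masses.append(rec.exact_mass)
        values.append(ratio)
    if not values:
        raise ValueError(
            f"no record has isotope peak {pair or isotope_index}; cannot build table"
        )
    mass_arr = np.array(masses)
    val_arr = np.array(values)
    window_count = int(mass_arr.max() // window_size) + 1
    matrix = np.full((len(p_grid), window_count), np.nan)
    windows = (mass_arr // window_size).astype(int)
    for k in range(window_count):
        vals = val_arr[windows == k]
        if vals.size:
            matrix[:, k] = np.quantile(vals, p_grid)
    return QuantileTable(
        source_name=source_name,
        window_size=window_size,
        isotope_index=isotope_index,
        p_grid=p_grid,
        matrix=matrix,
        window_count=window_count,
    )


def build_quantile_tables(
    records: list[CompoundRecord],
    window_size: float = 50.0,
    isotope_indices: tuple[int, ...] = (1, 2, 3, 4, 5),
    p_grid: tuple[float, ...] = P_GRID,
    source_name: str = "custom",
) -> dict[int, QuantileTable]:
    """One QuantileTable per isotope index, as used by cluster validation."""
    return {
        i: build_quantile_table(
            records, window_size, i, p_grid=p_grid, source_name=source_name
        )
        for i in isotope_indices
    }


def lookup_interval(
    table: QuantileTable,
    mass: float,
    p_low: float = 0.005,
    p_high: float = 0.995,
) -> tuple[float, float]:
    """Confidence interval (ratio_low, ratio_high) for a monoisotopic mass."""
    if not p_low < p_high:
        raise ValueError("p_low must be smaller than p_high")
    return table.quantile(mass, p_low), table.quantile(mass, p_high)
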