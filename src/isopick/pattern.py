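"""Molecular formulas and theoretical isotope patterns.

A theoretical isotope pattern is obtained by convolving the isotope
distributions of all atoms in a molecular formula and merging the
resulting fine-structure centroids at the mass resolution of the
instrument (FWHM = mass / resolution).  The pattern is reported on a
relative intensity scale with the most intense centroid at 100, and
centroids below a prune threshold (percent of the monoisotopic peak)
are dropped.  Isotopic fine structure is deliberately not resolved:
at a resolution of 10,000 each centroid is a mixture of nuclide
combinations with (near-)equal nominal mass shift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .elements import DELTA_M, ISOTOPES, lightest_mass

__all__ = [
    "MolecularFormula",
    "TheoreticalPattern",
    "FormulaError",
    "parse_formula",
    "formula_to_string",
    "exact_mass",
    "theoretical_pattern",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: element count mapping, e.g. {"C": 4, "H": 7, "N": 1, "O": 4}
MolecularFormula = dict[str, int]


class FormulaError(ValueError):
    """Raised for malformed or unknown molecular formula strings."""


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style element-count string such as ``"C4H7NO4"``.

    Counts default to 1 for elements written without a number; repeated
    element symbols are summed.  Charges and isotope labels are not
    supported.

    Raises
    ------
    FormulaError
        If the string is empty, contains anything but element-count
        tokens, or names an element absent from the isotope table.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    formula: MolecularFormula = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos or not match.group(0):
            break
        symbol, digits = match.group(1), match.group(2)
        if symbol not in ISOTOPES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        count = int(digits) if digits else 1
        if count > 0:
            formula[symbol] = formula.get(symbol, 0) + count
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return formula


def formula_to_string(formula: MolecularFormula) -> str:
    """Hill-order string representation (C, H, then alphabetical)."""
    symbols = sorted(formula, key=lambda s: (s != "C", s != "H", s))
    return "".join(
        f"{s}{formula[s]}" if formula[s] != 1 else s for s in symbols if formula[s] > 0
    )


def exact_mass(formula: MolecularFormula) -> float:
    """Monoisotopic (lightest-isotope) mass of a neutral formula, in Da.

    An empty formula has mass 0.
    """
    return sum(count * lightest_mass(sym) for sym, count in formula.items())


@dataclass
class TheoreticalPattern:
    """Centroided theoretical isotope cluster of a neutral formula.

    ``masses`` are strictly increasing, ``intensities`` are percent of
    the most intense centroid (max exactly 100).  The first centroid is
    the monoisotopic peak, which need not be the most intense one.
    """

    masses: np.ndarray
    intensities: np.ndarray
    resolution: float
    prune_threshold: float
    formula: MolecularFormula = field(default_factory=dict)
    #: sum of raw convolution probabilities before normalization/pruning;
    #: ~1 up to terms beyond the max_isotopes window
    total_probability: float = 1.0

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def mono_mass(self) -> float:
        return float(self.masses[0])

    @property
    def mono_intensity(self) -> float:
        return float(self.intensities[0])

    def isotope_indices(self) -> np.ndarray:
        """Isotope number of each centroid (0 = monoisotopic).

        Indices are assigned by rounding the mass shift from the
        monoisotopic peak against the nominal 13C spacing; element
        combinations such as 37Cl (+1.997) land on the correct slot.
        """
        return np.rint((self.masses - self.masses[0]) / DELTA_M).astype(int)

    def intensity_of(self, isotope_index: int) -> float | None:
        """Relative intensity at a given isotope number, or None if absent."""
        idx = self.isotope_indices()
        hits = np.flatnonzero(idx == isotope_index)
        if hits.size == 0:
            return None
        return float(self.intensities[hits].sum())

    def mono_ratio(self, isotope_index: int) -> float | None:
        """Abundance ratio monoisotopic / i-th isotope peak, or None."""
        inten = self.intensity_of(isotope_index)
        if inten is None or inten <= 0:
            return None
        return self.mono_intensity / inten


def _convolve(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    prune: float,
    max_shift: float | None,
    base_mass: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two centroid lists, aggregating coincident masses.

    Terms with probability below ``prune`` (relative to the running
    maximum) and terms beyond ``base_mass + max_shift`` are dropped to
    bound the term count.
    """
    mass = (a[0][:, None] + b[0][None, :]).ravel()
    prob = (a[1][:, None] * b[1][None, :]).ravel()
    keep = prob >= prune * prob.max()
    if max_shift is not None:
        keep &= mass <= base_mass + max_shift
    mass, prob = mass[keep], prob[keep]
    # aggregate fine-structure terms identical to ~1e-7 Da
    key = np.round(mass, 7)
    uniq, inverse = np.unique(key, return_inverse=True)
    agg_prob = np.bincount(inverse, weights=prob)
    agg_mass = np.bincount(inverse, weights=prob * mass) / agg_prob
    return agg_mass, agg_prob


def _element_power(
    masses: np.ndarray, probs: np.ndarray, n: int, prune: float, max_shift: float
) -> tuple[np.ndarray, np.ndarray]:
    """Isotope distribution of n identical atoms by binary exponentiation."""
    base = masses[0] * n
    result: tuple[np.ndarray, np.ndarray] | None = None
    square = (masses.copy(), probs.copy())
    sq_base = masses[0]
    while n > 0:
        if n & 1:
            if result is None:
                result = square
            else:
                result = _convolve(result, square, prune, max_shift, base)
        n >>= 1
        if n:
            sq_base *= 2
            square = _convolve(square, square, prune, max_shift, sq_base)
    assert result is not None
    return result


def theoretical_pattern(
    formula: MolecularFormula,
    resolution: float = 10000.0,
    prune_threshold: float = 0.01,
    max_isotopes: int = 5,
    _conv_prune: float = 1e-9,
) -> TheoreticalPattern:
    """Theoretical isotope cluster of a neutral molecular formula.

    Parameters
    ----------
    formula
        Non-empty element-count mapping.
    resolution
        Instrument resolving power; centroids closer than
        ``mass / resolution`` (the implied FWHM) are merged by
        intensity-weighted mean mass.
    prune_threshold
        Minimum relative intensity, in percent of the *monoisotopic*
        peak, for a centroid to be reported.  0 keeps everything.
    max_isotopes
        Keep at most this many isotope peaks beyond the monoisotopic
        one (the conventional cluster depth is 5).
    """
    if not formula or not any(c > 0 for c in formula.values()):
        raise FormulaError("cannot compute a pattern for an empty formula")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if prune_threshold < 0:
        raise ValueError("prune_threshold must be non-negative")

    mono = exact_mass(formula)
    max_shift = (max_isotopes + 1.5) * DELTA_M

    dist: tuple[np.ndarray, np.ndarray] | None = None
    for sym, count in sorted(formula.items()):
        if count <= 0:
            continue
        iso = ISOTOPES[sym]
        masses = np.array([m for m, _ in iso])
        probs = np.array([p for _, p in iso])
        elem = _element_power(masses, probs, count, _conv_prune, max_shift)
        if dist is None:
            dist = elem
        else:
            dist = _convolve(dist, elem, _conv_prune, max_shift, mono)

    assert dist is not None
    mass, prob = dist
    total_probability = float(prob.sum())
    order = np.argsort(mass)
    mass, prob = mass[order], prob[order]

    # centroid merging at the FWHM implied by the resolution
    merged_m: list[float] = []
    merged_p: list[float] = []
    for m, p in zip(mass, prob):
        if merged_m and (m - merged_m[-1]) < merged_m[-1] / resolution:
            tot = merged_p[-1] + p
            merged_m[-1] = (merged_m[-1] * merged_p[-1] + m * p) / tot
            merged_p[-1] = tot
        else:
            merged_m.append(float(m))
            merged_p.append(float(p))

    cm = np.array(merged_m)
    cp = np.array(merged_p)

    # cap the cluster depth at max_isotopes beyond the monoisotopic peak
    idx = np.rint((cm - cm[0]) / DELTA_M).astype(int)
    keep = idx <= max_isotopes
    cm, cp = cm[keep], cp[keep]

    rel = 100.0 * cp / cp.max()
    # prune relative to the monoisotopic (first) centroid
    keep = 100.0 * cp / cp[0] >= prune_threshold
    keep[0] = True
    cm, rel = cm[keep], rel[keep]

    return TheoreticalPattern(
        masses=cm,
        intensities=rel,
        resolution=resolution,
        prune_threshold=prune_threshold,
        formula=dict(formula),
        total_probability=total_probability,
    )
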