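"""Synthetic data: reference spectra, raw maps, and formula databases.

Three generators support development and testing without instrument
data: (i) the bundled six-substance reference spectrum (printed
centroid masses and intensities of aspartic acid, cysteine,
chloramphenicol, digoxigenin monodigitoxoside,
2-chloro-2'-deoxyadenosine-5'-triphosphate, and autoinducer-2);
(ii) centroided LC-MS raw maps with planted isotope clusters, Gaussian
elution profiles, a uniform noise floor, and m/z jitter, together with
a ground-truth ledger; and (iii) random plausible small-molecule
formulas for building quantile tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .pattern import MolecularFormula, exact_mass, parse_formula, theoretical_pattern
from .peaks import Peak, RawMap

__all__ = [
    "REFERENCE_SUBSTANCES",
    "reference_cluster_table",
    "reference_spectrum",
    "SimulationConfig",
    "PlantedCompound",
    "simulate_raw_map",
    "simulate_formula_db",
    "DEFAULT_ELEMENT_PROFILE",
]

REFERENCE_SUBSTANCES = (
    "aspartic acid",
    "cysteine",
    "chloramphenicol",
    "digoxigenin monodigitoxoside",
    "2-chloro-2'-deoxyadenosine-5'-triphosphate",
    "autoinducer-2",
)


def reference_cluster_table() -> pd.DataFrame:
    """The bundled six-substance reference table (printed values)."""
    with resources.files("isopick.data").joinpath("reference_clusters.csv").open() as fh:
        return pd.read_csv(fh)


def reference_spectrum(
    substances: tuple[str, ...] | list[str] | None = None,
    rt: float = 300.0,
    sn: float = math.inf,
) -> list[Peak]:
    """The reference clusters pooled into one coeluting synthetic spectrum.

    All six substances yield 33 peaks sharing one retention time with
    infinite S/N by default (noise is a controlled variable in tests).
    """
    if substances is None:
        substances = REFERENCE_SUBSTANCES
    if not substances:
        raise ValueError("no substances selected")
    unknown = set(substances) - set(REFERENCE_SUBSTANCES)
    if unknown:
        raise ValueError(f"unknown substances: {sorted(unknown)}")
    df = reference_cluster_table()
    df = df[df.substance.isin(substances)]
    return [
        Peak(
            id=f"{row.substance}:{row.isotope}",
            mz=float(row.mass),
            rt=rt,
            intensity=float(row.rel_intensity),
            sn=sn,
        )
        for row in df.itertuples(index=False)
    ]


@dataclass
class PlantedCompound:
    """One compound planted into a synthetic raw map."""

    formula: str
    rt_center: float
    apex_intensity: float
    rt_sigma: float = 5.0


@dataclass
class SimulationConfig:
    """Conditions of a synthetic LC-MS raw map.

    The defaults emulate a short high-resolution gradient segment: 1 s
    scans, a noise floor of 100 counts, and centroid m/z jitter of
    0.002 Da (about 4 ppm at m/z 500).
    """

    compounds: list[PlantedCompound] = field(default_factory=list)
    rt_range: tuple[float, float] = (0.0, 120.0)
    scan_interval: float = 1.0
    mz_range: tuple[float, float] = (80.0, 1000.0)
    noise_level: float = 100.0
    noise_peaks_per_scan: int = 60
    mz_jitter: float = 0.002
    min_signal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval <= 0 or self.noise_level < 0 or self.mz_jitter < 0:
            raise ValueError("invalid simulation configuration")
        for c in self.compounds:
            if c.rt_sigma <= 0 or c.apex_intensity <= 0:
                raise ValueError(f"invalid planted compound {c.formula}")


def simulate_raw_map(config: SimulationConfig) -> tuple[RawMap, pd.DataFrame]:
    """Simulate a centroided raw map with planted isotope clusters.

    Each isotopologue of each planted compound elutes as a Gaussian
    profile whose apex is ``apex_intensity`` scaled by the theoretical
    relative intensity; the noise floor is uniform with median
    ``noise_level``.  Returns the map and a ground-truth ledger with
    one row per planted isotopologue (compound, isotope index, m/z,
    apex intensity, and true S/N against the noise floor).
    """
    rng = np.random.default_rng(config.seed)
    rts = np.arange(config.rt_range[0], config.rt_range[1] + 1e-9,
                    config.scan_interval)
    ledger_rows = []
    planted = []  # (mz, rt_center, rt_sigma, apex)
    for ci, comp in enumerate(config.compounds):
        pattern = theoretical_pattern(parse_formula(comp.formula))
        scale = comp.apex_intensity / float(pattern.intensities.max())
        for iso, (mass, rel) in zip(
            pattern.isotope_indices(), zip(pattern.masses, pattern.intensities)
        ):
            apex = rel * scale
            planted.append((float(mass), comp.rt_center, comp.rt_sigma, apex))
            ledger_rows.append(
                {
                    "compound": comp.formula,
                    "compound_index": ci,
                    "isotope": int(iso),
                    "mz": float(mass),
                    "rt": comp.rt_center,
                    "apex_intensity": apex,
                    "true_sn": apex / config.noise_level
                    if config.noise_level > 0
                    else math.inf,
                }
            )

    scan_mzs: list[np.ndarray] = []
    scan_intensities: list[np.ndarray] = []
    lo, hi = config.mz_range
    for rt in rts:
        mzs = list(rng.uniform(lo, hi, size=config.noise_peaks_per_scan))
        intens = list(rng.uniform(0.0, 2.0 * config.noise_level,
                                  size=config.noise_peaks_per_scan))
        for mass, center, sigma, apex in planted:
            signal = apex * math.exp(-0.5 * ((rt - center) / sigma) ** 2)
            if signal < config.min_signal:
                continue
            mzs.append(mass + rng.normal(0.0, config.mz_jitter))
            intens.append(signal)
        order = np.argsort(mzs, kind="stable")
        mz_arr = np.asarray(mzs)[order]
        # nudge exact duplicates apart to keep per-scan m/z strictly increasing
        dup = np.flatnonzero(np.diff(mz_arr) <= 0)
        for d in dup:
            mz_arr[d + 1] = np.nextafter(mz_arr[d], np.inf)
        scan_mzs.append(mz_arr)
        scan_intensities.append(np.asarray(intens)[order])
    raw = RawMap(scan_rts=rts, scan_mzs=scan_mzs,
                 scan_intensities=scan_intensities)
    return raw, pd.DataFrame(ledger_rows)


#: element -> average presence probability across the generated database
#: (the realized averages of the compound-class mixture below).  A custom
#: profile scales each element's presence relative to these defaults; a
#: weight of zero excludes the element entirely.
DEFAULT_ELEMENT_PROFILE: dict[str, float] = {
    "O": 0.935,
    "N": 0.49,
    "S": 0.10,
    "P": 0.12,
    "Cl": 0.08,
    "Br": 0.01,
}

# Compound-class mixture mimicking small-molecule database composition.
# Heteroatom content is correlated in real chemistry (nucleotides combine
# high N, high O, and phosphate; lipids are carbon-rich and oxygen-poor;
# sugars sit near O/C = 1), so classes — not independent ratios — shape
# the formulas.  Each class: sampling weight, H/C range, per-element
# (presence, ratio_low, ratio_high), and a phosphorus count distribution.
_CLASSES: tuple[tuple[float, str, tuple[float, float],
                      dict[str, tuple[float, float, float]],
                      dict[int, float]], ...] = (
    (0.50, "generic", (0.7, 2.0),
     {"O": (0.92, 0.05, 0.90), "N": (0.60, 0.02, 0.50),
      "S": (0.08, 0.03, 0.35)},
     {0: 0.97, 1: 0.024, 2: 0.006}),
    (0.15, "sugar-like", (1.4, 2.0),
     {"O": (1.00, 0.75, 1.25), "N": (0.10, 0.02, 0.25),
      "S": (0.02, 0.03, 0.20)},
     {0: 0.85, 1: 0.10, 2: 0.05}),
    (0.10, "nucleotide-like", (0.9, 1.6),
     {"O": (1.00, 0.45, 1.35), "N": (1.00, 0.35, 1.00),
      "S": (0.03, 0.03, 0.30)},
     {0: 0.45, 1: 0.22, 2: 0.165, 3: 0.165}),
    (0.20, "lipid-like", (1.5, 2.2),
     {"O": (0.90, 0.02, 0.35), "N": (0.25, 0.01, 0.15),
      "S": (0.02, 0.02, 0.10)},
     {0: 0.88, 1: 0.12}),
    (0.05, "sulfur-rich", (1.0, 2.0),
     {"O": (0.90, 0.10, 0.90), "N": (0.50, 0.05, 0.50),
      "S": (1.00, 0.15, 0.60)},
     {0: 0.98, 1: 0.02}),
)

_MONO_MASS = {"H": 1.00782503224, "C": 12.0, "N": 14.00307400443,
              "O": 15.99491461957, "P": 30.97376199842, "S": 31.9720711744,
              "Cl": 34.968852682, "Br": 78.9183376}


def simulate_formula_db(
    n: int,
    mass_range: tuple[float, float] = (50.0, 1000.0),
    element_profile: dict[str, float] | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> list[MolecularFormula]:
    """Generate random plausible CHNOPS(+halogen) molecular formulas.

    Formulas are carbon-count driven within a compound-class mixture:
    a target mass is drawn uniformly in ``mass_range``, a class sets
    correlated H/C, O/C, N/C, S/C ratios and the phosphorus count,
    chlorine/bromine occur as small integer counts, and hydrogens
    absorb the mass remainder.  ``element_profile`` rescales per-element
    presence probabilities relative to ``DEFAULT_ELEMENT_PROFILE`` (zero
    removes the element).  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = mass_range
    if not 0 < lo < hi:
        raise ValueError("invalid mass range")
    if hi < 14.0:
        raise ValueError("mass range infeasible for CH formulas")
    profile = dict(DEFAULT_ELEMENT_PROFILE if element_profile is None
                   else element_profile)
    scale = {
        el: profile.get(el, 0.0) / DEFAULT_ELEMENT_PROFILE[el]
        for el in DEFAULT_ELEMENT_PROFILE
    }
    rng = np.random.default_rng(seed)
    class_weights = np.array([c[0] for c in _CLASSES])
    class_weights = class_weights / class_weights.sum()
    p_counts = [
        (np.array(list(c[4].keys())), np.array(list(c[4].values())))
        for c in _CLASSES
    ]
    formulas: list[MolecularFormula] = []
    while len(formulas) < n:
        for _ in range(max_tries):
            target = rng.uniform(lo, hi)
            ci = int(rng.choice(len(_CLASSES), p=class_weights))
            _, _, h_range, ratio_spec, _ = _CLASSES[ci]
            h_per_c = rng.uniform(*h_range)
            ratios = {}
            for el, (presence, rlo, rhi) in ratio_spec.items():
                if rng.random() < min(1.0, presence * scale[el]):
                    ratios[el] = rng.uniform(rlo, rhi)
            counts, probs = p_counts[ci]
            n_p = int(rng.choice(counts, p=probs))
            if n_p and rng.random() >= min(1.0, scale["P"]):
                n_p = 0
            halogens = {}
            for el in ("Cl", "Br"):
                base = 0.08 if el == "Cl" else 0.01
                if rng.random() < min(1.0, base * scale[el]):
                    halogens[el] = int(rng.geometric(0.55))
            fixed_mass = n_p * _MONO_MASS["P"] + sum(
                _MONO_MASS[el] * c for el, c in halogens.items()
            )
            per_carbon = 12.0 + h_per_c * _MONO_MASS["H"] + sum(
                r * _MONO_MASS[el] for el, r in ratios.items()
            )
            n_c = max(1, round((target - fixed_mass) / per_carbon))
            formula: MolecularFormula = {"C": n_c}
            for el, r in ratios.items():
                count = round(r * n_c)
                if count > 0:
                    formula[el] = count
            if n_p:
                formula["P"] = n_p
            formula.update(halogens)
            hetero_mass = sum(_MONO_MASS[el] * c for el, c in formula.items())
            n_h = round((target - hetero_mass) / _MONO_MASS["H"])
            if n_h > 0:
                formula["H"] = n_h
            mass = exact_mass(formula)
            if lo <= mass <= hi:
                formulas.append(formula)
                break
        else:
            raise ValueError(
                f"could not generate a formula in mass range {mass_range}"
            )
    return formulas
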