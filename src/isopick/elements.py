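"""Element isotope masses and natural abundances.

The bundled table carries the IUPAC/CIAAW standard atomic masses and
isotopic compositions for the elements commonly found in small
biological molecules (CHNOPS plus halogens, boron, and a few metals).
Masses are in dalton, abundances are mole fractions summing to 1 per
element, and isotopes are listed in order of increasing mass.
"""

from __future__ import annotations

# symbol -> ((mass, abundance), ...) sorted by mass
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503224, 0.999885), (2.01410177812, 0.000115)),
    "B": ((10.01293695, 0.199), (11.00930536, 0.801)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.00307400443, 0.99636), (15.00010889888, 0.00364)),
    "O": (
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ),
    "F": ((18.99840316273, 1.0),),
    "Na": ((22.9897692820, 1.0),),
    "Mg": (
        (23.985041697, 0.7899),
        (24.985836976, 0.1000),
        (25.982592968, 0.1101),
    ),
    "Si": (
        (27.97692653465, 0.92223),
        (28.97649466490, 0.04685),
        (29.973770136, 0.03092),
    ),
    "P": ((30.97376199842, 1.0),),
    "S": (
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ),
    # chlorine's natural abundance varies; CIAAW quotes 37Cl in [0.239, 0.245]
    # with representative 0.2424.  We adopt 0.2436, the in-interval value
    # consistent with the reference centroid patterns used for calibration.
    "Cl": ((34.968852682, 0.7564), (36.965902602, 0.2436)),
    "K": (
        (38.9637064864, 0.932581),
        (39.963998166, 0.000117),
        (40.9618252579, 0.067302),
    ),
    "Ca": (
        (39.962590863, 0.96941),
        (41.95861783, 0.00647),
        (42.95876644, 0.00135),
        (43.95548156, 0.02086),
        (45.9536890, 0.00004),
        (47.95252276, 0.00187),
    ),
    "Fe": (
        (53.93960899, 0.05845),
        (55.93493633, 0.91754),
        (56.93539284, 0.02119),
        (57.93327443, 0.00282),
    ),
    "Br": ((78.9183376, 0.5069), (80.9162897, 0.4931)),
    "I": ((126.9044719, 1.0),),
}

#: m/z spacing between successive isotope peaks, mass(13C) - mass(12C),
#: fixed at six decimals and shared by ROI prediction and cluster detection.
DELTA_M: float = 1.003355


def lightest_mass(symbol: str) -> float:
    """Mass of the lightest isotope of *symbol* (monoisotopic convention)."""
    return ISOTOPES[symbol][0][0]


def _selfcheck() -> None:
    for sym, iso in ISOTOPES.items():
        total = sum(a for _, a in iso)
        if abs(total - 1.0) > 1e-6:
            raise AssertionError(f"abundances of {sym} sum to {total}")
        masses = [m for m, _ in iso]
        if masses != sorted(masses):
            raise AssertionError(f"isotope masses of {sym} not increasing")


_selfcheck()
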