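"""Detection of putative isotope clusters in coeluting peaks.

Two coeluting peaks are compatible with being successive isotope peaks
of a charge-z ion when

    | |mz(p1) - mz(p2)| - Δm/z |  <=  max(mz(mono) * ppm_tol / 1e6, abs_tol)

with Δm = mass(13C) - mass(12C) = 1.003355.  Putative clusters are
gap-free chains of successively compatible peaks; the chain with the
most peaks is retained, its peaks removed, and the search repeated
until no chain of at least two peaks remains.  The ppm tolerance is
referenced to the chain's monoisotopic (first) m/z.
"""

from __future__ import annotations

import numpy as np

from .elements import DELTA_M
from .peaks import IsotopeCluster, Peak

__all__ = [
    "pair_tolerance",
    "find_putative_clusters",
    "minimal_detection_errors",
    "group_by_rt",
]


def pair_tolerance(mono_mass: float, ppm_tol: float, abs_tol: float) -> float:
    """Allowed deviation from Δm/z for one isotope spacing, in dalton."""
    if mono_mass <= 0:
        raise ValueError("mono_mass must be positive")
    if ppm_tol < 0 or abs_tol < 0:
        raise ValueError("tolerances must be non-negative")
    if ppm_tol == 0 and abs_tol == 0:
        raise ValueError("ppm_tol and abs_tol cannot both be zero")
    return max(mono_mass * ppm_tol / 1e6, abs_tol)


def _best_chain(
    mzs: np.ndarray,
    intensities: np.ndarray,
    start: int,
    spacing: float,
    tol: float,
) -> list[int]:
    """Longest gap-free chain from ``start``; deterministic tie-breaks.

    All successor choices are explored (several peaks may satisfy the
    tolerance for the next slot); among equally long continuations the
    peak closest to the expected position wins, then the more intense.
    """
    candidates = np.flatnonzero(np.abs(np.abs(mzs - mzs[start]) - spacing) <= tol)
    candidates = candidates[mzs[candidates] > mzs[start]]
    if candidates.size == 0:
        return [start]
    order = sorted(
        candidates,
        key=lambda j: (abs(mzs[j] - mzs[start] - spacing), -intensities[j]),
    )
    best: list[int] = []
    for j in order:
        chain = _best_chain(mzs, intensities, j, spacing, tol)
        if len(chain) > len(best):
            best = chain
    return [start] + best


def find_putative_clusters(
    peaks: list[Peak],
    Z: int = 3,
    ppm_tol: float = 0.0,
    abs_tol: float = 0.01,
) -> list[IsotopeCluster]:
    """Detect disjoint putative isotope clusters among coeluting peaks.

    For each charge state and each possible monoisotopic peak all
    gap-free chains are computed; the largest chain is retained
    (ties: lower monoisotopic m/z, then smaller charge), its peaks
    removed, and the process repeated.  Clusters are returned sorted by
    monoisotopic m/z.  Fewer than two peaks yield an empty list.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    if len(peaks) < 2:
        return []
    peaks = sorted(peaks, key=lambda p: p.mz)
    alive = list(range(len(peaks)))
    clusters: list[IsotopeCluster] = []
    while len(alive) >= 2:
        mzs = np.array([peaks[i].mz for i in alive])
        intens = np.array([peaks[i].intensity for i in alive])
        best_chain: list[int] = []
        best_key: tuple | None = None
        for z in range(1, Z + 1):
            spacing = DELTA_M / z
            for s in range(len(alive)):
                tol = pair_tolerance(mzs[s], ppm_tol, abs_tol)
                chain = _best_chain(mzs, intens, s, spacing, tol)
                if len(chain) < 2:
                    continue
                key = (-len(chain), mzs[chain[0]], z)
                if best_key is None or key < best_key:
                    best_key = key
                    best_chain = chain
                    best_z = z
        if not best_chain:
            break
        members = [peaks[alive[i]] for i in best_chain]
        clusters.append(IsotopeCluster(peaks=members, charge=best_z))
        chosen = {alive[i] for i in best_chain}
        alive = [i for i in alive if i not in chosen]
    clusters.sort(key=lambda c: c.mono.mz)
    for k, cluster in enumerate(clusters):
        cluster.id = f"c{k}"
    return clusters


def minimal_detection_errors(cluster_masses: list[float]) -> tuple[float, float]:
    """Minimal absolute (Da) and relative (ppm) mass errors for detection.

    The absolute error is the largest deviation of a consecutive mass
    difference from Δm; the relative error refers it to the
    monoisotopic mass.  Assumes charge 1 and strictly increasing
    masses.
    """
    masses = np.asarray(cluster_masses, dtype=float)
    if masses.size < 2:
        raise ValueError("need at least two masses")
    if np.any(np.diff(masses) <= 0):
        raise ValueError("masses must be strictly increasing")
    abs_err = float(np.max(np.abs(np.diff(masses) - DELTA_M)))
    ppm_err = abs_err / float(masses[0]) * 1e6
    return abs_err, ppm_err


def group_by_rt(peaks: list[Peak], rt_window: float = 5.0) -> list[list[Peak]]:
    """Plumbing: group peaks into coeluting sets by a retention-time gap.

    Peaks sorted by rt start a new group whenever the gap to the
    previous peak exceeds ``rt_window``.  This stands in for proper
    pseudospectrum extraction, which is an upstream concern.
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: (p.rt, p.mz))
    groups = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.rt - prev.rt > rt_window:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    return groups
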