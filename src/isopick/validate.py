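"""Mass-specific validation of putative isotope clusters.

For each non-monoisotopic peak of a putative cluster the observed
abundance ratio monoisotopic/peak is bracketed by a noise-aware
interval and compared with the confidence interval of chemically
plausible ratios for the cluster's mass (from a compound-database
quantile table).  Non-overlap splits the cluster: the peak becomes the
monoisotopic peak of a new putative cluster which is validated in
turn.  This removes hydrogen-loss satellites ahead of the true
monoisotopic peak, deconvolves overlapping clusters, and truncates
trailing peaks with distorted intensities; clusters that shrink below
two peaks are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .peaks import IsotopeCluster, Peak
from .quantiles import QuantileTable, lookup_interval

logger = logging.getLogger(__name__)

__all__ = ["RatioInterval", "ratio_interval", "validate_cluster", "validate_clusters"]

_EPS = 1e-12


@dataclass(frozen=True)
class RatioInterval:
    """Noise-bracketed interval of an observed abundance ratio."""

    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_min <= self.r_max:
            raise ValueError("requires 0 <= r_min <= r_max")

    def overlaps(self, low: float, high: float) -> bool:
        return self.r_max >= low and self.r_min <= high


def ratio_interval(a1: float, sn1: float, a2: float, sn2: float) -> RatioInterval:
    """Bracket the abundance ratio a1/a2 given signal-to-noise estimates.

    With noise levels n_k = a_k / sn_k the extreme ratios are
    (a1 - n1)/(a2 + n2) and (a1 + n1)/(a2 - n2); infinite S/N collapses
    to the point ratio.  Peaks with unknown S/N should be passed with
    sn = inf (strictest interpretation).
    """
    if a1 <= 0 or a2 <= 0 or sn1 <= 0 or sn2 <= 0:
        raise ValueError("abundances and signal-to-noise ratios must be positive")
    n1 = 0.0 if math.isinf(sn1) else a1 / sn1
    n2 = 0.0 if math.isinf(sn2) else a2 / sn2
    r_min = max(a1 - n1, 0.0) / (a2 + n2)
    r_max = (a1 + n1) / max(a2 - n2, _EPS)
    return RatioInterval(r_min, r_max)


def _sn(peak: Peak) -> float:
    return peak.sn if peak.sn and peak.sn > 0 else math.inf


def validate_cluster(
    cluster: IsotopeCluster,
    tables: dict[int, QuantileTable],
    p_low: float = 0.005,
    p_high: float = 0.995,
    rejected: list[Peak] | None = None,
) -> list[IsotopeCluster]:
    """Validate one putative cluster, splitting it where ratios are implausible.

    Walks the peaks after the monoisotopic one; at the first peak whose
    observed mono/peak ratio interval does not overlap the
    [p_low, p_high] quantile interval for the cluster's neutral mass,
    the cluster is split there and the suffix revalidated as a new
    putative cluster.  Fragments with fewer than two peaks are released
    (collected in ``rejected`` when given).  Returns the validated
    sub-clusters.

    Raises
    ------
    KeyError
        If ``tables`` lacks a needed isotope index.
    """
    out: list[IsotopeCluster] = []
    _walk(list(cluster.peaks), cluster, tables, p_low, p_high, out, rejected)
    return out


def _walk(
    peaks: list[Peak],
    origin: IsotopeCluster,
    tables: dict[int, QuantileTable],
    p_low: float,
    p_high: float,
    out: list[IsotopeCluster],
    rejected: list[Peak] | None,
) -> None:
    if len(peaks) < 2:
        if peaks and rejected is not None:
            rejected.extend(peaks)
        return
    mono = peaks[0]
    mass = mono.mz * origin.charge
    for j in range(1, len(peaks)):
        if j not in tables:
            raise KeyError(f"no quantile table for isotope index {j}")
        q_low, q_high = lookup_interval(tables[j], mass, p_low, p_high)
        observed = ratio_interval(mono.intensity, _sn(mono),
                                  peaks[j].intensity, _sn(peaks[j]))
        if not observed.overlaps(q_low, q_high):
            logger.info(
                "splitting cluster at isotope %d (mass %.3f): observed "
                "[%.3g, %.3g] vs plausible [%.3g, %.3g]",
                j, mass, observed.r_min, observed.r_max, q_low, q_high,
            )
            prefix = peaks[:j]
            if len(prefix) >= 2:
                out.append(
                    IsotopeCluster(peaks=prefix, charge=origin.charge,
                                   validated=True, id=origin.id)
                )
            elif rejected is not None:
                rejected.extend(prefix)
            _walk(peaks[j:], origin, tables, p_low, p_high, out, rejected)
            return
    out.append(
        IsotopeCluster(peaks=peaks, charge=origin.charge, validated=True,
                       id=origin.id)
    )


def validate_clusters(
    clusters: list[IsotopeCluster],
    tables: dict[int, QuantileTable],
    p_low: float = 0.005,
    p_high: float = 0.995,
) -> tuple[list[IsotopeCluster], list[Peak]]:
    """Validate a set of putative clusters.

    Returns the validated clusters (renumbered, sorted by monoisotopic
    m/z) and the peaks released during splitting.
    """
    validated: list[IsotopeCluster] = []
    rejected: list[Peak] = []
    for cluster in clusters:
        validated.extend(
            validate_cluster(cluster, tables, p_low, p_high, rejected=rejected)
        )
    validated.sort(key=lambda c: c.mono.mz)
    for k, cluster in enumerate(validated):
        cluster.id = f"v{k}"
    return validated, rejected
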