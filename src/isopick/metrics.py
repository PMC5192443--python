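"""Peak-picking performance measures.

Isotope coverage is the fraction of detected peaks assigned to isotope
clusters (0 = none, 1 = all); the Peak Picking Score (PPS) is the
number of reliable peaks (cluster members) squared over the number of
non-reliable peaks — peaks that are not in a cluster although one
would expect them to be.  The expectation rule is pluggable; the
default flags non-cluster peaks whose predicted first-isotope
intensity (peak intensity divided by the median mono/1st ratio at its
mass) exceeds the weakest detected intensity in the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .peaks import IsotopeCluster, Peak
from .quantiles import QuantileTable

__all__ = ["EvalSummary", "isotope_coverage", "pps", "default_expectation_rule",
           "evaluate"]

ExpectationRule = Callable[[Peak, Sequence[Peak]], bool]


@dataclass
class EvalSummary:
    n_peaks: int
    n_isotope_peaks: int
    n_clusters: int
    isotope_coverage: float
    pps: float


def _cluster_peak_ids(peaks: Sequence[Peak], clusters: Sequence[IsotopeCluster]) -> set[str]:
    known = {p.id for p in peaks}
    ids: set[str] = set()
    for cluster in clusters:
        for p in cluster.peaks:
            if p.id not in known:
                raise ValueError(f"cluster references unknown peak {p.id!r}")
            ids.add(p.id)
    return ids


def isotope_coverage(
    peaks: Sequence[Peak], clusters: Sequence[IsotopeCluster]
) -> float:
    """Fraction of detected peaks that are members of isotope clusters."""
    if not peaks:
        return 0.0
    return len(_cluster_peak_ids(peaks, clusters)) / len(peaks)


def default_expectation_rule(table: QuantileTable) -> ExpectationRule:
    """Expectation rule from a mono/1st-isotope quantile table.

    A non-cluster peak is expected to have a detectable first isotope
    peak when its intensity divided by the median (p=0.5) mono/1st
    ratio at its mass exceeds the minimum intensity among all peaks in
    the table.
    """

    def rule(peak: Peak, all_peaks: Sequence[Peak]) -> bool:
        min_intensity = min(p.intensity for p in all_peaks)
        median_ratio = table.quantile(peak.mz, 0.5)
        return peak.intensity / median_ratio > min_intensity

    return rule


def pps(
    peaks: Sequence[Peak],
    clusters: Sequence[IsotopeCluster],
    expectation_rule: ExpectationRule | None = None,
) -> float:
    """Peak Picking Score: reliable^2 / non-reliable.

    Reliable peaks are cluster members.  Without an expectation rule
    every non-cluster peak counts as non-reliable.  When no peak is
    non-reliable the score is reliable^2 (convention: a perfect table
    scores high instead of erroring).
    """
    reliable_ids = _cluster_peak_ids(peaks, clusters)
    reliable = len(reliable_ids)
    if reliable == 0:
        return 0.0
    others = [p for p in peaks if p.id not in reliable_ids]
    if expectation_rule is None:
        non_reliable = len(others)
    else:
        non_reliable = sum(1 for p in others if expectation_rule(p, peaks))
    if non_reliable == 0:
        return float(reliable**2)
    return reliable**2 / non_reliable


def evaluate(
    peaks: Sequence[Peak],
    clusters: Sequence[IsotopeCluster],
    expectation_rule: ExpectationRule | None = None,
) -> EvalSummary:
    """All performance measures for one annotated peak table."""
    return EvalSummary(
        n_peaks=len(peaks),
        n_isotope_peaks=len(_cluster_peak_ids(peaks, clusters)),
        n_clusters=len(clusters),
        isotope_coverage=isotope_coverage(peaks, clusters),
        pps=pps(peaks, clusters, expectation_rule),
    )
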