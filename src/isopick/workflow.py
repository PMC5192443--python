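"""End-to-end workflow: targeted picking, detection, validation, metrics.

The stages mirror the untargeted annotation workflow: a traditional
peak table is extended by targeted picking at predicted isotope ROIs
with a relaxed signal-to-noise threshold, the merged table is grouped
into coeluting sets, putative isotope clusters are detected by their
m/z spacings and validated against mass-specific abundance-ratio
confidence intervals, and summary performance measures are computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path

from .detect import find_putative_clusters, group_by_rt
from .metrics import EvalSummary, evaluate
from .peaks import IsotopeCluster, Peak, RawMap
from .quantiles import QuantileTable
from .roi import (
    examine_rois,
    merge_peak_tables,
    predict_isotope_rois,
    relaxed_threshold,
)
from .validate import validate_clusters

logger = logging.getLogger(__name__)

__all__ = ["WorkflowConfig", "WorkflowResult", "run_workflow",
           "load_default_tables", "load_tables", "save_tables"]

DEFAULT_TABLES_RESOURCE = "quantiles_synthetic_w50.json"


@dataclass
class WorkflowConfig:
    """Workflow parameters with the recommended defaults.

    Z/I bound the charge states and isotope numbers of predicted ROIs;
    snthr is the traditional signal-to-noise threshold and r the
    relaxation percentage for targeted picking (snthr' = snthr*r/100);
    abs_tol/ppm_tol parameterize the isotope-spacing test; window_size
    and the p-pair define the validation confidence interval.
    """

    Z: int = 3
    I: int = 5
    snthr: float = 25.0
    r: int = 25
    ppm_tol: float = 0.0
    abs_tol: float = 0.01
    window_size: float = 50.0
    p_low: float = 0.005
    p_high: float = 0.995
    rt_group_window: float = 5.0
    merge_ppm_tol: float = 10.0
    merge_abs_tol: float = 0.005
    merge_rt_tol: float = 5.0
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "WorkflowConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WorkflowResult:
    peaks: list[Peak]
    putative_clusters: list[IsotopeCluster]
    clusters: list[IsotopeCluster]
    rejected_peaks: list[Peak]
    summary: EvalSummary
    stage_counts: dict[str, int] = field(default_factory=dict)


def save_tables(tables: dict[int, QuantileTable], path) -> None:
    with open(path, "w") as fh:
        json.dump({str(i): t.to_dict() for i, t in tables.items()}, fh)


def load_tables(path) -> dict[int, QuantileTable]:
    with open(path) as fh:
        obj = json.load(fh)
    return {int(i): QuantileTable.from_dict(t) for i, t in obj.items()}


def load_default_tables() -> dict[int, QuantileTable]:
    """The bundled quantile tables (synthetic compound database, w=50).

    Prebuilt from 20,000 random formulas (masses 50-1000 Da) with the
    default element profile, so validation works out of the box.
    """
    ref = _importlib_resources.files("isopick.data").joinpath(
        DEFAULT_TABLES_RESOURCE
    )
    with ref.open() as fh:
        obj = json.load(fh)
    return {int(i): QuantileTable.from_dict(t) for i, t in obj.items()}


def run_workflow(
    config: WorkflowConfig,
    peaks: list[Peak],
    raw: RawMap | None = None,
    tables: dict[int, QuantileTable] | None = None,
) -> WorkflowResult:
    """Run the annotation workflow on a traditional peak table.

    When a raw map is supplied, isotope ROIs predicted from ``peaks``
    are examined at the relaxed threshold and the recovered peaks
    merged in; otherwise the supplied table is annotated as is.  An
    empty peak table yields empty outputs and zero metrics.
    """
    if tables is None:
        tables = load_default_tables()
    counts = {"traditional_peaks": len(peaks)}
    merged = list(peaks)
    if raw is not None and peaks:
        iso_rois = predict_isotope_rois(peaks, Z=config.Z, I=config.I)
        snthr_relaxed = relaxed_threshold(config.snthr, config.r)
        targeted = examine_rois(raw, iso_rois, snthr=snthr_relaxed)
        merged = merge_peak_tables(
            peaks, targeted,
            ppm_tol=config.merge_ppm_tol,
            abs_tol=config.merge_abs_tol,
            rt_tol=config.merge_rt_tol,
        )
        counts["isotope_rois"] = len(iso_rois)
        counts["targeted_peaks"] = len(targeted)
    counts["merged_peaks"] = len(merged)

    putative: list[IsotopeCluster] = []
    for group in group_by_rt(merged, rt_window=config.rt_group_window):
        putative.extend(
            find_putative_clusters(
                group, Z=config.Z, ppm_tol=config.ppm_tol, abs_tol=config.abs_tol
            )
        )
    putative.sort(key=lambda c: c.mono.mz)
    for k, cluster in enumerate(putative):
        cluster.id = f"c{k}"
    counts["putative_clusters"] = len(putative)

    validated, rejected = validate_clusters(
        putative, tables, p_low=config.p_low, p_high=config.p_high
    )
    counts["validated_clusters"] = len(validated)
    counts["rejected_peaks"] = len(rejected)

    summary = evaluate(merged, validated)
    for stage, count in counts.items():
        logger.info("%s: %d", stage, count)
    return WorkflowResult(
        peaks=merged,
        putative_clusters=putative,
        clusters=validated,
        rejected_peaks=rejected,
        summary=summary,
        stage_counts=counts,
    )
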