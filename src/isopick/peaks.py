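"""Core LC-MS domain types: peaks, ROIs, raw maps, isotope clusters.

Coordinates are m/z in dalton and retention time in seconds throughout.
CSV column names are the external contract shared by all subcommands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Peak", "ROI", "RawMap", "IsotopeCluster",
           "peaks_to_frame", "peaks_from_frame",
           "rois_to_frame", "rois_from_frame",
           "clusters_to_frame", "clusters_from_frame"]

PROVENANCES = ("traditional", "targeted-isotope", "targeted-noise")


@dataclass
class Peak:
    """One detected LC-MS feature."""

    id: str
    mz: float
    rt: float
    intensity: float
    sn: float = math.inf
    mz_width: float = 0.01
    rt_width: float = 5.0
    provenance: str = "traditional"

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.intensity <= 0 or self.sn <= 0:
            raise ValueError(f"peak {self.id}: mz, intensity and sn must be positive")
        if self.mz_width <= 0 or self.rt_width <= 0:
            raise ValueError(f"peak {self.id}: widths must be positive")


@dataclass
class ROI:
    """Rectangular m/z x retention-time search region.

    ``origin`` is "isotope" (with charge z and isotope number i) for
    predicted isotope ROIs, "noise" for sampled control ROIs, or
    "traditional" for user-supplied regions.
    """

    mz_min: float
    mz_max: float
    rt_min: float
    rt_max: float
    origin: str = "traditional"
    z: int | None = None
    i: int | None = None
    source_peak: str | None = None

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("ROI requires mz_min < mz_max")
        if not self.rt_min < self.rt_max:
            raise ValueError("ROI requires rt_min < rt_max")

    @property
    def provenance(self) -> str:
        return {"isotope": "targeted-isotope", "noise": "targeted-noise"}.get(
            self.origin, "traditional"
        )


@dataclass
class RawMap:
    """Centroided LC-MS raw data: one (rt, mz[], intensity[]) per scan."""

    scan_rts: np.ndarray
    scan_mzs: list[np.ndarray]
    scan_intensities: list[np.ndarray]

    def __post_init__(self) -> None:
        self.scan_rts = np.asarray(self.scan_rts, dtype=float)
        if np.any(np.diff(self.scan_rts) <= 0):
            raise ValueError("scan retention times must be strictly increasing")
        for mz in self.scan_mzs:
            if mz.size > 1 and np.any(np.diff(mz) <= 0):
                raise ValueError("per-scan m/z arrays must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scan_rts)

    @property
    def mz_range(self) -> tuple[float, float]:
        lo = min((mz[0] for mz in self.scan_mzs if mz.size), default=0.0)
        hi = max((mz[-1] for mz in self.scan_mzs if mz.size), default=0.0)
        return lo, hi

    @property
    def rt_range(self) -> tuple[float, float]:
        return float(self.scan_rts[0]), float(self.scan_rts[-1])


@dataclass
class IsotopeCluster:
    """Ordered isotopologue peaks of one analyte; index 0 is monoisotopic."""

    peaks: list[Peak]
    charge: int
    validated: bool = False
    id: str = ""
    #: isotope number of each member peak (0 = monoisotopic)
    isotope_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.peaks) < 2:
            raise ValueError("an isotope cluster needs at least two peaks")
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("cluster peak m/z must be strictly increasing")
        if not self.isotope_numbers:
            self.isotope_numbers = list(range(len(self.peaks)))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mono(self) -> Peak:
        return self.peaks[0]

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic m/z scaled by charge (proton mass ignored)."""
        return self.mono.mz * self.charge


# ---------------------------------------------------------------------------
# DataFrame converters (CSV contract)

PEAK_COLUMNS = ["id", "mz", "rt", "intensity", "sn", "mz_width", "rt_width",
                "provenance"]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [[p.id, p.mz, p.rt, p.intensity, p.sn, p.mz_width, p.rt_width, p.provenance]
         for p in peaks],
        columns=PEAK_COLUMNS,
    )


def peaks_from_frame(df: pd.DataFrame) -> list[Peak]:
    return [
        Peak(
            id=str(row.id),
            mz=float(row.mz),
            rt=float(row.rt),
            intensity=float(row.intensity),
            sn=float(row.sn) if not pd.isna(row.sn) else math.inf,
            mz_width=float(row.mz_width),
            rt_width=float(row.rt_width),
            provenance=str(row.provenance),
        )
        for row in df.itertuples(index=False)
    ]


ROI_COLUMNS = ["mz_min", "mz_max", "rt_min", "rt_max", "origin", "z", "i",
               "source_peak"]


def rois_to_frame(rois: list[ROI]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.mz_min, r.mz_max, r.rt_min, r.rt_max, r.origin, r.z, r.i, r.source_peak]
         for r in rois],
        columns=ROI_COLUMNS,
    )


def rois_from_frame(df: pd.DataFrame) -> list[ROI]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ROI(
                mz_min=float(row.mz_min),
                mz_max=float(row.mz_max),
                rt_min=float(row.rt_min),
                rt_max=float(row.rt_max),
                origin=str(row.origin),
                z=None if pd.isna(row.z) else int(row.z),
                i=None if pd.isna(row.i) else int(row.i),
                source_peak=None if pd.isna(row.source_peak) else str(row.source_peak),
            )
        )
    return out


CLUSTER_COLUMNS = ["cluster_id", "charge", "validated", "isotope_index",
                   "peak_id", "mz", "rt", "intensity", "sn", "mz_width",
                   "rt_width", "provenance"]


def clusters_to_frame(clusters: list[IsotopeCluster]) -> pd.DataFrame:
    rows = []
    for ci, cluster in enumerate(clusters):
        cid = cluster.id or f"c{ci}"
        for iso, p in zip(cluster.isotope_numbers, cluster.peaks):
            rows.append([cid, cluster.charge, cluster.validated, iso, p.id,
                         p.mz, p.rt, p.intensity, p.sn, p.mz_width, p.rt_width,
                         p.provenance])
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def clusters_from_frame(df: pd.DataFrame) -> list[IsotopeCluster]:
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=False):
        grp = grp.sort_values("isotope_index").rename(columns={"peak_id": "id"})
        peaks = peaks_from_frame(grp[PEAK_COLUMNS])
        clusters.append(
            IsotopeCluster(
                peaks=peaks,
                charge=int(grp.charge.iloc[0]),
                validated=bool(grp.validated.iloc[0]),
                id=str(cid),
                isotope_numbers=[int(v) for v in grp.isotope_index],
            )
        )
    return clusters
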