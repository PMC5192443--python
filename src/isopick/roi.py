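"""Targeted peak picking with predicted isotope ROIs.

Given a table of previously detected peaks, one putative isotope ROI is
predicted per peak, charge state z in 1..Z, and isotope number i in
1..I: the peak's retention-time interval combined with its m/z interval
shifted by i*Δm/z, Δm = mass(13C) - mass(12C) = 1.003355.  ROIs are
then examined in the raw data at a relaxed signal-to-noise threshold
snthr' = snthr * r / 100, and the resulting targeted peak table is
merged with the traditional one, dropping redundant peaks.  Matched
noise ROIs, sampled from the empirical distribution of ROI centers and
peak widths, serve as a specificity control.
"""

from __future__ import annotations

import logging

import numpy as np

from .elements import DELTA_M
from .peaks import Peak, RawMap, ROI

logger = logging.getLogger(__name__)

__all__ = [
    "isotope_mz_shift",
    "predict_isotope_rois",
    "sample_noise_rois",
    "relaxed_threshold",
    "examine_rois",
    "merge_peak_tables",
]

#: allowed relaxation percentages for the signal-to-noise threshold
R_GRID = tuple(range(5, 101, 5))


def isotope_mz_shift(z: int, i: int) -> float:
    """Theoretical m/z distance i*Δm/z of the i-th isotope peak at charge z."""
    if z < 1 or i < 1:
        raise ValueError("charge z and isotope number i must be >= 1")
    return i * DELTA_M / z


def predict_isotope_rois(
    peaks: list[Peak], Z: int = 3, I: int = 5
) -> list[ROI]:
    """Predict one putative isotope ROI per peak, charge and isotope number.

    Each ROI keeps the source peak's retention-time interval and shifts
    its m/z interval by ``isotope_mz_shift(z, i)``; the origin records
    (z, i) and the source peak id.  Returns ``len(peaks) * Z * I`` ROIs.
    """
    if Z < 1 or I < 1:
        raise ValueError("Z and I must be >= 1")
    rois: list[ROI] = []
    for peak in peaks:
        half_mz = peak.mz_width / 2.0
        half_rt = peak.rt_width / 2.0
        for z in range(1, Z + 1):
            for i in range(1, I + 1):
                shift = isotope_mz_shift(z, i)
                rois.append(
                    ROI(
                        mz_min=peak.mz - half_mz + shift,
                        mz_max=peak.mz + half_mz + shift,
                        rt_min=peak.rt - half_rt,
                        rt_max=peak.rt + half_rt,
                        origin="isotope",
                        z=z,
                        i=i,
                        source_peak=peak.id,
                    )
                )
    return rois


def _sample_from_histogram(
    rng: np.random.Generator, values: np.ndarray, size: int, bins: int = 50
) -> np.ndarray:
    """Draw from the empirical histogram: bin by frequency, uniform within."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot sample from an empty histogram")
    counts, edges = np.histogram(values, bins=bins)
    probs = counts / counts.sum()
    which = rng.choice(len(counts), size=size, p=probs)
    return rng.uniform(edges[which], edges[which + 1])


def sample_noise_rois(
    iso_rois: list[ROI], peaks: list[Peak], seed: int = 0
) -> list[ROI]:
    """Sample one matched noise ROI per predicted isotope ROI.

    ROI centers are drawn uniformly within the bounding box of the
    predicted isotope ROI centers; m/z widths are drawn from the
    histogram of detected relative peak widths (width/mz, scaled by the
    sampled m/z) and rt widths from the histogram of detected rt
    widths.  Deterministic for a fixed seed.
    """
    if not iso_rois:
        raise ValueError("no isotope ROIs to match")
    rng = np.random.default_rng(seed)
    centers_mz = np.array([(r.mz_min + r.mz_max) / 2 for r in iso_rois])
    centers_rt = np.array([(r.rt_min + r.rt_max) / 2 for r in iso_rois])
    n = len(iso_rois)
    mz = rng.uniform(centers_mz.min(), centers_mz.max(), size=n)
    rt = rng.uniform(centers_rt.min(), centers_rt.max(), size=n)
    rel_widths = np.array([p.mz_width / p.mz for p in peaks])
    rt_widths = np.array([p.rt_width for p in peaks])
    mz_w = _sample_from_histogram(rng, rel_widths, n) * mz
    rt_w = _sample_from_histogram(rng, rt_widths, n)
    mz_w = np.maximum(mz_w, 1e-6)
    rt_w = np.maximum(rt_w, 1e-3)
    return [
        ROI(
            mz_min=float(m - w / 2),
            mz_max=float(m + w / 2),
            rt_min=float(t - v / 2),
            rt_max=float(t + v / 2),
            origin="noise",
        )
        for m, t, w, v in zip(mz, rt, mz_w, rt_w)
    ]


def relaxed_threshold(snthr: float, r: int) -> float:
    """Relaxed signal-to-noise threshold snthr' = snthr * r / 100.

    ``r`` must lie on the 5..100 percent grid in steps of 5.
    """
    if snthr <= 0:
        raise ValueError("snthr must be positive")
    if r not in R_GRID:
        raise ValueError(f"relaxation r={r} not in {{5, 10, ..., 100}}")
    return snthr * r / 100.0


def _roi_trace(
    raw: RawMap, mz_min: float, mz_max: float, lo: int, hi: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extracted-ion trace: per scan in [lo, hi), the max intensity and its m/z."""
    rts = raw.scan_rts[lo:hi]
    inten = np.zeros(hi - lo)
    mzs = np.zeros(hi - lo)
    for k in range(lo, hi):
        mz_arr = raw.scan_mzs[k]
        a = np.searchsorted(mz_arr, mz_min, side="left")
        b = np.searchsorted(mz_arr, mz_max, side="right")
        if b > a:
            seg = raw.scan_intensities[k][a:b]
            j = int(np.argmax(seg))
            inten[k - lo] = seg[j]
            mzs[k - lo] = mz_arr[a + j]
    return rts, inten, mzs


def _local_noise(
    raw: RawMap,
    mz_center: float,
    band: float,
    lo: int,
    hi: int,
    exclude: tuple[int, int],
) -> float:
    """Median positive centroid intensity near the ROI, floored at 1 count.

    All centroids within ``mz_center ± band`` across scans [lo, hi),
    excluding the peak's scan span, probe the local noise floor.
    """
    values: list[np.ndarray] = []
    for k in range(lo, hi):
        if exclude[0] <= k <= exclude[1]:
            continue
        mz_arr = raw.scan_mzs[k]
        a = np.searchsorted(mz_arr, mz_center - band, side="left")
        b = np.searchsorted(mz_arr, mz_center + band, side="right")
        if b > a:
            values.append(raw.scan_intensities[k][a:b])
    if not values:
        return 1.0
    pooled = np.concatenate(values)
    pooled = pooled[pooled > 0]
    if pooled.size == 0:
        return 1.0
    return max(float(np.median(pooled)), 1.0)


def examine_rois(
    raw: RawMap,
    rois: list[ROI],
    snthr: float = 25.0,
    min_points: int = 3,
    noise_band: float = 0.5,
    noise_rt_factor: float = 3.0,
) -> list[Peak]:
    """Examine ROIs for chromatographic peaks (lightweight ROI examination).

    For each ROI the extracted-ion trace is built, the most intense
    point inside the ROI taken as the apex, the local noise estimated
    as the median positive centroid intensity within ``noise_band`` Da
    of the ROI center over an rt window extended by ``noise_rt_factor``
    times the ROI span on both sides (the apex's half-height span is
    excluded; the estimate is floored at 1 count), and a peak emitted
    when apex/noise >= ``snthr``.  The peak intensity is the
    trapezoidal area of the half-height span.  This is intentionally
    simple — where to look is the point, not the wavelet machinery —
    and externally produced peak tables can be supplied instead
    wherever a peak list is accepted.
    """
    mz_lo, mz_hi = raw.mz_range
    rt_lo, rt_hi = raw.rt_range
    found: list[Peak] = []
    n_skipped = 0
    for ri, roi in enumerate(rois):
        if roi.mz_max < mz_lo or roi.mz_min > mz_hi or roi.rt_max < rt_lo \
                or roi.rt_min > rt_hi:
            n_skipped += 1
            continue
        pad = noise_rt_factor * (roi.rt_max - roi.rt_min)
        lo = int(np.searchsorted(raw.scan_rts, roi.rt_min - pad, side="left"))
        hi = int(np.searchsorted(raw.scan_rts, roi.rt_max + pad, side="right"))
        rts, inten, mzs = _roi_trace(raw, roi.mz_min, roi.mz_max, lo, hi)
        in_roi = (rts >= roi.rt_min) & (rts <= roi.rt_max)
        if np.count_nonzero(in_roi) < min_points or not np.any(inten[in_roi] > 0):
            continue
        apex = int(np.argmax(np.where(in_roi, inten, -np.inf)))
        half = inten[apex] / 2.0
        left = apex
        while left > 0 and inten[left - 1] >= half:
            left -= 1
        right = apex
        while right < inten.size - 1 and inten[right + 1] >= half:
            right += 1
        # exclude the full chromatographic peak from the noise estimate:
        # extend the half-height span outward while the trace keeps falling
        ex_left = left
        while ex_left > 0 and inten[ex_left - 1] <= inten[ex_left]:
            ex_left -= 1
        ex_right = right
        while ex_right < inten.size - 1 and inten[ex_right + 1] <= inten[ex_right]:
            ex_right += 1
        noise = _local_noise(
            raw,
            (roi.mz_min + roi.mz_max) / 2.0,
            noise_band,
            lo,
            hi,
            exclude=(lo + ex_left, lo + ex_right),
        )
        sn = inten[apex] / noise
        if sn < snthr:
            continue
        span = slice(left, right + 1)
        if right > left:
            area = float(np.trapezoid(inten[span], rts[span]))
        else:
            area = float(inten[apex])
        area = max(area, float(inten[apex]))
        in_span = inten[span] > 0
        mz_vals = mzs[span][in_span]
        weights = inten[span][in_span]
        mz = float(np.average(mz_vals, weights=weights))
        mz_width = max(float(mz_vals.max() - mz_vals.min()), 1e-4)
        rt_width = max(float(rts[right] - rts[left]),
                       float(np.min(np.diff(raw.scan_rts))) if len(raw) > 1 else 1.0)
        prefix = {"traditional": "t", "targeted-isotope": "i",
                  "targeted-noise": "n"}[roi.provenance]
        found.append(
            Peak(
                id=f"{prefix}{ri}",
                mz=mz,
                rt=float(rts[apex]),
                intensity=area,
                sn=float(sn),
                mz_width=mz_width,
                rt_width=rt_width,
                provenance=roi.provenance,
            )
        )
    if n_skipped:
        logger.info("skipped %d ROIs outside the raw map range", n_skipped)
    return found


def merge_peak_tables(
    base: list[Peak],
    added: list[Peak],
    ppm_tol: float = 10.0,
    abs_tol: float = 0.005,
    rt_tol: float = 5.0,
) -> list[Peak]:
    """Merge two peak tables, dropping added peaks redundant with base.

    An added peak is redundant when some already retained peak (from
    the base table or an earlier added peak) lies within
    ``max(mz * ppm_tol / 1e6, abs_tol)`` in m/z and ``rt_tol`` in
    retention time.  Base peaks are always retained; the result is
    sorted by (rt, mz).
    """
    if ppm_tol < 0 or abs_tol < 0 or rt_tol < 0:
        raise ValueError("tolerances must be non-negative")
    kept = list(base)
    for peak in added:
        tol = max(peak.mz * ppm_tol / 1e6, abs_tol)
        redundant = any(
            abs(q.mz - peak.mz) <= tol and abs(q.rt - peak.rt) <= rt_tol
            for q in kept
        )
        if not redundant:
            kept.append(peak)
    return sorted(kept, key=lambda p: (p.rt, p.mz))
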