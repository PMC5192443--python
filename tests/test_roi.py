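"""Isotope ROI prediction, noise ROIs, and targeted peak picking."""

import numpy as np
import pytest

from conftest import make_peaks
from isopick.elements import DELTA_M
from isopick.peaks import ROI
from isopick.roi import (
    examine_rois,
    isotope_mz_shift,
    merge_peak_tables,
    predict_isotope_rois,
    relaxed_threshold,
    sample_noise_rois,
)
from isopick.simulate import PlantedCompound, SimulationConfig, simulate_raw_map


class TestIsotopeMzShift:
    @pytest.mark.parametrize(
        "z,i,expected",
        [(1, 1, 1.003355), (2, 2, 1.003355), (3, 5, 1.672258), (1, 5, 5.016775)],
    )
    def test_examples(self, z, i, expected):
        assert isotope_mz_shift(z, i) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("z,i", [(0, 1), (1, 0), (-1, 2)])
    def test_invalid(self, z, i):
        with pytest.raises(ValueError):
            isotope_mz_shift(z, i)


class TestPredictIsotopeRois:
    def test_counts_and_geometry(self):
        peaks = make_peaks([363.075], rt=291.0)
        rois = predict_isotope_rois(peaks, Z=3, I=5)
        assert len(rois) == 15
        assert all(r.rt_min == peaks[0].rt - peaks[0].rt_width / 2 for r in rois)
        z1 = sorted(
            ((r.mz_min + r.mz_max) / 2 for r in rois if r.z == 1)
        )
        expected = [363.075 + i * DELTA_M for i in range(1, 6)]
        np.testing.assert_allclose(z1, expected, atol=1e-9)

    def test_two_peaks_single_isotope(self):
        peaks = make_peaks([200.0, 300.0])
        rois = predict_isotope_rois(peaks, Z=1, I=1)
        centers = sorted((r.mz_min + r.mz_max) / 2 for r in rois)
        np.testing.assert_allclose(
            centers, [200.0 + DELTA_M, 300.0 + DELTA_M]
        )

    def test_empty_peaks_empty_rois(self):
        assert predict_isotope_rois([], Z=3, I=5) == []

    def test_origin_records_source(self):
        peaks = make_peaks([250.0])
        rois = predict_isotope_rois(peaks, Z=2, I=2)
        assert {(r.z, r.i) for r in rois} == {(1, 1), (1, 2), (2, 1), (2, 2)}
        assert all(r.source_peak == "p0" and r.origin == "isotope" for r in rois)

    def test_order_invariance(self):
        peaks = make_peaks([150.0, 400.0, 220.0])
        a = predict_isotope_rois(peaks, Z=2, I=3)
        b = predict_isotope_rois(peaks[::-1], Z=2, I=3)
        key = lambda r: (r.mz_min, r.z, r.i)
        assert sorted(((r.mz_min, r.z, r.i) for r in a)) == sorted(
            ((r.mz_min, r.z, r.i) for r in b)
        )


class TestSampleNoiseRois:
    def test_matched_count_envelope_and_determinism(self):
        peaks = make_peaks([200.0, 320.0, 480.0], rt=50.0)
        iso = predict_isotope_rois(peaks, Z=3, I=5)
        noise = sample_noise_rois(iso, peaks, seed=42)
        assert len(noise) == len(iso)
        centers_mz = [(r.mz_min + r.mz_max) / 2 for r in iso]
        centers_rt = [(r.rt_min + r.rt_max) / 2 for r in iso]
        for r in noise:
            assert min(centers_mz) <= (r.mz_min + r.mz_max) / 2 <= max(centers_mz)
            assert min(centers_rt) <= (r.rt_min + r.rt_max) / 2 <= max(centers_rt)
            assert r.origin == "noise"
        again = sample_noise_rois(iso, peaks, seed=42)
        assert [(r.mz_min, r.rt_min) for r in noise] == [
            (r.mz_min, r.rt_min) for r in again
        ]
        other = sample_noise_rois(iso, peaks, seed=43)
        assert [(r.mz_min, r.rt_min) for r in noise] != [
            (r.mz_min, r.rt_min) for r in other
        ]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sample_noise_rois([], make_peaks([100.0]), seed=0)


class TestRelaxedThreshold:
    @pytest.mark.parametrize(
        "snthr,r,expected", [(25, 25, 6.25), (25, 100, 25.0), (10, 5, 0.5)]
    )
    def test_examples(self, snthr, r, expected):
        assert relaxed_threshold(snthr, r) == pytest.approx(expected)

    @pytest.mark.parametrize("snthr,r", [(25, 3), (25, 101), (25, 24), (0, 50)])
    def test_invalid(self, snthr, r):
        with pytest.raises(ValueError):
            relaxed_threshold(snthr, r)


def _planted_map(seed=0, apex=2.0e4):
    config = SimulationConfig(
        compounds=[PlantedCompound("C12H22O11", 60.0, apex)],
        rt_range=(0.0, 120.0),
        mz_range=(330.0, 352.0),
        noise_peaks_per_scan=2200,
        noise_level=100.0,
        seed=seed,
    )
    return simulate_raw_map(config)


class TestExamineRois:
    def test_planted_peak_found_above_threshold_only(self):
        raw, ledger = _planted_map()
        mono = ledger[ledger.isotope == 0].iloc[0]
        roi = ROI(mz_min=mono.mz - 0.01, mz_max=mono.mz + 0.01,
                  rt_min=mono.rt - 10, rt_max=mono.rt + 10)
        found = examine_rois(raw, [roi], snthr=6.25)
        assert len(found) == 1
        peak = found[0]
        assert peak.mz == pytest.approx(mono.mz, abs=0.01)
        assert peak.rt == pytest.approx(mono.rt, abs=3.0)
        assert peak.sn == pytest.approx(mono.true_sn, rel=0.5)
        # same ROI at a threshold above the planted S/N: nothing
        assert examine_rois(raw, [roi], snthr=10 * mono.true_sn) == []

    def test_roi_outside_map_skipped(self):
        raw, _ = _planted_map()
        outside = ROI(mz_min=900.0, mz_max=900.1, rt_min=10, rt_max=20)
        assert examine_rois(raw, [outside], snthr=5) == []

    def test_noiseless_map_recovers_all_isotopologues(self):
        config = SimulationConfig(
            compounds=[PlantedCompound("C12H22O11", 60.0, 1.0e5)],
            rt_range=(0.0, 120.0),
            mz_range=(330.0, 352.0),
            noise_peaks_per_scan=0,
            noise_level=0.0,
            mz_jitter=0.0,
            seed=1,
        )
        raw, ledger = simulate_raw_map(config)
        planted = ledger[ledger.apex_intensity >= 2.0]
        rois = [
            ROI(mz_min=row.mz - 0.01, mz_max=row.mz + 0.01,
                rt_min=row.rt - 10, rt_max=row.rt + 10)
            for _, row in planted.iterrows()
        ]
        found = examine_rois(raw, rois, snthr=25.0)
        assert len(found) == len(rois)


class TestMergePeakTables:
    def test_full_redundancy(self):
        base = make_peaks([100.0, 200.0])
        merged = merge_peak_tables(base, base, abs_tol=0.01, rt_tol=5)
        assert [p.id for p in merged] == [p.id for p in base]

    def test_disjoint_concatenation(self):
        base = make_peaks([100.0, 200.0])
        added = make_peaks([300.0, 400.0])
        merged = merge_peak_tables(base, added, abs_tol=0.01, rt_tol=5)
        assert len(merged) == 4
        assert merged == sorted(merged, key=lambda p: (p.rt, p.mz))

    def test_matches_quadratic_dedup_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = make_peaks(np.sort(rng.uniform(100, 110, 25)),
                              rng.uniform(10, 1e4, 25),
                              rt=float(rng.uniform(10, 20)))
            added = make_peaks(np.sort(rng.uniform(100, 110, 25)),
                               rng.uniform(10, 1e4, 25),
                               rt=float(rng.uniform(10, 20)))
            merged = merge_peak_tables(base, added, ppm_tol=0.0,
                                       abs_tol=0.05, rt_tol=5.0)
            # quadratic oracle: incrementally keep non-redundant peaks
            kept = list(base)
            for p in added:
                if not any(
                    abs(q.mz - p.mz) <= 0.05 and abs(q.rt - p.rt) <= 5.0
                    for q in kept
                ):
                    kept.append(p)
            assert len(merged) == len(kept)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        base = make_peaks(np.sort(rng.uniform(100, 105, 10)))
        added = make_peaks(np.sort(rng.uniform(100, 105, 10)), rt=101.0)
        once = merge_peak_tables(base, added, abs_tol=0.02, rt_tol=2.0)
        twice = merge_peak_tables(once, added, abs_tol=0.02, rt_tol=2.0)
        assert [(p.id, p.mz) for p in once] == [(p.id, p.mz) for p in twice]
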