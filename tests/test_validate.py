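"""Mass-specific cluster validation and deconvolution."""

import math

import numpy as np
import pytest

from conftest import make_peaks
from isopick.detect import find_putative_clusters
from isopick.peaks import IsotopeCluster, Peak
from isopick.quantiles import build_quantile_tables
from isopick.simulate import reference_spectrum
from isopick.validate import (
    RatioInterval,
    ratio_interval,
    validate_cluster,
    validate_clusters,
)


class TestRatioInterval:
    def test_noiseless_point_ratio(self):
        ri = ratio_interval(100.0, math.inf, 5.0, math.inf)
        assert (ri.r_min, ri.r_max) == (20.0, 20.0)

    def test_noise_widens_the_bracket(self):
        ri = ratio_interval(100.0, 10.0, 5.0, 10.0)
        assert ri.r_min == pytest.approx(90 / 5.5, abs=0.01)
        assert ri.r_max == pytest.approx(110 / 4.5, abs=0.01)

    @pytest.mark.parametrize(
        "a1,sn1,a2,sn2",
        [(100, 10, 5, 10), (1, 2, 1000, 3), (7, math.inf, 3, 5), (50, 1.5, 2, 1.1)],
    )
    def test_brackets_point_ratio(self, a1, sn1, a2, sn2):
        ri = ratio_interval(a1, sn1, a2, sn2)
        assert ri.r_min <= a1 / a2 <= ri.r_max

    def test_nonpositive_inputs_raise(self):
        for bad in [(0, 1, 1, 1), (1, 0, 1, 1), (1, 1, -2, 1), (1, 1, 1, 0)]:
            with pytest.raises(ValueError):
                ratio_interval(*bad)

    def test_interval_invariant(self):
        with pytest.raises(ValueError):
            RatioInterval(5.0, 2.0)


def _cluster_from_pattern(intensities, mono_mz=250.0, sn=math.inf, charge=1):
    from isopick.elements import DELTA_M

    mzs = mono_mz + DELTA_M * np.arange(len(intensities))
    peaks = make_peaks(mzs, intensities, sn=sn)
    return IsotopeCluster(peaks=peaks, charge=charge)


class TestValidateCluster:
    def test_reference_clusters_intact_except_boron_compound(
        self, reference_peaks, default_tables
    ):
        clusters = find_putative_clusters(reference_peaks, Z=3, abs_tol=0.01)
        validated, rejected = validate_clusters(clusters, default_tables)
        assert len(validated) == 6
        assert [p.id for p in rejected] == ["autoinducer-2:0"]
        by_substance = {c.mono.id.split(":")[0]: c for c in validated}
        assert len(by_substance["autoinducer-2"]) == 5
        assert by_substance["autoinducer-2"].mono.mz == pytest.approx(
            193.052059
        )
        for name, size in [("aspartic acid", 4), ("cysteine", 5),
                           ("chloramphenicol", 6),
                           ("digoxigenin monodigitoxoside", 6)]:
            assert len(by_substance[name]) == size

    def test_median_ratio_cluster_returned_unchanged(self, default_tables):
        """A cluster sitting exactly on the database median validates."""
        mono_mz = 275.0
        intensities = [100.0]
        for i in (1, 2, 3):
            intensities.append(100.0 / default_tables[i].quantile(mono_mz, 0.5))
        cluster = _cluster_from_pattern(intensities, mono_mz)
        out = validate_cluster(cluster, default_tables)
        assert len(out) == 1
        assert [p.id for p in out[0].peaks] == [p.id for p in cluster.peaks]
        assert out[0].validated

    def test_overlapping_clusters_are_deconvolved(self, default_tables):
        """Two reference patterns chained by a spurious link split apart."""
        from isopick.elements import DELTA_M

        a = reference_spectrum(["aspartic acid"])  # 133.04..136.04
        b = reference_spectrum(["cysteine"])  # 121.02..125.02
        # shift the second pattern so its mono continues the first chain
        shift = (a[-1].mz + DELTA_M) - b[0].mz
        for p in b:
            p.mz += shift
        merged = sorted(a + b, key=lambda p: p.mz)
        clusters = find_putative_clusters(merged, Z=3, abs_tol=0.01)
        assert len(clusters) == 1 and len(clusters[0]) == 9
        validated, _ = validate_clusters(clusters, default_tables)
        assert len(validated) == 2
        assert [len(c) for c in validated] == [4, 5]
        assert validated[0].mono.id == "aspartic acid:0"
        assert validated[1].mono.id == "cysteine:0"

    def test_underestimated_trailing_peak_removed(self, default_tables):
        """A trailing peak 100x too weak is truncated from the cluster."""
        peaks = reference_spectrum(["digoxigenin monodigitoxoside"])
        weak = peaks[-1]
        peaks[-1] = Peak(id=weak.id, mz=weak.mz, rt=weak.rt,
                         intensity=weak.intensity / 100.0, sn=weak.sn)
        cluster = IsotopeCluster(peaks=peaks, charge=1)
        validated, rejected = validate_clusters([cluster], default_tables)
        assert len(validated) == 1
        assert len(validated[0]) == 5
        assert [p.id for p in rejected] == [weak.id]

    def test_hydrogen_loss_prefix_released(self, default_tables):
        """A weak satellite ahead of the true mono is released alone."""
        peaks = reference_spectrum(["aspartic acid"])
        satellite = Peak(id="hloss", mz=peaks[0].mz - 1.00335,
                         rt=peaks[0].rt, intensity=0.5, sn=math.inf)
        cluster = IsotopeCluster(peaks=[satellite] + peaks, charge=1)
        validated, rejected = validate_clusters([cluster], default_tables)
        assert [p.id for p in rejected] == ["hloss"]
        assert len(validated) == 1 and len(validated[0]) == 4
        assert validated[0].mono.id == "aspartic acid:0"

    def test_missing_table_index_raises(self, default_tables):
        cluster = _cluster_from_pattern([100, 10, 2, 0.5, 0.1, 0.02])
        partial = {1: default_tables[1], 2: default_tables[2]}
        with pytest.raises(KeyError):
            validate_cluster(cluster, partial)

    def test_validation_idempotent(self, reference_peaks, default_tables):
        clusters = find_putative_clusters(reference_peaks, Z=3, abs_tol=0.01)
        once, _ = validate_clusters(clusters, default_tables)
        twice, rejected = validate_clusters(once, default_tables)
        assert rejected == []
        assert [[p.id for p in c.peaks] for c in twice] == [
            [p.id for p in c.peaks] for c in once
        ]

    def test_output_peaks_subset_order_preserved(self, default_tables):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            intensities = 100.0 * rng.uniform(1e-4, 1.0, size=n)
            intensities[0] = 100.0
            mono_mz = float(rng.uniform(60.0, 900.0))
            cluster = _cluster_from_pattern(intensities, mono_mz,
                                            sn=float(rng.uniform(3, 50)))
            out = validate_cluster(cluster, default_tables)
            input_ids = [p.id for p in cluster.peaks]
            seen = []
            for c in out:
                assert len(c) >= 2 and c.validated
                seen.extend(p.id for p in c.peaks)
            assert [i for i in input_ids if i in set(seen)] == seen

    def test_lower_sn_is_monotonically_lenient(self, default_tables):
        """Wider observed ratio intervals can only relax each comparison."""
        rng = np.random.default_rng(7)
        # unit level: the bracket widens monotonically as S/N drops
        for _ in range(50):
            a1, a2 = rng.uniform(1.0, 1e4, size=2)
            hi = ratio_interval(a1, 20.0, a2, 20.0)
            lo = ratio_interval(a1, 4.0, a2, 4.0)
            assert lo.r_min <= hi.r_min and lo.r_max >= hi.r_max
        # cluster level: a cluster accepted intact at infinite S/N stays
        # intact at any finite S/N (clusters drawn from theoretical
        # patterns of random database-like formulas)
        from isopick.pattern import theoretical_pattern
        from isopick.simulate import simulate_formula_db

        intact_checked = 0
        for k, formula in enumerate(simulate_formula_db(30, (80, 800), seed=3)):
            pat = theoretical_pattern(formula, prune_threshold=0.5)
            if len(pat) < 3:
                continue
            rel = 100.0 * pat.intensities / pat.mono_intensity
            strict = _cluster_from_pattern(rel, pat.mono_mass, sn=math.inf)
            out = validate_cluster(strict, default_tables)
            if len(out) == 1 and len(out[0]) == len(rel):
                loose = _cluster_from_pattern(
                    rel, pat.mono_mass, sn=float(rng.uniform(2.0, 30.0))
                )
                out_loose = validate_cluster(loose, default_tables)
                assert len(out_loose) == 1 and len(out_loose[0]) == len(rel)
                intact_checked += 1
        assert intact_checked > 0
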