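"""Signal-to-noise statistics, twin alignment and the D/S classification."""
import numpy as np
import pandas as pd
import pytest

import methylvar as mv
from methylvar.snr import (SNR_CAP, IneligibleSeries, snr_cloud_probe,
                           snr_trajectories_probe, snr_twin_pairs_probe,
                           twin_alignment)

from conftest import make_cohort


class TestTrajectorySnr:
    def test_hand_worked_example(self):
        # fit 0.3 + 0.005*age; deviations 0.05, 0.1, 0.05 -> (11+6+13)/3
        assert mv.snr_trajectory([50, 60, 70], [0.5, 0.7, 0.6]) == \
            pytest.approx(10.0, abs=1e-12)

    def test_perfect_line_maps_to_cap(self):
        assert mv.snr_trajectory([50, 60, 70], [0.5, 0.6, 0.7]) == SNR_CAP

    def test_scale_invariance(self):
        a = mv.snr_trajectory([50, 60, 70], [0.2, 0.35, 0.3])
        b = mv.snr_trajectory([50, 60, 70], [0.4, 0.7, 0.6])
        assert a == pytest.approx(b, rel=1e-12)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(IneligibleSeries):
            mv.snr_trajectory([50, 60], [0.5, 0.6])
        with pytest.raises(IneligibleSeries):
            mv.snr_trajectory([50, 50, 60], [0.5, 0.6, 0.7])

    def test_probe_mean_over_individuals(self):
        # two individuals, one ineligible (2 visits) is skipped
        ages = [50, 60, 70, 50, 60, 70, 55, 58]
        inds = ["a"] * 3 + ["b"] * 3 + ["c"] * 2
        vals = [0.5, 0.7, 0.6, 0.25, 0.35, 0.3, 0.4, 0.5]
        cohort = make_cohort([vals], ages=ages, individual_ids=inds)
        expected = np.mean([mv.snr_trajectory([50, 60, 70], [0.5, 0.7, 0.6]),
                            mv.snr_trajectory([50, 60, 70], [0.25, 0.35, 0.3])])
        got = snr_trajectories_probe(cohort, "cg00000")
        assert got == pytest.approx(expected, rel=1e-12)


class TestTwinAlignment:
    def test_interpolation_inside_span(self):
        ages, va, vb = mv.align_twin_points([60, 70], [0.4, 0.6], [65], [0.55])
        assert list(ages) == [65]
        assert va[0] == pytest.approx(0.5)
        assert vb[0] == pytest.approx(0.55)
        # a single synchronized point is below the P >= 2 eligibility bar
        with pytest.raises(IneligibleSeries):
            mv.snr_twin_pair(va, vb)

    def test_identical_schedules_align_exactly(self):
        ages, va, vb = mv.align_twin_points([60, 70], [0.4, 0.6],
                                            [60, 70], [0.5, 0.7])
        assert list(ages) == [60, 70]
        assert np.allclose(va, [0.4, 0.6])
        assert np.allclose(vb, [0.5, 0.7])

    def test_no_extrapolation_outside_span(self):
        # B measured before A's first age: that point is dropped
        ages, _, _ = mv.align_twin_points([60, 70], [0.4, 0.6],
                                          [55, 60, 70], [0.3, 0.5, 0.7])
        assert list(ages) == [60, 70]

    def test_weight_matrices_reproduce_interpolation(self):
        ages, Wa, Wb = twin_alignment(np.array([60.0, 70.0]),
                                      np.array([65.0, 70.0]))
        va = Wa @ np.array([0.4, 0.6])
        assert list(ages) == [65, 70]
        assert va[0] == pytest.approx(0.5)


class TestTwinSnr:
    def test_hand_worked_example(self):
        # sigma_s = 0.1, 0.1 -> (5 + 6) / 2
        assert mv.snr_twin_pair([0.6, 0.7], [0.4, 0.5]) == \
            pytest.approx(5.5, abs=1e-12)

    def test_identical_twins_map_to_cap(self):
        assert mv.snr_twin_pair([0.5, 0.6], [0.5, 0.6]) == SNR_CAP

    def test_probe_averages_over_pairs(self):
        ages = [60, 70] * 4
        inds = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
        pairs = ["tpA"] * 4 + ["tpB"] * 4
        vals = [0.6, 0.7, 0.4, 0.5,            # pair A: SNR 5.5
                0.62, 0.72, 0.38, 0.48]        # pair B: sigma 0.12 each
        cohort = make_cohort([vals], ages=ages, individual_ids=inds,
                             twin_pair_ids=pairs)
        pair_b = mv.snr_twin_pair([0.62, 0.72], [0.38, 0.48])
        got = snr_twin_pairs_probe(cohort, "cg00000")
        assert got == pytest.approx((5.5 + pair_b) / 2, rel=1e-12)

    def test_opposite_sex_pairs_are_excluded(self):
        ages = [60, 70] * 2
        cohort = make_cohort([[0.6, 0.7, 0.4, 0.5]], ages=ages,
                             individual_ids=["a1", "a1", "a2", "a2"],
                             sexes=["male", "male", "female", "female"],
                             twin_pair_ids=["tpA"] * 4)
        assert np.isnan(snr_twin_pairs_probe(cohort, "cg00000"))


class TestCloudSnr:
    def test_equal_betas_map_to_cap(self):
        assert mv.snr_cloud([50, 51, 52], [0.4, 0.4, 0.4]) == SNR_CAP

    def test_two_point_window_hand_value(self):
        # shared window: means 0.5, deviations 0.1 -> SNR 5
        assert mv.snr_cloud([50, 51], [0.4, 0.6]) == pytest.approx(5.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(48, 90, 40)
        vals = rng.uniform(0.2, 0.8, 40)
        perm = rng.permutation(40)
        assert mv.snr_cloud(ages, vals) == \
            pytest.approx(mv.snr_cloud(ages[perm], vals[perm]), rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize("traj,cloud,expected", [
        (10.0, 1.0, "deterministic"),
        (0.8, 1.0, "stochastic"),
        (1.0, 1.0, "stochastic"),      # strict inequality at the boundary
        (float("nan"), 1.0, "NA"),
    ])
    def test_call_rule(self, traj, cloud, expected):
        assert mv.classify_determinism(traj, cloud) == expected


class TestSnrProfile:
    def test_vectorized_matches_per_probe_loop(self, mixed_longitudinal):
        _, cohort = mixed_longitudinal
        probes = cohort.probe_ids[:6] + cohort.probe_ids[-6:]
        prof = mv.snr_profile(cohort, probes)
        for p in probes:
            assert prof.loc[p, "snr_trajectories"] == pytest.approx(
                snr_trajectories_probe(cohort, p), rel=1e-9)
            assert prof.loc[p, "snr_twin_pairs"] == pytest.approx(
                snr_twin_pairs_probe(cohort, p), rel=1e-9)
            assert prof.loc[p, "snr_cloud"] == pytest.approx(
                snr_cloud_probe(cohort, p), rel=1e-9)

    def test_duplicated_probe_rows_get_identical_statistics(self,
                                                            mixed_longitudinal):
        _, cohort = mixed_longitudinal
        beta = cohort.beta.iloc[:3]
        dup = beta.copy()
        dup.index = [f"{p}_copy" for p in dup.index]
        both = mv.Cohort(pd.concat([beta, dup]), cohort.samples)
        prof = mv.snr_profile(both)
        for p in beta.index:
            assert prof.loc[p, "snr_cloud"] == \
                pytest.approx(prof.loc[f"{p}_copy", "snr_cloud"], rel=1e-12)
            assert prof.loc[p, "log10_ratio"] == \
                pytest.approx(prof.loc[f"{p}_copy", "log10_ratio"], rel=1e-12)

    def test_fig3_ordering_on_divergence_probes(self, mixed_longitudinal):
        _, cohort = mixed_longitudinal
        div = [p for p in cohort.probe_ids if p.startswith("div")]
        prof = mv.snr_profile(cohort, div)
        assert (np.median(prof["snr_trajectories"])
                > np.median(prof["snr_twin_pairs"])
                > np.median(prof["snr_cloud"]))


class TestKsCompare:
    def test_identical_samples_give_zero_statistic(self):
        stat, p = mv.ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_fully_separated_samples_give_one(self):
        stat, _ = mv.ks_compare([1.0, 2.0], [10.0, 11.0])
        assert stat == 1.0

    def test_interleaved_example(self):
        stat, _ = mv.ks_compare([1.0, 2.0], [1.5, 2.5])
        assert stat == pytest.approx(0.5)

    def test_statistic_matches_ecdf_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(0.3, 1.2, rng.integers(3, 30))
            grid = np.concatenate([a, b])
            ecdf_gap = max(abs((a <= x).mean() - (b <= x).mean())
                           for x in grid)
            stat, _ = mv.ks_compare(a, b)
            assert stat == pytest.approx(ecdf_gap, abs=1e-10)
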