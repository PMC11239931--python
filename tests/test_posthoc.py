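"""Signatures, projections, variability, sweep, and group statistics."""

import numpy as np
import pandas as pd
import pytest

from lgpc.grids import TFGrid
from lgpc.posthoc import (component_brain_map, contrast_minmax, group_compare,
                          joint_topography, mean_frequency, peak_latency,
                          project_trial, rank_sum, region_contribution,
                          sensitivity_sweep, signed_rank, st_mask,
                          variability_stats)


class TestTopography:
    def test_single_ic_is_its_normalized_map(self):
        m = np.array([0.0, -2.0, 1.0, 4.0])
        np.testing.assert_allclose(joint_topography(m[None]),
                                   np.abs(m) / 4.0)

    def test_two_identical_ics_same_map(self):
        m = np.array([[1.0, 3.0, 2.0]])
        one = joint_topography(m)
        two = joint_topography(np.vstack([m, m]))
        np.testing.assert_allclose(one, two)

    def test_matches_hand_computation(self):
        maps = np.array([[1.0, 2.0], [-4.0, 2.0]])
        # normalized: [0.5, 1.0] and [1.0, 0.5] -> average [0.75, 0.75]
        np.testing.assert_allclose(joint_topography(maps), [0.75, 0.75])

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            joint_topography(np.zeros((1, 5)))


class TestRegions:
    def test_all_mass_in_one_region(self):
        labels = np.array(["pTC"] * 3 + ["other"] * 5, dtype=object)
        topo = np.array([1.0, 2.0, 1.0] + [0.0] * 5)
        frac = region_contribution(topo, labels)
        assert frac["pTC"] == 1.0 and frac["aTC"] == 0.0

    def test_uniform_map_proportional_to_region_size(self):
        labels = np.array(["pTC"] * 24 + ["other"] * 72, dtype=object)
        frac = region_contribution(np.ones(96), labels)
        assert frac["pTC"] == pytest.approx(0.25)

    def test_fractions_plus_remainder_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = np.array(["pTC"] * 30 + ["aTC"] * 30 + ["aPFC"] * 16
                          + ["other"] * 20, dtype=object)
        topo = np.abs(rng.standard_normal(96))
        frac = region_contribution(topo, labels)
        remainder = topo[labels == "other"].sum() / topo.sum()
        assert sum(frac.values()) + remainder == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            region_contribution(np.ones(4), np.array(["pTC"] * 5))


class TestLatencyAndFrequency:
    def test_delta_peak_latency(self, standard_grid):
        m = np.zeros(standard_grid.shape)
        ti = np.argmin(np.abs(standard_grid.times - (0.8 + 0.067)))
        m[80, ti] = 1.0
        assert peak_latency(m, standard_grid) == pytest.approx(67.0, abs=2.0)

    def test_tie_breaks_toward_earlier_peak(self, standard_grid):
        m = np.zeros(standard_grid.shape)
        t50 = np.argmin(np.abs(standard_grid.times - 0.85))
        t90 = np.argmin(np.abs(standard_grid.times - 0.89))
        m[60, t50] = m[60, t90] = 1.0
        assert peak_latency(m, standard_grid) == pytest.approx(50.0, abs=2.0)

    def test_flat_profile_undefined(self, standard_grid):
        with pytest.raises(ValueError, match="flat"):
            peak_latency(np.ones(standard_grid.shape), standard_grid)

    def test_single_bump_mean_frequency(self, standard_grid):
        m = np.zeros(standard_grid.shape)
        m[91, :] = 1.0  # 92 Hz row (freqs start at 1 Hz)
        assert mean_frequency(m, standard_grid) == pytest.approx(92.0)

    def test_uniform_profile_mean_frequency(self, standard_grid):
        assert mean_frequency(np.ones(standard_grid.shape), standard_grid) \
            == pytest.approx(75.5)

    def test_zero_profile_undefined(self, standard_grid):
        with pytest.raises(ValueError, match="zero"):
            mean_frequency(np.zeros(standard_grid.shape), standard_grid)


class TestComponentMaps:
    def test_one_hot_loading_returns_that_map(self):
        maps = np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 1.0]])
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = component_brain_map(maps, B)
        np.testing.assert_allclose(out[0], maps[0])

    def test_zero_loadings_zero_map(self):
        maps = np.array([[1.0, 0.5]])
        out = component_brain_map(maps, np.zeros((1, 2)))
        np.testing.assert_allclose(out, 0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="IC count"):
            component_brain_map(np.ones((2, 4)), np.ones((3, 2)))

    def test_contrast_minmax_per_contrast(self):
        m = np.zeros((2, 1, 3, 4))
        m[0, 0, 0, 0] = 2.5
        m[1, 0, 1, 1] = -1.5
        mm = contrast_minmax(m)
        assert mm["xy|xx - xx|xx"] == (0.0, 2.5)
        assert mm["xy|xy - xx|xy"] == (-1.5, 0.0)


class TestMask:
    def test_uniform_map_keeps_75_percent_of_high_gamma(self, roi_grid):
        mask, _ = st_mask(np.ones(roi_grid.shape), roi_grid, fmin=40.0)
        hg_bins = (roi_grid.freqs > 40.0).sum() * roi_grid.n_times
        assert mask.sum() == hg_bins  # all values tie at the threshold

    def test_graded_map_mask_fraction(self, roi_grid):
        rng = np.random.default_rng(1)
        m = np.abs(rng.standard_normal(roi_grid.shape))
        mask, structure = st_mask(m, roi_grid, fmin=40.0)
        hg = roi_grid.freqs > 40.0
        frac = mask[hg].mean()
        assert frac == pytest.approx(0.75, abs=0.01)
        assert np.all(structure[~mask] == 0)

    def test_low_frequency_energy_gives_empty_mask(self):
        grid = TFGrid.reduced(10, 12, fmin=5.0, fmax=120.0)
        m = np.zeros(grid.shape)
        m[grid.freqs <= 40.0, :] = 1.0
        mask, structure = st_mask(m, grid, fmin=40.0)
        assert not mask.any() and not structure.any()

    def test_no_high_gamma_bins_rejected(self):
        grid = TFGrid.reduced(5, 8, fmin=5.0, fmax=30.0)
        with pytest.raises(ValueError, match="40"):
            st_mask(np.ones(grid.shape), grid, fmin=40.0)


class TestProjection:
    def test_counting_example(self):
        n, f, t = 3, 4, 5
        FT = np.zeros((f, t))
        FT[:2, :3] = 1.0  # m = 6 active bins
        val = project_trial(np.ones(n), np.ones((n, f, t)), FT)
        assert val == n * 6

    def test_linearity_in_ersp(self):
        rng = np.random.default_rng(2)
        S, E, FT = rng.standard_normal(3), rng.standard_normal((3, 4, 5)), \
            rng.standard_normal((4, 5))
        assert project_trial(S, 3.0 * E, FT) == pytest.approx(
            3.0 * project_trial(S, E, FT))

    def test_invariant_to_matched_ic_permutation(self):
        rng = np.random.default_rng(3)
        S, E, FT = rng.standard_normal(4), rng.standard_normal((4, 3, 6)), \
            rng.standard_normal((3, 6))
        perm = rng.permutation(4)
        assert project_trial(S, E, FT) == pytest.approx(
            project_trial(S[perm], E[perm], FT))

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            project_trial(np.ones(2), np.ones((3, 4, 5)), np.ones((4, 5)))


def _records(values_by_type, component="PE1"):
    rows = []
    for t, vals in values_by_type.items():
        for i, v in enumerate(vals):
            rows.append({"trial_index": i, "trial_type": t,
                         "component": component, "value": v})
    return pd.DataFrame(rows)


class TestVariability:
    def test_constant_projections(self):
        rec = _records({t: [2.0, 2.0, 2.0] for t in
                        ("xx|xx", "xy|xx", "xy|xy", "xx|xy")})
        vs = variability_stats(rec)
        assert vs.sd["PE1"] == 0.0 and vs.cv["PE1"] == 0.0 and vs.sv == 0.0

    def test_two_type_arithmetic(self):
        # means 1 and 3, sds 0.1 and 0.3 -> pooled mean 2, mean sd 0.2, cv 0.1
        # (sample sd of [m-s/sqrt(2), m+s/sqrt(2)] is exactly s)
        a = [1 - 0.1 / np.sqrt(2), 1 + 0.1 / np.sqrt(2)]
        b = [3 - 0.3 / np.sqrt(2), 3 + 0.3 / np.sqrt(2)]
        vs = variability_stats(_records({"xx|xx": a, "xy|xx": b}))
        assert vs.mean["PE1"] == pytest.approx(2.0)
        assert vs.sd["PE1"] == pytest.approx(0.2)
        assert vs.cv["PE1"] == pytest.approx(0.1)
        assert vs.sv == pytest.approx(0.2)

    def test_cv_from_averages_not_average_of_cvs(self):
        a = [1 - 0.1 / np.sqrt(2), 1 + 0.1 / np.sqrt(2)]   # cv 0.1
        b = [4 - 0.2 / np.sqrt(2), 4 + 0.2 / np.sqrt(2)]   # cv 0.05
        vs = variability_stats(_records({"xx|xx": a, "xy|xx": b}))
        assert vs.cv["PE1"] == pytest.approx(0.15 / 2.5)
        assert vs.cv["PE1"] != pytest.approx(0.075)

    def test_single_trial_type_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            variability_stats(_records({"xx|xx": [1.0]}))

    def test_gain_sd_monotonically_increases_sv(self):
        from lgpc.benchmarks import sv_of_dataset
        from lgpc.model import ScalingParams
        from lgpc.synthetic import SyntheticConfig, simulate_ersp_dataset
        from scipy.stats import spearmanr
        levels = [0.05, 0.1, 0.2, 0.4, 0.8]
        svs = []
        for i, g in enumerate(levels):
            cfg = SyntheticConfig(grid=TFGrid.response_roi(12, 18),
                                  n_trials_per_type=48, trial_gain_sd=g,
                                  noise_sd=0.25, seed=40 + i)
            _, vs = sv_of_dataset(simulate_ersp_dataset(cfg))
            svs.append(vs.sv)
        rho = spearmanr(levels, svs).statistic
        assert rho > 0.9


@pytest.fixture(scope="module")
def fitted(clean_dataset):
    from lgpc.benchmarks import contrast_tensor
    from lgpc.pipeline import _structures_from_fit
    from lgpc.tensorfit import ScalingGridSearch
    X = contrast_tensor(clean_dataset).values
    gs = ScalingGridSearch(s0_values=np.linspace(0, 1, 6)[1:],
                           s1_values=np.linspace(0.2, 1.8, 5),
                           s2_values=np.linspace(0.3, 1.9, 5)).fit(X)
    fn = _structures_from_fit(clean_dataset, clean_dataset.grid, 40.0, 0.75)
    return gs, fn


class TestSweep:
    def test_default_thresholds_give_61_rows(self, clean_dataset, fitted):
        gs, fn = fitted
        sweep = sensitivity_sweep(gs, clean_dataset, range(3), fn)
        assert len(sweep) == 61
        np.testing.assert_allclose(sweep["threshold"], np.arange(40.0, 101.0))

    def test_single_threshold_single_row(self, clean_dataset, fitted):
        gs, fn = fitted
        sweep = sensitivity_sweep(gs, clean_dataset, range(3), fn,
                                  thresholds=np.array([80.0]))
        assert len(sweep) == 1

    def test_noise_free_params_stable_across_thresholds(self, clean_dataset, fitted):
        gs, fn = fitted
        sweep = sensitivity_sweep(gs, clean_dataset, range(3), fn)
        found = sweep[sweep["found"]]
        assert found["s0"].nunique() == 1
        assert found["s1"].nunique() == 1
        assert found["s2"].nunique() == 1


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        x = np.arange(10.0)
        assert rank_sum(x, x) > 0.05
        assert signed_rank(x, x) == 1.0

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 61)
        b = rng.normal(8.0, 1.0, 61)
        assert rank_sum(a, b) < 1e-10

    def test_bonferroni_factor_counts_pairs(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(i * 0.01, 1.0, 8) for i in range(5)}
        out = group_compare(groups)
        assert len(out) == 10
        np.testing.assert_allclose(out["p_bonferroni"],
                                   np.minimum(out["p_raw"] * 10, 1.0))

    def test_bonferroni_kills_marginal_p(self):
        # e.g. raw p = 0.01 with 10 pairs fails the corrected 0.05 level
        rng = np.random.default_rng(7)
        groups = {f"g{i}": rng.normal(0, 1, 6) for i in range(5)}
        out = group_compare(groups, alpha=0.05)
        marginal = out[(out["p_raw"] > 0.005) & (out["p_raw"] < 0.05)]
        assert not marginal["significant"].any()

    def test_paired_lengths_checked(self):
        with pytest.raises(ValueError, match="equal length"):
            signed_rank(np.ones(4), np.ones(5))
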