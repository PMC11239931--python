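"""Synthetic-data generator: kernels, ERSP datasets, raw time series."""

import numpy as np
import pytest

from lgpc.grids import TFGrid, FIFTH_TONE_ONSET_S
from lgpc.model import ScalingParams, contrast_design
from lgpc.spectral import MorletERSP
from lgpc.synthetic import (DEFAULT_KERNELS, KernelSpec, SyntheticConfig,
                            _trial_gains, make_kernels, simulate_ersp_dataset,
                            simulate_timeseries)


class TestKernels:
    def test_default_pe1_kernel_peaks_at_planted_center(self, standard_grid):
        k = make_kernels(DEFAULT_KERNELS, standard_grid)
        fi, ti = np.unravel_index(np.argmax(k[0]), k[0].shape)
        assert standard_grid.freqs[fi] == 95.0
        latency = (standard_grid.times[ti] - FIFTH_TONE_ONSET_S) * 1000
        assert abs(latency - 65.0) <= 1000 / 300  # within one time bin

    def test_unit_energy(self, roi_grid):
        k = make_kernels(DEFAULT_KERNELS, roi_grid)
        np.testing.assert_allclose((k ** 2).sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KernelSpec(latency_ms=65, freq_hz=95, time_sd_ms=0.0)

    def test_center_outside_grid_rejected(self, roi_grid):
        bad = {"PE1": KernelSpec(latency_ms=2000.0, freq_hz=95.0)}
        with pytest.raises(ValueError, match="outside"):
            make_kernels(bad, roi_grid)

    def test_no_energy_in_baseline(self, standard_grid):
        k = make_kernels(DEFAULT_KERNELS, standard_grid)
        assert np.all(k[:, :, standard_grid.times < 0] == 0)


class TestGains:
    def test_lognormal_gains_mean_one_and_positive(self):
        rng = np.random.default_rng(0)
        g = _trial_gains(rng, 20000, 2, 0.3)
        assert np.all(g > 0)
        assert g.mean() == pytest.approx(1.0, abs=0.01)
        assert g.std() == pytest.approx(0.3, abs=0.01)

    def test_zero_sd_gains_are_unity(self):
        g = _trial_gains(np.random.default_rng(0), 5, 2, 0.0)
        np.testing.assert_array_equal(g, 1.0)


class TestSimulateERSP:
    def test_noise_free_type_means_equal_planted_sum(self, clean_dataset):
        cfg_truth = clean_dataset.metadata["ground_truth"]
        kernels = make_kernels(DEFAULT_KERNELS, clean_dataset.grid)
        w = np.asarray(cfg_truth["ic_loadings"])
        mags = cfg_truth["pe_magnitudes"]
        tm = clean_dataset.type_means()
        for t, m in tm.items():
            expected = sum(mags[name][t] * np.einsum("i,ft->ift", w[k], kernels[k])
                           for k, name in enumerate(cfg_truth["component_names"]))
            np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_same_seed_identical_tensors(self, roi_grid):
        cfg = dict(grid=roi_grid, n_trials_per_type=8, seed=21)
        a = simulate_ersp_dataset(SyntheticConfig(**cfg))
        b = simulate_ersp_dataset(SyntheticConfig(**cfg))
        np.testing.assert_array_equal(a.ersp, b.ersp)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_contrast_projection_proportional_to_design_column(self, roi_grid):
        # empirical type-contrast projected on K1 tracks the PE1 design column
        params = ScalingParams(0.4, 0.85, 0.75)
        cfg = SyntheticConfig(grid=roi_grid, n_trials_per_type=256, seed=3,
                              true_params=params, noise_sd=0.05, trial_gain_sd=0.05)
        ds = simulate_ersp_dataset(cfg)
        kernels = make_kernels(cfg.kernel_spec, roi_grid)
        tm = ds.type_means()
        contrasts = [tm["xy|xx"] - tm["xx|xx"], tm["xy|xy"] - tm["xx|xy"]]
        A = contrast_design(params).A
        # project each contrast (summed over ICs with the planted loadings)
        # onto kernel 1, removing the overlap with kernel 2
        k1, k2 = kernels[0].ravel(), kernels[1].ravel()
        G = np.array([[k1 @ k1, k1 @ k2], [k2 @ k1, k2 @ k2]])
        w = cfg.ic_loadings
        proj = []
        for c in contrasts:
            y = np.stack([c[i].ravel() for i in range(ds.n_ics)])
            # least-squares component amplitudes per IC, then match loadings
            coef = np.linalg.solve(G, np.stack([y @ k1, y @ k2]))  # (2, n_ics)
            proj.append(coef)
        est_A = np.array([[proj[0][0] @ w[0] / (w[0] @ w[0]),
                           proj[0][1] @ w[1] / (w[1] @ w[1])],
                          [proj[1][0] @ w[0] / (w[0] @ w[0]),
                           proj[1][1] @ w[1] / (w[1] @ w[1])]])
        np.testing.assert_allclose(est_A, A, atol=0.03)

    def test_nonpositive_trial_count_rejected(self, roi_grid):
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(grid=roi_grid, n_trials_per_type=0)

    def test_dataset_shapes_and_labels(self, small_dataset):
        assert small_dataset.ersp.shape[0] == 4 * 32
        assert small_dataset.ersp.shape[1] == 3
        assert set(small_dataset.labels) == {"xx|xx", "xy|xx", "xy|xy", "xx|xy"}
        assert small_dataset.spatial_maps.shape == (3, 96)


class TestSimulateTimeseries:
    def test_planted_burst_recovered_by_spectral_module(self):
        grid = TFGrid.standard()
        spec = {"PE1": KernelSpec(latency_ms=65.0, freq_hz=95.0, time_sd_ms=25.0)}
        cfg = SyntheticConfig(grid=grid, n_trials_per_type=2, seed=4,
                              kernel_spec=spec, n_ics=1,
                              ic_loadings=np.array([[1.0]]),
                              trial_gain_sd=0.0)
        signals, labels, _ = simulate_timeseries(cfg, burst_amplitude=40.0,
                                                 noise_amplitude=0.5)
        # average ERSP over the high-PE trials of the loudest type
        est = MorletERSP(freqs=np.arange(60.0, 131.0))
        sel = labels == "xy|xx"
        db = est.fit_transform(signals[sel][:, 0, :]).mean(axis=0)
        fi, ti = np.unravel_index(np.argmax(db), db.shape)
        assert abs(est.grid_.freqs[fi] - 95.0) <= 1.0
        t_peak_ms = (est.grid_.times[ti] - FIFTH_TONE_ONSET_S) * 1000
        assert abs(t_peak_ms - 65.0) <= 10.0

    def test_silent_trials_near_zero_db(self):
        grid = TFGrid.standard()
        cfg = SyntheticConfig(grid=grid, n_trials_per_type=16, seed=8, n_ics=1,
                              ic_loadings=np.array([[0.0], [0.0]]),
                              trial_gain_sd=0.0)
        signals, _, _ = simulate_timeseries(cfg, burst_amplitude=0.0,
                                            noise_amplitude=1.0)
        from lgpc.spectral import morlet_tfr
        power = morlet_tfr(signals[:, 0, :], freqs=np.arange(60.0, 140.0, 10.0))
        t = grid.times
        # "~0 dB": with a trial-averaged baseline (enough degrees of freedom
        # to avoid the inverse-moment bias of single-trial baselines), the
        # central-epoch power sits at the baseline level
        base = power[..., t < 0].mean(axis=(0, -1), keepdims=True)
        central = (t > 0.2) & (t < 1.4)
        ratio = (power[..., central] / base).mean()
        assert abs(10 * np.log10(ratio)) < 0.5

    def test_doubling_amplitude_adds_six_db_at_peak(self):
        grid = TFGrid.standard()
        spec = {"PE1": KernelSpec(latency_ms=65.0, freq_hz=95.0, time_sd_ms=25.0)}
        base = dict(grid=grid, n_trials_per_type=2, seed=4, kernel_spec=spec,
                    n_ics=1, ic_loadings=np.array([[1.0]]), trial_gain_sd=0.0)
        est = MorletERSP(freqs=np.arange(80.0, 111.0))

        def peak_db(amp):
            s, labels, _ = simulate_timeseries(SyntheticConfig(**base),
                                               burst_amplitude=amp,
                                               noise_amplitude=0.05)
            db = est.fit_transform(s[labels == "xy|xx"][:, 0, :]).mean(axis=0)
            return db.max()

        assert peak_db(80.0) - peak_db(40.0) == pytest.approx(6.02, abs=0.7)
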