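import numpy as np
import pytest

from ptsdconn.atlas import make_atlas
from ptsdconn.connectivity import (
    CensorMask,
    SubjectRunTimeSeries,
    bandpass,
    build_nuisance_design,
    compute_censor_mask,
    compute_connectome,
    denoise,
    preprocess_run,
)
from ptsdconn.errors import ConfigurationError, InputError
from ptsdconn.simulate import SimulationConfig, simulate_timeseries_cohort


def make_run(rng, n_nodes=5, t=120, motion=None, task=None, nuis=None, fd=None):
    return SubjectRunTimeSeries(
        subject_id="s1",
        session="baseline",
        run_id="run-1",
        data=rng.normal(size=(n_nodes, t)),
        tr_seconds=2.5,
        motion_params=motion if motion is not None else rng.normal(0, 0.01, (6, t)),
        task_covariates=task if task is not None else np.empty((0, t)),
        nuisance_signals=nuis if nuis is not None else np.empty((0, t)),
        fd_trace=fd if fd is not None else np.zeros(t),
    )


class TestCensoring:
    def test_still_run_retains_everything(self):
        mask = compute_censor_mask(np.zeros(50), np.ones((4, 50)))
        assert mask.retained.all() and mask.usable

    def test_single_high_fd_frame_censored(self):
        fd = np.zeros(60)
        fd[17] = 5.0  # 10x the default threshold
        mask = compute_censor_mask(fd, np.full((4, 60), 100.0))
        assert not mask.retained[17]
        assert mask.retained.sum() == 59

    def test_unusable_when_too_few_frames_survive(self, rng):
        fd = np.full(50, 3.0)
        fd[0] = 0.0
        mask = compute_censor_mask(fd, rng.normal(size=(3, 50)))
        assert not mask.usable

    def test_spike_rate_recovered_within_binomial_ci(self):
        rate, t_len, n_runs = 0.1, 120, 20
        cfg = SimulationConfig(
            n_patients=1, n_controls=1, n_runs=n_runs,
            n_timepoints_per_run=t_len, motion_spike_rate=rate, seed=21,
        )
        runs = [r for r in simulate_timeseries_cohort(cfg) if r.subject_id == "sub-001"]
        censored = sum(
            (~compute_censor_mask(r.fd_trace, r.data).retained).sum() for r in runs
        )
        n = t_len * n_runs
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(censored / n - rate) < 2.5 * se + 1 / t_len

    def test_zero_spike_rate_retains_all(self):
        cfg = SimulationConfig(
            n_patients=1, n_controls=1, n_runs=3, motion_spike_rate=0.0, seed=5
        )
        for r in simulate_timeseries_cohort(cfg):
            assert compute_censor_mask(r.fd_trace, r.data).retained.all()


class TestNuisanceDesign:
    def test_friston24_column_count(self, rng):
        run = make_run(rng)
        mask = CensorMask(np.ones(120, bool), 0.5, 1.5)
        design = build_nuisance_design(run, mask)
        assert design.shape[1] == 2 + 24  # intercept + drift + Friston-24

    def test_spike_columns_one_per_censored_frame(self, rng):
        run = make_run(rng)
        retained = np.ones(120, bool)
        retained[[10, 40, 41]] = False
        design = build_nuisance_design(run, CensorMask(retained, 0.5, 1.5))
        spikes = design[:, -3:]
        assert spikes.sum() == 3
        assert (spikes.sum(axis=0) == 1).all()

    def test_constant_motion_dropped_as_zero_variance(self, rng):
        motion = np.vstack([np.full(120, 0.3), rng.normal(0, 0.01, (5, 120))])
        run = make_run(rng, motion=motion)
        design = build_nuisance_design(run, CensorMask(np.ones(120, bool), 0.5, 1.5))
        # the constant param, its lag and both squares disappear
        assert design.shape[1] == 2 + 24 - 4


class TestDenoise:
    def test_data_in_design_span_gives_zero_residuals(self, rng):
        design = np.column_stack([np.ones(80), rng.normal(size=(80, 3))])
        coef = rng.normal(size=(4, 6))
        data = (design @ coef).T
        resid = denoise(data, design)
        assert np.abs(resid).max() < 1e-8 * np.abs(data).max()

    def test_intercept_only_mean_centers(self, rng):
        data = rng.normal(size=(3, 50)) + 7.0
        resid = denoise(data, np.ones((50, 1)))
        np.testing.assert_allclose(resid, data - data.mean(axis=1, keepdims=True))

    def test_residuals_orthogonal_to_design(self, rng):
        design = np.column_stack([np.ones(100), rng.normal(size=(100, 5))])
        data = rng.normal(size=(7, 100))
        resid = denoise(data, design)
        inner = np.abs(resid @ design)
        norms = np.linalg.norm(resid, axis=1)[:, None] * np.linalg.norm(design, axis=0)
        assert (inner <= 1e-8 * norms).all()

    def test_non_finite_rejected(self, rng):
        data = rng.normal(size=(2, 30))
        data[0, 3] = np.nan
        with pytest.raises(InputError):
            denoise(data, np.ones((30, 1)))


class TestBandpass:
    TR = 2.5

    def _ratio(self, freq_hz, t=4000):
        t_axis = np.arange(t) * self.TR
        x = np.sin(2 * np.pi * freq_hz * t_axis)[None, :]
        y = bandpass(x, self.TR)
        mid = slice(t // 4, 3 * t // 4)  # avoid filter edge effects
        return np.abs(y[0, mid]).max() / np.abs(x[0, mid]).max()

    def test_dc_removed(self):
        y = bandpass(np.full((1, 2000), 5.0), self.TR)
        assert np.abs(y).max() < 0.01 * 5.0

    def test_passband_preserved(self):
        assert self._ratio(0.03) > 0.9

    def test_stopband_attenuated(self):
        assert self._ratio(0.19) < 0.1

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(np.zeros((1, 200)), self.TR, 0.009, 0.25)

    def test_too_short_run_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(np.zeros((1, 20)), self.TR)


class TestConnectome:
    def _atlas(self, n):
        return make_atlas(n, [], ["A", "B"], seed=0)

    def test_identical_series_hit_the_clamp(self, rng):
        s = rng.normal(size=200)
        data = np.vstack([s, s, rng.normal(size=200)])
        mask = CensorMask(np.ones(200, bool), 0.5, 1.5)
        conn = compute_connectome([(data, mask)], self._atlas(3))
        assert conn.z_matrix[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_known_correlation_recovers_fisher_z(self):
        # construct two series with exact sample correlation 0.5
        n = 400
        a = np.sin(np.arange(n))
        a = (a - a.mean()) / a.std()
        g = np.cos(np.arange(n) * 1.7)
        g = g - g.mean()
        g -= a * (a @ g) / (a @ a)  # orthogonalise
        g /= g.std()
        r_target = 0.5
        b = r_target * a + np.sqrt(1 - r_target**2) * g
        mask = CensorMask(np.ones(n, bool), 0.5, 1.5)
        conn = compute_connectome(
            [(np.vstack([a, b, np.arange(n) % 7]), mask)], self._atlas(3)
        )
        assert conn.z_matrix[0, 1] == pytest.approx(0.5493, abs=1e-4)

    def test_white_noise_null_bound(self, rng):
        data = rng.normal(size=(10, 500))
        mask = CensorMask(np.ones(500, bool), 0.5, 1.5)
        conn = compute_connectome([(data, mask)], self._atlas(10))
        iu, ju = np.triu_indices(10, k=1)
        assert np.abs(conn.z_matrix[iu, ju]).mean() < 0.1

    def test_zero_variance_node_edges_zeroed(self, rng):
        data = rng.normal(size=(4, 100))
        data[2] = 3.14
        mask = CensorMask(np.ones(100, bool), 0.5, 1.5)
        conn = compute_connectome([(data, mask)], self._atlas(4))
        assert (conn.z_matrix[2] == 0).all()

    def test_symmetric_zero_diagonal_finite(self, rng):
        data = rng.normal(size=(6, 150))
        mask = CensorMask(np.ones(150, bool), 0.5, 1.5)
        z = compute_connectome([(data, mask)], self._atlas(6)).z_matrix
        np.testing.assert_array_equal(z, z.T)
        np.testing.assert_array_equal(np.diag(z), 0)
        assert np.isfinite(z).all()

    def test_scale_invariance(self, rng):
        data = rng.normal(size=(5, 120))
        mask = CensorMask(np.ones(120, bool), 0.5, 1.5)
        z1 = compute_connectome([(data, mask)], self._atlas(5)).z_matrix
        z2 = compute_connectome([(data * 37.2, mask)], self._atlas(5)).z_matrix
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_masking_equals_deletion(self, rng):
        data = rng.normal(size=(5, 100))
        retained = rng.random(100) > 0.2
        mask = CensorMask(retained, 0.5, 1.5)
        full = CensorMask(np.ones(retained.sum(), bool), 0.5, 1.5)
        z_masked = compute_connectome([(data, mask)], self._atlas(5)).z_matrix
        z_deleted = compute_connectome(
            [(data[:, retained], full)], self._atlas(5)
        ).z_matrix
        np.testing.assert_allclose(z_masked, z_deleted, atol=1e-12)


class TestPipelineOnSimulatedRuns:
    def test_block_structure_recovered_after_denoising(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_patients=1, n_controls=1, n_runs=2, seed=100 + seed,
                within_network_coupling=0.5, between_network_coupling=0.05,
            )
            atlas = cfg.atlas()
            runs = [
                r for r in simulate_timeseries_cohort(cfg) if r.subject_id == "sub-001"
            ]
            conn = compute_connectome([preprocess_run(r) for r in runs], atlas)
            iu, ju = np.triu_indices(atlas.n_nodes, k=1)
            same = atlas.networks[iu] == atlas.networks[ju]
            z = conn.z_matrix[iu, ju]
            hits += z[same].mean() > z[~same].mean()
        assert hits == 20

    def test_null_couplings_give_null_correlations(self):
        cfg = SimulationConfig(
            n_patients=1, n_controls=1, n_runs=2, seed=7, ar_coefficient=0.0,
            within_network_coupling=0.0, between_network_coupling=0.0,
            motion_spike_rate=0.0,
        )
        runs = [r for r in simulate_timeseries_cohort(cfg) if r.subject_id == "sub-001"]
        prepped = [preprocess_run(r) for r in runs]
        conn = compute_connectome(prepped, cfg.atlas())
        t_total = conn.n_retained_frames
        r = np.tanh(conn.edge_vector())
        assert np.abs(r).mean() < 3 / np.sqrt(t_total)
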