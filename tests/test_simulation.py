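"""Integration-layer tests: noise generation, stepping, repeats."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from thalabeta import (
    ConfigurationError,
    Drive,
    IntegrationError,
    ModelParameters,
    SimulationConfig,
    integrate,
    make_drive,
    output_potential,
    run_grid,
    run_repeats,
)
from thalabeta.model import make_batch_rhs


class TestMakeDrive:
    def test_zero_variance_is_constant_mean(self, short_config):
        d = make_drive(short_config, mu_r=86.0, phi_r=0.0)
        assert np.all(d.samples == 86.0)
        assert d(0.0) == 86.0 and d(short_config.duration) == 86.0

    def test_sample_mean_within_clt_bound(self):
        cfg = SimulationConfig(duration=30.0, dt=1e-3, seed=0)
        d = make_drive(cfg, mu_r=86.0, phi_r=1.0)
        assert len(d.samples) == 30_000
        assert abs(d.samples.mean() - 86.0) < 3 / np.sqrt(30_000)
        assert d.samples.var() == pytest.approx(1.0, rel=0.1)

    def test_reproducible_from_seed_and_repeat(self, short_config):
        a = make_drive(short_config, 86.0, 1.0, repeat_index=3)
        b = make_drive(short_config, 86.0, 1.0, repeat_index=3)
        c = make_drive(short_config, 86.0, 1.0, repeat_index=4)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_zero_order_hold_lookup(self):
        d = Drive(np.array([1.0, 2.0, 3.0]), dt=0.1)
        assert d(0.05) == 1.0 and d(0.1) == 2.0 and d(0.29) == 3.0

    def test_negative_variance_rejected(self, short_config):
        with pytest.raises(ConfigurationError):
            make_drive(short_config, 86.0, -1.0)


class TestIntegrate:
    def test_zero_drive_converges_to_fixed_point(self, params):
        """With no input the deterministic system settles onto the fixed
        point located independently by root-finding on the RHS."""
        cfg = SimulationConfig(duration=10.0, dt=1e-3, transient=2.0)
        t, traj = integrate(params, cfg, lambda tt: np.zeros_like(np.asarray(tt, float)))
        v = output_potential(traj, params)
        final = v[t >= 9.0]
        assert final.std() < 1e-6

        rhs = make_batch_rhs(params)

        def F(y):
            out = np.empty((6, 1))
            rhs(y.reshape(6, 1), np.array([0.0]), out)
            return out[:, 0]

        fp = fsolve(F, np.zeros(6))
        v_fp = params.C3 * fp[0] - params.C2 * fp[4]
        assert final[-1] == pytest.approx(v_fp, abs=1e-8)

    def test_halving_dt_changes_trace_below_one_percent(self, params):
        """Step-size refinement on the deterministic (zero-variance)
        limit cycle: the fixed-step solution is already converged at
        the 1 ms reference step."""
        drive = Drive(np.full(10_000, 86.0), dt=1e-3)
        t1, tr1 = integrate(params, SimulationConfig(duration=10.0, dt=1e-3), drive)
        t2, tr2 = integrate(params, SimulationConfig(duration=10.0, dt=5e-4), drive)
        v1 = output_potential(tr1, params)[t1 >= 2.0]
        v2 = output_potential(tr2, params)[t2 >= 2.0][::2]
        rel_rms = np.sqrt(np.mean((v1 - v2) ** 2)) / np.sqrt(np.mean(v1**2))
        assert rel_rms < 0.01

    def test_divergence_reports_time(self, params):
        cfg = SimulationConfig(duration=2.0, dt=1e-3, transient=0.0, blowup_bound=1e-3)
        with pytest.raises(IntegrationError) as err:
            integrate(params, cfg, lambda tt: np.full_like(np.asarray(tt, float), 86.0))
        assert err.value.time is not None and 0 < err.value.time <= 2.0

    def test_rk45_mode_tracks_rk4(self, params):
        """The adaptive solver over the same held noise stays close to
        the fixed-step reference (identical oscillation, small phase
        drift at most)."""
        drive = Drive(np.full(6_000, 86.0), dt=1e-3)
        cfg4 = SimulationConfig(duration=6.0, dt=1e-3)
        cfg45 = SimulationConfig(duration=6.0, dt=1e-3, method="rk45")
        t, tr4 = integrate(params, cfg4, drive)
        _, tr45 = integrate(params, cfg45, drive)
        v4 = output_potential(tr4, params)[t >= 2.0]
        v45 = output_potential(tr45, params)[t >= 2.0]
        rel = np.sqrt(np.mean((v4 - v45) ** 2)) / np.sqrt(np.mean(v4**2))
        assert rel < 0.05


class TestRunRepeats:
    def test_single_repeat_mean_is_the_trace(self, params):
        cfg = SimulationConfig(duration=6.0, n_repeats=1, seed=0)
        res = run_repeats(params, cfg)
        np.testing.assert_array_equal(res.mean_trace, res.traces[0])

    def test_mean_trace_is_pointwise_mean(self, params, short_config):
        res = run_repeats(params, short_config)
        np.testing.assert_allclose(
            res.mean_trace, res.traces.mean(axis=0), rtol=0, atol=1e-12)

    def test_zero_variance_repeats_identical_and_seed_independent(self, params):
        p0 = params.with_(phi_r=0.0)
        a = run_repeats(p0, SimulationConfig(duration=6.0, n_repeats=2, seed=1))
        b = run_repeats(p0, SimulationConfig(duration=6.0, n_repeats=2, seed=999))
        np.testing.assert_array_equal(a.traces[0], a.traces[1])
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_bitwise_reproducible(self, params, short_config):
        a = run_repeats(params, short_config)
        b = run_repeats(params, short_config)
        np.testing.assert_array_equal(a.traces, b.traces)
        assert a.seeds == b.seeds == [0, 1]

    def test_transient_discarded(self, params, short_config):
        res = run_repeats(params, short_config)
        assert res.time[0] == pytest.approx(short_config.transient)
        assert res.time[-1] == pytest.approx(short_config.duration)
        assert res.traces.shape == (short_config.n_repeats, len(res.time))
        assert np.all(np.isfinite(res.traces))

    def test_stability_envelope_corners(self, params, mapping):
        """No divergence anywhere on the corners of the swept ranges:
        amyloid 0-5, connectivity 0-100, drive 0-100."""
        from thalabeta import tau_i_of_beta
        cfg = SimulationConfig(duration=5.0, dt=1e-3, transient=1.0, n_repeats=1, seed=0)
        for beta in (0.0, 5.0):
            for c1 in (0.0, 100.0):
                for mu in (0.0, 100.0):
                    p = params.with_(tau_i=float(tau_i_of_beta(beta, mapping)),
                                     C1=c1, mu_r=mu)
                    res = run_repeats(p, cfg)
                    assert np.all(np.isfinite(res.traces))


class TestRunGrid:
    def test_single_point_grid_matches_run_repeats(self, params, short_config):
        direct = run_repeats(params, short_config)
        [gridded] = run_grid([params], short_config)
        np.testing.assert_array_equal(direct.traces, gridded.traces)

    def test_varying_tau_and_c1_across_points(self, params, short_config):
        """Batched multi-point integration equals running each point's
        repeats separately (same seeds per column layout)."""
        points = [params.with_(tau_i=20.0), params.with_(tau_i=30.0, C1=50.0)]
        batched = run_grid(points, short_config)
        solo0 = run_repeats(points[0], short_config)
        np.testing.assert_array_equal(batched[0].traces, solo0.traces)
        assert batched[1].tau_i_used == 30.0
        assert batched[1].seeds == [2, 3]

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(duration=1.0, dt=2.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(transient=40.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_repeats=0)
        with pytest.raises(ConfigurationError):
            run_grid([], SimulationConfig())
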