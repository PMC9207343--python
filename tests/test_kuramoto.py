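import numpy as np
import pytest

from phaseconn import (
    KuramotoConfig,
    coupling_sweep,
    gen_connectivity_matrix,
    lzc,
    order_parameter,
    run_ensemble,
    simulate,
    to_eeg,
)
from phaseconn.kuramoto import spawn_run_rngs, summed_signal
from phaseconn.synthetic import SynthCohortConfig


def two_oscillator_matrix(a):
    from phaseconn import ConnectivityMatrix

    return ConnectivityMatrix(weights=np.array([[0.0, a], [a, 0.0]]), channel_labels=["a", "b"])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"h": 0.0}, "step"),
            ({"freq_sd": -1.0}, "freq_sd"),
            ({"burn_in": 200, "n_samples": 100}, "burn_in"),
            ({"n_runs": 0}, "n_runs"),
            ({"phase_noise_sd": -0.1}, "phase_noise"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            KuramotoConfig(**kwargs)

    def test_dimension_mismatch(self, uniform_matrix):
        cfg = KuramotoConfig(n_oscillators=5)
        with pytest.raises(ValueError, match="nodes"):
            simulate(cfg, uniform_matrix(3, 0.5))


class TestSimulate:
    def test_uncoupled_phases_advance_linearly(self, uniform_matrix):
        """With k = 0 Euler is exact: theta(t) = theta0 + omega*h*t."""
        cfg = KuramotoConfig(
            n_oscillators=3, k=0.0, n_samples=500, burn_in=0, seed=1, time_unit_scale=0.01
        )
        freqs = np.array([8.0, 10.0, 12.0])
        theta0 = np.array([0.1, 0.2, 0.3])
        traj = simulate(cfg, uniform_matrix(3, 0.9), freqs=freqs, init_phases=theta0)
        steps = np.arange(500)[:, None]
        expected = theta0 + steps * cfg.h * (2 * np.pi * freqs * cfg.time_unit_scale)
        np.testing.assert_allclose(traj.phases, expected, atol=1e-9)

    def test_symmetric_pair_synchronizes(self):
        cfg = KuramotoConfig(
            n_oscillators=2, k=1.0, n_samples=20000, burn_in=0, seed=2, time_unit_scale=0.01
        )
        traj = simulate(
            cfg,
            two_oscillator_matrix(1.0),
            freqs=np.array([10.0, 10.0]),
            init_phases=np.array([0.0, 2.0]),
        )
        dphi = traj.phases[-1, 0] - traj.phases[-1, 1]
        assert abs((dphi + np.pi) % (2 * np.pi) - np.pi) < 1e-6
        assert traj.order_r[-1] > 1 - 1e-9

    @pytest.mark.parametrize("ratio", [2.0, 4.0])
    def test_locked_phase_offset_matches_closed_form(self, ratio):
        """dphi/dt = dw - 2ka sin(phi) locks at arcsin(dw / 2ka)."""
        k, a = 1.0, 0.5
        scale = 0.01
        dw = 2 * k * a / ratio
        df = dw / (2 * np.pi * scale)
        cfg = KuramotoConfig(
            n_oscillators=2, k=k, n_samples=120000, burn_in=20000, seed=3,
            h=0.01, time_unit_scale=scale,
        )
        traj = simulate(
            cfg,
            two_oscillator_matrix(a),
            freqs=np.array([10.0 + df, 10.0]),
            init_phases=np.array([0.3, 0.0]),
        )
        phi = traj.phases[-5000:, 0] - traj.phases[-5000:, 1]
        phi = (phi + np.pi) % (2 * np.pi) - np.pi
        assert phi.std() < 1e-6
        assert np.mean(phi) == pytest.approx(np.arcsin(dw / (2 * k * a)), rel=0.01)

    def test_above_threshold_detuning_drifts(self):
        k, a, scale = 1.0, 0.5, 0.01
        dw = 1.3 * 2 * k * a  # beyond the locking threshold
        df = dw / (2 * np.pi * scale)
        cfg = KuramotoConfig(
            n_oscillators=2, k=k, n_samples=60000, burn_in=0, seed=4,
            h=0.01, time_unit_scale=scale,
        )
        traj = simulate(
            cfg,
            two_oscillator_matrix(a),
            freqs=np.array([10.0 + df, 10.0]),
            init_phases=np.array([0.0, 0.0]),
        )
        phi = traj.phases[:, 0] - traj.phases[:, 1]
        assert phi[-1] - phi[0] > 4 * np.pi  # keeps slipping cycles

    def test_rotation_symmetry_of_order_parameter(self, uniform_matrix):
        """A common phase offset shifts psi but leaves r(t) unchanged."""
        cfg = KuramotoConfig(
            n_oscillators=5, n_samples=4000, burn_in=500, seed=5, time_unit_scale=1.0
        )
        mat = uniform_matrix(5, 0.5)
        rng = np.random.default_rng(9)
        freqs = rng.normal(10, 2, 5)
        theta0 = rng.uniform(0, 2 * np.pi, 5)
        t1 = simulate(cfg, mat, freqs=freqs, init_phases=theta0)
        t2 = simulate(cfg, mat, freqs=freqs, init_phases=theta0 + 1.234)
        np.testing.assert_allclose(t1.order_r, t2.order_r, atol=1e-9)
        dpsi = np.angle(np.exp(1j * (t2.mean_phase - t1.mean_phase)))
        np.testing.assert_allclose(dpsi, 1.234, atol=1e-6)

    def test_euler_step_halving_stability(self, uniform_matrix):
        """Halving the step changes r(t) by < 5% RMS in the stable regime."""
        mat = uniform_matrix(5, 0.5)
        rng = np.random.default_rng(11)
        freqs = rng.normal(10, 1, 5)
        theta0 = rng.uniform(0, 2 * np.pi, 5)
        base = KuramotoConfig(
            n_oscillators=5, n_samples=5000, burn_in=0, seed=6, h=0.1, time_unit_scale=0.01
        )
        fine = KuramotoConfig(
            n_oscillators=5, n_samples=10000, burn_in=0, seed=6, h=0.05, time_unit_scale=0.01
        )
        r1 = simulate(base, mat, freqs=freqs, init_phases=theta0).order_r
        r2 = simulate(fine, mat, freqs=freqs, init_phases=theta0).order_r[::2]
        rms = np.sqrt(np.mean((r1 - r2) ** 2)) / np.sqrt(np.mean(r1**2))
        assert rms < 0.05

    def test_strong_coupling_identical_frequencies_synchronize(self, uniform_matrix):
        # h chosen inside the Euler stability bound h*k*mean(a) < 2
        cfg = KuramotoConfig(
            n_oscillators=10, k=50.0, n_samples=3000, burn_in=0, seed=7,
            h=0.01, time_unit_scale=0.01, normalize_coupling=True,
        )
        traj = simulate(
            cfg, uniform_matrix(10, 1.0), freqs=np.full(10, 10.0),
            init_phases=np.random.default_rng(0).uniform(0, 2 * np.pi, 10),
        )
        assert traj.order_r[-1] > 0.99

    def test_order_parameter_bounds_on_trajectories(self, control_matrix):
        cfg = KuramotoConfig(n_samples=3000, burn_in=500, seed=8, time_unit_scale=1.0)
        traj = simulate(cfg, control_matrix)
        assert np.all(traj.order_r >= 0) and np.all(traj.order_r <= 1)
        assert traj.n_timepoints == 2500


class TestOrderParameter:
    def test_identical_phases_give_unity(self):
        for value in [0.0, 1.0, 2.5, 4.0, 6.0]:
            r, _ = order_parameter(np.full(21, value))
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_pair_cancels(self):
        r, _ = order_parameter(np.array([0.3, 0.3 + np.pi]))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_random_phase_expectation(self):
        """E[r] for uniform phases approaches sqrt(pi / 4N)."""
        rng = np.random.default_rng(42)
        r, _ = order_parameter(rng.uniform(0, 2 * np.pi, (10000, 21)))
        assert np.mean(r) == pytest.approx(np.sqrt(np.pi / (4 * 21)), rel=0.02)
        assert np.max(r) <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            order_parameter(np.empty((0, 5)))


class TestToEEG:
    def test_constant_phase_maps_to_sine_value(self, uniform_matrix):
        from phaseconn.kuramoto import PhaseTrajectory

        traj = PhaseTrajectory(
            phases=np.full((100, 2), np.pi / 2),
            natural_freqs=np.array([10.0, 10.0]),
            order_r=np.ones(100),
            mean_phase=np.zeros(100),
        )
        rec = to_eeg(traj, ["a", "b"])
        assert np.allclose(rec.data, 1.0)

    def test_output_bounded_and_labeled(self, control_matrix):
        cfg = KuramotoConfig(n_samples=2000, burn_in=100, seed=9)
        traj = simulate(cfg, control_matrix)
        rec = to_eeg(traj, control_matrix.channel_labels, group="simulated-control")
        assert rec.data.min() >= -1.0 and rec.data.max() <= 1.0
        assert rec.channel_labels == control_matrix.channel_labels
        with pytest.raises(ValueError, match="labels"):
            to_eeg(traj, ["just-one"])

    def test_locked_pair_peaks_at_locked_lag(self):
        """Phase-locked channels have maximal cross-correlation at the lag
        corresponding to the locked phase offset."""
        k, a, scale = 1.0, 0.5, 0.01
        dw = k * a  # ratio 2, locked offset arcsin(0.5)
        df = dw / (2 * np.pi * scale)
        cfg = KuramotoConfig(
            n_oscillators=2, k=k, n_samples=120000, burn_in=20000, seed=10,
            h=0.01, time_unit_scale=scale,
        )
        traj = simulate(
            cfg, two_oscillator_matrix(a),
            freqs=np.array([10.0 + df, 10.0]), init_phases=np.array([0.3, 0.0]),
        )
        rec = to_eeg(traj, ["lead", "lag"])
        x, y = rec.data  # x carries the leading oscillator
        # common instantaneous frequency of the locked pair, rad per sample
        w_common = np.mean(np.diff(traj.phases[:, 1]))
        expected_lag = np.arcsin(dw / (2 * k * a)) / w_common
        max_lag = int(3 * abs(expected_lag))
        # shifting the lagging channel forward by the locked offset aligns them
        corr = [
            np.corrcoef(y[lag : lag + 50000], x[:50000])[0, 1]
            for lag in range(max_lag)
        ]
        assert int(np.argmax(corr)) == pytest.approx(expected_lag, abs=1.0)

    def test_summed_signal_diagnostic(self, control_matrix):
        cfg = KuramotoConfig(n_samples=1500, burn_in=100, seed=11)
        traj = simulate(cfg, control_matrix)
        s = summed_signal(traj)
        np.testing.assert_allclose(s, np.sin(traj.phases).sum(axis=1))


class TestEnsembles:
    def test_single_run_matches_simulate_with_spawned_stream(self, control_matrix):
        cfg = KuramotoConfig(n_runs=1, n_samples=2000, burn_in=200, seed=12)
        rec = run_ensemble(cfg, control_matrix)[0]
        traj = simulate(cfg, control_matrix, rng=spawn_run_rngs(cfg.seed, 1)[0])
        np.testing.assert_array_equal(rec.data, np.sin(traj.phases).T)

    def test_same_master_seed_identical_ensemble(self, control_matrix):
        cfg = KuramotoConfig(n_runs=3, n_samples=1500, burn_in=100, seed=13)
        e1 = run_ensemble(cfg, control_matrix)
        e2 = run_ensemble(cfg, control_matrix)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.data, b.data)

    def test_default_config_yields_14000_samples(self, control_matrix):
        cfg = KuramotoConfig(n_runs=2, seed=14)
        recs = run_ensemble(cfg, control_matrix)
        assert len(recs) == 2
        assert all(r.n_samples == 14000 for r in recs)

    def test_runs_differ_from_each_other(self, control_matrix):
        cfg = KuramotoConfig(n_runs=2, n_samples=1500, burn_in=100, seed=15)
        recs = run_ensemble(cfg, control_matrix)
        assert not np.allclose(recs[0].data, recs[1].data)


class TestCouplingSweep:
    def test_single_k_matches_standard_pipeline(self, control_matrix):
        cfg = KuramotoConfig(n_runs=2, n_samples=3000, burn_in=500, seed=16, time_unit_scale=1.0)
        table = coupling_sweep(cfg, control_matrix, [1.0])
        assert set(table.measure) == {"LZC", "HFD", "FDispEn"}
        recs = run_ensemble(cfg, control_matrix)
        direct = np.mean([lzc(ch) for rec in recs for ch in rec.data])
        got = table.loc[table.measure == "LZC", "mean_value"].item()
        assert got == pytest.approx(direct, rel=1e-12)

    def test_empty_k_values_rejected(self, control_matrix):
        cfg = KuramotoConfig(n_runs=1, seed=17)
        with pytest.raises(ValueError, match="k_values"):
            coupling_sweep(cfg, control_matrix, [])

    def test_uncoupled_row_matches_baseline(self, control_matrix):
        """The k = 0 row equals the complexity of uncoupled oscillators."""
        from dataclasses import replace

        cfg = KuramotoConfig(n_runs=2, n_samples=3000, burn_in=500, seed=19, time_unit_scale=1.0)
        table = coupling_sweep(cfg, control_matrix, [0.0])
        recs = run_ensemble(replace(cfg, k=0.0), control_matrix)
        baseline = np.mean([lzc(ch) for rec in recs for ch in rec.data])
        got = table.loc[table.measure == "LZC", "mean_value"].item()
        assert got == pytest.approx(baseline, rel=1e-12)
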