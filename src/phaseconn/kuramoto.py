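"""Kuramoto mean-field simulation of EEG channel dynamics.

The model couples N phase oscillators through a connectivity matrix
``a_ij``::

    dtheta_i/dt = omega_i + k * sum_j a_ij * sin(theta_j - theta_i)

integrated with forward Euler at step ``h``. Each oscillator stands for one
electrode site; its natural frequency is drawn from a normal distribution
centred in the alpha band (10 +/- 2 Hz), and the simulated EEG channel is
``x_i(t) = sin(theta_i(t))``. Global synchrony is tracked by the order
parameter ``r(t)``, the modulus of the mean unit phasor.

Units
-----
The natural frequencies are given in Hz; the integration step ``h`` is a
dimensionless time unit. ``time_unit_scale`` fixes how many seconds one time
unit represents, i.e. ``omega_i = 2*pi*f_i*time_unit_scale`` rad per time
unit. At the default ``time_unit_scale = 0.01`` a 10 Hz oscillator advances
~0.063 rad per step (well sampled). ``time_unit_scale = 1`` reproduces the
f-in-Hz / h = 0.1 arithmetic literally, where a 10 Hz oscillator advances a
full cycle per step and the recorded signal is its stroboscopic
(once-per-cycle) sampling; see docs/methods.md for why that regime is the
one that places coupling and frequency dispersion on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import ConnectivityMatrix, EEGRecording

__all__ = [
    "KuramotoConfig",
    "PhaseTrajectory",
    "simulate",
    "order_parameter",
    "to_eeg",
    "summed_signal",
    "run_ensemble",
    "coupling_sweep",
]


@dataclass
class KuramotoConfig:
    """All simulator parameters.

    Attributes
    ----------
    n_oscillators:
        Number of phase oscillators (one per EEG channel).
    k:
        Global coupling strength multiplying the connectivity matrix.
    freq_mean, freq_sd:
        Mean and SD (Hz) of the normal distribution the natural
        frequencies are drawn from.
    h:
        Forward-Euler integration step, in dimensionless time units.
    n_samples:
        Total number of integration steps recorded (including burn-in).
    burn_in:
        Leading samples discarded as initial transient.
    n_runs:
        Ensemble size for :func:`run_ensemble`.
    seed:
        Master seed; per-run subseeds are spawned from it.
    time_unit_scale:
        Seconds per dimensionless time unit (see module docstring).
    phase_noise_sd:
        SD of additive Gaussian phase noise per unit time (rad/sqrt(unit));
        0 disables noise. The per-step increment has SD
        ``phase_noise_sd * sqrt(h)``.
    normalize_coupling:
        If True, divide the coupling sum by N (classical mean-field
        normalisation). Default False: the sum is used as written.
    freq_floor:
        Lower clip (Hz) for frequency draws, preventing non-oscillating
        nodes.
    """

    n_oscillators: int = 21
    k: float = 1.0
    freq_mean: float = 10.0
    freq_sd: float = 2.0
    h: float = 0.1
    n_samples: int = 15000
    burn_in: int = 1000
    n_runs: int = 15
    seed: int = 0
    time_unit_scale: float = 0.01
    phase_noise_sd: float = 0.0
    normalize_coupling: bool = False
    freq_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.n_oscillators < 1:
            raise ValueError("n_oscillators must be positive")
        if self.h <= 0:
            raise ValueError("integration step h must be positive")
        if self.freq_sd < 0:
            raise ValueError("freq_sd must be nonnegative")
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_samples")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if self.phase_noise_sd < 0:
            raise ValueError("phase_noise_sd must be nonnegative")


@dataclass
class PhaseTrajectory:
    """Result of one simulation run, after burn-in removal.

    ``phases`` are unwrapped (cumulative) phase angles in radians, shaped
    ``(timepoints, N)``; ``order_r``/``mean_phase`` are the synchrony order
    parameter r(t) in [0, 1] and the collective mean phase psi(t).
    """

    phases: np.ndarray
    natural_freqs: np.ndarray
    order_r: np.ndarray
    mean_phase: np.ndarray
    h: float = 0.1
    time_unit_scale: float = 0.01

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.phases.shape[0]

    @property
    def fs(self) -> float:
        """Equivalent sampling rate in Hz (one sample per Euler step)."""
        return 1.0 / (self.h * self.time_unit_scale)


def order_parameter(phases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Synchrony order parameter r(t) and mean phase psi(t).

    ``r(t) e^{-i psi(t)} = (1/N) sum_j e^{-i theta_j(t)}``; r is the modulus
    of the mean unit phasor (0 = incoherent, 1 = fully synchronized).

    Parameters
    ----------
    phases:
        ``(timepoints, N)`` array (a single 1-D phase vector is also
        accepted and treated as one timepoint).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase array")
    squeeze = phases.ndim == 1
    if squeeze:
        phases = phases[None, :]
    mean_phasor = np.exp(1j * phases).mean(axis=1)
    r = np.abs(mean_phasor)
    psi = np.angle(mean_phasor)
    if squeeze:
        return float(r[0]), float(psi[0])
    return r, psi


def _integrate(
    theta0: np.ndarray,
    omega: np.ndarray,
    coupling: np.ndarray,
    k: float,
    h: float,
    n_samples: int,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Batched forward-Euler integration.

    ``theta0``/``omega`` are ``(R, N)`` (R independent runs), ``coupling``
    is the symmetric ``(N, N)`` matrix already including any 1/N factor,
    ``noise`` is ``(n_samples - 1, R, N)`` per-step phase increments or
    None. Returns unwrapped phases ``(n_samples, R, N)``.

    The coupling sum uses the identity
    ``sum_j a_ij sin(theta_j - theta_i) = Im(e^{-i theta_i} (A e^{i theta})_i)``.
    """
    n_runs, n_osc = theta0.shape
    phases = np.empty((n_samples, n_runs, n_osc), dtype=float)
    theta = theta0.copy()
    phases[0] = theta
    a = coupling * k
    h_omega = h * omega
    for t in range(1, n_samples):
        # sum_j a_ij sin(th_j - th_i) = cos(th_i)*(A sin th)_i - sin(th_i)*(A cos th)_i
        sin_t = np.sin(theta)
        cos_t = np.cos(theta)
        drive = cos_t * (sin_t @ a) - sin_t * (cos_t @ a)
        theta = theta + h_omega + (h * drive)
        if noise is not None:
            theta = theta + noise[t - 1]
        phases[t] = theta
        if t % 1000 == 0 and not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"non-finite phase at integration step {t}")
    if not np.all(np.isfinite(phases)):
        bad = int(np.argwhere(~np.isfinite(phases))[0, 0])
        raise FloatingPointError(f"non-finite phase at integration step {bad}")
    return phases


def _draw_run(cfg: KuramotoConfig, rng: np.random.Generator):
    """Draw one run's natural frequencies (Hz), initial phases, and noise."""
    freqs = rng.normal(cfg.freq_mean, cfg.freq_sd, cfg.n_oscillators)
    freqs = np.clip(freqs, cfg.freq_floor, None)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, cfg.n_oscillators)
    noise = None
    if cfg.phase_noise_sd > 0:
        noise = rng.normal(
            0.0,
            cfg.phase_noise_sd * np.sqrt(cfg.h),
            (cfg.n_samples - 1, cfg.n_oscillators),
        )
    return freqs, theta0, noise


def _check_coupling(cfg: KuramotoConfig, coupling: ConnectivityMatrix) -> np.ndarray:
    if coupling.n_nodes != cfg.n_oscillators:
        raise ValueError(
            f"coupling matrix has {coupling.n_nodes} nodes but config requests "
            f"{cfg.n_oscillators} oscillators"
        )
    w = coupling.weights
    if cfg.normalize_coupling:
        w = w / cfg.n_oscillators
    return w


def simulate(
    cfg: KuramotoConfig,
    coupling: ConnectivityMatrix,
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | None = None,
    init_phases: np.ndarray | None = None,
) -> PhaseTrajectory:
    """Run one Kuramoto simulation and return the post-burn-in trajectory.

    Natural frequencies are drawn once from Normal(freq_mean, freq_sd) Hz
    (clipped at ``freq_floor``), initial phases i.i.d. uniform on
    [0, 2*pi). Deterministic given ``cfg.seed`` (or the supplied ``rng``).
    ``freqs`` (Hz) and ``init_phases`` (rad) override the random draws,
    e.g. to study fixed-frequency configurations.
    """
    w = _check_coupling(cfg, coupling)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    drawn_freqs, drawn_theta0, noise = _draw_run(cfg, rng)
    freqs = drawn_freqs if freqs is None else np.asarray(freqs, dtype=float)
    theta0 = drawn_theta0 if init_phases is None else np.asarray(init_phases, dtype=float)
    if freqs.shape != (cfg.n_oscillators,) or theta0.shape != (cfg.n_oscillators,):
        raise ValueError("freqs and init_phases must have length n_oscillators")
    omega = 2.0 * np.pi * freqs * cfg.time_unit_scale
    phases = _integrate(
        theta0[None, :],
        omega[None, :],
        w,
        cfg.k,
        cfg.h,
        cfg.n_samples,
        noise[:, None, :] if noise is not None else None,
    )[cfg.burn_in :, 0, :]
    r, psi = order_parameter(phases)
    return PhaseTrajectory(
        phases=phases,
        natural_freqs=freqs,
        order_r=r,
        mean_phase=psi,
        h=cfg.h,
        time_unit_scale=cfg.time_unit_scale,
    )


def to_eeg(
    traj: PhaseTrajectory,
    labels: list[str],
    fs: float | None = None,
    subject_id: str = "",
    group: str = "simulated-control",
) -> EEGRecording:
    """Convert a phase trajectory to a simulated EEG recording.

    Channel i carries ``sin(theta_i(t))``; amplitudes are dimensionless in
    [-1, 1]. ``fs`` defaults to the trajectory's equivalent sampling rate.
    """
    if len(labels) != traj.n_oscillators:
        raise ValueError(
            f"{len(labels)} labels for {traj.n_oscillators} oscillators"
        )
    return EEGRecording(
        data=np.sin(traj.phases).T,
        fs=fs if fs is not None else traj.fs,
        channel_labels=list(labels),
        subject_id=subject_id,
        group=group,
    )


def summed_signal(traj: PhaseTrajectory) -> np.ndarray:
    """Diagnostic single-channel output ``sum_i sin(theta_i(t))``.

    Provided for comparison with the literal one-signal reading of the
    channel model; the per-channel ``sin(theta_i)`` reading is what the
    pipeline uses.
    """
    return np.sin(traj.phases).sum(axis=1)


def spawn_run_rngs(seed: int, n_runs: int) -> list[np.random.Generator]:
    """Per-run generators spawned from one master seed.

    Uses numpy's SeedSequence spawning, so run i's stream depends only on
    (seed, i) and ensembles are reproducible run-by-run.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_runs)]


def run_ensemble(
    cfg: KuramotoConfig,
    coupling: ConnectivityMatrix,
    labels: list[str] | None = None,
    group: str = "simulated-control",
) -> list[EEGRecording]:
    """Simulate ``cfg.n_runs`` independent runs and return their EEG.

    Each run draws fresh natural frequencies and initial phases from its
    own subseed (see :func:`spawn_run_rngs`); the integration itself is
    batched across runs for speed, which leaves each run's arithmetic
    independent of the others.
    """
    w = _check_coupling(cfg, coupling)
    if labels is None:
        labels = list(coupling.channel_labels)
    draws = [_draw_run(cfg, rng) for rng in spawn_run_rngs(cfg.seed, cfg.n_runs)]
    freqs = np.stack([d[0] for d in draws])
    theta0 = np.stack([d[1] for d in draws])
    noise = None
    if cfg.phase_noise_sd > 0:
        noise = np.stack([d[2] for d in draws], axis=1)  # (T-1, R, N)
    omega = 2.0 * np.pi * freqs * cfg.time_unit_scale
    try:
        phases = _integrate(theta0, omega, w, cfg.k, cfg.h, cfg.n_samples, noise)
    except FloatingPointError as exc:
        raise FloatingPointError(f"ensemble integration failed: {exc}") from exc
    phases = phases[cfg.burn_in :]
    recordings = []
    for i in range(cfg.n_runs):
        traj = PhaseTrajectory(
            phases=phases[:, i, :],
            natural_freqs=freqs[i],
            order_r=order_parameter(phases[:, i, :])[0],
            mean_phase=order_parameter(phases[:, i, :])[1],
            h=cfg.h,
            time_unit_scale=cfg.time_unit_scale,
        )
        recordings.append(
            to_eeg(traj, labels, subject_id=f"run{i:02d}", group=group)
        )
    return recordings


def coupling_sweep(
    cfg: KuramotoConfig,
    coupling: ConnectivityMatrix,
    k_values,
    params=None,
    region_map: dict[str, str] | None = None,
):
    """Mean complexity of the simulated EEG as a function of coupling k.

    For each k an ensemble of ``cfg.n_runs`` runs is simulated and the
    across-channel, across-run mean of each complexity measure is reported.

    Returns a DataFrame with columns ``k``, ``measure``, ``mean_value``.
    """
    import pandas as pd

    from .complexity import ComplexityParams, score_recording

    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be non-empty")
    if params is None:
        params = ComplexityParams(hfd_kmax=6)
    rows = []
    for k in k_values:
        recs = run_ensemble(replace(cfg, k=float(k)), coupling)
        tables = [score_recording(rec, params, region_map) for rec in recs]
        scores = pd.concat(tables, ignore_index=True)
        for measure, mean_value in scores.groupby("measure")["value"].mean().items():
            rows.append({"k": float(k), "measure": measure, "mean_value": mean_value})
    return pd.DataFrame(rows)
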