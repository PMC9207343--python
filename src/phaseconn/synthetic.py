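"""Synthetic EEG cohorts and connectivity matrices with controlled group structure.

The clinical recordings behind the original MCI-AD study are not shareable,
so this module fabricates inputs with the statistical structure the
analysis assumes: symmetric connectivity matrices whose mean off-diagonal
strength is set to a target (0.5575 for control-like, 0.4945 for
patient-like groups), and alpha-band-dominated multichannel EEG whose
inter-channel phase coupling follows a known ground-truth matrix. The EEG
generator runs the package's own Kuramoto simulator on the ground-truth
coupling — with per-oscillator phase noise to keep the ensemble in the
partially synchronized regime — and adds broadband Gaussian sensor noise,
which closes the loop: WPLI estimates from the generated signals can be
checked against the matrix that generated them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ConnectivityMatrix, EEGRecording
from .kuramoto import KuramotoConfig, simulate, to_eeg
from .regions import DEFAULT_CHANNELS

__all__ = [
    "SynthCohortConfig",
    "gen_connectivity_matrix",
    "jitter_matrix",
    "gen_synthetic_eeg",
    "pairwise_phase_locking",
]

#: Group-mean connectivity strengths reported for the averaged WPLI matrices.
CONTROL_MEAN_STRENGTH = 0.5575
PATIENT_MEAN_STRENGTH = 0.4945
#: Edge-value range of the averaged patient matrix; the control upper bound
#: is a package choice (the source reports no control range).
PATIENT_EDGE_RANGE = (0.1, 0.6)
CONTROL_EDGE_RANGE = (0.1, 0.95)


@dataclass
class SynthCohortConfig:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_subjects:
        Number of subjects to generate (15 control / 13 patient in the
        emulated study design).
    group_label:
        ``"control"`` or ``"patient"``.
    target_mean_strength:
        Desired mean of the off-diagonal connectivity entries.
    edge_value_range:
        Closed interval the individual edge weights must lie in.
    n_channels, fs, duration:
        Montage size, sampling rate (Hz), and record length (seconds);
        defaults 21 channels, 400 Hz, 300 s.
    alpha_center, alpha_sd:
        Mean and SD (Hz) of the oscillators' natural frequencies.
    noise_sd:
        SD of additive broadband sensor noise, relative to the
        unit-amplitude oscillation.
    coupling_gain:
        Coupling strength of the generating simulation (mean-field
        normalized). Together with ``phase_noise_sd`` it places the
        cohort in the partially synchronized regime, where pairwise
        phase locking tracks edge strength instead of collapsing into
        global synchrony.
    phase_noise_sd:
        SD of the simulator's phase noise (rad per sqrt time-unit); keeps
        the coupled system short of full phase locking so pairwise
        synchrony tracks edge strength.
    subject_jitter_sd:
        SD of the symmetric truncated-Gaussian jitter that turns the group
        matrix into per-subject matrices (between-subject variance).
    seed:
        Master seed for the cohort.
    """

    n_subjects: int = 15
    group_label: str = "control"
    target_mean_strength: float = CONTROL_MEAN_STRENGTH
    edge_value_range: tuple[float, float] = CONTROL_EDGE_RANGE
    n_channels: int = 21
    fs: float = 400.0
    duration: float = 300.0
    alpha_center: float = 10.0
    alpha_sd: float = 2.0
    noise_sd: float = 0.2
    coupling_gain: float = 3.0
    phase_noise_sd: float = 1.5
    subject_jitter_sd: float = 0.05
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.group_label not in ("control", "patient"):
            raise ValueError("group_label must be 'control' or 'patient'")
        lo, hi = self.edge_value_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("edge_value_range must be an interval within [0, 1]")
        if not (0 < self.target_mean_strength < 1):
            raise ValueError("target_mean_strength must lie in (0, 1)")
        if not lo <= self.target_mean_strength <= hi:
            raise ValueError(
                f"target mean {self.target_mean_strength} is infeasible for edge "
                f"range [{lo}, {hi}]"
            )
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.noise_sd < 0 or self.phase_noise_sd < 0 or self.subject_jitter_sd < 0:
            raise ValueError("noise SDs must be nonnegative")

    def channel_labels(self) -> list[str]:
        if self.n_channels == len(DEFAULT_CHANNELS):
            return list(DEFAULT_CHANNELS)
        return [f"ch{i}" for i in range(self.n_channels)]


def _rng_for(cfg: SynthCohortConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible substream of the cohort's master seed."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def gen_connectivity_matrix(cfg: SynthCohortConfig) -> ConnectivityMatrix:
    """A symmetric matrix whose off-diagonal mean hits the configured target.

    Edges are drawn i.i.d. uniform on ``edge_value_range``, shifted toward
    the target mean, and iteratively re-centered after clipping (at most
    100 rounds, tolerance 5e-4) — a monotone transform, so the rank order
    of the initial draw is preserved and every entry stays in range.
    """
    lo, hi = cfg.edge_value_range
    target = cfg.target_mean_strength
    n = cfg.n_channels
    rng = _rng_for(cfg, 0)
    iu = np.triu_indices(n, k=1)
    edges = rng.uniform(lo, hi, iu[0].size)
    if hi == lo:
        edges = np.full(iu[0].size, lo)
    else:
        tol = 5e-4
        for _ in range(100):
            edges = np.clip(edges + (target - edges.mean()), lo, hi)
            if abs(edges.mean() - target) <= tol:
                break
        if abs(edges.mean() - target) > 0.005:
            raise ValueError(
                f"could not reach target mean {target} within edge range [{lo}, {hi}]"
            )
    w = np.zeros((n, n))
    w[iu] = edges
    w = w + w.T
    return ConnectivityMatrix(weights=w, channel_labels=cfg.channel_labels())


def jitter_matrix(
    mat: ConnectivityMatrix,
    sd: float,
    rng: np.random.Generator,
    truncate_at: float = 2.0,
) -> ConnectivityMatrix:
    """Per-subject variant: add symmetric truncated-Gaussian edge jitter.

    Jitter is drawn once per upper-triangle edge from N(0, sd) truncated at
    ``truncate_at`` SDs, mirrored to keep symmetry, and the result clipped
    to [0, 1].
    """
    if sd == 0:
        return mat
    n = mat.n_nodes
    iu = np.triu_indices(n, k=1)
    noise = np.clip(rng.normal(0.0, sd, iu[0].size), -truncate_at * sd, truncate_at * sd)
    e = np.zeros((n, n))
    e[iu] = noise
    e = e + e.T
    return ConnectivityMatrix(
        weights=np.clip(mat.weights + e, 0.0, 1.0),
        channel_labels=mat.channel_labels,
    )


def _eeg_kuramoto_config(cfg: SynthCohortConfig, n_samples: int) -> KuramotoConfig:
    """Simulator settings that make one Euler step equal one EEG sample.

    With step h = 0.1 the time-unit scale is set to ``1/(fs*h)`` so a
    10 Hz oscillator advances ``2*pi*10/fs`` rad per sample. Coupling is
    mean-field normalized (divided by N) so the operating point set by
    ``coupling_gain`` and ``phase_noise_sd`` is independent of montage
    size; the defaults keep the cohort partially synchronized.
    """
    h = 0.1
    return KuramotoConfig(
        n_oscillators=cfg.n_channels,
        k=cfg.coupling_gain,
        freq_mean=cfg.alpha_center,
        freq_sd=cfg.alpha_sd,
        h=h,
        n_samples=n_samples + cfg.burn_in,
        burn_in=cfg.burn_in,
        n_runs=1,
        seed=cfg.seed,
        time_unit_scale=1.0 / (cfg.fs * h),
        phase_noise_sd=cfg.phase_noise_sd,
        normalize_coupling=True,
    )


def gen_synthetic_eeg(
    cfg: SynthCohortConfig,
    ground_truth: ConnectivityMatrix,
) -> list[EEGRecording]:
    """One alpha-band-dominated EEG recording per subject of the cohort.

    Each subject gets a jittered copy of ``ground_truth``
    (``subject_jitter_sd``), a Kuramoto simulation coupled through it, and
    additive broadband Gaussian noise at ``noise_sd``. Deterministic given
    ``cfg.seed``.
    """
    if ground_truth.n_nodes != cfg.n_channels:
        raise ValueError(
            f"ground-truth matrix has {ground_truth.n_nodes} nodes, config requests "
            f"{cfg.n_channels} channels"
        )
    n_samples = int(round(cfg.fs * cfg.duration))
    kcfg = _eeg_kuramoto_config(cfg, n_samples)
    labels = list(ground_truth.channel_labels)
    master = np.random.SeedSequence([cfg.seed, 1])
    recordings = []
    for s, child in enumerate(master.spawn(cfg.n_subjects)):
        rng = np.random.default_rng(child)
        subject_mat = jitter_matrix(ground_truth, cfg.subject_jitter_sd, rng)
        traj = simulate(kcfg, subject_mat, rng=rng)
        rec = to_eeg(
            traj,
            labels,
            fs=cfg.fs,
            subject_id=f"{cfg.group_label}{s:02d}",
            group=cfg.group_label,
        )
        if cfg.noise_sd > 0:
            rec.data = rec.data + rng.normal(0.0, cfg.noise_sd, rec.data.shape)
        recordings.append(rec)
    return recordings


def pairwise_phase_locking(rec: EEGRecording) -> np.ndarray:
    """Phase-locking value between all channel pairs of a recording.

    Diagnostic used to validate the generator: the modulus of the mean
    relative-phase phasor between the channels' analytic signals,
    symmetric with unit diagonal. Stronger ground-truth edges should show
    higher values. This is a generator-fidelity metric, not part of the
    connectivity-estimation surface (which is WPLI-only).
    """
    from scipy.signal import hilbert

    z = hilbert(rec.data, axis=1)
    z = z / np.abs(z)
    n = rec.n_channels
    plv = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            plv[i, j] = plv[j, i] = np.abs(np.mean(z[i] * np.conj(z[j])))
    return plv
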