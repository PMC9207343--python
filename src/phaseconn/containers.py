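"""Core data containers: multichannel EEG recordings and connectivity matrices.

Both containers validate their invariants on construction and provide
plain-text (CSV) round-tripping so every pipeline artifact can be inspected
with ordinary tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed values of :attr:`EEGRecording.group`.
GROUP_TAGS = (
    "control",
    "patient",
    "simulated-control",
    "simulated-patient",
    "simulated-lesion",
)


@dataclass
class EEGRecording:
    """A multichannel EEG time series.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` real array. Amplitudes are kept in the
        units of the source (microvolts for real recordings, dimensionless
        unit-amplitude oscillations for simulated ones).
    fs:
        Sampling frequency in Hz.
    channel_labels:
        One label per row of ``data`` (10-20 montage names for clinical EEG).
    subject_id:
        Identifier of the subject or simulation run.
    group:
        Cohort tag; one of :data:`GROUP_TAGS` or empty.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        self.channel_labels = list(self.channel_labels)
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contain non-finite samples")
        if self.group and self.group not in GROUP_TAGS:
            raise ValueError(f"unknown group tag {self.group!r}; use one of {GROUP_TAGS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the samples of one channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]

    def to_csv(self, path) -> None:
        """Write as CSV with one column per channel, header = channel labels."""
        pd.DataFrame(self.data.T, columns=self.channel_labels).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float = 400.0, subject_id: str = "", group: str = "") -> "EEGRecording":
        """Load a CSV written by :meth:`to_csv` (one column per channel)."""
        df = pd.read_csv(path)
        return cls(
            data=df.to_numpy(dtype=float).T,
            fs=fs,
            channel_labels=[str(c) for c in df.columns],
            subject_id=subject_id,
            group=group,
        )

    @classmethod
    def from_edf(cls, path, subject_id: str = "", group: str = "") -> "EEGRecording":
        """Load from an EDF file (requires the optional ``mne`` dependency)."""
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("reading EDF requires mne (pip install phaseconn[edf])") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return cls(
            data=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            subject_id=subject_id,
            group=group,
        )


@dataclass
class ConnectivityMatrix:
    """A symmetric, zero-diagonal, [0, 1]-valued weighted graph over channels.

    This is both the output of WPLI estimation and the coupling matrix
    ``a_ij`` fed to the Kuramoto simulator.
    """

    weights: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    #: tolerance on the symmetry invariant
    _SYM_TOL = 1e-12

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] < 2:
            raise ValueError("connectivity matrix needs at least 2 nodes")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if np.max(np.abs(w - w.T)) >= self._SYM_TOL:
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w
        self.channel_labels = list(self.channel_labels)
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(w.shape[0])]
        if len(self.channel_labels) != w.shape[0]:
            raise ValueError("label count does not match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def mean_strength(self) -> float:
        """Arithmetic mean of the strict upper-triangle entries."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return float(self.weights[iu].mean())

    def to_csv(self, path) -> None:
        """Write as CSV with channel labels as header row and index column."""
        pd.DataFrame(
            self.weights, index=self.channel_labels, columns=self.channel_labels
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(weights=df.to_numpy(dtype=float), channel_labels=[str(c) for c in df.columns])
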