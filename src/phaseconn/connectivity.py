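"""Weighted phase lag index (WPLI) connectivity estimation and the lesion transform.

WPLI quantifies phase synchronization between two channels while
discounting zero-lag (volume-conduction) coupling: phase leads and lags are
weighted by the magnitude of the imaginary part of the cross-spectrum, so
consistent non-zero-lag interaction drives the index toward 1 while
zero-lag or inconsistent-lag activity drives it toward 0::

    WPLI = | sum_t |Im S_xy(t)| sgn(Im S_xy(t)) |  /  sum_t |Im S_xy(t)|

The default estimator of the cross-spectrum S_xy(t) is the instantaneous
(Hilbert analytic-signal) product z_x(t) * conj(z_y(t)), evaluated on
band-limited input; a Welch segment-averaged alternative is available. The
absolute value of the numerator keeps the index in [0, 1] (the sign only
encodes which channel leads).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .containers import ConnectivityMatrix, EEGRecording

__all__ = [
    "wpli_pair",
    "connectivity_matrix",
    "average_matrices",
    "mean_strength",
    "induce_lesion",
]

#: Minimum number of samples accepted by the pairwise estimator.
MIN_SAMPLES = 64


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D time series")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    return x, y


def _wpli_from_imag(imag_sxy: np.ndarray, magnitude: float) -> float:
    """WPLI from the imaginary cross-spectrum terms.

    ``magnitude`` is the summed modulus of the full cross-spectrum; when
    the imaginary part is zero relative to it (phase-identical signals,
    where only rounding noise survives), the 0/0 convention returns 0 (no
    lagged interaction detectable).
    """
    denom = np.sum(np.abs(imag_sxy))
    if denom <= 1e-12 * magnitude or magnitude == 0.0:
        return 0.0
    return float(np.abs(np.sum(np.abs(imag_sxy) * np.sign(imag_sxy))) / denom)


def wpli_pair(
    x: np.ndarray,
    y: np.ndarray,
    edge_fraction: float = 0.05,
    estimator: str = "hilbert",
    fs: float | None = None,
    nperseg: int = 1024,
    band: tuple[float, float] = (8.0, 13.0),
) -> float:
    """WPLI between two band-limited time series; value in [0, 1].

    Parameters
    ----------
    x, y:
        Equal-length 1-D series (>= 64 samples), expected band-limited.
    edge_fraction:
        Fraction of samples discarded at each end of the analytic signal
        before summation, to suppress Hilbert edge transients.
    estimator:
        ``"hilbert"`` (default): instantaneous cross-spectrum from analytic
        signals, one term per time point. ``"welch"``: cross-spectra of
        Hanning-windowed segments, summed over segments and the frequency
        bins inside ``band`` (requires ``fs``).
    """
    x, y = _validate_pair(x, y)
    if not 0 <= edge_fraction < 0.5:
        raise ValueError("edge_fraction must lie in [0, 0.5)")
    if estimator == "hilbert":
        zx = hilbert(x)
        zy = hilbert(y)
        sxy = zx * np.conj(zy)
        n_trim = int(round(edge_fraction * x.size))
        if n_trim > 0:
            sxy = sxy[n_trim:-n_trim]
        return _wpli_from_imag(sxy.imag, np.abs(sxy).sum())
    if estimator == "welch":
        if fs is None:
            raise ValueError("the welch estimator requires fs")
        terms = _welch_imag_cross(x, y, fs=fs, nperseg=nperseg, band=band)
        return _wpli_from_imag(terms.imag, np.abs(terms).sum())
    raise ValueError(f"unknown estimator {estimator!r}")


def _welch_imag_cross(x, y, fs, nperseg, band):
    """Complex cross-spectrum terms over segments x in-band frequency bins."""
    nperseg = int(min(nperseg, x.size))
    step = nperseg // 2  # 50% overlap
    window = np.hanning(nperseg)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError(f"no FFT bins inside band {band} at fs={fs}, nperseg={nperseg}")
    terms = []
    for start in range(0, x.size - nperseg + 1, max(step, 1)):
        seg_x = np.fft.rfft(window * x[start : start + nperseg])
        seg_y = np.fft.rfft(window * y[start : start + nperseg])
        terms.append((seg_x * np.conj(seg_y))[in_band])
    return np.concatenate(terms)


def connectivity_matrix(
    rec: EEGRecording,
    edge_fraction: float = 0.05,
    estimator: str = "hilbert",
    nperseg: int = 1024,
    band: tuple[float, float] = (8.0, 13.0),
) -> ConnectivityMatrix:
    """Pairwise WPLI over all channel pairs of a recording.

    Entry (i, j) is ``wpli_pair(channel_i, channel_j)``; the diagonal is 0
    and the matrix is symmetric by construction.
    """
    n = rec.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    if rec.n_samples < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {rec.n_samples}")
    weights = np.zeros((n, n), dtype=float)
    if estimator == "hilbert":
        # compute analytic signals once, pairwise products after
        z = hilbert(rec.data, axis=1)
        n_trim = int(round(edge_fraction * rec.n_samples))
        sl = slice(n_trim, rec.n_samples - n_trim) if n_trim > 0 else slice(None)
        for i in range(n):
            for j in range(i + 1, n):
                sxy = (z[i] * np.conj(z[j]))[sl]
                weights[i, j] = weights[j, i] = _wpli_from_imag(sxy.imag, np.abs(sxy).sum())
        return ConnectivityMatrix(weights=weights, channel_labels=rec.channel_labels)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                weights[i, j] = weights[j, i] = wpli_pair(
                    rec.data[i],
                    rec.data[j],
                    edge_fraction=edge_fraction,
                    estimator=estimator,
                    fs=rec.fs,
                    nperseg=nperseg,
                    band=band,
                )
            except ValueError as exc:
                raise ValueError(
                    f"WPLI failed for channel pair "
                    f"({rec.channel_labels[i]}, {rec.channel_labels[j]}): {exc}"
                ) from exc
    return ConnectivityMatrix(weights=weights, channel_labels=rec.channel_labels)


def average_matrices(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise arithmetic mean of connectivity matrices (e.g. across subjects)."""
    if not mats:
        raise ValueError("cannot average an empty list of matrices")
    labels = mats[0].channel_labels
    for m in mats[1:]:
        if m.channel_labels != labels:
            raise ValueError("all matrices must share the same channel labels")
    stacked = np.stack([m.weights for m in mats])
    return ConnectivityMatrix(weights=stacked.mean(axis=0), channel_labels=labels)


def mean_strength(mat: ConnectivityMatrix) -> float:
    """Mean of the strict upper-triangle entries (N(N-1)/2 edge weights)."""
    return mat.mean_strength()


def induce_lesion(
    mat: ConnectivityMatrix,
    region_channels,
    strength: float = 0.1,
) -> ConnectivityMatrix:
    """Replace every edge incident to a region's channels by a constant strength.

    Emulates a network lesion: all off-diagonal entries (i, j) with i or j
    in ``region_channels`` are set to ``strength``; everything else is
    unchanged. The matrix is undirected, so "edges originating in" the
    region is read as all incident edges, applied symmetrically.
    """
    if not 0 <= strength <= 1:
        raise ValueError("lesion strength must lie in [0, 1]")
    region_channels = list(region_channels)
    unknown = [c for c in region_channels if c not in mat.channel_labels]
    if unknown:
        raise ValueError(f"unknown channel labels: {unknown}")
    idx = np.array(
        [mat.channel_labels.index(c) for c in region_channels], dtype=int
    )
    w = mat.weights.copy()
    if idx.size:
        mask = np.zeros(mat.n_nodes, dtype=bool)
        mask[idx] = True
        incident = mask[:, None] | mask[None, :]
        np.fill_diagonal(incident, False)
        w[incident] = strength
    return ConnectivityMatrix(weights=w, channel_labels=mat.channel_labels)
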