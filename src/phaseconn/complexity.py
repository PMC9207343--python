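"""Signal-complexity estimators: Lempel-Ziv complexity, Higuchi's fractal
dimension, and fluctuation-based dispersion entropy.

All three quantify different facets of "structural richness" of a time
series and are invariant to positive affine transforms of the input:

* **LZC** binarizes the signal at its median and counts the distinct
  productions of an exhaustive left-to-right LZ76 parsing, normalized by
  the random-sequence asymptote ``n / log2(n)``. Regular signals score near
  0, i.i.d. binary noise near 1.
* **HFD** estimates a fractal dimension in [1, 2] from the log-log slope of
  mean curve lengths at subsampling scales ``k = 1..kmax`` (1 = smooth
  curve, 2 = noise-like).
* **FDispEn** maps samples to ``c`` classes through the normal CDF, embeds
  with dimension ``m`` and delay ``d``, takes successive differences of the
  class patterns, and returns the Shannon entropy of the resulting
  fluctuation-pattern distribution over the ``(2c-1)**(m-1)`` possible
  patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import EEGRecording

__all__ = [
    "ComplexityParams",
    "MEASURES",
    "lz76_count",
    "lzc",
    "hfd",
    "fdispen",
    "score_recording",
    "regional_means",
]

MEASURES = ("LZC", "HFD", "FDispEn")


@dataclass
class ComplexityParams:
    """Tunable parameters of the three estimators.

    ``hfd_kmax`` is 18 for real EEG and 6 for simulated signals in the
    reference configuration; FDispEn uses embedding dimension ``m = 3``,
    ``c = 3`` classes, delay 1, and a normal-CDF amplitude mapping by
    default, reported as unnormalized natural-log entropy.
    """

    hfd_kmax: int = 6
    fdispen_m: int = 3
    fdispen_c: int = 3
    fdispen_d: int = 1
    fdispen_mapping: str = "normal-cdf"
    fdispen_normalize: bool = False
    lzc_threshold_rule: str = "median"

    def __post_init__(self) -> None:
        if self.hfd_kmax < 2:
            raise ValueError("hfd_kmax must be >= 2")
        if self.fdispen_m < 2:
            raise ValueError("fdispen_m must be >= 2")
        if self.fdispen_c < 2:
            raise ValueError("fdispen_c must be >= 2")
        if self.fdispen_d < 1:
            raise ValueError("fdispen_d must be >= 1")
        if self.fdispen_mapping not in ("normal-cdf", "linear"):
            raise ValueError("fdispen_mapping must be 'normal-cdf' or 'linear'")
        if self.lzc_threshold_rule != "median":
            raise ValueError("only the median threshold rule is supported")


# ---------------------------------------------------------------------------
# Lempel-Ziv complexity
# ---------------------------------------------------------------------------


def _lz76_scan_bytes(s: bytes) -> int:
    """Reference LZ76 scan using C-speed substring search."""
    n = len(s)
    c = 1  # the first symbol is always a production
    p = 1
    while p < n:
        e = p + 1
        # extend the candidate word while it still occurs earlier
        while e <= n and s.find(s[p:e], 0, e - 1) != -1:
            e += 1
        c += 1
        p = e
    return c


try:  # compiled scan: same parsing, linear-memory Kaspar-Schuster loop
    from numba import njit

    @njit(cache=True)
    def _lz76_scan_arr(ss):  # pragma: no cover - exercised via lz76_count
        n = ss.size
        i = 0
        k = 1
        l = 1
        k_max = 1
        c = 1
        while l + 1 <= n:
            if ss[i + k - 1] == ss[l + k - 1]:
                k += 1
                if l + k > n:
                    c += 1
                    break
            else:
                if k > k_max:
                    k_max = k
                i += 1
                if i == l:
                    c += 1
                    l += k_max
                    if l + 1 > n:
                        break
                    i = 0
                    k = 1
                    k_max = 1
                else:
                    k = 1
        return c

except ImportError:  # pragma: no cover - numba is an optional accelerator
    _lz76_scan_arr = None


def lz76_count(bits) -> int:
    """Number of productions in the exhaustive LZ76 parsing of a binary string.

    The sequence is scanned left to right; each production is the shortest
    prefix of the remaining suffix that does not occur as a substring of
    the sequence read so far (overlap with the production's own start is
    allowed; the final, possibly incomplete word counts as one production).
    Example: ``0100`` parses as ``0 | 1 | 00`` giving 3.
    """
    arr = np.asarray(bits)
    if arr.dtype != np.uint8:
        arr = np.array([1 if int(b) else 0 for b in np.ravel(arr)], dtype=np.uint8)
    if arr.size == 0:
        raise ValueError("empty sequence")
    if _lz76_scan_arr is not None:
        return int(_lz76_scan_arr(arr))
    return _lz76_scan_bytes(arr.tobytes())


def binarize_median(signal: np.ndarray) -> np.ndarray:
    """Median binarization: strictly above the median -> 1, else (ties) -> 0."""
    signal = np.asarray(signal, dtype=float)
    return (signal > np.median(signal)).astype(np.uint8)


def lzc(signal: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity ``C(n) = c(n) / (n / log2 n)``.

    The signal is binarized at its median (strict comparison, so a
    constant signal becomes all zeros) before LZ76 parsing. Values near 0
    indicate regular signals, near 1 (asymptotically) random ones.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 32:
        raise ValueError(f"need at least 32 samples for LZC, got {n}")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    c = lz76_count(binarize_median(signal))
    return c * np.log2(n) / n


# ---------------------------------------------------------------------------
# Higuchi's fractal dimension
# ---------------------------------------------------------------------------


def hfd(signal: np.ndarray, kmax: int = 6) -> float:
    """Higuchi's fractal dimension of a 1-D series.

    For each scale ``k`` and offset ``m`` in ``1..k``, the subsampled curve
    ``y(m), y(m+k), y(m+2k), ...`` has normalized length::

        L_m(k) = (1/k) * [ (N-1) / (floor((N-m)/k) * k) * sum_i |y(m+ik) - y(m+(i-1)k)| ]

    The scale lengths ``L(k) = mean_m L_m(k)`` follow ``L(k) ~ k**(-D)``
    for a fractal curve; the dimension is the least-squares slope of
    ``ln L(k)`` against ``ln(1/k)`` over ``k = 1..kmax`` (unweighted fit).
    Smooth curves give D near 1, uncorrelated noise near 2.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < 10 * kmax:
        raise ValueError(f"signal too short for kmax={kmax}: need >= {10 * kmax} samples, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    log_lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = np.empty(k)
        for m in range(1, k + 1):
            idx = np.arange(m - 1, n, k)
            n_int = (n - m) // k  # number of increments (Gauss bracket)
            if n_int < 1:
                raise ValueError(f"kmax={kmax} too large for signal length {n}")
            total = np.abs(np.diff(x[idx])).sum()
            lengths[m - 1] = (total * (n - 1) / (n_int * k)) / k
        log_lk[k - 1] = np.log(lengths.mean())
    log_inv_k = -np.log(np.arange(1, kmax + 1))
    slope, _ = np.polyfit(log_inv_k, log_lk, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# Fluctuation-based dispersion entropy
# ---------------------------------------------------------------------------


def _map_to_classes(x: np.ndarray, c: int, mapping: str) -> np.ndarray:
    """Map amplitudes to integer classes 1..c."""
    if mapping == "normal-cdf":
        mu = x.mean()
        sd = x.std()
        if sd == 0:
            # zero-variance fallback: every sample to the middle class
            return np.full(x.size, (c + 1) // 2, dtype=int)
        y = norm.cdf(x, loc=mu, scale=sd)
    elif mapping == "linear":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.full(x.size, (c + 1) // 2, dtype=int)
        y = (x - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return np.clip(np.round(c * y + 0.5).astype(int), 1, c)


def fdispen(signal: np.ndarray, params: ComplexityParams | None = None) -> float:
    """Fluctuation-based dispersion entropy of a 1-D series.

    Samples are mapped to classes 1..c, embedded with dimension ``m`` and
    delay ``d``, and each embedded vector is reduced to its vector of
    successive class differences (each in ``-(c-1)..(c-1)``). The result is
    the Shannon entropy (natural log) of the relative frequencies of the
    ``(2c-1)**(m-1)`` possible fluctuation patterns, optionally divided by
    its maximum ``ln((2c-1)**(m-1))``.
    """
    if params is None:
        params = ComplexityParams()
    m, c, d = params.fdispen_m, params.fdispen_c, params.fdispen_d
    x = np.asarray(signal, dtype=float)
    n = x.size
    min_len = (m - 1) * d + 100
    if n < min_len:
        raise ValueError(f"need at least {min_len} samples for FDispEn, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    u = _map_to_classes(x, c, params.fdispen_mapping)
    n_vec = n - (m - 1) * d
    # embedded class vectors, then successive differences -> pattern codes
    emb = np.stack([u[i * d : i * d + n_vec] for i in range(m)], axis=1)
    fluct = np.diff(emb, axis=1) + (c - 1)  # each in 0..2c-2
    base = 2 * c - 1
    codes = fluct @ (base ** np.arange(m - 1))
    counts = np.bincount(codes, minlength=base ** (m - 1))
    p = counts[counts > 0] / n_vec
    entropy = float(-(p * np.log(p)).sum())
    if params.fdispen_normalize:
        entropy /= np.log(float(base ** (m - 1)))
    return entropy


# ---------------------------------------------------------------------------
# Per-recording scoring
# ---------------------------------------------------------------------------


def score_recording(
    rec: EEGRecording,
    params: ComplexityParams | None = None,
    region_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All three complexity measures for every channel of a recording.

    Returns a long-format table with one row per channel x measure and
    columns ``group, unit, channel, region, measure, value``. ``unit`` is
    the recording's subject/run identifier. If ``region_map`` is given,
    every channel must appear in it; if None, the region column is filled
    with ``"all"``.
    """
    if params is None:
        params = ComplexityParams()
    if region_map is not None:
        unmapped = [c for c in rec.channel_labels if c not in region_map]
        if unmapped:
            raise ValueError(f"channels missing from region map: {unmapped}")
    rows = []
    for label, x in zip(rec.channel_labels, rec.data):
        region = region_map[label] if region_map is not None else "all"
        values = {
            "LZC": lzc(x),
            "HFD": hfd(x, kmax=params.hfd_kmax),
            "FDispEn": fdispen(x, params),
        }
        for measure, value in values.items():
            rows.append(
                {
                    "group": rec.group,
                    "unit": rec.subject_id,
                    "channel": label,
                    "region": region,
                    "measure": measure,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def regional_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-unit regional summaries: mean over each region's channels.

    Input is a long-format complexity table (as from
    :func:`score_recording`, possibly concatenated over units); output has
    one row per (unit, region, measure).
    """
    required = {"unit", "region", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"complexity table lacks columns {sorted(missing)}")
    return (
        table.groupby(["unit", "region", "measure"], as_index=False)["value"]
        .mean()
        .sort_values(["unit", "region", "measure"], ignore_index=True)
    )
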