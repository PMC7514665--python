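"""Fixed sample entropy (fSampEn) on windows and as a moving-window series.

Sample entropy of a window ``x`` of length N is ``-ln(A/B)`` where B counts
pairs of length-``m`` templates whose Chebyshev distance is at most the
tolerance (self-matches excluded) and A counts the same for length ``m+1``;
both counts run over the N - m templates starting at i = 0..N-m-1
(Richman–Moorman convention). In fSampEn the tolerance is *fixed* in signal
units rather than rescaled per window, so the statistic tracks amplitude as
well as complexity — the property that lets it attenuate quasi-periodic
cardiac transients relative to conventional RMS/ARV amplitude estimators.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from .signals import EntropySeries, FSampEnParams, SampledSignal, WindowSeries

__all__ = [
    "YENTES_MIN_SAMPLES",
    "sampen_fixed",
    "sampen_profile",
    "window_positions",
    "moving_fsampen",
    "moving_fsampen_multi",
    "moving_rms",
]

#: Minimum window length (in samples) recommended for reliable fSampEn
#: (Yentes et al. criterion); shorter windows trigger a warning, not an error.
YENTES_MIN_SAMPLES = 200


def _template_distances(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev distance matrices between templates of length m and m+1.

    Returns (d_m, d_m1), each of shape (M, M) with M = N - m; entry (i, j)
    is max_k |x[i+k] - x[j+k]| over the template span.
    """
    n = x.size
    M = n - m
    D = np.abs(x[:, None] - x[None, :])
    dm = D[:M, :M].copy()
    for k in range(1, m):
        np.maximum(dm, D[k : k + M, k : k + M], out=dm)
    dm1 = np.maximum(dm, D[m : m + M, m : m + M])
    return dm, dm1


def _pair_count(d: np.ndarray, tol: float) -> int:
    """Number of unordered template pairs i < j with d[i, j] <= tol."""
    M = d.shape[0]
    return (int(np.count_nonzero(d <= tol)) - M) // 2


def _entropy_from_counts(a: int, b: int) -> tuple[float, bool]:
    """(-ln(A/B), capped_flag) with the degenerate-count conventions."""
    if b == 0:
        return math.nan, False
    if a == 0:
        return math.log(b), True  # cap at -ln(1/B)
    return -math.log(a / b), False


def sampen_fixed(window: Sequence[float], m: int, tolerance: float) -> float:
    """Sample entropy of one window at a fixed tolerance, in nats.

    Parameters
    ----------
    window
        Signal samples; length must exceed ``m + 1``.
    m
        Embedding dimension.
    tolerance
        Similarity radius in signal units (> 0). Two templates match when
        their Chebyshev distance is at most this value.

    Returns
    -------
    float
        ``-ln(A/B)``. If no m-length template pairs match (B = 0) the value
        is undefined and NaN is returned with a warning; if B > 0 but no
        (m+1)-length pairs match (A = 0) the value is capped at ``-ln(1/B)``
        (flagged via warning), keeping downstream cross-covariance usable.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("window must be one-dimensional")
    if not (tolerance > 0):
        raise ValueError("tolerance must be positive")
    m = int(m)
    if m < 1:
        raise ValueError("m must be a positive integer")
    if x.size <= m + 1:
        raise ValueError(f"window of {x.size} samples too short for m={m}")
    dm, dm1 = _template_distances(x, m)
    b = _pair_count(dm, tolerance)
    a = _pair_count(dm1, tolerance)
    value, capped = _entropy_from_counts(a, b)
    if math.isnan(value):
        warnings.warn(
            "no matching template pairs at length m; sample entropy undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    elif capped:
        warnings.warn(
            "no matching template pairs at length m+1; value capped at ln(B)",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


def sampen_profile(
    window: np.ndarray, m: int, tolerances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sample entropy of one window at several fixed tolerances.

    The template distance structure is computed once and shared across
    tolerances, which makes a tolerance grid nearly free compared with
    repeated :func:`sampen_fixed` calls. Returns ``(values, capped)`` arrays
    aligned with ``tolerances``. No warnings are emitted; degenerate windows
    yield NaN / capped entries silently (callers inspect the flags).
    """
    x = np.asarray(window, dtype=np.float64)
    tols = np.asarray(tolerances, dtype=np.float64)
    m = int(m)
    if x.size <= m + 1:
        raise ValueError(f"window of {x.size} samples too short for m={m}")
    if np.any(tols <= 0):
        raise ValueError("tolerances must be positive")
    dm, dm1 = _template_distances(x, m)
    M = dm.shape[0]
    values = np.empty(tols.size)
    capped = np.zeros(tols.size, dtype=bool)
    if tols.size >= 6:
        sm = np.sort(dm, axis=None)
        sm1 = np.sort(dm1, axis=None)
        bs = (np.searchsorted(sm, tols, side="right") - M) // 2
        as_ = (np.searchsorted(sm1, tols, side="right") - M) // 2
    else:
        bs = np.array([_pair_count(dm, t) for t in tols])
        as_ = np.array([_pair_count(dm1, t) for t in tols])
    for i, (a, b) in enumerate(zip(as_, bs)):
        values[i], capped[i] = _entropy_from_counts(int(a), int(b))
    return values, capped


def window_positions(n_samples: int, n_window: int, step: int) -> np.ndarray:
    """Start offsets 0, step, 2*step, ... with offset + n_window <= n_samples."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if n_window > n_samples:
        raise ValueError("window longer than signal")
    n_win = (n_samples - n_window) // step + 1
    return np.arange(n_win) * step


def _window_times(signal: SampledSignal, starts: np.ndarray, n_window: int) -> np.ndarray:
    return signal.t0 + (starts + (n_window - 1) / 2.0) / signal.fs


def moving_fsampen_multi(
    signal: SampledSignal,
    m: int,
    window_length_s: float,
    overlap: float,
    tolerances: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """fSampEn over a moving window for several tolerances at once.

    Returns ``(times, values, capped)`` where ``values`` has shape
    ``(n_windows, n_tolerances)``. This is the workhorse behind both
    :func:`moving_fsampen` and the parameter-grid evaluation.
    """
    tols = np.atleast_1d(np.asarray(tolerances, dtype=np.float64))
    n_window = int(round(window_length_s * signal.fs))
    if n_window <= m + 1:
        raise ValueError("window too short for embedding dimension")
    if n_window > signal.n:
        raise ValueError(
            f"signal of {signal.n} samples shorter than one {n_window}-sample window"
        )
    if n_window < YENTES_MIN_SAMPLES:
        warnings.warn(
            f"window of {n_window} samples is below the {YENTES_MIN_SAMPLES}-sample "
            "minimum recommended for fSampEn",
            UserWarning,
            stacklevel=2,
        )
    step = max(1, int(round((1.0 - overlap) * n_window)))
    starts = window_positions(signal.n, n_window, step)
    values = np.empty((starts.size, tols.size))
    capped = np.zeros((starts.size, tols.size), dtype=bool)
    x = signal.samples
    for i, s in enumerate(starts):
        values[i], capped[i] = sampen_profile(x[s : s + n_window], m, tols)
    return _window_times(signal, starts, n_window), values, capped


def moving_fsampen(signal: SampledSignal, params: FSampEnParams) -> EntropySeries:
    """fSampEn time-series of a signal with one fixed tolerance.

    Windows start at multiples of ``step = max(1, round((1-overlap)*N))``
    with ``N = round(window_length_s * fs)``; a trailing partial window is
    dropped. Each value equals :func:`sampen_fixed` on the extracted window
    with the constant tolerance ``params.tolerance``.
    """
    params.window_samples(signal.fs)  # validates N > m + 1
    times, values, capped = moving_fsampen_multi(
        signal, params.m, params.window_length_s, params.overlap,
        np.array([params.tolerance]),
    )
    if np.any(np.isnan(values)):
        warnings.warn(
            "windows with no template matches produced NaN fSampEn values",
            RuntimeWarning,
            stacklevel=2,
        )
    return EntropySeries(
        values=values[:, 0],
        times=times,
        source_label=signal.label,
        params=params,
        capped=capped[:, 0],
    )


def moving_rms(
    signal: SampledSignal, window_length_s: float, overlap: float
) -> WindowSeries:
    """Moving-window RMS with the same windowing scheme as fSampEn.

    Conventional amplitude estimator used as the comparison baseline for
    cardiac robustness; heavily influenced by cardiac transients because
    every sample contributes quadratically.
    """
    n_window = int(round(window_length_s * signal.fs))
    if n_window < 1 or n_window > signal.n:
        raise ValueError("invalid window length")
    step = max(1, int(round((1.0 - overlap) * n_window)))
    starts = window_positions(signal.n, n_window, step)
    x = signal.samples
    values = np.array(
        [math.sqrt(float(np.mean(x[s : s + n_window] ** 2))) for s in starts]
    )
    return WindowSeries(
        values=values,
        times=_window_times(signal, starts, n_window),
        source_label=signal.label,
    )
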