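"""Scoring of fSampEn series against pressures and the parameter grid.

An fSampEn time-series is scored against a respiratory pressure signal by
the maximum normalized cross-covariance ``c_max``: the pressure is oriented
effort-positive, interpolated onto the (coarser) entropy timestamps, both
series are mean-removed and the Pearson correlation is evaluated at every
integer-step lag within a bound, the maximum over lags being ``c_max`` in
[-1, 1]. The parameter grid spans window lengths 0.1-0.5 s (step 0.05 s),
tolerance multipliers r = 0.05-0.6 (step 0.05) and two SD modes (individual
vs global), with m = 2 and 90 % window overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .entropy import moving_fsampen_multi
from .signals import SampledSignal, WindowSeries

__all__ = [
    "GRID_WINDOWS_S",
    "GRID_R_VALUES",
    "SD_MODES",
    "GridResult",
    "DeltaCmax",
    "effort_positive",
    "max_crosscov",
    "enumerate_grid_series",
    "grid_series_count",
    "grid_evaluate",
    "summarize_cohort",
    "delta_cmax",
]

#: Window lengths tested in the parameter evaluation, seconds.
GRID_WINDOWS_S: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))
#: Tolerance multipliers tested in the parameter evaluation.
GRID_R_VALUES: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.601, 0.05), 2))
#: Reference-SD modes.
SD_MODES: tuple[str, str] = ("individual", "global")


def effort_positive(
    pressure: SampledSignal, polarity: str = "inspiratory-negative"
) -> SampledSignal:
    """Orient a pressure channel so inspiratory effort deflects positively.

    Mouth pressure during threshold-loaded inspiration is negative, so it is
    negated by default; transdiaphragmatic pressure is already
    effort-positive and should be passed with ``polarity="inspiratory-positive"``.
    """
    if polarity == "inspiratory-negative":
        return pressure.with_samples(-pressure.samples)
    if polarity == "inspiratory-positive":
        return pressure
    raise ValueError(f"unknown polarity {polarity!r}")


def _lagged_pearson(
    x: np.ndarray, y: np.ndarray, max_lag: int, normalized: bool, min_overlap: int = 10
) -> tuple[float, int]:
    """Max over lags of the (NaN-aware) correlation of x against y shifted.

    Positive lag means x is delayed by ``lag`` steps relative to y. NaN
    entries (undefined entropy windows, excluded cycles) are dropped
    pairwise per lag. Lags are scanned nearest-first so that ties (e.g. at
    one full breathing period in quasi-periodic series) resolve to the
    smallest |lag|.
    """
    n = x.size
    best_val, best_lag = -np.inf, 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        if lag >= 0:
            a, b = x[lag:], y[: n - lag]
        else:
            a, b = x[: n + lag], y[-lag:]
        valid = np.isfinite(a) & np.isfinite(b)
        if np.count_nonzero(valid) < min_overlap:
            continue
        a, b = a[valid], b[valid]
        a = a - a.mean()
        b = b - b.mean()
        if normalized:
            denom = np.sqrt((a @ a) * (b @ b))
            if denom == 0:
                raise ValueError("zero-variance series in cross-covariance")
            val = float((a @ b) / denom)
        else:
            val = float((a @ b) / a.size)
        if val > best_val:
            best_val, best_lag = val, lag
    if not np.isfinite(best_val):
        raise ValueError("insufficient overlapping points for cross-covariance")
    return best_val, best_lag


def _crosscov_xy(
    times: np.ndarray,
    values: np.ndarray,
    pressure: SampledSignal,
    max_lag_s: float,
    polarity: str,
    normalized: bool,
) -> tuple[float, float]:
    p = effort_positive(pressure, polarity)
    pt = p.times
    inside = (times >= pt[0]) & (times <= pt[-1])
    if np.count_nonzero(inside) < 10:
        raise ValueError("fewer than 10 overlapping points after alignment")
    t = times[inside]
    x = np.asarray(values, dtype=np.float64)[inside]
    y = np.interp(t, pt, p.samples)
    if x.size > 1:
        dt = float(np.median(np.diff(t)))
    else:
        dt = 1.0
    max_lag = min(int(round(max_lag_s / dt)), x.size - 10)
    max_lag = max(max_lag, 0)
    cmax, lag = _lagged_pearson(x, y, max_lag, normalized)
    return cmax, lag * dt


def max_crosscov(
    entropy: WindowSeries,
    pressure: SampledSignal,
    max_lag_s: float = 5.0,
    polarity: str = "inspiratory-negative",
    normalized: bool = True,
) -> tuple[float, float]:
    """Maximum cross-covariance of a windowed series and a pressure signal.

    Returns ``(c_max, lag_s)``; positive lag means the windowed series is
    delayed relative to the pressure. With ``normalized=True`` (default) the
    value is a Pearson correlation at the best lag, invariant to positive
    affine transforms of either input and bounded by [-1, 1]; with
    ``normalized=False`` the raw mean-removed covariance is returned.
    """
    return _crosscov_xy(
        entropy.times, entropy.values, pressure, max_lag_s, polarity, normalized
    )


def enumerate_grid_series(
    signal_labels: Sequence[str],
    conditions: Sequence[str],
    windows: Sequence[float] = GRID_WINDOWS_S,
    r_values: Sequence[float] = GRID_R_VALUES,
    sd_modes: Sequence[str] = SD_MODES,
) -> Iterator[tuple[str, str, float, float, str]]:
    """Every (signal, condition, window, r, sd_mode) combination of the grid.

    One fSampEn time-series is computed per combination; enumerating them
    gives the grid cardinality (e.g. 11 signals x 6 conditions x 9 windows
    x 12 r x 2 SD modes = 14,256 series for a healthy-montage subject).
    """
    for label in signal_labels:
        for cond in conditions:
            for w in windows:
                for r in r_values:
                    for mode in sd_modes:
                        yield (label, cond, w, r, mode)


def grid_series_count(
    n_signals: int,
    n_conditions: int,
    windows: Sequence[float] = GRID_WINDOWS_S,
    r_values: Sequence[float] = GRID_R_VALUES,
    sd_modes: Sequence[str] = SD_MODES,
) -> int:
    """Number of fSampEn series the grid evaluation computes for one subject."""
    labels = [f"s{i}" for i in range(n_signals)]
    conds = [f"c{i}" for i in range(n_conditions)]
    return sum(1 for _ in enumerate_grid_series(labels, conds, windows, r_values, sd_modes))


@dataclass(frozen=True)
class GridResult:
    """c_max matrix over (window length, r, SD mode) for one group/pressure.

    ``cmax[i, j, k]`` is the c_max at window ``window_lengths_s[i]``,
    multiplier ``r_values[j]`` and SD mode ``sd_modes[k]``, averaged over
    the group's member signals and recording conditions.
    """

    window_lengths_s: tuple[float, ...]
    r_values: tuple[float, ...]
    sd_modes: tuple[str, ...]
    cmax: np.ndarray
    group: str = ""
    pressure_label: str = ""
    n_subjects: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.cmax, dtype=np.float64)
        expected = (len(self.window_lengths_s), len(self.r_values), len(self.sd_modes))
        if c.shape != expected:
            raise ValueError(f"cmax shape {c.shape} != grid shape {expected}")
        object.__setattr__(self, "cmax", c)

    def _mode_index(self, sd_mode: str) -> int:
        return self.sd_modes.index(sd_mode)

    def row_argmax(self, sd_mode: str = "global") -> list[int]:
        """Best r index per window row (ties broken toward smaller r)."""
        k = self._mode_index(sd_mode)
        return [int(np.argmax(self.cmax[i, :, k])) for i in range(len(self.window_lengths_s))]

    def global_argmax(self, sd_mode: str = "global") -> tuple[int, int]:
        """(window index, r index) of the matrix-wide maximum.

        Ties are broken toward smaller r first, then smaller window.
        """
        k = self._mode_index(sd_mode)
        mat = self.cmax[:, :, k]
        best = mat.max()
        iw_list, ir_list = np.where(mat == best)
        order = np.lexsort((iw_list, ir_list))  # smallest r, then smallest window
        j = order[0]
        return int(iw_list[j]), int(ir_list[j])

    def at(self, window_s: float, r: float, sd_mode: str) -> float:
        iw = int(np.argmin(np.abs(np.asarray(self.window_lengths_s) - window_s)))
        ir = int(np.argmin(np.abs(np.asarray(self.r_values) - r)))
        if abs(self.window_lengths_s[iw] - window_s) > 1e-9:
            raise KeyError(f"window {window_s} s not on the grid")
        if abs(self.r_values[ir] - r) > 1e-9:
            raise KeyError(f"r {r} not on the grid")
        return float(self.cmax[iw, ir, self._mode_index(sd_mode)])

    def to_records(self) -> list[dict]:
        """Long-format rows (group, pressure, window_s, r, sd_mode, c_max)."""
        rows = []
        for i, w in enumerate(self.window_lengths_s):
            for j, r in enumerate(self.r_values):
                for k, mode in enumerate(self.sd_modes):
                    rows.append(
                        {
                            "group": self.group,
                            "pressure": self.pressure_label,
                            "window_s": w,
                            "r": r,
                            "sd_mode": mode,
                            "c_max": float(self.cmax[i, j, k]),
                        }
                    )
        return rows


def grid_evaluate(
    member_signals: Mapping[str, Mapping[str, SampledSignal]],
    pressures: Mapping[str, SampledSignal],
    sd_individual: float,
    sd_global: float,
    windows: Sequence[float] = GRID_WINDOWS_S,
    r_values: Sequence[float] = GRID_R_VALUES,
    m: int = 2,
    overlap: float = 0.9,
    max_lag_s: float = 5.0,
    pressure_polarity: str = "inspiratory-negative",
    normalized: bool = True,
    group: str = "",
    pressure_label: str = "",
    exclude_times: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> GridResult:
    """Evaluate the full (window, r, SD mode) grid for one signal group.

    ``member_signals`` maps channel label -> condition -> preprocessed
    signal; ``pressures`` maps condition -> the designated pressure channel.
    For every grid cell, every member signal and every condition, the
    fSampEn series is computed and scored with :func:`max_crosscov`; c_max
    is averaged (unweighted) over member signals and conditions. The 2x
    tolerance sets (r x individual SD and r x global SD) share one distance
    computation per window, so the SD-mode axis is nearly free.

    ``exclude_times`` optionally maps a condition to intervals (start, end)
    in seconds whose entropy windows are masked out of the scoring (rejected
    breath cycles).
    """
    if not pressures:
        raise ValueError("missing pressure channel")
    windows = tuple(windows)
    r_arr = np.asarray(r_values, dtype=np.float64)
    tol_ind = r_arr * sd_individual
    tol_glob = r_arr * sd_global
    tols = np.concatenate([tol_ind, tol_glob])
    acc = np.zeros((len(windows), len(r_arr), 2))
    count = 0
    import warnings as _warnings

    for label, per_cond in member_signals.items():
        for cond, sig in per_cond.items():
            if cond not in pressures:
                raise ValueError(f"missing pressure channel for condition {cond!r}")
            pressure = pressures[cond]
            cell = np.empty((len(windows), len(r_arr), 2))
            for i, w in enumerate(windows):
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", UserWarning)
                    times, vals, _ = moving_fsampen_multi(sig, m, w, overlap, tols)
                if exclude_times and cond in exclude_times:
                    for s0, s1 in exclude_times[cond]:
                        vals[(times >= s0) & (times < s1), :] = np.nan
                for j in range(tols.size):
                    c, _ = _crosscov_xy(
                        times, vals[:, j], pressure, max_lag_s,
                        pressure_polarity, normalized,
                    )
                    cell[i, j % len(r_arr), j // len(r_arr)] = c
            acc += cell
            count += 1
    if count == 0:
        raise ValueError("no member signals to evaluate")
    return GridResult(
        window_lengths_s=windows,
        r_values=tuple(float(r) for r in r_arr),
        sd_modes=SD_MODES,
        cmax=acc / count,
        group=group,
        pressure_label=pressure_label,
    )


def summarize_cohort(grids: Sequence[GridResult]) -> GridResult:
    """Elementwise mean of per-subject c_max matrices (argmaxes recomputed)."""
    if not grids:
        raise ValueError("need at least one subject grid")
    first = grids[0]
    for g in grids[1:]:
        if (
            g.window_lengths_s != first.window_lengths_s
            or g.r_values != first.r_values
            or g.sd_modes != first.sd_modes
        ):
            raise ValueError("subject grids have mismatched axes")
    mean = np.mean([g.cmax for g in grids], axis=0)
    return GridResult(
        window_lengths_s=first.window_lengths_s,
        r_values=first.r_values,
        sd_modes=first.sd_modes,
        cmax=mean,
        group=first.group,
        pressure_label=first.pressure_label,
        n_subjects=len(grids),
    )


@dataclass(frozen=True)
class DeltaCmax:
    """Cost of using cohort-global instead of subject-optimal parameters.

    ``delta_pct = 100 * |c_glob - c_ind| / c_ind`` where ``c_ind`` is the
    subject's best c_max over r (individual SD, fixed window) and ``c_glob``
    the c_max at the cohort-global r with the global SD.
    """

    c_ind: float
    c_glob: float
    individual_r: float
    global_r: float

    @property
    def delta_pct(self) -> float:
        return 100.0 * abs(self.c_glob - self.c_ind) / self.c_ind


def delta_cmax(
    grid: GridResult, global_r: float, window_s: float = 0.5
) -> DeltaCmax:
    """Compare subject-optimal and cohort-global parameters at a fixed window."""
    iw = int(np.argmin(np.abs(np.asarray(grid.window_lengths_s) - window_s)))
    if abs(grid.window_lengths_s[iw] - window_s) > 1e-9:
        raise KeyError(f"window {window_s} s not on the grid")
    k_ind = grid.sd_modes.index("individual")
    row = grid.cmax[iw, :, k_ind]
    ir_best = int(np.argmax(row))
    c_ind = float(row[ir_best])
    if c_ind == 0:
        raise ValueError("individual-optimal c_max is zero")
    c_glob = grid.at(window_s, global_r, "global")
    return DeltaCmax(
        c_ind=c_ind,
        c_glob=c_glob,
        individual_r=float(grid.r_values[ir_best]),
        global_r=float(global_r),
    )
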