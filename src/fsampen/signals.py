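"""Core containers for uniformly sampled physiological signals.

All channels — oesophageal/surface EMG (volts), accelerometer MMG (g) and
pressures (cmH2O) — are represented by :class:`SampledSignal`, a thin frozen
wrapper around a float64 array with a sampling rate, label, units and start
time. Moving-window estimators return :class:`WindowSeries` (generic) or
:class:`EntropySeries` (fSampEn, with its parameter set and cap flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SampledSignal",
    "FSampEnParams",
    "WindowSeries",
    "EntropySeries",
]


@dataclass(frozen=True)
class SampledSignal:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples
        Signal values; converted to a read-only float64 array.
    fs
        Sampling rate in Hz (> 0).
    label
        Channel identifier, e.g. ``"sEMGlic R"`` or ``"Pmo"``.
    units
        Unit string: ``"V"`` for EMG, ``"g"`` for MMG, ``"cmH2O"`` for
        pressures.
    t0
        Time of the first sample in seconds from recording start.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if x.size < 2:
            raise ValueError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite samples in channel {self.label!r}")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")
        x = x.copy()
        x.flags.writeable = False
        object.__setattr__(self, "samples", x)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, **changes) -> "SampledSignal":
        """Return a copy with new samples (and optional field changes)."""
        return replace(self, samples=samples, **changes)

    def index_range(self, start_s: float, end_s: float) -> tuple[int, int]:
        """Sample index range covering the half-open interval [start, end)."""
        eps = 1e-9
        i0 = int(np.ceil((start_s - self.t0) * self.fs - eps))
        i1 = int(np.ceil((end_s - self.t0) * self.fs - eps))
        return max(i0, 0), min(max(i1, 0), self.n)


@dataclass(frozen=True)
class FSampEnParams:
    """Parameter set for fixed sample entropy.

    The tolerance is ``r * sd_ref`` in signal units and is held constant
    across every window, signal and condition of a group — that fixity is
    what makes the estimator amplitude-sensitive.

    Attributes
    ----------
    m
        Embedding dimension (template length), typically 2.
    r
        Tolerance multiplier.
    sd_ref
        Reference standard deviation in signal units (individual or global
        SD of the signal group).
    window_length_s
        Moving-window length in seconds.
    overlap
        Fractional overlap of adjacent windows in [0, 1); 0.9 means 90 %.
    """

    m: int = 2
    r: float = 0.3
    sd_ref: float = 1.0
    window_length_s: float = 0.5
    overlap: float = 0.9

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("m must be a positive integer")
        object.__setattr__(self, "m", int(self.m))
        if not (self.r > 0):
            raise ValueError("r must be positive")
        if not (self.sd_ref > 0):
            raise ValueError("sd_ref must be positive")
        if not (self.window_length_s > 0):
            raise ValueError("window length must be positive")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def tolerance(self) -> float:
        """Similarity radius r * sd_ref, in signal units."""
        return self.r * self.sd_ref

    def window_samples(self, fs: float) -> int:
        """Window length in samples at rate ``fs``: round(window_length_s * fs)."""
        n = int(round(self.window_length_s * fs))
        if n <= self.m + 1:
            raise ValueError(
                f"window of {n} samples too short for m={self.m} (need > m + 1)"
            )
        return n

    def step_samples(self, fs: float) -> int:
        """Hop between window starts: max(1, round((1 - overlap) * N))."""
        n = self.window_samples(fs)
        return max(1, int(round((1.0 - self.overlap) * n)))


@dataclass(frozen=True)
class WindowSeries:
    """A moving-window summary series (e.g. RMS) with window-center times."""

    values: np.ndarray
    times: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        t = np.asarray(self.times, dtype=np.float64)
        if v.shape != t.shape or v.ndim != 1:
            raise ValueError("values and times must be 1-D arrays of equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("window times must be strictly increasing")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)


@dataclass(frozen=True)
class EntropySeries(WindowSeries):
    """fSampEn values (nats) at window-center timestamps.

    ``capped`` flags windows where no (m+1)-length matches were found and the
    value was capped at the information-theoretic bound -ln(1/B); windows
    with no m-length matches at all carry NaN.
    """

    params: FSampEnParams = field(default_factory=FSampEnParams)
    capped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        super().__post_init__()
        c = np.asarray(self.capped, dtype=bool)
        if c.size == 0:
            c = np.zeros(self.values.shape, dtype=bool)
        if c.shape != self.values.shape:
            raise ValueError("capped mask must match values")
        object.__setattr__(self, "capped", c)
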