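"""Breath segmentation from mouth pressure and SD calibration of tolerance.

Respiratory phases are delimited by zero crossings of the mouth-pressure
signal (sub-sample boundaries by linear interpolation). Phases shorter than
a minimum duration (default 0.5 s) are treated as spurious sign flips and
absorbed into the surrounding phase. The tolerance reference SD of a signal
group is the mean, across member channels, of the SD of all inspiratory
samples concatenated over every recording condition; cohort-level "global"
SDs are the mean of the per-subject individual SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .signals import SampledSignal

__all__ = [
    "INSPIRATORY",
    "EXPIRATORY",
    "Phase",
    "BreathSegmentation",
    "SignalGroup",
    "CohortCalibration",
    "detect_phases",
    "apply_exclusions",
    "inspiratory_samples",
    "individual_sd",
    "global_sd",
]

INSPIRATORY = "inspiratory"
EXPIRATORY = "expiratory"


class Phase(NamedTuple):
    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class BreathSegmentation:
    """Ordered, alternating inspiratory/expiratory intervals, [start, end)."""

    phases: tuple[Phase, ...]
    min_duration_s: float = 0.5

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_label = None
        for p in self.phases:
            if p.label not in (INSPIRATORY, EXPIRATORY):
                raise ValueError(f"unknown phase label {p.label!r}")
            if p.start < prev_end - 1e-12 or p.end <= p.start:
                raise ValueError("phases must be ordered and non-overlapping")
            if p.label == prev_label:
                raise ValueError("phase labels must alternate")
            prev_end, prev_label = p.end, p.label

    def __len__(self) -> int:
        return len(self.phases)

    def select(self, label: str) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.label == label)

    @property
    def n_cycles(self) -> int:
        """Number of breath cycles (= inspiratory phases)."""
        return len(self.select(INSPIRATORY))

    def cycles(self) -> list[tuple[Phase, ...]]:
        """Cycles as (inspiratory phase, following expiratory phase if any)."""
        out: list[tuple[Phase, ...]] = []
        phases = self.phases
        for i, p in enumerate(phases):
            if p.label != INSPIRATORY:
                continue
            if i + 1 < len(phases) and phases[i + 1].label == EXPIRATORY:
                out.append((p, phases[i + 1]))
            else:
                out.append((p,))
        return out

    def to_table(self) -> list[tuple[float, float, str]]:
        return [(p.start, p.end, p.label) for p in self.phases]


def _filled_signs(x: np.ndarray) -> np.ndarray:
    """Sample signs with zeros replaced by the next nonzero sign (then previous)."""
    s = np.sign(x)
    nz = s != 0
    if not nz.any():
        raise ValueError("no respiratory cycles detected: signal identically zero")
    idx = np.where(nz, np.arange(s.size), s.size)
    nxt = np.minimum.accumulate(idx[::-1])[::-1]
    filled = np.where(nxt < s.size, s[np.minimum(nxt, s.size - 1)], 0)
    # trailing zeros: carry last nonzero sign forward
    last = np.where(nz)[0][-1]
    filled[last + 1 :] = s[last]
    return filled


def detect_phases(
    pmo: SampledSignal,
    polarity: str = "inspiratory-negative",
    min_duration_s: float = 0.5,
) -> BreathSegmentation:
    """Segment breaths by the zero crossings of the mouth-pressure signal.

    Boundaries fall at sign changes, with linear interpolation between the
    straddling samples for sub-sample timing. Interior phases shorter than
    ``min_duration_s`` are absorbed into the preceding phase (the two
    boundaries around the short phase are removed, so a spurious sign flip
    inside a phase leaves the phase count unchanged); leading/trailing
    partial phases shorter than the threshold are dropped. ``polarity``
    states which pressure sign corresponds to inspiration.
    """
    if polarity not in ("inspiratory-negative", "inspiratory-positive"):
        raise ValueError(f"unknown polarity {polarity!r}")
    x = pmo.samples
    t = pmo.times
    signs = _filled_signs(x)
    change = np.where(signs[:-1] != signs[1:])[0]
    if change.size == 0:
        raise ValueError("no respiratory cycles detected: Pmo never crosses zero")
    # sub-sample crossing times
    crossings = []
    for i in change:
        x0, x1 = x[i], x[i + 1]
        frac = 0.0 if x1 == x0 else x0 / (x0 - x1)
        crossings.append(t[i] + np.clip(frac, 0.0, 1.0) / pmo.fs)
    t_end = pmo.t0 + pmo.n / pmo.fs
    bounds = [pmo.t0, *crossings, t_end]
    seg_signs = [signs[0], *[signs[i + 1] for i in change]]
    segments = [
        (bounds[k], bounds[k + 1], seg_signs[k]) for k in range(len(seg_signs))
        if bounds[k + 1] > bounds[k]
    ]

    # absorb short interior phases into the preceding phase
    changed = True
    while changed:
        changed = False
        for k in range(1, len(segments) - 1):
            if segments[k][1] - segments[k][0] < min_duration_s:
                a, b, c = segments[k - 1], segments[k], segments[k + 1]
                segments[k - 1 : k + 2] = [(a[0], c[1], a[2])]
                changed = True
                break
    # drop short edge partials
    while segments and segments[0][1] - segments[0][0] < min_duration_s:
        segments.pop(0)
    while segments and segments[-1][1] - segments[-1][0] < min_duration_s:
        segments.pop()
    if not segments:
        raise ValueError("no respiratory phases longer than the minimum duration")

    insp_sign = -1 if polarity == "inspiratory-negative" else 1
    phases = tuple(
        Phase(s, e, INSPIRATORY if sg == insp_sign else EXPIRATORY)
        for s, e, sg in segments
    )
    return BreathSegmentation(phases, min_duration_s=min_duration_s)


def apply_exclusions(
    segmentation: BreathSegmentation, excluded_cycles: Sequence[int]
) -> BreathSegmentation:
    """Remove listed breath cycles (0-based indices over inspiratory phases).

    A cycle is an inspiratory phase together with its following expiratory
    phase; removing both preserves label alternation. Excluded cycles drop
    out of all downstream SD and evaluation computations.
    """
    cycles = segmentation.cycles()
    for i in excluded_cycles:
        if not (0 <= i < len(cycles)):
            raise IndexError(f"cycle index {i} out of range (0..{len(cycles) - 1})")
    drop: set[tuple[float, float]] = set()
    for i in excluded_cycles:
        for p in cycles[i]:
            drop.add((p.start, p.end))
    kept = tuple(p for p in segmentation.phases if (p.start, p.end) not in drop)
    return BreathSegmentation(kept, min_duration_s=segmentation.min_duration_s)


def inspiratory_samples(
    signal: SampledSignal, segmentation: BreathSegmentation
) -> np.ndarray:
    """Concatenated samples of all kept inspiratory intervals of one channel."""
    parts = []
    for p in segmentation.select(INSPIRATORY):
        i0, i1 = signal.index_range(p.start, p.end)
        if i1 > i0:
            parts.append(signal.samples[i0:i1])
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


@dataclass(frozen=True)
class SignalGroup:
    """A subject's group of like signals sharing one fSampEn tolerance.

    Standard groups: ``oesEMGdi`` (five oesophageal electrode pairs, healthy
    subjects only), ``sEMG`` (surface EMG channels) and ``|sMMG|``
    (accelerometer norm channels).
    """

    group_label: str
    members: tuple[str, ...]
    individual_sd: float = 0.0
    cohort: str = "healthy"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a signal group needs at least one member channel")
        if self.individual_sd < 0:
            raise ValueError("individual SD cannot be negative")


def individual_sd(
    member_signals: Mapping[str, Sequence[SampledSignal]],
    segmentations: Sequence[BreathSegmentation],
) -> float:
    """Subject-level reference SD of a signal group.

    ``member_signals`` maps each member channel to its per-condition
    (preprocessed) signals; ``segmentations`` holds the matching
    per-condition breath segmentations (already filtered by any cycle
    exclusions). For each channel, all kept inspiratory samples across all
    conditions are concatenated and their population SD taken; the group SD
    is the arithmetic mean over channels. Order of channels and conditions
    is immaterial.
    """
    if not member_signals:
        raise ValueError("empty signal group")
    sds = []
    for label, signals in member_signals.items():
        if len(signals) != len(segmentations):
            raise ValueError(
                f"channel {label!r}: {len(signals)} signals for "
                f"{len(segmentations)} segmentations"
            )
        chunks = [
            inspiratory_samples(sig, seg)
            for sig, seg in zip(signals, segmentations)
        ]
        data = np.concatenate(chunks) if chunks else np.empty(0)
        if data.size == 0:
            raise ValueError(f"channel {label!r} has no inspiratory samples")
        sds.append(float(np.std(data)))  # population SD (ddof=0)
    return float(np.mean(sds))


def global_sd(individual_sds: Sequence[float]) -> float:
    """Cohort-level SD for a group: arithmetic mean of individual SDs."""
    if len(individual_sds) == 0:
        raise ValueError("need at least one individual SD")
    vals = np.asarray(individual_sds, dtype=np.float64)
    if np.any(vals <= 0):
        raise ValueError("individual SDs must be positive")
    return float(np.mean(vals))


@dataclass
class CohortCalibration:
    """Per-subject individual SDs and derived cohort-global SDs per group."""

    individual: dict[str, dict[str, float]] = field(default_factory=dict)
    cohort: str = "healthy"

    def add_subject(self, subject_id: str, sds: Mapping[str, float]) -> None:
        self.individual[subject_id] = dict(sds)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for sds in self.individual.values():
            for g in sds:
                if g not in seen:
                    seen.append(g)
        return seen

    def global_sd(self, group: str) -> float:
        vals = [sds[group] for sds in self.individual.values() if group in sds]
        return global_sd(vals)

    def as_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "individual": self.individual,
            "global": {g: self.global_sd(g) for g in self.groups()},
        }
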