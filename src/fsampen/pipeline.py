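"""Subject- and cohort-level orchestration of the analysis stages.

Glue between the raw :class:`~fsampen.simulate.SubjectRecord` (or files read
back from disk) and the per-module operations: conditioning every channel,
segmenting breaths from mouth pressure, calibrating individual/global SDs,
computing fSampEn series at the proposed general parameters and running the
full parameter grid. The CLI is a thin wrapper over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import preprocessing as prep
from .entropy import moving_fsampen
from .evaluation import (
    GRID_R_VALUES,
    GRID_WINDOWS_S,
    GridResult,
    grid_evaluate,
)
from .segmentation import (
    BreathSegmentation,
    apply_exclusions,
    detect_phases,
    individual_sd,
)
from .signals import EntropySeries, FSampEnParams, SampledSignal
from .simulate import SubjectRecord

__all__ = [
    "GENERAL_PARAMS",
    "GENERAL_GLOBAL_SD",
    "GENERAL_R",
    "ProcessedSubject",
    "preprocess_subject",
    "segment_subject",
    "calibrate_subject",
    "general_entropy_series",
    "evaluate_subject",
]

#: Proposed general reference SDs per signal group (cohort-global values):
#: volts for the EMG groups, g for the accelerometer-norm group.
GENERAL_GLOBAL_SD: dict[str, float] = {
    "oesEMGdi": 0.0121,
    "sEMG": 0.0022,
    "|sMMG|": 0.0060,
}

#: Proposed general tolerance multipliers per signal group.
GENERAL_R: dict[str, float] = {
    "oesEMGdi": 0.05,
    "sEMG": 0.3,
    "|sMMG|": 0.5,
}

#: Proposed general windowing: 0.5 s moving window, 90 % overlap, m = 2.
GENERAL_WINDOW_S = 0.5
GENERAL_OVERLAP = 0.9
GENERAL_M = 2

#: Full general parameter sets per group.
GENERAL_PARAMS: dict[str, FSampEnParams] = {
    g: FSampEnParams(
        m=GENERAL_M,
        r=GENERAL_R[g],
        sd_ref=GENERAL_GLOBAL_SD[g],
        window_length_s=GENERAL_WINDOW_S,
        overlap=GENERAL_OVERLAP,
    )
    for g in GENERAL_GLOBAL_SD
}


@dataclass
class ProcessedSubject:
    """A subject after signal conditioning.

    ``channels`` maps processed myographic labels (EMG channels, MMG norm
    channels) to per-condition signals; ``pressures`` holds ``Pmo`` and,
    when gastric/oesophageal pressures were recorded, the derived ``Pdi``.
    """

    subject_id: str
    montage: str
    conditions: tuple[str, ...]
    groups: dict[str, tuple[str, ...]]
    channels: dict[str, dict[str, SampledSignal]]
    pressures: dict[str, dict[str, SampledSignal]]
    segmentations: dict[str, BreathSegmentation] = field(default_factory=dict)


def preprocess_subject(
    record: SubjectRecord,
    copd_interference: bool | None = None,
    emg_fs: float = 2000.0,
    mmg_fs: float = 500.0,
    emg_band: tuple[float, float] = (10.0, 600.0),
    mmg_band: tuple[float, float] = (5.0, 40.0),
    order: int = 8,
    order_is_effective: bool = False,
) -> ProcessedSubject:
    """Condition every myographic channel of a subject.

    EMG channels run through the resample/band-pass/comb chain (plus the
    64 / 192.5 Hz notches when ``copd_interference``, which defaults to true
    for the COPD montage); MMG axis triplets are filtered then collapsed to
    their Euclidean norm. Pressure channels pass through, with
    transdiaphragmatic pressure derived from the gastric/oesophageal pair
    when present.
    """
    if copd_interference is None:
        copd_interference = record.montage == "copd"
    channels: dict[str, dict[str, SampledSignal]] = {}
    for lbl in record.emg_labels():
        channels[lbl] = {
            cond: prep.preprocess_emg(
                sig, target_fs=emg_fs, band=emg_band, order=order,
                copd_interference=copd_interference,
                order_is_effective=order_is_effective,
            )
            for cond, sig in record.channels[lbl].items()
        }
    for base, axes in record.mmg_sensors().items():
        out_label = f"|{base}|"
        channels[out_label] = {}
        for cond in record.conditions:
            channels[out_label][cond] = prep.preprocess_mmg(
                {ax: record.channels[raw_lbl][cond] for ax, raw_lbl in axes.items()},
                target_fs=mmg_fs, band=mmg_band, order=order,
                order_is_effective=order_is_effective, label=out_label,
            )
    pressures: dict[str, dict[str, SampledSignal]] = {
        "Pmo": dict(record.pressures["Pmo"])
    }
    if "Pga" in record.pressures and "Poes" in record.pressures:
        pressures["Pdi"] = {
            cond: prep.compute_pdi(
                record.pressures["Pga"][cond], record.pressures["Poes"][cond]
            )
            for cond in record.conditions
        }
    return ProcessedSubject(
        subject_id=record.subject_id,
        montage=record.montage,
        conditions=record.conditions,
        groups=dict(record.groups),
        channels=channels,
        pressures=pressures,
    )


def segment_subject(
    subject: ProcessedSubject,
    polarity: str = "inspiratory-negative",
    min_duration_s: float = 0.5,
    exclusions: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, BreathSegmentation]:
    """Per-condition breath segmentation from mouth pressure.

    ``exclusions`` maps a condition name to 0-based breath-cycle indices to
    reject; excluded cycles drop out of SD calibration and evaluation.
    The result is also stored on ``subject.segmentations``.
    """
    segs: dict[str, BreathSegmentation] = {}
    for cond in subject.conditions:
        seg = detect_phases(subject.pressures["Pmo"][cond], polarity=polarity,
                            min_duration_s=min_duration_s)
        if exclusions and cond in exclusions:
            seg = apply_exclusions(seg, exclusions[cond])
        segs[cond] = seg
    subject.segmentations = segs
    return segs


def calibrate_subject(
    subject: ProcessedSubject,
    segmentations: Mapping[str, BreathSegmentation] | None = None,
) -> dict[str, float]:
    """Individual (subject-level) SD per signal group."""
    segs = segmentations or subject.segmentations
    if not segs:
        raise ValueError("subject has no segmentations; run segment_subject first")
    ordered = [segs[c] for c in subject.conditions]
    out: dict[str, float] = {}
    for group, members in subject.groups.items():
        member_signals = {
            lbl: [subject.channels[lbl][c] for c in subject.conditions]
            for lbl in members
        }
        out[group] = individual_sd(member_signals, ordered)
    return out


def general_entropy_series(
    subject: ProcessedSubject,
    params: Mapping[str, FSampEnParams] = GENERAL_PARAMS,
) -> dict[str, dict[str, EntropySeries]]:
    """fSampEn series of every channel at the general parameters.

    Returns channel label -> condition -> series, using the parameter set of
    the channel's group.
    """
    by_channel: dict[str, dict[str, EntropySeries]] = {}
    group_of = {lbl: g for g, members in subject.groups.items() for lbl in members}
    for lbl, per_cond in subject.channels.items():
        p = params[group_of[lbl]]
        by_channel[lbl] = {
            cond: moving_fsampen(sig, p) for cond, sig in per_cond.items()
        }
    return by_channel


def evaluate_subject(
    subject: ProcessedSubject,
    sd_individual: Mapping[str, float],
    sd_global: Mapping[str, float],
    windows: Sequence[float] = GRID_WINDOWS_S,
    r_values: Sequence[float] = GRID_R_VALUES,
    m: int = 2,
    overlap: float = 0.9,
    max_lag_s: float = 5.0,
    groups: Sequence[str] | None = None,
    pressures: Sequence[str] | None = None,
) -> dict[tuple[str, str], GridResult]:
    """Run the parameter grid for every (signal group, pressure) pairing.

    Mouth pressure is evaluated for every group; transdiaphragmatic pressure
    additionally when available. Returns ``(group, pressure) -> GridResult``.
    """
    group_names = list(groups) if groups is not None else list(subject.groups)
    pressure_names = (
        list(pressures) if pressures is not None else list(subject.pressures)
    )
    exclude = _excluded_intervals(subject)
    results: dict[tuple[str, str], GridResult] = {}
    for group in group_names:
        members = subject.groups[group]
        member_signals = {lbl: subject.channels[lbl] for lbl in members}
        for plabel in pressure_names:
            polarity = (
                "inspiratory-positive" if plabel == "Pdi" else "inspiratory-negative"
            )
            results[(group, plabel)] = grid_evaluate(
                member_signals,
                subject.pressures[plabel],
                sd_individual=sd_individual[group],
                sd_global=sd_global[group],
                windows=windows,
                r_values=r_values,
                m=m,
                overlap=overlap,
                max_lag_s=max_lag_s,
                pressure_polarity=polarity,
                group=group,
                pressure_label=plabel,
                exclude_times=exclude,
            )
    return results


def _excluded_intervals(
    subject: ProcessedSubject,
) -> dict[str, list[tuple[float, float]]] | None:
    """Time spans of breath cycles rejected by the segmentation exclusions.

    Detected as gaps in the kept phase sequence (the raw segmentation is
    contiguous; exclusions leave holes).
    """
    if not subject.segmentations:
        return None
    out: dict[str, list[tuple[float, float]]] = {}
    for cond, seg in subject.segmentations.items():
        gaps = []
        for a, b in zip(seg.phases, seg.phases[1:]):
            if b.start - a.end > 1e-9:
                gaps.append((a.end, b.start))
        if gaps:
            out[cond] = gaps
    return out or None
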