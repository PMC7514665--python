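"""Seeded synthetic respiratory subjects for end-to-end testing.

The generator emulates the statistical structure the method assumes rather
than detailed physiology: inspiratory muscle activity is band-limited
Gaussian noise multiplied per-sample by a nonnegative effort envelope, with
quasi-periodic cardiac transients superimposed (biphasic ECG-like spikes on
EMG channels, damped MCG-like oscillations on MMG axes), and co-recorded
pressures follow an incremental threshold-loading protocol: quiet resting
breathing followed by loads at fixed fractions of a reference maximal
inspiratory pressure. Everything is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .signals import SampledSignal

__all__ = [
    "ProtocolSpec",
    "CardiacSpec",
    "SubjectRecord",
    "gen_pressure",
    "gen_muscle_signal",
    "gen_cardiac",
    "gen_subject",
    "gen_cohort",
    "HEALTHY_GROUPS",
    "COPD_GROUPS",
]

#: Processed-channel group membership for the healthy montage
#: (11 myographic signals: 5 oesophageal EMG, 3 surface EMG, 3 MMG norms).
HEALTHY_GROUPS: dict[str, tuple[str, ...]] = {
    "oesEMGdi": tuple(f"oesEMGdi{i}" for i in range(1, 6)),
    "sEMG": ("sEMGpara", "sEMGlicR", "sEMGlicL"),
    "|sMMG|": ("|sMMGpara|", "|sMMGlicR|", "|sMMGlicL|"),
}

#: COPD montage (4 myographic signals: 2 surface EMG, 2 MMG norms).
COPD_GROUPS: dict[str, tuple[str, ...]] = {
    "sEMG": ("sEMGpara", "sEMGlicR"),
    "|sMMG|": ("|sMMGpara|", "|sMMGlicR|"),
}

#: Nominal per-group signal scale (concatenated-inspiratory SD) the generator
#: aims for, in signal units: volts for EMG, g for MMG.
GROUP_TARGET_SD: dict[str, float] = {
    "oesEMGdi": 0.0121,
    "sEMG": 0.0022,
    "|sMMG|": 0.0060,
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Incremental inspiratory threshold-loading protocol.

    Conditions are quiet resting breathing followed by loads at increasing
    fractions of the reference maximal inspiratory pressure (defaults 12 %,
    24 %, 36 %, 48 %, 60 %). Acquisition rates default to the usual hardware
    rates: 100 Hz pressures, 4000 Hz EMG, 2000 Hz MMG (the conditioning
    chain later resamples EMG to 2000 Hz and MMG to 500 Hz).
    """

    fs_pressure: float = 100.0
    fs_emg: float = 4000.0
    fs_mmg: float = 2000.0
    pimax_cmh2o: float = 100.0
    load_fractions: tuple[float, ...] = (0.12, 0.24, 0.36, 0.48, 0.60)
    rest_fraction: float = 0.05
    breaths_per_condition: int = 30
    insp_duration_s: float = 1.2
    exp_duration_s: float = 1.8
    exp_rebound_fraction: float = 0.15
    pressure_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.load_fractions, self.load_fractions[1:])):
            raise ValueError("load fractions must be strictly increasing")
        if min(self.insp_duration_s, self.exp_duration_s) < 0.5:
            raise ValueError("phase durations must be at least the 0.5 s threshold")
        if self.breaths_per_condition < 1 or self.breaths_per_condition > 30:
            raise ValueError("breaths per condition must be in 1..30")

    @property
    def conditions(self) -> tuple[str, ...]:
        return ("rest",) + tuple(f"L{i + 1}" for i in range(len(self.load_fractions)))

    def load_fraction(self, condition: str) -> float:
        if condition == "rest":
            return self.rest_fraction
        return self.load_fractions[int(condition[1:]) - 1]

    @property
    def condition_duration_s(self) -> float:
        return self.breaths_per_condition * (self.insp_duration_s + self.exp_duration_s)


@dataclass(frozen=True)
class CardiacSpec:
    """Quasi-periodic cardiac transient train.

    ``amplitude_rel`` scales the transient peak relative to the SD of the
    contaminated muscle signal during resting breathing; the default of 3
    makes cardiac activity the dominant feature at rest, as in real surface
    recordings. ``kind`` selects a biphasic ECG-like spike or a damped
    MCG-like oscillation.
    """

    rate_bpm: float = 75.0
    kind: str = "ecg"
    amplitude_rel: float = 3.0
    jitter_sd_s: float = 0.02

    def __post_init__(self) -> None:
        if not (self.rate_bpm > 0):
            raise ValueError("heart rate must be positive")
        if self.amplitude_rel < 0:
            raise ValueError("cardiac amplitude cannot be negative")
        if self.kind not in ("ecg", "mcg"):
            raise ValueError(f"unknown cardiac transient kind {self.kind!r}")


def _breath_waveform(protocol: ProtocolSpec, amplitude: float) -> np.ndarray:
    """One breath of clean mouth pressure: negative inspiratory half-sine
    followed by a small positive expiratory rebound."""
    fs = protocol.fs_pressure
    n_insp = int(round(protocol.insp_duration_s * fs))
    n_exp = int(round(protocol.exp_duration_s * fs))
    insp = -amplitude * np.sin(np.pi * np.arange(n_insp) / n_insp)
    exp_amp = protocol.exp_rebound_fraction * amplitude
    exp = exp_amp * np.sin(np.pi * np.arange(n_exp) / n_exp)
    return np.concatenate([insp, exp])


def gen_pressure(
    protocol: ProtocolSpec,
    condition: str,
    rng: np.random.Generator | None = None,
) -> tuple[SampledSignal, SampledSignal]:
    """Mouth pressure and ground-truth effort envelope for one condition.

    Each breath is a half-sine inspiratory deflection with peak amplitude
    ``load_fraction * pimax`` (a small tidal amplitude at rest) followed by a
    smooth positive expiratory return, plus additive low-amplitude noise.
    The envelope is the rectified clean inspiratory effort, max(-clean, 0).
    Returns ``(pmo, envelope)``, both at the pressure sampling rate.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    amplitude = protocol.load_fraction(condition) * protocol.pimax_cmh2o
    breath = _breath_waveform(protocol, amplitude)
    clean = np.tile(breath, protocol.breaths_per_condition)
    noise = protocol.pressure_noise_sd * rng.standard_normal(clean.size)
    pmo = SampledSignal(clean + noise, fs=protocol.fs_pressure,
                        label="Pmo", units="cmH2O")
    env = SampledSignal(np.maximum(-clean, 0.0) + 1e-12,
                        fs=protocol.fs_pressure, label="envelope", units="cmH2O")
    return pmo, env


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) Hz outside Nyquist at fs={fs}")
    white = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_muscle_signal(
    envelope: SampledSignal,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
    floor_rel: float = 0.05,
    gain: float = 1.0,
    env_scale: float | None = None,
    label: str = "muscle",
    units: str = "V",
) -> SampledSignal:
    """Amplitude-modulated band-limited Gaussian muscle activity.

    Unit-SD band-limited noise is multiplied per sample by the resampled
    effort envelope (normalized by ``env_scale``, default its own peak) plus
    a tonic noise floor of ``floor_rel``, then scaled by ``gain``. Passing a
    common ``env_scale`` across conditions preserves the load-dependent
    amplitude differences between conditions. A zero envelope with zero
    floor yields an identically zero signal.
    """
    n = int(round(envelope.duration * fs))
    t = envelope.t0 + np.arange(n) / fs
    env = np.interp(t, envelope.times, envelope.samples)
    peak = env.max() if env_scale is None else float(env_scale)
    profile = (env / peak if peak > 0 else env) + floor_rel
    if profile.max() <= 0:
        samples = np.zeros(n)
    else:
        samples = gain * profile * _bandlimited_noise(n, fs, band, rng)
    return SampledSignal(samples, fs=fs, label=label, units=units, t0=envelope.t0)


def _cardiac_template(kind: str, fs: float) -> np.ndarray:
    if kind == "ecg":
        # biphasic spike, ~80 ms wide
        tt = np.arange(int(round(0.08 * fs))) / fs - 0.04
        tpl = np.sin(2 * np.pi * 12.5 * tt) * np.hanning(tt.size)
    else:
        # damped oscillation, ~250 ms
        tt = np.arange(int(round(0.25 * fs))) / fs
        tpl = np.sin(2 * np.pi * 18.0 * tt) * np.exp(-tt / 0.06)
    peak = np.abs(tpl).max()
    return tpl / peak if peak > 0 else tpl


def gen_cardiac(
    spec: CardiacSpec,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    amplitude: float = 1.0,
) -> SampledSignal:
    """Cardiac transient train: unit templates at jittered beat times.

    Beat times are nominally ``60 / rate_bpm`` seconds apart with Gaussian
    jitter of SD ``jitter_sd_s``; each transient peaks at ``amplitude``.
    """
    n = int(round(duration_s * fs))
    out = np.zeros(n)
    if spec.amplitude_rel == 0 or amplitude == 0:
        return SampledSignal(out, fs=fs, label=f"cardiac-{spec.kind}", units="a.u.")
    tpl = amplitude * _cardiac_template(spec.kind, fs)
    period = 60.0 / spec.rate_bpm
    nominal = np.arange(0.3, duration_s - 0.3, period)
    beats = nominal + spec.jitter_sd_s * rng.standard_normal(nominal.size)
    for tb in beats:
        i0 = int(round(tb * fs))
        i1 = min(i0 + tpl.size, n)
        if 0 <= i0 < n:
            out[i0:i1] += tpl[: i1 - i0]
    return SampledSignal(out, fs=fs, label=f"cardiac-{spec.kind}", units="a.u.")


@dataclass
class SubjectRecord:
    """One synthetic subject: raw channels, pressures and ground truth.

    ``channels`` maps raw myographic channel labels (EMG channels and MMG
    axis triplets such as ``sMMGparaX``) to per-condition signals;
    ``pressures`` holds Pmo always and Pga/Poes for the healthy montage;
    ``envelopes`` is the noiseless effort envelope per condition;
    ``groups`` names the processed group members (MMG sensors appear as
    their norm labels).
    """

    subject_id: str
    montage: str
    conditions: tuple[str, ...]
    channels: dict[str, dict[str, SampledSignal]]
    pressures: dict[str, dict[str, SampledSignal]]
    envelopes: dict[str, SampledSignal]
    groups: dict[str, tuple[str, ...]]
    seed: int = 0

    def emg_labels(self) -> list[str]:
        return [c for c in self.channels if not c.startswith("sMMG")]

    def mmg_sensors(self) -> dict[str, dict[str, str]]:
        """Sensor base label -> axis suffix -> raw channel label."""
        sensors: dict[str, dict[str, str]] = {}
        for c in self.channels:
            if c.startswith("sMMG"):
                sensors.setdefault(c[:-1], {})[c[-1]] = c
        return sensors


def _insp_rms(profile_env: np.ndarray, floor_rel: float) -> float:
    """RMS of the modulation profile over inspiratory (envelope > 0) samples."""
    mask = profile_env > 1e-9
    prof = profile_env[mask] + floor_rel if mask.any() else profile_env + floor_rel
    return float(np.sqrt(np.mean(prof**2)))


def gen_subject(
    protocol: ProtocolSpec,
    montage: str = "healthy",
    cardiac_emg: CardiacSpec | None = None,
    cardiac_mmg: CardiacSpec | None = None,
    seed: int = 0,
    subject_id: str = "S1",
    floor_rel: float = 0.05,
) -> SubjectRecord:
    """Generate a full synthetic subject.

    Healthy montage: 11 myographic signals (5 oesophageal EMG pairs, 3
    surface EMG, 3 triaxial MMG sensors) plus mouth pressure and the
    gastric/oesophageal pair from which transdiaphragmatic pressure is
    derived. COPD montage: 2 surface EMG and 2 MMG sensors plus mouth
    pressure only. Per-channel gains are drawn once per subject around the
    nominal group amplitude scales; cardiac trains are added with amplitude
    ``amplitude_rel`` times the channel's resting-breathing SD.
    """
    if montage not in ("healthy", "copd"):
        raise ValueError(f"unknown montage {montage!r}")
    if cardiac_emg is None:
        cardiac_emg = CardiacSpec(kind="ecg")
    if cardiac_mmg is None:
        cardiac_mmg = CardiacSpec(kind="mcg")
    groups = HEALTHY_GROUPS if montage == "healthy" else COPD_GROUPS
    root = np.random.SeedSequence(seed)
    ss_press, ss_chan, ss_subject = root.spawn(3)
    rng_subject = np.random.default_rng(ss_subject)

    conditions = protocol.conditions
    press_rngs = [np.random.default_rng(s) for s in ss_press.spawn(len(conditions))]
    pmo: dict[str, SampledSignal] = {}
    envelopes: dict[str, SampledSignal] = {}
    for cond, rng in zip(conditions, press_rngs):
        p, env = gen_pressure(protocol, cond, rng)
        pmo[cond] = p
        envelopes[cond] = env

    pressures: dict[str, dict[str, SampledSignal]] = {"Pmo": pmo}
    if montage == "healthy":
        # Poes mirrors the (negated) effort; Pga adds an independent
        # diaphragm-weighted component so Pmo and Pdi correlations differ.
        pga: dict[str, SampledSignal] = {}
        poes: dict[str, SampledSignal] = {}
        for cond in conditions:
            env = envelopes[cond].samples
            slow = sps.sosfiltfilt(
                sps.butter(2, 0.3, btype="lowpass", fs=protocol.fs_pressure,
                           output="sos"),
                rng_subject.standard_normal(env.size),
            )
            dia = 0.25 * env * (1.0 + 0.3 * np.tanh(slow))
            noise = 0.1 * rng_subject.standard_normal(env.size)
            poes_s = -0.9 * env + 0.1 * rng_subject.standard_normal(env.size)
            pga_s = (0.3 * env + dia + noise) + poes_s  # so Pga - Poes is effort-positive
            fs = protocol.fs_pressure
            pga[cond] = SampledSignal(pga_s, fs=fs, label="Pga", units="cmH2O")
            poes[cond] = SampledSignal(poes_s, fs=fs, label="Poes", units="cmH2O")
        pressures["Pga"] = pga
        pressures["Poes"] = poes

    # raw channel list with (label, kind, group)
    raw: list[tuple[str, str, str]] = []
    for group, members in groups.items():
        for member in members:
            if group == "|sMMG|":
                base = member.strip("|")
                for axis in "XYZ":
                    raw.append((base + axis, "mmg", group))
            else:
                raw.append((member, "emg", group))

    chan_rngs = {lbl: np.random.default_rng(s)
                 for (lbl, _, _), s in zip(raw, ss_chan.spawn(len(raw)))}

    # common envelope scale across conditions = the heaviest-load amplitude,
    # so the modulation profile carries the load-dependent amplitude ratios
    env_scale = max(protocol.load_fraction(c) for c in conditions) * protocol.pimax_cmh2o

    # expected RMS of the modulation profile over inspiratory samples across
    # all conditions; used to land the concatenated-inspiratory SD near the
    # nominal group scale
    x = np.sin(np.pi * np.linspace(0, 1, 512, endpoint=False))
    profile_ms = [
        np.mean(((protocol.load_fraction(c) * protocol.pimax_cmh2o / env_scale) * x
                 + floor_rel) ** 2)
        for c in conditions
    ]
    insp_profile_rms = float(np.sqrt(np.mean(profile_ms)))

    gains: dict[str, float] = {}
    for lbl, kind, group in raw:
        target = GROUP_TARGET_SD[group]
        if kind == "mmg":
            target = target / np.sqrt(3.0)  # split across the three axes
        spread = float(np.exp(0.15 * rng_subject.standard_normal()))
        gains[lbl] = target / insp_profile_rms * spread

    channels: dict[str, dict[str, SampledSignal]] = {lbl: {} for lbl, _, _ in raw}
    for lbl, kind, group in raw:
        fs = protocol.fs_emg if kind == "emg" else protocol.fs_mmg
        band = (10.0, 600.0) if kind == "emg" else (5.0, 40.0)
        units = "V" if kind == "emg" else "g"
        rng = chan_rngs[lbl]
        spec = cardiac_emg if kind == "emg" else cardiac_mmg
        rest_sd = None
        for cond in conditions:
            sig = gen_muscle_signal(
                envelopes[cond], fs, band, rng, floor_rel=floor_rel,
                gain=gains[lbl], env_scale=env_scale, label=lbl, units=units,
            )
            if rest_sd is None:  # conditions start with resting breathing
                rest_sd = float(sig.samples.std())
            cardiac = gen_cardiac(spec, sig.duration, fs, rng,
                                  amplitude=spec.amplitude_rel * rest_sd)
            channels[lbl][cond] = sig.with_samples(sig.samples + cardiac.samples)
    return SubjectRecord(
        subject_id=subject_id,
        montage=montage,
        conditions=conditions,
        channels=channels,
        pressures=pressures,
        envelopes=envelopes,
        groups={g: tuple(m) for g, m in groups.items()},
        seed=seed,
    )


def gen_cohort(
    n_subjects: int,
    protocol: ProtocolSpec,
    montage: str = "healthy",
    base_seed: int = 0,
    **kwargs,
) -> list[SubjectRecord]:
    """Generate a cohort of subjects with independent per-subject seeds."""
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(base_seed).spawn(n_subjects)]
    return [
        gen_subject(protocol, montage=montage, seed=s,
                    subject_id=f"S{i + 1}", **kwargs)
        for i, s in enumerate(seeds)
    ]
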