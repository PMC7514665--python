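import numpy as np
import pytest

from fsampen import (
    BreathSegmentation,
    SampledSignal,
    apply_exclusions,
    detect_phases,
    global_sd,
    individual_sd,
)
from fsampen.segmentation import EXPIRATORY, INSPIRATORY, inspiratory_samples


def sin_pmo(fs=100.0, duration=20.0, period=4.0, amp=1.0):
    """Mouth pressure -amp*sin(2*pi*t/period): inspiration first, negative."""
    t = np.arange(int(duration * fs)) / fs
    return SampledSignal(-amp * np.sin(2 * np.pi * t / period), fs=fs,
                         label="Pmo", units="cmH2O")


class TestDetectPhases:
    def test_sinusoid_gives_five_inspirations_at_analytic_zeros(self):
        seg = detect_phases(sin_pmo(), polarity="inspiratory-negative")
        insp = seg.select(INSPIRATORY)
        assert len(insp) == 5
        for k, p in enumerate(insp):
            assert p.duration == pytest.approx(2.0, abs=0.02)
            # analytic zeros at t = 4k and 4k + 2
            assert p.start == pytest.approx(4 * k, abs=1 / 100)
            assert p.end == pytest.approx(4 * k + 2, abs=1 / 100)

    def test_scale_invariance(self):
        a = detect_phases(sin_pmo(amp=1.0))
        b = detect_phases(sin_pmo(amp=0.1))
        assert a.to_table() == b.to_table()

    def test_polarity_flips_labels(self):
        neg = detect_phases(sin_pmo(), polarity="inspiratory-negative")
        pos = detect_phases(sin_pmo(), polarity="inspiratory-positive")
        assert [p.label for p in neg.phases] == [
            INSPIRATORY if q.label == EXPIRATORY else EXPIRATORY
            for q in pos.phases
        ]

    def test_short_sign_flip_absorbed(self):
        """A 0.3 s spurious flip inside an expiratory phase disappears."""
        pmo = sin_pmo()
        clean = detect_phases(pmo)
        x = pmo.samples.copy()
        # expiratory phase spans t in (2, 4); flip 0.3 s in its middle
        i0, i1 = int(2.8 * pmo.fs), int(3.1 * pmo.fs)
        x[i0:i1] = -0.2
        seg = detect_phases(SampledSignal(x, fs=pmo.fs, label="Pmo",
                                          units="cmH2O"))
        assert len(seg) == len(clean)
        assert [p.label for p in seg.phases] == [p.label for p in clean.phases]

    def test_no_zero_crossing_is_an_error(self):
        sig = SampledSignal(np.full(1000, -3.0) , fs=100, label="Pmo",
                            units="cmH2O")
        with pytest.raises(ValueError, match="no respiratory"):
            detect_phases(sig)


def _const_sd_signal(values, fs=100.0):
    """Signal whose population SD over any window is known: alternating +/-a."""
    return SampledSignal(values, fs=fs, label="x", units="V")


class TestExclusions:
    def test_empty_exclusion_is_identity(self):
        seg = detect_phases(sin_pmo())
        assert apply_exclusions(seg, []).to_table() == seg.to_table()

    def test_exclude_one_cycle_of_five(self):
        seg = detect_phases(sin_pmo())
        out = apply_exclusions(seg, [1])
        assert seg.n_cycles == 5
        assert out.n_cycles == 4

    def test_out_of_range_rejected(self):
        seg = detect_phases(sin_pmo())
        with pytest.raises(IndexError):
            apply_exclusions(seg, [7])

    def test_exclusion_changes_sd_as_concatenation_oracle_predicts(self):
        rng = np.random.default_rng(10)
        fs = 100.0
        pmo = sin_pmo(fs=fs)
        sig = SampledSignal(rng.standard_normal(pmo.n) * (1 + pmo.times / 10),
                            fs=fs, label="ch", units="V")
        seg = apply_exclusions(detect_phases(pmo), [0, 3])
        got = individual_sd({"ch": [sig]}, [seg])
        # oracle: concatenate kept inspiratory intervals by hand
        kept = [p for p in seg.phases if p.label == INSPIRATORY]
        chunks = [
            sig.samples[int(np.ceil(p.start * fs - 1e-9)):
                        int(np.ceil(p.end * fs - 1e-9))]
            for p in kept
        ]
        assert got == pytest.approx(np.std(np.concatenate(chunks)), abs=1e-15)


class TestSdCalibration:
    def test_mean_of_two_channels(self):
        """Channels with concatenated-inspiratory SDs 0.002 / 0.004 -> 0.003."""
        fs = 100.0
        pmo = sin_pmo(fs=fs)
        seg = detect_phases(pmo)

        def alternating(a):
            x = np.empty(pmo.n)
            x[::2], x[1::2] = a, -a
            return _const_sd_signal(x, fs)

        got = individual_sd(
            {"c1": [alternating(0.002)], "c2": [alternating(0.004)]}, [seg]
        )
        assert got == pytest.approx(0.003, rel=1e-9)

    def test_single_channel_group(self):
        fs = 100.0
        seg = detect_phases(sin_pmo(fs=fs))
        sig = _const_sd_signal(np.resize([0.01, -0.01], 2000), fs)
        assert individual_sd({"c": [sig]}, [seg]) == pytest.approx(0.01, rel=1e-9)

    def test_matches_explicit_concatenation_oracle(self, processed_subject):
        """Synthetic subject: SD equals the loop-written concatenate-and-average."""
        proc = processed_subject
        segs = [proc.segmentations[c] for c in proc.conditions]
        members = proc.groups["sEMG"]
        got = individual_sd(
            {m: [proc.channels[m][c] for c in proc.conditions] for m in members},
            segs,
        )
        per_channel = []
        for m in members:
            parts = []
            for cond, seg in zip(proc.conditions, segs):
                parts.append(inspiratory_samples(proc.channels[m][cond], seg))
            per_channel.append(np.std(np.concatenate(parts)))
        assert got == pytest.approx(np.mean(per_channel), abs=1e-15)

    def test_invariant_to_channel_and_condition_order(self, processed_subject):
        proc = processed_subject
        conds = list(proc.conditions)
        members = list(proc.groups["|sMMG|"])
        segs = {c: proc.segmentations[c] for c in conds}
        fwd = individual_sd(
            {m: [proc.channels[m][c] for c in conds] for m in members},
            [segs[c] for c in conds],
        )
        rev = individual_sd(
            {m: [proc.channels[m][c] for c in conds[::-1]] for m in members[::-1]},
            [segs[c] for c in conds[::-1]],
        )
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_empty_inspiratory_set_is_error(self):
        seg = BreathSegmentation(
            (  # a single expiratory phase
                __import__("fsampen").segmentation.Phase(0.0, 2.0, EXPIRATORY),
            )
        )
        sig = _const_sd_signal(np.ones(500), 100.0)
        with pytest.raises(ValueError, match="no inspiratory"):
            individual_sd({"c": [sig]}, [seg])


class TestCohortCalibration:
    def test_global_sd_is_mean_of_individuals_per_group(self):
        from fsampen import CohortCalibration, SignalGroup

        cal = CohortCalibration(cohort="healthy")
        cal.add_subject("H1", {"sEMG": 0.002, "|sMMG|": 0.005})
        cal.add_subject("H2", {"sEMG": 0.004, "|sMMG|": 0.007})
        assert cal.global_sd("sEMG") == pytest.approx(0.003)
        assert cal.global_sd("|sMMG|") == pytest.approx(0.006)
        assert cal.as_dict()["global"]["sEMG"] == pytest.approx(0.003)
        grp = SignalGroup("sEMG", ("sEMGpara", "sEMGlicR"), 0.002, "healthy")
        assert grp.members == ("sEMGpara", "sEMGlicR")
        with pytest.raises(ValueError):
            SignalGroup("sEMG", ())


class TestGlobalSd:
    def test_mean_and_identity(self):
        assert global_sd([0.002, 0.002]) == 0.002
        assert global_sd([0.004]) == 0.004
        assert global_sd([0.002, 0.004]) == pytest.approx(0.003)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_sd([])
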