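import math
import warnings

import numpy as np
import pytest

from fsampen import (
    FSampEnParams,
    SampledSignal,
    moving_fsampen,
    moving_rms,
    sampen_fixed,
    sampen_profile,
    window_positions,
)

from oracles import sampen_bruteforce


class TestSampenFixed:
    def test_matches_bruteforce_oracle_on_seeded_windows(self):
        """Vectorized pair counting equals naive O(N^2) enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(30, 120))
            x = rng.standard_normal(n)
            m = int(rng.integers(1, 4))
            tol = float(rng.uniform(0.05, 0.8))
            expected = sampen_bruteforce(x, m, tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = sampen_fixed(x, m, tol)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_fixed_gaussian_window_example(self):
        """The documented 40-sample Gaussian window agrees with the oracle."""
        x = np.random.default_rng(12345).standard_normal(40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short window may hit the cap
            got = sampen_fixed(x, 2, 0.2)
        assert got == pytest.approx(sampen_bruteforce(x, 2, 0.2), abs=1e-12)

    def test_constant_window_is_zero(self):
        assert sampen_fixed(np.full(100, 5.0), 2, 0.1) == 0.0

    def test_huge_tolerance_is_zero(self):
        x = np.random.default_rng(0).standard_normal(80)
        tol = float(np.ptp(x)) + 1.0
        assert sampen_fixed(x, 2, tol) == 0.0

    @pytest.mark.parametrize("c", [0.5, 3.0, 10.0])
    def test_joint_rescaling_invariance(self, c):
        """sampen(c*x, m, c*tol) == sampen(x, m, tol) for c > 0."""
        x = np.random.default_rng(1).standard_normal(120)
        assert sampen_fixed(c * x, 2, c * 0.25) == sampen_fixed(x, 2, 0.25)

    def test_amplitude_monotonicity(self):
        """At fixed tolerance, mean fSampEn strictly increases with amplitude."""
        rng = np.random.default_rng(3)
        windows = [rng.standard_normal(250) for _ in range(30)]
        means = []
        for a in (0.5, 1.0, 2.0):
            means.append(np.mean([sampen_fixed(a * w, 2, 0.25) for w in windows]))
        assert means[0] < means[1] < means[2]

    def test_no_m_matches_gives_nan_with_warning(self):
        x = np.arange(10, dtype=float)  # every template pair at distance >= 1
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert math.isnan(sampen_fixed(x, 2, 0.1))

    def test_no_m_plus_1_matches_capped_at_ln_b(self):
        # three identical (0, 0) templates whose continuations all differ
        x = np.array([0.0, 0.0, 5.0, 0.0, 0.0, 9.0, 0.0, 0.0, 13.0])
        with pytest.warns(RuntimeWarning, match="capped"):
            assert sampen_fixed(x, 2, 0.1) == pytest.approx(math.log(3))

    def test_rejects_short_window_and_bad_tolerance(self):
        with pytest.raises(ValueError):
            sampen_fixed([1.0, 2.0, 3.0], 2, 0.1)
        with pytest.raises(ValueError):
            sampen_fixed(np.zeros(50), 2, 0.0)

    def test_profile_matches_scalar_calls(self):
        x = np.random.default_rng(5).standard_normal(150)
        tols = np.array([0.15, 0.2, 0.3, 0.4, 0.5, 0.8, 1.2])
        vals, capped = sampen_profile(x, 2, tols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expected = [sampen_fixed(x, 2, t) for t in tols]
        np.testing.assert_allclose(vals, expected, rtol=0, atol=1e-14)
        assert not capped.any()


class TestWindowPositions:
    @pytest.mark.parametrize(
        "n, nw, step, expected",
        [(5, 5, 1, [0]), (7, 5, 1, [0, 1, 2]), (20000, 1000, 100, None)],
    )
    def test_examples(self, n, nw, step, expected):
        pos = window_positions(n, nw, step)
        if expected is None:
            assert len(pos) == 191  # floor((20000-1000)/100) + 1
            assert pos[0] == 0 and pos[-1] + nw <= n
        else:
            assert list(pos) == expected

    def test_window_longer_than_signal_raises(self):
        with pytest.raises(ValueError):
            window_positions(10, 11, 1)

    def test_enumeration_invariant(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(10, 500))
            nw = int(rng.integers(2, n + 1))
            step = int(rng.integers(1, 50))
            pos = window_positions(n, nw, step)
            brute = [s for s in range(0, n, step) if s + nw <= n]
            assert list(pos) == brute


class TestMovingFsampen:
    def test_window_count_at_90_percent_overlap(self):
        """10 s at 2000 Hz, 0.5 s window, 90 % overlap -> 191 windows."""
        sig = SampledSignal(np.random.default_rng(0).standard_normal(20000),
                            fs=2000, label="emg", units="V")
        params = FSampEnParams(m=2, r=0.2, sd_ref=1.0,
                               window_length_s=0.5, overlap=0.9)
        es = moving_fsampen(sig, params)
        assert len(es.values) == 191
        # window-center step = (1 - overlap) * window = 0.05 s
        np.testing.assert_allclose(np.diff(es.times), 0.05, atol=1e-9)

    def test_no_warning_at_250_samples(self, recwarn):
        """A 0.5 s window at 500 Hz holds 250 samples, above the minimum."""
        params = FSampEnParams(m=2, r=0.3, sd_ref=1.0,
                               window_length_s=0.5, overlap=0.9)
        assert params.window_samples(500) == 250
        sig = SampledSignal(np.random.default_rng(1).standard_normal(2500),
                            fs=500, label="mmg", units="g")
        moving_fsampen(sig, params)
        assert not any(w.category is UserWarning for w in recwarn.list)

    def test_short_window_triggers_warning(self):
        sig = SampledSignal(np.random.default_rng(1).standard_normal(2500),
                            fs=500, label="mmg", units="g")
        params = FSampEnParams(window_length_s=0.2, r=0.3)
        with pytest.warns(UserWarning, match="minimum"):
            moving_fsampen(sig, params)

    def test_constant_signal_gives_all_zeros(self):
        sig = SampledSignal(np.full(3000, 2.5), fs=500, label="c", units="V")
        es = moving_fsampen(sig, FSampEnParams(r=0.1, window_length_s=0.5))
        assert np.all(es.values == 0.0)

    def test_equals_independent_per_window_computation(self):
        """No cross-window state: each value is sampen of its own window."""
        rng = np.random.default_rng(9)
        sig = SampledSignal(rng.standard_normal(1500), fs=500,
                            label="x", units="V")
        params = FSampEnParams(m=2, r=0.2, sd_ref=1.3,
                               window_length_s=0.5, overlap=0.5)
        es = moving_fsampen(sig, params)
        n, step = 250, 125
        for i, v in enumerate(es.values):
            w = sig.samples[i * step : i * step + n]
            assert v == sampen_fixed(w, 2, params.tolerance)

    def test_signal_shorter_than_window_raises(self):
        sig = SampledSignal(np.random.default_rng(0).standard_normal(100),
                            fs=500, label="x", units="V")
        with pytest.raises(ValueError):
            moving_fsampen(sig, FSampEnParams(window_length_s=0.5))


def test_moving_rms_constant_signal():
    sig = SampledSignal(np.full(1000, -3.0), fs=100, label="x", units="V")
    ws = moving_rms(sig, 0.5, 0.9)
    np.testing.assert_allclose(ws.values, 3.0)
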