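import numpy as np
import pytest

from fsampen import (
    FSampEnParams,
    GridResult,
    SampledSignal,
    WindowSeries,
    delta_cmax,
    grid_evaluate,
    grid_series_count,
    max_crosscov,
    moving_fsampen,
    summarize_cohort,
)

from oracles import lag_scan_pearson


def make_series(values, dt=0.05):
    values = np.asarray(values, dtype=float)
    return WindowSeries(values=values, times=np.arange(values.size) * dt,
                        source_label="x")


def make_pressure(values, fs=100.0):
    return SampledSignal(values, fs=fs, label="Pmo", units="cmH2O")


class TestMaxCrosscov:
    def test_self_similarity_is_one_at_lag_zero(self):
        rng = np.random.default_rng(0)
        base = np.cumsum(rng.standard_normal(200))
        series = make_series(base)
        # pressure sampled on the same grid; inspiratory-positive (no negation)
        pressure = SampledSignal(base, fs=20.0, label="P", units="cmH2O")
        c, lag = max_crosscov(series, pressure, polarity="inspiratory-positive")
        assert c == pytest.approx(1.0, abs=1e-12)
        assert lag == 0.0

    def test_invariance_to_positive_affine_transform(self):
        rng = np.random.default_rng(1)
        base = np.cumsum(rng.standard_normal(300))
        series = make_series(rng.standard_normal(300))
        p1 = make_pressure(base, fs=20.0)
        p2 = make_pressure(3.7 * base + 11.0, fs=20.0)
        c1, l1 = max_crosscov(series, p1)
        c2, l2 = max_crosscov(series, p2)
        assert c1 == pytest.approx(c2, abs=1e-12)
        assert l1 == l2

    def test_known_shift_recovered_and_matches_bruteforce_scan(self):
        rng = np.random.default_rng(2)
        smooth = np.convolve(rng.standard_normal(400), np.ones(20) / 20, "same")
        x = np.roll(smooth, 3)  # series delayed by 3 steps
        series = make_series(x, dt=0.1)
        pressure = SampledSignal(smooth, fs=10.0, label="P", units="cmH2O")
        c, lag = max_crosscov(series, pressure, max_lag_s=2.0,
                              polarity="inspiratory-positive")
        assert lag == pytest.approx(0.3)
        oc, olag = lag_scan_pearson(x, smooth, 20)
        assert olag == 3
        assert c == pytest.approx(oc, abs=1e-10)

    def test_zero_variance_is_error(self):
        series = make_series(np.ones(50))
        with pytest.raises(ValueError):
            max_crosscov(series, make_pressure(np.ones(300)))

    def test_too_few_overlapping_points_is_error(self):
        series = make_series(np.arange(5.0))
        with pytest.raises(ValueError, match="overlap"):
            max_crosscov(series, make_pressure(np.arange(300.0)))


class TestGridCombinatorics:
    def test_single_cell_counts_one_series_per_signal_condition(self):
        assert grid_series_count(1, 1, windows=[0.5], r_values=[0.3],
                                 sd_modes=["global"]) == 1

    def test_default_grid_sizes(self):
        # 9 windows x 12 r values x 2 SD modes per signal and condition
        assert grid_series_count(1, 1) == 216


def make_grid(mat, windows=(0.1, 0.3, 0.5), rs=(0.1, 0.3), modes=("individual", "global")):
    return GridResult(window_lengths_s=windows, r_values=rs, sd_modes=modes,
                      cmax=np.asarray(mat))


class TestGridResult:
    def test_argmax_tie_broken_toward_smaller_r_then_window(self):
        mat = np.zeros((3, 2, 2))
        mat[:, :, 1] = [[0.5, 0.9], [0.9, 0.4], [0.9, 0.9]]
        g = make_grid(mat)
        # global max 0.9 appears at (0, r=1), (1, r=0), (2, both):
        # smallest r wins, then smallest window -> (window 1, r 0)
        assert g.global_argmax("global") == (1, 0)
        assert g.row_argmax("global") == [1, 0, 0]

    def test_summarize_identity_and_symmetric_pair(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 1, size=(3, 2, 2))
        g1 = make_grid(m)
        assert np.array_equal(summarize_cohort([g1]).cmax, m)
        g2 = make_grid(2 - m)
        np.testing.assert_allclose(summarize_cohort([g1, g2]).cmax, 1.0)

    def test_summarize_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        mats = [rng.uniform(-1, 1, size=(3, 2, 2)) for _ in range(3)]
        mean = summarize_cohort([make_grid(m) for m in mats]).cmax
        acc = np.zeros((3, 2, 2))
        for m in mats:
            acc += m
        np.testing.assert_allclose(mean, acc / 3, atol=1e-15)

    def test_shape_mismatch_rejected(self):
        g1 = make_grid(np.zeros((3, 2, 2)))
        g2 = make_grid(np.zeros((3, 1, 2)), rs=(0.1,))
        with pytest.raises(ValueError):
            summarize_cohort([g1, g2])


class TestDeltaCmax:
    def test_identical_parameters_give_zero(self):
        mat = np.zeros((3, 2, 2))
        mat[2, :, 0] = [0.6, 0.8]
        mat[2, :, 1] = [0.6, 0.8]
        dc = delta_cmax(make_grid(mat), global_r=0.3, window_s=0.5)
        assert dc.delta_pct == 0.0
        assert dc.individual_r == 0.3

    def test_percentage_arithmetic(self):
        mat = np.zeros((3, 2, 2))
        mat[2, :, 0] = [0.8, 0.7]   # individual optimum 0.8 at r=0.1
        mat[2, :, 1] = [0.5, 0.76]  # global r=0.3 -> 0.76
        dc = delta_cmax(make_grid(mat), global_r=0.3, window_s=0.5)
        assert dc.c_ind == 0.8 and dc.c_glob == 0.76
        assert dc.delta_pct == pytest.approx(5.0)

    def test_matches_stored_grid_recomputation(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0.1, 1, size=(3, 2, 2))
        g = make_grid(mat)
        dc = delta_cmax(g, global_r=0.1, window_s=0.3)
        iw = 1
        assert dc.c_ind == mat[iw, :, 0].max()
        assert dc.c_glob == mat[iw, 0, 1]


class TestGridEvaluate:
    def test_single_cell_reduces_to_direct_computation(self, processed_subject):
        proc = processed_subject
        lbl = "|sMMGlicR|"
        cond = proc.conditions[1]
        sig = proc.channels[lbl][cond]
        pressure = proc.pressures["Pmo"][cond]
        sd = 0.004
        grid = grid_evaluate(
            {lbl: {cond: sig}}, {cond: pressure},
            sd_individual=sd, sd_global=sd,
            windows=[0.5], r_values=[0.3], group="|sMMG|", pressure_label="Pmo",
        )
        params = FSampEnParams(m=2, r=0.3, sd_ref=sd, window_length_s=0.5,
                               overlap=0.9)
        es = moving_fsampen(sig, params)
        c, _ = max_crosscov(es, pressure)
        assert grid.cmax[0, 0, 0] == pytest.approx(c, abs=1e-12)
        assert grid.cmax[0, 0, 1] == pytest.approx(c, abs=1e-12)

    def test_missing_pressure_condition_is_error(self, processed_subject):
        proc = processed_subject
        lbl = "|sMMGlicR|"
        with pytest.raises(ValueError, match="pressure"):
            grid_evaluate({lbl: proc.channels[lbl]}, {},
                          sd_individual=0.004, sd_global=0.004,
                          windows=[0.5], r_values=[0.3])
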