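import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import udilab as u
from udilab.cystometry import (
    MicturitionCycle,
    _moving_average,
    compute_filling_volume,
    compute_pthresh,
    detect_cycles,
    normalize_no_cycle,
    smooth_pressure,
    summarize_recording,
)
from udilab.exceptions import DegenerateInputError, ValidationError
from udilab.io import UDIRecording


def flat_recording(value=10.0, fs=500.0, n=5000):
    return UDIRecording(
        time_s=np.arange(n) / fs,
        pressure_cmH2O=np.full(n, value),
        sampling_rate_hz=fs,
    )


# --- smoothing --------------------------------------------------------------


@pytest.mark.parametrize("fs,expected_window", [(500.0, 50), (5000.0, 500)])
def test_smoothing_window_in_samples(fs, expected_window):
    assert int(round(0.1 * fs)) == expected_window
    # constant trace is invariant under the moving average at any rate
    rec = flat_recording(fs=fs)
    np.testing.assert_array_equal(smooth_pressure(rec), rec.pressure_cmH2O)


def test_moving_average_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    x = rng.normal(size=300)
    for window in (1, 3, 4, 50):
        ours = _moving_average(x, window)
        left, right = (window - 1) // 2, window // 2
        oracle = np.array(
            [x[max(0, i - left) : i + right + 1].mean() for i in range(x.size)]
        )
        np.testing.assert_allclose(ours, oracle, atol=1e-10)


def test_smoothing_window_longer_than_trace_rejected():
    with pytest.raises(DegenerateInputError):
        smooth_pressure(flat_recording(n=10), window_s=1.0)


# --- threshold rule ---------------------------------------------------------


def brute_force_thresh(time_s, smoothed, t_pmax, lookback=20.0, fraction=0.65):
    """Independent difference-scan oracle for the 65 % rule."""
    i_peak = max(i for i, t in enumerate(time_s) if t <= t_pmax)
    i_lo = min(i for i, t in enumerate(time_s) if t >= t_pmax - lookback)
    diffs = [smoothed[i + 1] - smoothed[i] for i in range(i_lo, i_peak)]
    d_max = max(diffs)
    if d_max <= 0:
        return None
    for j, d in enumerate(diffs):
        if d >= fraction * d_max:
            return i_lo + j
    raise AssertionError("unreachable")


def test_linear_ramp_thresholds_at_window_start():
    fs = 100.0
    t = np.arange(0, 40, 1 / fs)
    p = 0.5 * t
    t_th, p_th = compute_pthresh(t, p, p, t_pmax_s=30.0)
    assert t_th == pytest.approx(10.0)  # start of the 20 s lookback window
    assert p_th == pytest.approx(5.0)


def test_two_slope_ramp_thresholds_at_slope_break():
    fs = 100.0
    t = np.arange(0, 30, 1 / fs)
    t_star = 22.0
    p = np.where(t < t_star, 1.0 * t, 1.0 * t_star + 2.0 * (t - t_star))
    t_th, _ = compute_pthresh(t, p, p, t_pmax_s=float(t[-1]))
    assert t_th == pytest.approx(t_star, abs=1.5 / fs)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 10_000))
def test_threshold_time_is_scale_invariant(scale, seed):
    rng = np.random.default_rng(seed)
    fs = 50.0
    t = np.arange(0, 30, 1 / fs)
    p = np.cumsum(rng.normal(0.05, 1.0, t.size))
    res1 = compute_pthresh(t, p, p, t_pmax_s=float(t[-1]))
    res2 = compute_pthresh(t, scale * p, scale * p, t_pmax_s=float(t[-1]))
    if res1 is None:
        assert res2 is None
    else:
        assert res1[0] == res2[0]


def test_threshold_agrees_with_brute_force_oracle_on_random_windows():
    rng = np.random.default_rng(123)
    fs = 50.0
    t = np.arange(0, 30, 1 / fs)
    for _ in range(200):
        p = np.cumsum(rng.normal(0.0, 1.0, t.size))
        got = compute_pthresh(t, p, p, t_pmax_s=float(t[-1]))
        want = brute_force_thresh(t, p, float(t[-1]))
        if want is None:
            assert got is None
        else:
            assert got[0] == pytest.approx(float(t[want]))


def test_non_increasing_window_is_flagged():
    fs = 50.0
    t = np.arange(0, 30, 1 / fs)
    p = -0.1 * t
    assert compute_pthresh(t, p, p, t_pmax_s=float(t[-1])) is None


# --- filling volume ---------------------------------------------------------


@pytest.mark.parametrize(
    "rate,interval,expected", [(10.0, 120.0, 20.0), (20.0, 0.0, 0.0)]
)
def test_filling_volume_examples(rate, interval, expected):
    assert compute_filling_volume(0.0, interval, rate) == pytest.approx(expected)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    start=st.floats(0, 1e3),
    interval=st.floats(0, 1e3),
    rate=st.floats(1e-3, 100),
)
def test_filling_volume_matches_direct_arithmetic(start, interval, rate):
    got = compute_filling_volume(start, start + interval, rate)
    assert got == pytest.approx(rate / 60.0 * interval, abs=1e-9, rel=1e-9)


def test_negative_interval_rejected():
    with pytest.raises(ValidationError):
        compute_filling_volume(10.0, 5.0, 10.0)


# --- cycle detection --------------------------------------------------------


def test_sham_cycles_recover_planted_voids(sham_low_noise):
    params, rec, truth = sham_low_noise
    cycles = detect_cycles(rec)
    assert len(cycles) == len(truth.true_void_times_s) == 3
    for cyc, t_pk, t_th in zip(
        cycles, truth.true_pmax_times_s, truth.true_thresh_times_s
    ):
        assert cyc.t_pmax_s == pytest.approx(t_pk, abs=0.2)
        assert cyc.t_thresh_s == pytest.approx(t_th, abs=0.2)


def test_sci_recording_yields_no_cycles(sci_low_noise):
    _, rec, _ = sci_low_noise
    assert detect_cycles(rec) == []


def test_flat_trace_yields_no_cycles():
    assert detect_cycles(flat_recording()) == []


def test_cycle_invariants_hold_across_seeds():
    for seed in range(8):
        rec, _ = u.simulate_recording(u.SimParams(seed=seed))
        for c in detect_cycles(rec):
            assert c.start_time_s <= c.t_thresh_s <= c.t_pmax_s <= c.end_time_s
            assert c.t_pmax_s - c.t_thresh_s <= 20.0
            assert c.pthresh_cmH2O <= c.pmax_cmH2O


# --- no-cycle normalisation -------------------------------------------------


def test_constant_trace_normalises_to_zero():
    normalized, pmax, events = normalize_no_cycle(flat_recording(value=30.0))
    assert np.all(normalized == 0.0)
    assert pmax == 0.0
    assert events == []


def test_normalized_minimum_is_exactly_zero(sci_low_noise):
    _, rec, _ = sci_low_noise
    normalized, _, _ = normalize_no_cycle(rec)
    assert normalized.min() == 0.0


def test_sci_pmax_matches_planted_plateau(sci_low_noise):
    params, rec, _ = sci_low_noise
    _, pmax, events = normalize_no_cycle(rec)
    planted = params.contraction_amplitude_cmH2O + params.osc_amplitude_cmH2O
    assert pmax == pytest.approx(planted, abs=1.0)
    assert len(events) > 0


# --- summaries --------------------------------------------------------------


def _cycle(pmax, pthresh=15.0, vfill=20.0):
    return MicturitionCycle(
        start_time_s=0.0,
        end_time_s=10.0,
        t_pmax_s=5.0,
        pmax_cmH2O=pmax,
        t_thresh_s=4.0,
        pthresh_cmH2O=pthresh,
        v_filling_ul=vfill,
    )


def test_summary_means_first_three_cycles():
    cycles = [_cycle(20.0), _cycle(22.0), _cycle(24.0), _cycle(100.0), _cycle(100.0)]
    s = summarize_recording(cycles, n_cycles=3)
    assert s["pmax_cmH2O"] == pytest.approx(22.0)
    assert s["n_cycles_used"] == 3
    assert not s["incomplete"]


def test_summary_with_fewer_cycles_is_flagged():
    s = summarize_recording([_cycle(20.0), _cycle(30.0)], n_cycles=3)
    assert s["pmax_cmH2O"] == pytest.approx(25.0)
    assert s["incomplete"]


def test_summary_of_nothing_rejected():
    with pytest.raises(DegenerateInputError):
        summarize_recording([])
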