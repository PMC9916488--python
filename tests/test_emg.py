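import numpy as np
import pytest

import udilab as u
from udilab.cystometry import ContractionEvent
from udilab.emd import hilbert_huang
from udilab.emg import (
    SectionEnergies,
    analyze_contractions,
    classify_vshape,
    mean_activity_pattern,
    preprocess_emg,
    section_energies,
    vshape_percentage,
)
from udilab.exceptions import DegenerateInputError, ValidationError
from udilab.io import UDIRecording

FS = 5000.0


def emg_recording(emg, fs=FS):
    n = len(emg)
    return UDIRecording(
        time_s=np.arange(n) / fs,
        pressure_cmH2O=np.full(n, 10.0),
        emg_v=np.asarray(emg, float),
        sampling_rate_hz=fs,
    )


def make_sections(pct_triple, t0=0.0):
    """SectionEnergies with the given percentage split (unit total energy)."""
    b, d, a = pct_triple
    bounds = np.linspace(t0, t0 + 5.0, 6)
    return SectionEnergies(
        e_before=b / 100.0, e_during=d / 100.0, e_after=a / 100.0,
        pct_before=float(b), pct_during=float(d), pct_after=float(a),
        section_bounds_s=bounds,
    )


# --- preprocessing ----------------------------------------------------------


def test_notch_removes_powerline_tone():
    t = np.arange(0, 4, 1 / FS)
    rec = emg_recording(np.sin(2 * np.pi * 50.0 * t))
    with pytest.warns(UserWarning, match="clipped"):
        out = preprocess_emg(rec, band_hz=(10.0, 10000.0), notch_hz=50.0)
    interior = out[int(FS) : -int(FS)]
    # peak amplitude of the residual sinusoid under 5 % of the input's
    assert np.max(np.abs(interior)) < 0.05


def test_zero_signal_stays_zero():
    rec = emg_recording(np.zeros(4000))
    out = preprocess_emg(rec, band_hz=(10.0, 2000.0))
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_band_clipped_below_nyquist_with_warning():
    rng = np.random.default_rng(0)
    rec = emg_recording(rng.normal(size=4000))
    with pytest.warns(UserWarning, match="Nyquist"):
        preprocess_emg(rec, band_hz=(10.0, 10000.0))


def test_missing_emg_channel_rejected():
    rec = UDIRecording(
        time_s=np.arange(100) / FS,
        pressure_cmH2O=np.zeros(100),
        sampling_rate_hz=FS,
    )
    with pytest.raises(DegenerateInputError):
        preprocess_emg(rec)


# --- section energies -------------------------------------------------------


def band_noise(n, rng, lo=100.0, hi=400.0):
    from scipy import signal

    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=FS, output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal(n))


def test_stationary_noise_splits_roughly_evenly():
    rng = np.random.default_rng(3)
    x = band_noise(int(6 * FS), rng)
    spec = hilbert_huang(x, FS)
    se = section_energies(spec, t_thresh_s=0.5, t_pmax_s=5.5)
    for pct in (se.pct_before, se.pct_during, se.pct_after):
        assert pct == pytest.approx(100.0 / 3.0, abs=8.0)


def test_planted_suppression_makes_during_the_minimum():
    rng = np.random.default_rng(4)
    n = int(6 * FS)
    t = np.arange(n) / FS
    env = np.ones(n)
    env[(t >= 2.5) & (t < 3.5)] = 0.2  # suppress exactly the middle fifth
    spec = hilbert_huang(band_noise(n, rng) * env, FS)
    se = section_energies(spec, t_thresh_s=0.5, t_pmax_s=5.5)
    assert se.pct_during < se.pct_before
    assert se.pct_during < se.pct_after
    assert classify_vshape(se)


def test_percentages_invariant_under_amplitude_scaling():
    rng = np.random.default_rng(5)
    x = band_noise(int(6 * FS), rng)
    se1 = section_energies(hilbert_huang(x, FS), 0.5, 5.5)
    se2 = section_energies(hilbert_huang(2.0 * x, FS), 0.5, 5.5)
    assert se2.pct_before == pytest.approx(se1.pct_before, abs=1e-6)
    assert se2.pct_during == pytest.approx(se1.pct_during, abs=1e-6)
    assert se2.pct_after == pytest.approx(se1.pct_after, abs=1e-6)
    assert se2.e_during == pytest.approx(4.0 * se1.e_during, rel=1e-6)


def test_percentages_sum_to_100_and_energies_nonnegative():
    rng = np.random.default_rng(6)
    for seed in range(5):
        x = band_noise(int(3 * FS), np.random.default_rng(seed))
        se = section_energies(hilbert_huang(x, FS), 0.3, 2.7)
        assert se.pct_before + se.pct_during + se.pct_after == pytest.approx(100.0, abs=1e-6)
        assert min(se.e_before, se.e_during, se.e_after) >= 0.0


def test_zero_energy_contraction_flagged():
    spec = hilbert_huang(np.zeros(int(FS)), FS)
    with pytest.raises(DegenerateInputError):
        section_energies(spec, 0.1, 0.9)


def test_window_ordering_enforced():
    spec = hilbert_huang(np.random.default_rng(0).normal(size=int(FS)), FS)
    with pytest.raises(ValidationError):
        section_energies(spec, 0.9, 0.1)


# --- classification ---------------------------------------------------------


@pytest.mark.parametrize(
    "triple,expected",
    [((40, 20, 40), True), ((30, 40, 30), False), ((30, 30, 40), False)],
)
def test_vshape_examples(triple, expected):
    assert classify_vshape(make_sections(triple)) is expected


def test_vshape_ties_never_count_as_lowest():
    """Exhaustive grid of integer compositions of 100 into three sections."""
    for b in range(0, 101, 5):
        for d in range(0, 101 - b, 5):
            a = 100 - b - d
            verdict = classify_vshape(make_sections((b, d, a)))
            assert verdict == (d < b and d < a)


@pytest.mark.parametrize(
    "n_total,n_v,expected", [(7, 5, 71), (10, 2, 20), (17, 11, 65)]
)
def test_vshape_percentage_ratio_arithmetic(n_total, n_v, expected):
    secs = [make_sections((40, 20, 40), t0=10.0 * i) for i in range(n_v)]
    secs += [make_sections((20, 40, 40), t0=10.0 * (n_v + i)) for i in range(n_total - n_v)]
    assert vshape_percentage(secs) == expected


def test_fewer_than_five_contractions_excluded():
    secs = [make_sections((40, 20, 40), t0=10.0 * i) for i in range(4)]
    assert vshape_percentage(secs) is None


def test_contractions_outside_ten_minutes_not_counted():
    secs = [make_sections((40, 20, 40), t0=100.0 * i) for i in range(8)]
    # only those starting within 600 s are analyzable: t0 = 0..600 -> 7
    assert vshape_percentage(secs, window_s=600.0) == 100
    assert len([s for s in secs if s.start_time_s <= 600.0]) == 7


def test_mean_activity_pattern_examples():
    (mb, md, ma), is_v = mean_activity_pattern(
        [make_sections((40, 20, 40)), make_sections((20, 40, 40))]
    )
    assert (mb, md, ma) == pytest.approx((30.0, 30.0, 40.0))
    assert is_v is False
    _, is_v2 = mean_activity_pattern([make_sections((40, 20, 40))] * 3)
    assert is_v2 is True


def test_mean_activity_matches_direct_average():
    rng = np.random.default_rng(7)
    triples = []
    for _ in range(6):
        x = rng.dirichlet([2, 2, 2]) * 100.0
        triples.append(tuple(x))
    (mb, md, ma), _ = mean_activity_pattern([make_sections(tr) for tr in triples])
    arr = np.array(triples)
    np.testing.assert_allclose([mb, md, ma], arr.mean(axis=0), atol=1e-9)


# --- pattern recovery on simulated contractions -----------------------------


def events_from_truth(truth, pad=0.5):
    return [
        ContractionEvent(
            start_time_s=tt - pad, end_time_s=tp + pad, t_pmax_s=tp,
            pmax_cmH2O=0.0, t_thresh_s=tt, pthresh_cmH2O=0.0,
        )
        for tt, tp in zip(truth.true_thresh_times_s, truth.true_pmax_times_s)
    ]


def test_vshape_and_dyssynergic_patterns_recovered():
    n_v = n_tot_v = n_d = n_tot_d = 0
    for seed in range(3):
        p = u.PRESETS["sham-5000hz"].replace(seed=seed, noise_sd=0.05)
        rec, truth = u.simulate_recording(p)
        for se in analyze_contractions(rec, events_from_truth(truth)):
            n_tot_v += 1
            n_v += classify_vshape(se)
        p = u.PRESETS["sci-5000hz"].replace(seed=seed, noise_sd=0.05, duration_s=100.0)
        rec, truth = u.simulate_recording(p)
        for se in analyze_contractions(rec, events_from_truth(truth)):
            n_tot_d += 1
            n_d += not classify_vshape(se)
    assert n_tot_v >= 9 and n_v / n_tot_v >= 0.9
    assert n_tot_d >= 9 and n_d / n_tot_d >= 0.9
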