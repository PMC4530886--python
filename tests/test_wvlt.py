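"""Wavelet transform, mask filtering, regression and read-off."""

from dataclasses import replace

import numpy as np
import pytest

import erpagree.wvlt as wv
from erpagree.exceptions import (
    FitError,
    InvalidArgumentError,
    RegressorConstructionError,
)
from erpagree.simulate import SimConfig, simulate_study
from erpagree.wvlt import (
    WaveletConfig,
    average_power_mask,
    build_regressors,
    extract_peak,
    filter_trial,
    fit_trial,
    morlet_cwt,
)

FS = 512.0
N = 1024
T = np.arange(N) / FS * 1000.0 - 200.0


def sine(f_hz, amp=1.0):
    return amp * np.sin(2 * np.pi * f_hz * np.arange(N) / FS)


# ---------------------------------------------------------------------------
# forward transform
# ---------------------------------------------------------------------------


def test_zero_trace_gives_zero_power():
    tf = morlet_cwt(np.zeros(N), T, WaveletConfig())
    assert np.all(tf.power == 0.0)


def test_power_scales_quadratically():
    cfg = WaveletConfig()
    p1 = morlet_cwt(sine(10.0), T, cfg).power
    p2 = morlet_cwt(sine(10.0, amp=2.0), T, cfg).power
    np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-10, atol=1e-30)


def test_cwt_linearity(rng):
    cfg = WaveletConfig()
    x, y = rng.standard_normal(N), rng.standard_normal(N)
    a, b = 2.5, -1.25
    lhs = morlet_cwt(a * x + b * y, T, cfg).coefficients
    rhs = a * morlet_cwt(x, T, cfg).coefficients + b * morlet_cwt(y, T, cfg).coefficients
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_peak_power_frequency_of_sinusoid():
    cfg = WaveletConfig()
    tf = morlet_cwt(sine(10.0), T, cfg)
    core = slice(N // 4, 3 * N // 4)
    mean_pow = tf.power[:, core].mean(axis=1)
    assert tf.frequencies_hz[np.argmax(mean_pow)] == pytest.approx(10.0)


def test_peak_frequency_cross_checked_against_pywavelets():
    pywt = pytest.importorskip("pywt")
    x = sine(8.0)
    # pywt's cmor uses the same Morlet parametrization (bandwidth-center)
    scales = 6.0 / np.arange(2.0, 20.5, 0.5) * FS  # pywt scales in samples
    coef, freqs = pywt.cwt(x, scales, "cmor0.05-6.0", sampling_period=1.0 / FS)
    ref_peak = freqs[np.argmax((np.abs(coef) ** 2)[:, N // 4 : 3 * N // 4].mean(axis=1))]
    cfg = WaveletConfig(frequencies_hz=tuple(np.arange(2.0, 20.5, 0.5)))
    tf = morlet_cwt(x, T, cfg)
    own_peak = tf.frequencies_hz[
        np.argmax(tf.power[:, N // 4 : 3 * N // 4].mean(axis=1))
    ]
    assert own_peak == pytest.approx(ref_peak, abs=0.51)
    assert own_peak == pytest.approx(8.0, abs=0.51)


def test_frequency_above_nyquist_rejected():
    cfg = WaveletConfig(frequencies_hz=(10.0, 300.0))
    with pytest.raises(InvalidArgumentError):
        morlet_cwt(sine(5.0), T, cfg)


# ---------------------------------------------------------------------------
# mask
# ---------------------------------------------------------------------------


def test_masks_nest_with_threshold():
    cfg = WaveletConfig()
    maps = [morlet_cwt(sine(6.0) + sine(12.0, 0.3), T, cfg)]
    m_low = average_power_mask(maps, 0.1)
    m_high = average_power_mask(maps, 0.2)
    assert np.all(m_high <= m_low)  # raising the threshold never adds cells
    # the global max power cell is always covered
    assert m_high.flat[np.argmax(maps[0].power)] == 1


def test_mask_equals_elementwise_oracle(rng):
    cfg = WaveletConfig(frequencies_hz=tuple(np.arange(2.0, 20.0, 2.0)))
    maps = [morlet_cwt(rng.standard_normal(N), T, cfg) for _ in range(4)]
    thr = 0.15
    mask = average_power_mask(maps, thr)
    mean_power = sum(m.power for m in maps) / 4.0
    oracle = np.zeros_like(mean_power, dtype=np.uint8)
    for i in range(mean_power.shape[0]):
        for j in range(0, mean_power.shape[1], 7):  # sparse elementwise check
            oracle[i, j] = mean_power[i, j] >= thr * mean_power.max()
            assert mask[i, j] == oracle[i, j]


def test_mask_axis_mismatch_rejected(rng):
    cfg = WaveletConfig()
    a = morlet_cwt(rng.standard_normal(N), T, cfg)
    b = morlet_cwt(rng.standard_normal(N // 2), T[: N // 2], cfg)
    with pytest.raises(InvalidArgumentError):
        average_power_mask([a, b], 0.1)


# ---------------------------------------------------------------------------
# filtering / reconstruction
# ---------------------------------------------------------------------------


def test_zero_mask_gives_zero_output(rng):
    cfg = WaveletConfig()
    x = rng.standard_normal(N)
    mask = np.zeros((len(cfg.frequencies_hz), N), np.uint8)
    assert np.all(filter_trial(x, T, mask, cfg) == 0.0)


def erp_like(t):
    return (
        -15 * np.exp(-0.5 * ((t - 90) / 15.0) ** 2)
        - 12 * np.exp(-0.5 * ((t - 140) / 18.0) ** 2)
        + 20 * np.exp(-0.5 * ((t - 250) / 45.0) ** 2)
    )


def test_all_ones_mask_round_trip():
    cfg = WaveletConfig()
    x = erp_like(T)
    mask = np.ones((len(cfg.frequencies_hz), N), np.uint8)
    rec = filter_trial(x, T, mask, cfg)
    assert np.corrcoef(rec, x)[0, 1] > 0.99


def test_signal_support_mask_improves_snr(rng):
    """A mask built from the clean ERP's own time-frequency support raises
    the peak-to-prestimulus-RMS ratio of noisy trials."""
    cfg = WaveletConfig()
    clean = erp_like(T)
    clean_map = morlet_cwt(clean, T, cfg)
    mask = (clean_map.power >= 0.01 * clean_map.power.max()).astype(np.uint8)
    pre = T < 0
    improved = 0
    for _ in range(10):
        noisy = clean + rng.standard_normal(N) * 5.0
        filt = filter_trial(noisy, T, mask, cfg)
        snr_in = np.max(np.abs(noisy)) / np.std(noisy[pre])
        snr_out = np.max(np.abs(filt)) / np.std(filt[pre])
        improved += snr_out > snr_in
    assert improved >= 9


def test_mask_shape_mismatch_rejected(rng):
    cfg = WaveletConfig()
    with pytest.raises(InvalidArgumentError):
        filter_trial(rng.standard_normal(N), T, np.ones((3, 3), np.uint8), cfg)


# ---------------------------------------------------------------------------
# regressors and least squares
# ---------------------------------------------------------------------------


LATS = {"N1": 90.0, "N2": 140.0, "P2": 250.0}


def test_negative_regressor_supported_only_where_average_negative():
    avg = erp_like(T)
    passes = build_regressors(avg, T, LATS)
    wave_n1 = passes["A"].design[:, 0]
    assert np.all(avg[wave_n1 != 0] < 0)
    assert np.any(wave_n1 != 0)


def test_p2_regressors_identical_across_passes():
    avg = erp_like(T)
    passes = build_regressors(avg, T, LATS)
    np.testing.assert_array_equal(passes["A"].design[:, 2:], passes["B"].design[:, 2:])


def test_segment_bounds_match_zero_crossing_scan():
    avg = erp_like(T)
    passes = build_regressors(avg, T, LATS)
    wave_p2 = passes["A"].design[:, 2]
    support = np.flatnonzero(wave_p2)
    lo, hi = support[0], support[-1]
    # brute-force scan: the contiguous same-sign run containing 250 ms
    i = int(np.argmin(np.abs(T - 250.0)))
    sign = np.sign(avg)
    slo = i
    while slo > 0 and sign[slo - 1] == sign[i]:
        slo -= 1
    shi = i
    while shi < N - 1 and sign[shi + 1] == sign[i]:
        shi += 1
    assert (lo, hi) == (slo, shi)


def test_wrong_polarity_latency_rejected():
    avg = erp_like(T)
    with pytest.raises(RegressorConstructionError):
        build_regressors(avg, T, {"N1": 250.0, "N2": 140.0, "P2": 90.0})


def test_fit_recovers_scaled_regressor():
    avg = erp_like(T)
    passes = build_regressors(avg, T, LATS)
    ra = passes["A"]
    trial = 2.0 * ra.design[:, 0]
    fitted, beta = fit_trial(trial, ra)
    assert beta[0] == pytest.approx(2.0, abs=1e-9)
    assert abs(beta[1]) < 1e-9
    np.testing.assert_allclose(fitted, trial, atol=1e-9)


def test_fit_matches_normal_equations(rng):
    avg = erp_like(T)
    ra = build_regressors(avg, T, LATS)["A"]
    for _ in range(20):
        y = rng.standard_normal(N)
        _, beta = fit_trial(y, ra)
        D = ra.design
        expected = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(beta, expected, atol=1e-8)


def test_rank_deficient_design_raises():
    avg = erp_like(T)
    ra = build_regressors(avg, T, LATS)
    bad = replace_design(ra["A"], np.column_stack([ra["A"].design[:, 0]] * 4))
    with pytest.raises(FitError):
        fit_trial(np.zeros(N), bad)


def replace_design(regset, design):
    from erpagree.wvlt import RegressorSet

    return RegressorSet(regset.pass_label, regset.peak_labels, design,
                        regset.peak_latencies_ms)


# ---------------------------------------------------------------------------
# read-off
# ---------------------------------------------------------------------------


def test_readoff_finds_positive_bump():
    cfg = WaveletConfig()
    fitted = 5.0 * np.exp(-0.5 * ((T - 250.0) / 30.0) ** 2)
    pf = extract_peak(fitted, T, "P2", 250.0, cfg)
    assert pf.present and pf.latency_ms == pytest.approx(250.0, abs=1.0)


def test_readoff_absent_when_wrong_polarity():
    cfg = WaveletConfig()
    pf = extract_peak(-np.ones(N), T, "P2", 250.0, cfg)
    assert not pf.present


def test_readoff_window_outside_epoch_rejected():
    cfg = WaveletConfig()
    with pytest.raises(InvalidArgumentError):
        extract_peak(np.zeros(N), T, "P2", 1750.0, cfg)


def test_readoff_matches_windowed_scan(rng):
    cfg = WaveletConfig()
    for _ in range(200):
        fitted = rng.standard_normal(N)
        pf = extract_peak(fitted, T, "N1", 90.0, cfg)
        hw = cfg.readoff_halfwidth_ms["N1"]
        sel = (T >= 90.0 - hw) & (T <= 90.0 + hw)
        neg = fitted[sel] < 0
        if not neg.any():
            assert not pf.present
        else:
            i = np.flatnonzero(sel)[int(np.argmin(fitted[sel]))]
            assert pf.present
            assert pf.latency_ms == T[i] and pf.amplitude_uv == fitted[i]


# ---------------------------------------------------------------------------
# full pipeline properties
# ---------------------------------------------------------------------------


def test_full_pipeline_recovers_noiseless_truth():
    """Noiseless, effectively non-overlapping peaks: latency within 5 ms and
    amplitude within 10% (wavelet smoothing bias allowed)."""
    cfg = SimConfig(sampling_rate=FS, n_subjects=1, n_trials_per_intensity=3, seed=2)
    narrow = {
        name: replace(t, half_width_ms=hw)
        for (name, t), hw in zip(cfg.peak_templates.items(), (14.0, 14.0, 45.0))
    }
    cfg = replace(cfg, peak_templates=narrow).noiseless()
    es, truth = simulate_study(cfg)
    # noiseless validation: no noise floor, so the mask threshold sits lower
    table = wv.detect_subject(es[0], WaveletConfig(threshold_fraction=0.02))
    tt = truth[truth.subject == "S01"]
    for peak in ("N1", "N2", "P2"):
        sub = tt[tt.peak == peak].reset_index()
        lat = table.feature(peak, "latency_ms")
        amp = table.feature(peak, "amplitude_uv")
        assert np.all(table.presence(peak) == 1)
        assert np.max(np.abs(lat - sub.latency_ms)) <= 5.0, peak
        assert np.max(np.abs((amp - sub.amplitude_uv) / sub.amplitude_uv)) <= 0.10, peak


def test_two_pass_scheme_separates_merged_n1_n2():
    """With fully merged N1/N2 (no zero crossing between them) the two-pass
    regression still yields distinct N1 and N2 read-offs."""
    cfg = SimConfig(sampling_rate=FS, n_subjects=1, n_trials_per_intensity=3, seed=4)
    cfg = cfg.noiseless()
    es, _ = simulate_study(cfg)
    avg = es[0].average()
    # confirm the merged-trough premise: one negative segment spans 90-140 ms
    t = es[0].time_ms
    seg = avg[(t > 80) & (t < 150)]
    assert np.all(seg < 0)
    table = wv.detect_subject(es[0])
    n1 = table.feature("N1", "latency_ms")
    n2 = table.feature("N2", "latency_ms")
    both = (table.presence("N1") == 1) & (table.presence("N2") == 1)
    assert both.any()
    assert np.all(n1[both] < n2[both])
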