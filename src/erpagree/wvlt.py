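"""Wavelet-filtering + multiple-linear-regression single-trial estimator.

Pipeline per subject:

1. Each trial is mapped to the time-frequency plane with a continuous Morlet
   wavelet transform (bandwidth parameter f_b = 0.05, center frequency
   parameter f_0 = 6) and squared to power.
2. The per-trial power maps are averaged and thresholded (fraction of the
   maximum mean power) into a binary mask marking the ERP's time-frequency
   support.
3. The mask is applied to each trial's complex coefficients; the denoised
   trial is reconstructed with the inverse transform (delta reconstruction
   over the frequency grid, amplitude-calibrated once per grid on a known
   sinusoid).
4. From the filtered average ERP, two regressors per peak are built — the
   average restricted to the zero-crossing-bounded segment containing the
   peak, and its first derivative. Because N1 and N2 usually overlap without
   a zero crossing between them, the regression is run in two passes: pass A
   fits N1 + P2 regressors, pass B fits N2 + P2.
5. Each filtered trial is fitted by ordinary least squares; amplitudes and
   latencies are read off the fitted trace as the correct-polarity extremum
   inside a window centred on the average-ERP peak latency. A peak is absent
   when no sample of the correct sign exists in its window.

The Morlet wavelet used is psi(t) = (pi*f_b)^(-1/2) exp(2i*pi*f_0*t) exp(-t^2/f_b),
whose Fourier transform is exp(-pi^2*f_b*(f - f_0)^2); the transform is
computed in the frequency domain with zero padding at the epoch edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .containers import PEAK_POLARITY, PEAKS, PeakFeature, TrialDetection
from .exceptions import FitError, InvalidArgumentError, RegressorConstructionError

__all__ = [
    "WaveletConfig",
    "TimeFrequencyMap",
    "RegressorSet",
    "morlet_cwt",
    "morlet_cwt_power",
    "average_power_mask",
    "filter_trial",
    "build_regressors",
    "fit_trial",
    "extract_peak",
    "detect_subject",
]


@dataclass(frozen=True)
class WaveletConfig:
    """Morlet-transform and read-off settings.

    The frequency grid spans the pre-filtered EEG band (0.5-30 Hz in 0.5 Hz
    steps by default); the mask threshold is a fraction of the maximum of the
    across-trial mean power; read-off windows are +/- half-widths (ms) around
    the average-ERP peak latencies.
    """

    f_b: float = 0.05
    f_0: float = 6.0
    frequencies_hz: tuple[float, ...] = tuple(np.arange(0.5, 30.0 + 1e-9, 0.5))
    threshold_fraction: float = 0.05
    # N1/N2 windows are kept narrower than their 50 ms separation so the
    # read-off cannot land on the neighbouring trough
    readoff_halfwidth_ms: dict[str, float] = field(
        default_factory=lambda: {"N1": 25.0, "N2": 25.0, "P2": 100.0}
    )

    def __post_init__(self) -> None:
        if self.f_b <= 0 or self.f_0 <= 0:
            raise InvalidArgumentError("f_b and f_0 must be positive")
        freqs = np.asarray(self.frequencies_hz, float)
        if freqs.size == 0 or (freqs <= 0).any():
            raise InvalidArgumentError("frequency grid must be positive")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise InvalidArgumentError("threshold fraction must be in (0, 1)")


@dataclass
class TimeFrequencyMap:
    """Complex CWT coefficients and their power on a time x frequency grid.

    coefficients has shape (n_frequencies, n_samples).
    """

    coefficients: np.ndarray
    frequencies_hz: np.ndarray
    time_ms: np.ndarray

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    def axes_match(self, other: "TimeFrequencyMap") -> bool:
        return (
            self.coefficients.shape == other.coefficients.shape
            and np.allclose(self.frequencies_hz, other.frequencies_hz)
            and np.allclose(self.time_ms, other.time_ms)
        )


def _wavelet_filterbank(n_samples: int, fs: float, config: WaveletConfig):
    """Frequency responses sqrt(a)*psi_hat(a f) for the padded FFT grid."""
    nfft = int(2 ** np.ceil(np.log2(2 * n_samples)))
    fgrid = np.fft.fftfreq(nfft, d=1.0 / fs)
    freqs = np.asarray(config.frequencies_hz, float)
    scales = config.f_0 / freqs
    bank = np.sqrt(scales)[:, None] * np.exp(
        -np.pi**2 * config.f_b * (scales[:, None] * fgrid[None, :] - config.f_0) ** 2
    )
    return nfft, scales, bank


def morlet_cwt(trace: np.ndarray, time_ms: np.ndarray, config: WaveletConfig) -> TimeFrequencyMap:
    """Continuous Morlet wavelet transform (complex coefficients).

    Linear in the input; computed via FFT with zero padding, so epoch edges
    see an implicit zero extension.
    """
    v = np.asarray(trace, float)
    t = np.asarray(time_ms, float)
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError("trace must be finite")
    fs = 1000.0 / float(np.mean(np.diff(t)))
    if max(config.frequencies_hz) >= fs / 2:
        raise InvalidArgumentError("frequency grid exceeds the Nyquist frequency")
    nfft, _, bank = _wavelet_filterbank(v.size, fs, config)
    X = np.fft.fft(v, nfft)
    W = np.fft.ifft(X[None, :] * np.conj(bank), axis=1)[:, : v.size]
    return TimeFrequencyMap(W, np.asarray(config.frequencies_hz, float), t)


def morlet_cwt_power(trace, time_ms, config: WaveletConfig) -> TimeFrequencyMap:
    """Convenience wrapper; .power of the returned map is magnitude-squared."""
    return morlet_cwt(trace, time_ms, config)


def average_power_mask(tf_maps: list[TimeFrequencyMap], threshold_fraction: float) -> np.ndarray:
    """Binary mask: cells whose across-trial mean power reaches the threshold
    fraction of the maximum mean power."""
    if not tf_maps:
        raise InvalidArgumentError("need at least one time-frequency map")
    first = tf_maps[0]
    for m in tf_maps[1:]:
        if not first.axes_match(m):
            raise InvalidArgumentError("time-frequency maps have mismatched axes")
    mean_power = np.mean([m.power for m in tf_maps], axis=0)
    return (mean_power >= threshold_fraction * mean_power.max()).astype(np.uint8)


#: relative response below which a frequency bin counts as out-of-band and is
#: not compensated (keeps the inverse bounded)
_GAIN_FLOOR = 0.05


@lru_cache(maxsize=8)
def _recon_response(freqs: tuple, f_b: float, f_0: float, fs: float, n: int):
    """Frequency response of the raw delta reconstruction.

    The composition CWT -> weighted real-part sum over scales is a linear
    operator, diagonal in the Fourier domain; its response on the padded FFT
    grid is

        D(f) = (G(f) + G(-f)) / 2,  G(f) = sum_j da_j psi_hat(a_j f) / a_j

    (the symmetrization accounts for taking the real part of the one-sided
    analytic coefficients). Dividing the raw reconstruction's spectrum by D
    inverts the transform exactly for in-band content; bins with
    D < _GAIN_FLOOR * max(D) are outside the analysis band and are zeroed.
    """
    cfg = WaveletConfig(f_b=f_b, f_0=f_0, frequencies_hz=freqs)
    nfft, scales, bank = _wavelet_filterbank(n, fs, cfg)
    da = np.abs(np.gradient(scales))
    g = (da / scales) @ (bank / np.sqrt(scales)[:, None])  # sum_j da_j psi_hat(a_j f)/a_j
    d = 0.5 * (g + g[(-np.arange(nfft)) % nfft])
    return nfft, d


def _extend_mask(mask: np.ndarray, nfft: int) -> np.ndarray:
    """Extend the epoch-length mask over the zero-padding region.

    Padding columns hold the (circular) spill-over of in-epoch content, so
    they replicate the mask value of the nearest epoch edge: the first half
    of the pad continues the last epoch column, the second half wraps to the
    first.
    """
    n = mask.shape[1]
    ext = np.empty((mask.shape[0], nfft), dtype=mask.dtype)
    ext[:, :n] = mask
    split = n + (nfft - n) // 2
    ext[:, n:split] = mask[:, -1:]
    ext[:, split:] = mask[:, :1]
    return ext


def _icwt_masked(
    trace: np.ndarray, mask: np.ndarray, config: WaveletConfig, fs: float
) -> np.ndarray:
    """Mask the trace's wavelet coefficients and invert the transform.

    Masking and reconstruction run at full padded length so the in-band
    frequency-response compensation is exact: with an all-ones mask the
    in-band part of the input is returned unchanged.
    """
    v = np.asarray(trace, float)
    n = v.size
    freqs = np.asarray(config.frequencies_hz, float)
    scales = config.f_0 / freqs
    da = np.abs(np.gradient(scales))
    nfft, d = _recon_response(tuple(config.frequencies_hz), config.f_b, config.f_0, fs, n)
    _, _, filt = _wavelet_filterbank(n, fs, config)
    X = np.fft.fft(v, nfft)
    W = np.fft.ifft(X[None, :] * np.conj(filt), axis=1)
    W *= _extend_mask(mask, nfft)
    raw = (da / scales**1.5) @ np.real(W)
    spec = np.fft.fft(raw)
    inband = d >= _GAIN_FLOOR * d.max()
    comp = np.zeros_like(spec)
    comp[inband] = spec[inband] / d[inband]
    return np.real(np.fft.ifft(comp))[:n]


def filter_trial(
    trace: np.ndarray,
    time_ms: np.ndarray,
    mask: np.ndarray,
    config: WaveletConfig,
) -> np.ndarray:
    """Mask the trial's wavelet coefficients and reconstruct the denoised trace.

    With an all-ones mask the in-band part of the input is recovered; masked
    cells remove their time-frequency content from the reconstruction.
    """
    v = np.asarray(trace, float)
    expected = (len(config.frequencies_hz), v.size)
    if mask.shape != expected:
        raise InvalidArgumentError(
            f"mask shape {mask.shape} does not match coefficient grid {expected}"
        )
    fs = 1000.0 / float(np.mean(np.diff(np.asarray(time_ms, float))))
    return _icwt_masked(v, mask, config, fs)


@dataclass
class RegressorSet:
    """Design matrix for one regression pass (A: N1+P2, B: N2+P2).

    design has shape (n_samples, 2 * n_peaks): for each peak, the average-ERP
    segment regressor followed by its first-derivative regressor.
    """

    pass_label: str
    peak_labels: tuple[str, ...]
    design: np.ndarray
    peak_latencies_ms: dict[str, float]


def _segment_bounds(avg: np.ndarray, idx: int) -> tuple[int, int]:
    """Half-open sample range of the same-sign segment containing idx."""
    s = np.sign(avg)
    target = s[idx]
    lo = idx
    while lo > 0 and s[lo - 1] == target:
        lo -= 1
    hi = idx + 1
    while hi < avg.size and s[hi] == target:
        hi += 1
    return lo, hi


def build_regressors(
    filtered_avg: np.ndarray,
    time_ms: np.ndarray,
    peak_latencies_ms: dict[str, float],
) -> dict[str, RegressorSet]:
    """Build the two regression passes from the filtered average ERP.

    Each waveform regressor is the average restricted to the zero-crossing-
    bounded segment containing the peak's latency (zero elsewhere); the second
    regressor is its first derivative. If the average has no sign structure at
    all (never crosses zero), whole-epoch segments are used.
    """
    avg = np.asarray(filtered_avg, float)
    t = np.asarray(time_ms, float)
    for name in PEAKS:
        if name not in peak_latencies_ms:
            raise InvalidArgumentError(f"missing latency for {name}")
        if not t[0] <= peak_latencies_ms[name] <= t[-1]:
            raise InvalidArgumentError(f"{name} latency outside the epoch")

    dt = float(np.mean(np.diff(t)))

    def regressor_pair(name: str) -> np.ndarray:
        idx = int(np.argmin(np.abs(t - peak_latencies_ms[name])))
        pol = PEAK_POLARITY[name]
        if np.sign(avg[idx]) != pol:
            raise RegressorConstructionError(
                f"{name}: filtered average has the wrong polarity at "
                f"{peak_latencies_ms[name]:g} ms"
            )
        if (avg > 0).all() or (avg < 0).all():
            lo, hi = 0, avg.size  # degenerate: no zero crossings anywhere
        else:
            lo, hi = _segment_bounds(avg, idx)
        wave = np.zeros_like(avg)
        wave[lo:hi] = avg[lo:hi]
        deriv = np.gradient(wave, dt)
        return np.column_stack([wave, deriv])

    passes = {}
    for label, names in (("A", ("N1", "P2")), ("B", ("N2", "P2"))):
        design = np.hstack([regressor_pair(n) for n in names])
        passes[label] = RegressorSet(
            label, names, design, {n: float(peak_latencies_ms[n]) for n in names}
        )
    return passes


def fit_trial(filtered_trial: np.ndarray, regressors: RegressorSet):
    """Ordinary least-squares fit of one filtered trial.

    Returns (fitted_trace, coefficients). Raises FitError on a rank-deficient
    design (collinear regressors).
    """
    y = np.asarray(filtered_trial, float)
    D = regressors.design
    if y.size != D.shape[0]:
        raise InvalidArgumentError("trial and regressors have different lengths")
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        raise FitError(
            f"rank-deficient design in pass {regressors.pass_label} "
            f"(rank {rank} < {D.shape[1]}); regressors are collinear"
        )
    return D @ beta, beta


def extract_peak(
    fitted: np.ndarray,
    time_ms: np.ndarray,
    peak_label: str,
    avg_latency_ms: float,
    config: WaveletConfig,
    window_ms: tuple[float, float] | None = None,
) -> PeakFeature:
    """Windowed read-off: correct-polarity extremum around the average latency.

    The peak is absent when no sample of the correct sign lies in the window.
    window_ms overrides the default avg_latency +/- half-width bounds (used to
    keep the N1 and N2 windows disjoint when their marked latencies are close).
    """
    t = np.asarray(time_ms, float)
    hw = config.readoff_halfwidth_ms[peak_label]
    w0, w1 = window_ms if window_ms is not None else (
        avg_latency_ms - hw, avg_latency_ms + hw
    )
    if w0 < t[0] or w1 > t[-1]:
        raise InvalidArgumentError(
            f"{peak_label} read-off window {w0:g}-{w1:g} ms outside the epoch"
        )
    sel = (t >= w0) & (t <= w1)
    pol = PEAK_POLARITY[peak_label]
    seg = np.asarray(fitted, float)[sel]
    tseg = t[sel]
    signed = pol * seg
    if (signed <= 0).all():
        return PeakFeature(False)
    i = int(np.argmax(signed))
    return PeakFeature(True, float(seg[i]), float(tseg[i]))


def _find_avg_latencies(avg: np.ndarray, time_ms: np.ndarray) -> dict[str, float]:
    """Automatic stand-in for the manual average-ERP peak marking.

    A windowed polarity-constrained extremum is used (rather than requiring a
    local extremum) because overlapping N1/N2 often merge into a single
    trough in the filtered average.
    """
    from .driv import windowed_peak_latencies

    return windowed_peak_latencies(avg, time_ms)


def detect_subject(
    epochs,
    config: WaveletConfig | None = None,
    peak_latencies_ms: dict[str, float] | None = None,
):
    """Run the full wavelet-regression pipeline on one subject's EpochSet.

    Average-ERP peak latencies may be supplied (the original procedure marks
    them manually); otherwise they are found automatically in the filtered
    average. N1 is read from the pass-A fit, N2 from pass B, P2 from pass A
    (the P2 regressors of the two passes coincide). Returns a DetectionTable.
    """
    from .containers import DetectionTable

    config = config or WaveletConfig()
    t = epochs.time_ms
    # streaming mean power (avoids holding every trial's complex map at once)
    mean_power = None
    for tr in epochs.traces:
        p = morlet_cwt(tr, t, config).power
        mean_power = p if mean_power is None else mean_power + p
    mean_power /= epochs.n_trials
    mask = (mean_power >= config.threshold_fraction * mean_power.max()).astype(np.uint8)
    filtered = np.array(
        [filter_trial(tr, t, mask, config) for tr in epochs.traces]
    )
    filt_avg = filtered.mean(axis=0)
    lats = peak_latencies_ms or _find_avg_latencies(filt_avg, t)
    passes = build_regressors(filt_avg, t, lats)
    # keep the two negative read-off windows disjoint: when the marked N1/N2
    # latencies are closer than two half-widths, cap both at their midpoint
    mid = 0.5 * (lats["N1"] + lats["N2"])
    dt = float(np.mean(np.diff(t)))
    hw1, hw2 = config.readoff_halfwidth_ms["N1"], config.readoff_halfwidth_ms["N2"]
    win_n1 = (lats["N1"] - hw1, min(lats["N1"] + hw1, mid))
    win_n2 = (max(lats["N2"] - hw2, mid + dt / 2), lats["N2"] + hw2)
    trials = []
    for i in range(epochs.n_trials):
        fitted_a, _ = fit_trial(filtered[i], passes["A"])
        fitted_b, _ = fit_trial(filtered[i], passes["B"])
        det = TrialDetection(
            {
                "N1": extract_peak(fitted_a, t, "N1", lats["N1"], config, win_n1),
                "N2": extract_peak(fitted_b, t, "N2", lats["N2"], config, win_n2),
                "P2": extract_peak(fitted_a, t, "P2", lats["P2"], config),
            },
            intensity_code=int(epochs.intensity_code[i])
            if epochs.intensity_code.size
            else None,
        )
        trials.append(det)
    return DetectionTable.from_trials("WVLT", epochs.subject_id, trials)
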