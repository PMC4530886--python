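"""Synthetic single-trial ERP study generator with known ground truth.

Emulates vertex (Cz) epochs evoked by graded electrical stimulation: three
stereotyped peaks — N1 (~90 ms, negative), N2 (~140 ms, negative) and P2
(~250 ms, positive) — whose amplitude and probability of being present grow
with stimulation intensity, superimposed on band-limited background noise.

Each peak is a Gaussian bump of configured polarity and half-width; N1 and N2
half-widths are chosen so the two negative deflections overlap, as they do in
lower-limb somatosensory recordings. Background noise is the sum of white
noise and a first-order autoregressive component, approximating the 0.5–30 Hz
EEG band.

A single integer seed fans out into independent per-subject substreams, so a
whole study and any individual subject are both reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import INTENSITY_FACTORS, PEAKS, EpochSet
from .exceptions import InvalidArgumentError

__all__ = [
    "PeakTemplate",
    "NoiseModel",
    "SimConfig",
    "simulate_trial",
    "simulate_study",
    "write_epochs_csv",
    "read_epochs_csv",
    "write_truth_csv",
    "truth_to_detection_tables",
]

# HWHM -> sigma for a Gaussian bump
_HWHM_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PeakTemplate:
    """Shape and variability of one ERP peak.

    amplitude magnitude (uV) for a trial at intensity factor x (in units of
    the reflex threshold) is drawn as

        |A| = base_amplitude_uv + amplitude_slope_uv * x + N(0, amplitude_jitter_sd_uv)

    truncated below at 0.25 uV so the polarity is never inverted. Presence is
    Bernoulli with logistic probability

        p(present) = 1 / (1 + exp(-(presence_intercept + presence_slope * x)))

    half_width_ms is the half width at half maximum of the Gaussian bump.
    """

    polarity: int
    mean_latency_ms: float
    latency_jitter_sd_ms: float
    base_amplitude_uv: float
    amplitude_slope_uv: float
    amplitude_jitter_sd_uv: float
    half_width_ms: float
    presence_intercept: float
    presence_slope: float

    def presence_probability(self, intensity_factor: float) -> float:
        z = self.presence_intercept + self.presence_slope * intensity_factor
        return 1.0 / (1.0 + math.exp(-z))


def _default_templates() -> dict[str, PeakTemplate]:
    # Base/slope chosen so mean amplitudes across intensities sit near the
    # magnitudes typical for nociceptive vertex potentials (N1 ~ -18 uV,
    # N2 ~ -18 uV, P2 ~ +24 uV); logistic presence parameters give average
    # detection fractions of roughly 0.80 (N1), 0.57 (N2) and 0.93 (P2),
    # increasing with intensity.
    return {
        "N1": PeakTemplate(-1, 90.0, 10.0, 8.0, 8.0, 3.0, 20.0, -0.90, 2.20),
        "N2": PeakTemplate(-1, 140.0, 10.0, 8.0, 8.0, 3.0, 25.0, -1.60, 1.49),
        "P2": PeakTemplate(+1, 250.0, 15.0, 12.0, 8.0, 4.0, 60.0, 0.09, 2.60),
    }


@dataclass(frozen=True)
class NoiseModel:
    """Background EEG noise: white + AR(1) mixture scaled to a total SD.

    ar_corner_hz sets the AR(1) coefficient via phi = exp(-2*pi*f_c/fs), i.e.
    the -3 dB corner of the Lorentzian noise spectrum; white_fraction is the
    share of total variance carried by the flat component.
    """

    background_sd_uv: float = 5.0
    ar_corner_hz: float = 8.0
    white_fraction: float = 0.2

    def sample(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        if self.background_sd_uv == 0:
            return np.zeros(n)
        from scipy.signal import lfilter

        phi = math.exp(-2.0 * math.pi * self.ar_corner_hz / fs)
        w = rng.standard_normal(n + 256)
        w[0] /= math.sqrt(1.0 - phi * phi)  # stationary start
        ar = lfilter([1.0], [1.0, -phi], w)
        ar = ar[256:] * math.sqrt(1.0 - phi * phi)  # unit variance, burn-in dropped
        white = rng.standard_normal(n)
        mix = (
            math.sqrt(self.white_fraction) * white
            + math.sqrt(1.0 - self.white_fraction) * ar
        )
        return self.background_sd_uv * mix


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings (defaults mirror the recording setup:
    2048 Hz sampling, 2000 ms epochs with 200 ms pre-stimulus, 16 subjects,
    6 graded intensities x 20 trials each)."""

    sampling_rate: float = 2048.0
    epoch_window_ms: tuple[float, float] = (-200.0, 1800.0)
    n_subjects: int = 16
    n_trials_per_intensity: int = 20
    intensity_factors: dict[int, float] = field(
        default_factory=lambda: dict(INTENSITY_FACTORS)
    )
    peak_templates: dict[str, PeakTemplate] = field(default_factory=_default_templates)
    noise: NoiseModel = field(default_factory=NoiseModel)
    rejection_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window_ms
        if not (t0 < 0.0 <= t1):
            raise InvalidArgumentError("epoch window must span stimulus onset (0 ms)")
        factors = list(self.intensity_factors.values())
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise InvalidArgumentError("intensity factors must be strictly increasing")
        for name, tpl in self.peak_templates.items():
            if min(tpl.latency_jitter_sd_ms, tpl.amplitude_jitter_sd_uv) < 0:
                raise InvalidArgumentError(f"{name}: jitter SDs must be >= 0")
            if tpl.half_width_ms <= 0:
                raise InvalidArgumentError(f"{name}: half width must be > 0")
            if not (t0 < tpl.mean_latency_ms < t1):
                raise InvalidArgumentError(f"{name}: mean latency outside epoch window")
        if not 0.0 <= self.rejection_fraction < 1.0:
            raise InvalidArgumentError("rejection fraction must be in [0, 1)")

    @property
    def time_ms(self) -> np.ndarray:
        t0, t1 = self.epoch_window_ms
        n = int(round((t1 - t0) * self.sampling_rate / 1000.0))
        return t0 + np.arange(n) * 1000.0 / self.sampling_rate

    def noiseless(self, zero_jitter: bool = True, all_present: bool = True) -> "SimConfig":
        """Copy of the config with noise (and optionally jitter/absence) off.

        Convenient for exactness checks: detectors applied to such traces
        must recover template latencies and amplitudes.
        """
        templates = {}
        for name, tpl in self.peak_templates.items():
            kw = {}
            if zero_jitter:
                kw.update(latency_jitter_sd_ms=0.0, amplitude_jitter_sd_uv=0.0)
            if all_present:
                kw.update(presence_intercept=50.0, presence_slope=0.0)
            templates[name] = replace(tpl, **kw)
        return replace(
            self,
            peak_templates=templates,
            noise=replace(self.noise, background_sd_uv=0.0),
        )


def _gaussian_bump(time_ms: np.ndarray, latency: float, amp: float, hwhm: float) -> np.ndarray:
    sigma = hwhm * _HWHM_TO_SIGMA
    return amp * np.exp(-0.5 * ((time_ms - latency) / sigma) ** 2)


def simulate_trial(
    config: SimConfig, intensity_code: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Simulate one epoch at the given intensity.

    Returns (trace, truth) where truth maps each peak to its drawn
    (present, amplitude_uv, latency_ms); absent peaks carry NaN features.
    """
    if intensity_code not in config.intensity_factors:
        raise InvalidArgumentError(f"unknown intensity code {intensity_code!r}")
    x = config.intensity_factors[intensity_code]
    t = config.time_ms
    trace = config.noise.sample(t.size, config.sampling_rate, rng)
    truth: dict = {"intensity_code": intensity_code}
    t0, t1 = config.epoch_window_ms
    for name in PEAKS:
        tpl = config.peak_templates[name]
        present = rng.random() < tpl.presence_probability(x)
        if present:
            lat = tpl.mean_latency_ms + tpl.latency_jitter_sd_ms * rng.standard_normal()
            lat = float(np.clip(lat, 10.0, t1 - 10.0))
            mag = (
                tpl.base_amplitude_uv
                + tpl.amplitude_slope_uv * x
                + tpl.amplitude_jitter_sd_uv * rng.standard_normal()
            )
            mag = max(mag, 0.25)
            amp = tpl.polarity * mag
            trace = trace + _gaussian_bump(t, lat, amp, tpl.half_width_ms)
            truth[name] = {"present": 1, "amplitude_uv": amp, "latency_ms": lat}
        else:
            truth[name] = {"present": 0, "amplitude_uv": np.nan, "latency_ms": np.nan}
    return trace, truth


def simulate_study(config: SimConfig) -> tuple[list[EpochSet], pd.DataFrame]:
    """Simulate the full study.

    Returns one EpochSet per subject plus a long-format ground-truth table
    with columns subject, trial, intensity_code, peak, present, amplitude_uv,
    latency_ms. Trial order within a subject interleaves intensities in a
    randomized block order, as in the recording protocol.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    epoch_sets: list[EpochSet] = []
    truth_rows: list[dict] = []
    for si, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        subject_id = f"S{si + 1:02d}"
        codes = np.repeat(list(config.intensity_factors), config.n_trials_per_intensity)
        rng.shuffle(codes)
        if config.rejection_fraction > 0.0:
            keep = rng.random(codes.size) >= config.rejection_fraction
            codes = codes[keep]
        traces = np.empty((codes.size, config.time_ms.size))
        for ti, code in enumerate(codes):
            trace, truth = simulate_trial(config, int(code), rng)
            traces[ti] = trace
            for name in PEAKS:
                truth_rows.append(
                    {
                        "subject": subject_id,
                        "trial": ti,
                        "intensity_code": int(code),
                        "peak": name,
                        **truth[name],
                    }
                )
        epoch_sets.append(
            EpochSet(subject_id, traces, config.time_ms, codes.astype(int))
        )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=[
            "subject",
            "trial",
            "intensity_code",
            "peak",
            "present",
            "amplitude_uv",
            "latency_ms",
        ],
    )
    return epoch_sets, truth_df


def write_epochs_csv(epoch_sets: list[EpochSet], path: str) -> str:
    """Export epochs as long-format CSV: subject, trial, time_ms, voltage_uV,
    intensity_code."""
    frames = []
    for es in epoch_sets:
        n_trials, n_samples = es.traces.shape
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(es.subject_id, n_trials * n_samples),
                    "trial": np.repeat(np.arange(n_trials), n_samples),
                    "time_ms": np.tile(es.time_ms, n_trials),
                    "voltage_uV": es.traces.ravel(),
                    "intensity_code": np.repeat(es.intensity_code, n_samples),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_epochs_csv(path: str) -> list[EpochSet]:
    """Read the long-format epoch CSV back into per-subject EpochSets."""
    df = pd.read_csv(path)
    out = []
    for subject, g in df.groupby("subject", sort=True):
        piv = g.pivot(index="trial", columns="time_ms", values="voltage_uV")
        codes = g.groupby("trial")["intensity_code"].first().loc[piv.index]
        out.append(
            EpochSet(str(subject), piv.to_numpy(), piv.columns.to_numpy(float),
                     codes.to_numpy(int))
        )
    return out


def write_truth_csv(truth_df: pd.DataFrame, path: str) -> str:
    """Export the long-format ground-truth table as CSV."""
    truth_df.to_csv(path, index=False)
    return path


def truth_to_detection_tables(truth_df: pd.DataFrame, method: str = "TRUTH"):
    """Pivot the long ground-truth table into per-subject DetectionTables,
    so simulator truth can stand in as a reference 'observer' in agreement
    analyses."""
    from .containers import MATRIX_COLUMNS, DetectionTable

    tables: dict[str, DetectionTable] = {}
    for subject, g in truth_df.groupby("subject", sort=True):
        wide = g.pivot(index="trial", columns="peak")
        df = pd.DataFrame(index=wide.index)
        for name in PEAKS:
            lo = name.lower()
            df[f"{lo}_latency_ms"] = wide[("latency_ms", name)]
            df[f"{lo}_amplitude_uv"] = wide[("amplitude_uv", name)]
            df[f"{lo}_present"] = wide[("present", name)]
        df["intensity_code"] = g.groupby("trial")["intensity_code"].first()
        tables[str(subject)] = DetectionTable(
            method, str(subject), df.loc[:, list(MATRIX_COLUMNS)]
        )
    return tables
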