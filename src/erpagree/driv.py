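"""Derivative-based single-trial peak detector with fuzzy-zone weighting.

The detector mimics a human observer's visual search. All local maxima and
minima of the trace are located where the first difference changes sign.
Each candidate extremum is then weighted inside three fuzzy zones — one per
peak (N1, N2, P2) — whose weight is 1 at the zone's central latency, falls
off quadratically towards the two boundaries and is 0 outside them:

    w(t) = 1 - ((t - c) / (b_side - c))^2

with b_side the boundary on t's side of the center c. For each zone the
admissible candidate (correct amplitude sign, weight > 0) with the largest
|amplitude| * weight score is selected. If one and the same minimum wins both
the N1 and the N2 zone, it is assigned to the zone whose central latency is
closer, and the other zone is re-searched among the remaining minima; a zone
with no remaining admissible candidate reports the peak as absent.

Deterministic conventions not fixed by the scheme itself: a plateau of equal
samples counts as a single extremum at its midpoint sample, and score ties
within a zone go to the earlier latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PEAK_POLARITY, PEAKS, PeakFeature, TrialDetection
from .exceptions import InvalidArgumentError, ZoneConstructionError

__all__ = [
    "FuzzyZone",
    "CandidateExtremum",
    "local_extrema",
    "fuzzy_weight",
    "zones_from_average",
    "detect_peaks",
    "detect_subject",
]

#: default zone half-widths (ms) about the average-ERP peak latency
DEFAULT_ZONE_HALFWIDTHS = {"N1": 35.0, "N2": 35.0, "P2": 70.0}

#: default latency windows (ms) searched for each peak in the average ERP
DEFAULT_SEARCH_WINDOWS = {
    "N1": (50.0, 125.0),
    "N2": (115.0, 210.0),
    "P2": (180.0, 400.0),
}


@dataclass(frozen=True)
class FuzzyZone:
    peak_label: str
    center_ms: float
    lower_ms: float
    upper_ms: float
    polarity: int

    def __post_init__(self) -> None:
        if not self.lower_ms < self.center_ms < self.upper_ms:
            raise InvalidArgumentError(
                f"{self.peak_label}: require lower < center < upper, got "
                f"{self.lower_ms} / {self.center_ms} / {self.upper_ms}"
            )
        if self.polarity not in (-1, 1):
            raise InvalidArgumentError("polarity must be -1 or +1")


@dataclass(frozen=True)
class CandidateExtremum:
    index: int
    latency_ms: float
    amplitude_uv: float
    weight: float = np.nan
    score: float = np.nan


def local_extrema(trace: np.ndarray, time_ms: np.ndarray | None = None):
    """Local maxima and minima at strict sign changes of the first difference.

    Plateaus (runs of zero difference) flanked by opposite slopes yield a
    single candidate at the run's midpoint sample. Endpoints are never
    returned.
    """
    v = np.asarray(trace, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise InvalidArgumentError("trace must be 1-D with at least 3 samples")
    t = np.arange(v.size, dtype=float) if time_ms is None else np.asarray(time_ms, float)
    d = np.diff(v)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    maxima: list[CandidateExtremum] = []
    minima: list[CandidateExtremum] = []
    for p, q in zip(nz[:-1], nz[1:]):
        if s[p] == s[q]:
            continue
        # samples p+1 .. q all share the extremal value (plateau if q > p+1)
        idx = (p + 1 + q) // 2
        cand = CandidateExtremum(int(idx), float(t[idx]), float(v[idx]))
        (maxima if s[p] > 0 else minima).append(cand)
    return maxima, minima


def fuzzy_weight(latency_ms: float, zone: FuzzyZone) -> float:
    """Quadratic fuzzy membership: 1 at the center, 0 at/beyond the boundaries."""
    t, c = float(latency_ms), zone.center_ms
    b = zone.lower_ms if t < c else zone.upper_ms
    if t <= zone.lower_ms or t >= zone.upper_ms:
        return 0.0
    return 1.0 - ((t - c) / (b - c)) ** 2


def zones_from_average(
    avg_erp: np.ndarray,
    time_ms: np.ndarray,
    boundary_halfwidths: dict[str, float | tuple[float, float]] | None = None,
    centers: dict[str, float] | None = None,
    search_windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, FuzzyZone]:
    """Place the three fuzzy zones from the average ERP (or manual centers).

    For each peak the center is the latency of the largest-magnitude local
    extremum of the required polarity inside the search window; boundaries
    are center -/+ the configured half-widths (a scalar or an asymmetric
    (below, above) pair).
    """
    halfwidths = {**DEFAULT_ZONE_HALFWIDTHS, **(boundary_halfwidths or {})}
    windows = {**DEFAULT_SEARCH_WINDOWS, **(search_windows or {})}
    centers = dict(centers or {})
    avg = np.asarray(avg_erp, dtype=float)
    t = np.asarray(time_ms, dtype=float)
    zones: dict[str, FuzzyZone] = {}
    for name in PEAKS:
        pol = PEAK_POLARITY[name]
        if name in centers:
            c = float(centers[name])
        else:
            maxima, minima = local_extrema(avg, t)
            cands = maxima if pol > 0 else minima
            w0, w1 = windows[name]
            cands = [
                e
                for e in cands
                if w0 <= e.latency_ms <= w1 and np.sign(e.amplitude_uv) == pol
            ]
            if not cands:
                raise ZoneConstructionError(
                    f"no admissible {name} extremum in the average ERP within "
                    f"{w0:g}-{w1:g} ms; supply a manual center"
                )
            c = max(cands, key=lambda e: abs(e.amplitude_uv)).latency_ms
        hw = halfwidths[name]
        below, above = (hw, hw) if np.isscalar(hw) else hw
        zones[name] = FuzzyZone(name, c, c - float(below), c + float(above), pol)
    return zones


def windowed_peak_latencies(
    avg_erp: np.ndarray,
    time_ms: np.ndarray,
    search_windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Correct-polarity extremum latency per peak inside its search window.

    Unlike zones_from_average this does not require a *local* extremum, so it
    also works when overlapping N1/N2 merge into a single trough of the
    average ERP.
    """
    windows = {**DEFAULT_SEARCH_WINDOWS, **(search_windows or {})}
    avg = np.asarray(avg_erp, float)
    t = np.asarray(time_ms, float)
    lats: dict[str, float] = {}
    for name in PEAKS:
        w0, w1 = windows[name]
        sel = (t >= w0) & (t <= w1)
        seg = PEAK_POLARITY[name] * avg[sel]
        if not sel.any() or (seg <= 0).all():
            raise ZoneConstructionError(
                f"average ERP has no {name}-polarity deflection in {w0:g}-{w1:g} ms"
            )
        lats[name] = float(t[sel][int(np.argmax(seg))])
    return lats


def _best_candidate(
    cands: list[CandidateExtremum], zone: FuzzyZone, exclude: set[int] = frozenset()
) -> CandidateExtremum | None:
    best: CandidateExtremum | None = None
    for e in cands:
        if e.index in exclude:
            continue
        if np.sign(e.amplitude_uv) != zone.polarity:
            continue
        w = fuzzy_weight(e.latency_ms, zone)
        if w <= 0.0:
            continue
        score = abs(e.amplitude_uv) * w
        if (
            best is None
            or score > best.score
            or (score == best.score and e.latency_ms < best.latency_ms)
        ):
            best = CandidateExtremum(e.index, e.latency_ms, e.amplitude_uv, w, score)
    return best


def detect_peaks(
    trace: np.ndarray, time_ms: np.ndarray, zones: dict[str, FuzzyZone]
) -> TrialDetection:
    """Apply the fuzzy-zone selection and the N1/N2 conflict rule to one trial."""
    maxima, minima = local_extrema(trace, time_ms)
    features: dict[str, PeakFeature] = {}

    best = {
        "N1": _best_candidate(minima, zones["N1"]),
        "N2": _best_candidate(minima, zones["N2"]),
    }
    if (
        best["N1"] is not None
        and best["N2"] is not None
        and best["N1"].index == best["N2"].index
    ):
        lat = best["N1"].latency_ms
        d1 = abs(lat - zones["N1"].center_ms)
        d2 = abs(lat - zones["N2"].center_ms)
        winner, loser = ("N1", "N2") if d1 <= d2 else ("N2", "N1")
        best[loser] = _best_candidate(
            minima, zones[loser], exclude={best[winner].index}
        )
    for name in ("N1", "N2"):
        e = best[name]
        features[name] = (
            PeakFeature(True, e.amplitude_uv, e.latency_ms)
            if e is not None
            else PeakFeature(False)
        )
    e = _best_candidate(maxima, zones["P2"])
    features["P2"] = (
        PeakFeature(True, e.amplitude_uv, e.latency_ms)
        if e is not None
        else PeakFeature(False)
    )
    return TrialDetection(features)


def detect_subject(
    epochs, zones: dict[str, FuzzyZone] | None = None, **zone_kwargs
):
    """Run the detector on every trial of an EpochSet.

    Zones default to zones_from_average of the subject's own average ERP, as
    in the original protocol; if the average lacks a distinct local extremum
    for some peak (merged N1/N2 trough), the windowed-extremum rule supplies
    the centers instead. Returns a DetectionTable.
    """
    from .containers import DetectionTable

    if zones is None:
        avg = epochs.average()
        try:
            zones = zones_from_average(avg, epochs.time_ms, **zone_kwargs)
        except ZoneConstructionError:
            centers = windowed_peak_latencies(
                avg, epochs.time_ms, zone_kwargs.get("search_windows")
            )
            zones = zones_from_average(
                avg, epochs.time_ms, centers=centers, **zone_kwargs
            )
    trials = []
    for i in range(epochs.n_trials):
        det = detect_peaks(epochs.traces[i], epochs.time_ms, zones)
        det.intensity_code = int(epochs.intensity_code[i]) if epochs.intensity_code.size else None
        trials.append(det)
    return DetectionTable.from_trials("DRIV", epochs.subject_id, trials)
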