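"""Core data containers shared across the simulator, detectors and IO.

Conventions
-----------
* Time is in milliseconds relative to stimulus onset at 0 ms; epochs start
  pre-stimulus (negative times).
* Voltages are in microvolts (uV). N1/N2 are negative peaks, P2 positive.
* Stimulation intensity is coded 1..6, mapping to 0.50, 0.75, 1.00, 1.25,
  1.50 and 2.00 times the reflex threshold (RTh).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidArgumentError

PEAKS = ("N1", "N2", "P2")
PEAK_POLARITY = {"N1": -1, "N2": -1, "P2": +1}

INTENSITY_FACTORS = {1: 0.50, 2: 0.75, 3: 1.00, 4: 1.25, 5: 1.50, 6: 2.00}

#: Fixed positional column order of the per-subject detection matrix
#: (j trials x 10 columns).
MATRIX_COLUMNS = (
    "n1_latency_ms",
    "n2_latency_ms",
    "p2_latency_ms",
    "n1_amplitude_uv",
    "n2_amplitude_uv",
    "p2_amplitude_uv",
    "n1_present",
    "n2_present",
    "p2_present",
    "intensity_code",
)


@dataclass
class PeakFeature:
    """Presence/amplitude/latency of one peak in one trial."""

    present: bool
    amplitude_uv: float = np.nan
    latency_ms: float = np.nan


@dataclass
class TrialDetection:
    """Detected N1/N2/P2 features for a single trial."""

    peaks: dict[str, PeakFeature]
    intensity_code: int | None = None

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for name in PEAKS:
            pf = self.peaks[name]
            lo = name.lower()
            row[f"{lo}_latency_ms"] = pf.latency_ms if pf.present else np.nan
            row[f"{lo}_amplitude_uv"] = pf.amplitude_uv if pf.present else np.nan
            row[f"{lo}_present"] = int(pf.present)
        row["intensity_code"] = (
            int(self.intensity_code) if self.intensity_code is not None else np.nan
        )
        return row


class DetectionTable:
    """Per-subject table of single-trial detections for one method.

    Wraps a :class:`pandas.DataFrame` with the fixed column set
    :data:`MATRIX_COLUMNS`. Rows are trials. Amplitudes/latencies of absent
    peaks are stored as NaN regardless of any placeholder present on disk.
    """

    def __init__(self, method: str, subject_id: str, df: pd.DataFrame):
        self.method = str(method)
        self.subject_id = str(subject_id)
        df = df.loc[:, list(MATRIX_COLUMNS)].reset_index(drop=True).astype(float)
        self.df = df
        self.validate()
        # absent peaks carry no amplitude/latency
        for name in PEAKS:
            lo = name.lower()
            absent = self.df[f"{lo}_present"] == 0
            self.df.loc[absent, [f"{lo}_latency_ms", f"{lo}_amplitude_uv"]] = np.nan

    # -- construction -----------------------------------------------------
    @classmethod
    def from_matrix(cls, method: str, subject_id: str, arr: np.ndarray) -> "DetectionTable":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(MATRIX_COLUMNS):
            raise FormatError(
                f"subject {subject_id!r}: expected a 2-D matrix with "
                f"{len(MATRIX_COLUMNS)} columns, got shape {arr.shape}"
            )
        return cls(method, subject_id, pd.DataFrame(arr, columns=list(MATRIX_COLUMNS)))

    @classmethod
    def from_trials(
        cls, method: str, subject_id: str, trials: list[TrialDetection]
    ) -> "DetectionTable":
        rows = [t.as_row() for t in trials]
        return cls(method, subject_id, pd.DataFrame(rows, columns=list(MATRIX_COLUMNS)))

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for name in PEAKS:
            pres = self.df[f"{name.lower()}_present"].to_numpy()
            if not np.isin(pres, (0.0, 1.0)).all():
                bad = int(np.flatnonzero(~np.isin(pres, (0.0, 1.0)))[0])
                raise FormatError(
                    f"subject {self.subject_id!r}, row {bad}: {name} presence "
                    f"value {pres[bad]!r} outside {{0, 1}}"
                )
        inten = self.df["intensity_code"].to_numpy()
        if not np.isin(inten, list(INTENSITY_FACTORS)).all():
            bad = int(np.flatnonzero(~np.isin(inten, list(INTENSITY_FACTORS)))[0])
            raise FormatError(
                f"subject {self.subject_id!r}, row {bad}: intensity code "
                f"{inten[bad]!r} outside 1..6"
            )

    # -- accessors --------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.df)

    def presence(self, peak: str) -> np.ndarray:
        return self.df[f"{peak.lower()}_present"].to_numpy().astype(int)

    def feature(self, peak: str, feature: str) -> np.ndarray:
        """Return amplitude_uv or latency_ms values (NaN where absent)."""
        if feature not in ("amplitude_uv", "latency_ms"):
            raise InvalidArgumentError(f"unknown feature {feature!r}")
        return self.df[f"{peak.lower()}_{feature}"].to_numpy()

    def intensity_codes(self) -> np.ndarray:
        return self.df["intensity_code"].to_numpy().astype(int)

    def subset_intensity(self, code: int) -> "DetectionTable":
        sub = self.df[self.df["intensity_code"] == code]
        return DetectionTable(self.method, self.subject_id, sub)

    def to_matrix(self) -> np.ndarray:
        return self.df.loc[:, list(MATRIX_COLUMNS)].to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DetectionTable):
            return NotImplemented
        a, b = self.to_matrix(), other.to_matrix()
        return (
            self.method == other.method
            and self.subject_id == other.subject_id
            and a.shape == b.shape
            and np.array_equal(a, b, equal_nan=True)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DetectionTable(method={self.method!r}, subject={self.subject_id!r}, "
            f"n_trials={self.n_trials})"
        )


@dataclass
class EpochSet:
    """Single-channel epochs for one subject.

    traces has shape (n_trials, n_samples); all trials share time_ms.
    """

    subject_id: str
    traces: np.ndarray
    time_ms: np.ndarray
    intensity_code: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.intensity_code = np.asarray(self.intensity_code, dtype=int)
        if self.traces.shape[1] != self.time_ms.size:
            raise InvalidArgumentError(
                "traces and time axis disagree: "
                f"{self.traces.shape[1]} samples vs {self.time_ms.size} time points"
            )
        if self.intensity_code.size not in (0, self.traces.shape[0]):
            raise InvalidArgumentError("one intensity code per trial required")

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def sampling_rate(self) -> float:
        dt_ms = float(np.mean(np.diff(self.time_ms)))
        return 1000.0 / dt_ms

    def average(self) -> np.ndarray:
        """Across-trial average ERP."""
        return self.traces.mean(axis=0)
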