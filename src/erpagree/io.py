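"""Reading/writing detection containers and minimal epoch preprocessing.

The on-disk container mirrors the deposited per-method result files: a MAT
(v5) file holding one numeric array per subject, each with j rows (trials)
and 10 positional columns — N1/N2/P2 latency (ms), N1/N2/P2 amplitude (uV),
N1/N2/P2 presence (1/0) and stimulation intensity code (1..6). Column order
is positional; no header inference is attempted. When presence is 0 the
stored latency/amplitude values are treated as missing regardless of the
placeholder used by the writer.

A tidy long-format CSV (method, subject, trial, peak, present, amplitude_uV,
latency_ms, intensity_code) is provided as the native text alternative.
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd
import scipy.io
from scipy import signal

from .containers import MATRIX_COLUMNS, PEAKS, DetectionTable, EpochSet
from .exceptions import FormatError, InvalidArgumentError

__all__ = [
    "read_detection_container",
    "write_detection_container",
    "read_detection_csv",
    "write_detection_csv",
    "bandpass_epoch_baseline",
]


def _subject_key(subject_id: str) -> str:
    # MAT variable names must be valid identifiers
    key = re.sub(r"\W", "_", str(subject_id))
    return key if key[:1].isalpha() else f"s_{key}"


def write_detection_container(tables: dict[str, DetectionTable], path: str) -> str:
    """Write per-subject detection matrices to a MAT (v5) container."""
    payload = {}
    for subject_id, table in tables.items():
        table.validate()
        payload[_subject_key(subject_id)] = table.to_matrix()
    scipy.io.savemat(path, payload)
    return path


def read_detection_container(path: str, method: str = "UNKNOWN") -> dict[str, DetectionTable]:
    """Read a per-method detection container.

    Accepts plain j x 10 numeric arrays and (for robustness against
    MATLAB struct wrapping) 1x1 structs whose single field holds the array.
    Subjects are returned keyed and ordered by variable name.
    """
    if not os.path.exists(path):
        raise FormatError(f"container not found: {path}")
    raw = scipy.io.loadmat(path)
    tables: dict[str, DetectionTable] = {}
    for key in sorted(k for k in raw if not k.startswith("__")):
        arr = raw[key]
        if isinstance(arr, np.ndarray) and arr.dtype.names:  # struct array
            fields = [arr[name].item() for name in arr.dtype.names]
            numeric = [f for f in fields if isinstance(f, np.ndarray) and f.ndim == 2]
            if len(numeric) != 1:
                raise FormatError(f"subject {key!r}: ambiguous struct contents")
            arr = numeric[0]
        if not isinstance(arr, np.ndarray) or arr.ndim != 2 or arr.shape[1] != 10:
            shape = getattr(arr, "shape", None)
            raise FormatError(
                f"subject {key!r}: expected j x 10 numeric matrix, got shape {shape}"
            )
        tables[key] = DetectionTable.from_matrix(method, key, np.asarray(arr, float))
    return tables


_CSV_COLUMNS = [
    "method",
    "subject",
    "trial",
    "peak",
    "present",
    "amplitude_uV",
    "latency_ms",
    "intensity_code",
]


def write_detection_csv(tables: dict[str, DetectionTable], path: str) -> str:
    """Export detection tables as a tidy long-format CSV."""
    rows = []
    for subject_id in sorted(tables):
        table = tables[subject_id]
        for trial, (_, row) in enumerate(table.df.iterrows()):
            for name in PEAKS:
                lo = name.lower()
                rows.append(
                    {
                        "method": table.method,
                        "subject": subject_id,
                        "trial": trial,
                        "peak": name,
                        "present": int(row[f"{lo}_present"]),
                        "amplitude_uV": row[f"{lo}_amplitude_uv"],
                        "latency_ms": row[f"{lo}_latency_ms"],
                        "intensity_code": int(row["intensity_code"]),
                    }
                )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    return path


def read_detection_csv(path: str) -> dict[str, DetectionTable]:
    """Read the tidy long-format CSV back into per-subject tables."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"CSV missing columns: {missing}")
    tables: dict[str, DetectionTable] = {}
    for subject, g in df.groupby("subject", sort=True):
        method = str(g["method"].iloc[0])
        wide = g.pivot(index="trial", columns="peak")
        out = pd.DataFrame(index=wide.index)
        for name in PEAKS:
            lo = name.lower()
            out[f"{lo}_latency_ms"] = wide[("latency_ms", name)]
            out[f"{lo}_amplitude_uv"] = wide[("amplitude_uV", name)]
            out[f"{lo}_present"] = wide[("present", name)]
        out["intensity_code"] = g.groupby("trial")["intensity_code"].first()
        tables[str(subject)] = DetectionTable(
            method, str(subject), out.loc[:, list(MATRIX_COLUMNS)]
        )
    return tables


def bandpass_epoch_baseline(
    traces: np.ndarray,
    time_ms: np.ndarray,
    low_hz: float = 0.5,
    high_hz: float = 30.0,
    pre_stimulus_ms: tuple[float, float] | None = None,
    order: int = 4,
    subject_id: str = "",
    intensity_code=None,
) -> EpochSet:
    """Zero-phase band-pass filter each epoch and baseline-correct it.

    The filter is a Butterworth band-pass applied forward-backward
    (no phase shift, so latencies are preserved); the mean of the
    pre-stimulus samples is then subtracted from each trial. By default the
    pre-stimulus interval is everything before 0 ms.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    time_ms = np.asarray(time_ms, dtype=float)
    fs = 1000.0 / float(np.mean(np.diff(time_ms)))
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidArgumentError(
            f"require 0 < low < high < Nyquist ({nyq:g} Hz); got {low_hz}-{high_hz} Hz"
        )
    if pre_stimulus_ms is None:
        pre_stimulus_ms = (float(time_ms[0]), 0.0)
    p0, p1 = pre_stimulus_ms
    if p0 < time_ms[0] or p1 > time_ms[-1] or p0 >= p1:
        raise InvalidArgumentError("pre-stimulus interval outside epoch window")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    # demean first: odd-reflection padding turns a DC offset into a large
    # low-frequency artifact. Maximal padding, because the low cut-off's
    # impulse response is long relative to a 2 s epoch.
    traces = traces - traces.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, traces, axis=1, padlen=traces.shape[1] - 1)
    pre = (time_ms >= p0) & (time_ms < p1)
    if not pre.any():
        raise InvalidArgumentError("pre-stimulus interval contains no samples")
    filtered = filtered - filtered[:, pre].mean(axis=1, keepdims=True)
    if intensity_code is None:
        codes = np.zeros(filtered.shape[0], int)
    else:
        codes = np.broadcast_to(np.asarray(intensity_code, int), (filtered.shape[0],)).copy()
    return EpochSet(subject_id, filtered, time_ms, codes)
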