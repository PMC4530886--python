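"""Categorical and quantitative agreement between two detection methods.

Categorical agreement (presence/absence of a peak) is summarized from the
2x2 contingency table of the two methods' presence flags:

    p_o   = 100 (a + d) / N            overall percent agreement
    p_pos = 100 * 2a / (2a + b + c)    positive (both-present) specific agreement
    p_neg = 100 * 2d / (2d + b + c)    negative (both-absent) specific agreement
    p_e   = 100 [(a+b)(a+c) + (c+d)(b+d)] / N^2   chance agreement
    kappa = (p_o - p_e) / (100 - p_e), floored at 0

where a = both present, b = only method A, c = only method B, d = both
absent. Negative kappa (agreement worse than chance) is reported as 0.

Quantitative agreement (amplitude/latency values on trials where both
methods report the peak) uses Bland-Altman bias and limits of agreement,
the two-way absolute-agreement single-measure intraclass correlation, and a
root-mean-square within-pair coefficient of variation. Only absolute values
of bias and LoA are reported: the analysis concerns how large the
between-method differences are, not their direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PEAKS, DetectionTable
from .exceptions import InsufficientDataError, InvalidArgumentError

__all__ = [
    "ContingencyTable2x2",
    "CategoricalAgreementResult",
    "QuantitativeAgreementResult",
    "contingency",
    "categorical_agreement",
    "paired_feature_series",
    "bland_altman",
    "icc_single_absolute",
    "cv_within_pairs",
    "MethodAgreement",
    "AgreementResults",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # both present
    b: int  # A present, B absent
    c: int  # A absent, B present
    d: int  # both absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidArgumentError("contingency counts must be non-negative")
        if self.n == 0:
            raise InvalidArgumentError("contingency table must contain trials")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CategoricalAgreementResult:
    p_o: float
    p_pos: float
    p_neg: float
    p_e: float
    kappa: float
    kappa_raw: float  # before flooring at 0


@dataclass(frozen=True)
class QuantitativeAgreementResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    icc: float
    cv_percent: float
    n_pairs: int

    @property
    def loa(self) -> float:
        """Single LoA summary: the larger of the two absolute bounds."""
        return max(self.loa_lower, self.loa_upper)


def contingency(presence_a, presence_b) -> ContingencyTable2x2:
    """Tabulate paired presence flags into a 2x2 table."""
    pa = np.asarray(presence_a).astype(bool)
    pb = np.asarray(presence_b).astype(bool)
    if pa.shape != pb.shape or pa.ndim != 1 or pa.size == 0:
        raise InvalidArgumentError("presence vectors must be equal-length, non-empty")
    return ContingencyTable2x2(
        a=int(np.sum(pa & pb)),
        b=int(np.sum(pa & ~pb)),
        c=int(np.sum(~pa & pb)),
        d=int(np.sum(~pa & ~pb)),
    )


def categorical_agreement(t: ContingencyTable2x2) -> CategoricalAgreementResult:
    """Percent agreements and chance-corrected kappa from a 2x2 table.

    Specific agreements with a zero denominator (no trial classified in that
    category by either method) are undefined and reported as NaN. kappa is
    undefined (NaN) when chance agreement is 100% (degenerate marginals).
    """
    a, b, c, d, n = t.a, t.b, t.c, t.d, t.n
    p_o = 100.0 * (a + d) / n
    p_pos = 100.0 * 2 * a / (2 * a + b + c) if (2 * a + b + c) > 0 else np.nan
    p_neg = 100.0 * 2 * d / (2 * d + b + c) if (2 * d + b + c) > 0 else np.nan
    p_e = 100.0 * ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e >= 100.0 - 1e-12:
        kappa_raw = np.nan
    else:
        kappa_raw = (p_o - p_e) / (100.0 - p_e)
    kappa = max(0.0, kappa_raw) if np.isfinite(kappa_raw) else np.nan
    return CategoricalAgreementResult(p_o, p_pos, p_neg, p_e, kappa, kappa_raw)


def paired_feature_series(
    table_a: DetectionTable,
    table_b: DetectionTable,
    peak: str,
    feature: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature values aligned by trial, restricted to both-present trials."""
    if table_a.n_trials != table_b.n_trials:
        raise InvalidArgumentError("tables must cover the same trials")
    both = (table_a.presence(peak) == 1) & (table_b.presence(peak) == 1)
    return table_a.feature(peak, feature)[both], table_b.feature(peak, feature)[both]


def bland_altman(x, y) -> tuple[float, float, tuple[float, float]]:
    """Absolute bias, SD of differences and absolute limits of agreement.

    Returns (|mean difference|, sd(diff, ddof=1), (|bias - 1.96 sd|,
    |bias + 1.96 sd|)). About 95% of the differences are expected inside the
    signed limits.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 paired values")
    diff = x - y
    m = float(np.mean(diff))
    s = float(np.std(diff, ddof=1))
    return abs(m), s, (abs(m - 1.96 * s), abs(m + 1.96 * s))


def icc_single_absolute(x, y) -> float:
    """Two-way absolute-agreement single-measure intraclass correlation (ICC(2,1)).

    Computed from the two-way ANOVA decomposition with n targets (trials) and
    k = 2 raters (methods):

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    NaN when the total variance is zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("ICC needs at least 2 paired values")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        return np.nan
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return np.nan
    return float((ms_r - ms_e) / denom)


def cv_within_pairs(x, y) -> float:
    """Root-mean-square within-pair coefficient of variation, in percent.

    Per pair i: s_i^2 = (x_i - y_i)^2 / 2 and m_i = (|x_i| + |y_i|) / 2;
    CV = 100 sqrt(mean(s_i^2 / m_i^2)). Magnitudes are used so the negative
    peaks (N1/N2) have positive denominators; pairs with m_i = 0 are dropped
    with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 1:
        raise InsufficientDataError("CV needs at least 1 pair")
    m = (np.abs(x) + np.abs(y)) / 2.0
    ok = m > 0
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} pair(s) with zero mean magnitude",
            stacklevel=2,
        )
    if not ok.any():
        return np.nan
    s2 = (x[ok] - y[ok]) ** 2 / 2.0
    return float(100.0 * np.sqrt(np.mean(s2 / m[ok] ** 2)))


# ---------------------------------------------------------------------------
# model/results interface
# ---------------------------------------------------------------------------

class MethodAgreement:
    """Agreement analysis between two methods' detections for one subject.

    Parameters
    ----------
    table_a, table_b : DetectionTable
        Trial-aligned detections of the same subject by two methods.
    peaks : sequence of str, optional
        Subset of ("N1", "N2", "P2") to analyze.
    """

    def __init__(self, table_a: DetectionTable, table_b: DetectionTable, peaks=PEAKS):
        if table_a.n_trials != table_b.n_trials:
            raise InvalidArgumentError(
                f"trial counts differ: {table_a.n_trials} vs {table_b.n_trials}"
            )
        self.table_a = table_a
        self.table_b = table_b
        self.peaks = tuple(peaks)

    def fit(self) -> "AgreementResults":
        rows = []
        for peak in self.peaks:
            cat = categorical_agreement(
                contingency(self.table_a.presence(peak), self.table_b.presence(peak))
            )
            row = {
                "peak": peak,
                "p_o": cat.p_o,
                "p_pos": cat.p_pos,
                "p_neg": cat.p_neg,
                "p_e": cat.p_e,
                "kappa": cat.kappa,
            }
            for feature, tag in (("amplitude_uv", "amplitude"), ("latency_ms", "latency")):
                x, y = paired_feature_series(self.table_a, self.table_b, peak, feature)
                if x.size >= 2:
                    bias, sd, (lo, hi) = bland_altman(x, y)
                    row[f"bias_{tag}"] = bias
                    row[f"loa_{tag}"] = max(lo, hi)
                    row[f"icc_{tag}"] = icc_single_absolute(x, y)
                    row[f"cv_{tag}"] = cv_within_pairs(x, y)
                else:
                    row[f"bias_{tag}"] = np.nan
                    row[f"loa_{tag}"] = np.nan
                    row[f"icc_{tag}"] = np.nan
                    row[f"cv_{tag}"] = np.nan
                row[f"n_pairs_{tag}"] = int(x.size)
            rows.append(row)
        table = pd.DataFrame(rows).set_index("peak")
        return AgreementResults(self, table)


class AgreementResults:
    """Per-peak agreement indices for one method pairing.

    Attributes
    ----------
    indices : pandas.DataFrame
        One row per peak: p_o, p_pos, p_neg, p_e, kappa, and per feature
        (amplitude/latency) bias, LoA, ICC, CV and pair count.
    """

    def __init__(self, model: MethodAgreement, indices: pd.DataFrame):
        self.model = model
        self.indices = indices

    @property
    def pairing(self) -> str:
        return f"{self.model.table_a.method}-{self.model.table_b.method}"

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            f"Agreement analysis: {self.pairing} "
            f"(subject {self.model.table_a.subject_id}, "
            f"{self.model.table_a.n_trials} trials)",
            "=" * 72,
        ]
        with pd.option_context("display.width", 110, "display.float_format", "{:.1f}".format):
            lines.append(str(self.indices.T))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AgreementResults {self.pairing}, peaks={list(self.indices.index)}>"
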