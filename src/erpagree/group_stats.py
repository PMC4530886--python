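"""Group-level tests across method pairings or stimulation intensities.

The repeated-measures design has one row per subject and one column per
condition (the six method pairings, or the six intensity codes), holding one
agreement index. Differences across conditions are tested with the
tie-corrected Friedman rank test; significant omnibus results are followed by
Student-Newman-Keuls stepwise comparisons on the Friedman mean ranks, using
the studentized-range distribution with SE = sqrt(k(k+1)/(12n)) and the SNK
protection rule (a non-significant range closes all of its sub-ranges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import (
    categorical_agreement,
    contingency,
    cv_within_pairs,
    paired_feature_series,
)
from .containers import DetectionTable
from .exceptions import InvalidArgumentError

__all__ = [
    "FriedmanResult",
    "friedman",
    "snk_posthoc",
    "stratify_by_intensity",
    "pairing_index_matrix",
]


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p_value: float
    mean_ranks: pd.Series
    n_rows: int


def _complete_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    complete = matrix.dropna(axis=0, how="any")
    dropped = len(matrix) - len(complete)
    if dropped:
        warnings.warn(
            f"dropping {dropped} row(s) with missing index values (listwise)",
            stacklevel=3,
        )
    return complete


def friedman(matrix: pd.DataFrame | np.ndarray) -> FriedmanResult:
    """Tie-corrected Friedman test on a subjects x conditions matrix.

    chi2 = [12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C with the tie
    correction C = 1 - sum(t^3 - t) / (n k (k^2 - 1)); p from chi-square with
    k - 1 degrees of freedom. Rows with any missing value are dropped.
    """
    matrix = pd.DataFrame(matrix)
    matrix = _complete_rows(matrix)
    n, k = matrix.shape
    if k < 2 or n < 2:
        raise InvalidArgumentError("need >= 2 conditions and >= 2 complete rows")
    values = matrix.to_numpy(float)
    ranks = stats.rankdata(values, axis=1)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:  # every row entirely tied
        chi2 = 0.0
    else:
        chi2 = chi2 / c
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    mean_ranks = pd.Series(rank_sums / n, index=matrix.columns, name="mean_rank")
    return FriedmanResult(float(chi2), df, p, mean_ranks, n)


def snk_posthoc(matrix: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Student-Newman-Keuls comparisons on Friedman mean ranks.

    Conditions are ordered by mean rank; each pair is tested at the
    studentized-range critical value for its span r (number of ordered means
    it encloses), q_crit(alpha, r, df=inf). Under the SNK stepwise rule, a
    pair inside a non-significant wider range is declared non-significant
    without testing.

    Returns a DataFrame with one row per condition pair: the rank difference,
    q statistic, span, critical value and significance flag.
    """
    matrix = pd.DataFrame(matrix)
    matrix = _complete_rows(matrix)
    n, k = matrix.shape
    if k < 2 or n < 2:
        raise InvalidArgumentError("need >= 2 conditions and >= 2 complete rows")
    ranks = stats.rankdata(matrix.to_numpy(float), axis=1)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=matrix.columns)
    order = mean_ranks.sort_values().index.to_list()
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    # positions in the ordered sequence
    pos = {cond: i for i, cond in enumerate(order)}
    rows = []
    blocked: set[tuple[int, int]] = set()
    # test wider spans first so the protection rule can close sub-ranges
    for span in range(k, 1, -1):
        q_crit = float(stats.studentized_range.ppf(1.0 - alpha, span, np.inf))
        if not np.isfinite(q_crit):  # pragma: no cover - scipy fallback
            q_crit = float(stats.studentized_range.ppf(1.0 - alpha, span, 1e6))
        for i in range(0, k - span + 1):
            j = i + span - 1
            ci, cj = order[i], order[j]
            diff = float(mean_ranks[cj] - mean_ranks[ci])
            q = diff / se
            protected = (i, j) in blocked
            significant = (not protected) and q > q_crit
            if not significant:
                # close every sub-range of a non-significant range
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        blocked.add((ii, jj))
            rows.append(
                {
                    "condition_low": ci,
                    "condition_high": cj,
                    "span": span,
                    "rank_diff": diff,
                    "q": q,
                    "q_crit": q_crit,
                    "significant": bool(significant),
                }
            )
    return pd.DataFrame(rows)


def _index_for_tables(
    table_a: DetectionTable, table_b: DetectionTable, peak: str, index: str
) -> float:
    """One agreement index for one subject's pair of tables."""
    if index == "kappa":
        try:
            res = categorical_agreement(
                contingency(table_a.presence(peak), table_b.presence(peak))
            )
        except InvalidArgumentError:
            return np.nan
        return res.kappa
    if index in ("cv_amplitude", "cv_latency"):
        feature = "amplitude_uv" if index == "cv_amplitude" else "latency_ms"
        x, y = paired_feature_series(table_a, table_b, peak, feature)
        if x.size < 1:
            return np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cv_within_pairs(x, y)
    raise InvalidArgumentError(f"unknown index {index!r}")


def stratify_by_intensity(
    tables_a: dict[str, DetectionTable],
    tables_b: dict[str, DetectionTable],
    peak: str,
    index: str,
) -> pd.DataFrame:
    """Per-subject x per-intensity agreement index matrix.

    index is "kappa", "cv_amplitude" or "cv_latency"; each cell is computed
    from only that intensity's trials (about 20 per subject by design).
    """
    subjects = sorted(set(tables_a) & set(tables_b))
    if not subjects:
        raise InvalidArgumentError("no common subjects between the two methods")
    codes = sorted(
        set(np.concatenate([tables_a[s].intensity_codes() for s in subjects]))
    )
    rows = {}
    for s in subjects:
        row = {}
        for code in codes:
            ta = tables_a[s].subset_intensity(code)
            tb = tables_b[s].subset_intensity(code)
            if ta.n_trials == 0 or ta.n_trials != tb.n_trials:
                row[code] = np.nan
            else:
                row[code] = _index_for_tables(ta, tb, peak, index)
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")[codes]


def pairing_index_matrix(
    tables_by_method: dict[str, dict[str, DetectionTable]],
    pairings: list[tuple[str, str]],
    peak: str,
    index: str,
) -> pd.DataFrame:
    """Subjects x pairings matrix of one agreement index.

    tables_by_method maps method name -> {subject -> DetectionTable}.
    """
    subjects = None
    for m in {m for pair in pairings for m in pair}:
        if m not in tables_by_method:
            raise InvalidArgumentError(f"missing detection tables for method {m!r}")
        s = set(tables_by_method[m])
        subjects = s if subjects is None else subjects & s
    subjects = sorted(subjects or [])
    data = {}
    for ma, mb in pairings:
        col = f"{ma}-{mb}"
        data[col] = [
            _index_for_tables(
                tables_by_method[ma][s], tables_by_method[mb][s], peak, index
            )
            for s in subjects
        ]
    return pd.DataFrame(data, index=subjects)
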