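"""Diagnostic-accuracy statistics for threshold category vs nerve distance.

Implements the study-level analysis on a cohort of site records: per-category
summaries and percentages, Spearman rank correlation between the ordinal
threshold category and distance, Welch t-tests between adjacent categories,
and the ROC / sensitivity-specificity panel for predicting a site-to-nerve
distance above a safety cutoff (default 10 mm, the radius beyond which an RF
lesion cannot plausibly reach the nerve).

The ROC predictor is the 5-level ordinal category with non-capture ranked
highest; AUC is the tie-corrected rank-sum (Mann–Whitney) estimator and its
CI a nonparametric bootstrap over sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .capture import ThresholdCategory

__all__ = [
    "CategoryRow",
    "CohortStats",
    "DiagnosticTable",
    "summarize_categories",
    "spearman_rho",
    "welch_t_test",
    "auc_mann_whitney",
    "sens_spec_at_cutoff",
    "build_table2",
    "roc_analysis",
]

CUTOFF_LABELS = {0: ">10 mA", 1: ">20 mA", 2: ">30 mA", 3: ">50 mA (no capture)"}


@dataclass(frozen=True)
class CategoryRow:
    label: str
    n: int
    percent: float        # of total sites, 1 decimal
    mean_mm: float
    sd_mm: float          # sample SD (n-1); 0 with sd_defined=False for n=1
    min_mm: float
    sd_defined: bool = True


@dataclass(frozen=True)
class CohortStats:
    total_n: int
    categories: tuple     # of CategoryRow, ordered by category
    capture_share_percent: float
    spearman_rho: float | None = None
    spearman_p: float | None = None
    adjacent_t_pvalues: tuple = ()


@dataclass(frozen=True)
class DiagnosticTable:
    """Se/Sp per threshold cutoff plus AUC for distance > cutoff prediction."""

    distance_cutoff_mm: float
    rows: tuple           # of dicts: cutoff label, sensitivity, specificity
    auc: float
    auc_ci_low: float = field(default=np.nan)
    auc_ci_high: float = field(default=np.nan)

    def __post_init__(self):
        for r in self.rows:
            if not (0 <= r["sensitivity"] <= 1 and 0 <= r["specificity"] <= 1):
                raise ValueError("proportions must be in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.rows))
        df["auc"] = round(self.auc, 3)
        return df


def _cats(records: pd.DataFrame) -> np.ndarray:
    return records["category"].to_numpy(dtype=int)


def summarize_categories(records: pd.DataFrame) -> CohortStats:
    """Counts, percentages (1 decimal) and distance mean/SD/min per category.

    SD is the sample SD (ddof=1); a single-record category reports SD 0 with
    ``sd_defined=False``. The capture share is the percentage of sites in the
    four capture categories.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    cats = _cats(records)
    d = records["distance_mm"].to_numpy(dtype=float)
    total = len(records)
    rows = []
    for cat in ThresholdCategory:
        sel = d[cats == int(cat)]
        n = len(sel)
        if n == 0:
            rows.append(CategoryRow(cat.label, 0, 0.0, np.nan, np.nan, np.nan, False))
            continue
        sd_def = n > 1
        rows.append(CategoryRow(
            cat.label, n, round(100.0 * n / total, 1),
            float(sel.mean()), float(sel.std(ddof=1)) if sd_def else 0.0,
            float(sel.min()), sd_def))
    capture_n = int(np.sum(cats != int(ThresholdCategory.NON_CAPTURE)))
    return CohortStats(total, tuple(rows), round(100.0 * capture_n / total, 1))


def spearman_rho(ordinal, distances):
    """Spearman rank correlation (mid-rank ties) with large-sample p-value.

    Returns ``(rho, p, valid)``; a constant input yields ``valid=False``.
    """
    x = np.asarray(ordinal, dtype=float)
    y = np.asarray(distances, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan, False
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), True


def welch_t_test(group_a, group_b):
    """Welch (unequal-variance) two-sided t-test; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def auc_mann_whitney(positive_mask, predictor) -> float:
    """Tie-corrected rank-sum AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    y = np.asarray(positive_mask, dtype=bool)
    x = np.asarray(predictor, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = sps.rankdata(x)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def sens_spec_at_cutoff(cats: np.ndarray, positive: np.ndarray, cutoff_index: int):
    """Se/Sp of the rule 'category above cutoff_index predicts remote (>cutoff) site'.

    cutoff_index k in 0..3 corresponds to the >10/>20/>30/>50 mA rules:
    predicted-positive means category > k.
    """
    pred = cats > cutoff_index
    se = float(np.mean(pred[positive])) if positive.any() else np.nan
    sp = float(np.mean(~pred[~positive])) if (~positive).any() else np.nan
    return se, sp


def build_table2(records: pd.DataFrame, distance_cutoff_mm: float = 10.0) -> DiagnosticTable:
    """Sensitivity/specificity panel at the four threshold cutoffs, plus AUC.

    Positives are sites with distance above the safety cutoff; the predictor
    is the ordinal category. Se decreases and Sp increases from the >10 mA to
    the >50 mA (non-capture) rule by construction of nested cutoffs.
    """
    cats = _cats(records)
    pos = records["distance_mm"].to_numpy(dtype=float) > distance_cutoff_mm
    rows = []
    for k in range(4):
        se, sp = sens_spec_at_cutoff(cats, pos, k)
        rows.append({"cutoff": CUTOFF_LABELS[k],
                     "sensitivity": round(se, 3), "specificity": round(sp, 3)})
    auc = auc_mann_whitney(pos, cats)
    return DiagnosticTable(distance_cutoff_mm, tuple(rows), auc)


def roc_analysis(records: pd.DataFrame, distance_cutoff_mm: float = 10.0,
                 n_boot: int = 2000, seed: int | np.random.Generator = 0) -> DiagnosticTable:
    """ROC analysis with bootstrap percentile CI on the AUC.

    Resamples sites with replacement ``n_boot`` times; resamples without both
    classes are redrawn. Errors if the cohort has a single class.
    """
    cats = _cats(records)
    pos = records["distance_mm"].to_numpy(dtype=float) > distance_cutoff_mm
    if pos.all() or not pos.any():
        raise ValueError("single-class cohort: ROC undefined")
    table = build_table2(records, distance_cutoff_mm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(records)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        while True:
            j = rng.integers(0, n, size=n)
            if pos[j].any() and not pos[j].all():
                break
        aucs[i] = auc_mann_whitney(pos[j], cats[j])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return DiagnosticTable(distance_cutoff_mm, table.rows, table.auc,
                           float(lo), float(hi))


def adjacent_category_tests(records: pd.DataFrame) -> tuple:
    """Welch p-values for each adjacent category pair (4 comparisons)."""
    cats = _cats(records)
    d = records["distance_mm"].to_numpy(dtype=float)
    out = []
    for k in range(4):
        a, b = d[cats == k], d[cats == k + 1]
        if len(a) >= 2 and len(b) >= 2:
            out.append(welch_t_test(a, b)[2])
        else:
            out.append(np.nan)
    return tuple(out)


def full_cohort_stats(records: pd.DataFrame) -> CohortStats:
    """Category summaries + Spearman correlation + adjacent-category t-tests."""
    base = summarize_categories(records)
    rho, p, valid = spearman_rho(_cats(records), records["distance_mm"])
    return CohortStats(base.total_n, base.categories, base.capture_share_percent,
                       rho if valid else None, p if valid else None,
                       adjacent_category_tests(records))
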