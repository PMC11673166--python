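"""Fidelity assessment: per-feature tests, labels and the URA total.

Three metrics judge how well a synthetic table resembles a reference
table, feature by feature:

* Welch's unequal-variance t test on every numeric feature column
  (pass iff two-sided p > 0.05);
* a chi-square test on the outcome class counts,
  ``chi2 = sum (S - R)^2 / R`` with ``categories - 1`` degrees of freedom
  (pass iff p > 0.05);
* the 1-Wasserstein distance between empirical CDFs of every numeric
  column, after min-max scaling by the reference column's range
  (pass iff distance < 0.1 by default).

Per metric, the pass count maps to a verbal label: "Excellent" above 50%
of features passing, "Poor" at zero, "Good" otherwise (a tie at exactly
50% is conservatively "Good").  The overall Univariate Resemblance
Assessment (URA) converts labels to 3/2/1, weights each by 1/n_metrics,
sums, rounds half-up and maps back to a label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schema import Table, TableSchema, ValidationError

__all__ = [
    "FeatureTestResult",
    "FidelityReport",
    "welch_t_pvalue",
    "chi_square_pvalue",
    "wasserstein_distance",
    "label_from_counts",
    "ura_total",
    "fidelity_report",
    "P_THRESHOLD",
    "WASSERSTEIN_THRESHOLD",
]

P_THRESHOLD = 0.05
WASSERSTEIN_THRESHOLD = 0.1

EXCELLENT, GOOD, POOR = "Excellent", "Good", "Poor"
_LABEL_SCORE = {EXCELLENT: 3, GOOD: 2, POOR: 1}
_SCORE_LABEL = {v: k for k, v in _LABEL_SCORE.items()}


@dataclass
class FeatureTestResult:
    column: str
    metric: str                    # t_test | chi_square | wasserstein
    statistic: float
    p_value: float | None
    passes: bool


@dataclass
class FidelityReport:
    results: dict[str, list[FeatureTestResult]]
    metric_labels: dict[str, str]
    ura_label: str
    proportionality_coefficient: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "column": r.column, "statistic": r.statistic,
             "p_value": r.p_value, "passes": r.passes}
            for m, lst in self.results.items() for r in lst
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        for m, lst in self.results.items():
            n_pass = sum(r.passes for r in lst)
            lines.append(f"{m}: {n_pass}/{len(lst)} features pass -> "
                         f"{self.metric_labels[m]}")
        lines.append(f"URA total: {self.ura_label} "
                     f"(M = {self.proportionality_coefficient:.2f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def welch_t_pvalue(real_col, synth_col) -> tuple[float, float]:
    """Welch t statistic and two-sided p (Welch–Satterthwaite df)."""
    a = np.asarray(real_col, dtype=float)
    b = np.asarray(synth_col, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t_pvalue: need at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 0.0, 1.0 if a.mean() == b.mean() else 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def chi_square_pvalue(real_counts, synth_counts) -> tuple[float, float]:
    """chi2 = sum (S - R)^2 / R, p from chi2 with (k - 1) df."""
    R = np.asarray(real_counts, dtype=float)
    S = np.asarray(synth_counts, dtype=float)
    if R.shape != S.shape or R.size < 2:
        raise ValidationError("chi_square_pvalue: need equal-length vectors (>= 2)")
    if np.any(R <= 0):
        bad = int(np.argmin(R))
        raise ValidationError(f"chi_square_pvalue: zero real count in category {bad}")
    chi2 = float(np.sum((S - R) ** 2 / R))
    p = float(sps.chi2.sf(chi2, df=R.size - 1))
    return chi2, p


def wasserstein_distance(real_col, synth_col, normalize: bool = True) -> float:
    """1-Wasserstein distance between empirical CDFs; both samples are
    min-max scaled by the *real* column's range when ``normalize``."""
    a = np.asarray(real_col, dtype=float)
    b = np.asarray(synth_col, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("wasserstein_distance: empty sample")
    if normalize:
        lo, hi = a.min(), a.max()
        if hi == lo:
            raise ValidationError("wasserstein_distance: degenerate real range")
        a = (a - lo) / (hi - lo)
        b = (b - lo) / (hi - lo)
    return float(sps.wasserstein_distance(a, b))


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def label_from_counts(n_pass: int, n_total: int) -> str:
    """Excellent above 50% of features passing, Poor at zero, else Good."""
    if not 0 <= n_pass <= n_total or n_total < 1:
        raise ValidationError("label_from_counts: bad counts")
    if n_pass == 0:
        return POOR
    if n_pass / n_total > 0.5:
        return EXCELLENT
    return GOOD


def ura_total(labels) -> str:
    """Weighted (1/n), half-up-rounded aggregate of per-metric labels."""
    labels = list(labels)
    if not labels:
        raise ValidationError("ura_total: empty label list")
    try:
        scores = [_LABEL_SCORE[l] for l in labels]
    except KeyError as exc:
        raise ValidationError(f"ura_total: unknown label {exc}") from exc
    M = 1.0 / len(labels)
    total = sum(s * M for s in scores)
    rounded = int(np.floor(total + 0.5))          # half-up
    rounded = min(max(rounded, 1), 3)
    return _SCORE_LABEL[rounded]


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def fidelity_report(real: Table, synth: Table,
                    schema: TableSchema | None = None,
                    p_threshold: float = P_THRESHOLD,
                    w_threshold: float = WASSERSTEIN_THRESHOLD) -> FidelityReport:
    """t test and Wasserstein distance per numeric feature column, chi-square
    on the outcome class counts, verbal labels and the URA total."""
    if schema is None:
        schema = real.schema
    feats = [c.name for c in schema.feature_columns]
    oc = schema.outcome_column.name

    t_results, w_results = [], []
    for name in feats:
        a, b = real.column(name), synth.column(name)
        t, p = welch_t_pvalue(a, b)
        t_results.append(FeatureTestResult(name, "t_test", t, p, p > p_threshold))
        d = wasserstein_distance(a, b, normalize=True)
        w_results.append(FeatureTestResult(name, "wasserstein", d, None,
                                           d < w_threshold))
    rc = np.array([np.sum(real.column(oc) == 0), np.sum(real.column(oc) == 1)])
    sc = np.array([np.sum(synth.column(oc) == 0), np.sum(synth.column(oc) == 1)])
    chi2, p = chi_square_pvalue(rc, sc)
    c_results = [FeatureTestResult(oc, "chi_square", chi2, p, p > p_threshold)]

    results = {"t_test": t_results, "chi_square": c_results,
               "wasserstein": w_results}
    metric_labels = {
        m: label_from_counts(sum(r.passes for r in lst), len(lst))
        for m, lst in results.items()
    }
    return FidelityReport(
        results=results,
        metric_labels=metric_labels,
        ura_label=ura_total(metric_labels.values()),
        proportionality_coefficient=1.0 / len(results),
    )
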