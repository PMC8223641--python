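"""Cohort-comparison descriptive statistics.

Chi-square tests for categorical variables (uncorrected Pearson) and
Wilcoxon-Mann-Whitney tests for continuous ones, between cohort pairs:
demographics are compared between every pair of cohorts, diet and
medication use between each patient cohort and healthy controls.
BH-FDR is applied across the whole comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_adjust

EXACT_WMW_MAX_N = 25


class DescriptivesError(ValueError):
    """Raised for invalid descriptive-statistics inputs."""


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction. Returns (statistic, df, p)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DescriptivesError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise DescriptivesError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DescriptivesError("zero marginal total; expected counts undefined")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def wmw_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test with midrank ties.

    Exact p for combined n <= 25 without ties, otherwise the normal
    approximation with tie correction (no continuity correction).
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DescriptivesError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size + y.size <= EXACT_WMW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ComparisonPlan:
    """One variable to compare: name, kind, and pairing scheme.

    kind: 'categorical' or 'continuous'; scheme: 'pairwise' (every
    cohort pair) or 'vs_hc' (each non-HC cohort against HC).
    """

    variable: str
    kind: str
    scheme: str = "vs_hc"


DEFAULT_PLAN = (
    ComparisonPlan("age", "continuous", "pairwise"),
    ComparisonPlan("sex", "categorical", "pairwise"),
    ComparisonPlan("bmi", "continuous", "pairwise"),
    ComparisonPlan("smoking", "categorical", "pairwise"),
    ComparisonPlan("read_depth", "continuous", "pairwise"),
    ComparisonPlan("antihypertensives", "categorical", "vs_hc"),
    ComparisonPlan("antidiabetics", "categorical", "vs_hc"),
    ComparisonPlan("statins", "categorical", "vs_hc"),
    ComparisonPlan("kcal", "continuous", "vs_hc"),
)


def _pairs(cohorts, scheme, reference="HC"):
    if scheme == "pairwise":
        return [(a, b) for i, a in enumerate(cohorts)
                for b in cohorts[i + 1:]]
    if scheme == "vs_hc":
        return [(c, reference) for c in cohorts if c != reference]
    raise DescriptivesError(f"unknown pairing scheme {scheme!r}")


def compare_cohorts(metadata: pd.DataFrame,
                    intake: pd.DataFrame | None = None,
                    plan=DEFAULT_PLAN,
                    cohort_column: str = "cohort",
                    fdr_max: float = 0.05) -> pd.DataFrame:
    """Run the planned cohort comparisons and BH-adjust the table.

    Diet variables are looked up in ``intake`` (subjects x foods,
    treated as continuous, compared vs HC) when they are not metadata
    columns. Returns one row per variable x cohort pair.
    """
    cohorts = sorted(metadata[cohort_column].unique())
    rows = []
    for item in plan:
        if item.variable in metadata.columns:
            source = metadata[item.variable]
        elif intake is not None and item.variable in intake.columns:
            source = intake[item.variable].reindex(metadata.index)
        else:
            raise DescriptivesError(f"unknown variable {item.variable!r}")
        for a, b in _pairs(cohorts, item.scheme):
            xa = source[metadata[cohort_column] == a].dropna()
            xb = source[metadata[cohort_column] == b].dropna()
            if item.kind == "categorical":
                levels = sorted(pd.concat([xa, xb]).unique())
                counts = np.array([[int((xa == lv).sum()) for lv in levels],
                                   [int((xb == lv).sum()) for lv in levels]])
                counts = counts[:, counts.sum(axis=0) > 0]
                if counts.shape[1] < 2:
                    stat, p, test = np.nan, 1.0, "chi-square"
                else:
                    stat, _, p = chi_square_test(counts)
                    test = "chi-square"
            elif item.kind == "continuous":
                stat, p = wmw_test(xa.to_numpy(), xb.to_numpy())
                test = "WMW"
            else:
                raise DescriptivesError(f"unknown variable kind {item.kind!r}")
            rows.append({"variable": item.variable, "cohort_a": a,
                         "cohort_b": b, "test": test,
                         "mean_a": float(np.mean(xa)) if len(xa) else np.nan,
                         "mean_b": float(np.mean(xb)) if len(xb) else np.nan,
                         "statistic": stat, "p": p})
    out = pd.DataFrame(rows, columns=["variable", "cohort_a", "cohort_b",
                                      "test", "mean_a", "mean_b",
                                      "statistic", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_max
    else:
        out["fdr"] = []
        out["significant"] = []
    return out
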