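"""Clinical association battery for the identified subtypes.

Categorical characteristics vs subtype use the Pearson chi-square test,
with the Yates continuity correction applied exactly and only for 2x2
tables; ordinal/continuous characteristics (grade, node counts, marker
levels) use the Kruskal-Wallis test (Wilcoxon rank-sum for two groups);
survival differences use Kaplan-Meier curves compared by the two-sided
log-rank test. Missing values are excluded variable by variable before
testing, and all tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import DataError

__all__ = ["TestResult", "chi_square", "kruskal_wallis", "wilcoxon_rank_sum",
           "km_logrank", "association_battery", "contingency_table"]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    table_or_n: object = None
    degenerate: bool = False


def chi_square(table, yates_2x2: bool = True) -> TestResult:
    """Pearson chi-square on an r x c count table; Yates only when r = c = 2."""
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise DataError("contingency table must be at least 2x2")
    if (T < 0).any():
        raise DataError("counts must be nonnegative")
    rows, cols = T.sum(axis=1), T.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        which = "row" if (rows == 0).any() else "column"
        raise DataError(f"zero {which} marginal in contingency table")
    correct = yates_2x2 and T.shape == (2, 2)
    res = st.chi2_contingency(T, correction=correct)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="chi-square" + (" (Yates)" if correct else ""),
                      df=int(res.dof), table_or_n=T.astype(int))


def kruskal_wallis(values, groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across the groups; NA values dropped."""
    df = pd.DataFrame({"v": pd.to_numeric(pd.Series(values), errors="coerce"),
                       "g": pd.Series(groups).values}).dropna()
    samples = [sub["v"].to_numpy() for _, sub in df.groupby("g")]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise DataError("need >= 2 non-empty groups")
    sizes = [len(s) for s in samples]
    if df["v"].nunique() == 1:
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis",
                          df=len(samples) - 1, table_or_n=sizes, degenerate=True)
    stat, p = st.kruskal(*samples)
    return TestResult(statistic=float(stat), p_value=float(p), method="kruskal-wallis",
                      df=len(samples) - 1, table_or_n=sizes)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided rank-sum test, normal approximation with tie correction and
    continuity correction."""
    x = pd.to_numeric(pd.Series(x), errors="coerce").dropna().to_numpy()
    y = pd.to_numeric(pd.Series(y), errors="coerce").dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise DataError("both samples must be non-empty")
    res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                          use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="wilcoxon rank-sum", table_or_n=(len(x), len(y)))


def km_logrank(followup_days, event, groups):
    """Kaplan-Meier curves per group plus the two-sided log-rank test.

    Returns ``(curves, TestResult)`` where curves maps group -> step-function
    DataFrame (time, survival). With no events anywhere the test is
    degenerate and p = 1.
    """
    df = pd.DataFrame({"t": np.asarray(followup_days, dtype=float),
                       "e": np.asarray(event, dtype=int),
                       "g": np.asarray(groups)})
    if (df["t"] < 0).any():
        raise DataError("follow-up times must be nonnegative")
    if df["g"].nunique() < 2:
        raise DataError("need at least two groups")
    curves = {}
    for g, sub in df.groupby("g"):
        if len(sub) == 0:
            raise DataError(f"group {g} has no observations")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["t"], event_observed=sub["e"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.iloc[:, 0].to_numpy()})
    if df["e"].sum() == 0:
        return curves, TestResult(statistic=0.0, p_value=1.0, method="log-rank",
                                  df=df["g"].nunique() - 1, degenerate=True,
                                  table_or_n=df["g"].value_counts().to_dict())
    res = multivariate_logrank_test(df["t"], df["g"], df["e"])
    return curves, TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value),
                              method="log-rank", df=df["g"].nunique() - 1,
                              table_or_n=df["g"].value_counts().to_dict())


def contingency_table(labels, categories) -> np.ndarray:
    """Count table subtypes x categories with NA rows excluded."""
    df = pd.DataFrame({"l": np.asarray(labels), "c": pd.Series(categories).values})
    df = df[df["c"].notna() & (df["c"].astype(str) != "NA")]
    return pd.crosstab(df["l"], df["c"]).to_numpy()


# variable -> designated test
_KW_VARS = ("gleason", "positive_node_count", "psa")
_CHI_VARS = ("path_n", "path_t", "clin_t", "lymph_status")


def association_battery(labels, clinical: pd.DataFrame) -> dict[str, TestResult]:
    """The full association report for one subtype labeling.

    Grade, positive-node count and the PSA-like marker get Kruskal-Wallis;
    stage/nodal categoricals get chi-square (Yates if the resulting table is
    2x2); survival gets the log-rank test. Variables absent from the table
    are skipped; NA is excluded per variable.
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical):
        raise DataError("labels and clinical table differ in length")
    out: dict[str, TestResult] = {}
    uniq = np.unique(labels)
    if uniq.size < 2:
        for var in (*_KW_VARS, *_CHI_VARS, "survival"):
            out[var] = TestResult(statistic=0.0, p_value=1.0, method="degenerate",
                                  degenerate=True)
        return out
    for var in _KW_VARS:
        if var in clinical.columns:
            out[var] = kruskal_wallis(clinical[var], labels)
    for var in _CHI_VARS:
        if var in clinical.columns:
            table = contingency_table(labels, clinical[var])
            out[var] = chi_square(table)
    if {"followup_days", "event"} <= set(clinical.columns):
        _, out["survival"] = km_logrank(clinical["followup_days"], clinical["event"], labels)
    return out
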