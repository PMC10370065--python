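"""Reliability statistics for crowding-distance threshold tables.

A threshold table has one row per (observer, method, meridian, session)
with a positive ``threshold_deg``.  All statistics operate on log10
thresholds, the convention of the crowding literature: geometric means
and log SDs per method, test-retest SD (square root of the mean
two-point variance across observer x meridian pairs), the retest/test
threshold ratio, Pearson correlations of per-observer geometric means
across methods, Spearman rank correlations across every method x session
cell, a one-way ANOVA on method, pairwise variance-ratio F-tests, and
the intraclass correlation coefficient (two-way random effects,
absolute agreement; both the single-measurement ICC(2,1) and the
average-measurement ICC(2,k) are reported).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "ReliabilityReport",
    "geometric_summary",
    "test_retest_sd",
    "retest_ratio",
    "correlation_matrix",
    "method_anova",
    "variance_ratio_tests",
    "icc",
    "reliability_report",
]

KEY_COLUMNS = ["observer", "method", "meridian", "session"]


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KEY_COLUMNS + ["threshold_deg"] if c not in table.columns]
    if missing:
        raise ValueError(f"threshold table is missing columns: {missing}")
    if (table["threshold_deg"] <= 0).any() or table["threshold_deg"].isna().any():
        raise ValueError("thresholds must be positive")
    if table.duplicated(KEY_COLUMNS).any():
        dup = table[table.duplicated(KEY_COLUMNS)].iloc[0]
        raise ValueError(f"duplicate threshold row for key {tuple(dup[KEY_COLUMNS])}")
    out = table.copy()
    out["log10_threshold"] = np.log10(out["threshold_deg"])
    return out


def geometric_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method geometric mean (deg) and SD of log10 thresholds."""
    t = _validate(table)
    out = t.groupby("method")["log10_threshold"].agg(["mean", "std", "size"])
    return pd.DataFrame(
        {
            "geometric_mean_deg": 10.0 ** out["mean"],
            "sd_log10": out["std"],
            "n": out["size"],
        }
    )


def _paired_logs(table: pd.DataFrame, method: str) -> pd.DataFrame:
    t = _validate(table)
    rows = t[t["method"] == method]
    if rows.empty:
        raise ValueError(f"no rows for method {method!r}")
    wide = rows.pivot_table(
        index=["observer", "meridian"], columns="session", values="log10_threshold"
    )
    for col in ("test", "retest"):
        if col not in wide.columns or wide[col].isna().any():
            bad = (
                wide.index[wide[col].isna()].tolist()
                if col in wide.columns
                else wide.index.tolist()
            )
            raise ValueError(f"method {method!r} missing {col} session for keys {bad}")
    return wide


def test_retest_sd(table: pd.DataFrame, method: str) -> float:
    """Test-retest SD in log10 units for one method.

    For each observer x meridian pair, take the two-point sample variance
    (denominator n-1 = 1) of the test and retest log thresholds; report
    the square root of the mean variance across pairs.
    """
    wide = _paired_logs(table, method)
    variances = wide[["test", "retest"]].var(axis=1, ddof=1)
    return float(np.sqrt(variances.mean()))


def retest_ratio(table: pd.DataFrame, method: str) -> float:
    """Geometric mean of retest/test threshold ratios for one method."""
    wide = _paired_logs(table, method)
    return float(10.0 ** (wide["retest"] - wide["test"]).mean())


def correlation_matrix(table: pd.DataFrame, kind: str = "pearson") -> pd.DataFrame:
    """Cross-method correlation matrix of per-observer summary thresholds.

    ``kind='pearson'`` correlates each observer's log geometric mean over
    all four thresholds of a method (two meridians x test/retest) across
    methods.  ``kind='spearman'`` correlates the per-observer geometric
    mean across meridians for every (method, session) cell, yielding a
    matrix that includes cross-method test-vs-retest entries.  Cells
    with zero variance come back as NaN.
    """
    t = _validate(table)
    if t["observer"].nunique() < 3:
        raise ValueError("need at least 3 observers for a correlation matrix")
    if kind == "pearson":
        wide = t.pivot_table(index="observer", columns="method", values="log10_threshold")
        return wide.corr(method="pearson")
    if kind == "spearman":
        wide = t.pivot_table(
            index="observer", columns=["method", "session"], values="log10_threshold"
        )
        wide.columns = [f"{m}:{s}" for m, s in wide.columns]
        return wide.corr(method="spearman")
    raise ValueError(f"kind must be 'pearson' or 'spearman', got {kind!r}")


def method_anova(table: pd.DataFrame) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA on log10 thresholds grouped by method: (F, df, p)."""
    t = _validate(table)
    groups = [g["log10_threshold"].to_numpy() for _, g in t.groupby("method")]
    if len(groups) < 2:
        raise ValueError("need at least two methods for an ANOVA")
    for (name, g) in zip(t.groupby("method").groups, groups):
        if len(g) < 2:
            raise ValueError(f"method {name!r} has fewer than 2 rows")
    f, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(f), (df1, df2), float(p)


def variance_ratio_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sided F-tests for equal variance of log10 thresholds.

    F = s1^2/s2^2 with (n1-1, n2-1) degrees of freedom;
    p = 2 * min(P(F <= f), P(F >= f)).
    """
    t = _validate(table)
    methods = sorted(t["method"].unique())
    rows = []
    for m1, m2 in itertools.combinations(methods, 2):
        a = t.loc[t["method"] == m1, "log10_threshold"].to_numpy()
        b = t.loc[t["method"] == m2, "log10_threshold"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each method needs at least 2 rows for a variance ratio")
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        if v2 == 0.0:
            raise ValueError(f"method {m2!r} has zero variance; F undefined")
        f = v1 / v2
        df1, df2 = len(a) - 1, len(b) - 1
        p = 2.0 * min(sps.f.cdf(f, df1, df2), sps.f.sf(f, df1, df2))
        rows.append(
            {"method_1": m1, "method_2": m2, "F": f, "df1": df1, "df2": df2, "p": min(p, 1.0)}
        )
    return pd.DataFrame(rows)


def _observer_method_means(table: pd.DataFrame) -> pd.DataFrame:
    t = _validate(table)
    wide = t.pivot_table(index="observer", columns="method", values="log10_threshold")
    if wide.isna().any().any():
        raise ValueError("observer x method matrix is incomplete; ICC undefined")
    return wide


def icc(table: pd.DataFrame, form: str = "ICC2") -> float:
    """Intraclass correlation of per-observer log geometric means across methods.

    Two-way random effects, absolute agreement.  ``form='ICC2'`` is the
    single-measurement coefficient; ``form='ICC2k'`` the
    average-measurement variant.
    """
    # pingouin labels the absolute-agreement forms either ICC2/ICC2k or
    # ICC(A,1)/ICC(A,k) depending on version
    aliases = {"ICC2": ("ICC2", "ICC(A,1)"), "ICC2k": ("ICC2k", "ICC(A,k)")}
    if form not in aliases:
        raise ValueError(f"form must be 'ICC2' or 'ICC2k', got {form!r}")
    wide = _observer_method_means(table)
    long = wide.reset_index().melt(id_vars="observer", var_name="method", value_name="value")
    res = pg.intraclass_corr(
        data=long, targets="observer", raters="method", ratings="value"
    ).set_index("Type")
    for label in aliases[form]:
        if label in res.index:
            return float(res.loc[label, "ICC"])
    raise RuntimeError(f"pingouin did not report an absolute-agreement ICC: {res.index.tolist()}")


@dataclass
class ReliabilityReport:
    """Every reliability statistic for one threshold table."""

    geometric: pd.DataFrame
    test_retest_sd: dict[str, float]
    retest_ratio: dict[str, float]
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    variance_ratios: pd.DataFrame
    icc2: float
    icc2k: float

    def to_dict(self) -> dict:
        """JSON-serializable summary (NaN correlations become None)."""

        def df_to_dict(df: pd.DataFrame) -> dict:
            return {
                str(k): {str(c): (None if pd.isna(v) else float(v)) for c, v in row.items()}
                for k, row in df.to_dict(orient="index").items()
            }

        return {
            "geometric": df_to_dict(self.geometric),
            "test_retest_sd": self.test_retest_sd,
            "retest_ratio": self.retest_ratio,
            "pearson": df_to_dict(self.pearson),
            "spearman": df_to_dict(self.spearman),
            "anova": {"F": self.anova_f, "df": list(self.anova_df), "p": self.anova_p},
            "variance_ratios": self.variance_ratios.to_dict(orient="records"),
            "icc": {"ICC2": self.icc2, "ICC2k": self.icc2k},
        }


def reliability_report(table: pd.DataFrame) -> ReliabilityReport:
    """Compute the full set of reliability statistics for a table."""
    t = _validate(table)
    methods = sorted(t["method"].unique())
    f, df, p = method_anova(t)
    return ReliabilityReport(
        geometric=geometric_summary(t),
        test_retest_sd={m: test_retest_sd(t, m) for m in methods},
        retest_ratio={m: retest_ratio(t, m) for m in methods},
        pearson=correlation_matrix(t, "pearson"),
        spearman=correlation_matrix(t, "spearman"),
        anova_f=f,
        anova_df=df,
        anova_p=p,
        variance_ratios=variance_ratio_tests(t),
        icc2=icc(t, "ICC2"),
        icc2k=icc(t, "ICC2k"),
    )
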