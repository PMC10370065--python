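"""Reliability statistics against independent brute-force recomputations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crowdtrack import (
    correlation_matrix,
    geometric_summary,
    icc,
    method_anova,
    reliability_report,
    retest_ratio,
    simulate_threshold_table,
    variance_ratio_tests,
)
from crowdtrack import test_retest_sd as retest_sd  # noqa: E402  (pytest would collect the bare name)


def make_table(values):
    """Threshold table from {(observer, method, meridian, session): deg}."""
    rows = [
        {"observer": o, "method": m, "meridian": mer, "session": s, "threshold_deg": v}
        for (o, m, mer, s), v in values.items()
    ]
    return pd.DataFrame(rows)


def full_table(rng, n_obs=4, methods=("a", "b"), noise=0.0, base=None):
    values = {}
    for i in range(n_obs):
        level = base[i] if base is not None else rng.uniform(2.0, 5.0)
        for m in methods:
            for mer in (-10, 10):
                for s in ("test", "retest"):
                    values[(f"S{i}", m, mer, s)] = level * math.exp(
                        noise * rng.normal()
                    )
    return make_table(values)


# ---------- brute-force oracles (plain Python, no pandas/scipy) ----------


def brute_mean(xs):
    return sum(xs) / len(xs)


def brute_sd(xs):
    mu = brute_mean(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / (len(xs) - 1))


def brute_pearson(xs, ys):
    mx, my = brute_mean(xs), brute_mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(
        sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)
    )
    return num / den


def brute_ranks(xs):
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_anova(groups):
    grand = brute_mean([x for g in groups for x in g])
    ssb = sum(len(g) * (brute_mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - brute_mean(g)) ** 2 for x in g) for g in groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return (ssb / df1) / (ssw / df2), (df1, df2)


def brute_icc2(matrix):
    """ICC(2,1) from the two-way ANOVA mean squares (n targets x k raters)."""
    n, k = len(matrix), len(matrix[0])
    grand = brute_mean([x for row in matrix for x in row])
    row_means = [brute_mean(row) for row in matrix]
    col_means = [brute_mean([matrix[i][j] for i in range(n)]) for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (matrix[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ------------------------------ tests ------------------------------


class TestGeometricSummary:
    def test_two_point_geometric_mean(self):
        table = make_table(
            {("S0", "a", -10, "test"): 2.0, ("S1", "a", -10, "test"): 8.0}
        )
        out = geometric_summary(table)
        assert out.loc["a", "geometric_mean_deg"] == pytest.approx(4.0)

    def test_identical_thresholds_have_zero_sd(self):
        table = make_table(
            {(f"S{i}", "a", -10, "test"): 3.0 for i in range(4)}
        )
        assert geometric_summary(table).loc["a", "sd_log10"] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        table = full_table(rng, n_obs=1, methods=("a",), noise=0.3)  # 4 rows
        logs = [math.log10(v) for v in table["threshold_deg"]]
        out = geometric_summary(table)
        assert abs(out.loc["a", "geometric_mean_deg"] - 10 ** brute_mean(logs)) < 1e-12
        assert abs(out.loc["a", "sd_log10"] - brute_sd(logs)) < 1e-12

    def test_nonpositive_threshold_rejected(self):
        table = make_table({("S0", "a", -10, "test"): -1.0})
        with pytest.raises(ValueError):
            geometric_summary(table)


class TestTestRetestSd:
    def test_identical_sessions_give_zero(self):
        rng = np.random.default_rng(1)
        table = full_table(rng, n_obs=3, methods=("a",), noise=0.0)
        assert retest_sd(table, "a") == 0.0

    def test_two_point_variance_formula(self):
        table = make_table(
            {
                ("S0", "a", -10, "test"): 10**0.4,
                ("S0", "a", -10, "retest"): 10**0.6,
            }
        )
        assert retest_sd(table, "a") == pytest.approx(math.sqrt(0.02), abs=1e-12)

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(2)
        table = full_table(rng, n_obs=3, methods=("a",), noise=0.2)
        scaled = table.copy()
        scaled["threshold_deg"] *= 7.3
        assert retest_sd(scaled, "a") == pytest.approx(
            retest_sd(table, "a"), abs=1e-12
        )

    def test_missing_pair_names_key(self):
        table = make_table({("S0", "a", -10, "test"): 3.0})
        with pytest.raises(ValueError, match="retest"):
            retest_sd(table, "a")

    def test_default_simulated_sessions_bracket_human_band(self):
        """Threshold tables at default generator settings (including the
        practice effect) land in the 0.05-0.25 log-unit band that brackets
        human test-retest SDs (~0.14-0.18)."""
        table = simulate_threshold_table(np.random.default_rng(5), n_observers=8)
        for method in table["method"].unique():
            assert 0.05 < retest_sd(table, method) < 0.25


class TestRetestRatio:
    def test_identity_when_sessions_equal(self):
        rng = np.random.default_rng(3)
        table = full_table(rng, n_obs=3, methods=("a",))
        assert retest_ratio(table, "a") == pytest.approx(1.0)

    def test_constant_ratio_recovered(self):
        rng = np.random.default_rng(4)
        table = full_table(rng, n_obs=3, methods=("a",))
        mask = table["session"] == "retest"
        table.loc[mask, "threshold_deg"] *= 0.8
        assert retest_ratio(table, "a") == pytest.approx(0.8)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        table = full_table(rng, n_obs=3, methods=("a",), noise=0.2)
        logs = {
            (r.observer, r.meridian, r.session): math.log10(r.threshold_deg)
            for r in table.itertuples()
        }
        diffs = [
            logs[(o, m, "retest")] - logs[(o, m, "test")]
            for o in ("S0", "S1", "S2")
            for m in (-10, 10)
        ]
        assert abs(retest_ratio(table, "a") - 10 ** brute_mean(diffs)) < 1e-10


class TestCorrelations:
    def test_method_against_itself_is_one(self):
        rng = np.random.default_rng(6)
        table = full_table(rng, n_obs=5, methods=("a", "b"), noise=0.1)
        mat = correlation_matrix(table, "pearson")
        assert mat.loc["a", "a"] == pytest.approx(1.0)

    def test_shared_observer_effect_gives_high_correlations(self):
        rng = np.random.default_rng(7)
        base = [3.0 * 10 ** rng.normal(0, 0.2) for _ in range(10)]
        table = full_table(rng, n_obs=10, methods=("a", "b", "c"), noise=0.05 * math.log(10), base=base)
        mat = correlation_matrix(table, "pearson")
        off_diag = [
            mat.loc[m1, m2] for m1, m2 in itertools.combinations("abc", 2)
        ]
        assert all(r > 0.8 for r in off_diag)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        table = full_table(rng, n_obs=6, methods=("a", "b"), noise=0.2)
        transformed = table.copy()
        mask = transformed["method"] == "a"
        transformed.loc[mask, "threshold_deg"] **= 2  # monotone on positives
        a = correlation_matrix(table, "spearman")
        b = correlation_matrix(transformed, "spearman")
        pd.testing.assert_frame_equal(a, b, atol=1e-12, rtol=0)

    def test_spearman_matches_brute_force(self):
        rng = np.random.default_rng(9)
        table = full_table(rng, n_obs=6, methods=("a", "b"), noise=0.2)
        mat = correlation_matrix(table, "spearman")
        t = table.copy()
        t["log10"] = np.log10(t["threshold_deg"])
        cells = {}
        for m in ("a", "b"):
            for s in ("test", "retest"):
                sub = t[(t["method"] == m) & (t["session"] == s)]
                cells[f"{m}:{s}"] = [
                    brute_mean(sub[sub["observer"] == f"S{i}"]["log10"].tolist())
                    for i in range(6)
                ]
        for c1, c2 in itertools.combinations(cells, 2):
            expected = brute_pearson(brute_ranks(cells[c1]), brute_ranks(cells[c2]))
            assert abs(mat.loc[c1, c2] - expected) < 1e-10

    def test_too_few_observers_rejected(self):
        table = make_table(
            {("S0", "a", -10, "test"): 3.0, ("S1", "a", -10, "test"): 2.0}
        )
        with pytest.raises(ValueError):
            correlation_matrix(table)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        values = {}
        for m in ("a", "b", "c"):
            for i, v in enumerate((1.0, 2.0, 3.0)):
                values[(f"S{i}", m, -10, "test")] = v
        f, df, p = method_anova(make_table(values))
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # log thresholds {1,2,3} vs {4,5,6}: F = 13.5 with df (1, 4)
        values = {}
        for i, v in enumerate((1.0, 2.0, 3.0)):
            values[(f"S{i}", "a", -10, "test")] = 10.0**v
        for i, v in enumerate((4.0, 5.0, 6.0)):
            values[(f"S{i}", "b", -10, "test")] = 10.0**v
        f, df, p = method_anova(make_table(values))
        assert f == pytest.approx(13.5, abs=1e-9)
        assert df == (1, 4)

    def test_three_methods_have_two_between_df(self):
        rng = np.random.default_rng(10)
        table = full_table(rng, n_obs=3, methods=("a", "b", "c"), noise=0.1)
        _, df, _ = method_anova(table)
        assert df[0] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        table = full_table(rng, n_obs=2, methods=("a", "b"), noise=0.3)  # 8+8 rows? no: 2obs*2mer*2sess=8 per method
        f, df, _ = method_anova(table)
        t = table.copy()
        t["log10"] = np.log10(t["threshold_deg"])
        groups = [t[t["method"] == m]["log10"].tolist() for m in ("a", "b")]
        bf, bdf = brute_anova(groups)
        assert abs(f - bf) < 1e-10
        assert df == bdf

    def test_invariant_to_additive_log_shift(self):
        rng = np.random.default_rng(12)
        table = full_table(rng, n_obs=3, methods=("a", "b"), noise=0.2)
        shifted = table.copy()
        shifted["threshold_deg"] *= 10.0  # +1 in log10
        f1, _, _ = method_anova(table)
        f2, _, _ = method_anova(shifted)
        assert f1 == pytest.approx(f2, rel=1e-10)


class TestVarianceRatio:
    def test_sample_against_itself_is_unity(self):
        rng = np.random.default_rng(13)
        table = full_table(rng, n_obs=3, methods=("a",), noise=0.2)
        doubled = pd.concat(
            [table, table.assign(method="b")], ignore_index=True
        )
        out = variance_ratio_tests(doubled)
        assert out.iloc[0]["F"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_df_for_twelve_observer_design(self):
        table = simulate_threshold_table(np.random.default_rng(14), n_observers=12)
        out = variance_ratio_tests(table)
        assert (out["df1"] == 47).all() and (out["df2"] == 47).all()

    def test_known_variances_and_brute_force(self):
        values = {}
        for i, v in enumerate((-2.0, 0.0, 2.0)):  # variance 4 in log10
            values[(f"S{i}", "a", -10, "test")] = 10.0**v
        for i, v in enumerate((-1.0, 0.0, 1.0)):  # variance 1
            values[(f"S{i}", "b", -10, "test")] = 10.0**v
        out = variance_ratio_tests(make_table(values))
        assert out.iloc[0]["F"] == pytest.approx(4.0, abs=1e-12)

    def test_two_sided_p_for_f_below_one(self):
        rng = np.random.default_rng(15)
        table = simulate_threshold_table(rng, n_observers=6, methods=("a", "b"))
        out = variance_ratio_tests(table)
        f = out.iloc[0]["F"]
        from scipy import stats as sps

        expected = 2 * min(
            sps.f.cdf(f, out.iloc[0]["df1"], out.iloc[0]["df2"]),
            sps.f.sf(f, out.iloc[0]["df1"], out.iloc[0]["df2"]),
        )
        assert out.iloc[0]["p"] == pytest.approx(min(expected, 1.0), abs=1e-12)


class TestIcc:
    def test_identical_columns_give_one(self):
        rng = np.random.default_rng(16)
        base = [2.0, 3.0, 4.5, 2.8, 3.6]
        table = full_table(rng, n_obs=5, methods=("a", "b", "c"), base=base)
        assert icc(table) == pytest.approx(1.0)

    def test_independent_columns_give_near_zero(self):
        estimates = []
        for seed in range(40):
            rng = np.random.default_rng(200 + seed)
            table = full_table(
                rng, n_obs=8, methods=("a", "b", "c"), noise=0.0,
                base=[3.0] * 8,
            )
            # replace with independent noise per observer x method cell
            noise = rng.normal(0, 0.2, size=len(table))
            table["threshold_deg"] = 3.0 * 10.0 ** noise
            estimates.append(icc(table))
        assert abs(np.mean(estimates)) < 0.15

    def test_variance_components_recovered(self):
        """Observer SD 0.2 and residual SD 0.1 imply ICC ~ 0.8."""
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(500 + seed)
            rows = []
            for i in range(12):
                level = rng.normal(0.5, 0.2)
                for m in ("a", "b", "c"):
                    val = level + rng.normal(0, 0.1)
                    for mer in (-10, 10):
                        for s in ("test", "retest"):
                            rows.append(
                                {
                                    "observer": f"S{i}",
                                    "method": m,
                                    "meridian": mer,
                                    "session": s,
                                    "threshold_deg": 10.0**val,
                                }
                            )
            estimates.append(icc(pd.DataFrame(rows)))
        assert abs(np.mean(estimates) - 0.8) < 0.1

    def test_matches_brute_force_mean_squares(self):
        rng = np.random.default_rng(17)
        table = full_table(rng, n_obs=4, methods=("a", "b", "c"), noise=0.2)
        t = table.copy()
        t["log10"] = np.log10(t["threshold_deg"])
        matrix = [
            [
                brute_mean(
                    t[(t["observer"] == f"S{i}") & (t["method"] == m)]["log10"].tolist()
                )
                for m in ("a", "b", "c")
            ]
            for i in range(4)
        ]
        assert abs(icc(table) - brute_icc2(matrix)) < 1e-10

    def test_incomplete_matrix_rejected(self):
        table = make_table(
            {
                ("S0", "a", -10, "test"): 3.0,
                ("S0", "b", -10, "test"): 3.1,
                ("S1", "a", -10, "test"): 2.5,
            }
        )
        with pytest.raises(ValueError):
            icc(table)


class TestReliabilityReport:
    def test_report_is_complete_and_serializable(self):
        table = simulate_threshold_table(np.random.default_rng(18), n_observers=5)
        report = reliability_report(table)
        payload = report.to_dict()
        assert set(payload) == {
            "geometric",
            "test_retest_sd",
            "retest_ratio",
            "pearson",
            "spearman",
            "anova",
            "variance_ratios",
            "icc",
        }
        import json

        json.dumps(payload)
        assert -1.0 <= report.icc2 <= 1.0
        assert report.anova_f >= 0.0
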