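import itertools
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ventrimetry.simulate import (FOLLOWUP_DELTAS, TABLE1_MOMENTS,
                                  simulate_cohort, simulate_followup)
from ventrimetry.stats import (binormal_auc, delong_ci, empirical_auc,
                               group_anova, icc_absolute_single, pairwise_bh,
                               roc_screen, shunt_change_test, stepwise_logistic)

# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def icc_a1_bruteforce(x):
    """Independent variance-components computation of ICC(A,1), by loops."""
    n, k = x.shape
    grand = x.mean()
    msr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def _matrix(self, rng, n=12, bias=0.0, noise=0.5):
        truth = rng.normal(50, 10, n)
        r1 = truth + rng.normal(0, noise, n)
        r2 = truth + bias + rng.normal(0, noise, n)
        return np.column_stack([r1, r2])

    def test_duplicate_raters_icc_one(self, rng):
        x = self._matrix(rng, noise=0.0)
        x[:, 1] = x[:, 0]
        res = icc_absolute_single(x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_offset_penalized_below_one(self, rng):
        x = self._matrix(rng, bias=5.0, noise=0.0)
        res = icc_absolute_single(x)
        assert res.icc < 1.0

    def test_matches_bruteforce_oracle(self, rng):
        x = self._matrix(rng, n=6)
        res = icc_absolute_single(x)
        assert res.icc == pytest.approx(icc_a1_bruteforce(x), abs=1e-12)

    def test_matches_pingouin(self, rng):
        x = self._matrix(rng, n=15, bias=1.0, noise=2.0)
        res = icc_absolute_single(x)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile(["a", "b"], 15),
            "score": x.ravel()})
        ref = pg.intraclass_corr(long, "subject", "rater", "score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=0.01)
        assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=0.01)

    def test_ci_contains_estimate(self, rng):
        x = self._matrix(rng, noise=3.0)
        res = icc_absolute_single(x)
        assert res.ci95[0] <= res.icc <= res.ci95[1]
        assert res.icc <= 1.0

    def test_monotone_degradation_with_noise(self, rng):
        base = self._matrix(rng, n=40, noise=0.1)
        noisier = base.copy()
        noisier[:, 1] += rng.normal(0, 8.0, 40)
        assert icc_absolute_single(noisier).icc < icc_absolute_single(base).icc

    def test_constant_ratings_flagged(self):
        res = icc_absolute_single(np.full((8, 2), 3.0))
        assert res.flagged is not None
        assert math.isnan(res.icc)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="5 subjects"):
            icc_absolute_single(np.ones((3, 2)))


# ---------------------------------------------------------------------------
# ANOVA and pairwise BH
# ---------------------------------------------------------------------------


def bh_stepup_bruteforce(pvals):
    """Independent BH step-up: adjusted[i] = min over j>=i of p_(j) * m / (j+1)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * m / (rank + 1))
        adj[i] = running
    return adj


class TestGroupComparison:
    def test_two_balanced_groups_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 15)
        table = pd.DataFrame({"group": ["a"] * 15 + ["b"] * 15,
                              "SA": np.concatenate([a, b])})
        f, p_f = group_anova(table, "SA")
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-12)
        assert p_f == pytest.approx(p_t, rel=1e-12)

    def test_null_case_finite(self, rng):
        vals = rng.normal(10, 2, 40)
        table = pd.DataFrame({"group": ["a", "b"] * 20, "SA": vals})
        f, p = group_anova(table, "SA")
        assert np.isfinite(f) and 0 <= p <= 1

    def test_single_group_rejected(self):
        table = pd.DataFrame({"group": ["a"] * 5, "SA": range(5)})
        with pytest.raises(ValueError, match="2 groups"):
            group_anova(table, "SA")

    def test_table1_cohort_sa_significant(self):
        table = simulate_cohort(seed=0)
        _, p = group_anova(table, "SA")
        assert p < 0.0001

    def test_bh_matrix_matches_bruteforce(self):
        table = simulate_cohort(seed=1)
        mat = pairwise_bh(table, "EI")
        groups = list(mat.index)
        pairs = list(itertools.combinations(groups, 2))
        raw = np.array([sps.ttest_ind(
            table.loc[table.group == a, "EI"],
            table.loc[table.group == b, "EI"]).pvalue for a, b in pairs])
        expected = bh_stepup_bruteforce(raw)
        for (a, b), e in zip(pairs, expected):
            assert mat.loc[a, b] == pytest.approx(e, rel=1e-12)
            assert mat.loc[b, a] == pytest.approx(e, rel=1e-12)

    def test_bh_known_vector(self):
        # classic step-up example on (0.01 ... 0.06)
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        expected = bh_stepup_bruteforce(p)
        from statsmodels.stats.multitest import multipletests
        got = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        np.testing.assert_allclose(expected, [0.06, 0.06, 0.06, 0.06, 0.06, 0.06])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_bh_properties(self, pvals):
        p = np.array(pvals)
        adj = bh_stepup_bruteforce(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        r = roc_screen(scores, labels, "higher")
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.accuracy == 1.0 and r.ppv == 1.0 and r.npv == 1.0

    def test_null_scores_auc_half(self, rng):
        scores = rng.normal(0, 1, 4000)
        labels = rng.integers(0, 2, 4000).astype(bool)
        assert empirical_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_lower_direction_flips(self, rng):
        scores = rng.normal(0, 1, 100)
        labels = rng.integers(0, 2, 100).astype(bool)
        a = empirical_auc(scores, labels, "higher")
        b = empirical_auc(scores, labels, "lower")
        assert a + b == pytest.approx(1.0)

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=4,
                    max_size=40),
           st.lists(st.booleans(), min_size=4, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_mannwhitney_u(self, scores, labels):
        n = min(len(scores), len(labels))
        s = np.round(np.array(scores[:n]), 1)  # rounding induces ties
        y = np.array(labels[:n])
        if y.all() or not y.any():
            return
        u = sps.mannwhitneyu(s[y], s[~y], alternative="two-sided").statistic
        expected = u / (y.sum() * (~y).sum())
        assert empirical_auc(s, y) == pytest.approx(expected, abs=1e-12)

    def test_cutoff_matches_exhaustive_search(self, rng):
        # 8-point toy set: enumerate every threshold by brute force
        scores = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        labels = np.array([0, 0, 1, 0, 1, 1, 0, 1], dtype=bool)
        r = roc_screen(scores, labels, "higher")
        best = None
        for t in np.unique(scores):
            pred = scores >= t
            sens = (pred & labels).sum() / labels.sum()
            spec = (~pred & ~labels).sum() / (~labels).sum()
            key = ((1 - sens) ** 2 + (1 - spec) ** 2, -spec, -t)
            if best is None or key < best[0]:
                best = (key, t, sens, spec)
        assert r.cutoff == best[1]
        assert r.sensitivity == pytest.approx(best[2])
        assert r.specificity == pytest.approx(best[3])
        # AUC against direct pair counting
        pos, neg = scores[labels], scores[~labels]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
                 for p in pos for q in neg]
        assert r.auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_cutoff_within_range_and_direction(self):
        table = simulate_cohort(seed=2)
        labels = (table.group == "NPH").to_numpy()
        r = roc_screen(table.SA.to_numpy(), labels, "lower")
        assert table.SA.min() <= r.cutoff <= table.SA.max()
        # narrower angles favor NPH: NPH mean far below cutoff
        assert table.loc[labels, "SA"].mean() < r.cutoff

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_screen(np.arange(5.0), np.ones(5, dtype=bool), "higher")

    def test_delong_ci_contains_auc(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        labels = np.repeat([False, True], 40)
        auc, (lo, hi) = delong_ci(scores, labels)
        assert 0 <= lo <= auc <= hi <= 1

    def test_delong_ci_shrinks_with_n(self, rng):
        widths = []
        for n in (30, 3000):
            scores = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
            labels = np.repeat([False, True], n)
            _, (lo, hi) = delong_ci(scores, labels)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestBinormalAuc:
    def test_equal_distributions_half(self):
        assert binormal_auc(10, 2, 10, 2) == 0.5

    def test_infinite_separation(self):
        assert binormal_auc(0, 1, 1e9, 1, "lower") == pytest.approx(1.0)

    def test_degenerate_zero_sd(self):
        assert binormal_auc(1, 0, 2, 0, "lower") == 1.0
        assert binormal_auc(2, 0, 2, 0, "lower") == 0.5

    def test_table1_hc_vs_nph_sa(self):
        # closed form on the canonical SA moments
        expected = sps.norm.cdf((75.7 - 25.0) / math.hypot(13.1, 9.74))
        assert binormal_auc(25.0, 9.74, 75.7, 13.1, "lower") == pytest.approx(expected)
        assert expected > 0.98

    def test_empirical_converges_to_binormal(self, rng):
        n = 100_000
        pos = rng.normal(25.0, 9.74, n)
        neg = rng.normal(75.7, 13.1, n)
        scores = np.concatenate([pos, neg])
        labels = np.repeat([True, False], n)
        emp = empirical_auc(scores, labels, "lower")
        assert emp == pytest.approx(binormal_auc(25.0, 9.74, 75.7, 13.1, "lower"),
                                    abs=0.005)


# ---------------------------------------------------------------------------
# Stepwise logistic and follow-up testing
# ---------------------------------------------------------------------------


class TestStepwise:
    def test_sa_retained_in_majority_of_replicates(self):
        kept = sum("SA" in stepwise_logistic(simulate_cohort(seed=s)).selected
                   for s in range(15))
        assert kept >= 12

    def test_reports_table_layout_aucs(self):
        sw = stepwise_logistic(simulate_cohort(seed=3))
        assert set(sw.model_aucs) == {"EI", "CA", "SA", "SA + EI", "SA + CA",
                                      "EI + CA + SA"}
        for auc, (lo, hi) in sw.model_aucs.values():
            assert 0 <= lo <= auc <= hi <= 1

    def test_single_candidate(self):
        table = simulate_cohort(seed=4)
        sw = stepwise_logistic(table, candidates=("SA",))
        assert sw.selected in ([], ["SA"])
        assert sw.selected == ["SA"]  # SA is strongly predictive

    def test_noise_candidate_dropped(self, rng):
        table = simulate_cohort(seed=5).copy()
        table["NOISE"] = rng.normal(0, 1, len(table))
        sw = stepwise_logistic(table, candidates=("SA", "NOISE"))
        assert "NOISE" not in sw.selected

    def test_trace_reproducible(self):
        table = simulate_cohort(seed=6)
        assert stepwise_logistic(table).trace == stepwise_logistic(table).trace

    def test_single_class_rejected(self):
        table = simulate_cohort(seed=0)
        table = table[table.group != "NPH"]
        with pytest.raises(ValueError, match="both classes"):
            stepwise_logistic(table)


class TestShuntChange:
    def _followup(self, seed):
        base = simulate_cohort(seed=seed)
        nph = base[base.group == "NPH"].reset_index(drop=True)
        return simulate_followup(nph, FOLLOWUP_DELTAS, seed=seed)

    def test_textbook_t_statistic(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        fu = pd.DataFrame({
            "arm": ["shunt"] * 3 + ["no_shunt"] * 3,
            "dEI": np.concatenate([a, b]),
            "dCA": np.concatenate([a, b]),
            "dSA": np.concatenate([a, b])})
        out = shunt_change_test(fu)
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        expected_t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        row = out[out.measure == "SA"].iloc[0]
        assert row.t == pytest.approx(expected_t, rel=1e-12)

    def test_null_arms_not_significant(self, rng):
        d = rng.normal(0, 1, 20)
        fu = pd.DataFrame({"arm": ["shunt"] * 10 + ["no_shunt"] * 10,
                           "dEI": d, "dCA": d[::-1], "dSA": rng.normal(0, 1, 20)})
        out = shunt_change_test(fu)
        assert (out.p > 0.001).all()

    def test_table3_power_majority(self):
        # deltas from the canonical parameters at n=6 vs 5: dSA significant
        # in the majority of replicates
        hits = 0
        reps = 40
        for s in range(reps):
            out = shunt_change_test(self._followup(s))
            hits += out.loc[out.measure == "SA", "p"].iloc[0] < 0.05
        assert hits > reps / 2

    def test_output_mirrors_arm_layout(self):
        out = shunt_change_test(self._followup(0))
        assert list(out.measure) == ["EI", "CA", "SA"]
        assert {"mean_shunt", "sd_shunt", "mean_no_shunt", "sd_no_shunt",
                "t", "p"} <= set(out.columns)

    def test_empty_arm_rejected(self):
        fu = self._followup(0)
        fu = fu[fu.arm == "shunt"]
        with pytest.raises(ValueError, match="two arms"):
            shunt_change_test(fu)
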