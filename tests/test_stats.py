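"""Cohort statistics: permutation tests, effect sizes, ROC, multi-group."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from neohfa.stats import (
    StatsError,
    games_howell,
    hedges_g,
    kruskal_wallis,
    permutation_test,
    roc_youden,
    run_study,
    welch_anova,
    wilson_interval,
)
from neohfa.synthetic import generate_cohort, study_cohort_spec, two_group_spec


class TestPermutationTest:
    def test_null_identity_split_gives_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [4.0, 3.0, 2.0, 1.0]
        res = permutation_test(x, y, n_resamples=2000, seed=0)
        assert res.p_value > 0.95

    def test_matches_exhaustive_enumeration(self):
        x, y = [1.0, 2.0], [10.0, 11.0]
        # brute force over all C(4,2)=6 label splits
        pooled = np.array(x + y)
        obs = abs(np.mean(x) - np.mean(y))
        stats = []
        for idx in itertools.combinations(range(4), 2):
            a = pooled[list(idx)]
            b = np.delete(pooled, list(idx))
            stats.append(abs(a.mean() - b.mean()))
        exact_p = np.mean([s >= obs - 1e-12 for s in stats])
        res = permutation_test(x, y, n_resamples=20_000, seed=1)
        se = np.sqrt(exact_p * (1 - exact_p) / 20_000)
        assert abs(res.p_value - exact_p) <= 3 * se + 1e-4

    def test_agrees_with_scipy_oracle(self, rng):
        x = rng.normal(0.3, 1.0, 15)
        y = rng.normal(0.0, 1.2, 12)
        res = permutation_test(x, y, n_resamples=20_000, seed=2)
        ref = sps.permutation_test(
            (x, y),
            lambda a, b, axis=-1: np.abs(a.mean(axis=axis) - b.mean(axis=axis)),
            permutation_type="independent", alternative="greater",
            n_resamples=20_000, rng=np.random.default_rng(3),
        )
        assert abs(res.p_value - ref.pvalue) < 0.02

    def test_seed_determinism_and_p_floor(self):
        x, y = [0.0, 0.1, 0.2], [10.0, 10.1, 10.2]
        r1 = permutation_test(x, y, n_resamples=999, seed=5)
        r2 = permutation_test(x, y, n_resamples=999, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1.0 / 1000.0  # add-one estimator floor

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            permutation_test([1.0], [2.0, 3.0])

    def test_type_one_error_calibrated(self):
        """Under the exchangeable null, P(p <= .05) stays near .05."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for i in range(n_rep):
            x = rng.normal(size=10)
            y = rng.normal(size=8)
            res = permutation_test(
                x, y, n_resamples=499, seed=int(rng.integers(2**31 - 1)),
                compute_effect_size=False,
            )
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestHedgesG:
    def test_equal_means_give_zero(self):
        x = [1.0, 2.0, 3.0]
        assert hedges_g(x, x) == 0.0

    def test_closed_form_unit_effect(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        x = (x - x.mean()) / x.std(ddof=1) + 1.0
        y = (y - y.mean()) / y.std(ddof=1)
        assert hedges_g(x, y) == pytest.approx(1.0 - 3.0 / 71.0)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(1, 1, 12), rng.normal(0, 2, 9)
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x))

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1.5, 15)
        ref = pingouin.compute_effsize(x, y, eftype="hedges")
        assert hedges_g(x, y) == pytest.approx(ref, abs=1e-9)  # classic J
        assert hedges_g(x, y, correction="exact") == pytest.approx(ref, abs=5e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            hedges_g([1.0, 1.0], [1.0, 1.0])


class TestWilsonInterval:
    @pytest.mark.parametrize(
        "s,n,lo,hi",
        [
            (8, 8, 0.6756, 1.0),
            (34, 47, 0.5824, 0.8306),
            (12, 16, 0.5050, 0.8982),
            (10, 11, 0.6226, 0.9838),
        ],
    )
    def test_reference_count_pairs(self, s, n, lo, hi):
        got = wilson_interval(s, n)
        assert got[0] == pytest.approx(lo, abs=5e-5)
        assert got[1] == pytest.approx(hi, abs=5e-5)

    def test_zero_successes_lower_bound_zero(self):
        assert wilson_interval(0, 12)[0] == 0.0

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(3, 10), (45, 60), (1, 50)]:
            ref = proportion_confint(s, n, method="wilson")
            got = wilson_interval(s, n, z=float(sps.norm.ppf(0.975)))
            assert got == pytest.approx(ref, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(1, 200), frac=st.floats(0.0, 1.0))
    def test_interval_contains_point_estimate(self, n, frac):
        s = int(round(frac * n))
        lo, hi = wilson_interval(s, n)
        assert 0.0 <= lo <= s / n <= hi <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            wilson_interval(1, 0)
        with pytest.raises(StatsError):
            wilson_interval(5, 4)


def _brute_force_youden(rates, labels):
    rates = np.asarray(rates, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(rates)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = None
    for thr in cands:
        calls = rates >= thr
        sens = (calls & labels).sum() / labels.sum()
        spec = (~calls & ~labels).sum() / (~labels).sum()
        if best is None or sens + spec - 1 > best[0] + 1e-12:
            best = (sens + spec - 1, thr, sens, spec)
    return best


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([0.1, 0.2, 0.9, 1.0], [0, 0, 1, 1])
        assert res.sensitivity == res.specificity == res.auc == 1.0
        assert res.youden_j == 1.0
        assert 0.2 < res.threshold < 0.9

    def test_four_point_example(self):
        res = roc_youden(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]))
        assert res.auc == 1.0
        assert 2.0 < res.threshold < 3.0

    def test_brute_force_equivalence_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            rates = np.round(rng.gamma(1.5, 0.1, n), 3)
            labels = np.zeros(n, bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            res = roc_youden(rates, labels)
            j, thr, sens, spec = _brute_force_youden(rates, labels)
            assert res.youden_j == pytest.approx(j)
            assert res.threshold == pytest.approx(thr)

    def test_auc_equals_mann_whitney_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        rates = rng.gamma(2.0, 0.1, 30)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        res = roc_youden(rates, labels)
        u = sps.mannwhitneyu(rates[labels], rates[~labels]).statistic
        assert res.auc == pytest.approx(u / (labels.sum() * (~labels).sum()))
        assert res.auc == pytest.approx(roc_auc_score(labels, rates))

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            roc_youden([1.0, 2.0], [1, 1])


class TestWelchAnovaAndGamesHowell:
    def test_two_group_reduction_to_squared_welch_t(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 2, 9)
        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_separated_groups_tiny_p(self):
        base = np.array([0.0, 0.1, -0.1, 0.05, -0.05])
        res = welch_anova([base, base + 100.0, base + 200.0])
        assert res.p_value < 1e-6

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.normal(0, 1, 10), rng.normal(0.5, 2, 14), rng.normal(1, 1.5, 8)]
        res = welch_anova(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [10, 14, 8]),
            }
        )
        ref = pingouin.welch_anova(dv="y", between="g", data=df)
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(1000):
            groups = [rng.normal(size=8), rng.normal(size=10), rng.normal(size=9)]
            rejections += welch_anova(groups).p_value <= 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_zero_variance_group_rejected(self):
        with pytest.raises(StatsError):
            welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])

    def test_games_howell_identical_groups_p_near_one(self, rng):
        g = rng.normal(size=12)
        out = games_howell([g, g + 1e-9, g - 1e-9])
        assert all(p > 0.99 for _, _, p in out)

    def test_games_howell_flags_only_separated_pair(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        c = rng.normal(10, 1, 10)  # 10 SDs away
        out = dict(((x, y), p) for x, y, p in games_howell([a, b, c], ["a", "b", "c"]))
        assert out[("a", "c")] < 0.001 and out[("b", "c")] < 0.001
        assert out[("a", "b")] > 0.2

    def test_games_howell_two_group_reduction(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2, 10)
        (_, _, p), = games_howell([a, b])
        ref = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert p == pytest.approx(ref, abs=1e-3)

    def test_agrees_with_pingouin_gameshowell(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.normal(0, 1, 10), rng.normal(1, 2, 12), rng.normal(0.2, 1.5, 9)]
        mine = [p for _, _, p in games_howell(groups)]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [10, 12, 9]),
            }
        )
        ref = pingouin.pairwise_gameshowell(dv="y", between="g", data=df)["pval"]
        np.testing.assert_allclose(mine, ref, atol=1e-6)


class TestKruskalWallis:
    def test_hand_computed_h_statistic(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(0.0273, abs=1e-3)

    def test_label_permutation_invariance(self, rng):
        g1, g2 = list(rng.normal(size=6)), list(rng.normal(size=7))
        assert kruskal_wallis([g1, g2]).statistic == pytest.approx(
            kruskal_wallis([g2, g1]).statistic
        )

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.gamma(2, 1, 8), rng.gamma(3, 1, 9)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.log(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_degenerate_input_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])


class TestRunStudy:
    def test_all_planned_comparisons_present(self):
        cohort = generate_cohort(study_cohort_spec(seed=3))
        report = run_study(cohort, seed=0)
        assert set(report) == {
            "seizure_vs_healthy", "etiology", "hypothermia_within_hie",
            "background_grade", "pne_vs_normal_dev", "term_vs_preterm",
        }
        assert all("skipped" not in block for block in report.values())
        sz = report["seizure_vs_healthy"]
        assert sz["n1"] == 47 and sz["n2"] == 8

    def test_identical_rates_give_null_results(self):
        cohort = generate_cohort(study_cohort_spec(seed=3))
        cohort["rate"] = 0.1
        report = run_study(cohort, seed=0)
        assert report["seizure_vs_healthy"]["p_value"] > 0.99
        # degenerate multi-group tests surface as skips, not crashes
        assert "skipped" in report["etiology"] or report["etiology"]["p_value"] > 0.5

    def test_missing_labels_skip_comparison(self):
        cohort = generate_cohort(two_group_spec("seizure", "healthy", seed=1))
        report = run_study(cohort, plan=("seizure_vs_healthy", "etiology"), seed=0)
        assert "p_value" in report["seizure_vs_healthy"]
        assert "skipped" in report["etiology"]

    def test_run_study_deterministic_under_seed(self):
        cohort = generate_cohort(study_cohort_spec(seed=3))
        r1 = run_study(cohort, seed=9)
        r2 = run_study(cohort, seed=9)
        assert r1 == r2
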