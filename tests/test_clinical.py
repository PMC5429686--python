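from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import netstrat as ns
from netstrat.errors import DataError


class TestChiSquare:
    """The three published 2x2 p-values reproduce only WITH the Yates
    correction and the 3x2 value only WITHOUT it, which jointly pins the
    Yates-for-2x2-only convention."""

    @pytest.mark.parametrize("table, yates, expected_p", [
        ([[145, 40], [107, 13]], True, 0.0229),   # nodal stage, subtype 1 vs 3
        ([[94, 26], [107, 13]], True, 0.0358),    # nodal stage, subtype 2 vs 3
        ([[41, 138], [26, 91], [13, 98]], False, 0.0469),  # lymph nodes, 3x2
        ([[145, 94, 107], [40, 26, 13]], False, 0.0361),   # nodal stage, 3 subtypes
    ])
    def test_published_contingency_pvalues(self, table, yates, expected_p):
        res = ns.chi_square(table, yates_2x2=yates)
        assert float(f"{res.p_value:.3g}") == expected_p

    def test_yates_only_applies_to_2x2(self):
        # on the 3x2 table the correction flag must be a no-op
        t = [[41, 138], [26, 91], [13, 98]]
        assert ns.chi_square(t, yates_2x2=True).p_value == \
            ns.chi_square(t, yates_2x2=False).p_value

    def test_proportional_table_gives_zero_statistic(self):
        res = ns.chi_square([[10, 20], [30, 60]], yates_2x2=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DataError, match="column"):
            ns.chi_square([[5, 0], [3, 0]])

    def test_yates_and_uncorrected_converge_at_scale(self):
        small = np.array([[8, 4], [3, 9]])
        big = small * 100
        gap_small = abs(ns.chi_square(small).p_value -
                        ns.chi_square(small, yates_2x2=False).p_value)
        gap_big = abs(ns.chi_square(big).p_value -
                      ns.chi_square(big, yates_2x2=False).p_value)
        assert gap_big < gap_small / 10


class TestKruskalWallis:
    def test_identical_rank_distributions_give_zero(self):
        values = [1, 2, 3, 1, 2, 3]
        groups = ["a", "a", "a", "b", "b", "b"]
        assert ns.kruskal_wallis(values, groups).statistic == pytest.approx(0.0)

    def test_matches_permutation_null_monte_carlo(self):
        # 10 per group with ties: large enough that the chi-square null is valid
        values = np.array([3.1, 2.2, 2.2, 5.0, 4.4, 4.4, 7.1, 6.0, 5.0, 3.1] * 3)
        values[10:20] += 0.9
        values[20:] += 1.8
        groups = np.repeat(["a", "b", "c"], 10)
        res = ns.kruskal_wallis(values, groups)
        rng = np.random.default_rng(1)
        stats = [st.kruskal(*(values[perm][groups == g] for g in "abc")).statistic
                 for perm in (rng.permutation(30) for _ in range(10000))]
        p_perm = np.mean(np.array(stats) >= res.statistic - 1e-12)
        assert abs(res.p_value - p_perm) < 0.01

    def test_two_group_h_equals_squared_standardized_rank_sum(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 10)
        values = np.concatenate([x, y])
        groups = ["x"] * 12 + ["y"] * 10
        H = ns.kruskal_wallis(values, groups).statistic
        p_norm = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=False).pvalue
        z = st.norm.isf(p_norm / 2)
        assert H == pytest.approx(z ** 2, rel=1e-10)

    def test_all_identical_values_degenerate(self):
        res = ns.kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_na_dropped_before_testing(self):
        res = ns.kruskal_wallis([1, 2, np.nan, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.table_or_n == [2, 3]


class TestWilcoxonRankSum:
    def test_identical_samples_high_p(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ns.wilcoxon_rank_sum(x, list(x)).p_value >= 0.99

    def test_separated_samples_tiny_p(self):
        assert ns.wilcoxon_rank_sum(range(10), range(100, 110)).p_value < 1e-3

    def test_close_to_exact_enumeration(self):
        x = np.array([1.2, 3.4, 2.2, 5.1, 0.7])
        y = np.array([2.9, 4.8, 3.9, 6.0, 5.5])
        res = ns.wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = st.rankdata(pooled)
        observed = ranks[:5].sum()
        null = [sum(ranks[list(c)]) for c in combinations(range(10), 5)]
        null = np.array(null)
        mean = null.mean()
        p_exact = np.mean(np.abs(null - mean) >= abs(observed - mean) - 1e-12)
        assert abs(res.p_value - p_exact) < 0.005


class TestKMLogrank:
    def test_no_events_degenerate(self):
        curves, res = ns.km_logrank([5, 6, 7, 8], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert res.degenerate and res.p_value == 1.0
        for c in curves.values():
            assert (c["survival"] == 1.0).all()

    def test_identical_groups_p_one(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        g = ["a"] * 3 + ["b"] * 3
        _, res = ns.km_logrank(t, e, g)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        """Worked product-limit/log-rank example.

        Group A: events at 1 and 3, censored at 5; group B: event at 2,
        censored at 4, event at 6. By hand: O_A = 2, E_A = 0.5 + 0.4 + 0.5
        = 1.4, Var = 0.25 + 0.24 + 0.25 = 0.74, so the log-rank statistic
        is 0.36/0.74 = 18/37.
        """
        curves, res = ns.km_logrank([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 0, 1],
                                    ["A", "A", "A", "B", "B", "B"])
        assert res.statistic == pytest.approx(18 / 37)
        assert res.p_value == pytest.approx(1 - st.chi2.cdf(18 / 37, df=1))
        a = dict(zip(curves["A"]["time"], curves["A"]["survival"]))
        assert a[1.0] == pytest.approx(2 / 3)
        assert a[3.0] == pytest.approx(1 / 3)
        b = dict(zip(curves["B"]["time"], curves["B"]["survival"]))
        assert b[2.0] == pytest.approx(2 / 3)
        assert b[6.0] == pytest.approx(0.0)

    def test_group_without_observations_rejected(self):
        with pytest.raises(DataError):
            ns.km_logrank([1, 2], [1, 1], ["a", "a"])


class TestAssociationBattery:
    def test_nodal_stage_from_reconstructed_patients(self):
        # expand the published subtype x N-stage counts into patient rows
        counts = {(1, "N0"): 145, (1, "N1"): 40, (2, "N0"): 94, (2, "N1"): 26,
                  (3, "N0"): 107, (3, "N1"): 13}
        labels, stage = [], []
        for (subtype, n), c in counts.items():
            labels += [subtype] * c
            stage += [n] * c
        table = ns.contingency_table(labels, stage)
        res = ns.chi_square(table)  # 3x2: no correction applies
        assert float(f"{res.p_value:.3g}") == 0.0361

    def test_null_clinical_table_rarely_significant(self):
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = rng.integers(0, 3, size=120)
            clin = ns.generate_clinical(labels, ns.ClinicalEffectSpec.null(3), seed=seed)
            battery = ns.association_battery(labels + 1, clin)
            pvals += [t.p_value for t in battery.values() if not t.degenerate]
        pvals = np.array(pvals)
        assert (pvals > 0.05).mean() >= 0.9

    def test_single_label_degenerates_without_crash(self):
        clin = ns.generate_clinical(np.zeros(30, dtype=int),
                                    ns.ClinicalEffectSpec.null(1), seed=0)
        battery = ns.association_battery(np.ones(30, dtype=int), clin)
        assert all(t.degenerate for t in battery.values())

    def test_invariant_to_patient_reordering(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, size=90)
        clin = ns.generate_clinical(labels, seed=5)
        perm = rng.permutation(90)
        b1 = ns.association_battery(labels, clin)
        b2 = ns.association_battery(labels[perm], clin.iloc[perm].reset_index(drop=True))
        for var in b1:
            assert b1[var].p_value == pytest.approx(b2[var].p_value)
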