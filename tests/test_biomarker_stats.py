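import numpy as np
import pytest
from scipy import stats as ss

from ncrpipe import (
    BehavioralRecord,
    SubjectResult,
    anova_one_way,
    anova_two_way,
    cognitive_quotient,
    neurocognitive_ratio,
    pairwise_roc,
    roc_analysis,
    stimulus_mean,
)
from ncrpipe.biomarker_stats import group_summary


class TestCognitiveQuotient:
    def test_group_mean_arithmetic(self):
        # controls' neutral-stimulus group means: 98.2 % at 0.9757 s
        assert cognitive_quotient(98.2, 0.9757) == pytest.approx(100.646, abs=5e-3)

    def test_unit_reaction_time_identity(self):
        assert cognitive_quotient(73.5, 1.0) == 73.5

    def test_zero_accuracy(self):
        assert cognitive_quotient(0.0, 1.3) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cognitive_quotient(50.0, 0.0)
        with pytest.raises(ValueError):
            cognitive_quotient(120.0, 1.0)


class TestNeurocognitiveRatio:
    def test_basic_arithmetic(self):
        r, ncr = neurocognitive_ratio(100.0, 0.30, 0.15)
        assert r == pytest.approx(2.0) and ncr == pytest.approx(200.0)

    def test_equal_efficiencies_identity(self):
        r, ncr = neurocognitive_ratio(87.3, 0.25, 0.25)
        assert r == 1.0 and ncr == pytest.approx(87.3)

    def test_zero_cq(self):
        assert neurocognitive_ratio(0.0, 0.4, 0.2)[1] == 0.0

    def test_scale_invariance(self, rng):
        for _ in range(20):
            cq, a, b, c = rng.uniform(0.1, 2.0, 4)
            base = neurocognitive_ratio(cq, a, b)[1]
            scaled = neurocognitive_ratio(cq, c * a, c * b)[1]
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_dm_efficiency_rejected(self):
        with pytest.raises(ValueError):
            neurocognitive_ratio(90.0, 0.3, 0.0)


class TestStimulusMean:
    def test_published_ncr_rows(self):
        # per-stimulus NCR means of the control group average to the
        # published across-stimulus value 209.89
        assert stimulus_mean((225.97, 226.84, 176.85)) == pytest.approx(209.89, abs=5e-3)

    def test_published_cq_row_rounds_to_94(self):
        mean = stimulus_mean({"N": 102.42, "C": 96.00, "I": 82.44})
        assert mean == pytest.approx(93.62, abs=5e-3)
        assert round(mean) == 94

    def test_constant_identity(self):
        assert stimulus_mean({"N": 3.3, "C": 3.3, "I": 3.3}) == pytest.approx(3.3)

    def test_missing_stimulus_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            stimulus_mean({"N": 1.0, "C": 2.0})


class TestAnovaOneWay:
    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.standard_normal(12), 0.5 + rng.standard_normal(15)
        f, p = anova_one_way(a, b)
        t, p_t = ss.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(p_t, abs=1e-12)

    def test_matches_scipy_three_groups(self, rng):
        groups = [rng.standard_normal(n) for n in (8, 11, 9)]
        f, p = anova_one_way(*groups)
        ref = ss.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_textbook_sums_of_squares(self):
        # hand computation: groups (1,2,3), (2,3,4), (4,5,6)
        # means 2,3,5; grand 10/3; SSB = 3*((2-10/3)^2+(3-10/3)^2+(5-10/3)^2) = 14
        # SSW = 6; F = (14/2)/(6/6) = 7; p = sf(7; 2, 6)
        f, p = anova_one_way([1, 2, 3], [2, 3, 4], [4, 5, 6])
        assert f == pytest.approx(7.0, abs=1e-12)
        assert p == pytest.approx(float(ss.f.sf(7.0, 2, 6)), abs=1e-12)

    def test_identical_groups_degenerate(self):
        with pytest.warns(UserWarning):
            f, p = anova_one_way([1.0, 1.0], [1.0, 1.0])
        assert f == 0.0 and p == 1.0

    def test_perfect_separation(self):
        with pytest.warns(UserWarning):
            f, p = anova_one_way([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(f) and p == 0.0


class TestAnovaTwoWay:
    @staticmethod
    def _simulate(rng, n_per_cell, group_shift=0.0):
        values, grp, stim = [], [], []
        for g in ("a", "b"):
            for st in ("N", "C", "I"):
                x = rng.standard_normal(n_per_cell)
                if g == "b":
                    x = x + group_shift
                values.extend(x)
                grp.extend([g] * n_per_cell)
                stim.extend([st] * n_per_cell)
        return values, grp, stim

    def test_balanced_equals_classical_decomposition(self, rng):
        # manual balanced two-way ANOVA as the oracle
        n = 6
        values, grp, stim = self._simulate(rng, n, group_shift=0.7)
        res = anova_two_way(values, grp, stim)

        y = np.asarray(values).reshape(2, 3, n)
        grand = y.mean()
        ss_a = 3 * n * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_b = 2 * n * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
        cell = y.mean(axis=2)
        ss_ab = n * (
            (cell - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + grand) ** 2
        ).sum()
        ss_e = ((y - cell[:, :, None]) ** 2).sum()
        df_e = 2 * 3 * (n - 1)
        f_a = (ss_a / 1) / (ss_e / df_e)
        f_b = (ss_b / 2) / (ss_e / df_e)
        f_ab = (ss_ab / 2) / (ss_e / df_e)
        assert res["group"][0] == pytest.approx(f_a, rel=1e-8)
        assert res["stimulus"][0] == pytest.approx(f_b, rel=1e-8)
        assert res["interaction"][0] == pytest.approx(f_ab, rel=1e-8)

    def test_group_shift_detected(self, rng):
        values, grp, stim = self._simulate(rng, 20, group_shift=1.5)
        res = anova_two_way(values, grp, stim)
        assert res["group"][1] < 1e-4

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            values, grp, stim = self._simulate(rng, 5)
            if anova_two_way(values, grp, stim)["group"][1] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            anova_two_way([1.0, 2.0, 3.0], ["a", "a", "b"], ["N", "C", "N"])


class TestRoc:
    def test_perfect_separation(self):
        rep = roc_analysis([1, 2, 3, 10, 11, 12], ["n"] * 3 + ["p"] * 3, "p")
        assert rep.auc == 100.0
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0
        assert rep.accuracy == 100.0

    def test_pairwise_counting_oracle(self):
        # negatives {0.1, 0.4}, positives {0.35, 0.8}: 3 of 4 pairs concordant
        rep = roc_analysis([0.1, 0.4, 0.35, 0.8], ["n", "n", "p", "p"], "p")
        assert rep.auc == pytest.approx(75.0)

    def test_all_tied_scores(self):
        rep = roc_analysis([1.0] * 6, ["n", "n", "n", "p", "p", "p"], "p")
        assert rep.auc == pytest.approx(50.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(40)
        labels = np.where(rng.random(40) < 0.4, "p", "n")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "p", "n"
        base = roc_analysis(scores, labels, "p")
        warped = roc_analysis(np.exp(2.0 * scores), labels, "p")
        assert warped.auc == pytest.approx(base.auc, abs=1e-9)
        assert warped.sensitivity == pytest.approx(base.sensitivity, abs=1e-9)

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(60)
        labels = np.where(rng.random(60) < 0.5, "p", "n")
        labels[:2] = ["p", "n"]
        rep = roc_analysis(scores, labels, "p")
        expected = 100.0 * roc_auc_score((labels == "p").astype(int), scores)
        assert rep.auc == pytest.approx(expected, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], ["p", "p"], "p")

    def test_youden_point_ties_prefer_sensitivity(self):
        # two thresholds reach J = 0.5; the lower one has higher sensitivity
        rep = roc_analysis([1, 2, 3, 4], ["n", "p", "n", "p"], "p")
        assert rep.sensitivity == 100.0


class TestPairwiseRoc:
    def test_two_groups_consistent_with_single(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 10), rng.normal(0, 1, 12)])
        groups = np.array(["a"] * 10 + ["b"] * 12)
        table = pairwise_roc(scores, groups)
        assert set(table) == {("a", "b")}
        direct = roc_analysis(scores, groups, "a")
        assert table[("a", "b")].auc == pytest.approx(direct.auc)

    def test_pair_count(self, rng):
        scores = rng.standard_normal(40)
        groups = np.repeat(["a", "b", "c", "d"], 10)
        assert len(pairwise_roc(scores, groups)) == 6

    def test_positive_class_is_higher_mean_group(self):
        scores = np.array([5.0, 6.0, 1.0, 2.0])
        groups = np.array(["hi", "hi", "lo", "lo"])
        rep = pairwise_roc(scores, groups)[("hi", "lo")]
        assert rep.positive_class == "hi"
        assert rep.auc == 100.0


class TestSubjectResult:
    def test_derived_fields_and_means(self):
        res = SubjectResult(
            subject_id="s",
            group="g",
            ge_cm={"N": 0.3, "C": 0.32, "I": 0.28},
            ge_dm={"N": 0.15, "C": 0.16, "I": 0.14},
            cq={"N": 100.0, "C": 95.0, "I": 80.0},
        )
        assert res.r["N"] == pytest.approx(2.0)
        assert res.ncr["N"] == pytest.approx(200.0)
        assert res.cq_bar == pytest.approx((100 + 95 + 80) / 3)
        assert res.ncr_bar == pytest.approx(np.mean([res.ncr[st] for st in "NCI"]))

    def test_group_summary_mean_sd(self):
        results = [
            SubjectResult(
                subject_id=f"s{k}",
                group="g",
                ge_cm={st: 0.3 + 0.01 * k for st in "NCI"},
                ge_dm={st: 0.2 for st in "NCI"},
                cq={st: 50.0 + k for st in "NCI"},
            )
            for k in range(4)
        ]
        table = group_summary(results, "cq")
        assert table.loc["g", "N_mean"] == pytest.approx(51.5)
        assert table.loc["g", "N_sd"] == pytest.approx(np.std([50, 51, 52, 53], ddof=1))


class TestBehavioralRecord:
    def test_validation(self):
        with pytest.raises(ValueError, match="missing"):
            BehavioralRecord("s", "g", acc={"N": 90.0}, rt={"N": 1.0})
        with pytest.raises(ValueError, match="positive"):
            BehavioralRecord(
                "s", "g",
                acc={st: 90.0 for st in "NCI"},
                rt={"N": 1.0, "C": -0.5, "I": 1.0},
            )
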