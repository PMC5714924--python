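"""Diagnostic-accuracy measures, DeLong comparison and the hierarchical
logistic analysis, each checked against an independent oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nsclcfinder.errors import ContractError, ValidationError
from nsclcfinder.stats import (
    ConfusionTable,
    accuracy_measures,
    confusion_table,
    delong_compare,
    describe_cohort,
    diagnostic_odds_ratio,
    hierarchical_logistic,
)

CASE_FINDING_TABLE = ConfusionTable(tp=1027, fp=51, fn=56, tn=219)
CONTROL_TABLE = ConfusionTable(tp=80, fp=231, fn=1003, tn=39)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_auc(scores, labels):
    """Concordant-pair count over all (positive, negative) pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def stratified_jackknife_var(scores, labels):
    """Delete-one-within-class jackknife variance of the AUC, recomputing the
    statistic by brute-force pair counting at every deletion."""
    scores = list(scores)
    labels = list(labels)
    var = 0.0
    for cls in (1, 0):
        idx = [i for i, y in enumerate(labels) if y == cls]
        thetas = []
        for i in idx:
            s = [x for j, x in enumerate(scores) if j != i]
            l = [y for j, y in enumerate(labels) if j != i]
            thetas.append(brute_force_auc(s, l))
        k = len(idx)
        mean = sum(thetas) / k
        var += (k - 1) / k * sum((t - mean) ** 2 for t in thetas)
    return var


# ---------------------------------------------------------------------------
# confusion table & measures
# ---------------------------------------------------------------------------

class TestConfusionTable:
    def test_counts_partition_cohort(self):
        pred = pd.Series({"a": "NSCLC", "b": "NSCLC", "c": "SCLC", "d": "NSCLC"})
        lab = pd.Series({"a": "NSCLC", "b": "NSCLC", "c": "SCLC", "d": "SCLC"})
        ct = confusion_table(pred, lab)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (2, 1, 0, 1)
        assert ct.total == 4

    def test_perfect_agreement_has_no_errors(self):
        pred = pd.Series({"a": "NSCLC", "b": "SCLC"})
        ct = confusion_table(pred, pred)
        assert ct.fp == ct.fn == 0

    def test_swapping_positive_class_transposes(self):
        pred = pd.Series({"a": "NSCLC", "b": "NSCLC", "c": "SCLC"})
        lab = pd.Series({"a": "NSCLC", "b": "SCLC", "c": "SCLC"})
        ct = confusion_table(pred, lab, positive_class="NSCLC")
        sw = confusion_table(pred, lab, positive_class="SCLC")
        assert (sw.tp, sw.fp, sw.fn, sw.tn) == (ct.tn, ct.fn, ct.fp, ct.tp)

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ContractError):
            confusion_table(pd.Series({"a": "NSCLC"}), pd.Series({"b": "NSCLC"}))


class TestAccuracyMeasures:
    def test_case_finding_table_headline_values(self):
        acc = accuracy_measures(CASE_FINDING_TABLE)
        assert acc.sensitivity.estimate == pytest.approx(0.948, abs=5e-4)
        assert acc.specificity.estimate == pytest.approx(0.811, abs=5e-4)
        assert acc.ppv.estimate == pytest.approx(0.953, abs=5e-4)
        assert acc.npv.estimate == pytest.approx(0.796, abs=5e-4)
        assert acc.accuracy.estimate == pytest.approx(0.921, abs=5e-4)
        assert acc.dor.dor == pytest.approx(78.8, abs=0.05)
        assert acc.auc.estimate == pytest.approx(0.88, abs=5e-3)

    def test_control_table_headline_values(self):
        acc = accuracy_measures(CONTROL_TABLE)
        assert acc.sensitivity.estimate == pytest.approx(0.074, abs=5e-4)
        assert acc.specificity.estimate == pytest.approx(0.144, abs=5e-4)
        assert acc.ppv.estimate == pytest.approx(0.257, abs=5e-4)
        assert acc.npv.estimate == pytest.approx(0.037, abs=5e-4)
        assert acc.accuracy.estimate == pytest.approx(0.088, abs=5e-4)
        assert acc.dor.dor == pytest.approx(0.01, abs=0.005)

    def test_perfect_classifier(self):
        acc = accuracy_measures(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        for m in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv, acc.accuracy):
            assert m.estimate == 1.0
        assert acc.auc.estimate == 1.0
        assert not acc.dor.defined  # zero cells, no correction enabled

    def test_cis_contain_their_point_estimates(self):
        acc = accuracy_measures(CASE_FINDING_TABLE)
        for m in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv,
                  acc.accuracy, acc.auc):
            assert m.ci_low <= m.estimate <= m.ci_high
        assert acc.dor.ci_low <= acc.dor.dor <= acc.dor.ci_high

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_accuracy_prevalence_identity(self, cells):
        tp, fp, fn, tn = cells
        acc = accuracy_measures(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
        prev = (tp + fn) / (tp + fp + fn + tn)
        assert acc.accuracy.estimate == pytest.approx(
            acc.sensitivity.estimate * prev + acc.specificity.estimate * (1 - prev)
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_dor_odds_identity(self, cells):
        tp, fp, fn, tn = cells
        acc = accuracy_measures(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
        se, sp = acc.sensitivity.estimate, acc.specificity.estimate
        assert acc.dor.dor == pytest.approx((se / (1 - se)) / ((1 - sp) / sp))


class TestDiagnosticOddsRatio:
    def test_haldane_correction_arithmetic(self):
        r = diagnostic_odds_ratio(
            ConfusionTable(tp=5, fp=0, fn=0, tn=5), zero_cell_correction="haldane"
        )
        assert r.dor == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))  # = 121
        assert r.correction_applied

    def test_zero_cell_without_correction_is_undefined(self):
        r = diagnostic_odds_ratio(ConfusionTable(tp=5, fp=0, fn=1, tn=5))
        assert not r.defined and r.reason

    def test_matches_direct_odds_ratio_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 200, size=4)
            r = diagnostic_odds_ratio(ConfusionTable(int(tp), int(fp), int(fn), int(tn)))
            assert r.dor == pytest.approx((tp * tn) / (fp * fn))


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

class TestDeLong:
    def test_identical_scores_give_p_one(self):
        y = [1, 1, 0, 0, 1, 0]
        s = [0.9, 0.7, 0.6, 0.2, 0.8, 0.4]
        r = delong_compare(s, s, y)
        assert r.auc_difference == 0.0
        assert r.chi_square == 0.0
        assert r.p_value == 1.0

    def test_auc_equals_brute_force_pair_counting_toy(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        r = delong_compare(s, s, y)
        assert r.auc_a == pytest.approx(brute_force_auc(s, y))  # 8/9

    def test_auc_equals_brute_force_on_random_scores(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(6, 21))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # rounding forces occasional ties
            r = delong_compare(s, s, y)
            assert r.auc_a == pytest.approx(brute_force_auc(s, y))

    def test_variance_matches_jackknife_oracle(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        r = delong_compare(s, s, y)
        jk = stratified_jackknife_var(s, y)
        assert r.var_a == pytest.approx(jk, rel=0.10)

    def test_auc_matches_trapezoidal_roc_area(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.random(40)
        r = delong_compare(s, s, y)
        assert r.auc_a == pytest.approx(roc_auc_score(y, s))

    def test_discriminating_vs_noise_scores_detected(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        good = np.where(rng.random(300) < 0.85, y, 1 - y).astype(float)
        noise = rng.random(300)
        r = delong_compare(good, noise, y)
        assert r.auc_a > 0.75 and abs(r.auc_b - 0.5) < 0.15
        assert r.p_value < 1e-4
        assert r.degrees_of_freedom == 1

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValidationError):
            delong_compare([0.1, 0.2], [0.3, 0.4], [1, 1])

    def test_binary_scores_agree_with_table_auc(self):
        # cross-module consistency: 0/1 scores <-> (Se+Sp)/2 on the induced table
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 400)
        pred = np.where(rng.random(400) < 0.8, y, 1 - y)
        r = delong_compare(pred.astype(float), pred.astype(float), y)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        acc = accuracy_measures(ConfusionTable(tp, fp, fn, tn))
        assert r.auc_a == pytest.approx(acc.auc.estimate)


# ---------------------------------------------------------------------------
# hierarchical logistic
# ---------------------------------------------------------------------------

class TestHierarchicalLogistic:
    def test_uninformative_covariate_gives_near_zero_r2(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = np.where(rng.random(n) < 0.8, "NSCLC", "SCLC")
        cov = pd.DataFrame({"noise": rng.normal(size=n)})
        alg = np.where(rng.random(n) < 0.9, y, np.where(y == "NSCLC", "SCLC", "NSCLC"))
        res = hierarchical_logistic(y, cov, alg)
        assert res.model1_pseudo_r2 == pytest.approx(0.0, abs=5e-3)
        assert res.delta_pseudo_r2 > 0.2

    def test_binary_covariate_matches_closed_form(self):
        # two covariate groups with success probabilities 0.9 / 0.1:
        # the one-covariate logistic is saturated, so its McFadden pseudo-R2
        # equals the closed form from the cell log-likelihoods
        n_group = 200
        y = ["NSCLC"] * 180 + ["SCLC"] * 20 + ["NSCLC"] * 20 + ["SCLC"] * 180
        x = [0.0] * n_group + [1.0] * n_group
        alg = ["NSCLC", "SCLC"] * n_group
        res = hierarchical_logistic(y, pd.DataFrame({"x": x}), alg, fit_interactions=False)

        p_bar = 0.5
        ll_null = 2 * n_group * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar))
        ll_sat = 2 * n_group * (0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert res.model1_pseudo_r2 == pytest.approx(1 - ll_sat / ll_null, abs=1e-6)

    def test_pure_noise_covariate_barely_moves_r2(self):
        rng = np.random.default_rng(1)
        n = 5000
        y = np.where(rng.random(n) < 0.8, "NSCLC", "SCLC")
        alg = np.where(rng.random(n) < 0.9, y, np.where(y == "NSCLC", "SCLC", "NSCLC"))
        x1 = rng.normal(size=n)
        base = hierarchical_logistic(
            y, pd.DataFrame({"x1": x1}), alg, fit_interactions=False
        )
        more = hierarchical_logistic(
            y, pd.DataFrame({"x1": x1, "noise": rng.normal(size=n)}),
            alg, fit_interactions=False,
        )
        assert abs(more.model2_pseudo_r2 - base.model2_pseudo_r2) < 0.01

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            hierarchical_logistic(
                ["NSCLC", "SCLC"] * 10,
                pd.DataFrame({"c": [1.0] * 20}),
                ["NSCLC", "SCLC"] * 10,
            )

    def test_separation_is_flagged_not_fatal(self):
        y = ["NSCLC"] * 10 + ["SCLC"] * 10
        cov = pd.DataFrame({"x": [1.0] * 10 + [0.0] * 10})  # perfectly separates
        res = hierarchical_logistic(y, cov, ["NSCLC", "SCLC"] * 10, fit_interactions=False)
        assert res.separation_flag
        assert 0.0 <= res.model1_pseudo_r2 <= 1.0


# ---------------------------------------------------------------------------
# cohort description
# ---------------------------------------------------------------------------

class TestDescribeCohort:
    def make(self):
        patients = pd.DataFrame({
            "patient_id": ["a", "b", "c"],
            "index_date": pd.to_datetime(["2015-01-01"] * 3),
            "age_at_index": [50.0, 70.0, 64.0],
            "gender": ["male", "female", "female"],
            "bmi": [25.0, 27.0, 30.0],
            "dci_score": [5, 7, 8],
            "cancer_stage": ["IV", "IV", "Limited"],
            "insurance": ["commercial"] * 3,
            "region": ["South", "West", "South"],
        })
        labels = pd.DataFrame({
            "patient_id": ["a", "b", "c"], "subtype": ["NSCLC", "NSCLC", "SCLC"]
        })
        return patients, labels

    def test_mean_and_median_age(self):
        table = describe_cohort(*self.make())
        age = table[(table.variable == "age")].set_index("statistic")
        assert age.loc["mean", "NSCLC"] == pytest.approx(60.0)
        assert age.loc["median", "NSCLC"] == pytest.approx(60.0)

    def test_subtype_percentages_sum_to_100(self):
        table = describe_cohort(*self.make())
        pct = table[(table.variable == "patients") & (table.statistic == "pct_of_total")]
        assert float(pct["NSCLC"].iloc[0] + pct["SCLC"].iloc[0]) == pytest.approx(100.0)

    def test_stage_levels_restricted_to_recognised_set(self):
        from nsclcfinder.claims import STAGES

        table = describe_cohort(*self.make())
        levels = set(table[table.variable == "cancer_stage"]["level"])
        assert levels <= set(STAGES)
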