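"""Cohort diagnostics vs independent enumeration / counting oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest

from binbat.diagnostics import (
    ConfusionMatrix,
    clamp_sige,
    classify_reactivity,
    cohort_report,
    exclude_nonresponders,
    mann_whitney_auc,
    matrix_from_rates,
    predictive_values,
    roc_and_youden,
    wilcoxon_rank_sum,
)
from binbat.events import PatientRecord
from binbat.exceptions import BinbatError, DataIntegrityError


# --- independent oracles ---------------------------------------------------

def exact_wilcoxon_p(x, y, alternative):
    """Exhaustive enumeration over all C(m+n, m) rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    combined = np.sort(np.concatenate([x, y]))
    m = len(x)
    obs = sum(np.searchsorted(combined, xi) + 1 for xi in x)  # rank sum of x
    stats = np.array([sum(c) + m
                      for c in itertools.combinations(range(len(combined)), m)])
    if alternative == "greater":
        return float(np.mean(stats >= obs))
    return float(np.mean(stats <= obs))


def pair_counting_auc(pos, neg):
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_best_j(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best = -2.0
    for c in cands:
        pred = scores >= c
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec - 1)
    return best


# --- tests -----------------------------------------------------------------

class TestWilcoxon:
    def test_textbook_example(self):
        """x={3,5,7} vs y={1,2,4}, one-sided greater: p = 2/20."""
        r = wilcoxon_rank_sum([3, 5, 7], [1, 2, 4], "greater")
        assert r.p == pytest.approx(0.10)
        assert r.method == "exact"

    def test_single_tied_pair(self):
        r = wilcoxon_rank_sum([1.0], [1.0], "greater")
        assert r.p == pytest.approx(1.0)
        assert r.method == "asymptotic"  # ties force the corrected approximation

    def test_empty_sample_rejected(self):
        with pytest.raises(BinbatError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_exact_p_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(7)
        for _ in range(60):
            m, n = rng.integers(2, 6), rng.integers(2, 6)
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            r = wilcoxon_rank_sum(x, y, alternative)
            assert r.method == "exact"
            assert r.p == pytest.approx(exact_wilcoxon_p(x, y, alternative), abs=1e-12)

    def test_power_and_size(self):
        """Planted shift is detected above alpha; null rejects at ~alpha."""
        rng = np.random.default_rng(8)
        reps = 400
        null = shifted = 0
        for _ in range(reps):
            x = rng.normal(size=13)
            y = rng.normal(size=11)
            null += wilcoxon_rank_sum(x, y, "greater").p <= 0.05
            shifted += wilcoxon_rank_sum(x + 1.0, y, "greater").p <= 0.05
        assert shifted / reps > 0.5
        assert 0.02 <= null / reps <= 0.09


class TestAuc:
    def test_perfect_separation(self):
        assert mann_whitney_auc([40, 60], [10, 20]) == 1.0

    def test_partial_overlap_four_pairs(self):
        assert mann_whitney_auc([10, 30], [20, 5]) == 0.75

    def test_identical_multisets_give_half(self):
        assert mann_whitney_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            pos = rng.integers(0, 8, size=rng.integers(1, 30)).astype(float)
            neg = rng.integers(0, 8, size=rng.integers(1, 30)).astype(float)
            assert mann_whitney_auc(pos, neg) == pytest.approx(
                pair_counting_auc(pos, neg), abs=1e-12)


class TestRocYouden:
    def test_separable_case(self):
        roc, cut, m = roc_and_youden([8, 6, 5, 2], [True, True, False, False])
        assert 5 < cut <= 6
        assert (m.tp, m.fn, m.tn, m.fp) == (2, 0, 2, 0)
        assert roc.auc == 1.0

    def test_anti_discriminating_marker_warns(self):
        with pytest.warns(UserWarning, match="orientation|discriminate"):
            roc, cut, m = roc_and_youden([1, 2, 3, 4], [True, True, False, False])
        assert np.isinf(cut)

    def test_youden_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = 20
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc, cut, m = roc_and_youden(scores, labels)
            pred = scores >= cut
            j = ((pred & labels).sum() / labels.sum()
                 + (~pred & ~labels).sum() / (~labels).sum() - 1)
            assert j == pytest.approx(brute_force_best_j(scores, labels), abs=1e-12)

    def test_tie_break_prefers_specificity(self):
        # two cutoffs reach J = 0.5; the higher one has fewer false positives
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [False, True, False, True]
        _, cut, m = roc_and_youden(scores, labels)
        assert cut > 3.0
        assert m.fp == 0

    def test_one_class_rejected(self):
        with pytest.raises(BinbatError):
            roc_and_youden([1, 2], [True, True])


class TestPredictiveValues:
    def test_bat_gluten_contingency(self):
        """Published pediatric BAT-gluten operating point: PPV 0.80, NPV 0.64."""
        pv = predictive_values(ConfusionMatrix(tp=8, fp=2, tn=9, fn=5))
        assert pv["ppv"][0] == pytest.approx(0.80, abs=0.005)
        assert pv["npv"][0] == pytest.approx(0.64, abs=0.005)

    def test_tri_a_19_contingency(self):
        """Published Tri a 19 operating point: PPV 1.00, NPV ~0.92."""
        pv = predictive_values(ConfusionMatrix(tp=12, fp=0, tn=11, fn=1))
        assert pv["ppv"][0] == 1.0
        assert pv["npv"][0] == pytest.approx(0.92, abs=0.005)

    def test_perfect_matrix(self):
        pv = predictive_values(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0))
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            assert pv[key][0] == 1.0

    def test_zero_denominator_reported_as_nan(self):
        pv = predictive_values(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(pv["ppv"][0])

    def test_ci_bounds_ordered_within_unit_interval(self):
        pv = predictive_values(ConfusionMatrix(tp=8, fp=2, tn=9, fn=5))
        for v, lo, hi in pv.values():
            assert 0.0 <= lo <= v <= hi <= 1.0

    def test_scaling_counts_narrows_cis_only(self):
        m1 = ConfusionMatrix(tp=8, fp=2, tn=9, fn=5)
        m5 = ConfusionMatrix(tp=40, fp=10, tn=45, fn=25)
        p1, p5 = predictive_values(m1), predictive_values(m5)
        for key in p1:
            assert p1[key][0] == pytest.approx(p5[key][0])
            assert (p5[key][2] - p5[key][1]) < (p1[key][2] - p1[key][1])


class TestMatrixFromRates:
    @pytest.mark.parametrize("sens,spec,ppv,npv", [
        (0.62, 0.82, 0.80, 0.64),   # BAT-gluten / BAT-wheat row
        (0.92, 1.00, 1.00, 0.92),   # sIgE Tri a 19 row
        (0.38, 1.00, 1.00, 0.58),   # sIgE wheat extract row
        (0.31, 1.00, 1.00, 0.55),   # sIgE gluten extract row
    ])
    def test_published_rows_reconstruct_printed_predictive_values(
            self, sens, spec, ppv, npv):
        """Printed sens/spec at 13/11 determine unique matrices whose
        PPV/NPV match the published table to printed precision."""
        m = matrix_from_rates(sens, spec, n_allergic=13, n_tolerant=11)
        pv = predictive_values(m)
        assert round(pv["ppv"][0], 2) == ppv
        assert round(pv["npv"][0], 2) == npv

    def test_ambiguous_rate_rejected(self):
        with pytest.raises(BinbatError):
            matrix_from_rates(0.5, 1.0, n_allergic=100, n_tolerant=10, decimals=1)


class TestClampAndClassify:
    @pytest.mark.parametrize("value,expected", [
        (0.02, 0.05), (250.0, 101.0), (50.0, 50.0), (0.1, 0.1), (100.0, 100.0)])
    def test_clamp_rule(self, value, expected):
        assert clamp_sige(value) == expected

    def test_clamp_rejects_negative(self):
        with pytest.raises(ValueError):
            clamp_sige(-1.0)

    @pytest.mark.parametrize("kind,value,label", [
        ("bat", 3.0, "negative"), ("bat", 40.0, "high"), ("bat", 20.0, "intermediate"),
        ("sige", 1.0, "intermediate"), ("sige", 0.1, "negative"), ("sige", 50.0, "high")])
    def test_default_boundaries(self, kind, value, label):
        rc = classify_reactivity("m", value, kind=kind)
        assert rc.label == label
        assert rc.boundaries[0] < rc.boundaries[1]

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            classify_reactivity("m", 1.0, boundaries=(5.0, 5.0))


class TestExcludeNonResponders:
    def _patients(self, n_allergic, n_tolerant):
        return ([PatientRecord(f"a{i}", "child", "allergic") for i in range(n_allergic)]
                + [PatientRecord(f"t{i}", "child", "tolerant") for i in range(n_tolerant)])

    def _activation(self, anti_ige):
        return pd.DataFrame([{"patient_id": pid, "condition": "anti_IgE",
                              "pct_cd63_pos": v} for pid, v in anti_ige.items()])

    def test_child_cohort_25_to_24(self):
        patients = self._patients(14, 11)
        anti = {p.patient_id: 60.0 for p in patients if p.status == "allergic"}
        anti["a0"] = 1.2  # the planted non-responder
        evaluable, log = exclude_nonresponders(patients, self._activation(anti))
        assert len(evaluable) == 24
        assert log[0]["patient_id"] == "a0"

    def test_adult_cohort_27_to_26(self):
        patients = self._patients(18, 9)
        anti = {p.patient_id: 45.0 for p in patients if p.status == "allergic"}
        anti["a7"] = 0.4
        evaluable, _ = exclude_nonresponders(patients, self._activation(anti))
        assert len(evaluable) == 26

    def test_no_nonresponders_unchanged(self):
        patients = self._patients(3, 2)
        anti = {f"a{i}": 50.0 for i in range(3)}
        evaluable, log = exclude_nonresponders(patients, self._activation(anti))
        assert len(evaluable) == 5 and log == []

    def test_tolerant_never_removed(self):
        patients = self._patients(1, 2)
        anti = {"a0": 50.0, "t0": 0.0, "t1": 0.0}
        evaluable, _ = exclude_nonresponders(patients, self._activation(anti))
        assert sum(p.status == "tolerant" for p in evaluable) == 2

    def test_missing_anti_ige_sample_names_patient(self):
        patients = self._patients(2, 0)
        anti = {"a0": 50.0}
        with pytest.raises(DataIntegrityError, match="a1"):
            exclude_nonresponders(patients, self._activation(anti))


class TestCohortReport:
    def _cohort_frame(self, rng, n_allergic=13, n_tolerant=11):
        status = ["allergic"] * n_allergic + ["tolerant"] * n_tolerant
        sep = np.where(np.array(status) == "allergic",
                       10 ** rng.normal(1.0, 0.5, len(status)),
                       10 ** rng.normal(-1.6, 0.4, len(status)))
        null = rng.normal(5.0, 2.0, len(status)).clip(0.0)
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(len(status))],
            "status": status,
            "sige_tri_a_19": sep,
            "bat_gluten": null,  # deliberately uninformative marker
        })

    def test_planted_separator_recovered(self, rng):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # null marker may anti-discriminate
            summaries, classes = cohort_report(self._cohort_frame(rng))
        by_marker = {s.marker: s for s in summaries}
        assert by_marker["sige_tri_a_19"].auc >= 0.9
        assert by_marker["sige_tri_a_19"].wilcoxon_p < 0.01
        assert set(classes["marker"]) == {"sige_tri_a_19", "bat_gluten"}

    def test_single_marker_single_row(self, rng):
        df = self._cohort_frame(rng).drop(columns="bat_gluten")
        summaries, _ = cohort_report(df)
        assert len(summaries) == 1

    def test_too_few_patients_per_class_rejected(self, rng):
        df = self._cohort_frame(rng, n_allergic=1, n_tolerant=5)
        with pytest.raises(BinbatError):
            cohort_report(df)

    def test_missing_values_marker_dropped_with_warning(self, rng):
        df = self._cohort_frame(rng)
        df.loc[0, "bat_gluten"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            summaries, _ = cohort_report(df)
        assert [s.marker for s in summaries] == ["sige_tri_a_19"]
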