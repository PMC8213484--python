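"""Trial averaging, t-tests, ROC/AUC — each checked against a brute-force
or closed-form oracle."""

import json
import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipvi import (
    accuracy_at_best_threshold,
    independent_t_test,
    roc_auc,
    run_group_comparison,
    subject_means,
    trial_average_samples,
    write_report,
)


class TestSubjectMeans:
    def test_equal_values_and_running_mean(self):
        out = subject_means({"a": [5.0] * 12, "b": list(range(1, 13))})
        by_id = {s.subject_id: s for s in out}
        assert by_id["a"].value == 5.0
        assert by_id["b"].value == 6.5
        assert by_id["b"].n_trials_averaged == 12

    def test_group_labels_attached(self):
        out = subject_means({"a": [1.0]}, groups={"a": "older"})
        assert out[0].group == "older"

    def test_empty_subject_is_error(self):
        with pytest.raises(ValueError):
            subject_means({"a": []})


class TestTrialAverages:
    def test_12_choose_3_gives_220(self):
        vals = np.arange(12.0)
        out = trial_average_samples(vals, 3)
        assert len(out) == 220

    def test_k1_returns_originals_and_kn_overall_mean(self):
        vals = [3.0, 1.0, 4.0, 1.5]
        np.testing.assert_array_equal(trial_average_samples(vals, 1), vals)
        out = trial_average_samples(vals, 4)
        assert len(out) == 1
        assert out[0] == pytest.approx(np.mean(vals))

    @pytest.mark.parametrize("n", range(1, 9))
    def test_count_equals_binomial_coefficient(self, n):
        vals = np.random.default_rng(n).normal(size=n)
        for k in range(1, n + 1):
            assert len(trial_average_samples(vals, k)) == math.comb(n, k)

    def test_mean_of_subset_means_is_overall_mean(self):
        vals = np.random.default_rng(0).normal(size=9)
        for k in (2, 3, 5):
            assert trial_average_samples(vals, k).mean() == pytest.approx(vals.mean())

    def test_lexicographic_order(self):
        vals = [10.0, 20.0, 40.0]
        out = trial_average_samples(vals, 2)
        np.testing.assert_allclose(out, [15.0, 25.0, 30.0])

    def test_bad_k(self):
        with pytest.raises(ValueError):
            trial_average_samples([1.0, 2.0], 3)
        with pytest.raises(ValueError):
            trial_average_samples([1.0, 2.0], 0)


def t_test_direct(a, b):
    """From-scratch pooled-variance Student's t and CDF-based p (oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p, df


class TestStudentT:
    def test_identical_samples(self):
        t, p, df = independent_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0) and df == 4

    def test_matches_direct_formula(self):
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        t, p, df = independent_t_test(a, b)
        t0, p0, df0 = t_test_direct(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)
        assert df == df0 == 8

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(1.0, size=10)
        t1, p1, _ = independent_t_test(a, b)
        t2, p2, _ = independent_t_test(a + 100.0, b + 100.0)
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            independent_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            independent_t_test([2.0, 2.0], [2.0, 2.0])


def auc_pair_counting(scores, labels):
    """Brute-force concordant/discordant/tie counting (oracle)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=30).astype(float)  # many ties
        labels = rng.integers(0, 2, size=30)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12
        )

    def test_label_flip_complements_exactly(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            1.0 - roc_auc(scores, 1 - labels), abs=1e-15
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


def accuracy_brute_force(scores, labels):
    """Exhaustive threshold/orientation enumeration (oracle)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cands = np.concatenate(([s.min() - 1], (np.unique(s)[:-1] + np.unique(s)[1:]) / 2,
                            [s.max() + 1]))
    best = 0.0
    for thr in cands:
        for pred in ((s > thr).astype(int), (s < thr).astype(int)):
            best = max(best, float(np.mean(pred == y)))
    return best


class TestBestThresholdAccuracy:
    def test_perfectly_separable(self):
        acc, thr = accuracy_at_best_threshold([1, 2, 8, 9], [0, 0, 1, 1])
        assert acc == 1.0
        assert 2 < thr < 8

    def test_one_of_each(self):
        acc, _ = accuracy_at_best_threshold([0.2, 0.9], [0, 1])
        assert acc == 1.0

    def test_random_labels_match_oracle_and_stay_near_chance(self):
        rng = np.random.default_rng(123)
        scores = rng.normal(size=1000)
        labels = np.repeat([0, 1], 500)
        rng.shuffle(labels)
        acc, _ = accuracy_at_best_threshold(scores, labels)
        assert acc == pytest.approx(accuracy_brute_force(scores, labels), abs=1e-12)
        assert acc <= 0.56

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle_on_small_tied_instances(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, size=20).astype(float)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        acc, _ = accuracy_at_best_threshold(scores, labels)
        assert acc == pytest.approx(accuracy_brute_force(scores, labels), abs=1e-12)


def _trial_table(values_by_subject, group_of, feature="ipvi"):
    rows = []
    for sid, vals in values_by_subject.items():
        for i, v in enumerate(vals):
            rows.append(
                {"subject_id": sid, "group": group_of[sid], "session": 1,
                 "trial": i + 1, feature: v,
                 "mv_ap": v * 10 if feature == "ipvi" else v}
            )
    return pd.DataFrame(rows)


class TestGroupComparison:
    def test_forced_separation(self):
        vals = {f"y{i}": list(np.linspace(0.1, 0.2, 4) + 0.005 * i) for i in range(4)}
        vals.update(
            {f"o{i}": list(np.linspace(0.8, 0.9, 4) + 0.005 * i) for i in range(4)}
        )
        groups = {s: ("older" if s.startswith("o") else "younger") for s in vals}
        rep = run_group_comparison(_trial_table(vals, groups), k_average=3)
        assert rep["group_comparison"]["ipvi"]["p"] < 0.05
        assert rep["classification"]["ipvi"]["auc"] == 1.0
        assert rep["classification"]["ipvi"]["accuracy"] == 1.0

    def test_duplicated_cohort_is_null(self):
        base = {f"s{i}": [0.5 + 0.01 * i + 0.001 * j for j in range(4)] for i in range(4)}
        vals = {}
        groups = {}
        for sid, v in base.items():
            vals[f"a_{sid}"], groups[f"a_{sid}"] = v, "younger"
            vals[f"b_{sid}"], groups[f"b_{sid}"] = v, "older"
        rep = run_group_comparison(_trial_table(vals, groups), k_average=2)
        assert rep["group_comparison"]["ipvi"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert rep["group_comparison"]["ipvi"]["p"] == pytest.approx(1.0)
        assert rep["classification"]["ipvi"]["auc"] == 0.5

    def test_report_regenerates_identically(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = {f"s{i}": list(rng.normal(0.8, 0.05, size=5)) for i in range(6)}
        groups = {s: ("older" if i % 2 else "younger") for i, s in enumerate(vals)}
        table = _trial_table(vals, groups)
        outs = []
        for run in ("r1", "r2"):
            rep = run_group_comparison(table, k_average=3)
            write_report(rep, tmp_path / run)
            outs.append((tmp_path / run / "report.json").read_bytes())
        assert outs[0] == outs[1]
        assert json.loads(outs[0])["classification"]["ipvi"]["n_samples"] == 60

    def test_one_group_rejected(self):
        vals = {"a": [1.0, 2.0], "b": [2.0, 3.0]}
        groups = {"a": "older", "b": "older"}
        with pytest.raises(ValueError, match="two groups"):
            run_group_comparison(_trial_table(vals, groups))

    def test_median_split_table_analysed_per_group(self):
        split = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["younger"] * 4 + ["older"] * 4,
                "mv_ap_larger_half": [6.0, 6.1, 6.2, 5.9, 8.8, 9.0, 8.7, 9.1],
                "mv_ap_smaller_half": [4.8, 4.9, 4.7, 5.0, 5.7, 5.9, 5.6, 5.8],
            }
        )
        vals = {f"s{i}": [0.8, 0.9] for i in range(8)}
        vals["s0"] = [0.7, 0.8]  # break zero variance
        vals["s4"] = [0.95, 0.97]
        groups = {f"s{i}": ("younger" if i < 4 else "older") for i in range(8)}
        rep = run_group_comparison(
            _trial_table(vals, groups), window_split_table=split, k_average=1
        )
        for grp in ("younger", "older"):
            d = rep["median_split"][grp]
            assert d["mv_ap_larger_half_mean"] > d["mv_ap_smaller_half_mean"]
            assert d["p"] < 0.05
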