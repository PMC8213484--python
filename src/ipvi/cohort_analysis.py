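"""Group-level statistics: trial averaging, t-tests, ROC/AUC classification.

Implements the study's statistical machinery for comparing two age groups
on per-trial features: per-subject 12-trial means compared by independent
Student's t-tests; per-subject window median splits by IPVI; and
single-feature threshold classification of 3-trial-average samples scored
by ROC AUC and best-threshold (resubstitution) accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class SubjectFeatureSample:
    """One subject's averaged feature value entering a group comparison."""

    subject_id: str
    group: str
    value: float
    n_trials_averaged: int

    def __post_init__(self) -> None:
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")


def subject_means(
    per_trial_values: Mapping[str, Sequence[float]],
    groups: Mapping[str, str] | None = None,
) -> list[SubjectFeatureSample]:
    """Arithmetic mean of each subject's trial values.

    ``per_trial_values`` maps subject id to its trial feature values;
    ``groups`` optionally maps subject id to group label.
    """
    out = []
    for sid in per_trial_values:
        vals = np.asarray(list(per_trial_values[sid]), dtype=float)
        if len(vals) == 0:
            raise ValueError(f"subject {sid!r} has no trials")
        out.append(
            SubjectFeatureSample(
                subject_id=sid,
                group=(groups or {}).get(sid, "unknown"),
                value=float(np.mean(vals)),
                n_trials_averaged=len(vals),
            )
        )
    return out


def trial_average_samples(per_trial_values: Sequence[float], k: int) -> np.ndarray:
    """Means of every unordered k-subset of trials, lexicographic order.

    12 trials with k = 3 give C(12, 3) = 220 samples; k = n gives the
    single overall mean.
    """
    vals = np.asarray(list(per_trial_values), dtype=float)
    n = len(vals)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    return np.array([vals[list(c)].mean() for c in combinations(range(n), k)])


def independent_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, int]:
    """Two-sided equal-variance (Student's) two-sample t-test.

    Returns ``(t, p, df)`` with df = n_a + n_b - 2.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled == 0:
        raise ValueError("zero pooled variance")
    res = _st.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue), len(a) + len(b) - 2


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC with the positive class scored high; ties count one half.

    ``labels`` are 1 for the positive class (here: older group). The
    trapezoidal ROC area equals the tie-corrected Mann-Whitney statistic.
    """
    y = np.asarray(list(labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, s))


def accuracy_at_best_threshold(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Best single-threshold classification accuracy and its threshold.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus one below the minimum and one above the maximum;
    both orientations (positive above or below the threshold) are scanned
    and ties break toward the lower threshold.
    """
    y = np.asarray(list(labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2
    candidates = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    n = len(y)
    n_pos = int(y.sum())
    order = np.argsort(s, kind="stable")
    cum_pos = np.concatenate(([0], np.cumsum(y[order])))
    # split index: samples strictly below each candidate threshold
    below = np.searchsorted(s[order], candidates, side="left")
    pos_below = cum_pos[below]
    # positive class above the threshold / below the threshold
    acc_above = ((n_pos - pos_below) + (below - pos_below)) / n
    acc_below = (pos_below + (n - below) - (n_pos - pos_below)) / n
    acc = np.maximum(acc_above, acc_below)
    best = float(acc.max())
    best_thr = float(candidates[int(np.argmax(acc))])  # lowest on ties
    return best, best_thr


# ---------------------------------------------------------------------------
# Full group comparison report
# ---------------------------------------------------------------------------

def run_group_comparison(
    trial_table: pd.DataFrame,
    window_split_table: pd.DataFrame | None = None,
    features: Sequence[str] = ("ipvi", "mv_ap"),
    positive_group: str = "older",
    k_average: int = 3,
) -> dict:
    """Compare two groups on trial-level features.

    Parameters
    ----------
    trial_table : DataFrame
        One row per trial with columns ``subject_id, group`` plus one
        column per feature.
    window_split_table : DataFrame, optional
        One row per subject with columns ``subject_id, group,
        mv_ap_larger_half, mv_ap_smaller_half`` (per-subject means of the
        window-level MV_AP over the larger/smaller IPVI halves).
    features : sequence of str
        Feature columns to analyse.
    positive_group : str
        Group scored as the positive class for ROC/accuracy.
    k_average : int
        Size of the trial subsets averaged into classification samples.

    Returns a report dict with three sections: ``group_comparison``
    (per-feature group means, SDs and Student's t-test p on per-subject
    trial means), ``median_split`` (per-group MV_AP means of the
    larger/smaller IPVI window halves with p), and ``classification``
    (per-feature AUC and best-threshold accuracy on k-trial-average
    samples). NaN feature values are excluded from averages.
    """
    required = {"subject_id", "group"} | set(features)
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    group_names = sorted(trial_table["group"].unique())
    if len(group_names) != 2:
        raise ValueError(f"two groups required, found {group_names}")
    counts = trial_table.groupby("group")["subject_id"].nunique()
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 subjects")

    report: dict = {
        "groups": group_names,
        "positive_group": positive_group,
        "group_comparison": {},
        "classification": {},
    }

    subj = (
        trial_table.groupby(["group", "subject_id"])[list(features)]
        .mean()
        .reset_index()
    )
    for feat in features:
        a = subj.loc[subj["group"] == group_names[0], feat].to_numpy()
        b = subj.loc[subj["group"] == group_names[1], feat].to_numpy()
        t, p, df = independent_t_test(a, b)
        report["group_comparison"][feat] = {
            "group_means": {group_names[0]: float(a.mean()), group_names[1]: float(b.mean())},
            "group_sds": {
                group_names[0]: float(a.std(ddof=1)),
                group_names[1]: float(b.std(ddof=1)),
            },
            "t": t,
            "p": p,
            "df": df,
        }

        # classification on k-trial-average samples
        scores, labels = [], []
        for (grp, sid), sub in trial_table.groupby(["group", "subject_id"]):
            vals = sub[feat].dropna().to_numpy()
            if len(vals) < k_average:
                continue
            means = trial_average_samples(vals, k_average)
            scores.extend(means.tolist())
            labels.extend([1 if grp == positive_group else 0] * len(means))
        auc = roc_auc(scores, labels)
        acc, thr = accuracy_at_best_threshold(scores, labels)
        report["classification"][feat] = {
            "auc": auc,
            "accuracy": acc,
            "threshold": thr,
            "n_samples": len(scores),
            "k_average": k_average,
        }

    if window_split_table is not None:
        report["median_split"] = {}
        for grp, sub in window_split_table.groupby("group"):
            hi = sub["mv_ap_larger_half"].to_numpy()
            lo = sub["mv_ap_smaller_half"].to_numpy()
            t, p, df = independent_t_test(hi, lo)
            report["median_split"][grp] = {
                "mv_ap_larger_half_mean": float(hi.mean()),
                "mv_ap_larger_half_sd": float(hi.std(ddof=1)),
                "mv_ap_smaller_half_mean": float(lo.mean()),
                "mv_ap_smaller_half_sd": float(lo.std(ddof=1)),
                "t": t,
                "p": p,
                "df": df,
            }
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the report as a JSON summary plus delimited-text tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    rows = []
    for feat, d in report["group_comparison"].items():
        row = {"feature": feat, "t": d["t"], "p": d["p"], "df": d["df"]}
        for g in report["groups"]:
            row[f"mean_{g}"] = d["group_means"][g]
            row[f"sd_{g}"] = d["group_sds"][g]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "group_comparison.tsv", sep="\t", index=False)
    rows = [
        {"feature": feat, **d} for feat, d in report["classification"].items()
    ]
    pd.DataFrame(rows).to_csv(out_dir / "classification.tsv", sep="\t", index=False)
    if "median_split" in report:
        rows = [{"group": g, **d} for g, d in report["median_split"].items()]
        pd.DataFrame(rows).to_csv(out_dir / "median_split.tsv", sep="\t", index=False)
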