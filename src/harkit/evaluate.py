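"""Recognition-correctness and dispersion statistics, and report tables.

For one sensor s the statistics are:

* per activity a: R_s_a = 100 * P_s_a / W_s_a, the percentage of correctly
  identified repetitions pooled over subjects, and U_s_a, the weighted
  standard deviation of the per-subject rates x_i around R_s_a with
  weights w_i = that subject's repetition count of a;
* overall: R_s_a_ALL over all activities and subjects, with U_s_a_ALL
  (groups = subjects, weights = subject totals) and U_s_V_ALL (groups =
  activities, weights = all-subject activity totals);
* per subject V: R_s_V with U_s_V (groups = activities performed by V).

The weighted standard deviation of group rates x_i with weights w_i around
a reference rate R is

    U = sqrt( sum_i w_i (x_i - R)^2 / ( ((n-1)/n) * sum_i w_i ) ),

with n the number of contributing (positive-weight) groups.  The center is
the pooled rate R, not the weighted mean of the x_i — the two differ when
weights are unequal.  With equal weights and R set to the mean, U reduces
to the classical sample standard deviation.

Confusion matrices are column-normalized: entry (recognized r, performed
p) is the percentage of performed-p repetitions recognized as r, so every
column sums to 100 and the diagonal carries R_s_a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archetypes import ACTIVITIES
from .errors import HarkitError


def recognition_rate(correct: int, total: int) -> float:
    """Percentage of correctly identified repetitions, 100 * correct/total."""
    if total <= 0:
        raise HarkitError("recognition rate needs a positive repetition count")
    if not 0 <= correct <= total:
        raise HarkitError(f"need 0 <= correct <= total, got {correct}/{total}")
    return 100.0 * correct / total


def weighted_sd(values, weights, center: float) -> float:
    """Weighted dispersion of group rates around a reference rate.

    ``values`` are the per-group rates, ``weights`` the (positive) group
    repetition counts, ``center`` the pooled reference rate.  The group
    count n is ``len(values)``; doubling all weights leaves the result
    unchanged.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 2:
        raise HarkitError("weighted SD needs at least 2 groups")
    if x.shape != w.shape:
        raise HarkitError("values and weights must align")
    if (w <= 0).any():
        raise HarkitError("weights must be strictly positive")
    num = np.sum(w * (x - center) ** 2)
    den = (n - 1) / n * np.sum(w)
    return float(np.sqrt(num / den))


def build_confusion(predictions: pd.DataFrame, labels=ACTIVITIES) -> pd.DataFrame:
    """Column-normalized confusion matrix (percent).

    ``predictions`` needs columns ``activity_true`` and ``activity_pred``;
    rows index the recognized activity, columns the performed one.  Every
    performed class must occur at least once.
    """
    labels = list(labels)
    bad = (set(predictions["activity_true"]) | set(predictions["activity_pred"])) - set(labels)
    if bad:
        raise HarkitError(f"labels outside the class set: {sorted(bad)}")
    counts = pd.crosstab(predictions["activity_pred"], predictions["activity_true"])
    counts = counts.reindex(index=labels, columns=labels, fill_value=0)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        missing = totals.index[totals == 0].tolist()
        raise HarkitError(f"performed class(es) with zero repetitions: {missing}")
    out = 100.0 * counts / totals
    out.index.name = "recognized"
    out.columns.name = "performed"
    return out


@dataclass
class RecognitionReport:
    """All R/U statistics of one sensor's predictions.

    ``per_activity``: columns P, W, R, U (U is NaN when only one subject
    contributes).  ``per_subject``: columns P, W, R, U.  ``overall`` holds
    R_ALL, U_ALL (inter-subject) and U_V_ALL (inter-activity).  Activities
    or subjects absent from the predictions are listed in ``missing``.
    """

    sensor: str
    per_activity: pd.DataFrame
    per_subject: pd.DataFrame
    overall: dict[str, float]
    missing: dict[str, list] = field(default_factory=dict)


def _group_rates(predictions: pd.DataFrame, by: str) -> pd.DataFrame:
    correct = (predictions["activity_true"] == predictions["activity_pred"])
    grp = predictions.assign(correct=correct).groupby(by, sort=True)
    out = pd.DataFrame({
        "P": grp["correct"].sum().astype(int),
        "W": grp.size(),
    })
    out["R"] = 100.0 * out["P"] / out["W"]
    return out


def _dispersion(sub: pd.DataFrame, center: float) -> float:
    """Weighted SD over the groups of ``sub`` (rates R, weights W)."""
    if len(sub) < 2:
        return float("nan")
    return weighted_sd(sub["R"].to_numpy(), sub["W"].to_numpy(), center)


def build_report(predictions: pd.DataFrame, sensor: str = "",
                 labels=ACTIVITIES) -> RecognitionReport:
    """Compute the full recognition report from test-set predictions.

    ``predictions`` needs columns ``subject``, ``activity_true``,
    ``activity_pred``.  Rates are computed on these rows only (training
    repetitions carry no honest prediction).
    """
    required = {"subject", "activity_true", "activity_pred"}
    if not required.issubset(predictions.columns):
        raise HarkitError(f"predictions must have columns {sorted(required)}")
    labels = list(labels)
    subjects = sorted(predictions["subject"].unique())

    # per (activity, subject) counts feed every dispersion below
    pair = _group_rates(predictions.assign(
        key=list(zip(predictions["activity_true"], predictions["subject"]))), "key")
    pair.index = pd.MultiIndex.from_tuples(pair.index, names=["activity", "subject"])

    per_act = _group_rates(predictions, "activity_true").reindex(labels)
    per_act.index.name = "activity"
    u_act = []
    for act in labels:
        if act in pair.index.get_level_values("activity"):
            sub = pair.xs(act, level="activity")
            u_act.append(_dispersion(sub, float(per_act.loc[act, "R"])))
        else:
            u_act.append(float("nan"))
    per_act["U"] = u_act

    per_subj = _group_rates(predictions, "subject").reindex(subjects)
    per_subj.index.name = "subject"
    u_subj = []
    for s in subjects:
        sub = pair.xs(s, level="subject")
        u_subj.append(_dispersion(sub, float(per_subj.loc[s, "R"])))
    per_subj["U"] = u_subj

    p_all = int(per_act["P"].sum())
    w_all = int(per_act["W"].sum())
    r_all = recognition_rate(p_all, w_all)
    u_all = _dispersion(per_subj, r_all)
    present = per_act.dropna(subset=["R"])
    u_v_all = _dispersion(present, r_all)

    missing = {
        "activities": [a for a in labels
                       if a not in set(predictions["activity_true"])],
        "subjects": [],
    }
    return RecognitionReport(
        sensor=sensor,
        per_activity=per_act,
        per_subject=per_subj,
        overall={"R_ALL": r_all, "U_ALL": u_all, "U_V_ALL": u_v_all,
                 "P_ALL": p_all, "W_ALL": w_all},
        missing=missing,
    )


def table_activities(reports: dict[str, RecognitionReport],
                     labels=ACTIVITIES, decimals: int = 1) -> pd.DataFrame:
    """Per-activity R over U table: one R row and one U row per sensor,
    columns the 12 activities plus All."""
    rows = {}
    for sensor, rep in sorted(reports.items()):
        r = rep.per_activity["R"].reindex(list(labels))
        u = rep.per_activity["U"].reindex(list(labels))
        rows[(sensor, "R")] = list(r) + [rep.overall["R_ALL"]]
        rows[(sensor, "U")] = list(u) + [rep.overall["U_ALL"]]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(labels) + ["All"])
    out.index = pd.MultiIndex.from_tuples(out.index, names=["sensor", "stat"])
    return out.round(decimals)


def table_subjects(reports: dict[str, RecognitionReport],
                   decimals: int = 1) -> pd.DataFrame:
    """Per-subject R over U table, columns the subjects plus All."""
    subjects = sorted({s for rep in reports.values() for s in rep.per_subject.index})
    rows = {}
    for sensor, rep in sorted(reports.items()):
        r = rep.per_subject["R"].reindex(subjects)
        u = rep.per_subject["U"].reindex(subjects)
        rows[(sensor, "R")] = list(r) + [rep.overall["R_ALL"]]
        rows[(sensor, "U")] = list(u) + [rep.overall["U_V_ALL"]]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=subjects + ["All"])
    out.index = pd.MultiIndex.from_tuples(out.index, names=["sensor", "stat"])
    return out.round(decimals)
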