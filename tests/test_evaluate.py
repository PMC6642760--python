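"""Recognition rates, weighted dispersion, confusion matrices, reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from harkit import (ACTIVITIES, HarkitError, build_confusion, build_report,
                    recognition_rate, table_activities, table_subjects,
                    weighted_sd)


class TestRecognitionRate:
    def test_examples_and_bounds(self):
        assert recognition_rate(49, 50) == pytest.approx(98.0)
        assert recognition_rate(0, 7) == 0.0
        assert recognition_rate(7, 7) == 100.0
        with pytest.raises(HarkitError):
            recognition_rate(1, 0)
        with pytest.raises(HarkitError):
            recognition_rate(5, 3)

    def test_overall_rate_is_the_count_weighted_mean_of_group_rates(self, rng):
        correct = rng.integers(0, 20, size=10)
        totals = correct + rng.integers(1, 10, size=10)
        rates = [recognition_rate(c, t) for c, t in zip(correct, totals)]
        pooled = recognition_rate(int(correct.sum()), int(totals.sum()))
        assert pooled == pytest.approx(np.average(rates, weights=totals))


class TestWeightedSD:
    def test_zero_when_all_groups_sit_at_the_center(self):
        assert weighted_sd([80.0, 80.0, 80.0], [3, 9, 1], 80.0) == 0.0

    def test_equal_weight_two_point_case(self):
        # values 0 and 100 around 50: sqrt((2500+2500)/1) = 70.71...
        assert weighted_sd([0.0, 100.0], [5, 5], 50.0) == pytest.approx(
            70.71067811865476, abs=1e-9)

    def test_equal_weights_with_mean_center_reduce_to_sample_sd(self, rng):
        for _ in range(100):
            x = rng.random(rng.integers(2, 12)) * 100
            u = weighted_sd(x, np.full(x.size, 3.0), float(x.mean()))
            assert u == pytest.approx(np.std(x, ddof=1), abs=1e-9)

    def test_weight_scale_invariance(self, rng):
        x = rng.random(6) * 100
        w = rng.integers(1, 30, size=6).astype(float)
        assert weighted_sd(x, w, 50.0) == pytest.approx(
            weighted_sd(x, 2 * w, 50.0), abs=1e-12)

    def test_degenerate_groups_are_rejected(self):
        with pytest.raises(HarkitError):
            weighted_sd([50.0], [1], 50.0)
        with pytest.raises(HarkitError):
            weighted_sd([0.0, 1.0], [1, 0], 0.5)


def _preds(rows):
    return pd.DataFrame(rows, columns=["subject", "activity_true", "activity_pred"])


class TestConfusion:
    def test_perfect_predictions_put_100_on_the_diagonal(self):
        rows = [("S01", a, a) for a in ACTIVITIES for _ in range(3)]
        cm = build_confusion(_preds(rows))
        np.testing.assert_allclose(np.diag(cm.to_numpy()), 100.0)
        np.testing.assert_allclose(cm.sum(axis=0), 100.0)

    def test_three_class_toy_columns(self):
        rows = ([("s", "A", "A")] * 2 + [("s", "A", "B")]
                + [("s", "B", "B")] + [("s", "C", "C")])
        cm = build_confusion(_preds(rows), labels=("A", "B", "C"))
        np.testing.assert_allclose(cm["A"], [200 / 3, 100 / 3, 0.0])
        np.testing.assert_allclose(cm.sum(axis=0), 100.0)

    def test_every_column_sums_to_100_before_rounding(self, rng):
        rows = [("s", rng.choice(ACTIVITIES), rng.choice(ACTIVITIES))
                for _ in range(600)]
        cm = build_confusion(_preds(rows))
        np.testing.assert_allclose(cm.sum(axis=0), 100.0, atol=1e-9)

    def test_missing_performed_class_and_foreign_labels_are_rejected(self):
        rows = [("s", "1a", "1a")]
        with pytest.raises(HarkitError):
            build_confusion(_preds(rows))  # 11 classes never performed
        with pytest.raises(HarkitError):
            build_confusion(_preds([("s", "9z", "1a")]))


class TestReport:
    def test_all_correct_gives_r_100_and_u_0(self):
        rows = [(f"V{i}", a, a) for i in (1, 2) for a in ACTIVITIES for _ in range(2)]
        rep = build_report(_preds(rows), "B")
        assert rep.overall["R_ALL"] == 100.0
        np.testing.assert_allclose(rep.per_activity["R"], 100.0)
        np.testing.assert_allclose(rep.per_activity["U"], 0.0)
        np.testing.assert_allclose(rep.per_subject["U"], 0.0)
        assert rep.overall["U_ALL"] == 0.0 and rep.overall["U_V_ALL"] == 0.0

    def test_two_subject_toy_matches_hand_arithmetic(self):
        rows = ([("V1", "1a", "1a")] * 3 + [("V1", "1a", "1b")]
                + [("V1", "1b", "1b")] * 2
                + [("V2", "1a", "1a")] * 4 + [("V2", "1a", "1b")]
                + [("V2", "1b", "1b")] + [("V2", "1b", "1a")] * 2)
        rep = build_report(_preds(rows), "B", labels=("1a", "1b"))

        r_1a = 100.0 * 7 / 9
        assert rep.per_activity.loc["1a", "R"] == pytest.approx(r_1a, abs=1e-9)
        u_1a = np.sqrt((4 * (75.0 - r_1a) ** 2 + 5 * (80.0 - r_1a) ** 2) / (0.5 * 9))
        assert rep.per_activity.loc["1a", "U"] == pytest.approx(u_1a, abs=1e-9)

        r_1b = 60.0
        x = (100.0, 100.0 / 3)
        u_1b = np.sqrt((2 * (x[0] - r_1b) ** 2 + 3 * (x[1] - r_1b) ** 2) / (0.5 * 5))
        assert rep.per_activity.loc["1b", "R"] == pytest.approx(r_1b, abs=1e-9)
        assert rep.per_activity.loc["1b", "U"] == pytest.approx(u_1b, abs=1e-9)

        r_all = 100.0 * 10 / 14
        assert rep.overall["R_ALL"] == pytest.approx(r_all, abs=1e-9)
        y = (100.0 * 5 / 6, 100.0 * 5 / 8)
        u_all = np.sqrt((6 * (y[0] - r_all) ** 2 + 8 * (y[1] - r_all) ** 2) / (0.5 * 14))
        assert rep.overall["U_ALL"] == pytest.approx(u_all, abs=1e-9)
        u_v_all = np.sqrt((9 * (r_1a - r_all) ** 2 + 5 * (r_1b - r_all) ** 2) / (0.5 * 14))
        assert rep.overall["U_V_ALL"] == pytest.approx(u_v_all, abs=1e-9)

        r_v1 = 100.0 * 5 / 6
        u_v1 = np.sqrt((4 * (75.0 - r_v1) ** 2 + 2 * (100.0 - r_v1) ** 2) / (0.5 * 6))
        assert rep.per_subject.loc["V1", "R"] == pytest.approx(r_v1, abs=1e-9)
        assert rep.per_subject.loc["V1", "U"] == pytest.approx(u_v1, abs=1e-9)

    def test_overall_rate_equals_summed_activity_counts(self, rng):
        rows = [(f"V{rng.integers(1, 5)}", rng.choice(ACTIVITIES), rng.choice(ACTIVITIES))
                for _ in range(800)]
        rep = build_report(_preds(rows), "C")
        assert rep.overall["R_ALL"] == pytest.approx(
            100.0 * rep.per_activity["P"].sum() / rep.per_activity["W"].sum())

    def test_confusion_diagonal_equals_per_activity_rates(self, rng):
        rows = [(f"V{rng.integers(1, 4)}", rng.choice(ACTIVITIES), rng.choice(ACTIVITIES))
                for _ in range(900)]
        df = _preds(rows)
        rep = build_report(df, "D")
        cm = build_confusion(df)
        np.testing.assert_allclose(np.diag(cm.to_numpy()),
                                   rep.per_activity["R"].to_numpy(), atol=1e-9)

    def test_absent_activities_are_reported_missing_not_dropped(self):
        rows = [("V1", a, a) for a in ACTIVITIES[:6] for _ in range(2)]
        rows += [("V2", a, a) for a in ACTIVITIES[:6]]
        rep = build_report(_preds(rows), "B")
        assert rep.missing["activities"] == list(ACTIVITIES[6:])
        assert rep.per_activity.loc["6b"].isna().all() or \
            np.isnan(rep.per_activity.loc["6b", "R"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rates_anticorrelate_with_dispersion_under_subject_heterogeneity(self, seed):
        # subjects differ in error-proneness, activities in difficulty: the
        # per-activity rate R then falls exactly where the inter-subject
        # dispersion U grows
        rng = np.random.default_rng(seed)
        p_subj = np.linspace(0.0, 0.5, 20)
        q_act = rng.permutation(np.linspace(0.2, 1.0, 12))
        rows = []
        for i in range(20):
            for a, act in enumerate(ACTIVITIES):
                for _ in range(30):
                    if rng.random() < p_subj[i] * q_act[a]:
                        pred = rng.choice([x for x in ACTIVITIES if x != act])
                    else:
                        pred = act
                    rows.append((f"V{i + 1:02d}", act, pred))
        rep = build_report(_preds(rows), "B")
        rho = spearmanr(rep.per_activity["R"], rep.per_activity["U"]).statistic
        assert rho < 0


class TestTables:
    def test_table_shapes_mirror_the_report_layout(self, rng):
        rows = [(f"V{rng.integers(1, 4)}", rng.choice(ACTIVITIES), rng.choice(ACTIVITIES))
                for _ in range(500)]
        reports = {s: build_report(_preds(rows), s) for s in ("B", "C")}
        t1 = table_activities(reports)
        assert list(t1.columns) == list(ACTIVITIES) + ["All"]
        assert t1.shape == (4, 13)  # (R, U) per sensor
        t6 = table_subjects(reports)
        assert t6.columns[-1] == "All"
        assert t6.shape[0] == 4
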