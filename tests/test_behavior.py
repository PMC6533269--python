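"""Trial filtering, choice/RT models, bootstrap contrasts, unfitted accuracy."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from summedstates import (
    choice_model,
    coefficient_difference_ci,
    filter_trials,
    rt_model,
    trial_predictor,
    unfitted_choice_accuracy,
)
from summedstates.containers import ChoiceTrialTable, CondensedSimilarity
from summedstates.errors import (
    AlignmentError,
    CollinearityError,
    SeparationError,
    ValidationError,
)

TARGETS = ["t0", "t1", "t2", "t3"]
# similarities for pairs (t0,t1) (t0,t2) (t0,t3) (t1,t2) (t1,t3) (t2,t3)
SIM = CondensedSimilarity(np.array([0.8, 0.3, 0.1, 0.5, 0.2, 0.4]), TARGETS, "state")


def _table(rows):
    return ChoiceTrialTable(
        pd.DataFrame(
            rows,
            columns=["participant_id", "reference", "option_a", "option_b",
                     "choice", "rt_ms"],
        )
    )


def _simulated_table(n_trials, n_participants, rng, choice_p=None, rt=None):
    refs, opta, optb = [], [], []
    for _ in range(n_trials):
        r, a, b = rng.choice(4, size=3, replace=False)
        refs.append(TARGETS[r])
        opta.append(TARGETS[a])
        optb.append(TARGETS[b])
    frame = pd.DataFrame(
        {
            "participant_id": np.repeat(
                [f"p{i}" for i in range(n_participants)],
                n_trials // n_participants,
            )[:n_trials],
            "reference": refs,
            "option_a": opta,
            "option_b": optb,
            "choice": "A",
            "rt_ms": 1000.0 if rt is None else rt,
        }
    )
    t = ChoiceTrialTable(frame)
    if choice_p is not None:
        frame = t.frame.copy()
        frame["choice"] = np.where(rng.random(n_trials) < choice_p, "A", "B")
        t = ChoiceTrialTable(frame)
    return t


class TestFilterTrials:
    def test_fast_trial_removed_boundary_retained(self):
        t = _table(
            [
                ["p0", "t0", "t1", "t2", "A", 400.0],
                ["p0", "t0", "t1", "t2", "A", 500.0],
                ["p0", "t0", "t1", "t2", "B", 900.0],
            ]
        )
        out = filter_trials(t)
        assert out.n_fast_trials_removed == 1
        assert out.table.n_trials == 2
        assert (out.table.frame["rt_ms"] >= 500).all()

    def test_chronically_fast_participant_removed_entirely(self):
        rows = [["fast", "t0", "t1", "t2", "A", 300.0]] * 19
        rows += [["fast", "t0", "t1", "t2", "A", 900.0]]  # the one slow trial
        rows += [["ok", "t0", "t1", "t2", "B", 800.0]] * 5
        out = filter_trials(_table(rows))
        # 19/20 = 95% fast > 90% cutoff: all 20 trials go, including the slow one
        assert out.n_participants_removed == 1
        assert out.n_trials_removed_with_participants == 20
        assert set(out.table.frame["participant_id"]) == {"ok"}

    def test_exactly_at_cutoff_is_retained(self):
        rows = [["p0", "t0", "t1", "t2", "A", 300.0]] * 9
        rows += [["p0", "t0", "t1", "t2", "A", 900.0]]  # 90% fast, not > 90%
        out = filter_trials(_table(rows))
        assert out.n_participants_removed == 0
        assert out.table.n_trials == 1

    def test_empty_result_raises(self):
        t = _table([["p0", "t0", "t1", "t2", "A", 100.0]])
        with pytest.raises(ValidationError):
            filter_trials(t)


class TestTrialPredictor:
    def test_hand_computed_difference(self):
        t = _table([["p0", "t2", "t0", "t1", "A", 900.0]])
        # sim(t0,t2)=0.3, sim(t1,t2)=0.5 -> predictor -0.2
        assert trial_predictor(t, SIM)[0] == pytest.approx(-0.2)

    def test_swapping_options_negates(self):
        t1 = _table([["p0", "t2", "t0", "t1", "A", 900.0]])
        t2 = _table([["p0", "t2", "t1", "t0", "A", 900.0]])
        assert trial_predictor(t1, SIM)[0] == pytest.approx(-trial_predictor(t2, SIM)[0])

    def test_missing_label_raises(self):
        t = _table([["p0", "t2", "t0", "unknown", "A", 900.0]])
        with pytest.raises(AlignmentError):
            trial_predictor(t, SIM)


class TestChoiceModel:
    def test_null_predictor_coefficient_near_zero(self, rng):
        t = _simulated_table(5000, 10, rng, choice_p=np.full(5000, 0.5))
        pred = trial_predictor(t, SIM)
        res = choice_model(t, {"states": pred})
        assert abs(res.coefficients["states"]) < 0.1
        assert res.exponentiated["states"] == pytest.approx(
            np.exp(res.coefficients["states"])
        )

    def test_recovers_generating_slope(self, rng):
        t = _simulated_table(4000, 10, rng)
        pred = trial_predictor(t, SIM)
        z = (pred - pred.mean()) / pred.std(ddof=1)
        t = ChoiceTrialTable(
            t.frame.assign(choice=np.where(rng.random(4000) < expit(1.5 * z), "A", "B"))
        )
        res = choice_model(t, {"states": pred})
        assert res.p["states"] < 1e-10
        assert abs(res.coefficients["states"] - 1.5) < 0.2

    def test_duplicate_predictor_raises(self, rng):
        t = _simulated_table(200, 4, rng, choice_p=np.full(200, 0.5))
        pred = trial_predictor(t, SIM)
        with pytest.raises(CollinearityError):
            choice_model(t, {"a": pred, "b": pred.copy()})

    def test_complete_separation_raises(self, rng):
        t = _simulated_table(500, 5, rng)
        pred = trial_predictor(t, SIM)
        keep = pred != 0
        frame = t.frame.loc[keep].reset_index(drop=True)
        frame["choice"] = np.where(pred[keep] > 0, "A", "B")
        with pytest.raises(SeparationError):
            choice_model(ChoiceTrialTable(frame), {"states": pred[keep]})


class TestRtModel:
    def test_null_predictor_coefficient_near_zero(self, rng):
        rt = np.exp(7 + 0.3 * rng.normal(size=5000))
        t = _simulated_table(5000, 10, rng, rt=rt)
        res = rt_model(t, {"states": trial_predictor(t, SIM)})
        assert abs(res.coefficients["states"]) < 0.05

    def test_scale_invariance_of_standardized_coefficients(self, rng):
        pred_source = _simulated_table(1000, 5, rng)
        pred = trial_predictor(pred_source, SIM)
        rt = np.exp(7 - 0.1 * pred + 0.3 * rng.normal(size=1000))
        t1 = ChoiceTrialTable(pred_source.frame.assign(rt_ms=rt))
        t2 = ChoiceTrialTable(pred_source.frame.assign(rt_ms=rt * 1000))
        r1 = rt_model(t1, {"states": pred})
        r2 = rt_model(t2, {"states": pred})
        assert r1.coefficients["states"] == pytest.approx(
            r2.coefficients["states"], abs=1e-12
        )

    def test_raw_coefficient_recovers_log_slope(self, rng):
        t0 = _simulated_table(6000, 10, rng)
        pred = trial_predictor(t0, SIM)
        z = (pred - pred.mean()) / pred.std(ddof=1)
        rt = np.exp(7 - 0.1 * z + 0.3 * rng.normal(size=6000))
        t = ChoiceTrialTable(t0.frame.assign(rt_ms=rt))
        res = rt_model(t, {"states": pred})
        assert res.raw_coefficients["states"] == pytest.approx(-0.1, abs=0.02)

    def test_non_positive_rt_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            _table([["p0", "t0", "t1", "t2", "A", -5.0]])


class TestCoefficientDifferenceCi:
    def _powered_table(self, rng, n_participants=40, trials_each=50):
        n = n_participants * trials_each
        t0 = _simulated_table(n, n_participants, rng)
        pred1 = trial_predictor(t0, SIM)
        z1 = (pred1 - pred1.mean()) / pred1.std(ddof=1)
        pred2 = rng.normal(size=n)  # pure noise competitor
        choice = np.where(rng.random(n) < expit(1.0 * z1), "A", "B")
        return ChoiceTrialTable(t0.frame.assign(choice=choice)), pred1, pred2

    def test_deterministic_under_seed(self, rng):
        t, p1, p2 = self._powered_table(rng, n_participants=10, trials_each=30)
        a = coefficient_difference_ci(t, p1, p2, kind="choice", n_boot=50, seed=3)
        b = coefficient_difference_ci(t, p1, p2, kind="choice", n_boot=50, seed=3)
        assert a == b

    def test_true_difference_excludes_zero(self, rng):
        t, p1, p2 = self._powered_table(rng)
        lo, hi = coefficient_difference_ci(t, p1, p2, kind="choice",
                                           n_boot=200, seed=0)
        assert lo > 0

    def test_collinear_predictors_raise(self, rng):
        t, p1, _ = self._powered_table(rng, n_participants=8, trials_each=20)
        with pytest.raises(CollinearityError):
            coefficient_difference_ci(t, p1, p1.copy(), kind="choice", n_boot=20)


class TestUnfittedAccuracy:
    def test_hand_counted_mixture(self):
        rows = [
            ["p0", "t2", "t0", "t1", "B", 900.0],  # sim 0.3 vs 0.5 -> B correct
            ["p0", "t2", "t1", "t0", "A", 900.0],  # 0.5 vs 0.3 -> A correct
            ["p0", "t3", "t0", "t1", "B", 900.0],  # 0.1 vs 0.2 -> B correct
            ["p0", "t3", "t1", "t0", "B", 900.0],  # 0.2 vs 0.1 -> B wrong
        ]
        acc = unfitted_choice_accuracy(_table(rows), SIM)
        assert acc.accuracy == pytest.approx(0.75)
        assert acc.n_ties == 0

    @pytest.mark.parametrize("choice,expected", [("A", 1.0), ("B", 0.0)])
    def test_perfect_agreement_and_disagreement(self, choice, expected):
        rows = [["p0", "t2", "t1", "t0", choice, 900.0]] * 5  # A is correct
        acc = unfitted_choice_accuracy(_table(rows), SIM)
        assert acc.accuracy == expected

    def test_ties_excluded_and_counted(self):
        tie_sim = CondensedSimilarity(
            np.array([0.5, 0.3, 0.3, 0.5, 0.2, 0.4]), TARGETS, "state"
        )
        rows = [
            ["p0", "t0", "t2", "t3", "A", 900.0],  # 0.3 vs 0.3 -> tie
            ["p0", "t2", "t1", "t0", "A", 900.0],  # 0.5 vs 0.3 -> correct
        ]
        acc = unfitted_choice_accuracy(_table(rows), tie_sim)
        assert acc.n_ties == 1
        assert acc.n_trials_used == 1
        assert acc.accuracy == 1.0

    def test_all_ties_raise(self):
        flat = CondensedSimilarity(np.full(6, 0.3), TARGETS, "state")
        rows = [["p0", "t0", "t1", "t2", "A", 900.0]]
        with pytest.raises(ValidationError):
            unfitted_choice_accuracy(_table(rows), flat)


class TestRelabelInvariance:
    def test_swapping_sides_preserves_statistics(self, rng):
        t0 = _simulated_table(2000, 8, rng)
        pred = trial_predictor(t0, SIM)
        z = (pred - pred.mean()) / pred.std(ddof=1)
        choice = np.where(rng.random(2000) < expit(1.2 * z), "A", "B")
        t = ChoiceTrialTable(t0.frame.assign(choice=choice))
        swapped = ChoiceTrialTable(
            t.frame.assign(
                option_a=t.frame["option_b"],
                option_b=t.frame["option_a"],
                choice=t.frame["choice"].map({"A": "B", "B": "A"}),
            )
        )
        res = choice_model(t, {"states": trial_predictor(t, SIM)})
        res_sw = choice_model(swapped, {"states": trial_predictor(swapped, SIM)})
        assert abs(res.coefficients["states"]) == pytest.approx(
            abs(res_sw.coefficients["states"]), abs=1e-8
        )
        acc = unfitted_choice_accuracy(t, SIM)
        acc_sw = unfitted_choice_accuracy(swapped, SIM)
        assert acc.accuracy == pytest.approx(acc_sw.accuracy)
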