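"""Choice and reaction-time analyses of the triadic similarity task.

Trials faster than the plausibility floor are dropped (and participants who
were implausibly fast on most trials are removed wholesale); each model
predicts the choice (logistic) or log reaction time (linear) from the
difference in similarity-to-reference between the two options, standardized
across retained trials.  Mixed-effects fits are replaced by fixed-effects
models with a participant-cluster bootstrap for the state-vs-trait
coefficient contrast.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .containers import ChoiceTrialTable, CondensedSimilarity
from .errors import AlignmentError, CollinearityError, SeparationError, ValidationError
from .synthetic import stage_rng

__all__ = [
    "TrialFilterResult",
    "BehaviorModelResult",
    "UnfittedAccuracy",
    "filter_trials",
    "trial_predictor",
    "choice_model",
    "rt_model",
    "coefficient_difference_ci",
    "unfitted_choice_accuracy",
]


@dataclasses.dataclass
class TrialFilterResult:
    table: ChoiceTrialTable
    n_participants_removed: int
    n_trials_removed_with_participants: int
    n_fast_trials_removed: int

    @property
    def n_trials_retained(self) -> int:
        return self.table.n_trials


def filter_trials(
    t: ChoiceTrialTable,
    rt_floor_ms: float = 500.0,
    fast_fraction_cutoff: float = 0.9,
) -> TrialFilterResult:
    """Remove implausibly fast trials and chronically fast participants.

    Participants whose fraction of trials faster than ``rt_floor_ms``
    (strictly) exceeds ``fast_fraction_cutoff`` are removed entirely,
    including their slow trials; the fraction is computed before any trial
    removal.  Then any remaining trial with rt strictly below the floor is
    dropped.
    """
    df = t.frame
    if df.empty:
        raise ValidationError("choice table is empty")
    fast = df["rt_ms"] < rt_floor_ms
    frac = fast.groupby(df["participant_id"]).mean()
    bad_participants = set(frac.index[frac > fast_fraction_cutoff])
    kept = df[~df["participant_id"].isin(bad_participants)]
    n_with_participants = len(df) - len(kept)
    final = kept[kept["rt_ms"] >= rt_floor_ms]
    n_fast = len(kept) - len(final)
    if final.empty:
        raise ValidationError("no trials remain after filtering")
    return TrialFilterResult(
        table=ChoiceTrialTable(final.reset_index(drop=True)),
        n_participants_removed=len(bad_participants),
        n_trials_removed_with_participants=n_with_participants,
        n_fast_trials_removed=n_fast,
    )


def trial_predictor(t: ChoiceTrialTable, sim: CondensedSimilarity) -> np.ndarray:
    """Per-trial raw predictor: sim(option_a, ref) - sim(option_b, ref).

    Returned unstandardized; the models standardize across the trials they
    are fitted on.
    """
    lut = sim.pair_lookup()
    df = t.frame
    out = np.empty(len(df))
    for i, (ref, a, b) in enumerate(
        zip(df["reference"], df["option_a"], df["option_b"])
    ):
        try:
            out[i] = lut[(a, ref)] - lut[(b, ref)]
        except KeyError as exc:
            raise AlignmentError(
                f"trial targets not present in similarity labels: {exc.args[0]}"
            ) from None
    return out


@dataclasses.dataclass
class BehaviorModelResult:
    """Fitted choice or RT model.

    ``coefficients`` are standardized (per-SD of the predictor; for RT the
    DV is standardized too).  ``raw_coefficients`` for the RT model are on
    the log-RT-per-predictor-SD scale, and ``se`` is reported on that raw
    scale (for choice models, on the log-odds scale).  ``exponentiated``
    (choice models only) are odds ratios per predictor SD.
    ``ci_difference`` is filled by :func:`coefficient_difference_ci` for the
    two-predictor model.
    """

    model: str
    kind: str  # "choice" or "rt"
    coefficients: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    exponentiated: dict[str, float] | None
    raw_coefficients: dict[str, float] | None
    bic: float
    n_trials: int
    n_participants: int
    ci_difference: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.ci_difference is not None:
            d["ci_difference"] = list(self.ci_difference)
        return d


def _zscore(v: np.ndarray, what: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"{what} has zero variance")
    return (v - v.mean()) / sd


def _design(predictors: Mapping[str, np.ndarray], n: int) -> tuple[list[str], np.ndarray]:
    names = list(predictors)
    if not 1 <= len(names) <= 2:
        raise ValidationError("expected one or two predictors")
    cols = []
    for name in names:
        v = np.asarray(predictors[name], dtype=float).ravel()
        if v.size != n:
            raise AlignmentError(f"predictor {name!r} length {v.size} != {n} trials")
        cols.append(_zscore(v, f"predictor {name!r}"))
    x = np.column_stack(cols)
    if len(names) == 2 and abs(np.corrcoef(x.T)[0, 1]) > 1 - 1e-10:
        raise CollinearityError(f"predictors {names} are collinear")
    return names, sm.add_constant(x, has_constant="add")


def _model_label(names: Sequence[str]) -> str:
    if len(names) == 2:
        return "both"
    return names[0]


def choice_model(
    t: ChoiceTrialTable, predictors: Mapping[str, np.ndarray]
) -> BehaviorModelResult:
    """Logistic regression of choice == A on standardized predictor(s).

    Coefficients are reported raw (log-odds per predictor SD) and
    exponentiated (odds); p-values come from the large-sample normal test.
    Complete separation raises :class:`SeparationError` (use
    :func:`unfitted_choice_accuracy` instead in that regime).
    """
    df = t.frame
    y = (df["choice"] == "A").to_numpy(dtype=float)
    names, x = _design(predictors, len(df))
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(
            "complete separation in the choice model; the unfitted choice "
            "accuracy statistic is the appropriate summary"
        ) from exc
    params = np.asarray(fit.params)
    if np.any(np.abs(params[1:]) > 50):
        raise SeparationError(
            "diverging choice-model coefficients (near-complete separation); "
            "use the unfitted choice accuracy statistic"
        )
    coefs = dict(zip(names, params[1:]))
    pvals = dict(zip(names, np.asarray(fit.pvalues)[1:]))
    bic = float(-2 * fit.llf + x.shape[1] * np.log(len(y)))
    return BehaviorModelResult(
        model=_model_label(names),
        kind="choice",
        coefficients={k: float(v) for k, v in coefs.items()},
        se={k: float(v) for k, v in zip(names, np.asarray(fit.bse)[1:])},
        p={k: float(v) for k, v in pvals.items()},
        exponentiated={k: float(np.exp(v)) for k, v in coefs.items()},
        raw_coefficients=None,
        bic=bic,
        n_trials=len(df),
        n_participants=len(t.participants),
    )


def rt_model(
    t: ChoiceTrialTable, predictors: Mapping[str, np.ndarray]
) -> BehaviorModelResult:
    """OLS regression of log reaction time on standardized predictor(s).

    Reaction times are log-transformed (they are strongly right-skewed).
    ``coefficients`` are fully standardized (z-scored DV and predictors);
    ``raw_coefficients`` are in log-RT units per predictor SD.
    """
    df = t.frame
    rt = df["rt_ms"].to_numpy(dtype=float)
    if np.any(rt <= 0):
        raise ValidationError("non-positive reaction time reached rt_model")
    y = np.log(rt)
    names, x = _design(predictors, len(df))
    fit = sm.OLS(y, x).fit()
    params = np.asarray(fit.params)[1:]
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise ValidationError("log reaction times have zero variance")
    bic = float(
        len(y) * np.log(fit.ssr / len(y)) + x.shape[1] * np.log(len(y))
    )
    return BehaviorModelResult(
        model=_model_label(names),
        kind="rt",
        coefficients={k: float(v / sd_y) for k, v in zip(names, params)},
        se={k: float(v) for k, v in zip(names, np.asarray(fit.bse)[1:])},
        p={k: float(v) for k, v in zip(names, np.asarray(fit.pvalues)[1:])},
        exponentiated=None,
        raw_coefficients={k: float(v) for k, v in zip(names, params)},
        bic=bic,
        n_trials=len(df),
        n_participants=len(t.participants),
    )


def coefficient_difference_ci(
    t: ChoiceTrialTable,
    pred1: np.ndarray,
    pred2: np.ndarray,
    kind: str = "choice",
    n_boot: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.1,
) -> tuple[float, float]:
    """Participant-cluster bootstrap 95% CI for the coefficient difference.

    Participants are resampled with replacement ``n_boot`` times; the
    two-predictor model is refitted on each resample (re-standardizing
    within the resample) and the difference of standardized coefficients
    (pred1 - pred2) recorded.  Returns the 2.5th-97.5th percentile interval.
    """
    if kind not in ("choice", "rt"):
        raise ValidationError(f"kind must be 'choice' or 'rt'; got {kind!r}")
    fit_fn = choice_model if kind == "choice" else rt_model
    preds = {"pred1": np.asarray(pred1, float), "pred2": np.asarray(pred2, float)}
    # The full-data fit must succeed (and raises on collinearity/separation).
    fit_fn(t, preds)

    df = t.frame
    groups = {p: np.flatnonzero((df["participant_id"] == p).to_numpy())
              for p in t.participants}
    ids = list(groups)
    rng = stage_rng(seed, "coefficient-difference-bootstrap")
    diffs = []
    failures = 0
    for _ in range(n_boot):
        chosen = rng.choice(len(ids), size=len(ids), replace=True)
        rows = np.concatenate([groups[ids[k]] for k in chosen])
        boot_df = df.iloc[rows].reset_index(drop=True)
        boot_t = ChoiceTrialTable(boot_df)
        boot_preds = {k: v[rows] for k, v in preds.items()}
        try:
            res = fit_fn(boot_t, boot_preds)
        except (SeparationError, CollinearityError, ValidationError):
            failures += 1
            continue
        diffs.append(res.coefficients["pred1"] - res.coefficients["pred2"])
    if failures > max_failure_fraction * n_boot:
        raise ValidationError(
            f"{failures}/{n_boot} bootstrap resamples failed to fit"
        )
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return float(lo), float(hi)


@dataclasses.dataclass
class UnfittedAccuracy:
    """Agreement between choices and a similarity model, with no fitting."""

    accuracy: float
    n_trials_used: int
    n_ties: int


def unfitted_choice_accuracy(
    t: ChoiceTrialTable, sim: CondensedSimilarity
) -> UnfittedAccuracy:
    """Fraction of trials whose choice has strictly higher similarity to the reference.

    Trials where the two options are exactly tied under ``sim`` are excluded
    from numerator and denominator (the count is reported); chance is 0.5.
    """
    diff = trial_predictor(t, sim)  # sim(a, ref) - sim(b, ref)
    ties = diff == 0
    used = ~ties
    if not used.any():
        raise ValidationError("all trials are tied; accuracy is undefined")
    chose_a = (t.frame["choice"] == "A").to_numpy()
    correct = np.where(chose_a, diff > 0, diff < 0)
    return UnfittedAccuracy(
        accuracy=float(correct[used].mean()),
        n_trials_used=int(used.sum()),
        n_ties=int(ties.sum()),
    )
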