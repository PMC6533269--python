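"""Comparative statistics for the summed-state vs trait model contest.

Item-level zero-order and semi-partial correlations treat elements of the
condensed similarity vector as units of analysis; group-level RSA correlates
each participant's neural similarity with a model prediction, Fisher
transforms, and t-tests; dependent correlations sharing the DV are compared
with Steiger's (1980) Z-bar-2* statistic; model fit is compared with the
Gaussian OLS BIC; and the share of *reliable* DV variance a predictor
explains is estimated by dividing its squared item-level correlation by the
DV's split-half (Spearman-Brown) reliability.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import CondensedSimilarity
from .errors import (
    AlignmentError,
    CollinearityError,
    DegeneratePatternError,
    ExactFitError,
    OverUnityWarning,
    ReliabilityWarning,
    ValidationError,
)
from .synthetic import stage_rng

__all__ = [
    "GroupRsaResult",
    "item_correlation",
    "semi_partial",
    "group_level_rsa",
    "paired_correlation_difference",
    "similarity_reliability",
    "disattenuate",
    "model_bic",
]


def _as_vector(x) -> np.ndarray:
    if isinstance(x, CondensedSimilarity):
        return x.values
    return np.asarray(x, dtype=float).ravel()


def _check_aligned(*vectors) -> list[np.ndarray]:
    sims = [v for v in vectors if isinstance(v, CondensedSimilarity)]
    for s in sims[1:]:
        sims[0].aligned_with(s)
    arrays = [_as_vector(v) for v in vectors]
    n = {a.size for a in arrays}
    if len(n) != 1:
        raise AlignmentError(f"vector lengths differ: {sorted(n)}")
    return arrays


def item_correlation(dv, pred) -> tuple[float, float]:
    """Item-level Pearson r over pair elements, with its two-sided p."""
    y, x = _check_aligned(dv, pred)
    if y.size < 3:
        raise ValidationError("item-level correlation requires at least 3 pairs")
    r, p = stats.pearsonr(y, x)
    return float(r), float(p)


def _residualize(x: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Least-squares residuals of x after regressing on control + intercept."""
    design = np.column_stack([np.ones_like(control), control])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def semi_partial(dv, x, control) -> tuple[float, float]:
    """Unique explanatory power of ``x`` for ``dv``, controlling ``control``.

    The *predictor* is residualized on the control (the DV is left intact),
    then correlated with the DV; this is the semi-partial correlation that
    quantifies each account's unique contribution to a common measure.
    """
    y, xv, cv = _check_aligned(dv, x, control)
    resid = _residualize(xv, cv)
    var_x = np.var(xv)
    if np.var(resid) < 1e-12 * max(var_x, 1.0):
        raise CollinearityError("predictor is collinear with the control")
    sr, _ = stats.pearsonr(y, resid)
    # t-test with one df spent on the estimated control regression (df = n-3)
    n = y.size
    if n < 4:
        raise ValidationError("semi-partial test requires at least 4 pairs")
    df = n - 3
    t = sr * np.sqrt(df / max(1.0 - sr * sr, np.finfo(float).tiny))
    p = 2 * stats.t.sf(abs(t), df)
    return float(sr), float(p)


@dataclasses.dataclass
class GroupRsaResult:
    """Group-level RSA: per-participant correlations tested on the Fisher scale."""

    per_participant_r: np.ndarray
    mean_z: float
    t: float
    p: float
    cohens_d: float

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_participant_r))

    @property
    def n_participants(self) -> int:
        return int(self.per_participant_r.size)

    def to_dict(self) -> dict:
        return {
            "per_participant_r": self.per_participant_r.tolist(),
            "mean_r": self.mean_r,
            "mean_z": self.mean_z,
            "t": self.t,
            "p": self.p,
            "cohens_d": self.cohens_d,
        }


def group_level_rsa(
    per_participant_dv: Sequence[CondensedSimilarity], pred: CondensedSimilarity
) -> GroupRsaResult:
    """Correlate a model prediction with each participant's similarity vector.

    Per-participant Pearson r values are Fisher transformed (z = atanh r),
    entered into a two-sided one-sample t-test against 0, and summarized
    with the one-sample Cohen's d on the z scale.
    """
    if len(per_participant_dv) < 2:
        raise ValidationError("group-level RSA requires at least 2 participants")
    rs = []
    for k, dv in enumerate(per_participant_dv):
        r, _ = item_correlation(dv, pred)
        if abs(r) >= 1.0 - 1e-15:
            raise ValidationError(
                f"participant {k} has |r| = 1; Fisher z is infinite"
            )
        rs.append(r)
    rs = np.asarray(rs)
    z = np.arctanh(rs)
    sd = z.std(ddof=1)
    if sd == 0:
        raise DegeneratePatternError("zero variance of Fisher-z values across participants")
    t, p = stats.ttest_1samp(z, 0.0)
    return GroupRsaResult(
        per_participant_r=rs,
        mean_z=float(z.mean()),
        t=float(t),
        p=float(p),
        cohens_d=float(z.mean() / sd),
    )


def paired_correlation_difference(dv, x1, x2) -> tuple[float, float]:
    """Steiger's (1980) Z-bar-2* test for two dependent correlations sharing ``dv``.

    Compares r(dv, x1) against r(dv, x2) accounting for r(x1, x2), pooling
    via the back-transformed mean of the two Fisher z values.  Returns the
    Z statistic and its two-sided normal p-value.
    """
    y, a, b = _check_aligned(dv, x1, x2)
    n = y.size
    if n < 10:
        raise ValidationError("paired correlation difference requires >= 10 pairs")
    if np.array_equal(a, b):
        # Identical predictors: the difference is exactly zero by construction.
        return 0.0, 1.0
    r12, _ = stats.pearsonr(y, a)
    r13, _ = stats.pearsonr(y, b)
    r23, _ = stats.pearsonr(a, b)
    for r in (r12, r13, r23):
        if abs(r) >= 1.0:
            raise ValidationError("|r| = 1 input; the test statistic is undefined")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = np.tanh((z12 + z13) / 2.0)
    psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    c = psi / (1 - rbar**2) ** 2
    # c approximates corr(z12, z13); the large-sample formula can stray just
    # outside [-1, 1] at extreme input correlations, so clamp before the sqrt.
    c = min(c, 1.0 - 1e-12)
    z_stat = (z12 - z13) * np.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * stats.norm.sf(abs(z_stat))
    return float(z_stat), float(p)


def similarity_reliability(
    per_participant_dv: Sequence[CondensedSimilarity],
    n_splits: int = 20,
    seed: int = 0,
    floor: float = 1e-3,
) -> float:
    """Split-half, Spearman-Brown-corrected reliability of a group similarity.

    Participants are split into random halves; the correlation between the
    half-averaged similarity vectors is stepped up with the Spearman-Brown
    formula 2r/(1+r) and averaged over ``n_splits`` seeded splits.  The
    result is clipped to (0, 1]; a non-positive estimate is floored at
    ``floor`` with a warning.
    """
    p = len(per_participant_dv)
    if p < 4:
        raise ValidationError("reliability requires at least 4 participants")
    for s in per_participant_dv[1:]:
        per_participant_dv[0].aligned_with(s)
    stacked = np.stack([s.values for s in per_participant_dv], axis=0)
    rng = stage_rng(seed, "similarity-reliability")
    half = p // 2
    vals = []
    for _ in range(n_splits):
        order = rng.permutation(p)
        a = stacked[order[:half]].mean(axis=0)
        b = stacked[order[half:]].mean(axis=0)
        r, _ = stats.pearsonr(a, b)
        vals.append(2 * r / (1 + r) if r > -1 else -1.0)
    rel = float(np.mean(vals))
    if rel <= 0:
        warnings.warn(
            f"non-positive split-half reliability ({rel:.4f}); floored at {floor}",
            ReliabilityWarning,
        )
        return floor
    return min(rel, 1.0)


def disattenuate(item_r: float, reliability: float) -> float:
    """Share of reliable DV variance explained: item_r**2 / reliability.

    Multiply by 100 for percent display.  Shares above 1 are possible as a
    sampling artifact and are returned with :class:`OverUnityWarning`.
    """
    if not 0 < reliability <= 1:
        raise ValidationError(f"reliability must be in (0, 1]; got {reliability}")
    share = float(item_r**2 / reliability)
    if share > 1:
        warnings.warn(
            f"disattenuated share {share:.3f} exceeds 1 (sampling artifact)",
            OverUnityWarning,
        )
    return share


def model_bic(dv, *predictors) -> float:
    """Gaussian OLS BIC: n*ln(RSS/n) + k*ln(n), k = predictors + intercept.

    Constant terms of the Gaussian likelihood are dropped consistently, so
    only BIC *differences* between models of the same DV are meaningful.
    """
    if not predictors:
        raise ValidationError("model_bic requires at least one predictor")
    arrays = _check_aligned(dv, *predictors)
    y, xs = arrays[0], arrays[1:]
    n = y.size
    k = len(xs) + 1
    if n <= k:
        raise ValidationError(f"need more than {k} observations; got {n}")
    design = np.column_stack([np.ones(n)] + list(xs))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss <= 1e-12 * max(tss, 1.0):
        raise ExactFitError("residual sum of squares is (numerically) zero")
    return float(n * np.log(rss / n) + k * np.log(n))
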