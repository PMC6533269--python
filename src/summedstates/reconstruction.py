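"""The direct test: weighted-sum reconstruction of person patterns.

Frequency ratings are dual sum-normalized (first within state, then within
target); each target's pattern is reconstructed as the weighted sum of the
group state patterns; and reconstructions are scored within each participant
by the matched-minus-unmatched correlation contrast.  Subtracting the mean
unmatched correlation removes any generic "person pattern" shared across
targets, so surviving accuracy is target-specific.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .containers import PatternMatrix, WeightMatrix
from .errors import (
    AlignmentError,
    DegeneratePatternError,
    NormalizationError,
    ValidationError,
)

__all__ = [
    "ReconstructionResult",
    "normalize_weights",
    "reconstruct_targets",
    "score_reconstruction",
]


def normalize_weights(raw: WeightMatrix) -> WeightMatrix:
    """Dual sum-normalization: within state (columns), then within target (rows).

    Step 1 divides each state column by its column sum, putting states on a
    common footing; step 2 divides each target row of the result by its row
    sum, so each target's weights form a unit-sum mixing profile.  Rows of
    the output sum to 1; columns need not, by construction order.
    """
    v = raw.values
    col_sums = v.sum(axis=0)
    zero_cols = np.flatnonzero(col_sums == 0)
    if zero_cols.size:
        names = [raw.state_labels[j] for j in zero_cols]
        raise NormalizationError(f"state column(s) sum to zero: {names}")
    v = v / col_sums
    row_sums = v.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(row_sums.ravel() == 0)
    if zero_rows.size:
        names = [raw.target_labels[i] for i in zero_rows]
        raise NormalizationError(f"target row(s) sum to zero: {names}")
    v = v / row_sums
    return WeightMatrix(
        v, list(raw.target_labels), list(raw.state_labels), normalized=True
    )


def reconstruct_targets(state_patterns: PatternMatrix, w: WeightMatrix) -> PatternMatrix:
    """Weighted sums of state patterns, one reconstructed column per target.

    State labels are matched by name (order-insensitive); the weights must be
    in dual-normalized form.
    """
    if not w.normalized:
        raise ValidationError("weights must be dual-normalized before reconstruction")
    missing = [s for s in w.state_labels if s not in state_patterns.condition_labels]
    if missing:
        raise AlignmentError(f"state patterns missing for: {missing}")
    aligned = state_patterns.reorder_conditions(list(w.state_labels))
    recon = aligned.values @ w.values.T
    return PatternMatrix(recon, list(w.target_labels), list(state_patterns.voxel_ids))


@dataclasses.dataclass
class ReconstructionResult:
    """Per-participant matched/unmatched correlation summaries and group stats.

    ``group_t``, ``group_p`` and ``cohens_d`` are NaN (and
    ``group_stats_available`` False) when only one participant is scored.
    """

    per_participant_matched: np.ndarray
    per_participant_unmatched: np.ndarray
    per_participant_difference: np.ndarray
    group_t: float
    group_p: float
    cohens_d: float
    n_participants: int
    group_stats_available: bool
    participant_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "per_participant_matched": self.per_participant_matched.tolist(),
            "per_participant_unmatched": self.per_participant_unmatched.tolist(),
            "per_participant_difference": self.per_participant_difference.tolist(),
            "group_t": self.group_t,
            "group_p": self.group_p,
            "cohens_d": self.cohens_d,
            "n_participants": self.n_participants,
            "group_stats_available": self.group_stats_available,
            "participant_ids": self.participant_ids,
        }

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.per_participant_difference))


def _cross_correlations(recon: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """All pairwise Pearson correlations between columns of two matrices."""
    for mat, name in ((recon, "reconstruction"), (actual, "actual")):
        if np.any(mat.std(axis=0) == 0):
            raise DegeneratePatternError(f"constant {name} pattern column")
    rz = (recon - recon.mean(axis=0)) / recon.std(axis=0)
    az = (actual - actual.mean(axis=0)) / actual.std(axis=0)
    return (rz.T @ az) / recon.shape[0]


def score_reconstruction(
    recon: PatternMatrix,
    person_sets: list[PatternMatrix],
    fisher: bool = False,
) -> ReconstructionResult:
    """Matched-minus-unmatched scoring of reconstructions against actual patterns.

    Within each participant, every reconstruction is Pearson-correlated with
    every actual target pattern.  The matched correlation is the same-target
    entry; the unmatched value is the mean of the other T-1 correlations in
    that reconstruction's row.  Per-target differences are averaged within
    participant on the raw r scale (set ``fisher=True`` to average and
    difference on the Fisher-z scale instead), then entered into a two-sided
    one-sample t-test across participants; Cohen's d is the one-sample
    mean/sd of the participant-level differences.
    """
    if recon.n_voxels < 2:
        raise ValidationError("scoring requires at least 2 voxels")
    if not person_sets:
        raise ValidationError("scoring requires at least one participant")
    targets = list(recon.condition_labels)
    matched_means, unmatched_means, ids = [], [], []
    for m in person_sets:
        missing = [t for t in targets if t not in m.condition_labels]
        if missing:
            raise AlignmentError(
                f"participant {m.participant_id!r} missing targets: {missing}"
            )
        if list(m.voxel_ids) != list(recon.voxel_ids):
            raise AlignmentError("voxel ids differ between reconstruction and data")
        actual = m.reorder_conditions(targets)
        corr = _cross_correlations(recon.values, actual.values)
        if fisher:
            corr = np.arctanh(np.clip(corr, -1 + 1e-15, 1 - 1e-15))
        t = len(targets)
        diag = np.diag(corr)
        off_mean = (corr.sum(axis=1) - diag) / (t - 1)
        matched_means.append(float(diag.mean()))
        unmatched_means.append(float(off_mean.mean()))
        ids.append(m.participant_id or f"participant_{len(ids)}")

    matched = np.asarray(matched_means)
    unmatched = np.asarray(unmatched_means)
    diff = matched - unmatched
    if len(person_sets) >= 2:
        t_stat, p_val = stats.ttest_1samp(diff, 0.0)
        sd = diff.std(ddof=1)
        d = float(diff.mean() / sd) if sd > 0 else np.nan
        available = True
    else:
        t_stat = p_val = d = np.nan
        available = False
    return ReconstructionResult(
        per_participant_matched=matched,
        per_participant_unmatched=unmatched,
        per_participant_difference=diff,
        group_t=float(t_stat),
        group_p=float(p_val),
        cohens_d=d,
        n_participants=len(person_sets),
        group_stats_available=available,
        participant_ids=ids,
    )
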