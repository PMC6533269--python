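"""Pattern standardization, group averaging, and reliability-based voxel selection.

Every observed pattern is z-scored within participant (each condition's voxel
vector to mean 0, sd 1) so that pattern correlations reflect shape rather
than amplitude, then averaged across participants to form a single set of
group patterns.  Voxel selection retains the voxels whose condition profiles
replicate across random half-splits of participants, at the voxelwise
reliability threshold that maximizes the patternwise reliability of the
retained set.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .containers import PatternMatrix
from .errors import AlignmentError, DegeneratePatternError, SelectionError, ValidationError
from .synthetic import stage_rng

__all__ = [
    "VoxelMask",
    "zscore_pattern",
    "average_across_participants",
    "select_reliable_voxels",
]


@dataclasses.dataclass
class VoxelMask:
    """Outcome of reliability-based voxel selection."""

    selected: list[str]
    threshold_used: float
    patternwise_reliability: float

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValidationError("voxel mask must retain at least one voxel")


def zscore_pattern(m: PatternMatrix) -> PatternMatrix:
    """Standardize each condition's voxel vector to mean 0, sample sd 1.

    Uses the sample (n-1) standard deviation.  A constant column has no
    pattern shape and raises :class:`DegeneratePatternError` naming the
    condition.
    """
    sd = m.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [m.condition_labels[j] for j in bad]
        raise DegeneratePatternError(f"constant pattern column(s): {names}")
    z = (m.values - m.values.mean(axis=0)) / sd
    return PatternMatrix(z, list(m.condition_labels), list(m.voxel_ids), m.participant_id)


def _stack_aligned(ms: Sequence[PatternMatrix]) -> np.ndarray:
    """Validate shared labels and stack to participants x voxels x conditions."""
    if not ms:
        raise ValidationError("need at least one pattern matrix")
    ref = ms[0]
    arrays = [ref.values]
    for m in ms[1:]:
        if list(m.voxel_ids) != list(ref.voxel_ids):
            raise AlignmentError("voxel ids differ across participants")
        if list(m.condition_labels) != list(ref.condition_labels):
            if set(m.condition_labels) == set(ref.condition_labels):
                m = m.reorder_conditions(ref.condition_labels)
            else:
                diff = sorted(
                    set(m.condition_labels) ^ set(ref.condition_labels)
                )
                raise AlignmentError(f"condition labels differ: {diff}")
        arrays.append(m.values)
    return np.stack(arrays, axis=0)


def average_across_participants(ms: Sequence[PatternMatrix]) -> PatternMatrix:
    """Element-wise mean of aligned matrices; clears the participant id."""
    stacked = _stack_aligned(ms)
    return PatternMatrix(
        stacked.mean(axis=0), list(ms[0].condition_labels), list(ms[0].voxel_ids)
    )


def _columnwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding columns of two equal-shape matrices."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=0) / denom


def select_reliable_voxels(
    person_sets: Sequence[PatternMatrix],
    n_splits: int = 10,
    thresholds: Sequence[float] | None = None,
    seed: int = 0,
) -> VoxelMask:
    """Select voxels at the reliability threshold maximizing patternwise reliability.

    Voxelwise reliability is each voxel's condition-profile correlation
    between the averages of two random half-splits of participants, averaged
    over ``n_splits`` splits.  Patternwise reliability at a threshold is the
    between-half pattern correlation (per condition, restricted to voxels at
    or above the threshold), averaged over conditions and splits.  The grid
    argmax is returned; ties break toward the lowest threshold so that more
    voxels are retained.  A threshold of -1 is the no-op that keeps every
    voxel, so the default grid always contains the unmasked baseline.
    """
    if len(person_sets) < 4:
        raise ValidationError("voxel selection requires at least 4 participants")
    stacked = _stack_aligned(person_sets)  # P x V x C
    n_part, n_vox, n_cond = stacked.shape
    if n_cond < 2:
        raise ValidationError("voxel selection requires at least 2 conditions")
    if thresholds is None:
        thresholds = np.round(np.arange(-1.0, 0.9001, 0.05), 10)
    thresholds = np.asarray(sorted(thresholds), dtype=float)

    rng = stage_rng(seed, "voxel-selection")
    half = n_part // 2
    if half < 2:
        raise ValidationError("voxel selection requires at least 2 participants per half")

    halves = []
    vox_rel = np.zeros((n_splits, n_vox))
    for s in range(n_splits):
        order = rng.permutation(n_part)
        a = stacked[order[:half]].mean(axis=0)  # V x C
        b = stacked[order[half:]].mean(axis=0)
        halves.append((a, b))
        # correlation of each voxel's condition profile between halves
        vox_rel[s] = _columnwise_corr(a.T, b.T)
    mean_vox_rel = np.nanmean(vox_rel, axis=0)

    best_thr = None
    best_rel = -np.inf
    best_mask = None
    for thr in thresholds:
        mask = mean_vox_rel >= thr
        if mask.sum() < 2:
            continue
        rels = [
            np.nanmean(_columnwise_corr(a[mask], b[mask])) for a, b in halves
        ]
        rel = float(np.mean(rels))
        if rel > best_rel + 1e-12:  # strict improvement; ties keep lowest threshold
            best_rel = rel
            best_thr = float(thr)
            best_mask = mask
    if best_mask is None:
        raise SelectionError("no threshold retained at least 2 voxels")
    voxel_ids = [v for v, keep in zip(person_sets[0].voxel_ids, best_mask) if keep]
    return VoxelMask(voxel_ids, best_thr, best_rel)
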