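"""Core data containers shared across the analysis.

Four objects move through the pipeline:

* :class:`PatternMatrix` — a voxels x conditions matrix of GLM coefficients,
  the unit of neural data (conditions are either mental states or target
  people).
* :class:`WeightMatrix` — a targets x states matrix of non-negative state
  frequency ratings, either raw or in dual sum-normalized form.
* :class:`CondensedSimilarity` — the strictly-upper-triangle vectorization of
  a symmetric targets x targets similarity matrix; the common currency in
  which neural, state, trait, text, and rating similarity are compared.
* :class:`ChoiceTrialTable` — trials of the triadic similarity judgment task
  (reference, two options, choice, reaction time).

All containers validate on construction and carry explicit labels so that
every downstream combination is checked by name, never by position alone.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

__all__ = [
    "PatternMatrix",
    "WeightMatrix",
    "CondensedSimilarity",
    "ChoiceTrialTable",
    "condensed_index",
]

# Canonical float format for CSV round-trips: 17 significant digits preserve
# float64 exactly, so files mode reproduces in-memory statistics bit-for-bit.
CSV_FLOAT_FORMAT = "%.17g"


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes}")
    return labels


@dataclasses.dataclass
class PatternMatrix:
    """A voxels x conditions matrix of pattern coefficients with labels."""

    values: np.ndarray
    condition_labels: Sequence[str]
    voxel_ids: Sequence[str]
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("pattern values must be a 2-D matrix")
        self.condition_labels = _check_unique(self.condition_labels, "condition labels")
        self.voxel_ids = _check_unique(self.voxel_ids, "voxel ids")
        if self.values.shape != (len(self.voxel_ids), len(self.condition_labels)):
            raise ValidationError(
                f"pattern shape {self.values.shape} does not match "
                f"{len(self.voxel_ids)} voxels x {len(self.condition_labels)} conditions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("pattern contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.condition_labels.index(label)
        except ValueError:
            raise AlignmentError(f"condition {label!r} not present") from None
        return self.values[:, j]

    def reorder_conditions(self, labels: Sequence[str]) -> "PatternMatrix":
        """Return a copy with columns in the requested label order."""
        missing = [x for x in labels if x not in self.condition_labels]
        if missing:
            raise AlignmentError(f"conditions not present: {missing}")
        idx = [self.condition_labels.index(x) for x in labels]
        return PatternMatrix(
            self.values[:, idx], list(labels), list(self.voxel_ids), self.participant_id
        )

    def subset_voxels(self, voxel_ids: Sequence[str]) -> "PatternMatrix":
        pos = {v: i for i, v in enumerate(self.voxel_ids)}
        missing = [v for v in voxel_ids if v not in pos]
        if missing:
            raise AlignmentError(f"voxels not present: {missing[:5]}")
        idx = [pos[v] for v in voxel_ids]
        return PatternMatrix(
            self.values[idx, :], list(self.condition_labels), list(voxel_ids),
            self.participant_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.voxel_ids), columns=list(self.condition_labels)
        )


@dataclasses.dataclass
class WeightMatrix:
    """Targets x states non-negative frequency ratings.

    ``normalized`` marks the dual sum-normalized form (first within state,
    then within target), in which every row sums to 1.
    """

    values: np.ndarray
    target_labels: Sequence[str]
    state_labels: Sequence[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("weight values must be a 2-D matrix")
        self.target_labels = _check_unique(self.target_labels, "target labels")
        self.state_labels = _check_unique(self.state_labels, "state labels")
        if self.values.shape != (len(self.target_labels), len(self.state_labels)):
            raise ValidationError("weight shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("weights contain non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("weights must be non-negative")
        if self.normalized:
            rows = self.values.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > 1e-9):
                raise ValidationError("normalized weight rows must sum to 1 +- 1e-9")
            if np.any(self.values > 1 + 1e-9):
                raise ValidationError("normalized weights must lie in [0, 1]")

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.target_labels), columns=list(self.state_labels)
        )


def condensed_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the canonical pair ordering.

    Pairs (i, j) with i < j are enumerated in row-major order over the label
    order, matching :func:`numpy.triu_indices` with ``k=1`` and SciPy's
    condensed-distance convention.
    """
    return np.triu_indices(n, k=1)


@dataclasses.dataclass
class CondensedSimilarity:
    """Length T*(T-1)/2 vector of pairwise target similarities."""

    values: np.ndarray
    target_labels: Sequence[str]
    kind: str = "neural"

    KINDS = ("neural", "state", "trait", "text", "rating")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.target_labels = _check_unique(self.target_labels, "target labels")
        t = len(self.target_labels)
        if self.values.size != t * (t - 1) // 2:
            raise ValidationError(
                f"condensed vector length {self.values.size} does not match "
                f"{t} targets ({t * (t - 1) // 2} pairs)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("similarity contains non-finite values")
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown similarity kind {self.kind!r}")

    @property
    def n_targets(self) -> int:
        return len(self.target_labels)

    @classmethod
    def from_square(
        cls, matrix: np.ndarray, target_labels: Sequence[str], kind: str
    ) -> "CondensedSimilarity":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] != matrix.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if not np.allclose(matrix, matrix.T, equal_nan=True):
            raise ValidationError("similarity matrix must be symmetric")
        i, j = condensed_index(matrix.shape[0])
        return cls(matrix[i, j], target_labels, kind)

    def to_square(self, diagonal: float = np.nan) -> np.ndarray:
        t = self.n_targets
        out = np.full((t, t), diagonal, dtype=float)
        i, j = condensed_index(t)
        out[i, j] = self.values
        out[j, i] = self.values
        return out

    def pairs(self) -> Iterable[tuple[str, str]]:
        return itertools.combinations(self.target_labels, 2)

    def pair_lookup(self) -> dict[tuple[str, str], float]:
        """Mapping from unordered label pair to similarity value."""
        out: dict[tuple[str, str], float] = {}
        for (a, b), v in zip(self.pairs(), self.values):
            out[(a, b)] = v
            out[(b, a)] = v
        return out

    def aligned_with(self, other: "CondensedSimilarity") -> None:
        if list(self.target_labels) != list(other.target_labels):
            raise AlignmentError(
                "condensed similarities have different target labels/order"
            )

    def to_frame(self) -> pd.DataFrame:
        i, j = condensed_index(self.n_targets)
        labels = np.asarray(self.target_labels, dtype=object)
        return pd.DataFrame(
            {
                "target_i": labels[i],
                "target_j": labels[j],
                "value": self.values,
                "kind": self.kind,
            }
        )


CHOICE_COLUMNS = ["participant_id", "reference", "option_a", "option_b", "choice", "rt_ms"]


@dataclasses.dataclass
class ChoiceTrialTable:
    """Trials of the triadic similarity task, one row per trial."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CHOICE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"choice table missing columns: {missing}")
        df = self.frame.loc[:, CHOICE_COLUMNS].reset_index(drop=True).copy()
        df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="raise").astype(float)
        if not np.all(np.isfinite(df["rt_ms"])) or np.any(df["rt_ms"] <= 0):
            raise ValidationError("rt_ms must be finite and positive")
        if not df["choice"].isin(["A", "B"]).all():
            bad = sorted(set(df["choice"]) - {"A", "B"})
            raise ValidationError(f"choice values must be 'A' or 'B'; got {bad}")
        trio = df[["reference", "option_a", "option_b"]]
        if (trio.nunique(axis=1) != 3).any():
            raise ValidationError(
                "reference, option_a and option_b must be mutually distinct per trial"
            )
        self.frame = df

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    @property
    def participants(self) -> list:
        return list(pd.unique(self.frame["participant_id"]))
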