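"""The five interpersonal-similarity representations, as condensed vectors.

Neural similarity correlates target-specific voxel patterns; state similarity
correlates targets' frequency-rating rows; trait similarity is the
reverse-coded (negated) Euclidean distance in a three-component PCA synthesis
of the trait scales (power, valence, sociality by convention); text
similarity is the negated summed absolute difference of within-document
relative word frequencies.  All share one canonical pair ordering so that
item-level statistics can mix any two of them.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .containers import CondensedSimilarity, PatternMatrix, WeightMatrix, condensed_index
from .errors import DegeneratePatternError, ValidationError

__all__ = [
    "TraitSpace",
    "neural_similarity",
    "state_similarity",
    "trait_pca",
    "trait_similarity",
    "text_similarity",
]

COMPONENT_LABELS = ["power", "valence", "sociality"]


def _corr_condensed(columns: np.ndarray, labels: Sequence[str], kind: str,
                    axis_name: str) -> CondensedSimilarity:
    """Pearson correlations between columns, in canonical pair order."""
    sd = columns.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [labels[j] for j in bad]
        raise DegeneratePatternError(f"constant {axis_name}: {names}")
    corr = np.corrcoef(columns, rowvar=False)
    i, j = condensed_index(len(labels))
    return CondensedSimilarity(corr[i, j], list(labels), kind)


def neural_similarity(person: PatternMatrix) -> CondensedSimilarity:
    """Pairwise Pearson correlation of target-specific voxel patterns."""
    if person.n_conditions < 2:
        raise ValidationError("neural similarity requires at least 2 targets")
    return _corr_condensed(
        person.values, person.condition_labels, "neural", "pattern column"
    )


def state_similarity(ratings: WeightMatrix) -> CondensedSimilarity:
    """Pairwise Pearson correlation of targets' raw frequency-rating rows."""
    if ratings.n_states < 2:
        raise ValidationError("state similarity requires at least 2 states")
    return _corr_condensed(
        ratings.values.T, ratings.target_labels, "state", "target row"
    )


@dataclasses.dataclass
class TraitSpace:
    """Three-component PCA synthesis of the trait scales."""

    scores: pd.DataFrame  # targets x components
    component_labels: list[str]
    explained_variance: np.ndarray  # percent of total variance per component
    loadings: pd.DataFrame  # traits x components

    def __post_init__(self) -> None:
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValidationError("explained variance must be non-increasing")


def trait_pca(trait_ratings: pd.DataFrame, n_components: int = 3) -> TraitSpace:
    """Correlation-matrix PCA of the trait scales.

    Trait columns are standardized (the scales have arbitrary units) before
    extraction.  Component signs are fixed so that each component's
    largest-magnitude loading is positive.  ``explained_variance`` is the
    percentage of total variance per component.
    """
    x = trait_ratings.to_numpy(dtype=float)
    n, k = x.shape
    if k < n_components:
        raise ValidationError(f"need at least {n_components} trait columns; got {k}")
    if n < n_components + 1:
        raise ValidationError(
            f"need at least {n_components + 1} targets; got {n}"
        )
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [trait_ratings.columns[j] for j in bad]
        raise DegeneratePatternError(f"constant trait column(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(z)
    if rank < n_components:
        raise ValidationError(
            f"trait matrix rank {rank} is below {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    components = pca.components_.copy()  # components x traits
    for c in range(n_components):
        j = int(np.argmax(np.abs(components[c])))
        if components[c, j] < 0:
            components[c] *= -1
            scores[:, c] *= -1
    labels = (
        COMPONENT_LABELS[:n_components]
        if n_components <= len(COMPONENT_LABELS)
        else [f"pc{c + 1}" for c in range(n_components)]
    )
    return TraitSpace(
        scores=pd.DataFrame(scores, index=trait_ratings.index, columns=labels),
        component_labels=labels,
        explained_variance=100.0 * pca.explained_variance_ratio_,
        loadings=pd.DataFrame(
            components.T, index=trait_ratings.columns, columns=labels
        ),
    )


def trait_similarity(space: TraitSpace) -> CondensedSimilarity:
    """Reverse-coded (negated) Euclidean distance between trait-score rows."""
    d = pdist(space.scores.to_numpy(dtype=float), metric="euclidean")
    return CondensedSimilarity(-d, list(space.scores.index), "trait")


def text_similarity(
    counts: pd.DataFrame, stopwords: Sequence[str] = ()
) -> CondensedSimilarity:
    """Negated summed absolute difference of relative word frequencies.

    ``counts`` is a words x targets table of token counts.  Stopword rows are
    removed, counts are converted to within-document relative frequencies
    (so documents of unequal length are comparable), and each pair's
    similarity is minus the L1 distance between frequency vectors.
    """
    stop = set(map(str, stopwords))
    kept = counts.loc[[w for w in counts.index if str(w) not in stop]]
    if kept.shape[0] < 1:
        raise ValidationError("no vocabulary left after stopword removal")
    totals = kept.sum(axis=0).to_numpy(dtype=float)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        names = [kept.columns[j] for j in empty]
        raise ValidationError(f"empty document(s) after filtering: {names}")
    freqs = kept.to_numpy(dtype=float) / totals
    d = pdist(freqs.T, metric="cityblock")
    return CondensedSimilarity(-d, list(counts.columns), "text")
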