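"""Synthetic data with known ground truth for the summed-state pipeline.

The generator is the exact inverse of the analysis: it draws a pool of
mental-state patterns, mixes them into person patterns with known frequency
weights, and then emits everything the pipeline consumes — per-participant
noisy patterns, raw frequency ratings, trait ratings derived from the
(log) frequency profiles, biography-like token counts, triadic choice
trials with reaction times, and pairwise similarity judgments.

Two deliberate calibrations make the inversion exact in the noise-free
limit:

* true state patterns are column-standardized after the standard-normal
  draw, because the analysis z-scores every observed state pattern;
* the true weight matrix is the Sinkhorn-balanced form of a symmetric
  Dirichlet draw (rows sum to 1, columns sum to T/S), which makes it a
  fixed point of the analysis's dual sum-normalization.

With all noise parameters at zero, reconstructing person patterns from the
generated ratings therefore reproduces the generated person patterns
exactly, and every matched correlation equals 1.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (
    CSV_FLOAT_FORMAT,
    ChoiceTrialTable,
    CondensedSimilarity,
    PatternMatrix,
    WeightMatrix,
    condensed_index,
)
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "TRAIT_NAMES",
    "generate_neural",
    "generate_ratings",
    "generate_traits",
    "generate_behavior",
    "generate_text",
    "generate_pairwise_ratings",
    "generate_dataset",
    "write_run_directory",
]

#: The 13 rated trait dimensions (the standard person-perception scales plus
#: intelligence and attractiveness).
TRAIT_NAMES = [
    "agency",
    "experience",
    "warmth",
    "competence",
    "trustworthiness",
    "dominance",
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
    "intelligence",
    "attractiveness",
]

_COUNT_FIELDS = (
    "n_voxels",
    "n_states",
    "n_targets",
    "n_state_participants",
    "n_person_participants",
    "n_raters",
    "n_behavior_participants",
    "trials_per_participant",
    "vocab_size",
    "doc_length",
)
_SD_FIELDS = (
    "participant_noise_sd",
    "rater_noise_sd",
    "trait_noise_sd",
    "residual_signal_sd",
    "text_noise_sd",
    "rt_sd_log",
    "pairwise_distortion_sd",
)


@dataclasses.dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the study-scale defaults.

    Counts default to the study conditions (60 targets, 15 states, 29
    person-study participants, 28 state-study participants, 644 raters,
    103 behavior participants x 50 trials, a 10,216-voxel mask).  Noise
    magnitudes are the generator's own calibration; see docs/methods.md.
    """

    n_voxels: int = 10216
    n_states: int = 15
    n_targets: int = 60
    n_state_participants: int = 28
    n_person_participants: int = 29
    n_raters: int = 644
    n_behavior_participants: int = 103
    trials_per_participant: int = 50
    participant_noise_sd: float = 1.0
    rater_noise_sd: float = 0.05
    trait_noise_sd: float = 1.0
    residual_signal_sd: float = 0.2
    choice_slope: float = 3.0
    rt_base_ms: float = 1500.0
    rt_sd_log: float = 0.4
    rt_sim_slope: float = -0.1
    vocab_size: int = 300
    doc_length: int = 2000
    text_noise_sd: float = 0.1
    pairwise_distortion_sd: float = 0.15
    dirichlet_concentration: float = 1.0
    log_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 2:
                raise ConfigurationError(f"{name} must be an integer >= 2; got {v!r}")
        for name in _SD_FIELDS:
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0; got {v!r}")
        for name in ("choice_slope", "rt_base_ms", "rt_sim_slope",
                     "dirichlet_concentration", "log_floor"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite; got {v!r}")
        if self.rt_base_ms <= 0:
            raise ConfigurationError("rt_base_ms must be positive")
        if self.dirichlet_concentration <= 0:
            raise ConfigurationError("dirichlet_concentration must be positive")
        if self.log_floor <= 0:
            raise ConfigurationError("log_floor must be positive")
        if self.vocab_size < self.n_states:
            raise ConfigurationError("vocab_size must be >= n_states")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**d)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream.

    One top-level seed fans out to independent streams keyed by stage name,
    so changing options in one stage never perturbs another.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    true_state_patterns: PatternMatrix
    true_weights: WeightMatrix
    true_person_patterns: PatternMatrix
    true_trait_loadings: pd.DataFrame  # states x traits
    true_state_similarity: CondensedSimilarity


def _labels(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    return (x - mu) / sd


def _sinkhorn_balance(w: np.ndarray, tol: float = 1e-14, max_iter: int = 1000) -> np.ndarray:
    """Scale a positive matrix so rows sum to 1 and columns sum to T/S.

    Such a matrix is a fixed point of the analysis's dual sum-normalization
    (divide by column sums, then by row sums), which is what makes the
    generator its exact inverse.
    """
    t, s = w.shape
    w = w.copy()
    for _ in range(max_iter):
        w /= w.sum(axis=0, keepdims=True)  # columns sum to 1
        rows = w.sum(axis=1, keepdims=True)
        w /= rows  # rows sum to 1
        col = w.sum(axis=0)
        if np.max(np.abs(col - t / s)) < tol * t / s:
            break
    return w


def _row_correlations(rows: np.ndarray) -> np.ndarray:
    c = np.corrcoef(rows)
    return np.asarray(c, dtype=float)


def generate_neural(
    config: GeneratorConfig,
) -> tuple[SyntheticTruth, list[PatternMatrix], list[PatternMatrix]]:
    """Draw ground truth and per-participant noisy state/person patterns.

    True state patterns are i.i.d. standard normal per voxel (then exactly
    column-standardized); true weights are Sinkhorn-balanced symmetric
    Dirichlet rows; each true person pattern is the weighted sum of state
    patterns plus a residual pattern with sd ``residual_signal_sd``.  Each
    participant observes truth plus i.i.d. noise with sd
    ``participant_noise_sd``.
    """
    cfg = config
    voxels = _labels("v", cfg.n_voxels)
    states = _labels("state_", cfg.n_states)
    targets = _labels("target_", cfg.n_targets)

    rng = stage_rng(cfg.seed, "truth-states")
    state_true = _zscore_columns(rng.standard_normal((cfg.n_voxels, cfg.n_states)))

    rng = stage_rng(cfg.seed, "truth-weights")
    raw = rng.dirichlet(
        np.full(cfg.n_states, cfg.dirichlet_concentration), size=cfg.n_targets
    )
    weights = _sinkhorn_balance(raw)

    rng = stage_rng(cfg.seed, "truth-residual")
    residual = cfg.residual_signal_sd * rng.standard_normal((cfg.n_voxels, cfg.n_targets))
    person_true = state_true @ weights.T + residual

    rng = stage_rng(cfg.seed, "truth-traits")
    loadings = rng.standard_normal((cfg.n_states, len(TRAIT_NAMES)))

    sim_square = _row_correlations(weights)
    i, j = condensed_index(cfg.n_targets)
    truth = SyntheticTruth(
        true_state_patterns=PatternMatrix(state_true, states, voxels),
        true_weights=WeightMatrix(weights, targets, states, normalized=True),
        true_person_patterns=PatternMatrix(person_true, targets, voxels),
        true_trait_loadings=pd.DataFrame(loadings, index=states, columns=TRAIT_NAMES),
        true_state_similarity=CondensedSimilarity(sim_square[i, j], targets, "state"),
    )

    rng = stage_rng(cfg.seed, "participants-state")
    state_sets = [
        PatternMatrix(
            state_true
            + cfg.participant_noise_sd * rng.standard_normal(state_true.shape),
            states,
            voxels,
            participant_id=f"state_sub{p:03d}",
        )
        for p in range(cfg.n_state_participants)
    ]

    rng = stage_rng(cfg.seed, "participants-person")
    person_sets = [
        PatternMatrix(
            person_true
            + cfg.participant_noise_sd * rng.standard_normal(person_true.shape),
            targets,
            voxels,
            participant_id=f"person_sub{p:03d}",
        )
        for p in range(cfg.n_person_participants)
    ]
    return truth, state_sets, person_sets


def generate_ratings(truth: SyntheticTruth, config: GeneratorConfig) -> WeightMatrix:
    """Raw frequency ratings: per-rater truth + noise, clipped at 0, averaged."""
    rng = stage_rng(config.seed, "ratings")
    w = truth.true_weights.values
    rated = w[None, :, :] + config.rater_noise_sd * rng.standard_normal(
        (config.n_raters,) + w.shape
    )
    agg = np.clip(rated, 0.0, None).mean(axis=0)
    return WeightMatrix(
        agg,
        list(truth.true_weights.target_labels),
        list(truth.true_weights.state_labels),
        normalized=False,
    )


def generate_traits(
    truth: SyntheticTruth,
    config: GeneratorConfig,
    loadings: np.ndarray | None = None,
) -> pd.DataFrame:
    """Trait ratings as noisy linear functions of log state frequencies.

    ``trait_value[t, k] = log(max(w[t], floor)) . loadings[:, k] + noise``.
    ``trait_noise_sd`` tunes how much independent information traits carry —
    at 0 traits are a deterministic re-expression of the state profile, the
    condition under which summed states should fully mediate traits.
    """
    if loadings is None:
        load = truth.true_trait_loadings.to_numpy()
        trait_names = list(truth.true_trait_loadings.columns)
    else:
        load = np.asarray(loadings, dtype=float)
        trait_names = [f"trait_{k:02d}" for k in range(load.shape[1])]
    logw = np.log(np.maximum(truth.true_weights.values, config.log_floor))
    rng = stage_rng(config.seed, "traits")
    vals = logw @ load + config.trait_noise_sd * rng.standard_normal(
        (truth.true_weights.n_targets, load.shape[1])
    )
    return pd.DataFrame(
        vals, index=list(truth.true_weights.target_labels), columns=trait_names
    )


def generate_behavior(
    state_sim: CondensedSimilarity, config: GeneratorConfig
) -> ChoiceTrialTable:
    """Triadic choice trials from a logistic model on similarity differences.

    Per trial three distinct targets are sampled; the probability of choosing
    option A is ``logistic(choice_slope * (sim(A, ref) - sim(B, ref)))``.
    Reaction times are lognormal with median ``rt_base_ms`` and log-sd
    ``rt_sd_log``; expected log-RT decreases with the magnitude of the
    similarity difference at ``rt_sim_slope`` per SD of that magnitude,
    emulating easier (faster) decisions for clearer trials.
    """
    t = state_sim.n_targets
    if t < 3:
        raise ConfigurationError("behavior generation requires at least 3 targets")
    rng = stage_rng(config.seed, "behavior")
    labels = np.asarray(state_sim.target_labels, dtype=object)
    square = state_sim.to_square(diagonal=1.0)

    n = config.n_behavior_participants * config.trials_per_participant
    # Vectorized distinct-triple sampling: ranks of uniforms give a random
    # permutation per trial; take the first three.
    order = np.argsort(rng.random((n, t)), axis=1)[:, :3]
    ref, a, b = order[:, 0], order[:, 1], order[:, 2]
    diff = square[a, ref] - square[b, ref]
    p_a = expit(config.choice_slope * diff)
    choice = np.where(rng.random(n) < p_a, "A", "B")

    mag = np.abs(diff)
    sd = mag.std(ddof=1)
    z = (mag - mag.mean()) / sd if sd > 0 else np.zeros_like(mag)
    log_rt = (
        np.log(config.rt_base_ms)
        + config.rt_sim_slope * z
        + config.rt_sd_log * rng.standard_normal(n)
    )
    participant = np.repeat(
        [f"beh_sub{p:03d}" for p in range(config.n_behavior_participants)],
        config.trials_per_participant,
    )
    frame = pd.DataFrame(
        {
            "participant_id": participant,
            "reference": labels[ref],
            "option_a": labels[a],
            "option_b": labels[b],
            "choice": choice,
            "rt_ms": np.exp(log_rt),
        }
    )
    return ChoiceTrialTable(frame)


def generate_text(truth: SyntheticTruth, config: GeneratorConfig) -> pd.DataFrame:
    """Token counts per target whose document distances track state similarity.

    A fixed non-negative vocabulary map sends each target's weight row to a
    vocabulary-length probability vector (plus truncated noise); counts are
    multinomial with ``doc_length`` tokens per document.  Returns a
    words x targets count table.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "text")
    w = truth.true_weights.values  # T x S
    vocab_map = np.abs(rng.standard_normal((cfg.vocab_size, cfg.n_states)))
    base = vocab_map @ w.T  # vocab x T
    noisy = base + cfg.text_noise_sd * rng.standard_normal(base.shape)
    noisy = np.clip(noisy, 1e-12, None)
    probs = noisy / noisy.sum(axis=0, keepdims=True)
    # Common random numbers: each document is drawn from an identically seeded
    # stream, so targets with identical probability vectors get identical
    # documents (sampling noise is paired across targets, not compounded).
    counts = np.column_stack(
        [
            stage_rng(cfg.seed, "text-counts").multinomial(
                cfg.doc_length, probs[:, t]
            )
            for t in range(w.shape[0])
        ]
    )
    words = _labels("w", cfg.vocab_size)
    return pd.DataFrame(
        counts, index=words, columns=list(truth.true_weights.target_labels)
    )


def generate_pairwise_ratings(
    truth: SyntheticTruth, config: GeneratorConfig
) -> CondensedSimilarity:
    """Pairwise similarity-judgment DV: true state similarity + rater noise.

    Emulates explicit "how similar are these two people?" ratings under the
    summed-state world model: every rater reports the true state-similarity
    of the pair plus a *shared* pair-level distortion (systematic folk
    judgments that do not average away across raters, with sd
    ``pairwise_distortion_sd``) plus idiosyncratic rater noise; ratings are
    averaged across raters.
    """
    rng = stage_rng(config.seed, "pairwise-ratings")
    base = (
        truth.true_state_similarity.values
        + config.pairwise_distortion_sd
        * rng.standard_normal(truth.true_state_similarity.values.size)
    )
    rated = base[None, :] + config.rater_noise_sd * rng.standard_normal(
        (config.n_raters, base.size)
    )
    return CondensedSimilarity(
        rated.mean(axis=0), list(truth.true_state_similarity.target_labels), "rating"
    )


@dataclasses.dataclass
class SyntheticDataset:
    """Everything a pipeline run consumes, plus the generating truth."""

    config: GeneratorConfig
    truth: SyntheticTruth
    state_sets: list[PatternMatrix]
    person_sets: list[PatternMatrix]
    ratings: WeightMatrix
    traits: pd.DataFrame
    text_counts: pd.DataFrame
    choices: ChoiceTrialTable
    pairwise_ratings: CondensedSimilarity


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full synthetic study (a pure function of the config)."""
    truth, state_sets, person_sets = generate_neural(config)
    return SyntheticDataset(
        config=config,
        truth=truth,
        state_sets=state_sets,
        person_sets=person_sets,
        ratings=generate_ratings(truth, config),
        traits=generate_traits(truth, config),
        text_counts=generate_text(truth, config),
        choices=generate_behavior(truth.true_state_similarity, config),
        pairwise_ratings=generate_pairwise_ratings(truth, config),
    )


def write_run_directory(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write all generated inputs (and the truth bundle) as CSV/JSON files."""
    out = Path(out_dir)
    (out / "state_patterns").mkdir(parents=True, exist_ok=True)
    (out / "person_patterns").mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)

    kw = dict(float_format=CSV_FLOAT_FORMAT)
    for m in dataset.state_sets:
        m.to_frame().to_csv(out / "state_patterns" / f"{m.participant_id}.csv", **kw)
    for m in dataset.person_sets:
        m.to_frame().to_csv(out / "person_patterns" / f"{m.participant_id}.csv", **kw)
    dataset.ratings.to_frame().to_csv(out / "ratings.csv", **kw)
    dataset.traits.to_csv(out / "traits.csv", **kw)
    dataset.text_counts.to_csv(out / "text_counts.csv")
    dataset.choices.frame.to_csv(out / "choices.csv", index=False, **kw)
    dataset.pairwise_ratings.to_frame().to_csv(
        out / "pairwise_ratings.csv", index=False, **kw
    )

    dataset.truth.true_weights.to_frame().to_csv(truth_dir / "true_weights.csv", **kw)
    dataset.truth.true_state_patterns.to_frame().to_csv(
        truth_dir / "true_state_patterns.csv", **kw
    )
    dataset.truth.true_person_patterns.to_frame().to_csv(
        truth_dir / "true_person_patterns.csv", **kw
    )
    dataset.truth.true_trait_loadings.to_csv(truth_dir / "true_trait_loadings.csv", **kw)
    dataset.truth.true_state_similarity.to_frame().to_csv(
        truth_dir / "true_state_similarity.csv", index=False, **kw
    )
    with open(truth_dir / "config.json", "w") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=2, sort_keys=True)
    return out
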