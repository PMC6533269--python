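"""End-to-end orchestration: model object, results object, run configuration.

:class:`SummedStateModel` bundles the inputs of one study — per-participant
state and person patterns, frequency ratings, trait ratings, text counts,
choice trials — whether generated synthetically or loaded from files.
``fit()`` executes the full analysis (pattern prep, optional voxel
selection, weighted-sum reconstruction with matched/unmatched scoring, the
five similarity measures, the state-vs-trait comparison table, choice and
RT models) and returns a :class:`SummedStateResults` with a
``summary()`` table and a machine-readable report.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    BehaviorModelResult,
    TrialFilterResult,
    UnfittedAccuracy,
    choice_model,
    coefficient_difference_ci,
    filter_trials,
    rt_model,
    trial_predictor,
    unfitted_choice_accuracy,
)
from .containers import (
    CSV_FLOAT_FORMAT,
    ChoiceTrialTable,
    CondensedSimilarity,
    PatternMatrix,
    WeightMatrix,
)
from .errors import ConfigurationError, ValidationError
from .inference import (
    GroupRsaResult,
    _residualize,
    disattenuate,
    group_level_rsa,
    item_correlation,
    model_bic,
    paired_correlation_difference,
    semi_partial,
    similarity_reliability,
)
from .io import (
    load_choice_csv,
    load_pattern_csv,
    load_similarity_csv,
    load_stopwords,
    load_weight_csv,
    write_similarity_csv,
    write_voxel_mask,
)
from .patterns import (
    VoxelMask,
    average_across_participants,
    select_reliable_voxels,
    zscore_pattern,
)
from .reconstruction import (
    ReconstructionResult,
    normalize_weights,
    reconstruct_targets,
    score_reconstruction,
)
from .similarity import (
    TraitSpace,
    neural_similarity,
    state_similarity,
    text_similarity,
    trait_pca,
    trait_similarity,
)
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

__all__ = [
    "AnalysisOptions",
    "RunConfig",
    "SummedStateModel",
    "SummedStateResults",
    "run_pipeline",
]

REPORT_SCHEMA_VERSION = 1


def _from_dict_strict(cls, d: dict):
    unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    return cls(**d)


@dataclasses.dataclass
class AnalysisOptions:
    """Tunable analysis settings, independent of where the data came from."""

    voxel_selection: bool = False
    n_selection_splits: int = 10
    n_reliability_splits: int = 20
    n_boot: int = 1000
    rt_floor_ms: float = 500.0
    fast_fraction_cutoff: float = 0.9
    fisher: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisOptions":
        return _from_dict_strict(cls, d)


@dataclasses.dataclass
class RunConfig:
    """One pipeline run: synthetic mode or files mode, plus analysis options."""

    mode: str = "synthetic"
    generator: GeneratorConfig | None = None
    paths: dict[str, str] | None = None
    analysis: AnalysisOptions = dataclasses.field(default_factory=AnalysisOptions)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"mode must be 'synthetic' or 'files'; got {self.mode!r}")
        if self.mode == "synthetic":
            if self.paths is not None:
                raise ConfigurationError("synthetic mode must not set paths")
            if self.generator is None:
                self.generator = GeneratorConfig()
        else:
            if self.generator is not None:
                raise ConfigurationError("files mode must not set a generator config")
            if not self.paths:
                raise ConfigurationError("files mode requires paths")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "generator": self.generator.to_dict() if self.generator else None,
            "paths": self.paths,
            "analysis": self.analysis.to_dict(),
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown RunConfig keys: {sorted(unknown)}")
        gen = d.get("generator")
        if gen is not None:
            d["generator"] = GeneratorConfig.from_dict(gen)
        ana = d.get("analysis")
        if isinstance(ana, dict):
            d["analysis"] = AnalysisOptions.from_dict(ana)
        elif ana is None:
            d.pop("analysis", None)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output_dir excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclasses.dataclass
class ComparisonRow:
    """One Table-style row: how one account fares on one similarity measure."""

    measure: str
    model: str
    coefficient: float
    p: float
    semi_partial: float
    semi_partial_p: float
    difference: Any  # p-value (float) or CI (tuple), on the better model's row
    difference_type: str | None
    bic: float


class SummedStateModel:
    """The summed-state analysis, bundled with its input data.

    Construct with :meth:`from_synthetic` (generator config) or
    :meth:`from_files` (paths to CSV inputs), then call :meth:`fit`.
    """

    def __init__(
        self,
        state_sets: Sequence[PatternMatrix],
        person_sets: Sequence[PatternMatrix],
        ratings: WeightMatrix,
        traits: pd.DataFrame,
        text_counts: pd.DataFrame | None = None,
        choices: ChoiceTrialTable | None = None,
        pairwise_ratings: CondensedSimilarity | None = None,
        stopwords: Sequence[str] = (),
        truth=None,
        provenance: dict | None = None,
    ) -> None:
        if not state_sets or not person_sets:
            raise ValidationError("state_sets and person_sets must be non-empty")
        self.state_sets = list(state_sets)
        self.person_sets = list(person_sets)
        self.ratings = ratings
        self.traits = traits
        self.text_counts = text_counts
        self.choices = choices
        self.pairwise_ratings = pairwise_ratings
        self.stopwords = list(stopwords)
        self.truth = truth
        self.provenance = provenance or {}

    @classmethod
    def from_synthetic(cls, config: GeneratorConfig | None = None) -> "SummedStateModel":
        config = config or GeneratorConfig()
        ds: SyntheticDataset = generate_dataset(config)
        return cls(
            state_sets=ds.state_sets,
            person_sets=ds.person_sets,
            ratings=ds.ratings,
            traits=ds.traits,
            text_counts=ds.text_counts,
            choices=ds.choices,
            pairwise_ratings=ds.pairwise_ratings,
            truth=ds.truth,
            provenance={"mode": "synthetic", "generator": config.to_dict()},
        )

    @classmethod
    def from_files(cls, paths: dict[str, str]) -> "SummedStateModel":
        """Load a study from CSV files.

        ``paths`` keys: ``state_patterns`` and ``person_patterns``
        (directories of per-participant pattern CSVs), ``ratings``,
        ``traits``, and optionally ``text_counts``, ``choices``,
        ``pairwise_ratings``, ``stopwords``.
        """
        required = {"state_patterns", "person_patterns", "ratings", "traits"}
        missing = required - set(paths)
        if missing:
            raise ConfigurationError(f"missing path keys: {sorted(missing)}")

        def load_dir(key: str) -> list[PatternMatrix]:
            folder = Path(paths[key])
            files = sorted(folder.glob("*.csv"))
            if not files:
                raise ConfigurationError(f"no CSV files in {folder}")
            return [load_pattern_csv(f) for f in files]

        traits = pd.read_csv(paths["traits"], index_col=0)
        return cls(
            state_sets=load_dir("state_patterns"),
            person_sets=load_dir("person_patterns"),
            ratings=load_weight_csv(paths["ratings"]),
            traits=traits,
            text_counts=(
                pd.read_csv(paths["text_counts"], index_col=0)
                if "text_counts" in paths
                else None
            ),
            choices=load_choice_csv(paths["choices"]) if "choices" in paths else None,
            pairwise_ratings=(
                load_similarity_csv(paths["pairwise_ratings"])
                if "pairwise_ratings" in paths
                else None
            ),
            stopwords=(
                load_stopwords(paths["stopwords"]) if "stopwords" in paths else ()
            ),
            provenance={"mode": "files", "paths": {k: str(v) for k, v in paths.items()}},
        )

    # ------------------------------------------------------------------ fit

    def fit(self, options: AnalysisOptions | None = None) -> "SummedStateResults":
        """Run the full analysis and return the results object."""
        opt = options or AnalysisOptions()

        # Step 1 — standardize within participant, average across participants.
        state_z = [zscore_pattern(m) for m in self.state_sets]
        person_z = [zscore_pattern(m) for m in self.person_sets]
        group_states = average_across_participants(state_z)

        voxel_mask: VoxelMask | None = None
        if opt.voxel_selection:
            voxel_mask = select_reliable_voxels(
                person_z, n_splits=opt.n_selection_splits, seed=opt.seed
            )
            group_states = group_states.subset_voxels(voxel_mask.selected)
            person_z = [m.subset_voxels(voxel_mask.selected) for m in person_z]

        # Steps 2-5 — dual-normalize ratings, reconstruct, score.
        weights = normalize_weights(self.ratings)
        recon = reconstruct_targets(group_states, weights)
        reconstruction = score_reconstruction(recon, person_z, fisher=opt.fisher)

        # Similarity construction.
        participant_sims = [neural_similarity(m) for m in person_z]
        mean_person = average_across_participants(person_z)
        neural_mean = neural_similarity(mean_person)
        state_pred = state_similarity(self.ratings)
        trait_space = trait_pca(self.traits)
        trait_pred = trait_similarity(trait_space)
        state_pred.aligned_with(trait_pred)
        state_pred.aligned_with(neural_mean)

        rows: list[ComparisonRow] = []
        rsa: dict[str, GroupRsaResult] = {}

        # --- neural measure: group level ---------------------------------
        rsa["states"] = group_level_rsa(participant_sims, state_pred)
        rsa["traits"] = group_level_rsa(participant_sims, trait_pred)
        resid_state = _residualize(state_pred.values, trait_pred.values)
        resid_trait = _residualize(trait_pred.values, state_pred.values)
        rsa["states_semi"] = group_level_rsa(participant_sims, resid_state)
        rsa["traits_semi"] = group_level_rsa(participant_sims, resid_trait)
        from scipy import stats as _st

        r_diff = rsa["states"].per_participant_r - rsa["traits"].per_participant_r
        t_diff, p_diff = _st.ttest_1samp(r_diff, 0.0)
        rows.append(
            ComparisonRow(
                "neural", "states",
                rsa["states"].mean_r, rsa["states"].p,
                rsa["states_semi"].mean_r, rsa["states_semi"].p,
                float(p_diff), "p",
                model_bic(neural_mean, state_pred),
            )
        )
        rows.append(
            ComparisonRow(
                "neural", "traits",
                rsa["traits"].mean_r, rsa["traits"].p,
                rsa["traits_semi"].mean_r, rsa["traits_semi"].p,
                None, None,
                model_bic(neural_mean, trait_pred),
            )
        )

        # --- item-level measures: rating judgments and text --------------
        item_dvs: dict[str, CondensedSimilarity] = {}
        if self.pairwise_ratings is not None:
            item_dvs["rating"] = self.pairwise_ratings
        if self.text_counts is not None:
            item_dvs["text"] = text_similarity(self.text_counts, self.stopwords)
        for measure, dv in item_dvs.items():
            dv.aligned_with(state_pred)
            r_s, p_s = item_correlation(dv, state_pred)
            r_t, p_t = item_correlation(dv, trait_pred)
            sr_s, srp_s = semi_partial(dv, state_pred, trait_pred)
            sr_t, srp_t = semi_partial(dv, trait_pred, state_pred)
            _, steiger_p = paired_correlation_difference(dv, state_pred, trait_pred)
            rows.append(
                ComparisonRow(measure, "states", r_s, p_s, sr_s, srp_s,
                              steiger_p, "p", model_bic(dv, state_pred))
            )
            rows.append(
                ComparisonRow(measure, "traits", r_t, p_t, sr_t, srp_t,
                              None, None, model_bic(dv, trait_pred))
            )

        # --- behavioral measures: choices and reaction times -------------
        behavior: dict[str, BehaviorModelResult] = {}
        trial_filter: TrialFilterResult | None = None
        unfitted: dict[str, UnfittedAccuracy] = {}
        if self.choices is not None:
            trial_filter = filter_trials(
                self.choices, opt.rt_floor_ms, opt.fast_fraction_cutoff
            )
            trials = trial_filter.table
            pred_s = trial_predictor(trials, state_pred)
            pred_t = trial_predictor(trials, trait_pred)
            for kind, fit_fn in (("choice", choice_model), ("rt", rt_model)):
                m_s = fit_fn(trials, {"states": pred_s})
                m_t = fit_fn(trials, {"traits": pred_t})
                m_b = fit_fn(trials, {"states": pred_s, "traits": pred_t})
                m_b.ci_difference = coefficient_difference_ci(
                    trials, pred_s, pred_t, kind=kind,
                    n_boot=opt.n_boot, seed=opt.seed,
                )
                behavior[f"{kind}_states"] = m_s
                behavior[f"{kind}_traits"] = m_t
                behavior[f"{kind}_both"] = m_b
                if kind == "choice":
                    coef = lambda m, k: m.exponentiated[k]  # odds
                else:
                    coef = lambda m, k: m.coefficients[k]
                measure = "choices" if kind == "choice" else "rt"
                rows.append(
                    ComparisonRow(
                        measure, "states",
                        coef(m_s, "states"), m_s.p["states"],
                        coef(m_b, "states"), m_b.p["states"],
                        m_b.ci_difference, "ci", m_s.bic,
                    )
                )
                rows.append(
                    ComparisonRow(
                        measure, "traits",
                        coef(m_t, "traits"), m_t.p["traits"],
                        coef(m_b, "traits"), m_b.p["traits"],
                        None, None, m_t.bic,
                    )
                )
            unfitted["states"] = unfitted_choice_accuracy(trials, state_pred)
            unfitted["traits"] = unfitted_choice_accuracy(trials, trait_pred)

        # --- disattenuation: share of reliable neural variance -----------
        reliability = similarity_reliability(
            participant_sims, n_splits=opt.n_reliability_splits, seed=opt.seed
        )
        r_states_item, _ = item_correlation(neural_mean, state_pred)
        r_traits_item, _ = item_correlation(neural_mean, trait_pred)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            share = {
                "states": disattenuate(r_states_item, reliability),
                "traits": disattenuate(r_traits_item, reliability),
            }

        comparisons = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        provenance = dict(self.provenance)
        provenance.update(
            {
                "schema_version": REPORT_SCHEMA_VERSION,
                "package_version": __version__,
                "analysis": opt.to_dict(),
                "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            }
        )
        return SummedStateResults(
            reconstruction=reconstruction,
            comparisons=comparisons,
            rsa=rsa,
            behavior=behavior,
            unfitted_accuracy=unfitted,
            trial_filter=trial_filter,
            reliability=reliability,
            reliable_variance_share=share,
            trait_space=trait_space,
            voxel_mask=voxel_mask,
            similarities={
                "neural_mean": neural_mean,
                "state": state_pred,
                "trait": trait_pred,
                **{k: v for k, v in item_dvs.items()},
            },
            participant_similarities=participant_sims,
            provenance=provenance,
        )


@dataclasses.dataclass
class SummedStateResults:
    """Fitted results: reconstruction scores, comparison table, behavior models."""

    reconstruction: ReconstructionResult
    comparisons: pd.DataFrame
    rsa: dict[str, GroupRsaResult]
    behavior: dict[str, BehaviorModelResult]
    unfitted_accuracy: dict[str, UnfittedAccuracy]
    trial_filter: TrialFilterResult | None
    reliability: float
    reliable_variance_share: dict[str, float]
    trait_space: TraitSpace
    voxel_mask: VoxelMask | None
    similarities: dict[str, CondensedSimilarity]
    participant_similarities: list[CondensedSimilarity]
    provenance: dict

    def summary(self) -> str:
        """Human-readable summary of the main results."""
        rec = self.reconstruction
        lines = [
            "Summed-state analysis",
            "=" * 70,
            f"Reconstruction (matched - unmatched r, {rec.n_participants} participants):",
            f"  mean difference = {rec.mean_difference:+.4f}   "
            f"t = {rec.group_t:.2f}, p = {rec.group_p:.3g}, d = {rec.cohens_d:.2f}",
            "",
            "Model comparison (summed states vs traits):",
        ]
        fmt = "  {:<8} {:<7} coef={:+.3f} (p={:.2g})  semi={:+.3f} (p={:.2g})  BIC={:.1f}"
        for _, row in self.comparisons.iterrows():
            lines.append(
                fmt.format(
                    row["measure"], row["model"], row["coefficient"], row["p"],
                    row["semi_partial"], row["semi_partial_p"], row["bic"],
                )
            )
        lines += [
            "",
            f"Neural reliability (split-half): {self.reliability:.3f}",
            "Reliable neural variance explained: "
            + ", ".join(
                f"{k} {100 * v:.1f}%" for k, v in self.reliable_variance_share.items()
            ),
        ]
        if self.unfitted_accuracy:
            lines.append(
                "Unfitted choice accuracy: "
                + ", ".join(
                    f"{k} {v.accuracy:.3f} ({v.n_ties} ties)"
                    for k, v in self.unfitted_accuracy.items()
                )
            )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Machine-readable report (JSON-serializable)."""

        def _row(r):
            d = dict(r)
            if isinstance(d.get("difference"), tuple):
                d["difference"] = list(d["difference"])
            return d

        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "reconstruction": self.reconstruction.to_dict(),
            "comparisons": [_row(r) for _, r in self.comparisons.iterrows()],
            "rsa": {k: v.to_dict() for k, v in self.rsa.items()},
            "behavior": {k: v.to_dict() for k, v in self.behavior.items()},
            "unfitted_accuracy": {
                k: dataclasses.asdict(v) for k, v in self.unfitted_accuracy.items()
            },
            "reliability": self.reliability,
            "reliable_variance_share": self.reliable_variance_share,
            "trait_explained_variance_pct": self.trait_space.explained_variance.tolist(),
        }
        if self.trial_filter is not None:
            report["trial_filter"] = {
                "n_participants_removed": self.trial_filter.n_participants_removed,
                "n_fast_trials_removed": self.trial_filter.n_fast_trials_removed,
                "n_trials_retained": self.trial_filter.n_trials_retained,
            }
        if self.voxel_mask is not None:
            report["voxel_selection"] = {
                "n_selected": len(self.voxel_mask.selected),
                "threshold_used": self.voxel_mask.threshold_used,
                "patternwise_reliability": self.voxel_mask.patternwise_reliability,
            }
        return report

    def save(self, out_dir: str | Path) -> Path:
        """Write report.json, the comparison table, and per-participant CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_report(), fh, indent=2, sort_keys=True,
                      default=_json_default)
        self.comparisons.to_csv(
            out / "comparisons.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
        rec = self.reconstruction
        pd.DataFrame(
            {
                "participant_id": rec.participant_ids,
                "matched": rec.per_participant_matched,
                "unmatched": rec.per_participant_unmatched,
                "difference": rec.per_participant_difference,
            }
        ).to_csv(out / "reconstruction_per_participant.csv", index=False,
                 float_format=CSV_FLOAT_FORMAT)
        for name, sim in self.similarities.items():
            write_similarity_csv(sim, out / f"similarity_{name}.csv")
        if self.voxel_mask is not None:
            write_voxel_mask(self.voxel_mask, out / "voxel_mask.txt")
        return out

    def plot_reconstruction(self, ax=None):
        """Matched vs unmatched mean correlations, one point per participant."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        rec = self.reconstruction
        n = rec.n_participants
        rng = np.random.default_rng(0)
        for k, (vals, color, label) in enumerate(
            (
                (rec.per_participant_matched, "tab:blue", "matched"),
                (rec.per_participant_unmatched, "tab:green", "unmatched"),
            )
        ):
            x = k + rng.uniform(-0.08, 0.08, size=n)
            ax.scatter(x, vals, s=18, alpha=0.6, color=color, label=label)
            ax.scatter([k], [vals.mean()], s=90, facecolors="none",
                       edgecolors="black", zorder=3)
        ax.set_xticks([0, 1], ["matched", "unmatched"])
        ax.set_ylabel("mean pattern correlation (r)")
        ax.legend(frameon=False)
        ax.set_title(
            f"diff = {rec.mean_difference:+.3f}, p = {rec.group_p:.2g}"
        )
        return ax


def run_pipeline(cfg: RunConfig) -> SummedStateResults:
    """Execute one configured run and (optionally) write its outputs."""
    if cfg.mode == "synthetic":
        model = SummedStateModel.from_synthetic(cfg.generator)
    else:
        model = SummedStateModel.from_files(cfg.paths)
    model.provenance["config_hash"] = cfg.config_hash()
    model.provenance["config"] = cfg.to_dict()
    results = model.fit(cfg.analysis)
    if cfg.output_dir:
        results.save(cfg.output_dir)
    return results
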