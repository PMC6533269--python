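"""Generator contracts: determinism, noise-free limits, graded signal."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import summedstates as ss
from summedstates.containers import CondensedSimilarity, PatternMatrix, WeightMatrix
from summedstates.errors import ConfigurationError
from summedstates.synthetic import (
    TRAIT_NAMES,
    SyntheticTruth,
    generate_behavior,
    generate_neural,
    generate_ratings,
    generate_text,
    generate_traits,
)


def _uniform_truth(n_targets=6, n_states=4, n_voxels=30) -> SyntheticTruth:
    """Hand-built truth with identical (uniform) weight rows for symmetry tests."""
    rng = np.random.default_rng(0)
    states = [f"state_{i:02d}" for i in range(n_states)]
    targets = [f"target_{i:02d}" for i in range(n_targets)]
    voxels = [f"v{i:04d}" for i in range(n_voxels)]
    w = np.full((n_targets, n_states), 1.0 / n_states)
    sp = rng.standard_normal((n_voxels, n_states))
    sp = (sp - sp.mean(0)) / sp.std(0, ddof=1)
    pp = sp @ w.T
    # uniform rows are perfectly correlated; similarity of constant rows is
    # undefined, so store a unit vector placeholder for ops that need labels
    n_pairs = n_targets * (n_targets - 1) // 2
    return SyntheticTruth(
        true_state_patterns=PatternMatrix(sp, states, voxels),
        true_weights=WeightMatrix(w, targets, states, normalized=True),
        true_person_patterns=PatternMatrix(pp, targets, voxels),
        true_trait_loadings=pd.DataFrame(
            rng.standard_normal((n_states, 13)), index=states, columns=TRAIT_NAMES
        ),
        true_state_similarity=CondensedSimilarity(np.ones(n_pairs), targets, "state"),
    )


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_voxels", 1),
            ("n_states", 0),
            ("participant_noise_sd", -0.1),
            ("rater_noise_sd", float("nan")),
            ("choice_slope", float("inf")),
            ("rt_base_ms", 0.0),
            ("dirichlet_concentration", 0.0),
        ],
    )
    def test_invalid_values_rejected(self, small_config, field, value):
        with pytest.raises(ConfigurationError):
            ss.GeneratorConfig(**{**small_config.to_dict(), field: value})

    def test_vocab_smaller_than_states_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            ss.GeneratorConfig(
                **{**small_config.to_dict(), "vocab_size": 5, "n_states": 8}
            )

    def test_unknown_key_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            ss.GeneratorConfig.from_dict({**small_config.to_dict(), "bogus": 1})

    def test_roundtrip(self, small_config):
        assert ss.GeneratorConfig.from_dict(small_config.to_dict()) == small_config


class TestDeterminism:
    def test_identical_config_gives_bit_identical_outputs(self, small_config):
        d1 = ss.generate_dataset(small_config)
        d2 = ss.generate_dataset(dataclasses.replace(small_config))
        assert np.array_equal(
            d1.truth.true_state_patterns.values, d2.truth.true_state_patterns.values
        )
        assert np.array_equal(d1.ratings.values, d2.ratings.values)
        assert np.array_equal(d1.traits.to_numpy(), d2.traits.to_numpy())
        assert np.array_equal(d1.text_counts.to_numpy(), d2.text_counts.to_numpy())
        assert d1.choices.frame.equals(d2.choices.frame)
        for a, b in zip(d1.person_sets, d2.person_sets):
            assert np.array_equal(a.values, b.values)

    def test_different_seed_changes_outputs(self, small_config):
        d1 = ss.generate_dataset(small_config)
        d2 = ss.generate_dataset(dataclasses.replace(small_config, seed=small_config.seed + 1))
        assert not np.array_equal(d1.ratings.values, d2.ratings.values)


class TestNeural:
    def test_dimensions_and_weight_normalization(self):
        cfg = ss.GeneratorConfig(
            n_voxels=1000, n_states=15, n_targets=60,
            n_state_participants=2, n_person_participants=2, seed=0,
        )
        truth, state_sets, person_sets = generate_neural(cfg)
        assert truth.true_state_patterns.values.shape == (1000, 15)
        assert truth.true_person_patterns.values.shape == (1000, 60)
        w = truth.true_weights.values
        assert w.shape == (60, 15)
        assert np.abs(w.sum(axis=1) - 1).max() < 1e-12
        assert len(state_sets) == 2 and len(person_sets) == 2

    def test_noise_free_factorization(self, small_config):
        cfg = dataclasses.replace(
            small_config, participant_noise_sd=0.0, residual_signal_sd=0.0
        )
        truth, state_sets, person_sets = generate_neural(cfg)
        expected = truth.true_state_patterns.values @ truth.true_weights.values.T
        assert np.allclose(truth.true_person_patterns.values, expected, atol=1e-12)
        for m in person_sets:
            assert np.allclose(m.values, expected, atol=1e-12)
        for m in state_sets:
            assert np.allclose(m.values, truth.true_state_patterns.values, atol=1e-12)


class TestRatings:
    def test_noise_free_equals_truth(self, small_config):
        cfg = dataclasses.replace(small_config, rater_noise_sd=0.0)
        truth, _, _ = generate_neural(cfg)
        ratings = generate_ratings(truth, cfg)
        assert np.allclose(ratings.values, truth.true_weights.values, atol=1e-15)

    def test_error_decreases_with_rater_count(self, small_config):
        maes = []
        for n_raters in (5, 50, 500):
            cfg = dataclasses.replace(small_config, n_raters=n_raters, rater_noise_sd=0.2)
            truth, _, _ = generate_neural(cfg)
            ratings = generate_ratings(truth, cfg)
            maes.append(np.abs(ratings.values - truth.true_weights.values).mean())
        assert maes[0] > maes[1] > maes[2]

    def test_uniform_weights_give_uniform_normalized_ratings(self, small_config):
        truth = _uniform_truth()
        cfg = dataclasses.replace(small_config, n_states=4, n_targets=6, n_raters=500,
                                  rater_noise_sd=0.05)
        ratings = generate_ratings(truth, cfg)
        normalized = ss.normalize_weights(ratings)
        assert np.allclose(normalized.values, 1.0 / 4, atol=0.02)

    def test_output_non_negative(self, small_config):
        cfg = dataclasses.replace(small_config, rater_noise_sd=5.0)
        truth, _, _ = generate_neural(cfg)
        assert np.all(generate_ratings(truth, cfg).values >= 0)


class TestTraits:
    def test_identity_loadings_relabel_log_weights(self, small_config):
        cfg = dataclasses.replace(small_config, trait_noise_sd=0.0)
        truth, _, _ = generate_neural(cfg)
        n_states = cfg.n_states
        loadings = np.eye(n_states, 13)
        traits = generate_traits(truth, cfg, loadings=loadings)
        logw = np.log(np.maximum(truth.true_weights.values, cfg.log_floor))
        assert np.allclose(traits.to_numpy()[:, :n_states], logw, atol=1e-12)

    def test_zero_noise_traits_track_state_similarity(self):
        # Deterministic traits carry state information, but the log transform,
        # the 3-component compression and the distance-vs-correlation metric
        # mismatch attenuate the item-level coupling; it stays reliably positive.
        rs = []
        for seed in range(20):
            cfg = ss.GeneratorConfig(
                n_voxels=100, n_states=15, n_targets=60,
                n_state_participants=2, n_person_participants=2,
                trait_noise_sd=0.0, seed=seed,
            )
            truth, _, _ = generate_neural(cfg)
            traits = generate_traits(truth, cfg)
            tsim = ss.trait_similarity(ss.trait_pca(traits))
            rs.append(ss.item_correlation(tsim, truth.true_state_similarity)[0])
        assert min(rs) > 0.0
        assert np.mean(rs) > 0.15

    def test_huge_noise_decouples_traits(self):
        rs = []
        for seed in range(20):
            cfg = ss.GeneratorConfig(
                n_voxels=100, n_states=15, n_targets=60,
                n_state_participants=2, n_person_participants=2,
                trait_noise_sd=1000.0, seed=seed,
            )
            truth, _, _ = generate_neural(cfg)
            traits = generate_traits(truth, cfg)
            tsim = ss.trait_similarity(ss.trait_pca(traits))
            rs.append(ss.item_correlation(tsim, truth.true_state_similarity)[0])
        assert abs(np.mean(rs)) < 0.1


class TestBehavior:
    def test_zero_slope_gives_chance_choice_rate(self, small_config):
        cfg = dataclasses.replace(
            small_config, choice_slope=0.0,
            n_behavior_participants=100, trials_per_participant=100, seed=5,
        )
        truth, _, _ = generate_neural(cfg)
        table = generate_behavior(truth.true_state_similarity, cfg)
        rate = (table.frame["choice"] == "A").mean()
        assert abs(rate - 0.5) < 0.02

    def test_steep_slope_gives_near_deterministic_choices(self, small_config):
        cfg = dataclasses.replace(
            small_config, choice_slope=500.0,
            n_behavior_participants=100, trials_per_participant=100, seed=5,
        )
        truth, _, _ = generate_neural(cfg)
        table = generate_behavior(truth.true_state_similarity, cfg)
        acc = ss.unfitted_choice_accuracy(table, truth.true_state_similarity)
        assert acc.accuracy > 0.99

    def test_rts_positive_and_finite(self, small_dataset):
        rt = small_dataset.choices.frame["rt_ms"]
        assert np.all(np.isfinite(rt)) and np.all(rt > 0)

    def test_fewer_than_three_targets_rejected(self, small_config):
        sim = CondensedSimilarity(np.array([0.5]), ["a", "b"], "state")
        with pytest.raises(ConfigurationError):
            generate_behavior(sim, small_config)

    def test_easy_trials_are_faster(self, small_config):
        cfg = dataclasses.replace(
            small_config, rt_sd_log=0.05, rt_sim_slope=-0.3,
            n_behavior_participants=50, trials_per_participant=100,
        )
        truth, _, _ = generate_neural(cfg)
        table = generate_behavior(truth.true_state_similarity, cfg)
        diff = np.abs(ss.trial_predictor(table, truth.true_state_similarity))
        rt = np.log(table.frame["rt_ms"].to_numpy())
        assert np.corrcoef(diff, rt)[0, 1] < -0.3


class TestText:
    def test_column_sums_equal_document_length(self, small_dataset, small_config):
        sums = small_dataset.text_counts.sum(axis=0)
        assert (sums == small_config.doc_length).all()

    def test_identical_weight_rows_give_identical_documents(self, small_config):
        truth = _uniform_truth()
        cfg = dataclasses.replace(
            small_config, n_states=4, n_targets=6, vocab_size=40, text_noise_sd=0.0
        )
        counts = generate_text(truth, cfg)
        first = counts.iloc[:, 0]
        for c in range(1, counts.shape[1]):
            assert np.array_equal(first.to_numpy(), counts.iloc[:, c].to_numpy())
        sim = ss.text_similarity(counts)
        assert np.allclose(sim.values, 0.0)

    def test_text_similarity_tracks_state_similarity(self):
        rs = []
        for seed in range(20):
            cfg = ss.GeneratorConfig(
                n_voxels=50, n_states=15, n_targets=60,
                n_state_participants=2, n_person_participants=2,
                vocab_size=300, doc_length=2000, seed=seed,
            )
            truth, _, _ = generate_neural(cfg)
            sim = ss.text_similarity(generate_text(truth, cfg))
            rs.append(ss.item_correlation(sim, truth.true_state_similarity)[0])
        assert np.mean(rs) > 0.3
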