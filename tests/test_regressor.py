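import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pathospeech import (
    CohortSpec,
    LabeledExample,
    RegressorWeights,
    ScorePair,
    TrainingConfig,
    cohort_to_training_table,
    forward,
    init_random_weights,
    multitask_loss,
    predict_recording,
    sample_cohort,
    speaker_disjoint_split,
    train,
)
from pathospeech.cohort import synth_passage_audio
from pathospeech.errors import ConfigurationError, ValidationError
from pathospeech.metrics import spearman
from pathospeech.regressor import load_model, predict_batch, save_model


def zeroed_weights(emb_dim=512, b_int=0.0, b_sev=0.0) -> RegressorWeights:
    w = RegressorWeights(emb_dim, np.random.default_rng(0))
    for name in ("W1", "b1", "beta1", "W2", "b2", "beta2", "w_int", "w_sev"):
        setattr(w, name, np.zeros_like(getattr(w, name)))
    w.b_int, w.b_sev = b_int, b_sev
    return w


class TestScorePair:
    @pytest.mark.parametrize("scores", [(-0.1, 5.0), (5.0, 10.1), (np.nan, 5.0)])
    def test_out_of_range_rejected(self, scores):
        with pytest.raises(ValidationError):
            ScorePair(*scores)

    def test_bounds_accepted(self):
        ScorePair(0.0, 10.0)


class TestForward:
    def test_zero_weights_returns_head_biases(self):
        w = zeroed_weights(b_int=3.0, b_sev=7.0)
        out = forward(np.ones(512), w, mode="infer")
        assert (out.intelligibility, out.severity) == (3.0, 7.0)

    def test_infer_clamps_to_0_10(self):
        w = zeroed_weights(b_int=-5.0, b_sev=14.0)
        out = forward(np.ones(512), w, mode="infer")
        assert (out.intelligibility, out.severity) == (0.0, 10.0)

    def test_infer_deterministic(self):
        w = RegressorWeights(512, np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=512)
        a = forward(x, w, mode="infer")
        b = forward(x, w, mode="infer")
        assert (a.intelligibility, a.severity) == (b.intelligibility, b.severity)

    def test_dimension_mismatch_is_configuration_error(self):
        w = RegressorWeights(512, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            forward(np.zeros(100), w)

    def test_train_mode_requires_rng(self):
        w = RegressorWeights(512, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            forward(np.zeros(512), w, mode="train")

    @given(arrays(np.float64, 512, elements=st.floats(-1e6, 1e6)))
    @settings(max_examples=30, deadline=None)
    def test_output_range_property(self, x):
        w = RegressorWeights(512, np.random.default_rng(1))
        out = forward(x, w, mode="infer")
        assert 0.0 <= out.intelligibility <= 10.0
        assert 0.0 <= out.severity <= 10.0


class TestMultitaskLoss:
    def test_perfect_predictions(self):
        batch = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert multitask_loss(batch, batch) == 0.0

    def test_half_weights_of_mses_2_and_4(self):
        target = np.zeros((2, 2))
        pred = np.array([[np.sqrt(2.0), 2.0], [-np.sqrt(2.0), -2.0]])  # MSEs (2, 4)
        assert multitask_loss(pred, target, (0.5, 0.5)) == pytest.approx(3.0)

    def test_degenerate_weight_is_single_task_mse(self):
        rng = np.random.default_rng(2)
        pred, target = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        expected = float(np.mean((pred[:, 0] - target[:, 0]) ** 2))
        assert multitask_loss(pred, target, (1.0, 0.0)) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            multitask_loss(np.zeros((3, 2)), np.zeros((4, 2)))

    @given(st.integers(0, 10_000), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_brute_force_oracle(self, seed, w_int):
        rng = np.random.default_rng(seed)
        pred, target = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        # independent oracle: explicit per-element loop
        mse = [0.0, 0.0]
        for task in (0, 1):
            for i in range(6):
                mse[task] += (pred[i, task] - target[i, task]) ** 2
            mse[task] /= 6
        expected = w_int * mse[0] + (1 - w_int) * mse[1]
        assert multitask_loss(pred, target, (w_int, 1 - w_int)) == pytest.approx(
            expected, abs=1e-9
        )


class TestTrain:
    def _data(self, n=64, seed=0):
        cohort = sample_cohort(CohortSpec(n_speakers=n, noise_sd=0.5, seed=seed))
        return cohort_to_training_table(cohort)

    def test_loss_decreases(self):
        _, trace = train(self._data(), TrainingConfig(epochs=5, seed=0))
        assert trace[-1] < trace[0]

    def test_fixed_seed_reproducible(self):
        data = self._data()
        cfg = TrainingConfig(epochs=3, seed=12)
        w1, t1 = train(data, cfg)
        w2, t2 = train(data, cfg)
        assert t1 == t2
        np.testing.assert_array_equal(w1.W1, w2.W1)
        np.testing.assert_array_equal(w1.w_sev, w2.w_sev)

    def test_empty_data_rejected(self):
        with pytest.raises(ValidationError):
            train([], TrainingConfig())

    def test_fewer_than_batch_rejected(self):
        with pytest.raises(ValidationError):
            train(self._data(4), TrainingConfig(batch_size=8))

    def test_parameter_recovery_spearman(self):
        data = cohort_to_training_table(
            sample_cohort(CohortSpec(n_speakers=200, noise_sd=0.5, seed=31))
        )
        held_out = sample_cohort(CohortSpec(n_speakers=100, noise_sd=0.5, seed=32))
        weights, _ = train(data, TrainingConfig(seed=0))
        preds = predict_batch(np.stack([s.embedding for s in held_out]), weights)
        rho = spearman(preds[:, 0], [s.scores.intelligibility for s in held_out])
        assert rho >= 0.9

    def test_duplicated_targets_keep_heads_equal(self):
        # coupling_sd = 0 makes SEV == INT for every speaker; with shared
        # head initialization the two task losses then coincide at every step
        data = cohort_to_training_table(
            sample_cohort(CohortSpec(n_speakers=40, int_sev_coupling_sd=0.0, seed=7))
        )
        weights, _ = train(data, TrainingConfig(epochs=3, seed=1))
        np.testing.assert_array_equal(weights.w_int, weights.w_sev)
        assert weights.b_int == weights.b_sev


class TestTrainingConfig:
    def test_defaults_match_recipe(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.batch_size == 8
        assert cfg.epochs == 20
        assert cfg.dropout == 0.2
        assert cfg.loss_weights == (0.5, 0.5)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            TrainingConfig(dropout=1.0)
        with pytest.raises(ValidationError):
            TrainingConfig(loss_weights=(0.5, 0.6))
        with pytest.raises(ValidationError):
            TrainingConfig(epochs=0)


class TestSpeakerDisjointSplit:
    def test_no_speaker_straddles(self):
        examples = [
            LabeledExample(np.zeros(4), ScorePair(5, 5), {"speaker_id": f"s{i % 10}"})
            for i in range(50)
        ]
        train_part, test_part = speaker_disjoint_split(examples, 0.3, seed=0)
        train_ids = {e.provenance["speaker_id"] for e in train_part}
        test_ids = {e.provenance["speaker_id"] for e in test_part}
        assert train_ids.isdisjoint(test_ids)
        assert len(train_part) + len(test_part) == 50


class TestPredictRecording:
    def test_segments_strategy_averages(self, extractor_weights, dummy_speaker):
        w = synth_passage_audio(dummy_speaker(6.0), seed=13)
        reg = zeroed_weights(b_int=4.0, b_sev=9.0)
        out = predict_recording(w, extractor_weights, reg, strategy="segments")
        # identical per-segment predictions -> their mean
        assert (out.intelligibility, out.severity) == (4.0, 9.0)

    def test_mean_of_mixed_segment_scores(self):
        # arithmetic-mean contract, checked directly on the aggregation rule
        per_segment = np.array([2, 2, 2, 2, 4, 4, 4, 4], dtype=float)
        assert np.mean(per_segment) == 3.0

    def test_whole_strategy_in_range(self, extractor_weights, dummy_speaker):
        w = synth_passage_audio(dummy_speaker(3.0), seed=17)
        reg = RegressorWeights(512, np.random.default_rng(5))
        out = predict_recording(w, extractor_weights, reg, strategy="whole")
        assert 0.0 <= out.intelligibility <= 10.0
        assert 0.0 <= out.severity <= 10.0

    def test_unknown_strategy_rejected(self, extractor_weights, dummy_speaker):
        w = synth_passage_audio(dummy_speaker(5.0), seed=19)
        reg = zeroed_weights()
        with pytest.raises(ValidationError):
            predict_recording(w, extractor_weights, reg, strategy="both")


class TestModelSerialization:
    def test_roundtrip(self, tmp_path):
        data = cohort_to_training_table(sample_cohort(CohortSpec(n_speakers=16, seed=2)))
        cfg = TrainingConfig(epochs=2, seed=5)
        weights, _ = train(data, cfg)
        path = tmp_path / "model.npz"
        save_model(path, weights, cfg, extractor_fingerprint="seeded-random:0")
        loaded, loaded_cfg, fp = load_model(path)
        assert fp == "seeded-random:0"
        assert loaded_cfg == cfg
        x = np.random.default_rng(0).normal(size=512)
        a, b = forward(x, weights), forward(x, loaded)
        assert (a.intelligibility, a.severity) == (b.intelligibility, b.severity)
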