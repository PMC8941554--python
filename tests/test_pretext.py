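import math

import numpy as np
import pytest

from sigcpc.data import EpochDataset
from sigcpc.pairs import batch_arrays, build_negative_pair, build_positive_pair, pair_batch
from sigcpc.pretext import (
    Encoder,
    PretextConfig,
    PretextModel,
    contextualize,
    encode,
    load_encoder,
    pair_probability,
    pretext_loss,
    save_encoder,
    train_pretext,
)


class TestPretextLoss:
    def test_chance_probability_gives_ln2(self):
        p = np.full(100, 0.5)
        y = (np.arange(100) % 2).astype(float)
        assert pretext_loss(p, y) == math.log(2.0)

    def test_hand_computed_two_sample_case(self):
        # -(1/2) * (ln 0.8 + ln 0.7)
        assert pretext_loss([0.8, 0.3], [1, 0]) == pytest.approx(
            -0.5 * (math.log(0.8) + math.log(0.7)), rel=1e-12
        )
        assert pretext_loss([0.8, 0.3], [1, 0]) == pytest.approx(0.2899, abs=5e-5)

    def test_perfect_probabilities_give_near_zero(self):
        assert pretext_loss([1.0, 0.0, 1.0], [1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pretext_loss([0.5, 0.5], [1])

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            pretext_loss([1.2], [1])


class TestEncoder:
    def test_output_width_is_d_z(self, small_dataset):
        enc = Encoder(64, (16, 16, 16, 16), d_z=10, rng=np.random.default_rng(0))
        z = encode(small_dataset.epochs[0], enc)
        assert z.shape == (10,)

    def test_infer_mode_deterministic(self, small_dataset):
        enc = Encoder(64, (16, 16, 16, 16), d_z=8, rng=np.random.default_rng(0))
        x = small_dataset.epochs[3]
        assert np.array_equal(encode(x, enc), encode(x, enc))

    def test_length_mismatch_rejected(self):
        enc = Encoder(64, (8, 8, 8, 8), d_z=4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="length"):
            encode(np.zeros(32), enc)

    def test_trained_encoder_separates_classes(self, trained_pretext, study_split):
        """Held-out same-class latents are on average more cosine-similar
        than different-class latents."""
        model, _ = trained_pretext
        _, test = study_split
        z = encode(test.epochs, model.encoder)
        z = z / np.linalg.norm(z, axis=1, keepdims=True)
        sim = z @ z.T
        same = test.labels[:, None] == test.labels[None, :]
        off_diag = ~np.eye(len(test), dtype=bool)
        assert sim[same & off_diag].mean() > sim[~same].mean()


class TestContextualize:
    def test_context_width_and_determinism(self):
        model = PretextModel(16, PretextConfig(hidden=(8, 8, 8, 8), d_z=5, d_c=7))
        z_seq = np.random.default_rng(0).normal(size=(4, 5))
        c = contextualize(z_seq, model)
        assert c.shape == (7,)
        assert np.array_equal(c, contextualize(z_seq, model))

    def test_wrong_sequence_length_rejected(self):
        model = PretextModel(16, PretextConfig(hidden=(8, 8, 8, 8), d_z=5, d_c=7))
        with pytest.raises(ValueError, match="sequence"):
            contextualize(np.zeros((3, 5)), model)


class TestPairProbability:
    def test_zero_predictors_give_exactly_half(self, small_dataset):
        model = PretextModel(64, PretextConfig(hidden=(8, 8, 8, 8), d_z=5, d_c=6))
        model.predictors.params["W"][:] = 0.0
        pair = build_positive_pair(small_dataset, 0, np.random.default_rng(0))
        assert pair_probability(pair, model) == 0.5

    def test_untrained_zero_predictor_model_scores_ln2_loss(self, small_dataset):
        model = PretextModel(64, PretextConfig(hidden=(8, 8, 8, 8), d_z=5, d_c=6))
        model.predictors.params["W"][:] = 0.0
        left, right, y = batch_arrays(pair_batch(small_dataset, 16, 0.5,
                                                 np.random.default_rng(1)))
        p, _ = model.forward(left, right, train=False)
        assert pretext_loss(p, y) == pytest.approx(math.log(2.0), rel=1e-12)

    def test_trained_model_ranks_positive_above_negative(self, trained_pretext, study_split):
        model, _ = trained_pretext
        _, test = study_split
        rng = np.random.default_rng(2)
        pos = np.mean([
            pair_probability(build_positive_pair(test, c, rng), model)
            for c in range(5) for _ in range(4)
        ])
        neg = np.mean([
            pair_probability(build_negative_pair(test, a, b, rng), model)
            for a in range(5) for b in range(5) if a != b
        ])
        assert pos > neg


class TestTraining:
    def test_zero_epochs_returns_untrained_model_and_empty_history(self, small_dataset):
        cfg = PretextConfig(epochs=0, iterations_per_epoch=10, batch_size=4,
                            hidden=(8, 8, 8, 8), d_z=5, d_c=5, eval_pairs=4, seed=0)
        model, history = train_pretext(small_dataset, small_dataset, cfg)
        assert history.loss == [] and history.test_accuracy == []

    def test_short_run_learns_and_history_is_finite(self, small_dataset):
        cfg = PretextConfig(epochs=2, iterations_per_epoch=40, batch_size=8,
                            hidden=(32, 16, 16, 16), d_z=8, d_c=8,
                            eval_pairs=16, seed=0)
        model, history = train_pretext(small_dataset, small_dataset, cfg)
        assert len(history.loss) == 2
        assert np.all(np.isfinite(history.loss))
        assert history.loss[-1] < math.log(2.0)  # below chance level

    def test_empty_dataset_rejected(self, small_dataset):
        empty = EpochDataset(np.zeros((0, 64)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="nonempty"):
            train_pretext(empty, small_dataset, PretextConfig(epochs=1))

    def test_infonce_variant_trains(self, small_dataset):
        cfg = PretextConfig(epochs=1, iterations_per_epoch=30, batch_size=8,
                            hidden=(16, 16, 16, 16), d_z=8, d_c=8,
                            eval_pairs=8, seed=1, loss="infonce")
        _, history = train_pretext(small_dataset, small_dataset, cfg)
        assert np.isfinite(history.loss[-1])


class TestEncoderCheckpoint:
    def test_round_trip_reproduces_latents(self, small_dataset, tmp_path):
        model = PretextModel(64, PretextConfig(hidden=(16, 16, 16, 16), d_z=6))
        path = tmp_path / "enc.npz"
        save_encoder(model, path, extra_meta={"seed": 0})
        loaded = load_encoder(path)
        probe = small_dataset.epochs[:5]
        assert np.array_equal(encode(probe, model.encoder), encode(probe, loaded))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises((IOError, FileNotFoundError)):
            load_encoder(tmp_path / "nope.npz")

    def test_checkpoint_contains_only_the_encoder(self, tmp_path):
        """The GRU and step predictors are pretext-only; the downstream task
        loads the encoder alone."""
        model = PretextModel(64, PretextConfig(hidden=(8, 8, 8, 8), d_z=4))
        path = tmp_path / "enc.npz"
        save_encoder(model, path)
        with np.load(path) as npz:
            assert not any("Wx" in k or "predictor" in k.lower() for k in npz.files)
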