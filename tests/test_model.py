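"""Model module: split arithmetic, architecture contracts, training
protocol, prediction mapping, and save/load round-trips."""

import numpy as np
import pytest

from cowave.errors import TrainingDivergedError, ValidationError
from cowave.model import (
    ModelConfig,
    TrainConfig,
    TrainedModel,
    build_model,
    load_model,
    predict_co,
    save_model,
    split_dataset,
    train_model,
    validation_size,
)


class TestSplitDataset:
    def test_split_counts_at_full_dataset_scale(self):
        # 9,446 screened segments at 80/20 -> 7,556 train and 1,890 test
        train, test = split_dataset(list(range(9446)), 0.8, seed=0)
        assert len(train) == 7556 and len(test) == 1890
        assert validation_size(len(train), 0.1) == 756

    def test_small_split(self):
        train, test = split_dataset(list(range(10)), 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2

    def test_disjoint_union_and_determinism(self):
        items = list(range(101))
        a_train, a_test = split_dataset(items, 0.8, seed=7)
        b_train, b_test = split_dataset(items, 0.8, seed=7)
        assert a_train == b_train and a_test == b_test
        assert sorted(a_train + a_test) == items
        c_train, _ = split_dataset(items, 0.8, seed=8)
        assert c_train != a_train

    def test_case_level_split_keeps_cases_together(self, tiny_segments):
        train, test = split_dataset(tiny_segments, 0.5, seed=3, split_level="case")
        assert {s.case_id for s in train}.isdisjoint({s.case_id for s in test})
        assert len(train) + len(test) == len(tiny_segments)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset([1], 0.8, seed=0)


class TestBuildModel:
    def test_forward_shape_contract(self, tiny_model_config, rng):
        model = build_model(tiny_model_config)
        out = model.forward(rng.normal(size=(4, 2, 64)))
        assert out.shape == (4,)

    def test_input_length_must_divide_by_pool_stages(self):
        with pytest.raises(ValidationError, match="divisible"):
            build_model(ModelConfig(input_length=2047))
        build_model(ModelConfig(input_length=64, depth=2, base_filters=2,
                                bottleneck_lstm_units=2, head_lstm_units=2))  # 64 = ok

    def test_encoder_decoder_shape_trace(self, rng):
        cfg = ModelConfig(input_length=32, depth=3, base_filters=2,
                          bottleneck_lstm_units=2, head_lstm_units=2, seed=0)
        model = build_model(cfg)
        model.forward(rng.normal(size=(1, 2, 32)))
        trace = model.last_trace
        # encoder level k: length input/2^k (pre-pool), channels base*2^k
        assert trace["encoder"] == [(2, 32), (4, 16), (8, 8)]
        assert trace["bottleneck"] == (16, 4)
        # decoder mirrors the encoder channels
        assert trace["decoder"] == [(8, 8), (4, 16), (2, 32)]

    def test_skip_concatenation_channel_arithmetic(self, tiny_model_config):
        model = build_model(tiny_model_config)
        f = tiny_model_config.base_filters
        for level, conv in enumerate(model.merge):  # stored top-down (deepest first)
            out_ch = f * 2 ** (tiny_model_config.depth - 1 - level)
            assert conv.w.shape == (out_ch, 2 * out_ch, tiny_model_config.kernel_size)

    def test_seeded_initialization_reproducible(self, tiny_model_config, rng):
        x = rng.normal(size=(2, 2, 64))
        a = build_model(tiny_model_config).forward(x).data
        b = build_model(tiny_model_config).forward(x).data
        assert np.array_equal(a, b)

    def test_wrong_input_shape_rejected(self, tiny_model_config, rng):
        model = build_model(tiny_model_config)
        with pytest.raises(ValidationError, match="expected input"):
            model.forward(rng.normal(size=(2, 2, 32)))


class TestTraining:
    def test_history_and_best_epoch(self, tiny_segments, tiny_model_config):
        model = build_model(tiny_model_config)
        trained = train_model(
            model, tiny_segments, TrainConfig(epochs=3, batch_size=16, seed=0)
        )
        assert len(trained.history["val_loss"]) == 3
        assert trained.best_epoch == int(np.argmin(trained.history["val_loss"])) + 1

    def test_loss_decreases(self, tiny_segments, tiny_model_config):
        model = build_model(tiny_model_config)
        trained = train_model(
            model, tiny_segments, TrainConfig(epochs=12, batch_size=16, seed=0)
        )
        losses = trained.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_empty_training_set_rejected(self, tiny_model_config):
        with pytest.raises(ValidationError, match="empty"):
            train_model(build_model(tiny_model_config), [], TrainConfig(epochs=1))

    def test_unnormalized_segments_rejected(self, tiny_sim, tiny_model_config):
        from cowave.preprocessing import segment_record
        from cowave.synthetic import generate_case

        segs = segment_record(generate_case(tiny_sim), window=64)
        with pytest.raises(ValidationError, match="normalized"):
            train_model(build_model(tiny_model_config), segs, TrainConfig(epochs=1))

    def test_non_finite_loss_aborts_with_diagnostic(self, tiny_segments, tiny_model_config):
        import dataclasses

        bad = [
            dataclasses.replace(s, ppg_in=np.full_like(s.ppg_in, np.nan))
            for s in tiny_segments[:8]
        ]
        model = build_model(tiny_model_config)
        with pytest.raises(TrainingDivergedError, match="non-finite"):
            train_model(model, bad, TrainConfig(epochs=1, batch_size=8, seed=0))

    def test_per_epoch_resample_mode_runs(self, tiny_segments, tiny_model_config):
        trained = train_model(
            build_model(tiny_model_config), tiny_segments,
            TrainConfig(epochs=2, batch_size=16, val_mode="per_epoch_resample", seed=0),
        )
        assert len(trained.history["val_loss"]) == 2


@pytest.fixture(scope="module")
def trained(tiny_segments, tiny_model_config):
    model = build_model(tiny_model_config)
    return train_model(model, tiny_segments, TrainConfig(epochs=2, batch_size=16, seed=0))


class TestPrediction:
    def test_outputs_in_l_min_and_order_preserved(self, trained, tiny_segments):
        preds = predict_co(trained, tiny_segments)
        assert preds.shape == (len(tiny_segments),)
        again = predict_co(trained, tiny_segments)
        assert np.array_equal(preds, again)  # inference determinism

    def test_scaled_output_maps_through_inverse_label(self, trained, tiny_segments):
        from cowave.model import _stack_inputs

        X = _stack_inputs(tiny_segments[:4], trained.config.channels)
        scaled = trained.model.predict(X)
        preds = predict_co(trained, tiny_segments[:4])
        assert np.allclose(preds, 2.0 + 8.0 * scaled)

    def test_length_mismatch_rejected(self, trained, tiny_segments):
        import dataclasses

        seg = tiny_segments[0]
        short = dataclasses.replace(seg, ppg_raw=seg.ppg_raw[:32], ppg_in=seg.ppg_in[:32],
                                    art_raw=seg.art_raw[:32], art_in=seg.art_in[:32])
        with pytest.raises(ValidationError, match="length"):
            predict_co(trained, [short])

    def test_save_load_round_trip(self, trained, tiny_segments, tmp_path):
        before = predict_co(trained, tiny_segments)
        save_model(trained, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        after = predict_co(loaded, tiny_segments)
        assert np.allclose(before, after, atol=1e-6)
        assert loaded.best_epoch == trained.best_epoch
        assert loaded.config == trained.config

    def test_truncated_save_rejected(self, trained, tmp_path):
        save_model(trained, tmp_path / "m")
        weights = np.load(tmp_path / "m" / "weights.npz")
        keep = {k: weights[k] for k in weights.files[:-2]}
        np.savez(tmp_path / "m" / "weights.npz", **keep)
        with pytest.raises(ValidationError, match="truncated|arrays"):
            load_model(tmp_path / "m")

    def test_missing_config_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            load_model(tmp_path / "nope")
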