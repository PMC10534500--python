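"""Particle-size CNN: schedule, shapes, splits, training behaviour."""

import numpy as np
import pytest

from dissomap.cnn import (
    CNNArchitecture,
    CNNTrainConfig,
    InvalidArchitectureError,
    build_particle_cnn,
    learning_rate_at_epoch,
    load_cnn,
    save_cnn,
    split_train_val,
    train_particle_cnn,
    predict_size,
)
from dissomap.unmix import ConcentrationMap


def blob_maps(n, size_px, shape=(31, 31), seed=0):
    """Toy maps with square blobs of a given pixel size (high contrast)."""
    rng = np.random.default_rng(seed)
    maps = np.zeros((n,) + shape)
    for i in range(n):
        for _ in range(max(1, 60 // size_px**2)):
            r = rng.integers(0, shape[0] - size_px)
            c = rng.integers(0, shape[1] - size_px)
            maps[i, r : r + size_px, c : c + size_px] = 100.0
    return maps


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [(1, 0.001), (10, 0.001), (11, 0.0009),
                                                (21, 0.00081), (100, 0.001 * 0.9**9)])
    def test_staircase_values(self, epoch, expected):
        assert learning_rate_at_epoch(epoch, CNNTrainConfig()) == pytest.approx(expected)

    def test_closed_form_at_every_epoch(self):
        cfg = CNNTrainConfig()
        for e in range(1, 101):
            assert learning_rate_at_epoch(e, cfg) == pytest.approx(
                0.001 * 0.9 ** ((e - 1) // 10)
            )


class TestArchitecture:
    @pytest.mark.parametrize("shape", [(31, 31), (48, 48)])
    def test_both_map_geometries_accepted(self, shape):
        model = build_particle_cnn(shape)
        assert model.input_shape == shape
        assert model.n_parameters > 0

    def test_parameter_count_deterministic(self):
        a = build_particle_cnn((31, 31), seed=1)
        b = build_particle_cnn((31, 31), seed=2)
        assert a.n_parameters == b.n_parameters

    def test_same_seed_same_weights(self):
        a = build_particle_cnn((31, 31), seed=5)
        b = build_particle_cnn((31, 31), seed=5)
        for la, lb in zip(a.layers, b.layers):
            if hasattr(la, "params"):
                for k in la.params:
                    assert np.array_equal(la.params[k], lb.params[k])

    def test_overpooling_rejected(self):
        arch = CNNArchitecture(2, (4, 4), (3, 3), 0.0, (6, 6), 8)
        with pytest.raises(InvalidArchitectureError):
            build_particle_cnn((31, 31), arch)

    def test_tiny_input_rejected(self):
        with pytest.raises(InvalidArchitectureError):
            build_particle_cnn((6, 6))


class TestSplit:
    def test_96_16_partition(self):
        records = [(i, f"S{i % 28}") for i in range(112)]
        train, val = split_train_val(records, 16, seed=0, strata_key=lambda r: r[1])
        assert len(train) == 96 and len(val) == 16
        assert set(train) | set(val) == set(records)
        assert set(train) & set(val) == set()

    def test_stratified_coverage(self):
        records = [(i, f"S{i % 28}") for i in range(112)]
        _, val = split_train_val(records, 16, seed=3, strata_key=lambda r: r[1])
        # 16 held-out records come from 16 distinct strata
        assert len({k for _, k in val}) == 16

    def test_deterministic(self):
        records = list(range(40))
        a = split_train_val(records, 8, seed=9, strata_key=lambda r: r % 5)
        b = split_train_val(records, 8, seed=9, strata_key=lambda r: r % 5)
        assert a == b

    def test_n_val_too_large(self):
        with pytest.raises(ValueError, match="n_val"):
            split_train_val(list(range(10)), 10, seed=0, strata_key=lambda r: r)


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_problem(self):
        maps = np.concatenate([blob_maps(12, 2, seed=1), blob_maps(12, 6, seed=2)])
        labels = np.array([45.0] * 12 + [150.0] * 12)
        return maps, labels

    def test_loss_decreases_on_contrasty_data(self, toy_problem):
        maps, labels = toy_problem
        model = build_particle_cnn((31, 31), seed=0)
        cfg = CNNTrainConfig(max_epochs=15, seed=0)
        hist = train_particle_cnn(model, maps, labels, cfg=cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == 15

    def test_training_deterministic_with_zero_dropout(self, toy_problem):
        maps, labels = toy_problem
        arch = CNNArchitecture(dropout_rate=0.0)
        outs = []
        for _ in range(2):
            model = build_particle_cnn((31, 31), arch, seed=4)
            train_particle_cnn(model, maps, labels, cfg=CNNTrainConfig(max_epochs=5, seed=4))
            outs.append(model.predict(maps))
        assert np.array_equal(outs[0], outs[1])

    def test_predictions_within_clip_bounds(self, toy_problem):
        maps, labels = toy_problem
        model = build_particle_cnn((31, 31), seed=0)
        train_particle_cnn(model, maps, labels, cfg=CNNTrainConfig(max_epochs=3, seed=0))
        preds = model.predict(maps)
        assert np.all(np.isfinite(preds))
        assert np.all((preds >= 22.5) & (preds <= 200.0))

    def test_predict_size_shape_guard(self, toy_problem):
        maps, labels = toy_problem
        model = build_particle_cnn((31, 31), seed=0)
        train_particle_cnn(model, maps, labels, cfg=CNNTrainConfig(max_epochs=2, seed=0))
        cmap = ConcentrationMap(maps[0], "HPMC", 40.0)
        assert 22.5 <= predict_size(model, cmap) <= 200.0
        with pytest.raises(ValueError, match="shape"):
            predict_size(model, np.zeros((48, 48)))

    def test_validation_loss_recorded_every_5_epochs(self, toy_problem):
        maps, labels = toy_problem
        model = build_particle_cnn((31, 31), seed=0)
        hist = train_particle_cnn(
            model, maps[:16], labels[:16], maps[16:], labels[16:],
            CNNTrainConfig(max_epochs=11, seed=0),
        )
        assert sorted(hist.val_loss) == [5, 10]

    def test_save_load_roundtrip(self, toy_problem, tmp_path):
        maps, labels = toy_problem
        model = build_particle_cnn((31, 31), seed=0)
        train_particle_cnn(model, maps, labels, cfg=CNNTrainConfig(max_epochs=2, seed=0))
        path = tmp_path / "cnn.npz"
        save_cnn(model, path)
        loaded = load_cnn(path)
        assert np.array_equal(loaded.predict(maps), model.predict(maps))
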