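"""Architecture contracts, training schedule semantics, and grid search."""

import numpy as np
import pytest

from fourmc import encode_dataset, generate
from fourmc.model import (
    ArchitectureSpec,
    Conv4mCClassifier,
    GridSpec,
    ShapeError,
    TrainConfig,
    build_model,
    count_parameters,
    grid_search,
    predict,
    train,
)
from fourmc.synthetic import SyntheticSpec


def hand_counted_default_params() -> int:
    """Parameter count of the default architecture on (41, 5) input,
    accumulated layer by layer with plain arithmetic."""
    total = 5 * 5 * 32 + 32        # conv1: k*c_in*f + f
    total += 32 + 32               # group norm 1 gamma/beta
    total += 5 * 32 * 32 + 32      # conv2
    total += 32 + 32               # group norm 2
    # positions: 41 -> pool -> 21 -> pool -> 11; flatten 11*32 = 352
    total += 352 * 32 + 32         # dense hidden
    total += 32 * 1 + 1            # output unit
    return total


class TestArchitecture:
    def test_parameter_count_matches_hand_computation(self):
        assert count_parameters(ArchitectureSpec(), (41, 5)) \
            == hand_counted_default_params() == 17441

    def test_default_model_emits_one_probability_per_record(self):
        net = build_model(input_shape=(41, 5))
        p = net.predict_proba(np.random.default_rng(0).random((7, 41, 5)))
        assert p.shape == (7,)
        assert np.all((p >= 0) & (p <= 1))

    def test_builds_on_smallest_inscope_input(self):
        net = build_model(input_shape=(55, 1))  # MMI feature vector
        assert net.predict_proba(np.zeros((2, 55, 1))).shape == (2,)

    def test_filters_groups_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureSpec(filters=30, groups=4)

    def test_too_short_for_conv_chain(self):
        arch = ArchitectureSpec(n_blocks=5, kernel_size=14, pool_stride=4)
        with pytest.raises(ShapeError, match="positions"):
            build_model(arch, (41, 5))

    @pytest.mark.parametrize("bad", [dict(dropout=1.0), dict(n_blocks=0),
                                     dict(l2_weight=-1e-4)])
    def test_invalid_spec_fields(self, bad):
        with pytest.raises(ValueError):
            ArchitectureSpec(**bad)


class TestTrainConfig:
    def test_patience_bounded_by_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, early_stopping_patience=11)

    def test_defaults_follow_reference_schedule(self):
        cfg = TrainConfig()
        assert (cfg.learning_rate, cfg.momentum, cfg.epochs,
                cfg.batch_size, cfg.early_stopping_patience) \
            == (0.005, 0.95, 100, 32, 30)


@pytest.fixture(scope="module")
def toy_xy():
    ds = generate(SyntheticSpec(n_per_class=60, motif="CCCC",
                                p_pos=1.0, p_neg=0.0, seed=21))
    return encode_dataset(ds, "BE")


class TestTraining:
    def test_separable_data_reaches_high_training_accuracy(self, toy_xy):
        X, y = toy_xy
        est = Conv4mCClassifier(epochs=40, early_stopping_patience=40,
                                random_state=0).fit(X, y)
        assert (est.predict(X) == y).mean() >= 0.95

    def test_identical_labels_converge_to_class_prior(self, toy_xy):
        X, _ = toy_xy
        y = np.ones(len(X))
        est = Conv4mCClassifier(epochs=15, early_stopping_patience=15,
                                random_state=0).fit(X, y)
        assert est.predict_proba(X)[:, 1].mean() > 0.9

    def test_patience_one_with_flat_validation_stops_after_two_epochs(self, toy_xy):
        X, y = toy_xy
        # a vanishing learning rate freezes the weights, so the validation
        # loss is exactly constant: improvement at epoch 1 (from +inf), none
        # at epoch 2 -> stop
        est = Conv4mCClassifier(learning_rate=1e-300, epochs=50,
                                early_stopping_patience=1,
                                random_state=0).fit(X, y)
        assert est.history_["epoch"] == [1, 2]

    def test_checkpoint_restores_best_validation_epoch(self, toy_xy):
        X, y = toy_xy
        Xv, yv = X[::3], y[::3]
        mask = np.ones(len(X), bool)
        mask[::3] = False
        est = Conv4mCClassifier(epochs=25, early_stopping_patience=25,
                                random_state=1)
        est.fit(X[mask], y[mask], X_val=Xv, y_val=yv)
        restored_val_loss = est.network_.loss(Xv, yv)
        assert restored_val_loss == pytest.approx(
            min(est.history_["val_loss"]), abs=1e-12)

    def test_full_batch_descent_loss_nonincreasing(self, toy_xy):
        # gradient descent (no dropout, no L2, no momentum, full batch)
        # on separable data: the training loss should fall monotonically
        # up to tiny numerical slack
        X, y = toy_xy
        est = Conv4mCClassifier(dropout=0.0, l2_weight=0.0, momentum=0.0,
                                learning_rate=0.005, batch_size=len(X),
                                epochs=20, early_stopping_patience=20,
                                random_state=0).fit(X, y)
        losses = np.array(est.history_["train_loss"])
        assert losses[-1] < losses[0]
        assert np.all(np.diff(losses) < 1e-3)

    def test_prediction_determinism_and_range(self, toy_xy):
        X, y = toy_xy
        est = Conv4mCClassifier(epochs=5, early_stopping_patience=5,
                                random_state=0).fit(X, y)
        p1 = est.predict_proba(X[:10])[:, 1]
        p2 = est.predict_proba(np.vstack([X[:10], X[:10]]))[:, 1]
        assert np.array_equal(p1, p2[:10])
        assert np.array_equal(p2[:10], p2[10:])  # duplicated rows agree
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_shape_mismatch_at_predict(self, toy_xy):
        X, y = toy_xy
        est = Conv4mCClassifier(epochs=2, early_stopping_patience=2,
                                random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="expects"):
            est.predict(np.zeros((3, 40, 25)))

    def test_functional_train_and_predict_wrappers(self, toy_xy):
        X, y = toy_xy
        est = train(X[:80], y[:80], X[80:], y[80:],
                    cfg=TrainConfig(epochs=3, early_stopping_patience=3))
        p = predict(est, X[:5])
        assert p.shape == (5,) and np.all((p >= 0) & (p <= 1))

    def test_save_load_roundtrip(self, toy_xy, tmp_path):
        X, y = toy_xy
        est = Conv4mCClassifier(epochs=3, early_stopping_patience=3,
                                random_state=0).fit(X, y)
        est.save(tmp_path / "m.npz")
        loaded = Conv4mCClassifier.load(tmp_path / "m.npz")
        assert np.array_equal(est.predict_proba(X[:8]),
                              loaded.predict_proba(X[:8]))

    def test_sklearn_get_set_params(self):
        est = Conv4mCClassifier()
        params = est.get_params()
        assert params["filters"] == 32 and params["momentum"] == 0.95
        est.set_params(filters=16, epochs=7)
        assert est.filters == 16 and est.epochs == 7


class TestGridSearch:
    def test_full_grid_cardinality(self):
        assert GridSpec().n_combinations() == 5 * 8 * 10 * 2 * 2 * 5 == 8000

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GridSpec(filters=[])

    def test_two_point_grid_returns_argmax(self):
        ds = generate(SyntheticSpec(n_per_class=30, motif="CCCC",
                                    p_pos=1.0, p_neg=0.0, seed=4))
        grid = GridSpec(conv_layers=[1], filters=[8], kernel_size=[3, 5],
                        pool_size=[2], pool_stride=[2], dropout=[0.2])
        cfg = TrainConfig(epochs=4, early_stopping_patience=4, batch_size=16)
        best, table = grid_search(grid, ds, "BE", cfg=cfg, k=3,
                                  base_arch=ArchitectureSpec(groups=4, filters=8))
        assert len(table) == 2
        assert best.kernel_size == int(table.loc[table.mcc.idxmax(), "kernel_size"])

    def test_degenerate_combinations_are_skipped_not_fatal(self):
        ds = generate(SyntheticSpec(n_per_class=15, motif="CC",
                                    p_pos=1.0, p_neg=0.0, seed=5))
        grid = GridSpec(conv_layers=[1, 5], filters=[8], kernel_size=[14],
                        pool_size=[4], pool_stride=[4], dropout=[0.2])
        cfg = TrainConfig(epochs=2, early_stopping_patience=2, batch_size=16)
        best, table = grid_search(grid, ds, "BE", cfg=cfg, k=3,
                                  base_arch=ArchitectureSpec(groups=4, filters=8))
        # 5 blocks of pool-stride 4 annihilate a 41-nt input; only the
        # single-block combination survives
        assert len(table) == 1
        assert best.n_blocks == 1
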