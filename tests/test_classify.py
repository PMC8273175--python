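"""Architectures, patient splits, balancing, early stopping, training."""

import numpy as np
import pytest

from spectroseize import classify as cl
from spectroseize.classify import ArchitectureSpec, SplitPlan, TrainConfig


class TestArchitectures:
    def test_resnet50_is_23_5_million_parameters(self):
        model = cl.build_model(ArchitectureSpec("resnet50"))
        assert round(model.n_params / 1e6, 1) == 23.5

    def test_resnet18_is_11_2_million_parameters(self):
        assert round(cl.trainable_parameter_count("resnet18") / 1e6, 1) == 11.2

    def test_cnn6_is_1_5_million_parameters_at_full_input(self):
        assert round(cl.cnn_param_count("cnn6") / 1e6, 1) == 1.5

    @pytest.mark.parametrize("arch", ["cnn6", "cnn7", "cnn12"])
    def test_built_cnn_matches_closed_form_count(self, arch):
        """Layer-wise arithmetic oracle vs the constructed network."""
        spec = ArchitectureSpec(arch, (32, 32, 3))
        model = cl.build_model(spec)
        assert model.n_params == cl.cnn_param_count(arch, (32, 32, 3))

    @pytest.mark.parametrize("arch", cl.ARCHITECTURE_IDS)
    def test_output_layer_has_two_units(self, arch):
        model = cl.build_model(ArchitectureSpec(arch, (32, 32, 3)))
        assert model.output_units == 2

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("cnn99")

    def test_resnet_forward_is_out_of_scope(self):
        with pytest.raises(NotImplementedError):
            cl.build_model(ArchitectureSpec("resnet50")).forward(None)


class TestFolds:
    def test_113_patients_split_72_18_23(self):
        patients = [f"P{i:03d}" for i in range(113)]
        plans = cl.make_folds(patients, seed=0)
        assert len(plans) == 5
        for plan in plans:
            assert (len(plan.train), len(plan.validation), len(plan.test)) == (72, 18, 23)
            assert set(plan.train) | set(plan.validation) | set(plan.test) == set(patients)
            cl.verify_disjoint(plan)  # no patient leakage

    def test_folds_are_seed_reproducible(self):
        patients = [f"P{i}" for i in range(50)]
        assert cl.make_folds(patients, seed=5) == cl.make_folds(patients, seed=5)
        assert cl.make_folds(patients, seed=5) != cl.make_folds(patients, seed=6)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            cl.make_folds(["P0", "P1"], seed=0)

    def test_leakage_guard_rejects_overlap(self):
        with pytest.raises(ValueError, match="leakage"):
            SplitPlan(0, ("P0", "P1"), ("P1",), ("P2",))


class TestBinSplits:
    def _patients(self, n=105, seed=0):
        rng = np.random.default_rng(seed)
        return [(f"P{i:03d}", int(rng.integers(10, 5000))) for i in range(n)]

    def test_bins_are_equal_and_count_ordered(self):
        bins = cl.assign_bins(self._patients())
        assert [len(b) for b in bins] == [21] * 5

    def test_each_size_draws_equally_from_bins(self):
        plans = cl.make_bin_splits(self._patients(), seed=1)
        bins = cl.assign_bins(self._patients())
        bin_of = {p: i for i, b in enumerate(bins) for p in b}
        for plan, size in zip(plans, range(10, 81, 10)):
            assert len(plan.train) == size
            counts = np.bincount([bin_of[p] for p in plan.train], minlength=5)
            assert list(counts) == [size // 5] * 5

    def test_training_sets_are_nested(self):
        plans = cl.make_bin_splits(self._patients(), seed=2)
        for small, large in zip(plans, plans[1:]):
            assert set(small.train) <= set(large.train)

    @pytest.mark.parametrize("n_train,expected", [(10, 5), (20, 5), (30, 6), (40, 8),
                                                  (50, 10), (80, 16)])
    def test_validation_sizes(self, n_train, expected):
        assert cl.validation_size(n_train) == expected

    def test_validation_sets_match_rule_and_are_disjoint(self):
        plans = cl.make_bin_splits(self._patients(), seed=3)
        for plan, size in zip(plans, range(10, 81, 10)):
            assert len(plan.validation) == cl.validation_size(size)
            assert not set(plan.validation) & set(plan.train)

    def test_indivisible_sizes_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            cl.make_bin_splits(self._patients(), sizes=[12], seed=0)
        with pytest.raises(ValueError, match="bins"):
            cl.assign_bins(self._patients(104))


class TestBalance:
    def test_majority_downsampled_to_minority(self, rng):
        out = cl.balance_training({"nsz": list(range(1000)), "sz": list(range(400))}, rng)
        assert len(out["nsz"]) == len(out["sz"]) == 400

    def test_already_balanced_unchanged(self, rng):
        items = {"nsz": [1, 2, 3], "sz": [4, 5, 6]}
        out = cl.balance_training(items, rng)
        assert out == items

    def test_downsampling_is_seed_reproducible(self):
        items = {"nsz": list(range(100)), "sz": list(range(30))}
        a = cl.balance_training(items, np.random.default_rng(7))
        b = cl.balance_training(items, np.random.default_rng(7))
        assert a == b

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError, match="sz"):
            cl.balance_training({"nsz": [1], "sz": []}, rng)


class TestEarlyStopping:
    def test_constant_accuracy_stops_at_epoch_11(self):
        assert cl.stopping_epoch([80.0] * 70) == 11

    def test_steady_improvement_runs_all_70_epochs(self):
        accs = [50 + 0.5 * e for e in range(70)]
        assert cl.stopping_epoch(accs) == 70

    def test_sub_threshold_improvement_does_not_reset_window(self):
        # +0.05 pp per epoch is below the 0.1 pp improvement threshold
        accs = [80 + 0.05 * e for e in range(70)]
        assert cl.stopping_epoch(accs) == 11

    def test_late_improvement_extends_training(self):
        accs = [80.0] * 9 + [85.0] + [85.0] * 60
        assert cl.stopping_epoch(accs) == 20


class TestTraining:
    def _toy_data(self, n=120, side=16, seed=0):
        """Two trivially separable image classes (bright vs dark corner)."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        x = rng.uniform(-1, 1, size=(n, side, side, 3)).astype(np.float32) * 0.1
        x[y == 1, :8, :8, :] += 0.8
        return x, y

    def test_separable_toy_problem_learns(self):
        x, y = self._toy_data(240)
        model = cl.build_model(ArchitectureSpec("cnn6", (16, 16, 3)), seed=0)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=20, seed=0)
        hist = cl.train(model, x[:180], y[:180], x[180:], y[180:], cfg)
        assert hist["val_accuracy_pct"].iloc[-1] >= 95.0
        assert len(hist) <= 20

    def test_best_epoch_weights_are_restored(self):
        x, y = self._toy_data(120)
        model = cl.build_model(ArchitectureSpec("cnn6", (16, 16, 3)), seed=1)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=12, seed=1)
        hist = cl.train(model, x[:90], y[:90], x[90:], y[90:], cfg)
        proba = model.predict_proba(x[90:])
        acc = 100.0 * (proba.argmax(axis=1) == y[90:]).mean()
        assert acc == pytest.approx(hist["val_accuracy_pct"].max(), abs=1e-9)

    def test_label_shuffled_training_stays_at_chance(self):
        """Sanity null: no signal means ~50% validation accuracy."""
        rng = np.random.default_rng(4)
        x, y = self._toy_data(300, seed=4)
        y = rng.permutation(y)
        model = cl.build_model(ArchitectureSpec("cnn6", (16, 16, 3)), seed=4)
        cfg = TrainConfig(learning_rate=1e-4, max_epochs=12, seed=4)
        hist = cl.train(model, x[:200], y[:200], x[200:], y[200:], cfg)
        assert 30.0 <= hist["val_accuracy_pct"].iloc[-1] <= 70.0

    def test_empty_sets_rejected(self):
        model = cl.build_model(ArchitectureSpec("cnn6", (16, 16, 3)))
        with pytest.raises(ValueError):
            cl.train(model, np.zeros((0, 8, 8, 3)), np.zeros(0, dtype=int),
                     np.zeros((1, 8, 8, 3)), np.zeros(1, dtype=int))

    def test_default_learning_rates_follow_architecture(self):
        cfg = TrainConfig()
        assert cfg.resolve_lr("cnn6") == 1e-6
        assert cfg.resolve_lr("resnet50") == 1e-7
        assert TrainConfig(learning_rate=5e-4).resolve_lr("cnn6") == 5e-4
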