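import copy

import numpy as np
import pytest

from dendrimod import modnet as mn
from dendrimod import synthetic_data as sd


def small_stack(seed=0, sizes=(2, 10), head="modulated_output_unit"):
    return mn.build_stack(list(sizes), head=head, seed=seed)


class TestForwardModulated:
    def test_identity_reduces_to_relu(self):
        layer = mn.ModulatedLayerParams(W=np.eye(2))
        layer.register_task("t")
        np.testing.assert_array_equal(
            mn.forward_modulated(layer, "t", np.array([1.0, -2.0])),
            [1.0, 0.0],
        )

    def test_zero_gain_passes_bias(self):
        layer = mn.ModulatedLayerParams(W=np.eye(2), b=np.array([-1.0, 2.0]))
        layer.register_task("t", np.zeros(2))
        np.testing.assert_array_equal(
            mn.forward_modulated(layer, "t", np.array([9.0, -9.0])),
            [0.0, 2.0],
        )

    def test_hand_evaluated_example(self):
        layer = mn.ModulatedLayerParams(
            W=np.array([[1.0, 1.0], [1.0, -1.0]]),
            x_shift=np.array([0.5, 0.5]),
            b=np.array([0.0, -0.5]),
        )
        layer.register_task("t", np.array([2.0, 1.0]))
        np.testing.assert_allclose(
            mn.forward_modulated(layer, "t", np.array([2.0, 1.0])),
            [5.0, 0.0],
        )

    def test_unregistered_task(self):
        layer = mn.ModulatedLayerParams(W=np.eye(2))
        with pytest.raises(mn.TaskUnknownError):
            mn.forward_modulated(layer, "missing", np.zeros(2))

    def test_shape_error(self):
        layer = mn.ModulatedLayerParams(W=np.eye(2))
        layer.register_task("t")
        with pytest.raises(ValueError):
            mn.forward_modulated(layer, "t", np.zeros(3))

    def test_reparameterization_identity(self, rng):
        # sigma(g(Wx - xs) + b) == sigma(gWx + (b - g*xs))
        W = rng.normal(size=(5, 3))
        xs = rng.normal(size=5)
        b = rng.normal(size=5)
        g = rng.normal(size=5)
        layer_a = mn.ModulatedLayerParams(W=W, x_shift=xs, b=b)
        layer_a.register_task("t", g)
        layer_b = mn.ModulatedLayerParams(W=W, x_shift=np.zeros(5),
                                          b=b - g * xs)
        layer_b.register_task("t", g)
        for _ in range(1000):
            x = rng.normal(size=3)
            a = mn.forward_modulated(layer_a, "t", x)
            bb = mn.forward_modulated(layer_b, "t", x)
            assert np.max(np.abs(a - bb)) < 1e-10


class TestTraining:
    def test_zero_lr_is_noop(self, dataset_2d):
        stack = small_stack(seed=1)
        untrained = small_stack(seed=1)
        for t in dataset_2d.task_ids:
            untrained.register_task(t)
        base = mn.evaluate(untrained, dataset_2d)
        cfg = mn.TrainConfig(learning_rate=0.0, epochs=1, batch_size=32,
                             seed=0)
        _, table = mn.train_multitask(stack, dataset_2d, cfg,
                                      tasks=dataset_2d.task_ids[:8])
        merged = table.merge(base, on=["task_id", "split"],
                            suffixes=("_a", "_b"))
        np.testing.assert_array_equal(merged.accuracy_a, merged.accuracy_b)

    def test_learns_above_chance(self, dataset_2d):
        stack = small_stack(seed=2, sizes=(2, 30))
        cfg = mn.TrainConfig(learning_rate=0.3, epochs=30, batch_size=64,
                             seed=2, momentum=0.9)
        _, table = mn.train_multitask(stack, dataset_2d, cfg,
                                      tasks=dataset_2d.task_ids[:4])
        acc = table[table.split == "test"].accuracy.mean()
        assert acc > 0.7

    def test_degenerate_task_rejected(self, dataset_2d):
        broken = copy.deepcopy(dataset_2d)
        t = broken.task_ids[0]
        broken.labels[t][broken.train_idx] = 1
        stack = small_stack()
        cfg = mn.TrainConfig(epochs=1, batch_size=16, seed=0)
        with pytest.raises(mn.DegenerateTaskError):
            mn.train_multitask(stack, broken, cfg, tasks=[t])

    def test_seeded_training_bit_reproducible(self, dataset_2d):
        results = []
        for _ in range(2):
            stack = small_stack(seed=3)
            cfg = mn.TrainConfig(learning_rate=0.2, epochs=2, batch_size=32,
                                 seed=5)
            stack, _ = mn.train_multitask(stack, dataset_2d, cfg,
                                          tasks=dataset_2d.task_ids[:4])
            results.append(stack)
        a, b = results
        np.testing.assert_array_equal(a.layers[0].W, b.layers[0].W)
        for t in dataset_2d.task_ids[:4]:
            np.testing.assert_array_equal(a.layers[0].gains[t],
                                          b.layers[0].gains[t])


class TestFreezingAndTransfer:
    def test_shared_params_bit_identical(self, dataset_2d):
        stack = small_stack(seed=4)
        cfg = mn.TrainConfig(learning_rate=0.2, epochs=3, batch_size=32,
                             seed=1)
        mn.train_multitask(stack, dataset_2d, cfg,
                           tasks=dataset_2d.task_ids[:4])
        W_before = stack.layers[0].W.copy()
        xs_before = np.array(stack.layers[0].x_shift, copy=True)
        b_before = np.array(stack.layers[0].b, copy=True)
        tcfg = mn.TrainConfig(
            learning_rate=0.2, epochs=3, batch_size=32, seed=2,
            frozen_parameter_set=frozenset({"W", "x_shift", "b"}),
        )
        mn.train_transfer(stack, dataset_2d, tcfg,
                          tasks=dataset_2d.task_ids[4:8])
        np.testing.assert_array_equal(stack.layers[0].W, W_before)
        np.testing.assert_array_equal(stack.layers[0].x_shift, xs_before)
        np.testing.assert_array_equal(stack.layers[0].b, b_before)

    def test_transfer_changes_only_new_gains(self, dataset_2d):
        stack = small_stack(seed=4)
        cfg = mn.TrainConfig(learning_rate=0.2, epochs=2, batch_size=32,
                             seed=1)
        mn.train_multitask(stack, dataset_2d, cfg,
                           tasks=dataset_2d.task_ids[:4])
        old_gains = {t: stack.layers[0].gains[t].copy()
                     for t in dataset_2d.task_ids[:4]}
        tcfg = mn.TrainConfig(
            learning_rate=0.2, epochs=2, batch_size=32, seed=2,
            frozen_parameter_set=frozenset({"W", "x_shift", "b"}),
        )
        mn.train_transfer(stack, dataset_2d, tcfg,
                          tasks=dataset_2d.task_ids[4:6])
        for t, g in old_gains.items():
            np.testing.assert_array_equal(stack.layers[0].gains[t], g)
        assert not np.allclose(
            stack.layers[0].gains[dataset_2d.task_ids[4]], 1.0)

    def test_unfrozen_shared_params_config_error(self, dataset_2d):
        stack = small_stack()
        cfg = mn.TrainConfig(frozen_parameter_set=frozenset({"W"}))
        with pytest.raises(mn.ConfigError):
            mn.train_transfer(stack, dataset_2d, cfg)

    def test_zero_transfer_tasks(self, dataset_2d):
        stack = small_stack(seed=4)
        W_before = stack.layers[0].W.copy()
        cfg = mn.TrainConfig(
            frozen_parameter_set=frozenset({"W", "x_shift", "b"}))
        _, table = mn.train_transfer(stack, dataset_2d, cfg, tasks=[])
        assert len(table) == 0
        np.testing.assert_array_equal(stack.layers[0].W, W_before)

    def test_readout_transfer_touches_only_new_rows(self, dataset_2d):
        stack = small_stack(seed=5, head="task_specific_readouts")
        cfg = mn.TrainConfig(learning_rate=0.2, epochs=2, batch_size=32,
                             seed=3)
        mn.train_multitask(stack, dataset_2d, cfg,
                           tasks=dataset_2d.task_ids[:3])
        old = {t: stack.head.w[t].copy() for t in dataset_2d.task_ids[:3]}
        tcfg = mn.TrainConfig(
            learning_rate=0.2, epochs=2, batch_size=32, seed=4,
            frozen_parameter_set=frozenset({"W", "x_shift", "b"}),
        )
        mn.train_transfer(stack, dataset_2d, tcfg,
                          tasks=dataset_2d.task_ids[3:5])
        for t, w in old.items():
            np.testing.assert_array_equal(stack.head.w[t], w)
        assert dataset_2d.task_ids[3] in stack.head.w


class TestReadoutBaseline:
    def test_single_task_trains(self, dataset_2d):
        cfg = mn.TrainConfig(learning_rate=0.3, epochs=20, batch_size=16,
                             seed=0, momentum=0.9)
        _, table = mn.readout_baseline([2, 20], dataset_2d, cfg,
                                       tasks=dataset_2d.task_ids[:1])
        assert table[table.split == "test"].accuracy.iloc[0] > 0.6


class TestDecisionBoundaryNormals:
    def test_matches_finite_difference(self, rng):
        stack = mn.build_stack([4, 8, 6], seed=6)
        stack.register_task("t")
        # make gains non-trivial
        stack.layers[0].gains["t"] = rng.uniform(0.5, 1.5, 8)
        stack.layers[1].gains["t"] = rng.uniform(0.5, 1.5, 6)
        x = rng.normal(size=4)
        normal = mn.decision_boundary_normals(stack, "t", x)
        eps = 1e-6
        fd = np.empty(4)
        for i in range(4):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            zp = stack.head.logits("t", _hidden(stack, "t", xp))
            zm = stack.head.logits("t", _hidden(stack, "t", xm))
            fd[i] = (zp[0] - zm[0]) / (2 * eps)
        np.testing.assert_allclose(normal, fd, atol=1e-5)

    def test_in_row_space_of_first_layer(self, rng):
        stack = mn.build_stack([5, 9, 7], seed=7)
        stack.register_task("t")
        x = rng.normal(size=5)
        normal = mn.decision_boundary_normals(stack, "t", x)
        W1 = stack.layers[0].W
        coef, *_ = np.linalg.lstsq(W1.T, normal, rcond=None)
        assert np.linalg.norm(W1.T @ coef - normal) < 1e-8

    def test_all_inactive_gives_zero(self):
        stack = mn.build_stack([3, 4], seed=8)
        stack.register_task("t")
        stack.layers[0].b = np.full(4, -100.0)
        normal = mn.decision_boundary_normals(stack, "t", np.zeros(3) + 0.1)
        np.testing.assert_array_equal(normal, np.zeros(3))

    def test_kink_raises(self):
        stack = mn.build_stack([2, 3], seed=9)
        stack.register_task("t")
        with pytest.raises(mn.NondifferentiablePointError):
            mn.decision_boundary_normals(stack, "t", np.zeros(2))

    def test_linear_network_closed_form(self):
        # all units forced active: normal = g2*W2^T diag(g1) w_head ... via
        # chain; with gains 1 and large positive biases it is w_head@W
        stack = mn.build_stack([3, 4], seed=10)
        stack.register_task("t")
        stack.layers[0].b = np.full(4, 100.0)
        x = np.array([0.1, -0.2, 0.3])
        normal = mn.decision_boundary_normals(stack, "t", x)
        expected = (stack.head.gains["t"] * stack.head.w) @ stack.layers[0].W
        np.testing.assert_allclose(normal, expected, atol=1e-12)


def _hidden(stack, task, x):
    H = x[None, :]
    for layer in stack.layers:
        g = layer.gains[task]
        P = g * (H @ layer.W.T - layer.x_shift) + layer.b
        H = np.maximum(P, 0.0)
    return H


class TestPersistence:
    def test_roundtrip(self, tmp_path, dataset_2d):
        stack = small_stack(seed=11)
        cfg = mn.TrainConfig(learning_rate=0.2, epochs=1, batch_size=32,
                             seed=0)
        mn.train_multitask(stack, dataset_2d, cfg,
                           tasks=dataset_2d.task_ids[:2])
        stack.save(tmp_path / "stack.npz")
        loaded = mn.ModulatedStack.load(tmp_path / "stack.npz")
        np.testing.assert_array_equal(loaded.layers[0].W, stack.layers[0].W)
        t = dataset_2d.task_ids[0]
        np.testing.assert_array_equal(loaded.layers[0].gains[t],
                                      stack.layers[0].gains[t])
        X = dataset_2d.X[:5]
        np.testing.assert_allclose(loaded.forward(t, X),
                                   stack.forward(t, X))
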