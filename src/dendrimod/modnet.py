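"""Gain-modulated feedforward networks with task-specific parameters.

A layer computes ``relu(g_t * (W x - x_shift) + b)`` where ``W``,
``x_shift`` and ``b`` are shared across tasks and ``g_t`` is a per-task
gain vector.  Stacks of such layers are trained on binary multitask
problems with one of two heads:

* a single *modulated output unit* whose own gain is task-specific while
  its weights are shared, or
* *task-specific readouts*, one linear readout per task on top of an
  unmodulated trunk (the standard multitask baseline).

Training is plain (optionally momentum) SGD on a sigmoid binary
cross-entropy, with manual gradients, balanced batches, and a freezing
contract: any parameter group named in ``TrainConfig.frozen_parameter_set``
is bit-identical before and after training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import rng_for
from .synthetic_data import MultitaskDataset, balanced_batches

__all__ = [
    "ConfigError",
    "DegenerateTaskError",
    "ModulatedLayerParams",
    "ModulatedStack",
    "NondifferentiablePointError",
    "TaskUnknownError",
    "TrainConfig",
    "build_stack",
    "decision_boundary_normals",
    "evaluate",
    "forward_modulated",
    "readout_baseline",
    "train_multitask",
    "train_transfer",
]


class TaskUnknownError(KeyError):
    """Raised when a gain is requested for an unregistered task."""


class DegenerateTaskError(ValueError):
    """Raised when a task has a single class in its training split."""


class NondifferentiablePointError(ValueError):
    """Raised when a pre-activation sits exactly on a rectifier kink."""


class ConfigError(ValueError):
    """Raised on invalid training configuration."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


class ModulatedLayerParams:
    """Shared ``(W, x_shift, b)`` plus per-task gain vectors.

    ``x_shift`` and ``b`` may each be a scalar (shared across units) or a
    length-``k_out`` vector.
    """

    def __init__(
        self,
        W: np.ndarray,
        x_shift: float | np.ndarray = 0.0,
        b: float | np.ndarray = 0.0,
        gains: dict[str, np.ndarray] | None = None,
    ):
        self.W = np.asarray(W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2D (k_out x k_in)")
        self.x_shift = self._check_broadcast(x_shift, "x_shift")
        self.b = self._check_broadcast(b, "b")
        self.gains: dict[str, np.ndarray] = {}
        for task, g in (gains or {}).items():
            self.register_task(task, g)

    def _check_broadcast(self, v, name):
        v = np.asarray(v, dtype=float)
        if v.ndim == 0:
            return v
        if v.shape != (self.k_out,):
            raise ValueError(f"{name} must be scalar or length k_out={self.k_out}")
        return v

    @property
    def k_out(self) -> int:
        return self.W.shape[0]

    @property
    def k_in(self) -> int:
        return self.W.shape[1]

    def register_task(self, task_id: str, gain: np.ndarray | None = None) -> None:
        if gain is None:
            gain = np.ones(self.k_out)
        gain = np.asarray(gain, dtype=float)
        if gain.shape != (self.k_out,):
            raise ValueError(f"gain must have length k_out={self.k_out}")
        self.gains[task_id] = gain

    def gain(self, task_id: str) -> np.ndarray:
        try:
            return self.gains[task_id]
        except KeyError:
            raise TaskUnknownError(
                f"task {task_id!r} not registered on this layer"
            ) from None


def forward_modulated(
    layer: ModulatedLayerParams, task_id: str, x: np.ndarray
) -> np.ndarray:
    """``relu(g_t * (W x - x_shift) + b)`` for a single input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (layer.k_in,):
        raise ValueError(f"input length {x.shape} != k_in={layer.k_in}")
    g = layer.gain(task_id)
    pre = g * (layer.W @ x - layer.x_shift) + layer.b
    return np.maximum(pre, 0.0)


# -- heads -------------------------------------------------------------------


class ModulatedOutputUnit:
    """Single linear unit with shared weights and a per-task scalar gain."""

    kind = "modulated_output_unit"

    def __init__(self, w: np.ndarray, x_shift: float = 0.0, b: float = 0.0):
        self.w = np.asarray(w, dtype=float)
        self.x_shift = float(x_shift)
        self.b = float(b)
        self.gains: dict[str, float] = {}

    def register_task(self, task_id: str, gain: float = 1.0) -> None:
        self.gains[task_id] = float(gain)

    def gain(self, task_id: str) -> float:
        try:
            return self.gains[task_id]
        except KeyError:
            raise TaskUnknownError(
                f"task {task_id!r} not registered on the output unit"
            ) from None

    def logits(self, task_id: str, H: np.ndarray) -> np.ndarray:
        return self.gain(task_id) * (H @ self.w - self.x_shift) + self.b


class TaskSpecificReadouts:
    """One independent linear readout per task (baseline head)."""

    kind = "task_specific_readouts"

    def __init__(self, k_in: int):
        self.k_in = k_in
        self.w: dict[str, np.ndarray] = {}
        self.b: dict[str, float] = {}

    def register_task(
        self, task_id: str, rng: np.random.Generator | None = None
    ) -> None:
        if rng is None:
            self.w[task_id] = np.zeros(self.k_in)
        else:
            self.w[task_id] = rng.normal(size=self.k_in) / np.sqrt(self.k_in)
        self.b[task_id] = 0.0

    def logits(self, task_id: str, H: np.ndarray) -> np.ndarray:
        if task_id not in self.w:
            raise TaskUnknownError(f"no readout for task {task_id!r}")
        return H @ self.w[task_id] + self.b[task_id]


class ModulatedStack:
    """Ordered modulated layers plus exactly one head."""

    def __init__(self, layers: Sequence[ModulatedLayerParams], head):
        self.layers = list(layers)
        self.head = head
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if a.k_out != b.k_in:
                raise ValueError("adjacent layer dimensions do not chain")
        if self.layers:
            head_k = head.w.shape[0] if hasattr(head, "w") and not isinstance(
                head.w, dict) else head.k_in
            if head_k != self.layers[-1].k_out:
                raise ValueError("head input dimension does not chain")

    @property
    def task_modulated(self) -> bool:
        return self.head.kind == "modulated_output_unit"

    def register_task(self, task_id: str, rng=None) -> None:
        """Register a task, keeping existing task parameters if present."""
        if self.task_modulated:
            for layer in self.layers:
                if task_id not in layer.gains:
                    layer.register_task(task_id)
            if task_id not in self.head.gains:
                self.head.register_task(task_id)
        else:
            if task_id not in self.head.w:
                self.head.register_task(task_id, rng=rng)

    # -- forward -----------------------------------------------------------

    def _layer_gain(self, layer: ModulatedLayerParams, task_id: str):
        if self.task_modulated:
            return layer.gain(task_id)
        return np.ones(layer.k_out)

    def forward(self, task_id: str, X: np.ndarray, with_cache: bool = False):
        """Batch forward; returns logits (N,) and optionally layer caches."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        caches = []
        H = X
        for layer in self.layers:
            g = self._layer_gain(layer, task_id)
            S = H @ layer.W.T - layer.x_shift
            P = g * S + layer.b
            mask = P > 0
            H_next = np.where(mask, P, 0.0)
            if with_cache:
                caches.append({"X": H, "S": S, "mask": mask, "g": g})
            H = H_next
        logits = self.head.logits(task_id, H)
        if with_cache:
            return logits, H, caches
        return logits

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        arch: dict = {"head": self.head.kind, "n_layers": len(self.layers)}
        for l, layer in enumerate(self.layers):
            arrays[f"layer{l}.W"] = layer.W
            arrays[f"layer{l}.x_shift"] = np.asarray(layer.x_shift)
            arrays[f"layer{l}.b"] = np.asarray(layer.b)
            for task, g in layer.gains.items():
                arrays[f"layer{l}.gain.{task}"] = g
        if self.head.kind == "modulated_output_unit":
            arrays["head.w"] = self.head.w
            arrays["head.x_shift"] = np.asarray(self.head.x_shift)
            arrays["head.b"] = np.asarray(self.head.b)
            for task, g in self.head.gains.items():
                arrays[f"head.gain.{task}"] = np.asarray(g)
        else:
            arch["head_k_in"] = self.head.k_in
            for task in self.head.w:
                arrays[f"head.w.{task}"] = self.head.w[task]
                arrays[f"head.b.{task}"] = np.asarray(self.head.b[task])
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(arch, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModulatedStack":
        path = Path(path)
        arch = json.loads(path.with_suffix(".json").read_text())
        with np.load(path) as data:
            layers = []
            for l in range(arch["n_layers"]):
                layer = ModulatedLayerParams(
                    W=data[f"layer{l}.W"],
                    x_shift=data[f"layer{l}.x_shift"],
                    b=data[f"layer{l}.b"],
                )
                prefix = f"layer{l}.gain."
                for key in data.files:
                    if key.startswith(prefix):
                        layer.register_task(key[len(prefix):], data[key])
                layers.append(layer)
            if arch["head"] == "modulated_output_unit":
                head = ModulatedOutputUnit(
                    w=data["head.w"],
                    x_shift=float(data["head.x_shift"]),
                    b=float(data["head.b"]),
                )
                for key in data.files:
                    if key.startswith("head.gain."):
                        head.register_task(key[len("head.gain."):],
                                           float(data[key]))
            else:
                head = TaskSpecificReadouts(arch["head_k_in"])
                for key in data.files:
                    if key.startswith("head.w."):
                        task = key[len("head.w."):]
                        head.w[task] = data[key]
                        head.b[task] = float(data[f"head.b.{task}"])
        return cls(layers, head)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_stack(
    layer_sizes: Sequence[int],
    head: str = "modulated_output_unit",
    seed: int = 0,
    *,
    per_unit_shift: bool = False,
) -> ModulatedStack:
    """Fan-in-scaled Gaussian weights, zero shifts/biases, gains at 1.

    ``layer_sizes`` is ``[n_in, h1, ..., hL]`` (the head adds the single
    output).  Default: per-layer scalar shared x-shift and per-unit bias.
    """
    rng = rng_for(seed, "build_stack")
    layers = []
    for k_in, k_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        W = rng.normal(size=(k_out, k_in)) / np.sqrt(k_in)
        x_shift = np.zeros(k_out) if per_unit_shift else 0.0
        layers.append(ModulatedLayerParams(W=W, x_shift=x_shift,
                                           b=np.zeros(k_out)))
    k_last = layer_sizes[-1]
    if head == "modulated_output_unit":
        head_obj = ModulatedOutputUnit(
            w=rng.normal(size=k_last) / np.sqrt(k_last))
    elif head == "task_specific_readouts":
        head_obj = TaskSpecificReadouts(k_last)
    else:
        raise ConfigError(f"unknown head type {head!r}")
    return ModulatedStack(layers, head_obj)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

_PARAM_GROUPS = {"W", "x_shift", "b", "gains", "head"}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    epochs: int = 20
    batch_size: int = 96
    seed: int = 0
    frozen_parameter_set: frozenset = frozenset()
    momentum: float = 0.0
    n_batches_per_epoch: int | None = None

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")
        unknown = set(self.frozen_parameter_set) - _PARAM_GROUPS
        if unknown:
            raise ConfigError(f"unknown frozen parameter groups: {unknown}")


def _check_tasks_trainable(data: MultitaskDataset, tasks: Sequence[str]):
    for t in tasks:
        y = data.labels[t][data.train_idx]
        if len(np.unique(y)) < 2:
            raise DegenerateTaskError(
                f"task {t!r} has a single class in the training split"
            )


class _Trainer:
    """Internal SGD driver over a ModulatedStack."""

    def __init__(self, stack: ModulatedStack, cfg: TrainConfig):
        self.stack = stack
        self.cfg = cfg
        self.frozen = set(cfg.frozen_parameter_set)
        self.vel: dict = {}

    def _backward_task(self, task_id, X, y):
        """Gradients of the mean BCE over one task's sub-batch."""
        stack, n = self.stack, len(y)
        logits, H, caches = stack.forward(task_id, X, with_cache=True)
        p = 1.0 / (1.0 + np.exp(-logits))
        dz = (p - y) / n  # (N,)

        grads: dict = {}
        # head backward
        head = stack.head
        if head.kind == "modulated_output_unit":
            g_h = head.gain(task_id)
            s_h = H @ head.w - head.x_shift
            grads[("head", "gain", task_id)] = float(dz @ s_h)
            ds = dz * g_h
            grads[("head", "w")] = H.T @ ds
            grads[("head", "x_shift")] = -float(ds.sum())
            grads[("head", "b")] = float(dz.sum())
            dH = np.outer(ds, head.w)
        else:
            grads[("head", "w", task_id)] = H.T @ dz
            grads[("head", "b", task_id)] = float(dz.sum())
            dH = np.outer(dz, head.w[task_id])

        for l in range(len(stack.layers) - 1, -1, -1):
            layer, cache = stack.layers[l], caches[l]
            dP = dH * cache["mask"]
            if stack.task_modulated:
                grads[(l, "gain", task_id)] = (dP * cache["S"]).sum(axis=0)
            dS = dP * cache["g"]
            db = dP.sum(axis=0)
            grads[(l, "b")] = db if np.ndim(layer.b) else float(db.sum())
            dxs = -dS.sum(axis=0)
            grads[(l, "x_shift")] = (
                dxs if np.ndim(layer.x_shift) else float(dxs.sum())
            )
            grads[(l, "W")] = dS.T @ cache["X"]
            if l > 0:
                dH = dS @ layer.W
        return grads

    @staticmethod
    def _group(key) -> str:
        """Freezing group of a gradient key.

        Per-task gains (layer or head) belong to ``gains``; shared head
        parameters and per-task readouts belong to ``head``; trunk shared
        parameters keep their own names.
        """
        owner, name = key[0], key[1]
        if name == "gain":
            return "gains"
        if owner == "head":
            return "head"
        return name

    def _apply(self, grads: dict):
        lr, mom = self.cfg.learning_rate, self.cfg.momentum
        stack = self.stack
        for key, g in grads.items():
            if self._group(key) in self.frozen:
                continue
            if mom > 0:
                self.vel[key] = mom * self.vel.get(key, 0.0) + g
                g = self.vel[key]
            step = lr * g
            owner, name = key[0], key[1]
            if owner == "head":
                head = stack.head
                if name == "gain":
                    head.gains[key[2]] -= step
                elif len(key) == 3 and name == "w":
                    head.w[key[2]] = head.w[key[2]] - step
                elif len(key) == 3 and name == "b":
                    head.b[key[2]] -= step
                elif name == "w":
                    head.w = head.w - step
                elif name == "x_shift":
                    head.x_shift -= step
                else:
                    head.b -= step
            else:
                layer = stack.layers[owner]
                if name == "gain":
                    layer.gains[key[2]] = layer.gains[key[2]] - step
                elif name == "W":
                    layer.W = layer.W - step
                elif name == "x_shift":
                    layer.x_shift = layer.x_shift - step
                else:
                    layer.b = layer.b - step

    def fit(self, data: MultitaskDataset, tasks: Sequence[str]):
        cfg = self.cfg
        # round the batch size down to a multiple of 2T (at least 2T) so
        # balanced batching is always feasible
        unit = 2 * len(tasks)
        batch_size = max(unit, (cfg.batch_size // unit) * unit)
        for epoch in range(cfg.epochs):
            batches = balanced_batches(
                data, batch_size,
                seed=cfg.seed * 100003 + epoch,
                n_batches=cfg.n_batches_per_epoch,
                tasks=tasks,
            )
            for Xb, task_list, yb in batches:
                task_arr = np.asarray(task_list)
                for t in dict.fromkeys(task_list):
                    sel = task_arr == t
                    grads = self._backward_task(t, Xb[sel], yb[sel])
                    # normalize by tasks in batch so the step size is a
                    # batch mean, not a per-task sum
                    grads = {k: v / len(set(task_list)) for k, v in grads.items()}
                    self._apply(grads)


# ---------------------------------------------------------------------------
# public training operations
# ---------------------------------------------------------------------------


def evaluate(
    stack: ModulatedStack,
    data: MultitaskDataset,
    tasks: Sequence[str] | None = None,
    splits: Sequence[str] = ("train", "test"),
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-task accuracy table (columns: task_id, split, accuracy, seed)."""
    tasks = list(tasks) if tasks is not None else data.task_ids
    rows = []
    for split in splits:
        idx = data.train_idx if split == "train" else data.test_idx
        for t in tasks:
            logits = stack.forward(t, data.X[idx])
            # ties at the 0.5 probability threshold predict the negative
            # ("all/other") class
            pred = (logits > 0).astype(int)
            acc = float((pred == data.labels[t][idx]).mean())
            rows.append({"task_id": t, "split": split,
                         "accuracy": acc, "seed": seed})
    return pd.DataFrame(rows)


def train_multitask(
    stack: ModulatedStack,
    data: MultitaskDataset,
    cfg: TrainConfig,
    tasks: Sequence[str] | None = None,
) -> tuple[ModulatedStack, pd.DataFrame]:
    """Train shared and task-specific parameters jointly on all tasks."""
    tasks = list(tasks) if tasks is not None else data.task_ids
    _check_tasks_trainable(data, tasks)
    rng = rng_for(cfg.seed, "register_tasks")
    for t in tasks:
        stack.register_task(t, rng=rng)
    trainer = _Trainer(stack, cfg)
    trainer.fit(data, tasks)
    return stack, evaluate(stack, data, tasks, seed=cfg.seed)


def train_transfer(
    stack: ModulatedStack,
    new_tasks: MultitaskDataset,
    cfg: TrainConfig,
    tasks: Sequence[str] | None = None,
) -> tuple[ModulatedStack, pd.DataFrame]:
    """Train only task-specific parameters for unseen tasks.

    Requires the shared parameter groups ``{W, x_shift, b}`` to be frozen;
    unfreezing them in transfer mode is a configuration error.
    """
    required = {"W", "x_shift", "b"}
    if not required <= set(cfg.frozen_parameter_set):
        raise ConfigError(
            "transfer mode requires frozen_parameter_set to include "
            "{'W', 'x_shift', 'b'}"
        )
    tasks = list(tasks) if tasks is not None else new_tasks.task_ids
    if not tasks:
        return stack, pd.DataFrame(
            columns=["task_id", "split", "accuracy", "seed"])
    _check_tasks_trainable(new_tasks, tasks)
    if stack.task_modulated:
        cfg = replace(cfg, frozen_parameter_set=frozenset(
            set(cfg.frozen_parameter_set) | {"head"}) - {"gains"})
    rng = rng_for(cfg.seed, "register_tasks")
    for t in tasks:
        if stack.task_modulated:
            stack.register_task(t)
        else:
            stack.register_task(t, rng=rng)
    trainer = _Trainer(stack, cfg)
    trainer.fit(new_tasks, tasks)
    return stack, evaluate(stack, new_tasks, tasks, seed=cfg.seed)


def readout_baseline(
    layer_sizes: Sequence[int],
    data: MultitaskDataset,
    cfg: TrainConfig,
    tasks: Sequence[str] | None = None,
) -> tuple[ModulatedStack, pd.DataFrame]:
    """Train a shared trunk with per-task linear readouts and no gains."""
    stack = build_stack(layer_sizes, head="task_specific_readouts",
                        seed=cfg.seed)
    return train_multitask(stack, data, cfg, tasks=tasks)


# ---------------------------------------------------------------------------
# decision-boundary normals
# ---------------------------------------------------------------------------


def decision_boundary_normals(
    stack: ModulatedStack, task_id: str, x: np.ndarray
) -> np.ndarray:
    """Gradient of the head pre-activation with respect to the input.

    This is the local normal vector of the decision-boundary region
    containing ``x``; for rectifier networks it is a linear combination of
    the rows of the first-layer weight matrix.  Raises
    :class:`NondifferentiablePointError` if any pre-activation is exactly
    zero (a rectifier kink).
    """
    x = np.asarray(x, dtype=float)
    H = x[None, :]
    caches = []
    for layer in stack.layers:
        g = stack._layer_gain(layer, task_id)
        S = H @ layer.W.T - layer.x_shift
        P = g * S + layer.b
        if np.any(P == 0.0):
            raise NondifferentiablePointError(
                "input lies exactly on a rectifier kink"
            )
        caches.append({"mask": P > 0, "g": g})
        H = np.maximum(P, 0.0)

    head = stack.head
    if head.kind == "modulated_output_unit":
        v = head.gain(task_id) * head.w
    else:
        v = head.w[task_id].copy()
    for layer, cache in zip(reversed(stack.layers), reversed(caches)):
        dP = v * cache["mask"][0]
        v = (dP * cache["g"]) @ layer.W
    return v
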