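"""Greedy layer-wise task-modulated contrastive learning (TMCL).

Each layer holds convolutional feedforward weights with per-unit task
gains and a shared x-shift.  Layers are trained strictly one at a time
and no gradients cross layer boundaries:

1. *CL phase* — the layer's filters (plus a throwaway 2-layer projection
   head) minimize a normalized-temperature cross-entropy over cosine
   similarities.  Positive pairs are two views of the same sample that
   differ by (i) input augmentations (occlusion, rotation, scaling) and
   (ii) the task modulations applied in the already-trained layers below.
2. *Gain phase* — per-task gains of the layer are learned supervised
   through a task-independent output unit (a single shared linear unit
   reading a coarse average-pooled grid of the layer's activity).

Modes ``cl_no_task`` (both views of a pair share one task modulation, so
similarity is never maximized across tasks), ``rp`` (random filters, no
CL) and ``rp_on_tmcl`` (random filters above one TMCL layer) provide the
ablation baselines.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import rng_for
from .synthetic_data import MultitaskDataset, balanced_batches, to_one_vs_all

__all__ = [
    "AugmentationConfig",
    "ConvLayerParams",
    "TMCLConfig",
    "TMCLStack",
    "augment",
    "contrastive_loss",
    "hash_layer_params",
    "stack_layers",
    "train_layer_cl",
    "train_layer_gains",
]

MODES = ("tmcl", "cl_no_task", "rp", "rp_on_tmcl")


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentationConfig:
    """Ranges for the input augmentations; all ranges include identity."""

    occlusion_frac: tuple[float, float] = (0.0, 0.25)
    rotation_deg: tuple[float, float] = (-20.0, 20.0)
    scale: tuple[float, float] = (0.85, 1.15)
    composition_prob: float = 0.7

    def __post_init__(self):
        for name, (lo, hi) in (
            ("occlusion_frac", self.occlusion_frac),
            ("rotation_deg", self.rotation_deg),
            ("scale", self.scale),
        ):
            if lo > hi:
                raise ValueError(f"degenerate {name} range ({lo}, {hi})")
        if not (0.0 <= self.composition_prob <= 1.0):
            raise ValueError("composition_prob must be in [0, 1]")
        if self.composition_prob >= 1.0:
            # with certain application, identity must lie inside the ranges
            if self.occlusion_frac[0] > 0.0:
                raise ValueError("occlusion range must include 0 (identity)")
            if not (self.rotation_deg[0] <= 0.0 <= self.rotation_deg[1]):
                raise ValueError("rotation range must include 0 (identity)")
            if not (self.scale[0] <= 1.0 <= self.scale[1]):
                raise ValueError("scale range must include 1 (identity)")


def _rescale(img: np.ndarray, factor: float) -> np.ndarray:
    """Zoom about the center, cropping or zero-padding back to shape."""
    h, w = img.shape
    out = ndimage.zoom(img, factor, order=1)
    oh, ow = out.shape
    if oh >= h:
        top, left = (oh - h) // 2, (ow - w) // 2
        return out[top:top + h, left:left + w]
    res = np.zeros_like(img)
    top, left = (h - oh) // 2, (w - ow) // 2
    res[top:top + oh, left:left + ow] = out
    return res


def augment(x: np.ndarray, cfg: AugmentationConfig, seed: int) -> np.ndarray:
    """One stochastic augmentation of a 2D (or leading-channel 3D) image.

    Deterministic given ``seed``; returns the input bitwise when all
    ranges collapse to the identity.
    """
    x = np.asarray(x, dtype=float)
    squeeze = False
    if x.ndim == 3:
        if x.shape[0] != 1:
            raise ValueError("only single-channel 3D images supported")
        x, squeeze = x[0], True
    elif x.ndim != 2:
        raise ValueError("image must be 2D or (1, H, W)")
    rng = rng_for(seed, "augment")
    out = x

    apply_rot = rng.random() < cfg.composition_prob
    angle = rng.uniform(*cfg.rotation_deg)
    if apply_rot and angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1,
                             mode="constant")

    apply_scale = rng.random() < cfg.composition_prob
    factor = rng.uniform(*cfg.scale)
    if apply_scale and factor != 1.0:
        out = _rescale(out, factor)

    apply_occ = rng.random() < cfg.composition_prob
    frac = rng.uniform(*cfg.occlusion_frac)
    if apply_occ and frac > 0.0:
        h, w = out.shape
        area = frac * h * w
        bh = max(1, int(round(np.sqrt(area))))
        bw = max(1, int(round(area / bh)))
        bh, bw = min(bh, h), min(bw, w)
        top = rng.integers(0, h - bh + 1)
        left = rng.integers(0, w - bw + 1)
        out = out.copy()
        out[top:top + bh, left:left + bw] = 0.0

    return out[None] if squeeze else out


# ---------------------------------------------------------------------------
# contrastive loss (NT-Xent) with analytic gradient
# ---------------------------------------------------------------------------


def _ntxent(Z_raw: np.ndarray, temperature: float):
    """Loss and gradient wrt the unnormalized projections.

    Rows ``i`` and ``i+N`` are a positive pair.  Cosine similarities are
    obtained by row normalization inside.
    """
    two_n, _ = Z_raw.shape
    if two_n % 2 != 0 or two_n < 4:
        raise ValueError("need an even number of rows and at least 2 pairs")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    n = two_n // 2
    norms = np.linalg.norm(Z_raw, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    Z = Z_raw / norms
    S = (Z @ Z.T) / temperature
    np.fill_diagonal(S, -np.inf)
    pos = np.concatenate([np.arange(n, two_n), np.arange(0, n)])

    S_max = S.max(axis=1, keepdims=True)
    expS = np.exp(S - S_max)
    denom = expS.sum(axis=1)
    logprob = S[np.arange(two_n), pos] - (np.log(denom) + S_max[:, 0])
    loss = float(-logprob.mean())

    softmax = expS / denom[:, None]
    dS = softmax
    dS[np.arange(two_n), pos] -= 1.0
    dS /= two_n
    # S = Z Z^T / tau with the diagonal masked (gradient there is zero)
    np.fill_diagonal(dS, 0.0)
    dZ = (dS + dS.T) @ Z / temperature
    # back through row normalization
    dZ_raw = (dZ - (dZ * Z).sum(axis=1, keepdims=True) * Z) / norms
    return loss, dZ_raw


def contrastive_loss(Z: np.ndarray, temperature: float) -> float:
    """NT-Xent loss over paired rows ``(i, i + N)`` of ``Z``."""
    loss, _ = _ntxent(np.asarray(Z, dtype=float), temperature)
    return loss


# ---------------------------------------------------------------------------
# convolutional layer
# ---------------------------------------------------------------------------


class ConvLayerParams:
    """Convolution filters with per-unit task gains and shared x-shift.

    Gains are task-specific and per hidden unit (channel x position),
    mirroring neuron-specific modulation in the dense case; they are
    allocated lazily once the output map size is known.
    """

    def __init__(self, K: np.ndarray, b: np.ndarray, stride: int = 1,
                 x_shift: float = 0.0):
        self.K = np.asarray(K, dtype=float)      # (C_out, C_in, kh, kw)
        self.b = np.asarray(b, dtype=float)      # (C_out,)
        self.stride = stride
        self.x_shift = float(x_shift)
        self.gains: dict[str, np.ndarray] = {}
        self.out_shape: tuple[int, int, int] | None = None  # (C, Ho, Wo)

    @property
    def c_out(self) -> int:
        return self.K.shape[0]

    def register_task(self, task_id: str) -> None:
        if self.out_shape is None:
            raise RuntimeError(
                "output map size unknown; run a forward pass before "
                "registering tasks")
        self.gains.setdefault(task_id, np.ones(self.out_shape))

    def patches(self, X: np.ndarray) -> np.ndarray:
        """Sliding patches ``(N, Ho, Wo, C_in, kh, kw)`` at this stride."""
        _, _, kh, kw = self.K.shape
        win = np.lib.stride_tricks.sliding_window_view(X, (kh, kw),
                                                       axis=(2, 3))
        # win: (N, C_in, H-kh+1, W-kw+1, kh, kw)
        win = win[:, :, ::self.stride, ::self.stride]
        return np.moveaxis(win, 1, 3)

    def conv(self, X: np.ndarray) -> np.ndarray:
        """Raw convolution output ``z``, shape ``(N, C_out, Ho, Wo)``."""
        p = self.patches(X)
        z = np.tensordot(p, self.K, axes=([3, 4, 5], [1, 2, 3]))
        z = np.moveaxis(z, 3, 1)
        self.out_shape = z.shape[1:]
        return z

    def activate(self, z: np.ndarray, gain: np.ndarray | None = None):
        """``relu(g * (z - x_shift) + b)``, gain per channel or per unit."""
        if gain is None:
            pre = (z - self.x_shift) + self.b[None, :, None, None]
        elif gain.ndim == 1:
            pre = gain[None, :, None, None] * (z - self.x_shift) \
                + self.b[None, :, None, None]
        else:
            pre = gain[None] * (z - self.x_shift) \
                + self.b[None, :, None, None]
        return np.maximum(pre, 0.0), pre > 0


class TMCLStack:
    """Ordered, independently trained convolutional layers."""

    def __init__(self, layers: Sequence[ConvLayerParams]):
        self.layers = list(layers)
        # per-layer shared output unit (set during the gain phase)
        self.ou: list[dict | None] = [None] * len(self.layers)

    def forward_below(self, X: np.ndarray, task_id: str | None,
                      upto: int) -> np.ndarray:
        """Representation entering layer ``upto`` (task-modulated below)."""
        H = X
        for l in range(upto):
            layer = self.layers[l]
            z = layer.conv(H)
            gain = layer.gains.get(task_id) if task_id is not None else None
            H, _ = layer.activate(z, gain)
        return H

    def head_logits(self, X: np.ndarray, task_id: str, layer_index: int):
        """Output-unit logits at ``layer_index`` for one task."""
        layer = self.layers[layer_index]
        H = self.forward_below(X, task_id, layer_index)
        z = layer.conv(H)
        gain = layer.gains.get(task_id)
        a, _ = layer.activate(z, gain)
        ou = self.ou[layer_index]
        pooled = _pool_grid(a, ou["grid"])
        return pooled.reshape(len(a), -1) @ ou["w"] + ou["b"]


def _pool_grid(a: np.ndarray, grid: int) -> np.ndarray:
    """Average-pool feature maps onto a coarse ``grid x grid`` spatial grid.

    A grid of 1 is global average pooling; maps smaller than the grid fall
    back to their own resolution.
    """
    n, c, h, w = a.shape
    gh, gw = min(grid, h), min(grid, w)
    edges_h = np.linspace(0, h, gh + 1).astype(int)
    edges_w = np.linspace(0, w, gw + 1).astype(int)
    out = np.empty((n, c, gh, gw))
    for i in range(gh):
        for j in range(gw):
            out[:, :, i, j] = a[:, :, edges_h[i]:edges_h[i + 1],
                                edges_w[j]:edges_w[j + 1]].mean(axis=(2, 3))
    return out


def _pool_grid_backward(da_pool: np.ndarray, shape, grid: int) -> np.ndarray:
    """Distribute pooled gradients uniformly back over each region."""
    n, c, h, w = shape
    gh, gw = min(grid, h), min(grid, w)
    edges_h = np.linspace(0, h, gh + 1).astype(int)
    edges_w = np.linspace(0, w, gw + 1).astype(int)
    out = np.zeros(shape)
    for i in range(gh):
        for j in range(gw):
            sh = slice(edges_h[i], edges_h[i + 1])
            sw = slice(edges_w[j], edges_w[j + 1])
            area = (edges_h[i + 1] - edges_h[i]) * (edges_w[j + 1] - edges_w[j])
            out[:, :, sh, sw] = da_pool[:, :, i, j, None, None] / area
    return out


def hash_layer_params(layer: ConvLayerParams) -> str:
    """SHA-256 over all parameters of a layer (weights, bias, gains)."""
    h = hashlib.sha256()
    h.update(layer.K.tobytes())
    h.update(layer.b.tobytes())
    h.update(np.asarray(layer.x_shift).tobytes())
    for task in sorted(layer.gains):
        h.update(task.encode())
        h.update(layer.gains[task].tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TMCLConfig:
    channels: tuple[int, ...] = (8, 12, 16)
    kernel: int = 3
    stride: int = 2
    head_hidden: int = 32
    head_out: int = 16
    temperature: float = 0.5
    cl_steps: int = 300
    cl_batch_pairs: int = 32
    cl_lr: float = 0.05
    cl_momentum: float = 0.9
    gain_epochs: int = 20
    gain_lr: float = 3.0
    ou_lr: float = 0.3   # smaller OU step pushes task specificity into gains
    gain_batch_size: int = 64
    ou_pool_grid: int = 2
    seed: int = 0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)


def _make_layer(c_in: int, c_out: int, cfg: TMCLConfig,
                rng: np.random.Generator) -> ConvLayerParams:
    fan_in = c_in * cfg.kernel * cfg.kernel
    K = rng.normal(size=(c_out, c_in, cfg.kernel, cfg.kernel)) / np.sqrt(fan_in)
    return ConvLayerParams(K=K, b=np.zeros(c_out), stride=cfg.stride)


# ---------------------------------------------------------------------------
# CL phase
# ---------------------------------------------------------------------------


def train_layer_cl(
    stack: TMCLStack,
    images: np.ndarray,
    layer_index: int,
    cfg: TMCLConfig,
    *,
    task_similarity: bool = True,
    task_pool: Sequence[str] | None = None,
    fixed_task: str | None = None,
    record_loss: bool = False,
) -> list[float]:
    """Contrastive training of one layer's filters (plus throwaway head).

    Positives are two views of one sample: independently augmented and,
    when ``task_similarity`` is on, passed through the frozen layers
    below under two distinct task modulations drawn from ``task_pool``.
    Only the filters/bias of ``layer_index`` and the local projection
    head receive gradients.
    """
    if task_similarity and not task_pool:
        if layer_index > 0:
            raise ValueError(
                "task_similarity requires registered tasks (task_pool)")
        task_pool = None  # layer 0 has no modulated layers below
    layer = stack.layers[layer_index]
    rng = rng_for(cfg.seed, f"cl_layer{layer_index}")

    if images.ndim == 3:
        images = images[:, None]
    n_samples = images.shape[0]

    # projection head dimensions from a probe forward pass
    probe = stack.forward_below(images[:1], None, layer_index)
    z = layer.conv(probe)
    feat_dim = int(np.prod(z.shape[1:]))
    W1 = rng.normal(size=(cfg.head_hidden, feat_dim)) / np.sqrt(feat_dim)
    b1 = np.zeros(cfg.head_hidden)
    W2 = rng.normal(size=(cfg.head_out, cfg.head_hidden)) / np.sqrt(cfg.head_hidden)
    b2 = np.zeros(cfg.head_out)

    vel: dict[str, np.ndarray] = {}
    losses: list[float] = []
    n_pairs = cfg.cl_batch_pairs
    for step in range(cfg.cl_steps):
        idx = rng.choice(n_samples, size=n_pairs, replace=n_samples < n_pairs)
        views = []
        view_tasks: list[str | None] = []
        for v in range(2):
            batch = np.stack([
                augment(images[i, 0], cfg.augmentation,
                        seed=int(rng.integers(0, 2**31 - 1)))
                for i in idx
            ])[:, None]
            views.append(batch)
        for i in range(n_pairs):
            if task_similarity and task_pool:
                pair = rng.choice(len(task_pool), size=2,
                                  replace=len(task_pool) < 2)
                view_tasks.append((task_pool[pair[0]], task_pool[pair[1]]))
            elif task_pool:
                # no cross-task similarity: both views of a pair share one
                # (randomly drawn) task modulation
                t = task_pool[int(rng.integers(0, len(task_pool)))]
                view_tasks.append((t, t))
            else:
                view_tasks.append((fixed_task, fixed_task))

        # forward the frozen layers below with per-view task modulations
        reps = []
        for v in range(2):
            if layer_index == 0:
                reps.append(views[v])
                continue
            tasks_v = [vt[v] for vt in view_tasks]
            shape = stack.forward_below(views[v][:1], tasks_v[0],
                                        layer_index).shape[1:]
            H = np.empty((n_pairs, *shape))
            for t in set(tasks_v):
                sel = np.array([tv == t for tv in tasks_v])
                H[sel] = stack.forward_below(views[v][sel], t, layer_index)
            reps.append(H)
        H_in = np.concatenate(reps, axis=0)  # (2N, C_in, H, W)

        # current layer + head forward
        patches = layer.patches(H_in)
        z = np.moveaxis(
            np.tensordot(patches, layer.K, axes=([3, 4, 5], [1, 2, 3])), 3, 1)
        a, mask = layer.activate(z)
        flat = a.reshape(a.shape[0], -1)
        h1 = flat @ W1.T + b1
        m1 = h1 > 0
        h1r = np.where(m1, h1, 0.0)
        out = h1r @ W2.T + b2

        loss, dout = _ntxent(out, cfg.temperature)
        losses.append(loss)

        dW2 = dout.T @ h1r
        db2 = dout.sum(axis=0)
        dh1 = (dout @ W2) * m1
        dW1 = dh1.T @ flat
        db1 = dh1.sum(axis=0)
        dflat = dh1 @ W1
        da = dflat.reshape(a.shape)
        dpre = da * mask                       # gain is 1 during CL
        db = dpre.sum(axis=(0, 2, 3))
        dz = np.moveaxis(dpre, 1, 3)           # (N, Ho, Wo, C_out)
        dK = np.tensordot(dz, patches, axes=([0, 1, 2], [0, 1, 2]))

        for name, param, grad in (
            ("K", layer.K, dK), ("b", layer.b, db),
            ("W1", W1, dW1), ("b1", b1, db1),
            ("W2", W2, dW2), ("b2", b2, db2),
        ):
            v_ = cfg.cl_momentum * vel.get(name, 0.0) + grad
            vel[name] = v_
            param -= cfg.cl_lr * v_

    return losses


# ---------------------------------------------------------------------------
# gain phase
# ---------------------------------------------------------------------------


def train_layer_gains(
    stack: TMCLStack,
    data: MultitaskDataset,
    layer_index: int,
    cfg: TMCLConfig,
    tasks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Supervised training of one layer's per-task gains through a shared OU.

    Only the gains of ``layer_index`` and the output unit (shared across
    tasks) change; filters and all earlier layers stay frozen.  Returns
    the per-task test accuracy table.
    """
    tasks = list(tasks) if tasks is not None else data.task_ids
    layer = stack.layers[layer_index]
    rng = rng_for(cfg.seed, f"gains_layer{layer_index}")

    images = data.images
    if images.ndim == 3:
        images = images[:, None]

    # OU input dimensionality from a probe pass (also fixes the output
    # map size so per-unit gains can be allocated)
    probe, _ = layer.activate(
        layer.conv(stack.forward_below(images[:1], None, layer_index)))
    for t in tasks:
        layer.register_task(t)
    grid = cfg.ou_pool_grid
    feat_dim = int(np.prod(_pool_grid(probe, grid).shape[1:]))
    ou = {"w": rng.normal(size=feat_dim) / np.sqrt(feat_dim), "b": 0.0,
          "grid": grid}
    stack.ou[layer_index] = ou

    n_batches = max(1, int(np.ceil(
        2 * len(data.train_idx) / cfg.gain_batch_size)))
    for epoch in range(cfg.gain_epochs):
        batches = balanced_batches(
            data, cfg.gain_batch_size,
            seed=cfg.seed * 7919 + 31 * layer_index + epoch,
            n_batches=n_batches, tasks=tasks,
        )
        for Xb, task_list, yb in batches:
            imgs = Xb.reshape(len(Xb), *images.shape[1:])
            task_arr = np.asarray(task_list)
            for t in dict.fromkeys(task_list):
                sel = task_arr == t
                xt, yt = imgs[sel], yb[sel]
                H = stack.forward_below(xt, t, layer_index)
                z = layer.conv(H)
                g = layer.gains[t]
                s = z - layer.x_shift
                a, mask = layer.activate(z, g)
                pooled = _pool_grid(a, grid)
                feats = pooled.reshape(len(a), -1)
                logits = feats @ ou["w"] + ou["b"]
                p = 1.0 / (1.0 + np.exp(-logits))
                dlog = (p - yt) / len(yt) / len(set(task_list))
                dfeat = np.outer(dlog, ou["w"]).reshape(pooled.shape)
                da = _pool_grid_backward(dfeat, a.shape, grid)
                dpre = da * mask
                dg = (dpre * s).sum(axis=0)
                dw = feats.T @ dlog
                db0 = dlog.sum()
                layer.gains[t] = g - cfg.gain_lr * dg
                ou["w"] -= cfg.ou_lr * dw
                ou["b"] -= cfg.ou_lr * db0
    return evaluate_layer(stack, data, layer_index, tasks, seed=cfg.seed)


def evaluate_layer(
    stack: TMCLStack,
    data: MultitaskDataset,
    layer_index: int,
    tasks: Sequence[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-task test accuracy of the OU readout at one layer."""
    tasks = list(tasks) if tasks is not None else data.task_ids
    images = data.images
    if images.ndim == 3:
        images = images[:, None]
    idx = data.test_idx
    rows = []
    for t in tasks:
        logits = stack.head_logits(images[idx], t, layer_index)
        pred = (logits > 0).astype(int)
        acc = float((pred == data.labels[t][idx]).mean())
        rows.append({"task_id": t, "split": "test", "accuracy": acc,
                     "layer": layer_index, "seed": seed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------


def stack_layers(
    images: np.ndarray,
    class_labels: np.ndarray,
    n_layers: int,
    cfg: TMCLConfig,
    mode: str = "tmcl",
    task_subset_size: int | None = None,
    data: MultitaskDataset | None = None,
) -> tuple[TMCLStack, pd.DataFrame]:
    """Alternate CL and gain phases layer by layer.

    Returns the stack and a table with per-layer mean test accuracy over
    *all* tasks (even when similarity was maximized over a subset).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if data is None:
        data = to_one_vs_all(images, class_labels, seed=cfg.seed)
    rng = rng_for(cfg.seed, "stack_layers")
    tasks = data.task_ids

    imgs = images[:, None] if images.ndim == 3 else images
    train_imgs = imgs[data.train_idx]

    layers: list[ConvLayerParams] = []
    c_in = imgs.shape[1]
    for l in range(n_layers):
        c_out = cfg.channels[min(l, len(cfg.channels) - 1)]
        layers.append(_make_layer(c_in, c_out, cfg, rng))
        c_in = c_out
    stack = TMCLStack(layers)

    subset = tasks
    if task_subset_size is not None:
        if not (1 <= task_subset_size <= len(tasks)):
            raise ValueError("task_subset_size out of range")
        pick = rng.choice(len(tasks), size=task_subset_size, replace=False)
        subset = [tasks[i] for i in sorted(pick)]

    records = []
    for l in range(n_layers):
        use_cl = mode in ("tmcl", "cl_no_task") or (
            mode == "rp_on_tmcl" and l == 0)
        if use_cl:
            similarity = mode in ("tmcl", "rp_on_tmcl") \
                and task_subset_size != 1
            train_layer_cl(
                stack, train_imgs, l,
                replace(cfg, seed=cfg.seed * 613 + l),
                task_similarity=similarity and l > 0,
                task_pool=subset if l > 0 else None,
                fixed_task=tasks[0] if l > 0 else None,
            )
        table = train_layer_gains(
            stack, data, l, replace(cfg, seed=cfg.seed * 613 + l))
        records.append({
            "layer": l,
            "mean_accuracy": float(table["accuracy"].mean()),
            "mode": mode,
            "seed": cfg.seed,
        })
    return stack, pd.DataFrame(records)
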