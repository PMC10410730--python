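"""Synthetic dataset generators.

Everything the other modules consume is produced here, with no downloads:

* :func:`gen_2d_multitask` — binary classification tasks on 2D inputs,
  each defined by a random smooth (quadratic) decision boundary.
* :func:`gen_glyph_images` — procedurally rendered stroke glyphs, a
  stand-in for handwritten-character image sets.
* :func:`to_one_vs_all` — convert a multiclass labeled set into a
  one-vs-all multitask problem (one binary task per class).
* :func:`balanced_batches` — batch iterator balanced across tasks and,
  within each task, across the two classes.
* :func:`gen_xor_episodes` — episode stream for the spiking module in
  which the target output is the XOR of two binary input channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from ._rng import rng_for

__all__ = [
    "MultitaskDataset",
    "XorEpisode",
    "balanced_batches",
    "gen_2d_multitask",
    "gen_glyph_images",
    "gen_xor_episodes",
    "read_idx",
    "to_one_vs_all",
]


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class MultitaskDataset:
    """Feature matrix plus per-task binary labels and train/test splits.

    Attributes
    ----------
    X:
        ``(n_samples, n_features)`` float array.
    labels:
        Mapping ``task_id -> (n_samples,)`` array of ``{0, 1}`` labels.
    train_idx, test_idx:
        Disjoint integer index arrays into the rows of ``X``.
    metadata:
        Generator name, seed and any generator-specific parameters.
    images:
        Optional unflattened view ``(n_samples, H, W)`` when the features
        are pixels.
    """

    X: np.ndarray
    labels: dict[str, np.ndarray]
    train_idx: np.ndarray
    test_idx: np.ndarray
    metadata: dict = field(default_factory=dict)
    images: np.ndarray | None = None

    @property
    def task_ids(self) -> list[str]:
        return list(self.labels)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on failure."""
        n = self.X.shape[0]
        if len(set(self.train_idx) & set(self.test_idx)) > 0:
            raise ValueError("train/test splits overlap")
        for name, idx in (("train", self.train_idx), ("test", self.test_idx)):
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"{name} split indexes out of range")
        for task, y in self.labels.items():
            if y.shape != (n,):
                raise ValueError(f"task {task!r}: label length {y.shape} != {n}")
            if not np.isin(y, (0, 1)).all():
                raise ValueError(f"task {task!r}: labels must be binary")
            for name, idx in (("train", self.train_idx), ("test", self.test_idx)):
                if len(idx) and len(np.unique(y[idx])) < 2:
                    raise ValueError(
                        f"task {task!r} has a single class in the {name} split"
                    )

    # -- persistence (NPZ + JSON sidecar) -----------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {
            "X": self.X,
            "split.train": self.train_idx,
            "split.test": self.test_idx,
        }
        for task, y in self.labels.items():
            arrays[f"labels.{task}"] = y
        if self.images is not None:
            arrays["images"] = self.images
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.metadata, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MultitaskDataset":
        path = Path(path)
        with np.load(path) as data:
            labels = {
                key[len("labels."):]: data[key]
                for key in data.files
                if key.startswith("labels.")
            }
            images = data["images"] if "images" in data.files else None
            ds = cls(
                X=data["X"],
                labels=labels,
                train_idx=data["split.train"],
                test_idx=data["split.test"],
                images=images,
            )
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            ds.metadata = json.loads(sidecar.read_text())
        return ds


def _split_indices(n: int, rng: np.random.Generator, test_frac: float = 0.25):
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_frac * n)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


# ---------------------------------------------------------------------------
# 2D multitask set
# ---------------------------------------------------------------------------


def gen_2d_multitask(
    n_tasks: int = 48,
    n_samples: int = 512,
    seed: int = 0,
    *,
    max_retries: int = 50,
) -> MultitaskDataset:
    """Binary tasks on 2D points, each with a smooth random boundary.

    Points are uniform in ``[-1, 1]^2``.  Each task evaluates a random
    quadratic polynomial on the points and labels them relative to the
    median value, which keeps both classes near 50%.  Tasks whose minority
    class falls below 25% in any split are resampled.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    rng = rng_for(seed, "gen_2d_multitask")
    X = rng.uniform(-1.0, 1.0, size=(n_samples, 2))
    train_idx, test_idx = _split_indices(n_samples, rng)

    feats = np.column_stack(
        [X[:, 0], X[:, 1], X[:, 0] ** 2, X[:, 0] * X[:, 1], X[:, 1] ** 2]
    )
    labels: dict[str, np.ndarray] = {}
    for t in range(n_tasks):
        for attempt in range(max_retries):
            coef = rng.normal(size=5)
            value = feats @ coef
            y = (value > np.median(value)).astype(np.int64)
            ok = True
            for idx in (train_idx, test_idx):
                frac = y[idx].mean()
                if not (0.25 <= frac <= 0.75):
                    ok = False
                    break
            if ok:
                labels[f"task{t:02d}"] = y
                break
        else:
            raise RuntimeError(f"could not balance task {t} in {max_retries} tries")

    ds = MultitaskDataset(
        X=X,
        labels=labels,
        train_idx=train_idx,
        test_idx=test_idx,
        metadata={"generator": "gen_2d_multitask", "seed": seed,
                  "n_tasks": n_tasks, "n_samples": n_samples},
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# procedural glyph images
# ---------------------------------------------------------------------------


def _render_strokes(strokes: np.ndarray, size: int) -> np.ndarray:
    """Rasterize stroke endpoints (fractional coords) onto a size×size grid."""
    img = np.zeros((size, size))
    n_pts = 4 * size
    for (x0, y0, x1, y1) in strokes:
        ts = np.linspace(0.0, 1.0, n_pts)
        xs = (x0 + ts * (x1 - x0)) * (size - 1)
        ys = (y0 + ts * (y1 - y0)) * (size - 1)
        ix = np.clip(np.round(xs).astype(int), 0, size - 1)
        iy = np.clip(np.round(ys).astype(int), 0, size - 1)
        img[iy, ix] = 1.0
    return img


def gen_glyph_images(
    n_classes: int,
    image_size: int = 16,
    n_per_class: int = 40,
    seed: int = 0,
    *,
    n_strokes: int = 3,
    jitter: float = 0.03,
    max_rotation_deg: float = 12.0,
    noise: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Procedural stroke glyphs: one stroke template per class plus jitter.

    Returns ``(images, class_labels)`` with ``images`` of shape
    ``(n_classes * n_per_class, image_size, image_size)`` and intensities
    in ``[0, 1]``.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if image_size < 8:
        raise ValueError("image_size too small to render glyph strokes")
    rng = rng_for(seed, "gen_glyph_images")

    # per-class stroke templates: segments between anchor points
    templates = []
    for _ in range(n_classes):
        anchors = rng.uniform(0.15, 0.85, size=(n_strokes + 1, 2))
        strokes = np.column_stack([anchors[:-1], anchors[1:]])
        templates.append(strokes)

    images = np.empty((n_classes * n_per_class, image_size, image_size))
    labels = np.repeat(np.arange(n_classes), n_per_class)
    i = 0
    for c in range(n_classes):
        for _ in range(n_per_class):
            strokes = templates[c].copy()
            strokes += rng.normal(scale=jitter, size=strokes.shape)
            img = _render_strokes(np.clip(strokes, 0.0, 1.0), image_size)
            angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant")
            img = ndimage.gaussian_filter(img, sigma=0.7)
            img = img + rng.normal(scale=noise, size=img.shape)
            img = np.clip(img, 0.0, None)
            peak = img.max()
            if peak > 0:
                img = img / peak
            images[i] = img
            i += 1
    return images, labels


def to_one_vs_all(
    images: np.ndarray,
    class_labels: np.ndarray,
    seed: int = 0,
    *,
    test_frac: float = 0.25,
) -> MultitaskDataset:
    """One binary task per class: positive = the class, negative = rest.

    Features are the flattened images; the image view is preserved in the
    ``images`` attribute. The split is stratified per class so each task
    has both classes in both splits.
    """
    classes = np.unique(class_labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for one-vs-all conversion")
    n = len(class_labels)
    rng = rng_for(seed, "to_one_vs_all")

    test_mask = np.zeros(n, dtype=bool)
    for c in classes:
        idx = np.flatnonzero(class_labels == c)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_frac * len(idx))))
        test_mask[idx[:n_test]] = True
    train_idx = np.flatnonzero(~test_mask)
    test_idx = np.flatnonzero(test_mask)

    X = images.reshape(n, -1).astype(float)
    labels = {
        f"class{int(c)}": (class_labels == c).astype(np.int64) for c in classes
    }
    ds = MultitaskDataset(
        X=X,
        labels=labels,
        train_idx=train_idx,
        test_idx=test_idx,
        metadata={"generator": "to_one_vs_all", "seed": seed,
                  "n_classes": int(len(classes))},
        images=images,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# balanced batching
# ---------------------------------------------------------------------------


def balanced_batches(
    data: MultitaskDataset,
    batch_size: int,
    seed: int = 0,
    *,
    n_batches: int | None = None,
    tasks: Sequence[str] | None = None,
) -> Iterator[tuple[np.ndarray, list[str], np.ndarray]]:
    """Yield ``(X_batch, task_ids, y_batch)`` balanced per task and class.

    Each batch contains ``batch_size / (2 T)`` positive and as many
    negative training samples for every included task.  The minority class
    (typically the positives of a one-vs-all task) is oversampled with
    replacement; majority-class draws are without replacement within a
    batch.  ``batch_size`` must be divisible by ``2 T``.
    """
    task_ids = list(tasks) if tasks is not None else data.task_ids
    n_tasks = len(task_ids)
    if batch_size % (2 * n_tasks) != 0:
        raise ValueError(
            f"batch_size {batch_size} not divisible by 2 x {n_tasks} tasks"
        )
    per_class = batch_size // (2 * n_tasks)
    rng = rng_for(seed, "balanced_batches")

    pools = {}
    for t in task_ids:
        y = data.labels[t][data.train_idx]
        pools[t] = (
            data.train_idx[y == 1],
            data.train_idx[y == 0],
        )

    if n_batches is None:
        n_batches = max(1, int(np.ceil(2 * len(data.train_idx) / batch_size)))

    for _ in range(n_batches):
        rows, batch_tasks, ys = [], [], []
        for t in task_ids:
            pos, neg = pools[t]
            for pool, label in ((pos, 1), (neg, 0)):
                replace = len(pool) < per_class
                pick = rng.choice(pool, size=per_class, replace=replace)
                rows.append(pick)
                batch_tasks.extend([t] * per_class)
                ys.append(np.full(per_class, label))
        idx = np.concatenate(rows)
        yield data.X[idx], batch_tasks, np.concatenate(ys)


# ---------------------------------------------------------------------------
# XOR episodes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class XorEpisode:
    """One XOR trial: two binary input channels, target = their XOR."""

    input_a: bool
    input_b: bool
    seed: int

    @property
    def label(self) -> int:
        return int(self.input_a != self.input_b)


def gen_xor_episodes(n_episodes: int, seed: int = 0) -> list[XorEpisode]:
    """Uniformly sampled XOR truth-table episodes, seeded per episode."""
    rng = rng_for(seed, "gen_xor_episodes")
    episodes = []
    for i in range(n_episodes):
        a, b = rng.integers(0, 2, size=2)
        episodes.append(
            XorEpisode(bool(a), bool(b), seed=int(rng.integers(0, 2**31 - 1)))
        )
    return episodes


# ---------------------------------------------------------------------------
# optional IDX reader (MNIST/EMNIST byte dialect)
# ---------------------------------------------------------------------------

_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: ">i2",
    0x0C: ">i4",
    0x0D: ">f4",
    0x0E: ">f8",
}


def read_idx(path: str | Path) -> np.ndarray:
    """Read a file in the IDX format (big-endian magic/dims header)."""
    raw = Path(path).read_bytes()
    if raw[:2] != b"\x00\x00":
        raise ValueError("not an IDX file (bad magic)")
    dtype_code, n_dims = raw[2], raw[3]
    if dtype_code not in _IDX_DTYPES:
        raise ValueError(f"unknown IDX dtype code 0x{dtype_code:02x}")
    dims = [
        int.from_bytes(raw[4 + 4 * i: 8 + 4 * i], "big") for i in range(n_dims)
    ]
    data = np.frombuffer(raw, dtype=_IDX_DTYPES[dtype_code], offset=4 + 4 * n_dims)
    return data.reshape(dims)
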