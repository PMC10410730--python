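"""Unsupervised feedforward weight matrices from sample differences.

A difference matrix holds rows ``x_i - x_j`` for sampled pairs of data
rows.  Weight matrices are learned so that their row space reconstructs
these differences well:

* ``dpca`` — rows are the top right singular vectors of the difference
  matrix (unconstrained optimum of the reconstruction loss at rank k).
* ``dsd``  — sparse dictionary learning: alternating L1-penalized sparse
  coding and exact per-atom dictionary updates with unit-L2 rows.
* ``dpmd`` — penalized matrix decomposition: sequential rank-1 factors
  under L1 bounds on both factors, via soft-thresholded power iterations
  with a binary search on the threshold level, and deflation.
* ``rp``   — i.i.d. Gaussian random projections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import Lasso

from ._rng import rng_for

__all__ = [
    "CoefficientMatrix",
    "DifferenceMatrix",
    "WeightMatrix",
    "delta_pca",
    "delta_pmd",
    "delta_sd",
    "random_projection",
    "reconstruction_residual",
    "sample_differences",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DifferenceMatrix:
    """Rows are differences ``X[i] - X[j]`` of sampled pairs ``(i, j)``."""

    rows: np.ndarray
    pair_index: np.ndarray  # (m, 2) integer pairs, i != j
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.rows.shape


@dataclass
class WeightMatrix:
    """A ``(k, n)`` weight matrix with its method and constraint metadata."""

    W: np.ndarray
    method: str
    constraints: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, W=self.W)
        meta = {"method": self.method, "k": self.k, "n": self.n,
                "constraints": self.constraints, "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WeightMatrix":
        path = Path(path)
        with np.load(path) as data:
            W = data["W"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(W=W, method=meta["method"],
                   constraints=meta.get("constraints", {}),
                   seed=meta.get("seed"))


@dataclass
class CoefficientMatrix:
    """Optimal reconstruction coefficients, one row per difference row."""

    C: np.ndarray


# ---------------------------------------------------------------------------
# difference sampling
# ---------------------------------------------------------------------------


def sample_differences(
    X: np.ndarray, n_pairs: int | None = None, seed: int = 0
) -> DifferenceMatrix:
    """Sample unordered pairs ``(i, j)``, ``i != j``, and form ``X[i]-X[j]``.

    Pairs are drawn uniformly without replacement while fewer than the
    number of available unordered pairs are requested, and with
    replacement beyond that.  Default ``n_pairs`` is ten times the number
    of samples.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples to form differences")
    if n_pairs is None:
        n_pairs = 10 * m
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = rng_for(seed, "sample_differences")

    n_avail = m * (m - 1) // 2
    if n_pairs <= n_avail:
        # draw distinct unordered pairs by rejection (cheap for the sizes
        # used here); encode pair (i<j) as a single integer for dedup
        chosen: set[int] = set()
        pairs = []
        while len(pairs) < n_pairs:
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            code = a * m + b
            if code in chosen:
                continue
            chosen.add(code)
            pairs.append((int(i), int(j)))
        pair_index = np.array(pairs)
    else:
        i = rng.integers(0, m, size=n_pairs)
        j = rng.integers(0, m - 1, size=n_pairs)
        j = np.where(j >= i, j + 1, j)
        pair_index = np.column_stack([i, j])

    rows = X[pair_index[:, 0]] - X[pair_index[:, 1]]
    return DifferenceMatrix(rows=rows, pair_index=pair_index, seed=seed)


# ---------------------------------------------------------------------------
# sign convention
# ---------------------------------------------------------------------------


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip rows so the largest-magnitude entry of each row is positive."""
    W = W.copy()
    for r in range(W.shape[0]):
        j = np.argmax(np.abs(W[r]))
        if W[r, j] < 0:
            W[r] = -W[r]
    return W


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


def delta_pca(dx: DifferenceMatrix, k: int) -> WeightMatrix:
    """Top-k right singular vectors of the difference matrix."""
    m, n = dx.shape
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n)={min(m, n)}")
    _, _, Vt = np.linalg.svd(dx.rows, full_matrices=False)
    W = _fix_signs(Vt[:k])
    return WeightMatrix(W=W, method="dpca", constraints={"k": k}, seed=dx.seed)


def _sparse_code(dx_rows: np.ndarray, W: np.ndarray, lam: float) -> np.ndarray:
    """Solve ``min_C ||DX - C W||^2 + lam ||C||_1`` for fixed W."""
    m, _ = dx_rows.shape
    k = W.shape[0]
    if lam == 0.0:
        C, *_ = np.linalg.lstsq(W.T, dx_rows.T, rcond=None)
        return C.T
    # sklearn Lasso minimizes (1/2n)||y - Ac||^2 + alpha ||c||_1 per row,
    # so alpha = lam / (2 n_features) matches our objective
    n = dx_rows.shape[1]
    lasso = Lasso(alpha=lam / (2 * n), fit_intercept=False, max_iter=2000)
    C = np.empty((m, k))
    A = W.T  # (n, k)
    for r in range(m):
        lasso.fit(A, dx_rows[r])
        C[r] = lasso.coef_
    return C


def _sd_objective(dx_rows, C, W, lam) -> float:
    return float(np.sum((dx_rows - C @ W) ** 2) + lam * np.abs(C).sum())


def delta_sd(
    dx: DifferenceMatrix,
    k: int,
    lam: float,
    n_iter: int = 20,
    seed: int = 0,
) -> tuple[WeightMatrix, CoefficientMatrix]:
    """Sparse dictionary learning on the difference matrix.

    Alternates exact L1 sparse coding (coordinate descent) with exact
    per-atom dictionary updates under unit-L2 row constraints, so the
    objective ``||DX - C W||^2 + lam ||C||_1`` is non-increasing per outer
    iteration.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    m, n = dx.shape
    rng = rng_for(seed, "delta_sd")
    W = rng.normal(size=(k, n))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    C = np.zeros((m, k))
    for _ in range(n_iter):
        C = _sparse_code(dx.rows, W, lam)
        # per-atom exact update: with residual R_j excluding atom j,
        # min_{||w||=1} ||R_j - c_j w^T||^2 is solved by w = R_j^T c_j / ||.||
        R = dx.rows - C @ W
        for j in range(k):
            cj = C[:, j]
            norm_cj = np.linalg.norm(cj)
            Rj = R + np.outer(cj, W[j])
            if norm_cj < 1e-12:
                continue  # unused atom: leave direction unchanged
            wj = Rj.T @ cj
            wn = np.linalg.norm(wj)
            if wn < 1e-12:
                continue
            W[j] = wj / wn
            R = Rj - np.outer(cj, W[j])
    W = _fix_signs(W)
    C = _sparse_code(dx.rows, W, lam)
    wm = WeightMatrix(W=W, method="dsd",
                      constraints={"k": k, "lambda": lam}, seed=seed)
    return wm, CoefficientMatrix(C=C)


def _soft(a: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - thr, 0.0)


def _l1_project(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 soft-thresholded vector with L1 norm <= c (binary search).

    Returns ``S(a, t) / ||S(a, t)||_2`` with the smallest soft-threshold
    ``t >= 0`` such that the L1 norm of the result does not exceed ``c``.
    """
    norm = np.linalg.norm(a)
    if norm < 1e-14:
        return np.zeros_like(a)
    u = a / norm
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        s = _soft(a, mid)
        ns = np.linalg.norm(s)
        if ns < 1e-14 or np.abs(s / ns).sum() > c:
            lo = mid
        else:
            hi = mid
    s = _soft(a, hi)
    return s / np.linalg.norm(s)


def delta_pmd(
    dx: DifferenceMatrix,
    k: int,
    eps: float,
    delta: float,
    n_iter: int = 50,
) -> tuple[WeightMatrix, CoefficientMatrix]:
    """Penalized matrix decomposition of the difference matrix.

    Extracts ``k`` rank-1 factors ``d u v^T`` sequentially with deflation.
    Each factor solves ``max u^T DX v`` subject to ``||u||_2 <= 1``,
    ``||v||_2 <= 1``, ``||u||_1 <= delta`` and ``||v||_1 <= eps`` through
    alternating soft-thresholded power iterations; L1 bounds are met via a
    binary search on the soft-threshold level.  Rows of the returned
    weight matrix are the right factors ``v``; coefficient columns are the
    scaled left factors ``d u``.
    """
    m, n = dx.shape
    if eps < 1.0 or delta < 1.0:
        raise ValueError(
            "infeasible constraint: eps and delta must be >= 1 "
            "(L1 bounds on unit-L2 vectors)"
        )
    R = dx.rows.copy()
    V = np.empty((k, n))
    U = np.empty((m, k))
    d = np.empty(k)
    for comp in range(k):
        _, _, Vt = np.linalg.svd(R, full_matrices=False)
        v = Vt[0]
        u = np.zeros(m)
        for _ in range(n_iter):
            u_new = _l1_project(R @ v, delta)
            v_new = _l1_project(R.T @ u_new, eps)
            if (np.linalg.norm(u_new - u) < 1e-10
                    and np.linalg.norm(v_new - v) < 1e-10):
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        dval = float(u @ R @ v)
        # deterministic orientation: largest-|.| entry of v positive
        jmax = np.argmax(np.abs(v)) if np.linalg.norm(v) > 0 else 0
        if v[jmax] < 0:
            v, u = -v, -u
        V[comp], U[:, comp], d[comp] = v, u, dval
        R = R - dval * np.outer(u, v)
    wm = WeightMatrix(
        W=V, method="dpmd",
        constraints={"k": k, "eps": eps, "delta": delta}, seed=dx.seed,
    )
    return wm, CoefficientMatrix(C=U * d)


def random_projection(n: int, k: int, seed: int = 0) -> WeightMatrix:
    """Gaussian random projection rows with entry variance ``1/n``."""
    rng = rng_for(seed, "random_projection")
    W = rng.normal(scale=1.0 / np.sqrt(n), size=(k, n))
    return WeightMatrix(W=W, method="rp", constraints={"k": k}, seed=seed)


# ---------------------------------------------------------------------------
# residual metric
# ---------------------------------------------------------------------------


def reconstruction_residual(W: WeightMatrix, dx: DifferenceMatrix) -> float:
    """Squared residual of projecting difference rows onto ``rowspace(W)``.

    Uses the unconstrained least-squares coefficients regardless of the
    method that produced ``W``.
    """
    A = W.W  # (k, n)
    if A.size == 0:
        return float(np.sum(dx.rows**2))
    C, *_ = np.linalg.lstsq(A.T, dx.rows.T, rcond=None)
    recon = C.T @ A
    return float(np.sum((dx.rows - recon) ** 2))
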