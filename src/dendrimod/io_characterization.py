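"""IO curves, threshold extraction and joint ReLU-family fits.

An IO curve is the mean output spike count in the decision window as a
function of the signed number of feedforward inputs (negative counts are
inhibitory inputs), at a fixed dendritic modulation level (number of
contextually driven compartments).  Thresholds are the input counts where
the linearly interpolated curve crosses the midpoints ``s + 0.5`` between
discrete spike counts; these thresholds are the fit points for a family
of rectified-linear models fitted jointly across modulation levels:

* ``gain_per_level_shared_bias`` — per-level gain, shared bias;
* ``bias_per_level_shared_gain`` — per-level bias, shared gain;
* ``gain_per_level_shared_bias_xshift`` — per-level gain, shared bias
  and shared x-shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._rng import rng_for
from .dendritic_sim import (
    DendriticNetwork,
    SpikeTrainSet,
    encode_context_burst,
)

__all__ = [
    "IOCurve",
    "ReLUFitResult",
    "VARIANTS",
    "extract_thresholds",
    "fit_relu_family",
    "io_curve",
]

VARIANTS = (
    "gain_per_level_shared_bias",
    "bias_per_level_shared_gain",
    "gain_per_level_shared_bias_xshift",
)


@dataclass
class IOCurve:
    modulation_level: int
    input_counts: np.ndarray       # sorted signed integers
    mean_spike_counts: np.ndarray  # >= 0, averaged over trials
    n_trials: int

    def __post_init__(self):
        self.input_counts = np.asarray(self.input_counts)
        self.mean_spike_counts = np.asarray(self.mean_spike_counts, dtype=float)
        if self.input_counts.shape != self.mean_spike_counts.shape:
            raise ValueError("input_counts and mean_spike_counts differ in length")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "modulation_level": self.modulation_level,
            "input_count": self.input_counts,
            "mean_spike_count": self.mean_spike_counts,
            "n_trials": self.n_trials,
        })


@dataclass
class ReLUFitResult:
    variant: str
    per_level_params: dict[int, float]     # level -> gain or bias
    shared_params: dict[str, float]        # gain or bias (+ x_shift)
    residual: float
    n_points: int = 0

    def predict_threshold(self, level: int, spike_level: int) -> float:
        """Input count at which the fitted ReLU crosses ``spike_level+0.5``."""
        y = spike_level + 0.5
        xs = self.shared_params.get("x_shift", 0.0)
        if self.variant == "bias_per_level_shared_gain":
            g = self.shared_params["gain"]
            b = self.per_level_params[level]
        else:
            g = self.per_level_params[level]
            b = self.shared_params["bias"]
        return xs + (y - b) / g


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------


def io_curve(
    network: DendriticNetwork,
    modulation_level: int,
    input_counts: Sequence[int],
    n_trials: int = 10,
    seed: int = 0,
    *,
    neuron: int = 0,
    window_ms: float = 50.0,
    ff_burst_width: float = 6.0,
    ctx_burst_width: float = 20.0,
    ctx_mean_spikes: float = 60.0,
    t0: float = 25.0,
    duration: float = 110.0,
    dt: float = 0.1,
    ff_channel: int = 0,
    inh_channel: int | None = None,
) -> IOCurve:
    """Mean spike count of one hidden neuron per signed input count.

    Positive counts send that many excitatory feedforward spikes on
    ``ff_channel``; negative counts send spikes on ``inh_channel`` (which
    should carry a negative feedforward weight).  ``modulation_level``
    compartments receive a context burst.  Spikes are counted in the
    decision window opened by the first feedforward spike.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    input_counts = np.asarray(sorted(input_counts))
    sd = ff_burst_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    means = np.empty(len(input_counts), dtype=float)
    for ci, count in enumerate(input_counts):
        total = 0
        for trial in range(n_trials):
            rng = rng_for(seed, f"io_curve:{modulation_level}:{count}:{trial}")
            n_spk = abs(int(count))
            if n_spk > 0:
                channel = ff_channel if count > 0 else inh_channel
                if channel is None:
                    raise ValueError(
                        "negative input counts require inh_channel")
                times = np.clip(rng.normal(t0, sd, size=n_spk), 0.0, None)
                ff = SpikeTrainSet(ids=np.full(n_spk, channel), times=times)
            else:
                ff = SpikeTrainSet.empty()
            ctx = _context_for_level(
                network, modulation_level, t0, ctx_burst_width,
                ctx_mean_spikes,
                seed=int(rng.integers(0, 2**31 - 1)), neuron=neuron,
            )
            res = network.simulate(ff, ctx, duration, dt)
            spikes = res.hidden_spikes[neuron]
            if len(ff):
                t_open = float(ff.times[0])
                in_win = (spikes >= t_open) & (spikes <= t_open + window_ms)
                total += int(in_win.sum())
        means[ci] = total / n_trials
    return IOCurve(modulation_level, input_counts, means, n_trials)


def _context_for_level(
    network: DendriticNetwork,
    level: int,
    t0: float,
    width: float,
    mean_spikes: float,
    seed: int,
    neuron: int,
) -> SpikeTrainSet:
    """Context bursts on the first ``level`` compartments of one neuron.

    Uses one context channel per driven compartment; the caller is
    expected to have configured ``w_ctx`` so channel ``d`` targets
    compartment ``d`` of ``neuron`` (see :func:`single_neuron_io_network`).
    """
    if level == 0:
        return SpikeTrainSet.empty()
    if level > network.n_ctx:
        raise ValueError("modulation level exceeds context channel count")
    trains = [
        encode_context_burst(True, t0, seed, channel=d,
                             mean_spikes=mean_spikes, width=width)
        for d in range(level)
    ]
    return SpikeTrainSet.merge(trains)


def single_neuron_io_network(
    n_compartments: int = 8,
    seed: int = 0,
    *,
    w_ctx: float = 0.8,
    ff_weight: float = 1.0,
    params=None,
    **net_kwargs,
) -> DendriticNetwork:
    """One hidden neuron wired for IO-curve probing.

    Feedforward channel 0 is excitatory (weight ``+ff_weight``), channel 1
    inhibitory (``-ff_weight``); context channel ``d`` targets compartment
    ``d`` only, so the modulation level equals the number of driven
    compartments.
    """
    from .dendritic_sim import DendriticNeuronParams

    if params is None:
        params = DendriticNeuronParams(n_compartments=n_compartments)
    W_ff = np.array([[ff_weight, -ff_weight]])
    net = DendriticNetwork(params, W_ff, n_ctx=n_compartments, seed=seed,
                           **net_kwargs)
    net.w_ctx[:] = 0.0
    for d in range(n_compartments):
        net.w_ctx[d, 0, d] = w_ctx
    return net


# ---------------------------------------------------------------------------
# threshold extraction
# ---------------------------------------------------------------------------


def extract_thresholds(curve: IOCurve) -> np.ndarray:
    """Input counts where the interpolated curve crosses ``s + 0.5``.

    For each integer spike level ``s`` the curve attains, the crossing of
    the midpoint ``s + 0.5`` is located by linear interpolation between
    adjacent grid points; an exact hit on a grid point returns that grid
    point.  Multiple crossings for one level raise a ``ValueError``
    listing the candidates.
    """
    x = np.asarray(curve.input_counts, dtype=float)
    y = curve.mean_spike_counts
    max_level = int(np.floor(y.max() - 0.5)) if y.max() >= 0.5 else -1
    thresholds = []
    for s in range(max_level + 1):
        target = s + 0.5
        candidates = []
        for i in range(len(x) - 1):
            y0, y1 = y[i], y[i + 1]
            if y0 == target and (i == 0 or y[i - 1] != target):
                candidates.append(x[i])
            lo, hi = min(y0, y1), max(y0, y1)
            if lo < target < hi:
                frac = (target - y0) / (y1 - y0)
                candidates.append(x[i] + frac * (x[i + 1] - x[i]))
        if y[-1] == target:
            candidates.append(x[-1])
        candidates = sorted(set(candidates))
        if len(candidates) > 1:
            raise ValueError(
                f"ambiguous crossing for spike level {s}: candidates "
                f"{candidates}"
            )
        if candidates:
            thresholds.append(candidates[0])
    return np.asarray(thresholds)


# ---------------------------------------------------------------------------
# joint ReLU fits
# ---------------------------------------------------------------------------


def _pack_points(thresholds_by_level: Mapping[int, Sequence[float]]):
    levels = sorted(thresholds_by_level)
    xs, ys, lv = [], [], []
    for level in levels:
        for s, thr in enumerate(thresholds_by_level[level]):
            xs.append(float(thr))
            ys.append(s + 0.5)
            lv.append(level)
    return levels, np.asarray(xs), np.asarray(ys), np.asarray(lv)


def fit_relu_family(
    thresholds_by_level: Mapping[int, Sequence[float]],
    variant: str,
    *,
    n_starts: int = 8,
    seed: int = 0,
) -> ReLUFitResult:
    """Joint sum-of-squares fit of one ReLU parameterization to all levels.

    Fit points are the pairs ``(threshold_{m,s}, s + 0.5)`` and the model
    evaluates the pre-rectifier line (the fit points lie above zero by
    construction).  Multi-start local least squares.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    levels, xs, ys, lv = _pack_points(thresholds_by_level)
    if len(levels) < 2:
        raise ValueError("need thresholds for at least 2 modulation levels")
    if len(xs) < len(levels) + 1:
        raise ValueError("not enough fit points for the parameter count")
    n_lv = len(levels)
    lv_index = np.searchsorted(levels, lv)

    def residuals(theta):
        if variant == "gain_per_level_shared_bias":
            g = theta[:n_lv][lv_index]
            b = theta[n_lv]
            return g * xs + b - ys
        if variant == "bias_per_level_shared_gain":
            g = theta[0]
            b = theta[1:][lv_index]
            return g * xs + b - ys
        g = theta[:n_lv][lv_index]
        b = theta[n_lv]
        x_shift = theta[n_lv + 1]
        return g * (xs - x_shift) + b - ys

    n_params = {
        "gain_per_level_shared_bias": n_lv + 1,
        "bias_per_level_shared_gain": n_lv + 1,
        "gain_per_level_shared_bias_xshift": n_lv + 2,
    }[variant]

    rng = rng_for(seed, "fit_relu_family")
    best = None
    for start in range(n_starts):
        if start == 0:
            theta0 = np.ones(n_params) * 0.1
        else:
            theta0 = rng.normal(scale=1.0, size=n_params)
        try:
            sol = least_squares(residuals, theta0, xtol=1e-14, ftol=1e-14,
                                gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")

    theta = best.x
    if variant == "gain_per_level_shared_bias":
        per_level = {m: float(theta[i]) for i, m in enumerate(levels)}
        shared = {"bias": float(theta[n_lv])}
    elif variant == "bias_per_level_shared_gain":
        per_level = {m: float(theta[1 + i]) for i, m in enumerate(levels)}
        shared = {"gain": float(theta[0])}
    else:
        per_level = {m: float(theta[i]) for i, m in enumerate(levels)}
        shared = {"bias": float(theta[n_lv]), "x_shift": float(theta[n_lv + 1])}
    res = residuals(theta)
    return ReLUFitResult(
        variant=variant,
        per_level_params=per_level,
        shared_params=shared,
        residual=float(res @ res),
        n_points=len(xs),
    )
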