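"""Spiking network with NMDA-like dendritic compartments.

Phenomenological reduction of a pyramidal neuron: a leaky
threshold-reset soma star-coupled to ``D`` leaky dendritic compartments.
Context synapses (AMPA + NMDA with a Jahr–Stevens-style Mg-block sigmoid)
impinge on the dendrites; current-based feedforward synapses impinge on
the soma.  Hidden neurons project to a single-compartment output neuron
through uniform-with-noise static weights.

Units: mV, ms, nS, pF, pA (so tau = C/g is in ms).

Episodes follow a 50-ms decision protocol: the first feedforward spike
opens the window; at least one output spike in the window means "other"
(random sample), zero spikes mean the target class.  Dendritic synapses
learn online with a four-factor rule,

    dw = eta * error * post_trace * pre_trace * phi(v_dend_trace),

where ``error`` is a global per-episode scalar in {-1, 0, +1} emitted
only on erroneous firing/silence, the traces are low-pass filters of
somatic spikes, presynaptic spikes and local dendritic voltage, and
``phi`` is a bounded non-negative voltage modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import rng_for

__all__ = [
    "DendriticNetwork",
    "DendriticNeuronParams",
    "EpisodeProtocol",
    "IntegrationError",
    "PlasticityConfig",
    "PlasticityState",
    "SimResult",
    "SpikeTrainSet",
    "build_xor_network",
    "classify_window",
    "effective_conductance",
    "encode_context_burst",
    "encode_image_burst",
    "phi_voltage_modulation",
    "plasticity_update",
    "run_online_learning",
    "simulate_network",
]

# Gaussian burst "width" is interpreted as a full width at half maximum;
# spike times are drawn with SD = width / (2 * sqrt(2 ln 2)).
_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class IntegrationError(RuntimeError):
    """Raised when a compartment voltage leaves the stable range."""


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrainSet:
    """Events ``(synapse_id, time_ms)`` sorted by time."""

    ids: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and self.times.min() < 0:
            raise ValueError("spike times must be >= 0")
        order = np.argsort(self.times, kind="stable")
        self.ids = self.ids[order]
        self.times = self.times[order]

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def empty(cls) -> "SpikeTrainSet":
        return cls(ids=np.empty(0, dtype=int), times=np.empty(0))

    @classmethod
    def merge(cls, trains: Sequence["SpikeTrainSet"]) -> "SpikeTrainSet":
        if not trains:
            return cls.empty()
        return cls(
            ids=np.concatenate([t.ids for t in trains]),
            times=np.concatenate([t.times for t in trains]),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"synapse_id": self.ids, "t_ms": self.times}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeTrainSet":
        df = pd.read_csv(path)
        return cls(ids=df["synapse_id"].to_numpy(),
                   times=df["t_ms"].to_numpy())


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class SomaParams:
    C_m: float = 200.0      # pF
    g_L: float = 10.0       # nS
    E_L: float = -70.0      # mV
    V_th: float = -50.0     # mV
    V_reset: float = -65.0  # mV
    t_ref: float = 3.0      # ms


@dataclass
class DendriteParams:
    C_m: float = 20.0   # pF
    g_L: float = 1.0    # nS
    E_L: float = -70.0  # mV
    g_c: float = 1.0    # nS, coupling to soma


@dataclass
class NmdaParams:
    g_max: float = 1.0        # nS per unit weight
    tau_rise: float = 2.0     # ms
    tau_decay: float = 80.0   # ms; plateau outlasts the burst by 50-100 ms
    E_rev: float = 0.0        # mV
    mg_half: float = -20.0    # mV, sigmoid midpoint of the Mg-block
    mg_slope: float = 12.0    # mV


@dataclass
class AmpaParams:
    g_max: float = 0.3   # nS per unit weight
    tau: float = 2.0     # ms
    E_rev: float = 0.0   # mV


@dataclass
class DendriticNeuronParams:
    soma: SomaParams = field(default_factory=SomaParams)
    dendrite: DendriteParams = field(default_factory=DendriteParams)
    nmda: NmdaParams = field(default_factory=NmdaParams)
    ampa: AmpaParams = field(default_factory=AmpaParams)
    n_compartments: int = 40

    def __post_init__(self):
        if self.n_compartments < 0:
            raise ValueError("n_compartments must be >= 0")
        for name, value in (
            ("soma.C_m", self.soma.C_m), ("soma.g_L", self.soma.g_L),
            ("dendrite.C_m", self.dendrite.C_m),
            ("dendrite.g_L", self.dendrite.g_L),
            ("dendrite.g_c", self.dendrite.g_c),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.soma.V_reset >= self.soma.V_th:
            raise ValueError("V_reset must be below V_th")


@dataclass
class EpisodeProtocol:
    """Timing and encoding constants of one classification episode."""

    window_ms: float = 50.0
    ff_burst_width: float = 6.0     # FWHM of the feedforward burst, ms
    ctx_burst_width: float = 20.0   # FWHM of the context burst, ms
    ctx_mean_spikes: float = 60.0
    out_weight_cv: float = 0.1      # sigma/mu of the output weights
    t0: float = 55.0                # feedforward burst center, ms
    ctx_t0: float = 15.0            # context burst center, ms; the context
                                    # leads so the NMDA plateau is
                                    # established when the fast burst hits
    duration: float = 130.0         # simulated time per episode, ms
    dt: float = 0.1                 # ms
    rate_scale: float = 15.0        # mean feedforward spikes per unit intensity


# ---------------------------------------------------------------------------
# burst encoders
# ---------------------------------------------------------------------------


def encode_image_burst(
    pixels: np.ndarray,
    t0: float,
    rate_scale: float,
    seed: int,
    width: float = 6.0,
) -> SpikeTrainSet:
    """Per-pixel Gaussian spike bursts, counts proportional to intensity.

    Pixel ``j`` contributes ``Poisson(rate_scale * pixels[j])`` spikes on
    synapse id ``j``, with times Gaussian around ``t0`` (FWHM ``width``).
    """
    pixels = np.asarray(pixels, dtype=float)
    if (pixels < 0).any():
        raise ValueError("pixel intensities must be >= 0")
    rng = rng_for(seed, "encode_image_burst")
    counts = rng.poisson(rate_scale * pixels)
    total = int(counts.sum())
    if total == 0:
        return SpikeTrainSet.empty()
    ids = np.repeat(np.arange(pixels.size), counts)
    times = rng.normal(t0, width * _FWHM_TO_SD, size=total)
    times = np.clip(times, 0.0, None)
    return SpikeTrainSet(ids=ids, times=times)


def encode_context_burst(
    active: bool,
    t0: float,
    seed: int,
    channel: int = 0,
    mean_spikes: float = 60.0,
    width: float = 20.0,
) -> SpikeTrainSet:
    """Wide Gaussian context burst; empty when the context is inactive."""
    if not active:
        return SpikeTrainSet.empty()
    rng = rng_for(seed, f"encode_context_burst:{channel}")
    count = rng.poisson(mean_spikes)
    if count == 0:
        return SpikeTrainSet.empty()
    times = np.clip(rng.normal(t0, width * _FWHM_TO_SD, size=count), 0.0, None)
    ids = np.full(count, channel, dtype=int)
    return SpikeTrainSet(ids=ids, times=times)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _mg_block(V: np.ndarray, nmda: NmdaParams) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(V - nmda.mg_half) / nmda.mg_slope))


def _nmda_norm(nmda: NmdaParams) -> float:
    tr, td = nmda.tau_rise, nmda.tau_decay
    tp = tr * td / (td - tr) * np.log(td / tr)
    return float(np.exp(-tp / td) - np.exp(-tp / tr))


@dataclass
class SimResult:
    output_spikes: np.ndarray                 # times, ms
    hidden_spikes: list[np.ndarray]           # per hidden neuron
    t: np.ndarray | None = None
    V_soma: np.ndarray | None = None          # (T, n_hidden)
    V_dend: np.ndarray | None = None          # (T, n_hidden, D)
    V_out: np.ndarray | None = None           # (T,)
    traces: dict | None = None                # plasticity traces at end


class DendriticNetwork:
    """Hidden layer of dendritic neurons plus a single output neuron.

    Parameters
    ----------
    params:
        Shared neuron parameters (``n_compartments`` sets ``D``).
    W_ff:
        ``(n_hidden, n_ff_channels)`` static feedforward weights; each
        entry scales the current injected into a hidden soma per spike on
        that channel.  Entries may be negative (inhibitory).
    n_ctx:
        Number of context channels.  Plastic weights ``w_ctx`` have shape
        ``(n_ctx, n_hidden, D)`` and scale AMPA+NMDA conductance
        increments on each compartment.
    """

    def __init__(
        self,
        params: DendriticNeuronParams,
        W_ff: np.ndarray,
        n_ctx: int,
        seed: int = 0,
        *,
        ff_current_scale: float = 30.0,   # pA per unit weight per spike
        ff_tau: float = 2.0,              # ms
        out_current_scale: float = 1.0,   # pA per unit output weight
        out_tau: float = 2.0,             # ms
        out_weight_mu: float = 120.0,     # pA, mean output weight
        out_weight_cv: float = 0.1,
        w_ctx_init: float = 0.5,
        w_max: float = 1.0,
    ):
        self.params = params
        self.W_ff = np.asarray(W_ff, dtype=float)
        self.n_hidden = self.W_ff.shape[0]
        self.n_ff = self.W_ff.shape[1]
        self.n_ctx = n_ctx
        self.D = params.n_compartments
        self.ff_current_scale = ff_current_scale
        self.ff_tau = ff_tau
        self.out_current_scale = out_current_scale
        self.out_tau = out_tau
        self.w_max = w_max
        rng = rng_for(seed, "dendritic_network")
        # output weights: uniform with Gaussian variability (sigma/mu fixed)
        self.w_out = np.clip(
            out_weight_mu * (1.0 + out_weight_cv * rng.normal(size=self.n_hidden)),
            0.0, None,
        )
        self.w_ctx = np.full((n_ctx, self.n_hidden, self.D), w_ctx_init)

    # -- simulation --------------------------------------------------------

    def simulate(
        self,
        ff_spikes: SpikeTrainSet,
        ctx_spikes: SpikeTrainSet,
        duration: float,
        dt: float = 0.1,
        *,
        record: bool = False,
        record_every: int = 1,
        trace_taus: tuple[float, float, float] = (30.0, 30.0, 50.0),
        clamp_soma: float | None = None,
        extra_soma_conductance: tuple[float, float] | None = None,
        trace_snapshot_t: float | None = None,
    ) -> SimResult:
        """Exponential-Euler integration of the full network.

        ``clamp_soma`` holds every hidden somatic voltage at the given
        value (voltage clamp); ``extra_soma_conductance`` adds a constant
        linear conductance ``(g_s, E_s)`` at the hidden somata.  Both are
        used by the effective-conductance probe.
        """
        p = self.params
        n_h, D = self.n_hidden, self.D
        n_steps = int(round(duration / dt))
        tau_pre, tau_post, tau_v = trace_taus

        V_s = np.full(n_h, p.soma.E_L)
        V_d = np.full((n_h, D), p.dendrite.E_L)
        g_ampa = np.zeros((n_h, D))
        z_r = np.zeros((n_h, D))
        z_d = np.zeros((n_h, D))
        I_ff = np.zeros(n_h)
        refrac = np.zeros(n_h)
        V_o = p.soma.E_L
        I_o = 0.0
        refrac_o = 0.0

        pre_trace = np.zeros(self.n_ctx)
        post_trace = np.zeros(n_h)
        v_trace = np.full((n_h, D), p.dendrite.E_L)

        nmda_norm = _nmda_norm(p.nmda)
        dec_ampa = np.exp(-dt / p.ampa.tau)
        dec_zr = np.exp(-dt / p.nmda.tau_rise)
        dec_zd = np.exp(-dt / p.nmda.tau_decay)
        dec_ff = np.exp(-dt / self.ff_tau)
        dec_out = np.exp(-dt / self.out_tau)
        dec_pre = np.exp(-dt / tau_pre)
        dec_post = np.exp(-dt / tau_post)
        alpha_v = dt / tau_v

        ff_steps = np.minimum((ff_spikes.times / dt).astype(int), n_steps - 1) \
            if len(ff_spikes) else np.empty(0, dtype=int)
        ctx_steps = np.minimum((ctx_spikes.times / dt).astype(int), n_steps - 1) \
            if len(ctx_spikes) else np.empty(0, dtype=int)

        out_spikes: list[float] = []
        hid_spikes: list[list[float]] = [[] for _ in range(n_h)]

        rec_t, rec_Vs, rec_Vd, rec_Vo = [], [], [], []
        ff_ptr = ctx_ptr = 0
        snapshot_step = (
            int(round(trace_snapshot_t / dt))
            if trace_snapshot_t is not None else None
        )
        snapshot: dict | None = None

        for step in range(n_steps):
            t = step * dt
            # deliver spikes binned to this step
            while ff_ptr < len(ff_steps) and ff_steps[ff_ptr] == step:
                ch = ff_spikes.ids[ff_ptr]
                I_ff += self.W_ff[:, ch] * self.ff_current_scale
                ff_ptr += 1
            while ctx_ptr < len(ctx_steps) and ctx_steps[ctx_ptr] == step:
                ch = ctx_spikes.ids[ctx_ptr]
                w = self.w_ctx[ch]
                g_ampa += w * p.ampa.g_max
                inc = w * p.nmda.g_max / nmda_norm
                z_r += inc
                z_d += inc
                pre_trace[ch] += 1.0
                ctx_ptr += 1

            g_nmda = (z_d - z_r) * _mg_block(V_d, p.nmda)
            g_syn = g_ampa + np.clip(g_nmda, 0.0, None)

            # dendrites (soma voltage frozen within the step)
            g_tot_d = p.dendrite.g_L + p.dendrite.g_c + g_syn
            E_eff_d = (
                p.dendrite.g_L * p.dendrite.E_L
                + p.dendrite.g_c * V_s[:, None]
                + g_syn * p.ampa.E_rev
            ) / g_tot_d
            V_d = E_eff_d + (V_d - E_eff_d) * np.exp(
                -dt * g_tot_d / p.dendrite.C_m
            )

            # hidden somata
            if clamp_soma is None:
                g_tot_s = p.soma.g_L + D * p.dendrite.g_c
                I_extra = 0.0
                if extra_soma_conductance is not None:
                    g_s, E_s = extra_soma_conductance
                    g_tot_s = g_tot_s + g_s
                    I_extra = g_s * E_s
                numer = (
                    p.soma.g_L * p.soma.E_L
                    + p.dendrite.g_c * V_d.sum(axis=1)
                    + I_ff + I_extra
                )
                E_eff_s = numer / g_tot_s
                V_new = E_eff_s + (V_s - E_eff_s) * np.exp(
                    -dt * g_tot_s / p.soma.C_m
                )
                in_ref = refrac > 0
                V_s = np.where(in_ref, p.soma.V_reset, V_new)
                refrac = np.maximum(refrac - dt, 0.0)
                fired = (V_s >= p.soma.V_th) & ~in_ref
                if fired.any():
                    for i in np.flatnonzero(fired):
                        hid_spikes[i].append(t)
                    I_o += float(self.w_out[fired].sum()) * self.out_current_scale
                    post_trace[fired] += 1.0
                    V_s[fired] = p.soma.V_reset
                    refrac[fired] = p.soma.t_ref
            else:
                V_s = np.full(n_h, clamp_soma)

            # output neuron
            g_tot_o = p.soma.g_L
            E_eff_o = (p.soma.g_L * p.soma.E_L + I_o) / g_tot_o
            V_o_new = E_eff_o + (V_o - E_eff_o) * np.exp(
                -dt * g_tot_o / p.soma.C_m
            )
            if refrac_o > 0:
                V_o = p.soma.V_reset
                refrac_o = max(refrac_o - dt, 0.0)
            else:
                V_o = V_o_new
                if V_o >= p.soma.V_th:
                    out_spikes.append(t)
                    V_o = p.soma.V_reset
                    refrac_o = p.soma.t_ref

            # decays and traces
            I_ff *= dec_ff
            I_o *= dec_out
            g_ampa *= dec_ampa
            z_r *= dec_zr
            z_d *= dec_zd
            pre_trace *= dec_pre
            post_trace *= dec_post
            v_trace += alpha_v * (V_d - v_trace)

            if not np.isfinite(V_d).all() or not np.isfinite(V_s).all():
                bad = np.argwhere(~np.isfinite(V_d))
                where = (
                    f"dendrite (neuron {bad[0][0]}, compartment {bad[0][1]})"
                    if len(bad) else "soma"
                )
                raise IntegrationError(
                    f"voltage diverged at t={t:.2f} ms in {where}"
                )

            if snapshot_step is not None and step == snapshot_step:
                snapshot = {
                    "pre": pre_trace.copy(),
                    "post": post_trace.copy(),
                    "v_dend": v_trace.copy(),
                }

            if record and step % record_every == 0:
                rec_t.append(t)
                rec_Vs.append(V_s.copy())
                rec_Vd.append(V_d.copy())
                rec_Vo.append(V_o)

        traces = snapshot if snapshot is not None else {
            "pre": pre_trace,
            "post": post_trace,
            "v_dend": v_trace,
        }
        return SimResult(
            output_spikes=np.asarray(out_spikes),
            hidden_spikes=[np.asarray(s) for s in hid_spikes],
            t=np.asarray(rec_t) if record else None,
            V_soma=np.asarray(rec_Vs) if record else None,
            V_dend=np.asarray(rec_Vd) if record else None,
            V_out=np.asarray(rec_Vo) if record else None,
            traces=traces,
        )


def simulate_network(
    network: DendriticNetwork,
    ff_spikes: SpikeTrainSet,
    ctx_spikes: SpikeTrainSet | None = None,
    duration: float = 110.0,
    dt: float = 0.1,
    **kwargs,
) -> SimResult:
    """Functional wrapper around :meth:`DendriticNetwork.simulate`."""
    if ctx_spikes is None:
        ctx_spikes = SpikeTrainSet.empty()
    return network.simulate(ff_spikes, ctx_spikes, duration, dt, **kwargs)


# ---------------------------------------------------------------------------
# decision window
# ---------------------------------------------------------------------------


def classify_window(
    output_spikes: np.ndarray, window: tuple[float, float]
) -> str:
    """At least one spike inside the closed window means "other"."""
    lo, hi = window
    output_spikes = np.asarray(output_spikes)
    inside = (output_spikes >= lo) & (output_spikes <= hi)
    return "other" if inside.any() else "target_class"


# ---------------------------------------------------------------------------
# plasticity
# ---------------------------------------------------------------------------


def phi_voltage_modulation(
    v: np.ndarray, mid: float = -55.0, slope: float = 5.0
) -> np.ndarray:
    """Bounded non-negative learning-rate modulation of dendritic voltage."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - mid) / slope))


@dataclass
class PlasticityState:
    """Trace snapshot entering a weight update."""

    pre_trace: np.ndarray      # (n_ctx,)
    post_trace: np.ndarray     # (n_hidden,)
    v_dend_trace: np.ndarray   # (n_hidden, D)
    eta: float
    error: int                 # in {-1, 0, +1}


def plasticity_update(
    state: PlasticityState,
    phi: Callable[[np.ndarray], np.ndarray] = phi_voltage_modulation,
) -> np.ndarray:
    """Four-factor weight deltas, shape ``(n_ctx, n_hidden, D)``.

    ``dw = eta * error * post * pre * phi(v_dend_trace)``; zero whenever
    any factor is zero.
    """
    if state.error == 0:
        n_ctx = len(state.pre_trace)
        n_h, D = state.v_dend_trace.shape
        return np.zeros((n_ctx, n_h, D))
    mod = phi(state.v_dend_trace)                      # (n_h, D)
    hebb = state.post_trace[:, None] * mod             # (n_h, D)
    return state.eta * state.error * state.pre_trace[:, None, None] * hebb


# ---------------------------------------------------------------------------
# online learning
# ---------------------------------------------------------------------------


@dataclass
class PlasticityConfig:
    eta: float = 0.05
    tau_pre: float = 30.0
    tau_post: float = 30.0
    tau_v: float = 50.0
    phi_mid: float = -55.0
    phi_slope: float = 5.0


@dataclass
class Episode:
    """Fully encoded episode for the online-learning loop."""

    ff_spikes: SpikeTrainSet
    ctx_spikes: SpikeTrainSet
    should_spike: bool   # True: output must spike ("other"/random sample)


def _episode_outcome(
    network: DendriticNetwork,
    ep: Episode,
    protocol: EpisodeProtocol,
    pcfg: PlasticityConfig,
):
    if len(ep.ff_spikes) == 0:
        t_open = None
        snapshot_t = None
    else:
        t_open = float(ep.ff_spikes.times[0])
        snapshot_t = min(t_open + protocol.window_ms,
                         protocol.duration - protocol.dt)
    res = network.simulate(
        ep.ff_spikes, ep.ctx_spikes, protocol.duration, protocol.dt,
        trace_taus=(pcfg.tau_pre, pcfg.tau_post, pcfg.tau_v),
        trace_snapshot_t=snapshot_t,
    )
    if t_open is None:
        decision = "target_class"
    else:
        decision = classify_window(
            res.output_spikes, (t_open, t_open + protocol.window_ms))
    spiked = decision == "other"
    correct = spiked == ep.should_spike
    if correct:
        error = 0
    else:
        # erroneous silence -> potentiate; erroneous firing -> depress
        error = +1 if ep.should_spike else -1
    return res, error, correct


def run_online_learning(
    network: DendriticNetwork,
    episodes: Sequence[Episode],
    protocol: EpisodeProtocol | None = None,
    pcfg: PlasticityConfig | None = None,
    *,
    eval_episodes: Sequence[Episode] | None = None,
    eval_every: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stream episodes, committing a weight update at each window close.

    Returns the learned context weights and a training curve with a
    moving-average accuracy (plus held-out accuracy when requested).
    """
    protocol = protocol or EpisodeProtocol()
    pcfg = pcfg or PlasticityConfig()
    rows = []
    recent: list[bool] = []
    phi = lambda v: phi_voltage_modulation(v, pcfg.phi_mid, pcfg.phi_slope)
    for i, ep in enumerate(episodes):
        res, error, correct = _episode_outcome(network, ep, protocol, pcfg)
        if error != 0 and pcfg.eta != 0.0:
            state = PlasticityState(
                pre_trace=res.traces["pre"],
                post_trace=res.traces["post"],
                v_dend_trace=res.traces["v_dend"],
                eta=pcfg.eta,
                error=error,
            )
            network.w_ctx = np.clip(
                network.w_ctx + plasticity_update(state, phi),
                0.0, network.w_max,
            )
        recent.append(correct)
        if len(recent) > 50:
            recent.pop(0)
        row = {"episode": i, "correct": correct,
               "train_acc_ma": float(np.mean(recent))}
        if (eval_episodes is not None and eval_every is not None
                and (i + 1) % eval_every == 0):
            row["eval_acc"] = evaluate_episodes(
                network, eval_episodes, protocol, pcfg)
        rows.append(row)
    return network.w_ctx, pd.DataFrame(rows)


def evaluate_episodes(
    network: DendriticNetwork,
    episodes: Sequence[Episode],
    protocol: EpisodeProtocol | None = None,
    pcfg: PlasticityConfig | None = None,
) -> float:
    """Accuracy over episodes with plasticity switched off."""
    protocol = protocol or EpisodeProtocol()
    pcfg = pcfg or PlasticityConfig()
    n_correct = 0
    for ep in episodes:
        _, _, correct = _episode_outcome(network, ep, protocol, pcfg)
        n_correct += correct
    return n_correct / max(len(episodes), 1)


# ---------------------------------------------------------------------------
# XOR network construction
# ---------------------------------------------------------------------------


def build_xor_network(
    seed: int = 0,
    *,
    n_hidden: int = 8,
    n_compartments: int = 4,
    params: DendriticNeuronParams | None = None,
    ff_weight: float = 1.0,
    **net_kwargs,
) -> DendriticNetwork:
    """Network for the XOR episode set.

    Two feedforward channels (the binary inputs).  Hidden feedforward
    weight rows cycle through the four signed combinations
    ``(+1,-1), (-1,+1), (+1,+1), (+0.5,+0.5)`` scaled by ``ff_weight`` —
    the difference directions of the XOR input set and their negations,
    each realized by its own neuron since a spiking neuron reads only one
    half-space.  A single always-active context channel is plastic.
    """
    if params is None:
        params = DendriticNeuronParams(n_compartments=n_compartments)
    else:
        params = replace(params, n_compartments=n_compartments)
    base = np.array([
        [1.0, -1.0],
        [-1.0, 1.0],
        [1.0, 1.0],
        [0.5, 0.5],
    ])
    reps = int(np.ceil(n_hidden / len(base)))
    W_ff = np.tile(base, (reps, 1))[:n_hidden] * ff_weight
    # calibrated so the strongest unboosted drive (both inputs on a
    # (+1,+1) neuron) stays subthreshold while a single input plus a full
    # dendritic plateau fires reliably
    net_kwargs.setdefault("ff_current_scale", 42.0)
    net_kwargs.setdefault("out_weight_mu", 2500.0)
    net_kwargs.setdefault("w_ctx_init", 0.9)
    return DendriticNetwork(params, W_ff, n_ctx=1, seed=seed, **net_kwargs)


# ---------------------------------------------------------------------------
# effective conductance probe
# ---------------------------------------------------------------------------


def effective_conductance(
    network: DendriticNetwork,
    ctx_spikes: SpikeTrainSet,
    holding_potentials: Sequence[float],
    duration: float = 100.0,
    dt: float = 0.1,
    *,
    neuron: int = 0,
    extra_soma_conductance: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Slope of clamp current vs holding potential at each time point.

    The hidden soma of ``neuron`` is voltage-clamped at each holding
    potential in turn while the same input pattern is replayed; the
    returned series is the least-squares slope (nS) of the clamp current
    across potentials, per time point.  Dendrites start from their
    per-potential steady state so the passive probe is time-invariant.
    """
    if len(holding_potentials) < 2:
        raise ValueError("need at least 2 holding potentials")
    p = network.params
    n_steps = int(round(duration / dt))
    currents = np.empty((len(holding_potentials), n_steps))
    for h, V_h in enumerate(holding_potentials):
        res = _clamped_run(network, ctx_spikes, V_h, duration, dt,
                           extra_soma_conductance)
        currents[h] = res[:, neuron]
    V = np.asarray(holding_potentials, dtype=float)
    Vc = V - V.mean()
    slope = (Vc @ (currents - currents.mean(axis=0))) / (Vc @ Vc)
    t = np.arange(n_steps) * dt
    return t, slope


def _clamped_run(
    network: DendriticNetwork,
    ctx_spikes: SpikeTrainSet,
    V_h: float,
    duration: float,
    dt: float,
    extra_soma_conductance: tuple[float, float] | None,
) -> np.ndarray:
    """Clamp currents (pA) per step and hidden neuron at holding V_h."""
    p = network.params
    n_h, D = network.n_hidden, network.D
    n_steps = int(round(duration / dt))

    # dendritic steady state under the clamp (no synaptic input)
    g_tot0 = p.dendrite.g_L + p.dendrite.g_c
    V_d = np.full(
        (n_h, D),
        (p.dendrite.g_L * p.dendrite.E_L + p.dendrite.g_c * V_h) / g_tot0,
    )
    g_ampa = np.zeros((n_h, D))
    z_r = np.zeros((n_h, D))
    z_d = np.zeros((n_h, D))
    nmda_norm = _nmda_norm(p.nmda)
    dec_ampa = np.exp(-dt / p.ampa.tau)
    dec_zr = np.exp(-dt / p.nmda.tau_rise)
    dec_zd = np.exp(-dt / p.nmda.tau_decay)
    ctx_steps = np.minimum((ctx_spikes.times / dt).astype(int), n_steps - 1) \
        if len(ctx_spikes) else np.empty(0, dtype=int)
    ptr = 0
    out = np.empty((n_steps, n_h))
    for step in range(n_steps):
        while ptr < len(ctx_steps) and ctx_steps[ptr] == step:
            ch = ctx_spikes.ids[ptr]
            w = network.w_ctx[ch]
            g_ampa += w * p.ampa.g_max
            inc = w * p.nmda.g_max / nmda_norm
            z_r += inc
            z_d += inc
            ptr += 1
        g_nmda = (z_d - z_r) * _mg_block(V_d, p.nmda)
        g_syn = g_ampa + np.clip(g_nmda, 0.0, None)
        # clamp current = what the electrode must supply to hold V_h
        I = p.soma.g_L * (V_h - p.soma.E_L) + (
            p.dendrite.g_c * (V_h - V_d)
        ).sum(axis=1)
        if extra_soma_conductance is not None:
            g_s, E_s = extra_soma_conductance
            I = I + g_s * (V_h - E_s)
        out[step] = I
        g_tot_d = p.dendrite.g_L + p.dendrite.g_c + g_syn
        E_eff_d = (
            p.dendrite.g_L * p.dendrite.E_L
            + p.dendrite.g_c * V_h
            + g_syn * p.ampa.E_rev
        ) / g_tot_d
        V_d = E_eff_d + (V_d - E_eff_d) * np.exp(-dt * g_tot_d / p.dendrite.C_m)
        g_ampa *= dec_ampa
        z_r *= dec_zr
        z_d *= dec_zd
    return out
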