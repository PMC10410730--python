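"""End-to-end spiking experiments: XOR and one-vs-all glyph tasks.

These wire the pieces together: feedforward weights come from
:mod:`dendrimod.delta_weights`, inputs are burst-encoded, and dendritic
context synapses learn online with the four-factor rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import derive_seed, rng_for
from .delta_weights import (
    WeightMatrix,
    delta_pmd,
    random_projection,
    sample_differences,
)
from .dendritic_sim import (
    DendriticNetwork,
    DendriticNeuronParams,
    Episode,
    EpisodeProtocol,
    PlasticityConfig,
    SpikeTrainSet,
    build_xor_network,
    encode_context_burst,
    encode_image_burst,
    evaluate_episodes,
    run_online_learning,
)
from .synthetic_data import XorEpisode, gen_glyph_images, gen_xor_episodes

__all__ = [
    "encode_xor_episode",
    "make_glyph_episodes",
    "make_glyph_network",
    "run_glyph_spiking_experiment",
    "run_xor_experiment",
]


# ---------------------------------------------------------------------------
# XOR
# ---------------------------------------------------------------------------


def encode_xor_episode(
    ep: XorEpisode,
    protocol: EpisodeProtocol,
    *,
    n_input_spikes: int = 30,
) -> Episode:
    """Burst-encode one XOR trial.

    Active binary inputs become feedforward bursts on channels 0/1; a
    single always-active context channel carries the wide burst.  The
    output neuron must spike when XOR is true.
    """
    trains = []
    for channel, active in ((0, ep.input_a), (1, ep.input_b)):
        if not active:
            continue
        rng = rng_for(ep.seed, f"xor_ff:{channel}")
        sd = protocol.ff_burst_width / (2 * np.sqrt(2 * np.log(2)))
        times = np.clip(
            rng.normal(protocol.t0, sd, size=n_input_spikes), 0.0, None)
        trains.append(SpikeTrainSet(ids=np.full(n_input_spikes, channel),
                                    times=times))
    ff = SpikeTrainSet.merge(trains) if trains else SpikeTrainSet.empty()
    ctx = encode_context_burst(
        True, protocol.ctx_t0, ep.seed, channel=0,
        mean_spikes=protocol.ctx_mean_spikes,
        width=protocol.ctx_burst_width,
    )
    return Episode(ff_spikes=ff, ctx_spikes=ctx, should_spike=bool(ep.label))


def run_xor_experiment(
    seed: int = 0,
    n_train: int = 400,
    n_eval: int = 80,
    *,
    protocol: EpisodeProtocol | None = None,
    pcfg: PlasticityConfig | None = None,
    network: DendriticNetwork | None = None,
) -> tuple[float, pd.DataFrame]:
    """Train the XOR network online; return held-out accuracy and curve."""
    protocol = protocol or EpisodeProtocol()
    pcfg = pcfg or PlasticityConfig(eta=0.1, phi_mid=-60.0, phi_slope=8.0)
    if network is None:
        network = build_xor_network(seed=derive_seed(seed, "xor_net"))
    train = [
        encode_xor_episode(e, protocol)
        for e in gen_xor_episodes(n_train, seed=derive_seed(seed, "xor_train"))
    ]
    evl = [
        encode_xor_episode(e, protocol)
        for e in gen_xor_episodes(n_eval, seed=derive_seed(seed, "xor_eval"))
    ]
    _, curve = run_online_learning(network, train, protocol, pcfg)
    acc = evaluate_episodes(network, evl, protocol, pcfg)
    return acc, curve


# ---------------------------------------------------------------------------
# glyph one-vs-all
# ---------------------------------------------------------------------------


def make_glyph_network(
    wm: WeightMatrix,
    n_tasks: int,
    seed: int = 0,
    *,
    n_compartments: int = 6,
    ff_row_scale: float = 8.0,
    **net_kwargs,
) -> DendriticNetwork:
    """Hidden neurons carry the rows of an unsupervised weight matrix.

    Rows are duplicated with both signs (a spiking neuron rectifies, so
    each learned direction needs a +/- pair) and scaled so typical images
    drive the somata near threshold.
    """
    W = np.concatenate([wm.W, -wm.W], axis=0) * ff_row_scale
    params = DendriticNeuronParams(n_compartments=n_compartments)
    return DendriticNetwork(params, W, n_ctx=n_tasks, seed=seed, **net_kwargs)


def make_glyph_episodes(
    images: np.ndarray,
    class_labels: np.ndarray,
    task_classes: list[int],
    n_episodes: int,
    protocol: EpisodeProtocol,
    seed: int = 0,
) -> list[tuple[int, Episode]]:
    """Episode stream over tasks: (task index, encoded episode).

    Each episode activates one task context; with probability 1/2 the
    image is from the task's target class (output must stay silent),
    otherwise it is a random sample from another class (output must
    spike).
    """
    rng = rng_for(seed, "glyph_episodes")
    flat = images.reshape(len(images), -1)
    episodes = []
    for _ in range(n_episodes):
        ti = int(rng.integers(0, len(task_classes)))
        target = task_classes[ti]
        if rng.random() < 0.5:
            pool = np.flatnonzero(class_labels == target)
            should_spike = False
        else:
            pool = np.flatnonzero(class_labels != target)
            should_spike = True
        i = int(rng.choice(pool))
        ep_seed = int(rng.integers(0, 2**31 - 1))
        ff = encode_image_burst(flat[i], protocol.t0, protocol.rate_scale,
                                seed=ep_seed, width=protocol.ff_burst_width)
        ctx = encode_context_burst(
            True, protocol.ctx_t0, ep_seed, channel=ti,
            mean_spikes=protocol.ctx_mean_spikes,
            width=protocol.ctx_burst_width,
        )
        episodes.append((ti, Episode(ff, ctx, should_spike)))
    return episodes


def run_glyph_spiking_experiment(
    method: str,
    seed: int = 0,
    *,
    n_classes: int = 4,
    image_size: int = 8,
    n_per_class: int = 20,
    k: int = 6,
    n_train: int = 600,
    n_eval: int = 80,
    protocol: EpisodeProtocol | None = None,
    pcfg: PlasticityConfig | None = None,
    net_kwargs: dict | None = None,
) -> float:
    """One-vs-all glyph tasks in the spiking network; returns accuracy.

    ``method`` selects the feedforward matrix: ``"dpmd"`` or ``"rp"``.
    """
    protocol = protocol or EpisodeProtocol()
    pcfg = pcfg or PlasticityConfig(eta=0.1, phi_mid=-60.0, phi_slope=8.0)
    images, labels = gen_glyph_images(
        n_classes, image_size=image_size, n_per_class=n_per_class,
        seed=derive_seed(seed, "glyphs"))
    flat = images.reshape(len(images), -1)
    dx = sample_differences(flat, n_pairs=10 * len(flat),
                            seed=derive_seed(seed, "pairs"))
    if method == "dpmd":
        wm, _ = delta_pmd(dx, k, eps=3.0, delta=5.0)
    elif method == "rp":
        wm = random_projection(flat.shape[1], k, seed=derive_seed(seed, "rp"))
        # match the dpmd row-norm convention so the scale is comparable
        wm.W = wm.W / np.linalg.norm(wm.W, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    task_classes = list(range(n_classes))
    kwargs = dict(out_weight_mu=600.0, w_ctx_init=0.45)
    kwargs.update(net_kwargs or {})
    network = make_glyph_network(wm, n_tasks=n_classes,
                                 seed=derive_seed(seed, "net"),
                                 **kwargs)
    train = make_glyph_episodes(images, labels, task_classes, n_train,
                                protocol, seed=derive_seed(seed, "train"))
    evl = make_glyph_episodes(images, labels, task_classes, n_eval,
                              protocol, seed=derive_seed(seed, "eval"))
    run_online_learning(network, [e for _, e in train], protocol, pcfg)
    return evaluate_episodes(network, [e for _, e in evl], protocol, pcfg)


# ---------------------------------------------------------------------------
# gain-modulated network experiments (reduced-scale protocols)
# ---------------------------------------------------------------------------


def run_2d_depth_comparison(
    seeds=range(1, 6),
    *,
    n_tasks: int = 48,
    n_samples: int = 512,
    data_seed: int = 100,
) -> pd.DataFrame:
    """Mean multitask test accuracy of 1- vs 4-hidden-layer networks.

    Learning rates are tuned per architecture (the shallow net tolerates a
    larger step); both get the same epoch budget.
    """
    from . import modnet as mn
    from .synthetic_data import gen_2d_multitask

    data = gen_2d_multitask(n_tasks, n_samples, seed=data_seed)
    rows = []
    for s in seeds:
        for depth, sizes, lr in ((1, [2, 50], 0.5),
                                 (4, [2, 50, 50, 50, 50], 0.3)):
            stack = mn.build_stack(sizes, seed=s)
            cfg = mn.TrainConfig(learning_rate=lr, epochs=150,
                                 batch_size=192, seed=s, momentum=0.9)
            _, tb = mn.train_multitask(stack, data, cfg)
            rows.append({
                "seed": s, "depth": depth,
                "mean_test_accuracy":
                    float(tb[tb.split == "test"].accuracy.mean()),
            })
    return pd.DataFrame(rows)


def run_glyph_transfer_comparison(
    seeds=range(20),
    *,
    n_classes: int = 8,
    n_pretrain_tasks: int = 4,
    data_seed: int = 1000,
) -> pd.DataFrame:
    """Depth-2 transfer: gains-only vs per-task-readout adaptation.

    A narrow final hidden layer makes the trunk a bottleneck shaped by the
    pretraining tasks; new tasks are then learned with frozen shared
    parameters, adapting either the per-task gains or a fresh readout.
    """
    from . import modnet as mn
    from .synthetic_data import gen_glyph_images, to_one_vs_all

    images, labels = gen_glyph_images(
        n_classes, 16, 30, seed=data_seed,
        jitter=0.06, max_rotation_deg=25.0, noise=0.05)
    data = to_one_vs_all(images, labels, seed=data_seed)
    tasks = data.task_ids
    pre, new = tasks[:n_pretrain_tasks], tasks[n_pretrain_tasks:]
    rows = []
    for s in seeds:
        for head in ("modulated_output_unit", "task_specific_readouts"):
            stack = mn.build_stack([images.shape[1] ** 2, 40, 6],
                                   head=head, seed=s)
            mn.train_multitask(
                stack, data,
                mn.TrainConfig(learning_rate=0.1, epochs=60, batch_size=120,
                               seed=s, momentum=0.9),
                tasks=pre)
            _, tb = mn.train_transfer(
                stack, data,
                mn.TrainConfig(
                    learning_rate=0.1, epochs=60, batch_size=120,
                    seed=s + 77, momentum=0.9,
                    frozen_parameter_set=frozenset({"W", "x_shift", "b"})),
                tasks=new)
            rows.append({
                "seed": s, "head": head,
                "transfer_test_accuracy":
                    float(tb[tb.split == "test"].accuracy.mean()),
            })
    return pd.DataFrame(rows)


def hard_glyph_multitask_images(seed: int = 7, n_classes: int = 8,
                                n_per_class: int = 20):
    """Glyph set with heavy jitter/rotation/noise (TMCL test bed).

    Tuned so single-layer accuracy sits well below ceiling, leaving room
    for the layer-stacking and task-similarity effects to show.
    """
    return gen_glyph_images(n_classes, 16, n_per_class, seed=seed,
                            jitter=0.08, max_rotation_deg=30.0, noise=0.08)
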