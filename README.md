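# dendrimod

Context-dependent dendritic modulation of feedforward networks, as a
testable desk-scale toolkit:

- **`dendrimod.modnet`** — feedforward networks whose layers compute
  `relu(g_t * (W x - x_shift) + b)` with shared weights/shifts/biases and
  per-task gain vectors. Supports joint multitask training, transfer
  learning with frozen shared parameters (gains-only adaptation), and a
  per-task-readout baseline. Plain momentum-SGD with manual gradients
  (no autograd dependency) and a strict freezing contract (frozen groups
  are bit-identical after training).
- **`dendrimod.delta_weights`** — unsupervised feedforward weight
  matrices aligned to difference vectors between data samples: principal
  components of the difference matrix (`dpca`), sparse dictionary
  learning (`dsd`), penalized matrix decomposition with L1 bounds on both
  factors (`dpmd`), and Gaussian random projections (`rp`), plus the
  least-squares reconstruction-residual metric.
- **`dendrimod.tmcl`** — greedy layer-wise task-modulated contrastive
  learning for small convolutional stacks: per layer, an NT-Xent
  contrastive phase (task modulations of earlier layers act as extra
  augmentations alongside occlusion/rotation/scaling) followed by a
  supervised gain phase through a task-independent output unit. No
  gradients ever cross layer boundaries.
- **`dendrimod.dendritic_sim`** — spiking network of simplified neurons:
  leaky threshold-reset soma star-coupled to leaky dendritic compartments
  carrying AMPA + NMDA (Mg-block sigmoid) context synapses, Gaussian
  burst encoders, a 50-ms decision-window protocol, and an online
  four-factor error-modulated Hebbian rule
  `dw = eta * error * post * pre * phi(v_dend)`.
- **`dendrimod.io_characterization`** — IO curves (spike count vs signed
  input count per modulation level), midpoint-crossing threshold
  extraction, and joint multi-start least-squares fits of three
  rectified-linear modulation models (per-level gain/shared bias,
  per-level bias/shared gain, per-level gain with shared bias + x-shift).
- **`dendrimod.synthetic_data`** — everything is generated procedurally:
  48-task 2D classification sets, stroke-glyph image classes (with an
  optional IDX reader for real MNIST/EMNIST-format files), one-vs-all
  conversion, task/class-balanced batching, and XOR episode streams.
- **`dendrimod.experiments`** — calibrated end-to-end protocols (XOR
  online learning, glyph one-vs-all spiking tasks with `dpmd` vs `rp`
  feedforward matrices, depth and transfer comparisons).

## CLI

All subcommands are seedable and write their artifacts plus a
`summary.json` and a resolved `config.yaml` under
`<outdir>/<command>/<tag>/`:

```bash
dendrimod gen-data --preset 2d48 --seed 1 --outdir out
dendrimod learn-weights --dataset out/gen-data/run/dataset.npz \
    --method dpmd --k 6 --eps 3 --delta 5
dendrimod train-multitask --dataset out/gen-data/run/dataset.npz \
    --hidden 50 --epochs 60
dendrimod train-transfer --stack out/train-multitask/run/stack.npz \
    --dataset out/gen-data/run/dataset.npz
dendrimod tmcl-stack --n-classes 8 --n-layers 3 --mode tmcl
dendrimod spike-train --episodes 250 --seed 1     # XOR protocol
dendrimod io-fit --curves curves.csv --variant gain_per_level_shared_bias_xshift
```

## Units and conventions

Simulations use mV / ms / nS / pF / pA. Gaussian burst "width" is a full
width at half maximum (spike-time SD = width / 2.355). In the decision
window (closed interval, opened by the first feedforward spike), at
least one output spike means "random sample", silence means "target
class".
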