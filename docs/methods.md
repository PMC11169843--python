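# Methods

## Neuron model

The basic unit is a leaky integrate-and-fire (LIF) neuron with hard reset.
With leakage factor λ ∈ [0, 1], previous membrane potential v(t−1), previous
resetting spike x₀(t−1) and synaptic current i(t):

```
v(t) = λ · v(t−1) · (1 − x₀(t−1)) + i(t)
xₖ(t) = 1  if v(t) ≥ Vthₖ  else 0
```

The dual-threshold neuron evaluates the same membrane against two learnable
thresholds. Only the primary threshold Vth₀ resets the membrane; the
secondary threshold Vth₁ reads it non-destructively. Threshold comparison is
inclusive (≥). The two thresholds are initialised equal (0.5 by default); no
ordering between them is enforced, because training can push the secondary
threshold to either side of the primary one. Setting Vth₁ = Vth₀ makes both
pathways emit identical spikes, so the dual-threshold network strictly
generalises a plain SCNN (a property test pins this down bit-for-bit).

## Architecture

Architecture strings use tokens `NcK` (conv, N maps, K×K kernels), `NdtcK`
(dual-threshold conv with N membrane maps emitting 2N spike maps, ordered as
[pathway-0 block, pathway-1 block]), `pS` (S×S average pooling), and `Nfc`
(fully connected; the last one is the non-spiking output layer, which
accumulates v(t) = λ·v(t−1) + i(t) and is read out by argmax). Convolutions
are stride-1 with same padding, which requires odd kernel sizes (all
reference networks use 3 or 5). Inputs are presented identically at every
timestep (direct encoding); the first layer therefore consumes real pixels
and all later layers consume binary spikes.

## Training

Training uses spatio-temporal backpropagation with a rectangular surrogate
derivative for the spike nonlinearity: h(u) = 1 iff |u − 1| < 1/2 with
u = v/Vth, zero elsewhere (strict inequality at the window edges). The loss
is softmax cross-entropy on the output accumulators.

Two temporal credit-assignment modes are implemented:

* **default ("variant") mode** — the backward recursion follows the layer's
  published update equations literally: the only temporal term is the
  reset-path contribution through pathway 0,
  −λ·v(t)·g_x0(t+1)·h(v(t+1)/Vth₀)/Vth₀, and the membrane gradient at each
  step is assembled from the per-pathway spike gradients;
* **standard mode** (`TrainConfig(temporal_membrane_path=True)`) — full STBP
  with the direct membrane→membrane path λ·(1 − x₀(t))·g_v(t+1).

The two modes coincide at a single timestep. Both are validated to ≈1e-16
against two independent scalar references: a literal chain-rule expansion of
the update equations, and a scalar reverse-mode autodiff tape with surrogate
spike partials.

Thresholds are trained jointly with the weights using
∂x/∂Vth = h(v/Vth)·(−v/Vth²), summed over the map, with a positivity floor
of 0.01. Optimisation is plain SGD (momentum available), learning rate
decayed by 10 % every 25 epochs, dropout 0.5 on spiking fully connected
layers, batch size 32. The **two-stage strategy** pre-trains from random
initialisation at five timesteps, then re-trains the resulting parameters at
one timestep; defaults (λ = 0.5, threshold init 0.5, lr 0.05) follow the
reference setup. Per-epoch metric accuracy is computed by a clean,
dropout-free evaluation pass (the training protocol for this metric is
otherwise unspecified).

## Complexity accounting

Per convolutional layer with output maps h′×w′, c_in input channels, k×k
kernels and m membrane maps: ops = h′·w′·c_in·k²·m, weights = c_in·k²·m,
membranes = h′·w′·m. For a DTC layer m is half the emitted channel count —
this is the source of the 2× saving. Operations in the first (coding) layer
are MACs, all later ones ACCs; operation totals scale with the number of
timesteps; pooling, threshold comparisons and resets are free. "Weights"
counts convolutional kernels only and "Vms" counts spiking membranes plus
output accumulators, the conventions under which the reference tables
reproduce. The efficiency ratio is R = accuracy (%) / operations (M).

### Known discrepancy

All 36 operation/weight/Vms cells of the nine reference networks reproduce
exactly under these conventions except one: the ACC count of the largest
dual-threshold network. Its listed architecture
(`48dtc3-128dtc3-p2-192dtc3-p2-192dtc3-128dtc3-p2-1024fc-10fc`) yields
301,475,840 ≈ 301M, not the printed 315M. The printed value is reproduced
exactly (315,107,328) by the structure-matched variant without the extra
pooling layer and with two 1024-unit fully connected layers, suggesting the
printed ACC was computed for that variant. The cell is excluded from exact
acceptance and recorded here as an open question.

## Synthetic data

The generator produces desk-scale classification sets in the regime the
networks target: pixels in [0, 1], balanced classes, deterministic in the
seed. Each class owns a disjoint grid cell of the image and draws an
oriented bar (orientation πk/n_classes) or a Gaussian blob there, plus
clipped additive Gaussian noise (σ = 0.1 by default). Disjoint supports make
the noise-free class means exactly orthogonal and the task separable by
construction — deliberately easy, so training behaviour (two-stage gap,
threshold differentiation) is attributable to the method rather than the
data. The reference study (`desk_scale_experiment`) uses 4 classes of bars
on 16×16 images, 50 samples per class, a `4dtc3-p2-32fc-4fc` network, and 30
epochs per stage; these problem sizes are this package's choice, scaled so
the full pipeline runs in seconds.

## Numerical choices

Everything is float64 NumPy. Convolutions use im2col via
`sliding_window_view`; their gradients are exact transposes of the forward
maps. Reported counts are rendered with decimal half-up rounding
(`format_si`) to match table conventions. Checkpoints are NumPy `.npz`
archives (version-tagged); datasets use the big-endian IDX container.

## Limitations

* No GPU or autodiff backend; practical problem sizes are desk-scale
  (the full MNIST/CIFAR recipes are expressible but slow in pure NumPy).
* Average/max pooling only, stride-1 same-padded convolutions only, odd
  kernels only.
* The desk-scale study saturates at 100 % accuracy; it demonstrates the
  pipeline and the zero two-stage gap, not benchmark-level accuracy claims.
* Data augmentation (cropping/mirroring) used in the largest reference
  recipe is not implemented.
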