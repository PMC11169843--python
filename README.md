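# dtscnn — dual-threshold spiking convolutional networks

Spiking convolutional neural networks (SCNNs) transmit binary spikes instead
of real activations, which makes them cheap to run on neuromorphic and edge
hardware — most synaptic operations are accumulations rather than
multiply-accumulates. Their cost is still dominated by the convolutional
layers: every output feature map needs its own kernels, its own membrane
potential map, and its own share of the synaptic operations.

This package implements the **dual-threshold** SCNN (DT-SCNN). A
dual-threshold convolutional (DTC) layer compares each membrane potential map
against *two* learnable firing thresholds and emits two spiking feature maps
per membrane map: the primary threshold resets the membrane when it fires,
the secondary one reads the same membrane without resetting it. A DTC layer
therefore produces the same number of spike maps as a conventional layer of
twice its width while carrying **half the convolutional weights, half the
membrane potentials, and half the convolutional operations**. Combined with a
two-stage training strategy — pre-train at five timesteps, then re-train the
same weights at a single timestep — the result is a low-latency,
low-memory spiking classifier trained end to end with surrogate-gradient
backpropagation (spatio-temporal backpropagation with a rectangular surrogate
window).

Everything is implemented in NumPy, including the full custom backward pass;
there is no autodiff framework underneath.

## Worked example

Profile a dual-threshold network for 28×28 grayscale inputs. The string
`8dtc5-p2-20dtc5-p2-256fc-10fc` means: a DTC layer with 8 membrane maps and
5×5 kernels (emitting 16 spike maps), 2×2 average pooling, a 20-membrane DTC
layer, pooling, a 256-unit spiking fully connected layer, and a 10-way
output layer.

```python
import dtscnn as d

arch = d.parse_arch("8dtc5-p2-20dtc5-p2-256fc-10fc", (28, 28, 1))
print(d.profile_network(arch, timesteps=1).render())
```

prints

```
layer       kind           ops   op   weights       Vms
8dtc        dtc         156800  MAC       200      6272
p2          pool             0    -         0         0
20dtc       dtc        1568000  ACC      8000      3920
p2          pool             0    -         0         0
256fc       fc          501760  ACC         0       256
10fc        fc_out        2560  ACC         0        10
-------------------------------------------------------
totals (T=1): 2.07M(ACC) + 157K(MAC), weights 8.20K, Vms 10.5K
```

The width-matched plain baseline `16c5-p2-40c5-p2-256fc-10fc` needs 16.4K
conv weights and 20.4K conv membranes — the DTC version carries exactly half
of each.

Train the reference desk-scale study (four classes of oriented bars on
16×16 images, two-stage strategy, ~6 s on a laptop):

```python
res = d.desk_scale_experiment(seed=0)
print(res.pretrain_accuracy, res.retrain_accuracy, res.efficiency_ratio)
```

prints

```
1.0 1.0 3886.81592039801
```

i.e. 100 % accuracy after the five-timestep pre-train stage, 100 % after
re-training at a single timestep (zero accuracy gap), at an efficiency ratio
of ≈3886.8 accuracy-percent per million operations. The trained first-layer
threshold pair of this run is `(0.4486, 0.3420)`, i.e. `(1.0, 0.762)` after
normalising the resetting threshold to 1 — the two thresholds start equal at
0.5 and differentiate during training.

## Command line

```
dtscnn count    --arch 8dtc5-p2-20dtc5-p2-256fc-10fc --input 28x28x1
dtscnn gen-data --classes 4 --per-class 50 --size 16x16 --out scratch/data
dtscnn train    --arch 4dtc3-p2-32fc-4fc --input 16x16x1 \
                --data scratch/data --stage both --out scratch/run
dtscnn eval     --checkpoint scratch/run/retrain.npz --data scratch/data
dtscnn analyze  --checkpoint scratch/run/retrain.npz --data scratch/data \
                --out scratch/analysis
```

`gen-data` writes MNIST-style IDX files plus a JSON manifest with checksums;
`train` runs the two-stage strategy and writes `.npz` checkpoints and
per-epoch CSV metrics; `analyze` reports pairwise spike-map similarity and
normalised threshold pairs.

## Reproduction

```
pip install --no-build-isolation -e .[test]
python -m pytest -q tests/                      # full suite, ~1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the profile of the nine reference network
variants, the weight/membrane reductions of each dual-threshold network over
its baseline (exactly 50 % kept), and the seeded desk-scale two-stage study,
and writes them to JSON. All randomness derives from `--seed`; repeated runs
with the same seed are bit-identical. See `docs/methods.md` for model
details, conventions, and known limitations.
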