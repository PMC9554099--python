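# plateau-snn

A spiking neural network that learns with **dendritic plateau potentials**
instead of backpropagated gradients, together with a **bit-faithful
fixed-point emulation** of its digital-hardware datapath.

The package is for computational-neuroscience and neuromorphic-engineering
work: it simulates three-layer networks of multi-compartment leaky
integrate-and-fire (MLIF) neurons — soma, basal dendrite and (in the hidden
layer) apical dendrite — in which output-layer spikes feed back through fixed
random weights onto the apical dendrites. Training runs in two 100 ms
phases per trial: a *forward* phase, and a *target* phase in which a
conductance-based teaching current I = g_E(E_E − V) + g_I(E_I − V) nudges
the output somata. The hidden-layer learning signal is the difference of
the two **plateau potentials** α = σ(V̄ᵃ), the sigmoid of the apical
potential averaged over the stable part of each phase:

    ΔW⁰ ∝ η⁰P⁰ g_b/(g_l+g_b+g_a) · (αᵗ − αᶠ) φ_max σ'(V̄⁰ᶠ) ⊗ x̄ᶠ
    ΔW¹ ∝ η¹P¹ g_d/(g_l+g_d) · (φ̄¹ᵗ − φ̄¹ᶠ) φ_max σ'(V̄¹ᶠ) ⊗ s̄⁰ᶠ

Weights update once per trial, at the end of the target phase; no
per-timestep state is stored for learning, so a synapse costs O(1) memory —
the property that makes the rule attractive for on-chip learning.

Two numeric backends generate the dynamics:

- `float` — exact floating-point reference;
- `hw` — value-level emulation of the digital circuit: 24-bit sign-magnitude
  fixed point (7 integer + 16 fraction bits, truncate-toward-zero,
  saturating), 5/6-segment piecewise-linear sigmoid and derivative whose
  slopes are sums of powers of two, a shift-add multiplier for
  variable×variable products, and Poisson spike generation from ten stored
  rate-binned lookup-table trains read through advancing addresses.

## Worked example

Train the 8×10×4 classifier on the four frequency-coded spike patterns
(channels at 20 or 200 Hz) and read out the prediction as the output neuron
with the most spikes:

```python
from plateau_snn import (build_network, make_classification_fixture,
                         train, evaluate_classification)

net = build_network((8, 10, 4), seed=0)        # 120 synapses
patterns = make_classification_fixture(0)      # 4 labelled patterns
train(net, patterns, epochs=500, eval_every=0)
print(evaluate_classification(net, patterns))  # -> 1.0
```

The same from the command line, plus the echo experiment (an 8×10×8 network
trained to reproduce its input's frequency distribution):

```
$ snn reproduce --epochs 300 --seed 0 --out run0
MAE = 7.6004 Hz, R^2 = 0.9805 (drop probability 0.0)
```

MAE is the mean absolute difference between the 8 target rates and the
measured output rates (Hz, over a 4 s readout); R² scores the same fit —
here the network echoes rates spanning 20–200 Hz to within ~8 Hz. The
error-evaluation table of the piecewise-linear circuits:

```
$ snn eval-pwl
function                            RMSE           MAE        R2
PWL5 sigmoid                     0.01007      0.004867    0.9995
PWL6 sigmoid derivative         0.001482     0.0002158    0.9946
```

and the fixed-point datapath against the floating-point reference:

```
$ snn eval-backends --seed 1
shift MUL vs exact product: RMSE=6.13397e-05 MAE=5.71606e-05 R2=1 (n=100000)
MLIF somatic trace hw vs float: RMSE=3.70045e-05 MAE=3.38e-05 R2=1 (n=200)
```

Drop noise (`--drop-prob P`, or `NoiseSpec` in the API) deletes spikes on
the inter-layer paths independently with probability P to probe robustness
of a trained network.

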