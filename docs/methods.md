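# Methods

## Model

The network is a three-layer feedforward spiking network. Input channels are
rate-coded: a channel with target rate r Hz emits a Bernoulli(r/1000) spike
per 1 ms step. Hidden units are multi-compartment leaky integrate-and-fire
(MLIF) neurons with a basal dendrite (driven by input spikes), an apical
dendrite (driven by output-layer spikes through a fixed random feedback
matrix Y) and a soma; output units have only a basal dendrite and a soma.

Spike trains entering a dendrite are filtered by the double-exponential
kernel K(t) = (e^(-t/τ_l) − e^(-t/τ_s)) / (τ_l − τ_s) with τ_l = 10 ms,
τ_s = 3 ms, truncated to a 10 ms window: both backends evaluate K at
τ = 1..10 ms through a shift register, because that is what the digital
implementation does and it keeps the two backends comparable. The truncation
discards at most the e^(−1) tail of the slow exponential. The dendritic
potentials are affine/linear maps of the filtered trains (V⁰ᵇ = W⁰x + b⁰,
V⁰ᵃ = Ys¹, V¹ᵇ = W¹s⁰ + b¹), and each soma takes one forward-Euler step per
millisecond,

    V⁰(t+1) = V⁰(t) + [g_l(V_res − V⁰) + g_b(V⁰ᵇ − V⁰) + g_a(V⁰ᵃ − V⁰)]/C_m
    V¹(t+1) = V¹(t) + [g_l(V_res − V¹) + g_d(V¹ᵇ − V¹) + I]/C_m,

with the instantaneous rate φ = φ_max σ(V) sampled into spikes each step.
The teaching current I = g_E(E_E − V¹) + g_I(E_I − V¹) is zero outside the
target phase. The g_a(V⁰ᵃ − V⁰) term is implemented as written even though
the default g_a = 0 silences it: at the defaults the apical dendrite
influences learning only, not the membrane.

All parameters default to the published table: dt = 1 ms, φ_max = 0.2/ms,
E_E = 12, E_I = −12, g_d = g_b = 0.6, g_l = 0.1, g_a = 0, V_res = 0, C_m = 1,
Δt = 30 ms, η⁰ = η¹ = 0.01, P⁰ = 20/φ_max = 100, P¹ = 20/φ_max² = 500.

## Two-phase plateau plasticity

A training trial is 200 ms: a 100 ms forward phase (no teaching) and a
100 ms target phase in which the output somata are nudged. A counter-driven
controller raises exactly one of forward-enable/target-enable, excludes the
first Δt = 30 ms of each phase from all averages while the voltages settle,
and pulses a clear signal at the wrap. Per phase the controller accumulates
the apical potentials, somatic voltages and presynaptic filtered traces over
the remaining 70 ms. At the trial end:

    α^f = σ(mean apical, forward),  α^t = σ(mean apical, target)
    e⁰ = (α^t − α^f) · φ_max σ'(V̄⁰ᶠ)
    ΔW⁰ ∝ η⁰P⁰ g_b/(g_l+g_b+g_a) · e⁰ ⊗ x̄ᶠ        (bias: same without x̄ᶠ)
    e¹ = (φ̄¹ᵗ − φ̄¹ᶠ) · φ_max σ'(V̄¹ᶠ),  φ̄ = φ_max σ(V̄)
    ΔW¹ ∝ η¹P¹ g_d/(g_l+g_d) · e¹ ⊗ s̄⁰ᶠ.

Y is never updated. No per-timestep state is retained for learning — the
memory per synapse is O(1) in trial length (an accumulator and the running
average), which is the point of the plateau formulation.

Three implementation decisions deserve explanation because the source
material leaves them open:

- **Update direction.** Taken literally, the published update *subtracts*
  the error-aligned outer product, which moves the forward activity away
  from the nudged activity; trained that way the network stays at or below
  chance on every configuration we tried. The rule is implemented with a
  configurable `update_sign`; the default (−1) applies the update in the
  direction that contracts the forward/target discrepancy, which trains to
  the published accuracies. `update_sign=+1` restores the literal form.
- **Presynaptic accumulators.** The hardware description divides the apical
  and somatic accumulators by 70 (the samples per phase) but shows no such
  divider on the presynaptic path, and the equations do not say. We keep
  x̄ᶠ and s̄⁰ᶠ as plain 70-sample sums (`presyn_mode="sum"`). Besides being
  the literal reading of the accumulate-register circuit, this sets the
  output layer's effective gain so that one trial corrects approximately
  100% of the rate error — with 1/70 means the per-trial step is ~70× too
  small for the small-network experiments to converge within their stated
  epoch budgets. `presyn_mode="mean"` restores the literal equations.
- **Plateau window.** The plateau integrals are written over the final
  Δt = 30 ms of each phase, while the hardware averages everything after the
  unstable time (70 ms, the 1/70 divider). Default is the hardware
  convention; `plateau_window_mode="eq-delta-t"` switches to the 30 ms
  window.

**Initialization** (unspecified in the source): W⁰, W¹ ~ U(−0.1, 0.1),
b = 0, Y ~ U(−4, 4), all from one seeded generator. The feedback scale
matters: the apical plateau difference α^t − α^f scales linearly with Y, and
it is the only learning signal the hidden layer receives. With |Y| ≤ 1 the
hidden layer differentiates the input patterns too slowly to reach 100%
classification within 500 epochs (median accuracy ~0.75 across seeds);
U(−4, 4) reaches 100% in 10/10 seeds while leaving the dynamics stable.
Teaching assignment for classification follows the source exactly: the
labelled output gets (g_E, g_I) = (1, 0), all others (0, 1).

## Hardware-emulation backend

The `hw` backend reproduces, at value level, the arithmetic of the digital
implementation:

- **24-bit fixed point** — sign-magnitude with 7 integer and 16 fraction
  bits. Encoding truncates the magnitude toward zero (matching shifter
  truncation) and saturates at 127 + 65535/65536 instead of wrapping. Every
  arithmetic block's output is re-quantised to this grid.
- **PWL nonlinearities** — the sigmoid is 5 linear segments clipped to
  [0, 1]; its derivative is 6 segments clipped to [0, ∞). The shipped
  coefficient tables use only slopes that are sums of powers of two, so the
  m·V products are exact shift-adds. The published derivative table prints
  border magnitudes only (3.2 appears twice) and an asymmetric centre
  intercept 0.26; we reconstruct the even-symmetric layout (borders −3.2,
  −2, 0, 2, 3.2; positive-side slopes negated; centre intercept 0.25), which
  peaks at exactly σ'(0) = 0.25 and matches the published error statistics
  more closely than the printed asymmetric variant.
- **Shift multiplier** — two-variable multiplication as a sum of bit-gated
  right shifts: operand a's integer bits are dropped, its 16 fraction bits
  gate copies of b shifted right by 1..16 positions. Each shift truncates,
  so |shift_mul(a,b) − ab| ≤ 2⁻¹⁶|b| + 16·2⁻¹⁶; the property suite verifies
  this against an exact integer oracle on 10⁵ random pairs.
- **Poisson lookup tables** — rates are clipped to 0–200 Hz and mapped to
  ten 20 Hz bins; each bin stores a 4096-bit Bernoulli(λ) train
  (λ = 0.02..0.2 per ms) read through a per-neuron address that advances one
  bit per read and wraps. 4096 bits means a 200 ms trial never rereads a
  bit. Each stored train must pass a chi-square Poisson conformity check
  (20 ms windows, tail categories pooled to expectation ≥ 5, α = 0.05);
  failing draws are regenerated with bounded retries. Note the check is
  slightly anticonservative for dense trains — Bernoulli counts are
  under-dispersed relative to Poisson by a factor (1 − λ) — so the realised
  pass rate at λ = 0.2 is ~0.8 rather than 0.95. Rates below 20 Hz read the
  λ = 0.02 train: a residual 20 Hz floor inherited from the circuit (there
  is no all-zero train). The float backend uses the true rate.

The backend is selected per network; mixing backends within one simulation
is not supported, so a voltage trace is always interpretable as one
datapath. On a shared 200 ms input raster the two backends' hidden somatic
voltage traces agree to R² > 0.999 (the filtering/Euler path is linear, so
the only divergence is 2⁻¹⁶-level quantisation; the published
hardware-vs-software comparison reports R² = 0.9944).

## PWL error evaluation and `fit_pwl`

The published error table (RMSE/MAE/R² of both PWL approximations) does not
state its evaluation grid. The three statistics jointly identify it: the
sigmoid triplet (0.0101, 0.0049, 0.9995) is reproduced by a uniform sweep of
[−10, 10] at step 0.01, and the derivative triplet (0.0015, 2.1643×10⁻⁴,
0.9948) by [−200, 200] — outside ±6.4 the clipped PWL derivative and the
true σ' are both ≈ 0, so the wide sweep dilutes the bump-region error by
exactly the observed √(range) factor. Those are the package's default
evaluation ranges; `pwl_error_report` accepts any grid, and on the
breakpoint-spanning ±8 sweep the sigmoid errors stay within 30% of the
published values.

`fit_pwl` re-derives coefficient tables by exhaustion on the stated grids
(border step 0.1, slope/intercept step 0.01). A joint exhaustion is
combinatorially infeasible for 5–6 segments, so the implementation runs
deterministic coordinate descent: borders warm-started at curvature-mass
quantiles (density ∝ |f''|^(2/5), the asymptotically optimal knot density
for L2 piecewise-linear approximation), then alternating per-segment
least-squares fits snapped to the coefficient grid and local per-border
scans. It matches or beats the published RMSE for both shipped tables
(0.0049 vs 0.0101 for the sigmoid; 0.0008 vs 0.0015 for the derivative).

## Experiments

**Classification** (8×10×4, 120 synapses): four 8-channel patterns with
rates from {20, 200} Hz — the published example (even-numbered channels
high), its complement, and the two half-split patterns — labels 0–3, one
train trial per pattern per epoch in fixed cyclic order, 500 epochs.
Prediction is the argmax of output spike counts over a 1000 ms forward-only
readout (readout length configurable; ties break to the lowest index). The
float backend reaches 100% accuracy in 10/10 seeds.

**Reproduction** (8×10×8, 160 synapses): one pattern with rates drawn
uniformly from [20, 200] Hz; the network must echo the input's frequency
distribution at its outputs. Teaching uses graded nudging with
g_E = (1 + σ⁻¹(r/200)/E_E)/2 and g_I = 1 − g_E: at the rule's zero-update
fixed point the forward somatic voltage converges to E_E(2g_E − 1), so this
choice makes the trained forward rate equal the target exactly (the logit is
clipped to [0.005, 0.995] because the extreme rates are asymptotic). The
readout estimates each output's rate from spike counts over 4000 ms, long
enough that Poisson shot noise (≤ ~2.5 Hz standard error at 200 Hz)
does not dominate the score. After 300 epochs: median MAE ≈ 4.7 Hz, median
R² ≈ 0.984 over 10 seeds (published: 6.89 Hz, 0.991).

**Drop noise**: every spike on the selected trains is deleted independently
with probability p. The default `NoiseSpec` thins the inter-layer traffic
(input-layer spikes and hidden soma outputs) at test time; 'output' may be
added to also thin the counted output spikes. Degradation is monotone in p
(median MAE 4.7 → 14.1 Hz, R² 0.984 → 0.895 at p = 0 → 0.5). This is milder
than the published figures at p = 0.5 (MAE 32.46, R² 0.6955): a network
trained on a single pattern stores much of the target in its biases, which
drop noise cannot reach. Thinning the output somata as well overshoots the
published point (MAE ≈ 47, R² < 0) because the counted rate then scales by
1 − p directly. The published noise protocol is not specified precisely
enough to reproduce the intermediate figure; note also that MAE = 32.46
with R² = 0.6955 jointly require a test pattern with a rate variance larger
than uniform-[20, 200] sampling provides, so the published test pattern
differed from this package's fixture in spread.

## What the synthetic fixtures do and do not show

All experiment inputs are generated by the package (frequency-coded Bernoulli
rasters); there is no external dataset. Passing the experiments demonstrates
that the two-phase plateau rule assigns credit through fixed random feedback
in a spiking substrate, and that the fixed-point datapath tracks the
floating-point one — it does not demonstrate generalisation: the
classification task has four training patterns and no held-out set, and the
echo task memorises one pattern (300 single-trial epochs are far too few to
learn the identity map over fresh random patterns, which we verified). The
architecture runs unchanged at 784-500-10 scale, but no claim is made about
image benchmarks.

## Numerical and degenerate-input conventions

- Fixed-point rounding is truncation toward zero everywhere, applied
  uniformly; −0 normalises to +0; encode saturates, never wraps.
- Prediction ties break to the lowest neuron index.
- R² is undefined (raises) for a constant reference sequence.
- The chi-square check fails, rather than raises, on degenerate all-zero or
  all-one trains; it raises only for trains shorter than 100 ms.
- Problem sizes used throughout the suite — 10 seeds, 500/300 epochs, 1000
  and 4000 ms readouts — are the experiment definitions above; the full
  suite and the acceptance script each complete in a few minutes on one CPU.

## Known limitations

- The hardware backend emulates values, not bit-level pipelines: it
  reproduces what each register holds after every block, but not timing,
  pipelining or resource behaviour, and there is no two's-complement mode.
- The update sign, presynaptic accumulator semantics, initialization scale
  and reproduction teaching are reconstructions of under-specified parts of
  the source system; each is a documented, configurable choice.
- Drop-noise robustness reproduces the published trend, not its magnitude
  (see above).
- The residual 20 Hz sampling floor means the hardware backend cannot
  express true silence; silent channels are only available on the float
  backend.
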