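"""Three-layer SNN assembly, the 200 ms two-phase trial loop, and the
classification / pattern-reproduction experiments.

The network is input -> hidden (3-compartment MLIF) -> output (2-compartment
MLIF) with fixed random feedback weights Y carrying output spikes back to the
hidden apical dendrites.  All inter-layer traffic is spike bits; membrane
voltages never leave their neuron.  Input channels are Poisson rate-coded at
20-200 Hz.

A training trial simulates 200 steps of 1 ms: forward phase (no teaching),
then target phase with conductance nudging of the output somata, then one
plasticity update at the wrap.  A test trial runs the forward dynamics alone
for a configurable readout window and counts output spikes; the predicted
class is the output neuron with the most spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .neuron_core import (FilterBank, NetworkParams, basal_potential,
                          apical_potential, make_backend, soma_step_hidden,
                          soma_step_output, teaching_current)
from .plasticity import (LearningConfig, PhaseSchedule, PlasticityAccumulators,
                         apply_trial_end)

DEFAULT_READOUT_MS = 1000
REPRODUCTION_READOUT_MS = 4000


@dataclass
class SpikePattern:
    """Per-channel target rates (Hz) plus a class label or target rates.

    ``label`` marks a classification pattern; ``target_rates`` marks a
    reproduction pattern (usually equal to ``rates``: the network should
    echo its input's frequency distribution).
    """

    rates: np.ndarray
    label: Optional[int] = None
    target_rates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.target_rates is not None:
            self.target_rates = np.asarray(self.target_rates, dtype=np.float64)

    @property
    def n_channels(self) -> int:
        return self.rates.size


@dataclass
class NoiseSpec:
    """Independent per-spike drop noise.

    ``where`` selects the spike trains it thins: 'input' (the encoded input
    rasters), 'hidden' (hidden soma outputs) and/or 'output' (output soma
    outputs, which also removes them from the prediction counters).  The
    default drops the inter-layer traffic — input and hidden spikes — and
    leaves the output counters intact.
    """

    drop_probability: float
    where: tuple = ("input", "hidden")

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ValueError("drop_probability must be in [0, 1]")
        unknown = set(self.where) - {"input", "hidden", "output"}
        if unknown:
            raise ValueError(f"unknown noise application points {unknown}")


def inject_drop_noise(raster, noise: NoiseSpec, rng) -> np.ndarray:
    """Thin a binary raster: each 1-bit survives with prob 1 - p."""
    raster = np.asarray(raster)
    if noise.drop_probability == 0.0:
        return raster.copy()
    keep = rng.random(raster.shape) >= noise.drop_probability
    return raster * keep


class SNNetwork:
    """Layer sizes, weights, parameters and RNG of one spiking network."""

    def __init__(self, sizes, params: NetworkParams, config: LearningConfig,
                 backend, seed: int, w_scale: float = 0.1,
                 y_scale: float = 4.0,
                 schedule: Optional[PhaseSchedule] = None) -> None:
        n_in, n_hidden, n_out = sizes
        if min(n_in, n_hidden, n_out) < 1:
            raise ValueError(f"invalid layer sizes {sizes}")
        self.sizes = (n_in, n_hidden, n_out)
        self.params = params
        self.config = config
        self.backend = backend
        self.schedule = schedule or PhaseSchedule()
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.W0 = self.rng.uniform(-w_scale, w_scale, (n_hidden, n_in))
        self.b0 = np.zeros(n_hidden)
        self.W1 = self.rng.uniform(-w_scale, w_scale, (n_out, n_hidden))
        self.b1 = np.zeros(n_out)
        self.Y = self.rng.uniform(-y_scale, y_scale, (n_hidden, n_out))
        if backend.is_hardware:
            q = backend.quantize
            self.W0, self.W1, self.Y = q(self.W0), q(self.W1), q(self.Y)

    @property
    def synapse_count(self) -> int:
        n_in, n_hidden, n_out = self.sizes
        return n_in * n_hidden + n_hidden * n_out


def build_network(sizes, params: Optional[NetworkParams] = None,
                  config: Optional[LearningConfig] = None,
                  backend="float", seed: int = 0, w_scale: float = 0.1,
                  y_scale: float = 4.0) -> SNNetwork:
    """Construct a seeded network; identical seeds give identical weights."""
    params = params or NetworkParams()
    config = config or LearningConfig()
    if isinstance(backend, str):
        backend = make_backend(backend, lut_seed=seed)
    return SNNetwork(sizes, params, config, backend, seed,
                     w_scale=w_scale, y_scale=y_scale)


# ---------------------------------------------------------------------------
# Teaching-conductance assignment
# ---------------------------------------------------------------------------

def classification_conductances(label: int, n_out: int):
    """Binary nudging: the labelled neuron is excited, the rest inhibited."""
    g_E = np.zeros(n_out)
    g_I = np.ones(n_out)
    g_E[label] = 1.0
    g_I[label] = 0.0
    return g_E, g_I


def reproduction_conductances(target_rates, params: NetworkParams):
    """Graded nudging whose trained fixed point reproduces the target rates.

    At the plasticity rule's zero-error fixed point the forward somatic
    voltage converges to E_E (2 g_E - 1) (with g_E + g_I = 1), so choosing
    g_E = (1 + sigma^-1(r / r_max) / E_E) / 2 makes the trained forward rate
    equal the target r exactly.  The logit argument is clipped away from 0
    and 1 because the extreme rates are only reached asymptotically.
    """
    r_max = params.phi_max * 1000.0
    q = np.clip(np.asarray(target_rates, dtype=np.float64) / r_max, 0.005, 0.995)
    g_E = 0.5 * (1.0 + np.log(q / (1.0 - q)) / params.E_E)
    g_E = np.clip(g_E, 0.0, 1.0)
    return g_E, 1.0 - g_E


def _teaching_for(pattern: SpikePattern, n_out: int, params: NetworkParams):
    if pattern.label is not None:
        if not 0 <= pattern.label < n_out:
            raise ValueError(f"label {pattern.label} outside output layer")
        return classification_conductances(pattern.label, n_out)
    if pattern.target_rates is not None:
        if pattern.target_rates.size != n_out:
            raise ValueError("target_rates length must equal n_out")
        return reproduction_conductances(pattern.target_rates, params)
    return np.zeros(n_out), np.zeros(n_out)


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    spike_counts: np.ndarray
    duration_ms: int
    traces: Optional[dict] = None


def run_trial(net: SNNetwork, pattern: SpikePattern, mode: str = "train",
              noise: Optional[NoiseSpec] = None,
              readout_ms: int = DEFAULT_READOUT_MS,
              record_traces: bool = False) -> TrialResult:
    """Simulate one trial.

    ``mode='train'``: 200 steps (forward + target phase), nudging applied in
    the target phase, one plasticity update at the wrap.  ``mode='test'``:
    ``readout_ms`` steps of the forward dynamics only.  Optional drop noise
    thins the configured spike trains.  All randomness comes from ``net.rng``
    (float backend) or the LUT addresses (hardware backend), so identical
    seeds give bit-identical rasters and weights.
    """
    if mode not in ("train", "test"):
        raise ValueError(f"unknown mode {mode!r}")
    n_in, n_hidden, n_out = net.sizes
    if pattern.n_channels != n_in:
        raise ValueError(
            f"pattern has {pattern.n_channels} channels, network expects {n_in}")
    params, backend, sched = net.params, net.backend, net.schedule
    train = mode == "train"
    T = sched.trial_length if train else int(readout_ms)
    hwq = backend.quantize if backend.is_hardware else None
    rng = net.rng

    p_in = pattern.rates / 1000.0 * params.dt
    g_E_t, g_I_t = _teaching_for(pattern, n_out, params) if train \
        else (np.zeros(n_out), np.zeros(n_out))

    f_in = FilterBank(n_in, params, quantize=hwq)
    f_hid = FilterBank(n_hidden, params, quantize=hwq)
    f_out = FilterBank(n_out, params, quantize=hwq)
    V0 = np.full(n_hidden, params.V_res)
    V1 = np.full(n_out, params.V_res)
    acc = PlasticityAccumulators(n_in, n_hidden, n_out) if train else None
    counts = np.zeros(n_out)
    s1 = np.zeros(n_out)
    traces = {"V0": np.empty((T, n_hidden)), "V1": np.empty((T, n_out))} \
        if record_traces else None

    drop_p = noise.drop_probability if noise is not None else 0.0
    drop_in = drop_p > 0 and "input" in noise.where
    drop_hid = drop_p > 0 and "hidden" in noise.where
    drop_out = drop_p > 0 and "output" in noise.where

    if not backend.is_hardware:
        # pre-drawn uniforms keep the float path fast and the draw order fixed
        U_in = rng.random((T, n_in))
        U_hid = rng.random((T, n_hidden))
        U_out = rng.random((T, n_out))

    for t in range(T):
        in_target = train and sched.phase(t) == "target"

        if backend.is_hardware:
            spk_in = backend.sample(p_in, "input", rng, params.dt)
        else:
            spk_in = (U_in[t] < p_in).astype(np.float64)
        if drop_in:
            spk_in = spk_in * (rng.random(n_in) >= drop_p)
        x = f_in.update(spk_in)

        V0a = apical_potential(net.Y, s1)
        V0b = basal_potential(net.W0, x, net.b0)
        if hwq is not None:
            V0a, V0b = hwq(V0a), hwq(V0b)
        V0 = soma_step_hidden(V0, V0b, V0a, params)
        if hwq is not None:
            V0 = hwq(V0)
        r0 = params.phi_max * backend.sigmoid(V0)
        if backend.is_hardware:
            spk_h = backend.sample(hwq(r0), "hidden", rng, params.dt)
        else:
            spk_h = (U_hid[t] < r0 * params.dt).astype(np.float64)
        if drop_hid:
            spk_h = spk_h * (rng.random(n_hidden) >= drop_p)
        s0 = f_hid.update(spk_h)

        V1b = basal_potential(net.W1, s0, net.b1)
        if hwq is not None:
            V1b = hwq(V1b)
        I = teaching_current(V1, g_E_t, g_I_t, params) if in_target else 0.0
        V1 = soma_step_output(V1, V1b, I, params)
        if hwq is not None:
            V1 = hwq(V1)
        r1 = params.phi_max * backend.sigmoid(V1)
        if backend.is_hardware:
            spk_o = backend.sample(hwq(r1), "output", rng, params.dt)
        else:
            spk_o = (U_out[t] < r1 * params.dt).astype(np.float64)
        if drop_out:
            spk_o = spk_o * (rng.random(n_out) >= drop_p)
        counts += spk_o
        s1 = f_out.update(spk_o)

        if record_traces:
            traces["V0"][t] = V0
            traces["V1"][t] = V1

        if train and sched.accumulating(t, net.config.plateau_window_mode):
            if in_target:
                acc.accumulate_target(V0a, V1)
            else:
                acc.accumulate_forward(V0a, V0, x, s0, V1)

    if train:
        apply_trial_end(net, acc, sched)
    return TrialResult(spike_counts=counts, duration_ms=T, traces=traces)


def predict(result: TrialResult) -> int:
    """Class = output neuron with the most spikes; ties -> lowest index."""
    return int(np.argmax(result.spike_counts))


# ---------------------------------------------------------------------------
# Training and evaluation harnesses
# ---------------------------------------------------------------------------

def evaluate_classification(net: SNNetwork, patterns: Sequence[SpikePattern],
                            readout_ms: int = DEFAULT_READOUT_MS,
                            noise: Optional[NoiseSpec] = None) -> float:
    """Fraction of patterns whose forward readout argmax equals the label."""
    hits = 0
    for p in patterns:
        result = run_trial(net, p, mode="test", noise=noise,
                           readout_ms=readout_ms)
        hits += predict(result) == p.label
    return hits / len(patterns)


def train(net: SNNetwork, patterns: Sequence[SpikePattern], epochs: int,
          eval_every: int = 1, readout_ms: int = DEFAULT_READOUT_MS,
          noise: Optional[NoiseSpec] = None) -> list:
    """Train on labelled patterns; one train trial per pattern per epoch.

    Patterns are presented in fixed cyclic order.  Returns the per-epoch test
    accuracy log (evaluated every ``eval_every`` epochs, carrying the last
    value forward in between; ``eval_every=0`` skips evaluation and returns
    an empty log, which is how long experiment harnesses run).
    """
    history = []
    last = float("nan")
    for epoch in range(epochs):
        for p in patterns:
            run_trial(net, p, mode="train", noise=noise)
        if eval_every:
            if (epoch + 1) % eval_every == 0:
                last = evaluate_classification(net, patterns, readout_ms,
                                               noise=noise)
            history.append(last)
    return history


def train_reproduction(net: SNNetwork, pattern: SpikePattern, epochs: int,
                       noise: Optional[NoiseSpec] = None) -> SNNetwork:
    """Train the echo task: one graded-nudging trial per epoch."""
    for _ in range(epochs):
        run_trial(net, pattern, mode="train", noise=noise)
    return net


def evaluate_reproduction(net: SNNetwork, pattern: SpikePattern,
                          readout_ms: int = REPRODUCTION_READOUT_MS,
                          noise: Optional[NoiseSpec] = None):
    """Unnudged forward run; score output rates against the target rates.

    Output rates are spike counts over the readout window scaled to Hz.
    Returns (output_rates_hz, mae, r_squared) with the pattern's target
    rates as the reference sequence.
    """
    from .evaluation import mae as _mae, r_squared as _r2
    n_out = net.sizes[2]
    target = pattern.target_rates if pattern.target_rates is not None \
        else pattern.rates
    if target.size != n_out:
        raise ValueError("need one target rate per output neuron")
    result = run_trial(net, pattern, mode="test", noise=noise,
                       readout_ms=readout_ms)
    out_hz = result.spike_counts / result.duration_ms * 1000.0
    return out_hz, _mae(target, out_hz), _r2(target, out_hz)
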