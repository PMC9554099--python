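"""Multi-compartment LIF (MLIF) neuron dynamics.

Hidden-layer neurons have three compartments — basal dendrite, apical
dendrite and soma — coupled to the soma by fixed conductances; output-layer
neurons have only the basal dendrite and the soma, plus a conductance-based
teaching current used to nudge them toward a target during learning.  Spike
trains entering a dendrite are low-pass filtered by a double-exponential
kernel evaluated over a 10 ms shift-register window, the somatic voltage
follows a forward-Euler update at 1 ms resolution, and the soma emits spikes
as a Poisson process of its instantaneous rate phi = phi_max * sigma(V).

Two numeric backends produce the dynamics: an exact floating-point reference
and a hardware emulation that quantises every state variable to the 24-bit
fixed-point grid, evaluates the sigmoid with the 5-segment PWL circuit and
draws spikes from the rate-binned lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hw_numerics as hw


@dataclass
class NetworkParams:
    """Simulation constants; the defaults are the published parameter table.

    Units: times in ms, rates in spikes/ms, voltages and conductances in the
    model's dimensionless units (C_m = 1 makes conductance x voltage a
    voltage increment per ms).
    """

    dt: float = 1.0            # ms
    phi_max: float = 0.2       # spikes/ms (200 Hz)
    tau_l: float = 10.0        # slow kernel time constant, ms
    tau_s: float = 3.0         # fast kernel time constant, ms
    E_E: float = 12.0          # excitatory nudging reversal
    E_I: float = -12.0         # inhibitory nudging reversal
    g_d: float = 0.6           # output basal->soma conductance
    g_a: float = 0.0           # hidden apical->soma conductance
    g_b: float = 0.6           # hidden basal->soma conductance
    g_l: float = 0.1           # leak conductance
    V_res: float = 0.0         # resting potential
    C_m: float = 1.0           # membrane capacitance
    delta_t: float = 30.0      # unstable time excluded from phase averages, ms
    eta0: float = 0.01         # hidden-layer learning rate
    eta1: float = 0.01         # output-layer learning rate
    kernel_window: int = 10    # shift-register taps, ms

    def __post_init__(self) -> None:
        if not self.tau_l > self.tau_s > 0:
            raise ValueError("require tau_l > tau_s > 0")
        if self.C_m <= 0 or self.dt <= 0:
            raise ValueError("C_m and dt must be positive")
        for name in ("g_d", "g_a", "g_b", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")

    @property
    def P0(self) -> float:
        """Hidden-layer plasticity scaling factor, 20 / phi_max."""
        return 20.0 / self.phi_max

    @property
    def P1(self) -> float:
        """Output-layer plasticity scaling factor, 20 / phi_max^2."""
        return 20.0 / self.phi_max ** 2


def kernel_value(t: float, params: NetworkParams) -> float:
    """Double-exponential synaptic kernel K(t), zero for t <= 0.

    K(t) = (exp(-t/tau_l) - exp(-t/tau_s)) / (tau_l - tau_s) for t > 0.
    """
    if t <= 0:
        return 0.0
    return (np.exp(-t / params.tau_l) - np.exp(-t / params.tau_s)) \
        / (params.tau_l - params.tau_s)


def kernel_taps(params: NetworkParams) -> np.ndarray:
    """K evaluated at tau = 1..window ms — the shift-register contents.

    The current-step spike sits in the 1-tap delay register and first
    contributes at the next step, so the taps start at tau = 1.
    """
    return np.array([kernel_value(t, params)
                     for t in range(1, params.kernel_window + 1)])


class FilterBank:
    """Per-channel 10 ms spike history and its kernel-filtered value s(t).

    ``update`` pushes one spike bit per channel and recomputes
    s(t) = sum_tau K(tau) * spike(t - tau) over the window.  s decays to
    exactly zero once the window has flushed — the truncation the hardware
    shift registers apply to the full kernel sum.
    """

    def __init__(self, n_channels: int, params: NetworkParams,
                 quantize=None) -> None:
        self.taps = kernel_taps(params)
        if quantize is not None:
            self.taps = quantize(self.taps)
        self.history = np.zeros((params.kernel_window, n_channels))
        self._quantize = quantize
        self.s = np.zeros(n_channels)

    def update(self, spikes) -> np.ndarray:
        spikes = np.asarray(spikes, dtype=np.float64)
        if spikes.shape != self.history[0].shape:
            raise ValueError(
                f"expected {self.history.shape[1]} channels, got {spikes.shape}")
        self.history[1:] = self.history[:-1]
        self.history[0] = spikes
        s = self.taps @ self.history
        self.s = self._quantize(s) if self._quantize is not None else s
        return self.s

    def reset(self) -> None:
        self.history[:] = 0.0
        self.s = np.zeros_like(self.s)


def basal_potential(W, filtered_input, b) -> np.ndarray:
    """Basal dendritic potential: the affine map W @ x + b."""
    W = np.asarray(W)
    x = np.asarray(filtered_input)
    b = np.asarray(b)
    if W.shape[1] != x.shape[0] or W.shape[0] != b.shape[0]:
        raise ValueError(f"dimension mismatch: W{W.shape}, x{x.shape}, b{b.shape}")
    return W @ x + b


def apical_potential(Y, filtered_feedback) -> np.ndarray:
    """Apical dendritic potential: the linear map Y @ s1 (no bias)."""
    Y = np.asarray(Y)
    s = np.asarray(filtered_feedback)
    if Y.shape[1] != s.shape[0]:
        raise ValueError(f"dimension mismatch: Y{Y.shape}, s{s.shape}")
    return Y @ s


def soma_step_hidden(V0, V0b, V0a, params: NetworkParams):
    """One Euler step of the hidden somatic voltage.

    V(t+1) = V(t) + (g_l (V_res - V) + g_b (V0b - V) + g_a (V0a - V)) / C_m.
    """
    p = params
    return V0 + (p.g_l * (p.V_res - V0) + p.g_b * (V0b - V0)
                 + p.g_a * (V0a - V0)) / p.C_m


def teaching_current(V1, g_E_active, g_I_active, params: NetworkParams):
    """Conductance-based nudging current g_E (E_E - V) + g_I (E_I - V).

    Zero in the forward phase (both active conductances are zero there).
    """
    return g_E_active * (params.E_E - V1) + g_I_active * (params.E_I - V1)


def soma_step_output(V1, V1b, I, params: NetworkParams):
    """One Euler step of the output somatic voltage, teaching current included.

    V(t+1) = V(t) + (g_l (V_res - V) + g_d (V1b - V) + I) / C_m.
    """
    p = params
    return V1 + (p.g_l * (p.V_res - V1) + p.g_d * (V1b - V1) + I) / p.C_m


@dataclass
class HiddenNeuronState:
    """Compartment voltages and the latest rate/spike of one hidden MLIF."""
    V0: float = 0.0
    V0b: float = 0.0
    V0a: float = 0.0
    rate: float = 0.0
    spike: int = 0


@dataclass
class OutputNeuronState:
    """Output MLIF state including the per-neuron nudging conductances."""
    V1: float = 0.0
    V1b: float = 0.0
    I: float = 0.0
    g_E_active: float = 0.0
    g_I_active: float = 0.0
    rate: float = 0.0
    spike: int = 0
    spike_counter: int = 0


# ---------------------------------------------------------------------------
# Numeric backends
# ---------------------------------------------------------------------------

class FloatBackend:
    """Exact floating-point reference dynamics."""

    name = "float"
    is_hardware = False

    def sigmoid(self, V):
        return 1.0 / (1.0 + np.exp(-np.asarray(V, dtype=np.float64)))

    def sigmoid_deriv(self, V):
        s = self.sigmoid(V)
        return s * (1.0 - s)

    def quantize(self, x):
        return x

    def sample(self, rates_per_ms, layer, rng, dt: float = 1.0):
        """Independent Bernoulli(rate * dt) per neuron per step."""
        r = np.asarray(rates_per_ms, dtype=np.float64)
        return (rng.random(r.shape) < r * dt).astype(np.float64)


class HardwareBackend:
    """Value-level emulation of the fixed-point digital datapath.

    Every arithmetic block's result is truncated to the 24-bit grid, the
    sigmoid and its derivative are the PWL circuits, and spike sampling reads
    the rate-binned lookup-table trains through advancing addresses.
    """

    name = "hw"
    is_hardware = True

    def __init__(self, lut_seed: int = 0, train_length: int = 4096) -> None:
        self.pwl_sigmoid = hw.pwl5_sigmoid()
        self.pwl_deriv = hw.pwl6_sigmoid_derivative()
        self.lut = hw.poisson_lut_build(lut_seed, train_length)

    def sigmoid(self, V):
        return hw.pwl_eval(self.pwl_sigmoid, V, fixed_point=True)

    def sigmoid_deriv(self, V):
        return hw.pwl_eval(self.pwl_deriv, V, fixed_point=True)

    def quantize(self, x):
        return hw.fx_quantize(x)

    def sample(self, rates_per_ms, layer, rng, dt: float = 1.0):
        """LUT read: the rate in Hz selects the 20 Hz bin for each neuron."""
        rates_hz = np.asarray(rates_per_ms, dtype=np.float64) * 1000.0 * dt
        return hw.poisson_lut_sample_rates(self.lut, rates_hz, layer)

    def reset_addresses(self) -> None:
        self.lut.addresses.clear()


def make_backend(name: str, lut_seed: int = 0):
    if name == "float":
        return FloatBackend()
    if name in ("hw", "hardware", "fixed"):
        return HardwareBackend(lut_seed=lut_seed)
    raise ValueError(f"unknown backend {name!r}")


def firing_rate(V, params: NetworkParams, backend) -> np.ndarray:
    """Instantaneous rate phi = phi_max * sigma(V), in spikes/ms."""
    return params.phi_max * backend.sigmoid(V)


def sample_spikes(rates, backend, rng=None, layer="default",
                  dt: float = 1.0) -> np.ndarray:
    """Draw one spike bit per neuron from its instantaneous rate."""
    return backend.sample(rates, layer, rng, dt)
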