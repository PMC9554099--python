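"""Two-phase plateau-potential learning rule.

A training trial is 200 ms: a 100 ms forward phase (teaching current off)
followed by a 100 ms target phase in which the output somata are nudged
toward the label or target rates.  During each phase, once the first
``delta_t`` = 30 ms of settling ("unstable time") has passed, the trial
controller accumulates the apical potentials, somatic voltages and filtered
presynaptic traces.  At the end of the target phase the accumulated phase
statistics drive one weight/bias update per layer and everything is cleared.

The hidden-layer error is the difference of the two dendritic plateau
potentials alpha = sigma(mean apical potential); the output-layer error is
the difference of the phase-averaged firing rates computed from the averaged
somatic voltages.  Both updates are outer products of a per-neuron error
with the accumulated presynaptic drive — no per-timestep gradient state is
kept, so memory is O(1) in trial length for every synapse.

The voltage and apical accumulators are divided by the number of accumulated
samples (the hardware's 1/70 divider); the presynaptic accumulators x_f and
s0_f enter the update as plain sums, which is how the accumulate registers
feed the multiplier and sets the rule's working learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hw_numerics as hw
from .neuron_core import NetworkParams


@dataclass
class PhaseSchedule:
    """Trial controller: system counter, phase enables and stable windows."""

    forward_duration: int = 100   # ms
    target_duration: int = 100    # ms
    unstable_time: int = 30       # ms excluded at the start of each phase

    def __post_init__(self) -> None:
        if self.unstable_time >= min(self.forward_duration, self.target_duration):
            raise ValueError("unstable_time must be shorter than each phase")

    @property
    def trial_length(self) -> int:
        return self.forward_duration + self.target_duration

    @property
    def samples_per_phase(self) -> int:
        """Accumulated samples per phase (70 at the defaults)."""
        return self.forward_duration - self.unstable_time

    def phase(self, counter: int) -> str:
        """'forward' while counter < 100, 'target' until the wrap at 200."""
        if not 0 <= counter < self.trial_length:
            raise ValueError(f"counter {counter} outside trial")
        return "forward" if counter < self.forward_duration else "target"

    def enables(self, counter: int):
        """(forward_enable, target_enable) — exactly one is set."""
        fwd = self.phase(counter) == "forward"
        return int(fwd), int(not fwd)

    def accumulating(self, counter: int, mode: str = "hardware-70ms") -> bool:
        """Whether this step's state enters the active phase's averages.

        'hardware-70ms': every step after the unstable time (70 samples per
        phase at defaults, matching the 1/70 divider).  'eq-delta-t': only
        the final unstable_time ms of the phase (the integral bounds
        t - delta_t .. t written for the plateau potentials).
        """
        within = counter % self.forward_duration if counter < self.forward_duration \
            else counter - self.forward_duration
        if mode == "hardware-70ms":
            return within >= self.unstable_time
        if mode == "eq-delta-t":
            dur = self.forward_duration if counter < self.forward_duration \
                else self.target_duration
            return within >= dur - self.unstable_time
        raise ValueError(f"unknown plateau_window_mode {mode!r}")


@dataclass
class LearningConfig:
    """Knobs of the plasticity rule.

    ``update_sign`` multiplies the leading minus sign of the printed update:
    +1 applies the rule exactly as published; -1 flips it.  The flipped sign
    is the default because the as-published direction moves weights away
    from the nudging target and fails to learn (see docs/methods.md).

    ``presyn_mode`` selects whether x_f and s0_f enter the update as
    accumulator sums ('sum', hardware reading, default) or as 1/n means
    ('mean', the literal reading of the equations).
    """

    update_sign: float = -1.0
    plateau_window_mode: str = "hardware-70ms"
    presyn_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.update_sign not in (-1.0, 1.0, -1, 1):
            raise ValueError("update_sign must be +1 or -1")
        if self.presyn_mode not in ("sum", "mean"):
            raise ValueError("presyn_mode must be 'sum' or 'mean'")


class PlasticityAccumulators:
    """Per-phase running sums feeding the end-of-trial update."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int) -> None:
        self._shapes = (n_in, n_hidden, n_out)
        self.reset()

    def reset(self) -> None:
        n_in, n_hidden, n_out = self._shapes
        self.apical_f = np.zeros(n_hidden)
        self.apical_t = np.zeros(n_hidden)
        self.soma_hidden_f = np.zeros(n_hidden)
        self.input_f = np.zeros(n_in)
        self.hidden_filtered_f = np.zeros(n_hidden)
        self.soma_output_f = np.zeros(n_out)
        self.soma_output_t = np.zeros(n_out)
        self.n_forward = 0
        self.n_target = 0
        self.finalized = False

    def accumulate_forward(self, V0a, V0, x, s0, V1) -> None:
        self.apical_f += V0a
        self.soma_hidden_f += V0
        self.input_f += x
        self.hidden_filtered_f += s0
        self.soma_output_f += V1
        self.n_forward += 1

    def accumulate_target(self, V0a, V1) -> None:
        self.apical_t += V0a
        self.soma_output_t += V1
        self.n_target += 1

    def finalize(self) -> None:
        if self.n_forward == 0 or self.n_target == 0:
            raise RuntimeError("both phases must accumulate before an update")
        self.finalized = True


def accumulate_step(acc: PlasticityAccumulators, counter: int,
                    schedule: PhaseSchedule, V0a, V0, x, s0, V1,
                    config: LearningConfig = LearningConfig()) -> None:
    """Route one step's state into the active phase's accumulators."""
    if not schedule.accumulating(counter, config.plateau_window_mode):
        return
    if schedule.phase(counter) == "forward":
        acc.accumulate_forward(V0a, V0, x, s0, V1)
    else:
        acc.accumulate_target(V0a, V1)


def plateau_potential(apical_mean, backend):
    """alpha = sigma(windowed apical mean); PWL sigmoid on hardware."""
    return backend.sigmoid(apical_mean)


def _presyn(config: LearningConfig, total, n: int):
    return total / n if config.presyn_mode == "mean" else total


def hidden_update(W0, b0, acc: PlasticityAccumulators, config: LearningConfig,
                  params: NetworkParams, backend):
    """Plateau-driven update of the input->hidden weights and biases.

    e_i = (alpha_i^t - alpha_i^f) * phi_max * sigma'(Vbar0f_i)
    dW  = -update_sign * eta0 P0 g_b/(g_l+g_b+g_a) * outer(e, x_f)
    and the bias update is the same without the presynaptic factor.
    """
    if not acc.finalized:
        raise RuntimeError("accumulators not finalized; call finalize() first")
    q = backend.quantize
    alpha_f = plateau_potential(q(acc.apical_f / acc.n_forward), backend)
    alpha_t = plateau_potential(q(acc.apical_t / acc.n_target), backend)
    V0f = q(acc.soma_hidden_f / acc.n_forward)
    xf = q(_presyn(config, acc.input_f, acc.n_forward))
    coef = config.update_sign * params.eta0 * params.P0 \
        * params.g_b / (params.g_l + params.g_b + params.g_a)
    if backend.is_hardware:
        # (alpha_t - alpha_f) in (-1,1) is the shift multiplier's "Input a"
        err = hw.shift_mul_array(alpha_t - alpha_f,
                                 q(params.phi_max * backend.sigmoid_deriv(V0f)))
        dW = q(coef * np.outer(err, xf))
        db = q(coef * err)
    else:
        err = (alpha_t - alpha_f) * params.phi_max * backend.sigmoid_deriv(V0f)
        dW = coef * np.outer(err, xf)
        db = coef * err
    return q(W0 - dW), q(b0 - db)


def output_update(W1, b1, acc: PlasticityAccumulators, config: LearningConfig,
                  params: NetworkParams, backend):
    """Rate-error update of the hidden->output weights and biases.

    The phase-average rates are phi_max * sigma(Vbar) of the averaged
    somatic voltages; the error (phibar1t - phibar1f) plays the role the
    plateau difference plays in the hidden layer.
    """
    if not acc.finalized:
        raise RuntimeError("accumulators not finalized; call finalize() first")
    q = backend.quantize
    V1f = q(acc.soma_output_f / acc.n_forward)
    V1t = q(acc.soma_output_t / acc.n_target)
    phi_f = q(params.phi_max * backend.sigmoid(V1f))
    phi_t = q(params.phi_max * backend.sigmoid(V1t))
    s0f = q(_presyn(config, acc.hidden_filtered_f, acc.n_forward))
    coef = config.update_sign * params.eta1 * params.P1 \
        * params.g_d / (params.g_l + params.g_d)
    if backend.is_hardware:
        err = hw.shift_mul_array(phi_t - phi_f,
                                 q(params.phi_max * backend.sigmoid_deriv(V1f)))
        dW = q(coef * np.outer(err, s0f))
        db = q(coef * err)
    else:
        err = (phi_t - phi_f) * params.phi_max * backend.sigmoid_deriv(V1f)
        dW = coef * np.outer(err, s0f)
        db = coef * err
    return q(W1 - dW), q(b1 - db)


def apply_trial_end(net, acc: PlasticityAccumulators,
                    schedule: PhaseSchedule) -> None:
    """Apply both layer updates once, clear accumulators and neuron state.

    The feedback weights Y are never touched.  Mirrors the controller's
    clear pulse at the counter wrap.
    """
    acc.finalize()
    net.W0, net.b0 = hidden_update(net.W0, net.b0, acc, net.config,
                                   net.params, net.backend)
    net.W1, net.b1 = output_update(net.W1, net.b1, acc, net.config,
                                   net.params, net.backend)
    acc.reset()
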