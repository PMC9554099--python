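"""Error metrics and software-vs-hardware agreement comparisons.

RMSE, MAE and R-square are the three indicators used for every accuracy
surface: the PWL approximations against the exact nonlinearities, the shift
multiplier against exact products, and the fixed-point MLIF voltage trace
against the floating-point reference on a shared input raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import hw_numerics as hw
from .neuron_core import (FilterBank, FloatBackend, HardwareBackend,
                          NetworkParams, soma_step_hidden)

# Evaluation grids for the shipped PWL tables.  The published error triplets
# pin these down: the sigmoid statistics correspond to a +/-10 sweep and the
# derivative statistics to a +/-200 sweep (the derivative is identically
# clipped far outside its bump, so the wide sweep mostly scores zeros).
SIGMOID_GRID = (-10.0, 10.0, 0.01)
DERIV_GRID = (-200.0, 200.0, 0.01)


@dataclass
class MetricReport:
    rmse: float
    mae: float
    r2: float
    n: int
    context: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.context or 'comparison'}: RMSE={self.rmse:.6g} "
                f"MAE={self.mae:.6g} R2={self.r2:.6g} (n={self.n})")


def _paired(reference, test):
    r = np.asarray(reference, dtype=np.float64).ravel()
    t = np.asarray(test, dtype=np.float64).ravel()
    if r.size == 0:
        raise ValueError("empty sequences")
    if r.size != t.size:
        raise ValueError(f"length mismatch: {r.size} vs {t.size}")
    return r, t


def rmse(reference, test) -> float:
    """Root-mean-square error between paired sequences."""
    r, t = _paired(reference, test)
    return float(np.sqrt(np.mean((r - t) ** 2)))


def mae(reference, test) -> float:
    """Mean absolute error between paired sequences."""
    r, t = _paired(reference, test)
    return float(np.mean(np.abs(r - t)))


def r_squared(reference, test) -> float:
    """Coefficient of determination with ``reference`` as the ground truth."""
    r, t = _paired(reference, test)
    sst = float(np.sum((r - r.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("reference sequence is constant; R^2 undefined")
    return 1.0 - float(np.sum((r - t) ** 2)) / sst


def metric_report(reference, test, context: str = "") -> MetricReport:
    r, t = _paired(reference, test)
    return MetricReport(rmse=rmse(r, t), mae=mae(r, t), r2=r_squared(r, t),
                        n=r.size, context=context)


# ---------------------------------------------------------------------------
# Backend comparisons
# ---------------------------------------------------------------------------

def pwl_error_report(which: str = "sigmoid", grid=None) -> MetricReport:
    """Approximation error of a shipped PWL table on a uniform grid."""
    if which == "sigmoid":
        spec = hw.pwl5_sigmoid()
        lo, hi, step = grid or SIGMOID_GRID
        V = np.arange(lo, hi + step / 2, step)
        exact = 1.0 / (1.0 + np.exp(-V))
        ctx = "PWL5 sigmoid"
    elif which in ("deriv", "derivative"):
        spec = hw.pwl6_sigmoid_derivative()
        lo, hi, step = grid or DERIV_GRID
        V = np.arange(lo, hi + step / 2, step)
        s = 1.0 / (1.0 + np.exp(-V))
        exact = s * (1.0 - s)
        ctx = "PWL6 sigmoid derivative"
    else:
        raise ValueError(f"unknown PWL table {which!r}")
    approx = hw.pwl_eval(spec, V)
    return metric_report(exact, approx, context=ctx)


def _single_neuron_trace(raster, weights, bias, params, backend):
    """Somatic voltage of one hidden MLIF driven by a fixed input raster."""
    hwq = backend.quantize if backend.is_hardware else None
    n_ch = raster.shape[1]
    f = FilterBank(n_ch, params, quantize=hwq)
    w = hwq(weights) if hwq is not None else weights
    b = hwq(np.asarray([bias]))[0] if hwq is not None else bias
    V = params.V_res
    trace = np.empty(raster.shape[0])
    for t in range(raster.shape[0]):
        x = f.update(raster[t])
        V0b = float(w @ x) + b
        if hwq is not None:
            V0b = float(hwq(V0b))
        V = float(soma_step_hidden(V, V0b, 0.0, params))
        if hwq is not None:
            V = float(hwq(V))
        trace[t] = V
    return trace


def compare_backends(component: str, seed: int = 0, n: int = 100_000,
                     duration_ms: int = 200) -> MetricReport:
    """Run the float and hardware paths on identical inputs and score them.

    Components: 'pwl_sigmoid' and 'pwl_deriv' (approximation error on the
    default grids), 'shift_mul' (random products, a in [0,1), b in [-8,8)),
    'mlif_trace' (somatic voltage of one hidden neuron over a shared random
    Poisson raster).
    """
    rng = np.random.default_rng(seed)
    if component == "pwl_sigmoid":
        return pwl_error_report("sigmoid")
    if component == "pwl_deriv":
        return pwl_error_report("deriv")
    if component == "shift_mul":
        a = rng.random(n)
        b = rng.uniform(-8.0, 8.0, n)
        exact = hw.fx_quantize(a) * hw.fx_quantize(b)
        approx = hw.shift_mul_array(a, b)
        return metric_report(exact, approx, context="shift MUL vs exact product")
    if component == "mlif_trace":
        params = NetworkParams()
        rates = rng.uniform(20.0, 200.0, 8)
        raster = (rng.random((duration_ms, 8)) < rates / 1000.0).astype(float)
        weights = rng.uniform(-1.0, 1.0, 8)
        bias = float(rng.uniform(-0.5, 0.5))
        ref = _single_neuron_trace(raster, weights, bias, params, FloatBackend())
        test = _single_neuron_trace(raster, weights, bias, params,
                                    HardwareBackend(lut_seed=seed))
        return metric_report(ref, test, context="MLIF somatic trace hw vs float")
    raise ValueError(f"unknown component {component!r}")


def approximation_table() -> list:
    """Error-evaluation table of both shipped PWL approximations."""
    return [pwl_error_report("sigmoid"), pwl_error_report("deriv")]
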