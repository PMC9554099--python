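"""Bit-faithful emulation of the digital-circuit arithmetic.

The hardware backend of the simulator computes with 24-bit sign-magnitude
fixed-point numbers (1 sign bit, 7 integer bits, 16 fraction bits), replaces
the sigmoid and its derivative by piecewise-linear (PWL) segments whose slopes
are sums of powers of two, multiplies two variables with a shift-add
multiplier, and draws Poisson spikes from ten pre-generated rate-binned spike
trains read through advancing addresses.  This module emulates each of those
circuits at value level: every operation returns exactly the number the
circuit would hold in its output register.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

FRACTION_BITS = 16
FRACTION_SCALE = 1 << FRACTION_BITS          # 65536
INTEGER_BITS = 7
MAX_RAW = (1 << (INTEGER_BITS + FRACTION_BITS)) - 1   # 0x7FFFFF
MAX_VALUE = MAX_RAW / FRACTION_SCALE                  # 127 + 65535/65536
RESOLUTION = 1.0 / FRACTION_SCALE


# ---------------------------------------------------------------------------
# 24-bit sign-magnitude fixed point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint24:
    """One 24-bit sign-magnitude word: (-1)^sign * (integer + fraction/2^16).

    ``sign`` is 0 or 1, ``integer`` is the 7-bit unsigned integer part and
    ``fraction`` the 16-bit unsigned numerator over 2^16.  Negative zero is
    normalised to positive zero on construction.
    """

    sign: int
    integer: int
    fraction: int

    def __post_init__(self) -> None:
        if self.sign not in (0, 1):
            raise ValueError(f"sign must be 0 or 1, got {self.sign}")
        if not 0 <= self.integer < (1 << INTEGER_BITS):
            raise ValueError(f"integer out of 7-bit range: {self.integer}")
        if not 0 <= self.fraction < FRACTION_SCALE:
            raise ValueError(f"fraction out of 16-bit range: {self.fraction}")
        if self.integer == 0 and self.fraction == 0 and self.sign == 1:
            object.__setattr__(self, "sign", 0)

    @property
    def magnitude_raw(self) -> int:
        """Unsigned magnitude in units of 2^-16."""
        return (self.integer << FRACTION_BITS) | self.fraction

    @property
    def raw(self) -> int:
        """The 24-bit word with the sign in bit 23."""
        return (self.sign << 23) | self.magnitude_raw

    @classmethod
    def from_raw(cls, raw: int) -> "FixedPoint24":
        if not 0 <= raw < (1 << 24):
            raise ValueError(f"raw word out of 24-bit range: {raw}")
        return cls(sign=(raw >> 23) & 1,
                   integer=(raw >> FRACTION_BITS) & 0x7F,
                   fraction=raw & 0xFFFF)

    def decode(self) -> float:
        return (-1.0) ** self.sign * (self.integer + self.fraction / FRACTION_SCALE)

    float = decode  # convenience alias


def fx_encode(x: float) -> FixedPoint24:
    """Encode a real number, truncating the magnitude toward zero.

    Truncation matches the behaviour of dropping low bits in a barrel
    shifter; values beyond the representable range saturate at the maximum
    magnitude instead of wrapping, and -0.0 normalises to +0.0.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot encode non-finite value {x!r}")
    sign = 1 if x < 0 else 0
    raw = min(int(abs(x) * FRACTION_SCALE), MAX_RAW)
    return FixedPoint24(sign=0 if raw == 0 else sign,
                        integer=raw >> FRACTION_BITS,
                        fraction=raw & 0xFFFF)


def fx_decode(v: FixedPoint24) -> float:
    """Exact real value of a fixed-point word."""
    return v.decode()


def fx_quantize(x):
    """Vectorised encode-decode round trip on floats.

    Returns the value a 24-bit register would hold after storing ``x``:
    magnitude truncated to a multiple of 2^-16 and saturated at
    127 + 65535/65536.  Scalar in, scalar out; array in, array out.
    Used by the hardware backend after every arithmetic block.
    """
    x = np.asarray(x, dtype=np.float64)
    q = np.minimum(np.trunc(np.abs(x) * FRACTION_SCALE), MAX_RAW)
    out = np.copysign(q / FRACTION_SCALE, x)
    out = out + 0.0  # -0.0 -> +0.0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Shift multiplier (two-variable multiplication without DSP blocks)
# ---------------------------------------------------------------------------

def _shift_mul_raw(a_frac: np.ndarray, b_raw: np.ndarray) -> np.ndarray:
    """Sum of bit-gated arithmetic right shifts on raw magnitudes.

    ``a_frac`` holds the 16 fraction bits of operand a; the bit with weight
    2^-i gates ``b_raw >> i``.  Integer right shift on the magnitude is
    truncation toward zero, exactly as in the barrel shifter.
    """
    acc = np.zeros_like(b_raw)
    for i in range(1, FRACTION_BITS + 1):
        bit = (a_frac >> (FRACTION_BITS - i)) & 1
        acc = acc + bit * (b_raw >> i)
    return acc


def shift_mul(a, b):
    """Multiply two fixed-point variables with the shift-add circuit.

    Operand ``a`` is expected in [0, 1): its integer bits are dropped and the
    16 fraction bits are split onto a bus, each bit gating a right-shifted
    copy of ``b``; the gated shifts are summed.  Accepts ``FixedPoint24`` or
    floats (floats are encoded first); returns the same kind.  The result
    saturates on overflow and carries the XOR of the operand signs.
    """
    wrap = isinstance(a, FixedPoint24) or isinstance(b, FixedPoint24)
    fa = a if isinstance(a, FixedPoint24) else fx_encode(float(a))
    fb = b if isinstance(b, FixedPoint24) else fx_encode(float(b))
    raw = int(_shift_mul_raw(np.asarray(fa.fraction), np.asarray(fb.magnitude_raw)))
    raw = min(raw, MAX_RAW)
    sign = fa.sign ^ fb.sign
    out = FixedPoint24(sign=0 if raw == 0 else sign,
                       integer=raw >> FRACTION_BITS,
                       fraction=raw & 0xFFFF)
    return out if wrap else out.decode()


def shift_mul_array(a, b):
    """Vectorised :func:`shift_mul` on float arrays (element-wise)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a_raw = np.minimum(np.trunc(np.abs(a) * FRACTION_SCALE), MAX_RAW).astype(np.int64)
    b_raw = np.minimum(np.trunc(np.abs(b) * FRACTION_SCALE), MAX_RAW).astype(np.int64)
    a_frac = a_raw & 0xFFFF
    raw = np.minimum(_shift_mul_raw(a_frac, b_raw), MAX_RAW)
    sign = np.where((a < 0) ^ (b < 0), -1.0, 1.0)
    return sign * raw / FRACTION_SCALE


# ---------------------------------------------------------------------------
# Piecewise-linear nonlinearities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWLSpec:
    """A piecewise-linear function: segment i applies y = m_i V + k_i.

    ``borders`` are the strictly increasing upper borders N_0..N_{n-2}; the
    first segment covers V <= N_0, interior segments N_{i-1} < V <= N_i and
    the last segment is unbounded above.  The output is clipped to
    [clip_low, clip_high] (either may be infinite).
    """

    slopes: tuple
    intercepts: tuple
    borders: tuple
    clip_low: float = -math.inf
    clip_high: float = math.inf

    def __post_init__(self) -> None:
        if len(self.slopes) != len(self.intercepts):
            raise ValueError("slopes and intercepts must have equal length")
        if len(self.borders) != len(self.slopes) - 1:
            raise ValueError("need exactly n_segments - 1 borders")
        b = np.asarray(self.borders, dtype=float)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("borders must be strictly increasing")
        if self.clip_low > self.clip_high:
            raise ValueError("clip_low must not exceed clip_high")

    @property
    def n_segments(self) -> int:
        return len(self.slopes)


def pwl_eval(spec: PWLSpec, V, fixed_point: bool = False):
    """Evaluate a PWL spec at V (scalar or array).

    With ``fixed_point=True`` the input, the slope product and the final sum
    are truncated to the 24-bit grid, mirroring the hardware datapath where
    the m_i * V product is formed by shift-add constant multiplication (all
    shipped slopes are sums of powers of two, so the product is exact on the
    fixed-point grid up to the final truncation).
    """
    V_arr = np.asarray(V, dtype=np.float64)
    scalar = V_arr.ndim == 0
    if fixed_point:
        V_arr = fx_quantize(V_arr)
    idx = np.searchsorted(np.asarray(spec.borders, dtype=float), V_arr, side="left")
    m = np.asarray(spec.slopes, dtype=float)[idx]
    k = np.asarray(spec.intercepts, dtype=float)[idx]
    y = m * V_arr + k
    if fixed_point:
        y = fx_quantize(y)
    y = np.clip(y, spec.clip_low, spec.clip_high)
    return float(y) if scalar else y


def pwl5_sigmoid() -> PWLSpec:
    """The shipped 5-segment approximation of the logistic sigmoid.

    Slopes and intercepts are the published coefficient table; the printed
    border magnitudes (3.4, 1.3) are signed to make the borders increasing,
    giving the odd-symmetric layout around 0.  Output clipped to [0, 1].
    """
    return PWLSpec(
        slopes=(0.0078125, 0.0625, 0.25, 0.0625, 0.0078125),
        intercepts=(0.05, 0.24, 0.5, 0.76, 0.95),
        borders=(-3.4, -1.3, 1.3, 3.4),
        clip_low=0.0, clip_high=1.0,
    )


def pwl6_sigmoid_derivative() -> PWLSpec:
    """The shipped 6-segment approximation of the sigmoid derivative.

    The coefficient table prints magnitudes only (with the border 3.2 listed
    twice); the derivative is an even bump, so the positive-side slopes are
    the negated mirror of the negative side and the centre intercept is the
    symmetric 0.25 (the function then peaks at exactly sigma'(0) = 0.25).
    Output clipped to [0, inf).
    """
    return PWLSpec(
        slopes=(0.0078125, 0.03125, 0.0625, -0.0625, -0.03125, -0.0078125),
        intercepts=(0.05, 0.15, 0.25, 0.25, 0.15, 0.05),
        borders=(-3.2, -2.0, 0.0, 2.0, 3.2),
        clip_low=0.0, clip_high=math.inf,
    )


def _pwl_rmse(spec: PWLSpec, x: np.ndarray, y: np.ndarray) -> float:
    err = pwl_eval(spec, x) - y
    return float(np.sqrt(np.mean(err ** 2)))


def fit_pwl(target_fn, n_segments: int,
            grid_steps: tuple = (0.1, 0.01, 0.01),
            fit_range: tuple = (-8.0, 8.0),
            clip: tuple = (-math.inf, math.inf),
            grid_resolution: float = 0.01,
            max_iter: int = 60, border_scan: int = 10) -> PWLSpec:
    """Fit a PWL approximation by deterministic coordinate descent.

    The borders live on a grid of step ``grid_steps[0]`` and the slopes and
    intercepts on grids of steps ``grid_steps[1]`` and ``grid_steps[2]``.  A
    full joint exhaustion over those grids is combinatorially infeasible for
    5-6 segments, so the search minimises the RMSE on the fit grid (step
    ``grid_resolution``) by alternating two exact sub-steps:

    1. per-segment least-squares fit of (m_i, k_i), snapped to the grid with
       a local +/-3-step search scored on the clipped segment error;
    2. per-border scan over +/-``border_scan`` grid steps around the current
       value (bounded by its neighbours), refitting only the two adjacent
       segments for each candidate.

    The warm start places borders at curvature-mass quantiles (density
    proportional to |f''|^(2/5), the asymptotically optimal knot density for
    L2 piecewise-linear approximation), so the local border scans start near
    the optimum even on very wide fit ranges.  Sub-steps only accept a
    candidate that lowers the total RMSE, so the procedure terminates and is
    deterministic.
    """
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if not hi > lo:
        raise ValueError("empty fit_range")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    step_n, step_m, step_k = (float(s) for s in grid_steps)
    if min(step_n, step_m, step_k) <= 0:
        raise ValueError("grid steps must be positive")

    x = np.arange(lo, hi + grid_resolution / 2, grid_resolution)
    y = np.asarray([target_fn(v) for v in x], dtype=np.float64)

    def snap(v, step):
        return round(v / step) * step

    if n_segments > 1:
        curv = np.abs(np.gradient(np.gradient(y, x), x))
        density = curv ** 0.4 + 1e-12
        cdf = np.cumsum(density)
        cdf /= cdf[-1]
        borders = []
        prev = lo
        for i in range(1, n_segments):
            q = float(x[np.searchsorted(cdf, i / n_segments)])
            b = max(snap(q, step_n), prev + step_n)
            borders.append(b)
            prev = b
    else:
        borders = []

    def masks_for(borders):
        idx = np.searchsorted(np.asarray(borders, dtype=float), x, side="left")
        return [idx == i for i in range(len(borders) + 1)]

    def ls_fit(mask):
        if mask.sum() < 2:
            return 0.0, float(y[mask].mean()) if mask.any() else 0.0
        A = np.vstack([x[mask], np.ones(mask.sum())]).T
        m, k = np.linalg.lstsq(A, y[mask], rcond=None)[0]
        return float(m), float(k)

    def fit_segment(mask):
        """LS fit of one segment snapped to the grid with local refinement."""
        m0, k0 = ls_fit(mask)
        xm, ym = x[mask], y[mask]
        best = None
        for dm in range(-3, 4):
            for dk in range(-3, 4):
                m = snap(m0, step_m) + dm * step_m
                k = snap(k0, step_k) + dk * step_k
                seg = np.clip(m * xm + k, clip[0], clip[1])
                sse = float(np.sum((seg - ym) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, m, k)
        return best[1], best[2]

    def fit_all(borders):
        return map(list, zip(*(fit_segment(m) for m in masks_for(borders)))) \
            if borders or n_segments == 1 else ([], [])

    ms, ks = (list(v) for v in fit_all(borders))
    spec = PWLSpec(tuple(ms), tuple(ks), tuple(borders), clip[0], clip[1])
    best_rmse = _pwl_rmse(spec, x, y)

    for _ in range(max_iter):
        improved = False
        for j in range(len(borders)):
            left = borders[j - 1] + step_n if j > 0 else lo + step_n
            right = borders[j + 1] - step_n if j + 1 < len(borders) else hi - step_n
            c_lo = max(snap(borders[j] - border_scan * step_n, step_n), left)
            c_hi = min(snap(borders[j] + border_scan * step_n, step_n), right)
            if c_hi < c_lo:
                continue
            for cand in np.arange(c_lo, c_hi + step_n / 2, step_n):
                if abs(cand - borders[j]) < step_n / 2:
                    continue
                trial_borders = list(borders)
                trial_borders[j] = float(cand)
                masks = masks_for(trial_borders)
                tms, tks = list(ms), list(ks)
                tms[j], tks[j] = fit_segment(masks[j])
                tms[j + 1], tks[j + 1] = fit_segment(masks[j + 1])
                trial = PWLSpec(tuple(tms), tuple(tks), tuple(trial_borders),
                                clip[0], clip[1])
                r = _pwl_rmse(trial, x, y)
                if r < best_rmse - 1e-12:
                    borders, ms, ks, best_rmse = trial_borders, tms, tks, r
                    spec = trial
                    improved = True
        if not improved:
            break
    return spec


# ---------------------------------------------------------------------------
# Lookup-table Poisson spike generation
# ---------------------------------------------------------------------------

N_BINS = 10
BIN_WIDTH_HZ = 20.0
MAX_RATE_HZ = 200.0


@dataclass
class PoissonLUT:
    """Ten stored binary spike trains, one per 20 Hz frequency segment.

    ``trains[b]`` was drawn Bernoulli(lambda_per_bin[b]) per millisecond with
    lambda in {0.02, 0.04, ..., 0.2}; each reader keeps a per-neuron address
    into every train which advances by one bit per read and wraps at
    ``train_length``, emulating the shift-register readout.
    """

    trains: np.ndarray                       # (10, train_length) uint8
    lambda_per_bin: np.ndarray               # (10,) per-ms probabilities
    train_length: int
    addresses: dict = field(default_factory=dict)   # consumer -> (n,) pointers

    def pointers(self, consumer, n: int) -> np.ndarray:
        if consumer not in self.addresses:
            # stagger start addresses so neurons do not replay each other
            self.addresses[consumer] = (np.arange(n, dtype=np.int64)
                                        * (self.train_length // max(n, 1)))
        return self.addresses[consumer]


def rate_to_bin(rate_hz) -> np.ndarray:
    """Map a firing rate in Hz to its 20 Hz frequency segment.

    Rates are clipped to [0, 200]; bin b covers [20b, 20(b+1)) Hz with the
    top bin closed at 200.  Rates below 20 Hz read the lambda=0.02 train, a
    residual floor inherited from the circuit (there is no all-zero train).
    """
    r = np.clip(np.asarray(rate_hz, dtype=np.float64), 0.0, MAX_RATE_HZ)
    return np.minimum((r / BIN_WIDTH_HZ).astype(np.int64), N_BINS - 1)


def chi_square_poisson_check(train, lam: float, window: int = 20,
                             alpha: float = 0.05):
    """Chi-square goodness of fit of a binary train to Poisson spike counts.

    Counts spikes per ``window``-ms window and compares the count histogram
    with the Poisson(lam * window) expectation, pooling adjacent categories
    until each expectation reaches 5.  Returns (statistic, p_value, passed)
    with passed = (p >= alpha).  A degenerate train fails with its computed
    p-value rather than raising.
    """
    train = np.asarray(train).ravel()
    if train.size < 100:
        raise ValueError("train too short for a meaningful test")
    n_windows = train.size // window
    counts = train[:n_windows * window].reshape(n_windows, window).sum(axis=1)
    mu = lam * window
    kmax = max(int(stats.poisson.ppf(1 - 1e-9, mu)) + 1, int(counts.max()) + 1)
    probs = stats.poisson.pmf(np.arange(kmax + 1), mu)
    probs[-1] = max(1.0 - probs[:-1].sum(), 0.0)
    expected = probs * n_windows
    observed = np.bincount(counts.astype(int), minlength=kmax + 1)[:kmax + 1]

    pooled_obs, pooled_exp = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            pooled_obs.append(o_acc)
            pooled_exp.append(e_acc)
            o_acc = e_acc = 0.0
    if pooled_obs:
        pooled_obs[-1] += o_acc
        pooled_exp[-1] += e_acc
    else:
        pooled_obs, pooled_exp = [o_acc], [e_acc]
    o = np.asarray(pooled_obs, dtype=float)
    e = np.asarray(pooled_exp, dtype=float)
    statistic = float(np.sum((o - e) ** 2 / e))
    df = max(len(o) - 1, 1)
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, p_value, p_value >= alpha


def poisson_lut_build(seed: int, train_length: int = 4096,
                      max_retries: int = 50) -> PoissonLUT:
    """Generate the ten rate-binned spike trains, validated by chi-square.

    Each train is Bernoulli(lambda) per millisecond with lambda = 0.02 b for
    bin b; a train that fails the Poisson conformity check at alpha = 0.05 is
    redrawn (bounded retries — the check is anticonservative for the densest
    trains because Bernoulli counts are slightly under-dispersed).
    """
    if train_length < 100:
        raise ValueError("train_length must be >= 100")
    rng = np.random.default_rng(seed)
    lambdas = (np.arange(1, N_BINS + 1)) * 0.02
    trains = np.empty((N_BINS, train_length), dtype=np.uint8)
    for b, lam in enumerate(lambdas):
        for attempt in range(max_retries):
            t = (rng.random(train_length) < lam).astype(np.uint8)
            if chi_square_poisson_check(t, lam)[2]:
                trains[b] = t
                break
        else:
            raise RuntimeError(
                f"could not generate a conforming train for lambda={lam:.2f} "
                f"after {max_retries} attempts")
    return PoissonLUT(trains=trains, lambda_per_bin=lambdas,
                      train_length=train_length)


def poisson_lut_sample(lut: PoissonLUT, rate_hz: float, neuron_id=("scalar", 0)):
    """Read one bit for one neuron at its current address and advance it."""
    consumer, idx = neuron_id
    ptr = lut.pointers(consumer, idx + 1)
    if idx >= ptr.size:
        ptr = np.concatenate([ptr, np.zeros(idx + 1 - ptr.size, dtype=np.int64)])
        lut.addresses[consumer] = ptr
    b = int(rate_to_bin(rate_hz))
    bit = int(lut.trains[b, ptr[idx] % lut.train_length])
    ptr[idx] = (ptr[idx] + 1) % lut.train_length
    return bit


def poisson_lut_sample_rates(lut: PoissonLUT, rates_hz, consumer) -> np.ndarray:
    """Vectorised per-layer read: one bit per neuron, all pointers advance."""
    rates_hz = np.asarray(rates_hz, dtype=np.float64)
    ptr = lut.pointers(consumer, rates_hz.size)
    bins = rate_to_bin(rates_hz)
    bits = lut.trains[bins, ptr % lut.train_length].astype(np.float64)
    lut.addresses[consumer] = (ptr + 1) % lut.train_length
    return bits
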