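"""Constrained multi-exponential fitting of stopped-flow FRET-ratio decays.

The analysis is two-stage.  An agonist-only control decay is fit to a single
exponential

    y = a * exp(-b x) + c

capturing the nonspecific equilibration of the crude membrane preparation
(half-life ln2/b).  The quench decay (agonist + nanobody) is then fit to a
triple exponential

    y = a * exp(-b x) + c * exp(-d x) + f * exp(-g x) + h

with a and b *fixed* to the control values, so only the two specific
components (amplitudes c, f; rates d, g) and the offset h are estimated.
Components are ordered fast-first (d > g); the slow-state proportion is
reported over the specific components only, f/(c+f).

Fitting is unweighted nonlinear least squares (lmfit/Levenberg-Marquardt)
with a multistart over log-spaced rate seeds; rates are bounded to
[1e-5, 1e2] s⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "DecayTrace",
    "ExponentialFit",
    "ReplicateSummary",
    "FitError",
    "fret_ratio",
    "detect_decay_start",
    "fit_nonspecific",
    "fit_constrained_triple",
    "summarize_replicates",
    "interconversion_bound",
]

RATE_MIN, RATE_MAX = 1e-5, 1e2
DEFAULT_RATE_SEEDS = (1.0, 0.1, 0.01)


class FitError(RuntimeError):
    """Non-convergent or structurally invalid fit."""


@dataclass
class DecayTrace:
    """A sampled fluorescence time series (one channel, or their ratio)."""

    time: np.ndarray            # s, strictly increasing, uniform 4 ms default
    signal: np.ndarray
    channel: str = "ratio"      # "475nm", "525nm" or "ratio"
    n_injections: int = 1
    start_offset: float = 0.0   # s between acquisition start and decay start
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.signal = np.asarray(self.signal, float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same shape")
        if self.time.size < 50:
            raise ValueError(f"trace needs >= 50 samples, got {self.time.size}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


def fret_ratio(trace525: DecayTrace, trace475: DecayTrace) -> DecayTrace:
    """Pointwise acceptor/donor ratio (525 nm / 475 nm).

    Grids must agree to within one sample spacing; the 475 nm channel is
    interpolated onto the 525 nm grid if they are merely offset.
    """
    dt = trace525.dt
    if trace525.time.size != trace475.time.size or np.max(
            np.abs(trace525.time - trace475.time)) > dt:
        raise ValueError("channel time grids differ by more than one sample")
    den = np.interp(trace525.time, trace475.time, trace475.signal)
    if np.any(den <= 0):
        raise ValueError("nonpositive 475 nm samples; cannot form FRET ratio")
    return DecayTrace(
        time=trace525.time.copy(),
        signal=trace525.signal / den,
        channel="ratio",
        n_injections=min(trace525.n_injections, trace475.n_injections),
        start_offset=trace525.start_offset,
        meta={"numerator": trace525.channel, "denominator": trace475.channel},
    )


def detect_decay_start(trace: DecayTrace, window: int = 25) -> float:
    """Automatic decay-start estimate: time of steepest smoothed descent.

    A manual ``start_offset`` on the trace should take precedence over this
    detector when the injection time is known.
    """
    kernel = np.ones(window) / window
    smooth = np.convolve(trace.signal, kernel, mode="same")
    d = np.gradient(smooth, trace.time)
    return float(trace.time[int(np.argmin(d))])


@dataclass
class ExponentialFit:
    """Fitted exponential-decay parameters with constraint provenance.

    ``amplitudes``/``rates`` are keyed by the conventional symbols
    (a/b nonspecific, c/d fast specific, f/g slow specific); ``fixed`` lists
    parameters held constant rather than estimated.  Flags:

    * ``"degenerate"`` — near-flat trace, rate not determined (uncertainty
      spans zero);
    * ``"unresolved"`` — the two specific rates collapsed onto each other
      (or one amplitude is consistent with zero): a single-component fit;
    * ``"negative_amplitude"`` — a specific amplitude refined negative.
    """

    amplitudes: dict
    rates: dict
    offset: float
    fixed: tuple = ()
    stderr: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    flags: frozenset = frozenset()
    n_points: int = 0

    def __post_init__(self):
        for k, v in self.rates.items():
            if v <= 0:
                raise FitError(f"rate {k} must be positive, got {v}")

    @property
    def lifetimes(self) -> dict:
        return {k: 1.0 / v for k, v in self.rates.items()}

    def value_at_zero(self) -> float:
        return sum(self.amplitudes.values()) + self.offset

    @property
    def half_life_nonspecific(self) -> float:
        return math.log(2.0) / self.rates["b"]

    @property
    def slow_fraction(self) -> float:
        """Slow-state proportion f/(c+f) over the specific components."""
        c, f = self.amplitudes["c"], self.amplitudes["f"]
        return f / (c + f)

    @property
    def fast_fraction(self) -> float:
        return 1.0 - self.slow_fraction

    @property
    def resolved(self) -> bool:
        return not ({"unresolved", "degenerate"} & self.flags)

    def to_dict(self) -> dict:
        return {
            "amplitudes": dict(self.amplitudes),
            "rates": dict(self.rates),
            "offset": self.offset,
            "fixed": list(self.fixed),
            "stderr": {k: v for k, v in self.stderr.items()},
            "residual_norm": self.residual_norm,
            "flags": sorted(self.flags),
            "n_points": self.n_points,
        }


def _shifted(trace: DecayTrace) -> tuple[np.ndarray, np.ndarray]:
    return trace.time - trace.time[0], trace.signal


def _run_minimize(residual, params):
    try:
        return minimize(residual, params, method="leastsq")
    except Exception as exc:  # pragma: no cover - lmfit internal failures
        raise FitError(f"least-squares minimisation failed: {exc}") from exc


def fit_nonspecific(trace: DecayTrace,
                    rate_seeds=DEFAULT_RATE_SEEDS) -> ExponentialFit:
    """Fit the agonist-only control to y = a exp(-b x) + c.

    Multistart over log-spaced rate seeds; the best residual wins.  A
    near-flat trace is returned flagged ``"degenerate"`` (amplitude ~ 0,
    offset = mean) rather than raising.
    """
    x, y = _shifted(trace)
    span = float(y[0] - y[-1])
    best = None
    for b0 in rate_seeds:
        p = Parameters()
        p.add("a", value=span if abs(span) > 0 else 1e-3)
        p.add("b", value=b0, min=RATE_MIN, max=RATE_MAX)
        p.add("c", value=float(y[-1]))

        def residual(pars):
            return pars["a"] * np.exp(-pars["b"] * x) + pars["c"] - y

        res = _run_minimize(residual, p)
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise FitError("nonspecific single-exponential fit did not converge")
    pv = best.params
    a, b, c = pv["a"].value, pv["b"].value, pv["c"].value
    stderr = {k: pv[k].stderr for k in ("a", "b", "c")}
    flags = set()
    scale = max(abs(y).max(), 1.0)
    b_err = stderr.get("b")
    if abs(a) < 1e-6 * scale or b_err is None or (b_err > abs(b)):
        flags.add("degenerate")
    return ExponentialFit(
        amplitudes={"a": a},
        rates={"b": b},
        offset=c,
        stderr=stderr,
        residual_norm=math.sqrt(best.chisqr),
        flags=frozenset(flags),
        n_points=x.size,
    )


def fit_constrained_triple(
    trace: DecayTrace,
    ns: ExponentialFit,
    rate_seeds=DEFAULT_RATE_SEEDS,
) -> ExponentialFit:
    """Fit the quench decay to a triple exponential with the nonspecific
    component fixed to the control fit.

    a and b are taken verbatim from ``ns`` and are not re-estimated.  Only
    c, d, f, g, h vary, over a 3×3 multistart grid of (d, g) seeds.
    Components are ordered so d > g.
    """
    x, y = _shifted(trace)
    a_fix, b_fix = ns.amplitudes["a"], ns.rates["b"]
    ns_part = a_fix * np.exp(-b_fix * x)
    span = float(y[0] - y[-1])
    best = None
    for d0 in rate_seeds:
        for g0 in rate_seeds:
            if d0 <= g0:
                continue
            p = Parameters()
            p.add("c", value=0.5 * span if span != 0 else 1e-3)
            p.add("d", value=d0, min=RATE_MIN, max=RATE_MAX)
            p.add("f", value=0.5 * span if span != 0 else 1e-3)
            p.add("g", value=g0, min=RATE_MIN, max=RATE_MAX)
            p.add("h", value=float(y[-1]))

            def residual(pars):
                return (ns_part
                        + pars["c"] * np.exp(-pars["d"] * x)
                        + pars["f"] * np.exp(-pars["g"] * x)
                        + pars["h"] - y)

            res = _run_minimize(residual, p)
            if best is None or res.chisqr < best.chisqr:
                best = res
    if best is None or not best.success:
        raise FitError("constrained triple-exponential fit did not converge")
    pv = best.params
    c, d = pv["c"].value, pv["d"].value
    f, g = pv["f"].value, pv["g"].value
    h = pv["h"].value
    err = {k: pv[k].stderr for k in ("c", "d", "f", "g", "h")}
    if d < g:  # order fast-first
        c, f = f, c
        d, g = g, d
        err = {"c": err["f"], "d": err["g"], "f": err["c"],
               "g": err["d"], "h": err["h"]}
    flags = set()
    d_err, g_err = err.get("d"), err.get("g")
    joint = math.hypot(d_err or 0.0, g_err or 0.0)
    if (d - g) <= joint or d / g < 1.05 or d_err is None or g_err is None:
        flags.add("unresolved")
    f_err = err.get("f")
    amp_scale = abs(c) + abs(f)
    if f_err is not None and abs(f) < 2.0 * f_err and abs(f) < 0.05 * max(amp_scale, 1e-12):
        flags.add("unresolved")  # second specific component consistent with 0
    if c < 0 or f < 0:
        flags.add("negative_amplitude")
    return ExponentialFit(
        amplitudes={"a": a_fix, "c": c, "f": f},
        rates={"b": b_fix, "d": d, "g": g},
        offset=h,
        fixed=("a", "b"),
        stderr=err,
        residual_norm=math.sqrt(best.chisqr),
        flags=frozenset(flags),
        n_points=x.size,
    )


@dataclass
class ReplicateSummary:
    """Mean ± SD of the specific rates and slow-state proportion across
    replicate membrane preparations (component-matched by rate ordering)."""

    n_used: int
    n_excluded: int
    rate_fast_mean: float
    rate_fast_sd: float
    rate_slow_mean: float
    rate_slow_sd: float
    slow_fraction_mean: float
    slow_fraction_sd: float

    @property
    def lifetime_fast(self) -> float:
        return 1.0 / self.rate_fast_mean

    @property
    def lifetime_slow(self) -> float:
        return 1.0 / self.rate_slow_mean

    @property
    def resolved(self) -> bool:
        return self.n_used >= 1


def summarize_replicates(fits) -> ReplicateSummary:
    """Average specific rates and slow proportion over replicate fits.

    Fits flagged unresolved or degenerate are excluded (and counted); each
    remaining fit contributes its fast (d) and slow (g) components after
    rate ordering, so swapped component labels cannot corrupt the average.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 replicate fits to summarize")
    used = [f for f in fits if f.resolved]
    excluded = len(fits) - len(used)
    if not used:
        raise FitError("all replicate fits are flagged unresolved/degenerate")
    fast = np.array([max(f.rates["d"], f.rates["g"]) for f in used])
    slow = np.array([min(f.rates["d"], f.rates["g"]) for f in used])
    # slow_fraction is defined on ordered components already
    frac = np.array([f.slow_fraction for f in used])
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return ReplicateSummary(
        n_used=len(used),
        n_excluded=excluded,
        rate_fast_mean=float(fast.mean()),
        rate_fast_sd=sd(fast),
        rate_slow_mean=float(slow.mean()),
        rate_slow_sd=sd(slow),
        slow_fraction_mean=float(frac.mean()),
        slow_fraction_sd=sd(frac),
    )


def _round_1sf(x: float) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def interconversion_bound(summary) -> tuple[float, float]:
    """Upper bound on the G-bound interconversion rate from the quench data.

    Two distinct lifetimes can only be resolved if interconversion is no
    faster than the reciprocal of the longer lifetime; e.g. a 150 s slow
    lifetime bounds the rate at 1/150 ≈ 0.007 s⁻¹.

    Accepts a :class:`ReplicateSummary` or the long lifetime in seconds.
    Returns ``(full_precision, display)`` where the display value is rounded
    to one significant figure.
    """
    if isinstance(summary, ReplicateSummary):
        if not summary.resolved:
            raise FitError("cannot bound interconversion from an unresolved summary")
        lifetime = summary.lifetime_slow
    else:
        lifetime = float(summary)
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    bound = 1.0 / lifetime
    return bound, _round_1sf(bound)
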