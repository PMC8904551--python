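"""Synthetic stopped-flow traces and pulldown observations.

The generator emulates the acquisition statistics of the stopped-flow FRET
quench assay: two emission channels (475 nm donor, 525 nm acceptor) sampled
every 4 ms for 115 s, each injection carrying independent additive Gaussian
counting noise, with at least 5 injections averaged per decay before the
ratio is formed.  The control (agonist-only) ratio follows a single
exponential with a 15 s half-life; the quench ratio adds two specific decay
components with off-rates 0.3 s⁻¹ and 0.006 s⁻¹, the slow component
carrying 75% of the specific amplitude.  Replicate "membrane preparations"
jitter the true parameters log-normally.

All noise parameters are synthetic conventions — the real instrument's
noise statistics are not modelled (no photophysics, bleaching or
inner-filter effects).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy.stats import truncnorm

from .parameters import LN2
from .stopped_flow import DecayTrace, fret_ratio

__all__ = [
    "GeneratorSpec",
    "ResolvabilityWarning",
    "generate_quench_pair",
    "generate_membrane_set",
    "generate_pulldown_observations",
]


class ResolvabilityWarning(UserWarning):
    """The acquisition window under-constrains the slowest component."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameters and acquisition settings for one decay pair.

    The control ratio is ``baseline + ns_amplitude * exp(-k_ns t)``; the
    quench ratio shares the identical nonspecific component and adds the two
    specific components, starting from the same t=0 ratio (its offset is
    ``baseline - specific_amplitude``).
    """

    k_fast: float = 0.3               # s⁻¹, weak-state off-rate
    k_slow: float = 0.006             # s⁻¹, strong-state off-rate
    slow_fraction: float = 0.75       # share of specific amplitude, slow comp.
    specific_amplitude: float = 0.3   # total specific ratio amplitude
    k_ns: float = LN2 / 15.0          # s⁻¹, nonspecific decay (t1/2 = 15 s)
    ns_amplitude: float = 0.2
    baseline: float = 1.0             # control ratio offset
    dt: float = 0.004                 # s, sampling interval
    duration: float = 115.0           # s
    n_injections: int = 5
    channel_base: float = 1000.0      # counts, 475 nm level
    channel_noise_sd: float = 2.0     # counts, per sample per injection
    jitter_rel_sd: float = 0.05       # inter-replicate log-normal rel. SD
    seed: int = 0

    def __post_init__(self):
        if self.channel_noise_sd < 0 or self.jitter_rel_sd < 0:
            raise ValueError("noise SD and jitter must be nonnegative")
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise ValueError("slow_fraction must be in [0, 1]")
        if self.n_injections < 1:
            raise ValueError("need at least one injection")
        if min(self.k_fast, self.k_slow, self.k_ns) <= 0:
            raise ValueError("rates must be positive")

    @property
    def time(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt

    # analytic truth curves ------------------------------------------------

    def control_signal(self, t: np.ndarray) -> np.ndarray:
        return self.baseline + self.ns_amplitude * np.exp(-self.k_ns * t)

    def quench_signal(self, t: np.ndarray) -> np.ndarray:
        A = self.specific_amplitude
        c = A * (1.0 - self.slow_fraction)
        f = A * self.slow_fraction
        return (self.baseline - A
                + self.ns_amplitude * np.exp(-self.k_ns * t)
                + c * np.exp(-self.k_fast * t)
                + f * np.exp(-self.k_slow * t))

    def truth(self) -> dict:
        return asdict(self)


def _channels(spec: GeneratorSpec, ratio: np.ndarray, rng, label: str):
    """Average noisy per-injection channels; the signal rides on 525 nm."""
    n = ratio.size
    acc475 = np.zeros(n)
    acc525 = np.zeros(n)
    for _ in range(spec.n_injections):
        acc475 += spec.channel_base + rng.normal(0.0, spec.channel_noise_sd, n)
        acc525 += spec.channel_base * ratio + rng.normal(0.0, spec.channel_noise_sd, n)
    t = spec.time
    tr475 = DecayTrace(t, acc475 / spec.n_injections, channel="475nm",
                       n_injections=spec.n_injections,
                       meta={"condition": label})
    tr525 = DecayTrace(t, acc525 / spec.n_injections, channel="525nm",
                       n_injections=spec.n_injections,
                       meta={"condition": label})
    return tr525, tr475


def generate_quench_pair(spec: GeneratorSpec, rng=None):
    """One (control, quench) FRET-ratio pair with embedded ground truth.

    Both traces are assembled from two noisy channels per injection, the
    injections averaged, and the ratio formed — mirroring the acquisition
    pipeline the fitter expects.  With zero noise the traces equal the
    analytic forms exactly.
    """
    longest = 1.0 / min(spec.k_slow, spec.k_ns)
    if spec.duration < 3.0 * longest:
        warnings.warn(
            f"duration {spec.duration} s is below 3x the longest lifetime "
            f"({longest:.0f} s): slow-component resolvability at risk",
            ResolvabilityWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    t = spec.time
    control = fret_ratio(*_channels(spec, spec.control_signal(t), rng, "control"))
    quench = fret_ratio(*_channels(spec, spec.quench_signal(t), rng, "quench"))
    control.meta["truth"] = spec.truth()
    quench.meta["truth"] = spec.truth()
    control.meta["condition"] = "control"
    quench.meta["condition"] = "quench"
    return control, quench


def generate_membrane_set(spec: GeneratorSpec, n_membranes: int):
    """Replicate (control, quench) pairs from jittered parameter sets.

    Per-replicate rates and specific amplitudes are multiplied by
    independent log-normal factors with relative SD ``spec.jitter_rel_sd``
    (the slow proportion then varies through the amplitude jitter); replicate
    seeds derive deterministically from the master seed.
    """
    if n_membranes < 1:
        raise ValueError("n_membranes must be >= 1")
    master = np.random.default_rng(spec.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_membranes)
    pairs = []
    for i in range(n_membranes):
        jit_rng = np.random.default_rng(child_seeds[i])
        s = spec.jitter_rel_sd
        if s > 0:
            lognorm = lambda: float(jit_rng.lognormal(mean=-0.5 * s * s, sigma=s))
            c = spec.specific_amplitude * (1 - spec.slow_fraction) * lognorm()
            f = spec.specific_amplitude * spec.slow_fraction * lognorm()
            rep = replace(
                spec,
                k_fast=spec.k_fast * lognorm(),
                k_slow=spec.k_slow * lognorm(),
                k_ns=spec.k_ns * lognorm(),
                specific_amplitude=c + f,
                slow_fraction=f / (c + f),
                seed=int(child_seeds[i]),
            )
        else:
            rep = replace(spec, seed=int(child_seeds[i]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ResolvabilityWarning)
            pairs.append(generate_quench_pair(rep, np.random.default_rng(child_seeds[i])))
    return pairs


def generate_pulldown_observations(fraction: float, noise_sd: float, n: int,
                                   seed: int = 0) -> np.ndarray:
    """Truncated-Gaussian fraction-bound samples in [0, 1].

    Emulates the affinity-sequestration readout (fraction bound = 1 -
    fraction of receptor left in the supernatant) around a model-predicted
    ternary-complex fraction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if noise_sd == 0:
        return np.full(n, fraction)
    a = (0.0 - fraction) / noise_sd
    b = (1.0 - fraction) / noise_sd
    rng = np.random.default_rng(seed)
    return truncnorm.rvs(a, b, loc=fraction, scale=noise_sd, size=n,
                         random_state=rng)
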