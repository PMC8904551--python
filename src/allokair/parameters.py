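"""Kinetic parameters for the two-state receptor / ternary complex model.

Units are µM for concentrations, s for time, s⁻¹ for first-order rates and
µM⁻¹s⁻¹ for bimolecular association rates, throughout the package.

The hormone-bound receptor interconverts slowly between a partially active
state (HR') and a fully active state (HR*).  Both states bind the G-protein
α5 peptide with the same association rate; the ~50-fold affinity difference
is carried entirely by the dissociation rates (k_off_weak for HR'G,
k_off_strong for HR*G).  Derived equilibrium constants:

    K_D      = k_off_weak  / k_on_G      (G affinity for HR')
    K_D/α    = k_off_strong / k_on_G     (G affinity for HR*)
    α        = k_off_weak / k_off_strong
    K_act    = k_act_f / k_act_r         (free receptor interconversion)
    K_actG   = α · K_act                 (G-bound, by thermodynamic closure)

An allokairic effector E competes with G for the receptor and catalyses the
HR' ⇌ HR* transition by a factor gamma_E on both rates (a pure catalyst,
leaving K_act unchanged).  A quenching nanobody N captures free receptor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from types import SimpleNamespace

import yaml

__all__ = [
    "KineticParameters",
    "DetailedBalanceWarning",
    "ParameterError",
    "paper_defaults",
    "load_parameters",
    "save_parameters",
]

LN2 = math.log(2.0)


class ParameterError(ValueError):
    """Inconsistent or invalid kinetic parameters."""


class DetailedBalanceWarning(UserWarning):
    """A rate override breaks thermodynamic cycle closure."""


#: expected unit string per field, written to / validated against config files
UNITS = {
    "k_on_G": "1/(uM*s)",
    "k_off_weak": "1/s",
    "k_off_strong": "1/s",
    "K_D": "uM",
    "k_act_f": "1/s",
    "k_act_r": "1/s",
    "k_actG_f": "1/s",
    "k_actG_r": "1/s",
    "K_E": "uM",
    "k_on_E": "1/(uM*s)",
    "k_off_E": "1/s",
    "gamma_E": "dimensionless",
    "gamma_E_f": "dimensionless",
    "gamma_E_r": "dimensionless",
    "k_on_N": "1/(uM*s)",
    "k_off_N": "1/s",
    "k_ns": "1/s",
    "C_eff": "uM",
    "R_total": "uM",
    "G_total": "uM",
    "E_total": "uM",
    "N_total": "uM",
}


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and total concentrations of the kinetic model.

    Optional fields left as ``None`` are resolved by convention (see
    :meth:`resolved`):

    * ``k_actG_f`` defaults to ``k_act_f``;
    * ``k_actG_r`` defaults to the detailed-balance closure
      ``k_actG_f / (alpha * K_act)``;
    * ``k_off_E`` defaults to ``K_E * k_on_E``;
    * ``gamma_E_f`` / ``gamma_E_r`` default to ``gamma_E`` (pure catalyst).

    ``K_D`` may be supplied redundantly; it is checked against
    ``k_off_weak / k_on_G`` and a mismatch is an error.
    """

    k_on_G: float = 0.01          # µM⁻¹s⁻¹, shared by both receptor states
    k_off_weak: float = 0.3       # s⁻¹, HR'G dissociation (measured)
    k_off_strong: float = 0.006   # s⁻¹, HR*G dissociation (measured)
    K_D: float | None = None      # µM, redundant consistency input
    k_act_f: float = 0.002        # s⁻¹, HR' -> HR* (below the 0.007 bound)
    k_act_r: float = 0.002        # s⁻¹, HR* -> HR'
    k_actG_f: float | None = None
    k_actG_r: float | None = None
    K_E: float = 100.0            # µM, effector affinity (weak regime)
    k_on_E: float = 0.01          # µM⁻¹s⁻¹
    k_off_E: float | None = None
    gamma_E: float = 100.0        # catalytic acceleration of interconversion
    gamma_E_f: float | None = None
    gamma_E_r: float | None = None
    k_on_N: float = 1.0           # µM⁻¹s⁻¹, nanobody capture of free receptor
    k_off_N: float = 0.0          # s⁻¹, irreversible capture by default
    k_ns: float = LN2 / 15.0      # s⁻¹, nonspecific decay (t1/2 = 15 s)
    C_eff: float = 10.0           # µM, tethered-peptide effective concentration
    R_total: float = 0.1          # µM
    G_total: float = 30.0         # µM
    E_total: float = 0.0          # µM
    N_total: float = 0.0          # µM

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise ParameterError(f"{f.name} must be nonnegative, got {v}")
        for name in ("k_on_G", "k_off_weak", "k_off_strong", "k_act_f",
                     "k_act_r", "k_on_E", "K_E"):
            if getattr(self, name) == 0:
                raise ParameterError(f"{name} must be positive")
        if self.k_off_strong > self.k_off_weak:
            raise ParameterError(
                "alpha = k_off_weak/k_off_strong must be >= 1; got "
                f"k_off_weak={self.k_off_weak} < k_off_strong={self.k_off_strong}"
            )
        if self.K_D is not None:
            implied = self.k_off_weak / self.k_on_G
            if abs(self.K_D - implied) > 1e-9 * max(self.K_D, implied):
                raise ParameterError(
                    "inconsistent redundant parameters: K_D = "
                    f"{self.K_D} µM but k_off_weak/k_on_G = {implied} µM "
                    "(offending pair: K_D vs k_on_G/k_off_weak)"
                )
        r = self.resolved()
        # cycle HR' -> HR* -> HR*G -> HR'G -> HR' must close
        cycle = (r.K_act * (self.k_on_G / self.k_off_strong)
                 * (r.k_actG_r / r.k_actG_f)
                 * (self.k_off_weak / self.k_on_G))
        if abs(cycle - 1.0) > 1e-6:
            warnings.warn(
                "G-bound interconversion overrides break detailed balance "
                f"(cycle product {cycle:.4g} != 1)",
                DetailedBalanceWarning,
                stacklevel=2,
            )
        if r.gamma_E_f != r.gamma_E_r:
            warnings.warn(
                "asymmetric effector catalysis (gamma_E_f != gamma_E_r) "
                "breaks detailed balance on the effector-bound cycle",
                DetailedBalanceWarning,
                stacklevel=2,
            )
        elif self.gamma_E < 1 and self.gamma_E_f is None:
            warnings.warn(
                f"gamma_E = {self.gamma_E} < 1: effector decelerates "
                "interconversion (negative modulation)",
                UserWarning,
                stacklevel=2,
            )

    # -- derived quantities -------------------------------------------------

    @property
    def alpha(self) -> float:
        """Affinity-enhancement factor of the fully active state."""
        return self.k_off_weak / self.k_off_strong

    @property
    def K_D_value(self) -> float:
        """G dissociation constant for HR' (µM)."""
        return self.k_off_weak / self.k_on_G

    @property
    def K_D_over_alpha(self) -> float:
        """G dissociation constant for HR* (µM)."""
        return self.k_off_strong / self.k_on_G

    @property
    def K_act(self) -> float:
        return self.k_act_f / self.k_act_r

    def resolved(self) -> SimpleNamespace:
        """Return every rate with ``None`` fields resolved by convention."""
        k_actG_f = self.k_actG_f if self.k_actG_f is not None else self.k_act_f
        if self.k_actG_r is not None:
            k_actG_r = self.k_actG_r
        else:
            k_actG_r = k_actG_f / (self.alpha * self.K_act)
        k_off_E = self.k_off_E if self.k_off_E is not None else self.K_E * self.k_on_E
        gamma_E_f = self.gamma_E_f if self.gamma_E_f is not None else self.gamma_E
        gamma_E_r = self.gamma_E_r if self.gamma_E_r is not None else self.gamma_E
        return SimpleNamespace(
            k_actG_f=k_actG_f,
            k_actG_r=k_actG_r,
            K_actG=k_actG_f / k_actG_r,
            k_off_E=k_off_E,
            gamma_E_f=gamma_E_f,
            gamma_E_r=gamma_E_r,
            K_act=self.K_act,
            alpha=self.alpha,
            K_D=self.K_D_value,
        )

    # -- constructors / evolution ------------------------------------------

    def evolve(self, **changes) -> "KineticParameters":
        """Return a copy with the given primary fields replaced."""
        return replace(self, **changes)

    def with_affinities(self, K_D: float, K_D_over_alpha: float) -> "KineticParameters":
        """Set G affinities for HR' and HR* by adjusting off-rates.

        Keeps the shared association rate fixed — agonist efficacy tunes
        the HR' affinity through its dissociation rate.
        """
        return self.evolve(
            K_D=None,
            k_off_weak=K_D * self.k_on_G,
            k_off_strong=K_D_over_alpha * self.k_on_G,
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self, with_units: bool = True) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            out[f.name] = {"value": v, "unit": UNITS[f.name]} if with_units else v
        return out


def paper_defaults() -> KineticParameters:
    """The bundled default parameter set (see ``data/defaults.yaml``)."""
    import importlib.resources as resources

    with resources.files("allokair.data").joinpath("defaults.yaml").open() as fh:
        return _from_mapping(yaml.safe_load(fh))


def _from_mapping(mapping: dict) -> KineticParameters:
    kwargs = {}
    valid = {f.name for f in fields(KineticParameters)}
    for name, entry in mapping.items():
        if name not in valid:
            raise ParameterError(f"unknown parameter {name!r}; valid: {sorted(valid)}")
        if isinstance(entry, dict):
            unit = entry.get("unit")
            if unit is not None and unit != UNITS[name]:
                raise ParameterError(
                    f"{name}: expected unit {UNITS[name]!r}, got {unit!r}"
                )
            kwargs[name] = float(entry["value"])
        else:
            kwargs[name] = float(entry)
    return KineticParameters(**kwargs)


def load_parameters(path) -> KineticParameters:
    """Load a parameter set from a YAML (or JSON) file with unit annotations."""
    with open(path) as fh:
        return _from_mapping(yaml.safe_load(fh))


def save_parameters(params: KineticParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
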