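"""Mass-action reaction networks for the two-state receptor model.

Species names follow the field's convention: HR' (partially active,
hormone-bound receptor), HR* (fully active), G (free G-peptide), HR'G / HR*G
(ternary complexes), E / HR'E / HR*E (allokairic effector), N / HR'N / HR*N
(quenching nanobody).  Every reaction is elementary mass action with total
reactant order at most two.  Each species carries the set of molecular
components it contains (R, G, E, N), which drives conservation-group
bookkeeping and the mutual-exclusivity audit (no species carries both G and
E, or both G and N — effector and nanobody compete with G for the same
receptor surface).

In tethered-sensor mode the G-peptide has no free concentration: binding is
pseudo-first-order at the effective concentration C_eff set by the ER/K
linker, and no free-G species exists (the G component is then not a
conserved group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import KineticParameters

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "build_two_state_model",
    "build_extended_model",
    "build_quench_model",
    "check_conservation",
    "NetworkError",
]

COMPONENTS = ("R", "G", "E", "N")


class NetworkError(ValueError):
    """Structurally invalid network or species mismatch."""


@dataclass(frozen=True)
class Species:
    name: str
    components: frozenset

    def __post_init__(self):
        bad = set(self.components) - set(COMPONENTS)
        if bad:
            raise NetworkError(f"unknown components {bad} in species {self.name}")


@dataclass(frozen=True)
class Reaction:
    """Elementary reaction: reactants -> products with rate constant ``rate``."""

    name: str
    reactants: tuple  # ((species_name, stoich), ...)
    products: tuple
    rate: float

    def __post_init__(self):
        order = sum(s for _, s in self.reactants)
        if order > 2:
            raise NetworkError(
                f"reaction {self.name}: total reactant order {order} > 2"
            )
        if self.rate < 0:
            raise NetworkError(f"reaction {self.name}: negative rate")


def _sp(name: str) -> Species:
    comps = set()
    if "R" in name:
        comps.add("R")
    # G/E/N appear at most once in a name and only as complex partners
    for c in "GEN":
        if c in name.replace("R", ""):
            comps.add(c)
    return Species(name, frozenset(comps))


@dataclass
class ReactionNetwork:
    species: list
    reactions: list
    params: KineticParameters
    tethered: bool = False
    name: str = "network"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate species names")
        self._index = {n: i for i, n in enumerate(names)}
        for r in self.reactions:
            for n, _ in r.reactants + r.products:
                if n not in self._index:
                    raise NetworkError(f"reaction {r.name} references unknown species {n}")

    # -- structure ----------------------------------------------------------

    @property
    def species_names(self) -> list:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self._index[name]

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, species × reactions."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for n, s in r.reactants:
                S[self._index[n], j] -= s
            for n, s in r.products:
                S[self._index[n], j] += s
        return S

    def conservation_groups(self) -> dict:
        """Component -> per-species count vector, for components conserved
        by every reaction (checked symbolically against the stoichiometry)."""
        S = self.stoichiometry_matrix()
        groups = {}
        for comp in COMPONENTS:
            w = np.array([1.0 if comp in s.components else 0.0 for s in self.species])
            if w.any() and np.all(np.abs(w @ S) < 1e-12):
                groups[comp] = w
        return groups

    def audit_mutual_exclusivity(self) -> None:
        """G and E, and G and N, never coexist within one species."""
        for s in self.species:
            if "G" in s.components and ("E" in s.components or "N" in s.components):
                raise NetworkError(f"species {s.name} combines G with E or N")

    # -- dynamics -----------------------------------------------------------

    def rate_arrays(self):
        """Precomputed (reactant index/stoich lists, rates, S) for the RHS."""
        S = self.stoichiometry_matrix()
        terms = []
        for r in self.reactions:
            idx = []
            for n, s in r.reactants:
                idx.extend([self._index[n]] * s)
            terms.append(tuple(idx))
        rates = np.array([r.rate for r in self.reactions])
        return terms, rates, S

    def rhs(self):
        """Return f(t, c) and its analytic Jacobian for the mass-action ODEs."""
        terms, rates, S = self.rate_arrays()
        n_sp = len(self.species)

        def f(t, c):
            flux = rates.copy()
            for j, idx in enumerate(terms):
                for i in idx:
                    flux[j] *= c[i]
            return S @ flux

        def jac(t, c):
            dflux = np.zeros((len(terms), n_sp))
            for j, idx in enumerate(terms):
                if len(idx) == 1:
                    dflux[j, idx[0]] = rates[j]
                elif len(idx) == 2:
                    a, b = idx
                    if a == b:
                        dflux[j, a] = 2.0 * rates[j] * c[a]
                    else:
                        dflux[j, a] = rates[j] * c[b]
                        dflux[j, b] = rates[j] * c[a]
            return S @ dflux

        return f, jac

    def default_initial(self) -> dict:
        """Totals-consistent start: all receptor as HR', all partners free."""
        p = self.params
        init = {n: 0.0 for n in self.species_names}
        init["HR'"] = p.R_total
        if "G" in init:
            init["G"] = p.G_total
        if "E" in init:
            init["E"] = p.E_total
        if "N" in init:
            init["N"] = p.N_total
        return init

    def initial_vector(self, initial=None) -> np.ndarray:
        init = self.default_initial() if initial is None else dict(initial)
        extra = set(init) - set(self.species_names)
        if extra:
            raise NetworkError(f"unknown species in initial condition: {sorted(extra)}")
        c0 = np.array([init.get(n, 0.0) for n in self.species_names], float)
        if (c0 < 0).any():
            raise ValueError("negative initial concentrations")
        return c0


# -- builders ---------------------------------------------------------------


def _base_species(tethered: bool):
    names = ["HR'", "HR*", "HR'G", "HR*G"]
    if not tethered:
        names.insert(2, "G")
    return [_sp(n) for n in names]


def _base_reactions(params: KineticParameters, tethered: bool):
    r = params.resolved()
    p = params
    if tethered:
        bind_w = Reaction("G_bind_weak", (("HR'", 1),), (("HR'G", 1),),
                          p.k_on_G * p.C_eff)
        bind_s = Reaction("G_bind_strong", (("HR*", 1),), (("HR*G", 1),),
                          p.k_on_G * p.C_eff)
    else:
        bind_w = Reaction("G_bind_weak", (("HR'", 1), ("G", 1)), (("HR'G", 1),),
                          p.k_on_G)
        bind_s = Reaction("G_bind_strong", (("HR*", 1), ("G", 1)), (("HR*G", 1),),
                          p.k_on_G)
    unbind_w = Reaction("G_unbind_weak", (("HR'G", 1),),
                        (("HR'", 1),) if tethered else (("HR'", 1), ("G", 1)),
                        p.k_off_weak)
    unbind_s = Reaction("G_unbind_strong", (("HR*G", 1),),
                        (("HR*", 1),) if tethered else (("HR*", 1), ("G", 1)),
                        p.k_off_strong)
    return [
        Reaction("act_f", (("HR'", 1),), (("HR*", 1),), p.k_act_f),
        Reaction("act_r", (("HR*", 1),), (("HR'", 1),), p.k_act_r),
        bind_w, unbind_w, bind_s, unbind_s,
        Reaction("actG_f", (("HR'G", 1),), (("HR*G", 1),), r.k_actG_f),
        Reaction("actG_r", (("HR*G", 1),), (("HR'G", 1),), r.k_actG_r),
    ]


def build_two_state_model(params: KineticParameters, tethered: bool = False) -> ReactionNetwork:
    """Base model: HR' ⇌ HR*, each binding G, with cycle-closed interconversion.

    With ``tethered=True`` G binding is pseudo-first-order at C_eff (SPASM
    sensor geometry) and no free-G species exists.
    """
    return ReactionNetwork(
        species=_base_species(tethered),
        reactions=_base_reactions(params, tethered),
        params=params,
        tethered=tethered,
        name="two_state" + ("_tethered" if tethered else ""),
    )


def build_extended_model(params: KineticParameters, tethered: bool = False) -> ReactionNetwork:
    """Base model plus a competing allokairic effector E.

    E binds HR' and HR* with the same affinity K_E and accelerates the
    effector-bound interconversion by gamma_E on both rates.  E-bound
    receptor cannot bind G (mutually exclusive binding surfaces).
    """
    r = params.resolved()
    p = params
    species = _base_species(tethered) + [_sp(n) for n in ("E", "HR'E", "HR*E")]
    reactions = _base_reactions(params, tethered) + [
        Reaction("E_bind_weakstate", (("HR'", 1), ("E", 1)), (("HR'E", 1),), p.k_on_E),
        Reaction("E_unbind_weakstate", (("HR'E", 1),), (("HR'", 1), ("E", 1)), r.k_off_E),
        Reaction("E_bind_strongstate", (("HR*", 1), ("E", 1)), (("HR*E", 1),), p.k_on_E),
        Reaction("E_unbind_strongstate", (("HR*E", 1),), (("HR*", 1), ("E", 1)), r.k_off_E),
        Reaction("actE_f", (("HR'E", 1),), (("HR*E", 1),), r.gamma_E_f * p.k_act_f),
        Reaction("actE_r", (("HR*E", 1),), (("HR'E", 1),), r.gamma_E_r * p.k_act_r),
    ]
    return ReactionNetwork(species, reactions, params, tethered,
                           name="extended" + ("_tethered" if tethered else ""))


def build_quench_model(params: KineticParameters) -> ReactionNetwork:
    """Tethered-sensor model plus nanobody capture of free receptor.

    N binds HR' and HR* (not the G-bound states) with k_on_N; capture is
    irreversible when k_off_N = 0 (the default).
    """
    if params.N_total <= 0:
        raise ValueError("build_quench_model requires N_total > 0")
    p = params
    species = _base_species(tethered=True) + [_sp(n) for n in ("N", "HR'N", "HR*N")]
    reactions = _base_reactions(params, tethered=True) + [
        Reaction("N_capture_weakstate", (("HR'", 1), ("N", 1)), (("HR'N", 1),), p.k_on_N),
        Reaction("N_capture_strongstate", (("HR*", 1), ("N", 1)), (("HR*N", 1),), p.k_on_N),
    ]
    if p.k_off_N > 0:
        reactions += [
            Reaction("N_release_weakstate", (("HR'N", 1),), (("HR'", 1), ("N", 1)), p.k_off_N),
            Reaction("N_release_strongstate", (("HR*N", 1),), (("HR*", 1), ("N", 1)), p.k_off_N),
        ]
    return ReactionNetwork(species, reactions, params, tethered=True, name="quench")


def check_conservation(network: ReactionNetwork, trajectory) -> dict:
    """Max absolute drift of each conserved-component total over a trajectory.

    Returns ``{component: max_t |total(t) - total(0)|}`` in µM.
    """
    if trajectory.network.species_names != network.species_names:
        raise NetworkError("trajectory species do not match network")
    out = {}
    for comp, w in network.conservation_groups().items():
        totals = trajectory.concentrations @ w
        out[comp] = float(np.max(np.abs(totals - totals[0])))
    return out
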