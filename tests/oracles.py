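"""Independent algebraic oracles used to cross-check the ODE machinery.

These never call the package's integrator: equilibria are computed from
conservation totals plus mass-action equilibrium relations by root finding,
and relaxation kinetics from closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def equilibrium_base(params) -> dict:
    """Algebraic equilibrium of the two-state model (free G, detailed balance).

    Unknowns: free [HR'] = r and free [G] = g.  All other species follow
    from the equilibrium constants.
    """
    K_D = params.K_D_value
    K_act = params.K_act
    alpha = params.alpha
    R_tot, G_tot = params.R_total, params.G_total

    def species(r, g):
        return {
            "HR'": r,
            "HR*": K_act * r,
            "G": g,
            "HR'G": r * g / K_D,
            "HR*G": alpha * K_act * r * g / K_D,
        }

    def residual(x):
        r, g = np.exp(x)
        s = species(r, g)
        recep = s["HR'"] + s["HR*"] + s["HR'G"] + s["HR*G"]
        return [(recep - R_tot) / max(R_tot, 1e-12),
                (s["G"] + s["HR'G"] + s["HR*G"] - G_tot) / max(G_tot, 1e-12)]

    x0 = np.log([R_tot / 2 + 1e-12, G_tot / 2 + 1e-12])
    sol = least_squares(residual, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    assert sol.success and np.max(np.abs(sol.fun)) < 1e-9
    return species(*np.exp(sol.x))


def equilibrium_extended(params) -> dict:
    """Algebraic equilibrium of the extended model (equal-K_E effector,
    symmetric catalysis so the effector-bound interconversion keeps K_act)."""
    K_D = params.K_D_value
    K_E = params.K_E
    K_act = params.K_act
    alpha = params.alpha
    R_tot, G_tot, E_tot = params.R_total, params.G_total, params.E_total

    def species(r, g, e):
        return {
            "HR'": r,
            "HR*": K_act * r,
            "G": g,
            "HR'G": r * g / K_D,
            "HR*G": alpha * K_act * r * g / K_D,
            "E": e,
            "HR'E": r * e / K_E,
            "HR*E": K_act * r * e / K_E,
        }

    def residual(x):
        r, g, e = np.exp(x)
        s = species(r, g, e)
        recep = s["HR'"] + s["HR*"] + s["HR'G"] + s["HR*G"] + s["HR'E"] + s["HR*E"]
        return [
            (recep - R_tot) / max(R_tot, 1e-12),
            (s["G"] + s["HR'G"] + s["HR*G"] - G_tot) / max(G_tot, 1e-12),
            (s["E"] + s["HR'E"] + s["HR*E"] - E_tot) / max(E_tot, 1e-12),
        ]

    x0 = np.log([R_tot / 2 + 1e-12, G_tot / 2 + 1e-12, E_tot / 2 + 1e-12])
    sol = least_squares(residual, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    assert sol.success and np.max(np.abs(sol.fun)) < 1e-9
    return species(*np.exp(sol.x))


def equilibrium_tethered_base(params) -> dict:
    """Closed-form equilibrium of the tethered-sensor two-state model:
    per-receptor Boltzmann weights over the four states."""
    K_D = params.K_D_value
    K_act = params.K_act
    alpha = params.alpha
    w = np.array([1.0, K_act, params.C_eff / K_D, alpha * K_act * params.C_eff / K_D])
    w = w / w.sum() * params.R_total
    return dict(zip(["HR'", "HR*", "HR'G", "HR*G"], w))


def ternary_fraction_equilibrium(species: dict, R_total: float) -> float:
    return (species["HR'G"] + species["HR*G"]) / R_total


def pseudo_first_order_complex(t, A0, B_conc, k_on, k_off):
    """Closed-form [AB](t) for A + B ⇌ AB with B in large excess and
    AB(0) = 0: exponential relaxation at rate k_on*[B] + k_off."""
    k_obs = k_on * B_conc + k_off
    AB_eq = A0 * k_on * B_conc / k_obs
    return AB_eq * (1.0 - np.exp(-k_obs * t))
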