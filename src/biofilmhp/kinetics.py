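"""Pointwise kinetic rate laws shared by the tank and the biofilm.

Growth follows Monod kinetics on glucose; hydrogen peroxide kills live
biomass at a rate first order in both HP and live biomass (converting it to
dead biomass without mass loss); both live and dead biomass neutralize HP
(catalase activity survives cell death); detachment erodes the biofilm
surface at K_det*Lf^2.

All functions accept scalars or numpy arrays and are vectorized.  Negative
concentrations, which a stiff integrator may produce transiently, are
clamped to zero inside the rate evaluations only — the state itself is
never mutated.
"""

from __future__ import annotations

import numpy as np

from .parameters import DoseSchedule, ModelParameters


def influent_hp(schedule: DoseSchedule, t: float) -> float:
    """Influent HP concentration (g/m^3) at time ``t`` under ``schedule``."""
    return schedule.influent_hp(t)


def growth_rate(S_G, p: ModelParameters):
    """Monod specific growth rate mu_max*S/(K_M + S), 1/day.

    Raises ValueError for (strictly) negative scalar substrate input;
    array inputs are clamped at zero.
    """
    if np.isscalar(S_G) and S_G < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {S_G}")
    S = np.maximum(S_G, 0.0)
    return p.mu_max * S / (p.K_M + S)


def particulate_rates(X_L, X_D, S_G, S_H, p: ModelParameters):
    """Net volumetric rates (R_X_L, R_X_D) for live and dead biomass, g/m^3/day.

    Live biomass grows on glucose and is killed by HP; killing transfers
    biomass to the dead pool conservatively: R_X_L + R_X_D equals the Monod
    growth term alone.
    """
    X_L = np.maximum(X_L, 0.0)
    S_H = np.maximum(S_H, 0.0)
    growth = growth_rate(S_G, p) * X_L
    kill = p.k_dis * S_H * X_L
    return growth - kill, kill + 0.0 * X_D


def solute_rates(X_L, X_D, S_G, S_H, p: ModelParameters):
    """Net volumetric rates (R_S_G, R_S_H) for glucose and HP, g/m^3/day.

    Glucose is consumed by growth (scaled by the inverse yield); HP is
    neutralized by catalase in both live and dead biomass.
    """
    if p.Y_GL == 0:
        raise ValueError("Y_GL must be nonzero")
    X_L = np.maximum(X_L, 0.0)
    X_D = np.maximum(X_D, 0.0)
    S_H = np.maximum(S_H, 0.0)
    R_G = -(1.0 / p.Y_GL) * growth_rate(S_G, p) * X_L
    R_H = -p.k_B_L * S_H * X_L - p.k_B_D * S_H * X_D
    return R_G, R_H


def detachment_velocity(Lf: float, p: ModelParameters) -> float:
    """Surface erosion velocity K_det*Lf^2, m/day."""
    return p.K_det * Lf * Lf
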