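"""Model parameters and the hydrogen-peroxide dosing schedule.

All quantities use SI-with-days units throughout the package: lengths in m,
time in days, concentrations in g/m^3, diffusivities in m^2/day.  The
defaults describe a single-species biofilm (live and dead biomass) growing
on glucose in a continuous stirred-tank reactor, challenged with hydrogen
peroxide (HP) in the influent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class DoseSchedule:
    """Piecewise-constant influent HP concentration.

    The influent concentration is 0 before ``time1``, ``dose1`` on the
    closed interval [``time1``, ``time2``], and ``dose2`` after ``time2``.
    """

    time1: float = 2.0  # day
    time2: float = 6.0  # day
    dose1: float = 0.0  # g/m^3
    dose2: float = 0.0  # g/m^3

    def __post_init__(self) -> None:
        if self.time1 > self.time2:
            raise ValueError(f"time1 ({self.time1}) must be <= time2 ({self.time2})")
        if self.dose1 < 0 or self.dose2 < 0:
            raise ValueError("doses must be >= 0")

    def influent_hp(self, t: float) -> float:
        """Influent HP concentration (g/m^3) at time ``t`` (day)."""
        if t < self.time1:
            return 0.0
        if t <= self.time2:
            return self.dose1
        return self.dose2

    @property
    def switch_times(self) -> tuple[float, float]:
        """Times at which the influent concentration is discontinuous."""
        return (self.time1, self.time2)


# index convention used everywhere: particulates [live, dead], solutes
# [glucose, HP]
LIVE, DEAD = 0, 1
GLUCOSE, HP = 0, 1


@dataclass
class ModelParameters:
    """Standard parameter set for the tank + biofilm system.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate of live biomass, 1/day.
    K_M : float
        Monod half-saturation constant for glucose, g/m^3.
    Q, V, A : float
        Tank flow rate (m^3/day), tank volume (m^3) and biofilm surface
        area (m^2).
    k_dis : float
        Disinfection rate coefficient: first-order-in-HP killing of live
        biomass, per (g_H/m^3) per day.
    Y_GL : float
        Yield of live biomass on glucose, g_L/g_G.
    S_in_G : float
        Influent glucose concentration, g/m^3.
    k_B_L, k_B_D : float
        HP neutralization rate coefficients (catalase activity) of live and
        dead biomass.  Applied as R_H = -k_B_L*S_H*X_L - k_B_D*S_H*X_D,
        i.e. numerically per (g biomass/m^3) per day.
    rho_L, rho_D : float
        Densities of live and dead biomass, g/m^3.
    D_b_G, D_b_H : float
        In-biofilm diffusivities of glucose and HP, m^2/day.
    D_aq_G, D_aq_H : float
        Aqueous diffusivities (used across the mass-transfer boundary
        layer), m^2/day.
    L_L : float
        Boundary-layer thickness, m.
    K_det : float
        Detachment coefficient in v_det = K_det*Lf^2, 1/(m day).
    Lf0 : float
        Initial biofilm thickness, m.
    X_t0, S_t0 : list of float
        Initial tank particulate [live, dead] and solute [glucose, HP]
        concentrations, g/m^3.
    P_b0 : list of float
        Initial biofilm volume fractions [live, dead] (dimensionless).
    S_b0 : list of float
        Initial biofilm solute concentrations [glucose, HP], g/m^3.
    Nz : int
        Number of grid cells across the biofilm.
    t_final : float
        Default simulation horizon, days.
    """

    mu_max: float = 9.6
    K_M: float = 5.0
    Q: float = 1.0
    V: float = 0.1
    A: float = 1.0
    k_dis: float = 0.5
    Y_GL: float = 0.26
    S_in_G: float = 100.0
    k_B_L: float = 10.0
    k_B_D: float = 10.0
    rho_L: float = 2.5e5
    rho_D: float = 2.5e5
    D_b_G: float = 1.3e-5
    D_b_H: float = 6.52e-5
    D_aq_G: float = 5.2e-5
    D_aq_H: float = 1.09e-4
    L_L: float = 1.0e-5
    K_det: float = 1.0e4
    Lf0: float = 50e-6
    X_t0: list[float] = field(default_factory=lambda: [1.0, 0.0])
    S_t0: list[float] = field(default_factory=lambda: [100.0, 0.0])
    P_b0: list[float] = field(default_factory=lambda: [0.08, 0.0])
    S_b0: list[float] = field(default_factory=lambda: [0.0, 0.0])
    Nz: int = 50
    t_final: float = 100.0

    _NONNEG = (
        "mu_max", "K_M", "Q", "V", "A", "k_dis", "Y_GL", "S_in_G",
        "k_B_L", "k_B_D", "rho_L", "rho_D", "D_b_G", "D_b_H",
        "D_aq_G", "D_aq_H", "L_L", "K_det",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._NONNEG:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {getattr(self, name)}")
        if self.Nz < 2:
            raise ValueError(f"Nz must be >= 2, got {self.Nz}")
        if self.Lf0 <= 0:
            raise ValueError(f"Lf0 must be > 0, got {self.Lf0}")
        if len(self.X_t0) != 2 or len(self.S_t0) != 2 or len(self.P_b0) != 2 or len(self.S_b0) != 2:
            raise ValueError("X_t0, S_t0, P_b0, S_b0 must each have two entries [live/dead or glucose/HP]")
        if any(p < 0 for p in self.P_b0) or sum(self.P_b0) > 1 or sum(self.P_b0) <= 0:
            raise ValueError(f"initial volume fractions must be >= 0 with 0 < sum <= 1, got {self.P_b0}")
        if self.t_final <= 0:
            raise ValueError("t_final must be > 0")

    def replace(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
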