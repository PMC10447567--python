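"""Derived quantities: areal biomass, viability, log reductions, penetration.

Conventions
-----------
* "Areal" biomass integrates a particulate concentration over the biofilm
  depth (midpoint rule), g/m^2.
* "Percent live" is areal live biomass over areal total biomass; the
  "mean live fraction" averages the local live fraction uniformly over
  depth.  With equal live/dead densities both are volume-fraction based.
* Log reduction at steady state is referenced to the untreated steady
  state; log reduction after one day of dosing is referenced to the state
  at dose onset.  Both conventions are plain function arguments here.
* Penetration depth is measured downward from the biofilm surface to where
  a solute first falls below a threshold fraction (default 5%) of its
  surface value, interpolating linearly between cell centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kinetics
from .parameters import ModelParameters, LIVE, DEAD, GLUCOSE, HP
from .solver import SimulationResult, SystemState, ERADICATION_LF

DEFAULT_PENETRATION_THRESHOLD = 0.05


@dataclass
class SteadyStateMetrics:
    """Summary of a (near-)steady biofilm state."""

    Lf_ss: float  # m
    areal_live: float  # g/m^2
    areal_dead: float  # g/m^2
    percent_live: float  # % of areal biomass that is live
    mean_live_fraction: float  # % depth-average of local live fraction
    log_reduction_ss: float | None  # vs a supplied untreated reference
    penetration_depth_G: float  # m
    penetration_depth_H: float  # m
    S_t_ss: tuple[float, float]  # tank (glucose, HP), g/m^3
    eradicated: bool

    def to_dict(self) -> dict:
        d = {
            "Lf_ss_um": self.Lf_ss * 1e6,
            "areal_live_g_per_m2": self.areal_live,
            "areal_dead_g_per_m2": self.areal_dead,
            "percent_live": self.percent_live,
            "mean_live_fraction": self.mean_live_fraction,
            "penetration_depth_G_um": self.penetration_depth_G * 1e6,
            "penetration_depth_H_um": self.penetration_depth_H * 1e6,
            "S_t_G": self.S_t_ss[0],
            "S_t_H": self.S_t_ss[1],
            "eradicated": self.eradicated,
        }
        if self.log_reduction_ss is not None:
            d["log_reduction_ss"] = self.log_reduction_ss
        return d


def areal_biomass(state: SystemState, grid_Nz: int | None = None) -> tuple[float, float]:
    """Live and dead biomass per unit of colonized area, g/m^2."""
    Nz = state.X_b.shape[1]
    dz = state.Lf / Nz
    live = float(state.X_b[LIVE].sum() * dz)
    dead = float(state.X_b[DEAD].sum() * dz)
    return live, dead


def log_reduction(reference_live: float, treated_live: float) -> float:
    """log10(reference/treated); math.inf when the treated biofilm holds no
    viable biomass (eradication)."""
    if reference_live <= 0:
        raise ValueError("reference live biomass must be > 0")
    if treated_live < 0:
        raise ValueError("treated live biomass must be >= 0")
    if treated_live == 0:
        return math.inf
    return math.log10(reference_live / treated_live)


def viability_log_reduction(state: SystemState) -> float:
    """log10 of (total areal biomass / live areal biomass), i.e. -log10 of
    the viable fraction of the biofilm population.

    At dose onset the biofilm is all-live (viable fraction 1), so this is
    the natural "log reduction in viable cells" after an exposure window:
    it counts cells killed and retained in the film against those still
    alive.  Returns math.inf for a biofilm with no live biomass.
    """
    live, dead = areal_biomass(state)
    if live <= 0:
        return math.inf
    return math.log10((live + dead) / live)


def planktonic_log_reduction(S_H: float, duration: float, k_dis: float) -> float:
    """Closed-form log10 reduction of freely suspended cells held at a
    constant HP concentration: dX/dt = -k_dis*S_H*X."""
    if S_H < 0 or duration < 0 or k_dis < 0:
        raise ValueError("inputs must be >= 0")
    return k_dis * S_H * duration / math.log(10.0)


def penetration_depth(profile: np.ndarray, Lf: float,
                      threshold_fraction: float = DEFAULT_PENETRATION_THRESHOLD) -> float:
    """Depth below the surface where ``profile`` (cell centers, base to
    surface) first falls under threshold_fraction x surface concentration.

    Returns ``Lf`` (full penetration) if the profile never drops below the
    threshold.  Linear interpolation between cell centers; the topmost
    cell value stands in for the surface concentration.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    profile = np.asarray(profile, float)
    Nz = len(profile)
    z = (np.arange(Nz) + 0.5) * Lf / Nz  # cell centers, base to surface
    surface = profile[-1]
    if surface <= 0:
        return 0.0
    target = threshold_fraction * surface
    # walk downward from the surface
    for i in range(Nz - 1, 0, -1):
        upper, lower = profile[i], profile[i - 1]
        if lower < target <= upper:
            frac = (upper - target) / (upper - lower)
            z_cross = z[i] - frac * (z[i] - z[i - 1])
            return Lf - z_cross
    if profile[0] < target:  # below threshold already in the deepest cell
        return Lf - z[0]
    return Lf


def consumption_rate_profile(state: SystemState, p: ModelParameters) -> np.ndarray:
    """Per-cell volumetric glucose consumption rate, g/m^3/day (>= 0)."""
    R_G, _ = kinetics.solute_rates(state.X_b[LIVE], state.X_b[DEAD],
                                   state.S_b[GLUCOSE], state.S_b[HP], p)
    return -R_G


def mean_bulk_concentration(result: SimulationResult, solute: int,
                            t_start: float, t_end: float) -> float:
    """Time-averaged tank concentration of a solute over [t_start, t_end]
    (trapezoidal rule on the sampled series)."""
    if t_end <= t_start:
        raise ValueError("empty averaging window")
    t, S = result.t, result.S_t[:, solute]
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise ValueError("averaging window outside the simulated horizon")
    # include interpolated endpoints for an exact window
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inside], [t_end]])
    SS = np.concatenate([[np.interp(t_start, t, S)], S[inside], [np.interp(t_end, t, S)]])
    return float(np.trapezoid(SS, tt) / (t_end - t_start))


def steady_state_metrics(result: SimulationResult,
                         reference_areal_live: float | None = None,
                         threshold_fraction: float = DEFAULT_PENETRATION_THRESHOLD
                         ) -> SteadyStateMetrics:
    """Summarize the final state of a run."""
    state = result.final_state
    eradicated = result.eradicated or state.Lf < ERADICATION_LF
    live, dead = areal_biomass(state)
    if eradicated:
        live_eff, dead_eff = 0.0, 0.0
        percent_live = 0.0
        mean_live = 0.0
        pen_G = pen_H = 0.0
    else:
        live_eff, dead_eff = live, dead
        total = live + dead
        percent_live = 100.0 * live / total if total > 0 else 0.0
        X_L, X_D = state.X_b[LIVE], state.X_b[DEAD]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(X_L + X_D > 0, X_L / (X_L + X_D), 0.0)
        mean_live = 100.0 * float(frac.mean())
        pen_G = penetration_depth(state.S_b[GLUCOSE], state.Lf, threshold_fraction)
        pen_H = penetration_depth(state.S_b[HP], state.Lf, threshold_fraction)
    log_red = None
    if reference_areal_live is not None:
        log_red = log_reduction(reference_areal_live, live_eff)
    return SteadyStateMetrics(
        Lf_ss=0.0 if eradicated else float(state.Lf),
        areal_live=live_eff,
        areal_dead=dead_eff,
        percent_live=percent_live,
        mean_live_fraction=mean_live,
        log_reduction_ss=log_red,
        penetration_depth_G=pen_G,
        penetration_depth_H=pen_H,
        S_t_ss=(float(state.S_t[GLUCOSE]), float(state.S_t[HP])),
        eradicated=eradicated,
    )
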