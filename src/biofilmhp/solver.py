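"""Method-of-lines discretization and stiff time integration.

The coupled system consists of well-mixed tank balances for particulates
(live/dead biomass) and solutes (glucose/HP), reaction–advection equations
for particulates and reaction–diffusion equations for solutes on the
one-dimensional biofilm domain, and an ODE for the biofilm thickness Lf
driven by the growth velocity at the surface minus detachment.

The moving domain is mapped to the fixed normalized coordinate
zeta = z/Lf.  Particulate transport uses a conservative first-order upwind
scheme on the relative face velocity w = v - zeta*dLf/dt plus the domain
dilation term -(dLf/dt / Lf) * X; solute diffusion uses central second
differences with a zero-flux base and a Robin (boundary-layer flux
matching) closure at the surface.  Integration uses scipy's BDF with
integrator stops forced at the dosing discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import kinetics
from .grid import BiofilmGrid
from .parameters import ModelParameters, DoseSchedule, LIVE, DEAD, GLUCOSE, HP

# numerical guards (m): LF_FLOOR keeps 1/Lf finite; ERADICATION_LF is the
# thickness below which a declining biofilm is declared eradicated;
# LF_STOP_EVENT terminates the integration well before the floor is reached.
LF_FLOOR = 1e-8
ERADICATION_LF = 1e-6
LF_STOP_EVENT = 2e-7

RTOL = 1e-6
ATOL = 1e-8

# steady state: relative drift of Lf and areal live biomass over the final
# 10% of the horizon below this value
STEADY_REL_TOL = 1e-3
T_FINAL_CAP = 2000.0


@dataclass
class SystemState:
    """Snapshot of the full system at one instant."""

    t: float
    X_t: np.ndarray  # (2,) tank particulates [live, dead], g/m^3
    S_t: np.ndarray  # (2,) tank solutes [glucose, HP], g/m^3
    X_b: np.ndarray  # (2, Nz) biofilm particulates, g/m^3
    S_b: np.ndarray  # (2, Nz) biofilm solutes, g/m^3
    Lf: float  # biofilm thickness, m


def volume_fractions(state: SystemState, p: ModelParameters) -> np.ndarray:
    """Per-cell particulate volume fractions P_b[j, i] = X_b[j, i]/rho_j."""
    rho = np.array([p.rho_L, p.rho_D])
    return state.X_b / rho[:, None]


@dataclass
class SimulationResult:
    """Sampled trajectory of the coupled tank–biofilm system."""

    t: np.ndarray  # (n,)
    X_t: np.ndarray  # (n, 2)
    S_t: np.ndarray  # (n, 2)
    X_b: np.ndarray  # (n, 2, Nz)
    S_b: np.ndarray  # (n, 2, Nz)
    Lf: np.ndarray  # (n,)
    eradicated: bool
    diagnostics: dict
    params: ModelParameters
    schedule: DoseSchedule
    grid: BiofilmGrid

    def state_at_index(self, i: int) -> SystemState:
        return SystemState(
            t=float(self.t[i]), X_t=self.X_t[i].copy(), S_t=self.S_t[i].copy(),
            X_b=self.X_b[i].copy(), S_b=self.S_b[i].copy(), Lf=float(self.Lf[i]),
        )

    def state_at_time(self, t: float) -> SystemState:
        """State at the sample closest to ``t`` (samples are dense)."""
        i = int(np.argmin(np.abs(self.t - t)))
        return self.state_at_index(i)

    @property
    def final_state(self) -> SystemState:
        return self.state_at_index(len(self.t) - 1)


# ----------------------------------------------------------------------
# state packing

def _pack(X_t, S_t, X_b, S_b, Lf) -> np.ndarray:
    return np.concatenate([X_t, S_t, X_b.ravel(), S_b.ravel(), [Lf]])


def _unpack(y: np.ndarray, Nz: int):
    X_t = y[0:2]
    S_t = y[2:4]
    X_b = y[4:4 + 2 * Nz].reshape(2, Nz)
    S_b = y[4 + 2 * Nz:4 + 4 * Nz].reshape(2, Nz)
    Lf = y[-1]
    return X_t, S_t, X_b, S_b, Lf


def initial_state_vector(p: ModelParameters) -> np.ndarray:
    """Initial condition: uniform biofilm fields from the volume fractions."""
    rho = np.array([p.rho_L, p.rho_D])
    X_b0 = (np.asarray(p.P_b0) * rho)[:, None] * np.ones((2, p.Nz))
    S_b0 = np.asarray(p.S_b0, dtype=float)[:, None] * np.ones((2, p.Nz))
    return _pack(np.asarray(p.X_t0, float), np.asarray(p.S_t0, float), X_b0, S_b0, p.Lf0)


# ----------------------------------------------------------------------
# spatial operators

def growth_velocity(X_b, S_b, Lf, p: ModelParameters, grid: BiofilmGrid) -> np.ndarray:
    """Advective growth velocity at the Nz+1 cell faces, m/day.

    v(z) integrates the net volumetric production of particulate volume
    (sum over species of R_X/rho, divided by the local total volume
    fraction) from the base to each face, by the midpoint rule.
    """
    R_L, R_D = kinetics.particulate_rates(X_b[LIVE], X_b[DEAD], S_b[GLUCOSE], S_b[HP], p)
    return _velocity_from_rates(np.stack([R_L, R_D]), X_b, Lf, p, grid)


def _velocity_from_rates(R_X, X_b, Lf, p: ModelParameters, grid: BiofilmGrid) -> np.ndarray:
    rho = np.array([p.rho_L, p.rho_D])
    P_tot = (np.maximum(X_b, 0.0) / rho[:, None]).sum(axis=0)
    if np.any(P_tot <= 0):
        raise FloatingPointError("total particulate volume fraction vanished in a cell")
    integrand = (R_X / rho[:, None]).sum(axis=0) / P_tot  # 1/day per cell
    dz = Lf * grid.dzeta
    v = np.empty(grid.Nz + 1)
    v[0] = 0.0
    np.cumsum(integrand * dz, out=v[1:])
    return v


def particulate_advection(X_b, v_faces, dLf_dt, Lf, grid: BiofilmGrid) -> np.ndarray:
    """Transport term of the particulate equations on the moving grid, g/m^3/day.

    Conservative upwind divergence of the relative flux w*X with
    w = v - zeta*dLf/dt, plus the dilation term -(dLf/dt/Lf)*X.  The base
    face carries zero flux; at the surface material leaves by detachment
    only (w(surface) = v_det when the thickness equation is unclamped) and
    nothing advects in.
    """
    Nz = grid.Nz
    w = v_faces - grid.zeta_faces * dLf_dt
    flux = np.empty((2, Nz + 1))
    flux[:, 0] = 0.0
    wi = w[1:Nz]
    donor = np.where(wi >= 0.0, X_b[:, :-1], X_b[:, 1:])
    flux[:, 1:Nz] = wi * donor
    flux[:, Nz] = max(w[Nz], 0.0) * X_b[:, -1]  # outflow only
    dz = Lf * grid.dzeta
    return -(flux[:, 1:] - flux[:, :-1]) / dz - (dLf_dt / Lf) * X_b


def solute_diffusion(S_b, S_t, Lf, p: ModelParameters, grid: BiofilmGrid):
    """Diffusion term of the solute equations plus the tank exchange flux.

    Returns ``(term, J_dif, S_surface)`` where ``term`` (2, Nz) is the
    discrete D_b * d2S/dz2 (g/m^3/day), ``J_dif`` (2,) is the solute flux
    seen by the tank balance (g/m^2/day, negative when solute enters the
    biofilm), and ``S_surface`` (2,) is the concentration at the
    biofilm–liquid interface from matching the in-film flux to the
    boundary-layer flux.
    """
    if Lf <= 0:
        raise FloatingPointError("solute diffusion requires Lf > 0")
    Nz = grid.Nz
    D_b = np.array([p.D_b_G, p.D_b_H])
    D_aq = np.array([p.D_aq_G, p.D_aq_H])
    dz = Lf * grid.dzeta

    g = np.zeros((2, Nz + 1))  # diffusive flux D*dS/dz at faces, +z direction
    g[:, 1:Nz] = D_b[:, None] * (S_b[:, 1:] - S_b[:, :-1]) / dz
    # Robin closure at the surface: D_b*(S_s - S_top)/(dz/2) = D_aq*(S_t - S_s)/L_L
    a = D_b / (dz / 2.0)
    b = D_aq / p.L_L
    S_s = (a * S_b[:, -1] + b * S_t) / (a + b)
    q_top = b * (S_t - S_s)  # flux into the biofilm through the boundary layer
    g[:, Nz] = q_top
    term = (g[:, 1:] - g[:, :-1]) / dz
    J_dif = -q_top
    return term, J_dif, S_s


def _solute_grid_advection(S_b, S_s, dLf_dt, Lf, grid: BiofilmGrid) -> np.ndarray:
    """Grid-motion term (zeta*dLf/dt/Lf) * dS/dzeta from the moving-domain
    chain rule, upwinded on the characteristic direction."""
    if dLf_dt == 0.0:
        return np.zeros_like(S_b)
    Nz = grid.Nz
    dzeta = grid.dzeta
    dSdz = np.empty((2, Nz))
    if dLf_dt > 0.0:  # characteristics move toward the base; donor is above
        dSdz[:, :-1] = (S_b[:, 1:] - S_b[:, :-1]) / dzeta
        dSdz[:, -1] = (S_s - S_b[:, -1]) / (dzeta / 2.0)
    else:  # donor is below; zero gradient at the base
        dSdz[:, 1:] = (S_b[:, 1:] - S_b[:, :-1]) / dzeta
        dSdz[:, 0] = 0.0
    return (grid.zeta_centers * dLf_dt / Lf) * dSdz


# ----------------------------------------------------------------------
# right-hand side

def assemble_rhs(t: float, y: np.ndarray, p: ModelParameters,
                 schedule: DoseSchedule, grid: BiofilmGrid) -> np.ndarray:
    """Time derivative of the packed state vector."""
    Nz = grid.Nz
    X_t, S_t, X_b, S_b, Lf = _unpack(y, Nz)
    Lf_eff = max(Lf, LF_FLOOR)

    # pointwise rates
    R_Xt = np.array(kinetics.particulate_rates(X_t[LIVE], X_t[DEAD], S_t[GLUCOSE], S_t[HP], p))
    R_St = np.array(kinetics.solute_rates(X_t[LIVE], X_t[DEAD], S_t[GLUCOSE], S_t[HP], p))
    R_Xb = np.stack(kinetics.particulate_rates(X_b[LIVE], X_b[DEAD], S_b[GLUCOSE], S_b[HP], p))
    R_Sb = np.stack(kinetics.solute_rates(X_b[LIVE], X_b[DEAD], S_b[GLUCOSE], S_b[HP], p))

    v_faces = _velocity_from_rates(R_Xb, X_b, Lf_eff, p, grid)
    v_det = kinetics.detachment_velocity(Lf_eff, p)
    dLf = v_faces[-1] - v_det
    if Lf <= LF_FLOOR and dLf < 0.0:
        dLf = 0.0

    diff_term, J_dif, S_s = solute_diffusion(S_b, S_t, Lf_eff, p, grid)

    dX_b = particulate_advection(X_b, v_faces, dLf, Lf_eff, grid) + R_Xb
    dS_b = diff_term + _solute_grid_advection(S_b, S_s, dLf, Lf_eff, grid) + R_Sb

    J_det = v_det * np.maximum(X_b[:, -1], 0.0)
    S_in = np.array([p.S_in_G, schedule.influent_hp(t)])
    dX_t = -(p.Q / p.V) * X_t + J_det * (p.A / p.V) + R_Xt
    dS_t = (p.Q / p.V) * (S_in - S_t) + J_dif * (p.A / p.V) + R_St

    dy = _pack(dX_t, dS_t, dX_b, dS_b, dLf)
    if not np.all(np.isfinite(dy)):
        blocks = {"X_t": dX_t, "S_t": dS_t, "X_b": dX_b, "S_b": dS_b, "Lf": np.array([dLf])}
        bad = [name for name, v in blocks.items() if not np.all(np.isfinite(v))]
        raise FloatingPointError(f"non-finite derivative at t={t:.6g} in fields {bad}")
    return dy


# ----------------------------------------------------------------------
# time integration

def _segment_edges(t0: float, t1: float, schedule: DoseSchedule) -> list[float]:
    edges = [t0]
    for ts in schedule.switch_times:
        if t0 < ts < t1:
            edges.append(ts)
    edges.append(t1)
    return sorted(set(edges))


def _default_samples(t0: float, t1: float, n: int, schedule: DoseSchedule) -> np.ndarray:
    pts = np.linspace(t0, t1, n)
    extra = [ts for ts in schedule.switch_times if t0 < ts < t1]
    return np.unique(np.concatenate([pts, extra]))


def integrate(p: ModelParameters,
              schedule: DoseSchedule | None = None,
              t_final: float | None = None,
              sample_times: Sequence[float] | None = None,
              n_samples: int = 401,
              rtol: float = RTOL,
              atol: float = ATOL,
              _y0: np.ndarray | None = None,
              _t0: float = 0.0) -> SimulationResult:
    """Integrate the coupled system from the standard initial condition.

    The stiff BDF integrator is restarted at the dosing discontinuities
    (time1, time2) so the influent step changes are resolved exactly.  A
    terminal event stops the run when the biofilm thickness collapses
    below the eradication floor.
    """
    schedule = schedule if schedule is not None else DoseSchedule()
    t_final = float(t_final if t_final is not None else p.t_final)
    grid = BiofilmGrid(p.Nz)
    y0 = initial_state_vector(p) if _y0 is None else np.asarray(_y0, float)
    t0 = float(_t0)
    if sample_times is None:
        sample_times = _default_samples(t0, t_final, n_samples, schedule)
    sample_times = np.asarray(sample_times, float)

    def rhs(t, y):
        return assemble_rhs(t, y, p, schedule, grid)

    def collapse(t, y):
        return y[-1] - LF_STOP_EVENT
    collapse.terminal = True
    collapse.direction = -1

    ts_list, ys_list = [], []
    diagnostics = {"nfev": 0, "njev": 0, "nlu": 0, "segments": 0,
                   "rtol": rtol, "atol": atol, "success": True, "message": ""}
    eradicated = False
    edges = _segment_edges(t0, t_final, schedule)
    y = y0
    stopped = False
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = sample_times[(sample_times >= a) & (sample_times <= b)]
        if len(t_eval) == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(rhs, (a, b), y, method="BDF", t_eval=t_eval,
                        events=collapse, rtol=rtol, atol=atol)
        diagnostics["nfev"] += sol.nfev
        diagnostics["njev"] += sol.njev
        diagnostics["nlu"] += sol.nlu
        diagnostics["segments"] += 1
        if not sol.success and sol.status != 1:
            diagnostics["success"] = False
            diagnostics["message"] = sol.message
            ts_list.append(sol.t)
            ys_list.append(sol.y)
            stopped = True
            break
        ts_list.append(sol.t)
        ys_list.append(sol.y)
        y = sol.y[:, -1]
        if sol.status == 1:  # thickness collapse event
            eradicated = True
            stopped = True
            if sol.t_events[0].size:
                ts_list.append(sol.t_events[0])
                ys_list.append(sol.y_events[0].T)
            break

    t_all = np.concatenate(ts_list)
    y_all = np.concatenate(ys_list, axis=1)
    # drop duplicate segment-boundary samples
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, y_all = t_all[keep], y_all[:, keep]

    Nz = grid.Nz
    n = len(t_all)
    result = SimulationResult(
        t=t_all,
        X_t=y_all[0:2].T.copy(),
        S_t=y_all[2:4].T.copy(),
        X_b=y_all[4:4 + 2 * Nz].T.reshape(n, 2, Nz).copy(),
        S_b=y_all[4 + 2 * Nz:4 + 4 * Nz].T.reshape(n, 2, Nz).copy(),
        Lf=y_all[-1].copy(),
        eradicated=eradicated,
        diagnostics=diagnostics,
        params=p,
        schedule=schedule,
        grid=grid,
    )
    if not eradicated:
        # declining below 1 um at the end of the horizon also counts
        if result.Lf[-1] < ERADICATION_LF:
            dy_end = assemble_rhs(t_all[-1], y_all[:, -1], p, schedule, grid)
            if dy_end[-1] <= 0:
                result.eradicated = True
    return result


def _areal_live(res: SimulationResult, i: int) -> float:
    dz = res.Lf[i] / res.grid.Nz
    return float(res.X_b[i, LIVE].sum() * dz)


def is_steady(res: SimulationResult, window_fraction: float = 0.1,
              rel_tol: float = STEADY_REL_TOL) -> bool:
    """True when Lf and areal live biomass drift by < rel_tol over the
    final ``window_fraction`` of the simulated horizon."""
    t = res.t
    mask = t >= t[-1] - window_fraction * (t[-1] - t[0])
    if mask.sum() < 3:
        return False
    Lf_w = res.Lf[mask]
    idx = np.flatnonzero(mask)
    live_w = np.array([_areal_live(res, i) for i in idx])
    for series in (Lf_w, live_w):
        scale = max(abs(series).max(), 1e-30)
        if (series.max() - series.min()) / scale > rel_tol:
            return False
    return True


def _concat_results(first: SimulationResult, second: SimulationResult) -> SimulationResult:
    keep = second.t > first.t[-1]
    diagnostics = dict(first.diagnostics)
    for k in ("nfev", "njev", "nlu", "segments"):
        diagnostics[k] += second.diagnostics[k]
    diagnostics["success"] = first.diagnostics["success"] and second.diagnostics["success"]
    return SimulationResult(
        t=np.concatenate([first.t, second.t[keep]]),
        X_t=np.concatenate([first.X_t, second.X_t[keep]]),
        S_t=np.concatenate([first.S_t, second.S_t[keep]]),
        X_b=np.concatenate([first.X_b, second.X_b[keep]]),
        S_b=np.concatenate([first.S_b, second.S_b[keep]]),
        Lf=np.concatenate([first.Lf, second.Lf[keep]]),
        eradicated=second.eradicated,
        diagnostics=diagnostics,
        params=first.params,
        schedule=first.schedule,
        grid=first.grid,
    )


def integrate_to_steady_state(p: ModelParameters,
                              schedule: DoseSchedule | None = None,
                              t_cap: float = T_FINAL_CAP,
                              n_samples: int = 401,
                              **kw) -> SimulationResult:
    """Integrate until the steady-state criterion holds, doubling the
    horizon (resuming from the final state) up to ``t_cap`` days.

    Eradication is a normal terminal outcome, not a failure.
    """
    res = integrate(p, schedule, t_final=p.t_final, n_samples=n_samples, **kw)
    horizon = float(res.t[-1])
    while (not res.eradicated and not is_steady(res)
           and horizon < t_cap and res.diagnostics["success"]):
        new_horizon = min(2.0 * horizon, t_cap)
        Nz = p.Nz
        y_end = _pack(res.X_t[-1], res.S_t[-1], res.X_b[-1], res.S_b[-1], res.Lf[-1])
        ext = integrate(p, res.schedule, t_final=new_horizon, n_samples=n_samples,
                        _y0=y_end, _t0=horizon, **kw)
        res = _concat_results(res, ext)
        horizon = float(res.t[-1])
    return res
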