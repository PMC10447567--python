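"""Simulation cases A–G, parameter sweeps and threshold searches.

Cases
-----
A  no dosing (standard parameters)
B  continuous dosing, 500 g/m^3 HP from day 2
C  dosing on at day 2, off at day 6 (recovery)
D  dose sweep: continuous dosing at a range of HP concentrations
E  only dead-cell neutralization (k_B_L = 0), continuous dosing
F  only live-cell neutralization (k_B_D = 0), continuous dosing
G  influent-glucose sweep under continuous dosing

Continuous treatment sets dose2 = dose1 so the treatment never ends; the
on/off case C keeps the standard time2 = 6 d with dose2 = 0.  Every sweep
point and threshold candidate starts cold from the standard initial
condition and runs to the solver's steady-state criterion (horizon
escalation capped at 2000 days); eradication is a normal outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .metrics import SteadyStateMetrics, steady_state_metrics
from .parameters import DoseSchedule, ModelParameters
from .solver import SimulationResult, integrate_to_steady_state

STANDARD_DOSE = 500.0  # g/m^3, cases B/C/E/F/G
DOSE_ON_TIME = 2.0  # day

CASE_NAMES = ("A", "B", "C", "D", "E", "F", "G")

DOSE_RESOLUTION = 100.0  # g/m^3, bisection resolution on dose axes
GLUCOSE_RESOLUTION = 1.0  # g/m^3, bisection resolution on the glucose axis


@dataclass
class ScenarioSpec:
    """A named case plus its parameter/schedule modifications."""

    name: str
    param_overrides: dict = field(default_factory=dict)
    schedule: DoseSchedule = field(default_factory=DoseSchedule)
    sweep_axis: str | None = None
    t_final: float | None = None


@dataclass
class SweepResult:
    """Per-axis-value steady-state metrics for a one-parameter sweep."""

    axis: str
    values: np.ndarray
    metrics: list[SteadyStateMetrics]
    failures: dict = field(default_factory=dict)  # axis value -> error message

    def thickness_um(self) -> np.ndarray:
        return np.array([m.Lf_ss * 1e6 for m in self.metrics])

    def percent_live(self) -> np.ndarray:
        return np.array([m.percent_live for m in self.metrics])

    def eradicated(self) -> np.ndarray:
        return np.array([m.eradicated for m in self.metrics])


def continuous_schedule(dose: float, t_on: float = DOSE_ON_TIME) -> DoseSchedule:
    """Continuous dosing at ``dose`` g/m^3 beginning at ``t_on`` days."""
    return DoseSchedule(time1=t_on, time2=t_on, dose1=dose, dose2=dose)


def scenario_spec(name: str, dose: float | None = None,
                  S_in_G: float | None = None) -> ScenarioSpec:
    """Build the ScenarioSpec for one of the cases A–G."""
    name = name.upper()
    if name not in CASE_NAMES:
        raise ValueError(f"unknown case {name!r}; expected one of {CASE_NAMES}")
    if name == "A":
        return ScenarioSpec("A", schedule=DoseSchedule())
    if name == "B":
        return ScenarioSpec("B", schedule=continuous_schedule(STANDARD_DOSE))
    if name == "C":
        return ScenarioSpec("C", schedule=DoseSchedule(time1=2.0, time2=6.0,
                                                       dose1=STANDARD_DOSE, dose2=0.0))
    if name == "D":
        if dose is None:
            raise ValueError("case D requires a dose value")
        return ScenarioSpec("D", schedule=continuous_schedule(dose), sweep_axis="dose1")
    if name == "E":
        return ScenarioSpec("E", param_overrides={"k_B_L": 0.0},
                            schedule=continuous_schedule(dose if dose is not None else STANDARD_DOSE))
    if name == "F":
        return ScenarioSpec("F", param_overrides={"k_B_D": 0.0},
                            schedule=continuous_schedule(dose if dose is not None else STANDARD_DOSE))
    # G
    if S_in_G is None:
        raise ValueError("case G requires an influent glucose value")
    return ScenarioSpec("G", param_overrides={"S_in_G": S_in_G},
                        schedule=continuous_schedule(dose if dose is not None else STANDARD_DOSE),
                        sweep_axis="S_in_G")


def run_case(name: str, p: ModelParameters | None = None,
             dose: float | None = None, S_in_G: float | None = None,
             t_final: float | None = None,
             reference_areal_live: float | None = None,
             ) -> tuple[SimulationResult, SteadyStateMetrics]:
    """Run one of the cases A–G to steady state and summarize it."""
    p = p if p is not None else ModelParameters()
    spec = scenario_spec(name, dose=dose, S_in_G=S_in_G)
    pc = p.replace(**spec.param_overrides) if spec.param_overrides else p
    if t_final is not None:
        pc = pc.replace(t_final=t_final)
        result = integrate_to_steady_state(pc, spec.schedule, t_cap=t_final)
    else:
        result = integrate_to_steady_state(pc, spec.schedule)
    return result, steady_state_metrics(result, reference_areal_live=reference_areal_live)


def _sweep(axis: str, values: Sequence[float],
           runner: Callable[[float], tuple[SimulationResult, SteadyStateMetrics]]
           ) -> SweepResult:
    metrics, failures, kept = [], {}, []
    for v in values:
        try:
            _, m = runner(float(v))
        except Exception as exc:  # solver failures recorded, not fatal
            failures[float(v)] = str(exc)
            continue
        kept.append(float(v))
        metrics.append(m)
    return SweepResult(axis=axis, values=np.array(kept), metrics=metrics, failures=failures)


def dose_sweep(doses: Sequence[float], p: ModelParameters | None = None,
               param_overrides: dict | None = None,
               reference_areal_live: float | None = None) -> SweepResult:
    """Steady-state response to continuous dosing at each dose (case D)."""
    p = p if p is not None else ModelParameters()
    if param_overrides:
        p = p.replace(**param_overrides)

    def runner(dose):
        result = integrate_to_steady_state(p, continuous_schedule(dose))
        return result, steady_state_metrics(result, reference_areal_live=reference_areal_live)

    return _sweep("dose1", doses, runner)


def glucose_sweep(S_in_values: Sequence[float], p: ModelParameters | None = None,
                  dose: float = STANDARD_DOSE) -> SweepResult:
    """Steady-state response to influent glucose under continuous dosing (case G)."""
    p = p if p is not None else ModelParameters()

    def runner(s):
        pc = p.replace(S_in_G=s)
        result = integrate_to_steady_state(pc, continuous_schedule(dose))
        return result, steady_state_metrics(result)

    return _sweep("S_in_G", S_in_values, runner)


def neutralization_sweep(k_values: Sequence[float], p: ModelParameters | None = None,
                         dose: float = STANDARD_DOSE) -> SweepResult:
    """Steady-state thickness versus the dead-biomass neutralization rate
    k_B_D under continuous dosing."""
    p = p if p is not None else ModelParameters()

    def runner(k):
        pc = p.replace(k_B_D=k)
        result = integrate_to_steady_state(pc, continuous_schedule(dose))
        return result, steady_state_metrics(result)

    return _sweep("k_B_D", k_values, runner)


def find_threshold(predicate: Callable[[float], bool], axis_lo: float,
                   axis_hi: float, resolution: float) -> float:
    """Bisect for the switching point of a monotone boolean predicate.

    ``predicate`` must differ between ``axis_lo`` and ``axis_hi``
    (bracketing); the search narrows the bracket to ``resolution`` and
    returns its midpoint.
    """
    lo, hi = float(axis_lo), float(axis_hi)
    if not hi > lo:
        raise ValueError("axis_hi must exceed axis_lo")
    p_lo, p_hi = predicate(lo), predicate(hi)
    if p_lo == p_hi:
        raise ValueError("predicate does not change across the bracket")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def eradication_dose_threshold(p: ModelParameters | None = None,
                               lo: float = 0.0, hi: float = 2e4,
                               resolution: float = DOSE_RESOLUTION,
                               param_overrides: dict | None = None) -> float:
    """Minimal continuous HP dose that eradicates the biofilm."""
    p = p if p is not None else ModelParameters()
    if param_overrides:
        p = p.replace(**param_overrides)

    def eradicated(dose):
        result = integrate_to_steady_state(p, continuous_schedule(dose))
        return steady_state_metrics(result).eradicated

    return find_threshold(eradicated, lo, hi, resolution)


def thickening_dose_threshold(p: ModelParameters | None = None,
                              baseline_Lf: float | None = None,
                              lo: float = 100.0, hi: float = 2e4,
                              resolution: float = DOSE_RESOLUTION) -> float:
    """Largest continuous dose for which the treated steady-state biofilm is
    still thicker than the untreated baseline."""
    p = p if p is not None else ModelParameters()
    if baseline_Lf is None:
        base = integrate_to_steady_state(p, DoseSchedule())
        baseline_Lf = float(base.Lf[-1])

    def thicker(dose):
        result = integrate_to_steady_state(p, continuous_schedule(dose))
        m = steady_state_metrics(result)
        return (not m.eradicated) and m.Lf_ss > baseline_Lf

    return find_threshold(thicker, lo, hi, resolution)


def glucose_elimination_threshold(p: ModelParameters | None = None,
                                  dose: float = STANDARD_DOSE,
                                  lo: float = 1.0, hi: float = 200.0,
                                  resolution: float = GLUCOSE_RESOLUTION) -> float:
    """Influent glucose concentration below which continuous dosing at
    ``dose`` eliminates the biofilm."""
    p = p if p is not None else ModelParameters()

    def eradicated(s):
        pc = p.replace(S_in_G=s)
        result = integrate_to_steady_state(pc, continuous_schedule(dose))
        return steady_state_metrics(result).eradicated

    return find_threshold(eradicated, lo, hi, resolution)
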