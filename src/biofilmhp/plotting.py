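"""Figure panels: thickness dynamics, dose response, depth profiles.

Each function draws on a provided axes (or creates one) and returns the
figure, so panels can be composed or saved individually.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .metrics import consumption_rate_profile  # noqa: E402
from .parameters import GLUCOSE, HP, LIVE, DEAD  # noqa: E402
from .scenarios import SweepResult  # noqa: E402
from .solver import SimulationResult  # noqa: E402


def _ax(ax):
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
    return ax.figure, ax


def plot_thickness_dynamics(results: dict[str, SimulationResult], ax=None):
    """Biofilm thickness versus time for several dosing regimes."""
    fig, ax = _ax(ax)
    styles = ["k-", "b--", "r:", "g-."]
    for (label, res), style in zip(results.items(), styles):
        ax.plot(res.t, res.Lf * 1e6, style, label=label)
    ax.set_xlabel("time (day)")
    ax.set_ylabel("biofilm thickness (µm)")
    ax.legend()
    return fig


def plot_dose_response(sweep: SweepResult, baseline_um: float | None = None, ax=None):
    """Steady-state thickness (and survival) versus continuous HP dose."""
    fig, ax = _ax(ax)
    ax.plot(sweep.values, sweep.thickness_um(), "o-", color="tab:blue")
    if baseline_um is not None:
        ax.axhline(baseline_um, color="0.5", ls="--", label="untreated")
        ax.legend()
    ax.set_xlabel("HP dose (g/m$^3$)")
    ax.set_ylabel("steady-state thickness (µm)")
    return fig


def plot_percent_live(sweep: SweepResult, ax=None):
    fig, ax = _ax(ax)
    ax.plot(sweep.values, sweep.percent_live(), "s-", color="tab:orange")
    ax.set_xlabel(sweep.axis)
    ax.set_ylabel("percent live cells (%)")
    ax.set_ylim(0, 105)
    return fig


def plot_solute_profiles(results: dict[str, SimulationResult], solute: int = GLUCOSE, ax=None):
    """Steady-state solute concentration versus depth for several runs."""
    fig, ax = _ax(ax)
    for label, res in results.items():
        state = res.final_state
        z = res.grid.z_centers(state.Lf) * 1e6
        ax.plot(z, state.S_b[solute], label=label)
    ax.set_xlabel("z, distance from substratum (µm)")
    ax.set_ylabel(("glucose" if solute == GLUCOSE else "H$_2$O$_2$") + " (g/m$^3$)")
    ax.legend()
    return fig


def plot_volume_fractions(results: dict[str, SimulationResult], ax=None):
    """Live (solid) and dead (dashed) volume fractions versus depth."""
    fig, ax = _ax(ax)
    colors = ["tab:red", "tab:blue", "tab:green"]
    for (label, res), c in zip(results.items(), colors):
        state = res.final_state
        p = res.params
        z = res.grid.z_centers(state.Lf) * 1e6
        ax.plot(z, state.X_b[LIVE] / p.rho_L, "-", color=c, label=f"{label} live")
        ax.plot(z, state.X_b[DEAD] / p.rho_D, "--", color=c, label=f"{label} dead")
    ax.set_xlabel("z (µm)")
    ax.set_ylabel("volume fraction (-)")
    ax.legend(fontsize=8)
    return fig


def plot_consumption_rate(results: dict[str, SimulationResult], ax=None):
    """Volumetric glucose consumption rate versus depth."""
    fig, ax = _ax(ax)
    for label, res in results.items():
        state = res.final_state
        z = res.grid.z_centers(state.Lf) * 1e6
        ax.plot(z, consumption_rate_profile(state, res.params), label=label)
    ax.set_xlabel("z (µm)")
    ax.set_ylabel("glucose consumption (g m$^{-3}$ d$^{-1}$)")
    ax.legend()
    return fig


def save_figure(fig, directory: str | Path, name: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / name
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
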