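"""Delimited-text serialization of runs, profiles and metric summaries.

All files are tab-separated with '#' comment headers documenting columns
and units, so they round-trip exactly through pandas.  Floats are printed
with 17 significant digits (bitwise round trip).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import SteadyStateMetrics, areal_biomass, consumption_rate_profile
from .parameters import LIVE, DEAD, GLUCOSE, HP
from .solver import SimulationResult

_FLOAT_FMT = "%.17g"


def _write(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT)
    path.write_text(buf.getvalue())


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def timeseries_frame(result: SimulationResult) -> pd.DataFrame:
    """Tank state, thickness and areal biomass at every sample time."""
    live = np.array([areal_biomass(result.state_at_index(i))[0] for i in range(len(result.t))])
    dead = np.array([areal_biomass(result.state_at_index(i))[1] for i in range(len(result.t))])
    return pd.DataFrame({
        "t_day": result.t,
        "Lf_m": result.Lf,
        "X_t_live": result.X_t[:, LIVE],
        "X_t_dead": result.X_t[:, DEAD],
        "S_t_glucose": result.S_t[:, GLUCOSE],
        "S_t_HP": result.S_t[:, HP],
        "areal_live_g_m2": live,
        "areal_dead_g_m2": dead,
    })


def write_timeseries(result: SimulationResult, directory: str | Path,
                     name: str = "timeseries.tsv") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / name
    _write(timeseries_frame(result), path, [
        "time series of the tank-biofilm system",
        "t_day [day], Lf_m [m], X_t_* [g/m^3], S_t_* [g/m^3], areal_* [g/m^2]",
    ])
    return path


def profiles_frame(result: SimulationResult, times: list[float]) -> pd.DataFrame:
    """Depth profiles (one row per grid cell) at the requested times."""
    p = result.params
    rows = []
    for t_req in times:
        state = result.state_at_time(t_req)
        cons = consumption_rate_profile(state, p)
        z = result.grid.z_centers(state.Lf)
        for i in range(result.grid.Nz):
            rows.append({
                "t_day": state.t,
                "z_m": z[i],
                "zeta": result.grid.zeta_centers[i],
                "X_b_live": state.X_b[LIVE, i],
                "X_b_dead": state.X_b[DEAD, i],
                "S_b_glucose": state.S_b[GLUCOSE, i],
                "S_b_HP": state.S_b[HP, i],
                "P_live": state.X_b[LIVE, i] / p.rho_L,
                "P_dead": state.X_b[DEAD, i] / p.rho_D,
                "glucose_consumption_g_m3_d": cons[i],
            })
    return pd.DataFrame(rows)


def write_profiles(result: SimulationResult, times: list[float],
                   directory: str | Path, name: str = "profiles.tsv") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / name
    _write(profiles_frame(result, times), path, [
        "depth profiles within the biofilm (z = 0 is the substratum)",
        "z_m [m], X_b_* [g/m^3], S_b_* [g/m^3], P_* volume fractions [-],",
        "glucose_consumption_g_m3_d [g/m^3/day]",
    ])
    return path


def write_metrics(metrics: SteadyStateMetrics | dict, directory: str | Path,
                  name: str = "metrics.tsv") -> Path:
    """Flat machine-readable key–value summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / name
    d = metrics.to_dict() if isinstance(metrics, SteadyStateMetrics) else dict(metrics)
    lines = ["# flat key-value metrics summary", "key\tvalue"]
    for k, v in d.items():
        if isinstance(v, bool):
            lines.append(f"{k}\t{str(v).lower()}")
        elif isinstance(v, float):
            lines.append(f"{k}\t{_FLOAT_FMT % v}")
        else:
            lines.append(f"{k}\t{v}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read any table written by this module."""
    return _read(Path(path))
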