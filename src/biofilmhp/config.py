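"""TOML run configuration: parameters, dose schedule, scenario selection.

Layout (all sections optional; defaults are the standard parameter set):

    [parameters]
    mu_max = 9.6
    S_in_G = 100.0

    [dose]
    time1 = 2.0
    time2 = 6.0
    dose1 = 500.0
    dose2 = 500.0

    [scenario]
    name = "B"            # A..G or "custom"
    t_final = 100.0
    sweep_axis = "dose1"  # optional: dose1 | S_in_G | k_B_D
    sweep_from = 0.0
    sweep_to = 20000.0
    sweep_points = 21

    [output]
    dir = "out"
    n_samples = 401
    rtol = 1e-6
    atol = 1e-8

Unknown keys anywhere are rejected (fail-fast), and invalid parameter
values surface as validation errors naming the offending field.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .parameters import DoseSchedule, ModelParameters

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_DOSE_FIELDS = {f.name for f in dataclasses.fields(DoseSchedule)}
_SCENARIO_FIELDS = {"name", "t_final", "sweep_axis", "sweep_from", "sweep_to",
                    "sweep_points", "dose", "S_in_G"}
_OUTPUT_FIELDS = {"dir", "n_samples", "rtol", "atol"}
_SECTIONS = {"parameters", "dose", "scenario", "output"}


@dataclass
class RunConfig:
    """Validated configuration for a run, sweep or threshold search."""

    params: ModelParameters = field(default_factory=ModelParameters)
    schedule: DoseSchedule = field(default_factory=DoseSchedule)
    scenario: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    overridden: dict = field(default_factory=dict)  # provenance: key -> value

    def effective_toml(self) -> str:
        """The full effective configuration as TOML text (provenance)."""
        lines = ["[parameters]"]
        for f in dataclasses.fields(ModelParameters):
            v = getattr(self.params, f.name)
            lines.append(f"{f.name} = {_toml_value(v)}")
        lines.append("")
        lines.append("[dose]")
        for name in ("time1", "time2", "dose1", "dose2"):
            lines.append(f"{name} = {_toml_value(getattr(self.schedule, name))}")
        for section, d in (("scenario", self.scenario), ("output", self.output)):
            if d:
                lines.append("")
                lines.append(f"[{section}]")
                for k, v in d.items():
                    lines.append(f"{k} = {_toml_value(v)}")
        return "\n".join(lines) + "\n"


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, int):
        return str(v)
    return repr(float(v))


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in [{section}]; "
            f"allowed: {sorted(allowed)}"
        )


def parse_config(text: str) -> RunConfig:
    """Parse TOML text into a validated RunConfig."""
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ValueError(f"config parse error: {exc}") from exc
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown section(s) {sorted(unknown)}; allowed: {sorted(_SECTIONS)}")

    p_over = dict(raw.get("parameters", {}))
    _check_keys("parameters", p_over, _PARAM_FIELDS)
    d_over = dict(raw.get("dose", {}))
    _check_keys("dose", d_over, _DOSE_FIELDS)
    scenario = dict(raw.get("scenario", {}))
    _check_keys("scenario", scenario, _SCENARIO_FIELDS)
    output = dict(raw.get("output", {}))
    _check_keys("output", output, _OUTPUT_FIELDS)

    try:
        params = ModelParameters(**p_over)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid [parameters]: {exc}") from exc
    try:
        schedule = DoseSchedule(**d_over)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid [dose]: {exc}") from exc

    overridden = {f"parameters.{k}": v for k, v in p_over.items()}
    overridden.update({f"dose.{k}": v for k, v in d_over.items()})
    return RunConfig(params=params, schedule=schedule, scenario=scenario,
                     output=output, overridden=overridden)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML configuration file."""
    path = Path(path)
    return parse_config(path.read_text())
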