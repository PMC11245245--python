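"""Run configuration: YAML parsing, validation and round-tripping.

A run config resolves to a complete, validated parameter set before any
simulation starts.  Unknown keys are rejected with messages naming the
offending key.  Schema (all sections optional unless noted)::

    preset: canine-default          # base parameter preset
    params: {G: 0.5, F: 0.02}       # field overrides on the preset
    input:                          # exactly one of:
      constant: 100.0               #   constant drive over t_span
      # meals: [{start: 60, duration: 60, amplitude: 100}]
      # ramp: 5.0                   #   (only with meals)
      # segments: [[0, 120, 100]]
    interventions:
      - {kind: diazinon, time: 60, inhibition: 1.0}
      - {kind: atropine, time: 59, block: 1.0}
      - {kind: damage, time: 100, severity: 0.5}
      - {kind: step, time: 10, target: k_cat, multiplier: 0.5}
    t_span: [0, 500]                # required
    solver: {rtol: 1.0e-8, atol: 1.0e-10, grid_dt: 1.0, method: LSODA}
    thresholds: {overflow_duration_min: 30, rest_tol: 1.0e-6, serum_gain: 1.0}
    output: {trajectory: traj.csv, summary: summary.json}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assessment import AssessmentThresholds
from .model import (
    ConfigurationError,
    InputSchedule,
    Intervention,
    ModelParameters,
)
from .presets import get_preset
from .scenarios import acinar_damage, atropine, diazinon, meal_schedule

__all__ = ["ConfigError", "RunConfig", "SolverOptions", "load_config", "save_config"]


class ConfigError(ConfigurationError):
    """Malformed or invalid run configuration."""


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_dt: float = 1.0
    method: str = "LSODA"


@dataclass(frozen=True)
class RunConfig:
    params: ModelParameters
    schedule: InputSchedule
    t_span: tuple[float, float]
    interventions: tuple[Intervention, ...] = ()
    solver: SolverOptions = SolverOptions()
    thresholds: AssessmentThresholds = AssessmentThresholds()
    preset: str | None = None
    trajectory_path: str | None = None
    summary_path: str | None = None


_PARAM_FIELDS = ("G", "F", "J", "k_cat", "N_max", "S_max", "tau_syn", "epsilon_h")
_TOP_KEYS = {
    "preset",
    "params",
    "input",
    "interventions",
    "t_span",
    "solver",
    "thresholds",
    "output",
}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in section {where!r}")


def _as_number(value, key: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"key {key!r} must be a number, got {value!r}")
    return float(value)


def _parse_params(raw: dict) -> tuple[ModelParameters, str | None]:
    preset = raw.get("preset")
    if preset is not None:
        if not isinstance(preset, str):
            raise ConfigError("key 'preset' must be a string")
        try:
            base = get_preset(preset)
        except KeyError as exc:
            raise ConfigError(str(exc)) from None
    else:
        base = ModelParameters()
    overrides = raw.get("params") or {}
    if not isinstance(overrides, dict):
        raise ConfigError("section 'params' must be a mapping")
    _check_keys(overrides, set(_PARAM_FIELDS), "params")
    clean = {k: _as_number(v, f"params.{k}") for k, v in overrides.items()}
    try:
        return base.replace(**clean), preset
    except ConfigurationError as exc:
        raise ConfigError(f"invalid parameter value: {exc}") from None


def _parse_input(raw, t_span: tuple[float, float]) -> InputSchedule:
    if raw is None:
        return InputSchedule.zero()
    if not isinstance(raw, dict):
        raise ConfigError("section 'input' must be a mapping")
    _check_keys(raw, {"constant", "meals", "ramp", "segments"}, "input")
    forms = [k for k in ("constant", "meals", "segments") if k in raw]
    if len(forms) != 1:
        raise ConfigError(
            "section 'input' requires exactly one of 'constant', 'meals', 'segments'"
        )
    if "ramp" in raw and forms != ["meals"]:
        raise ConfigError("key 'input.ramp' is only valid together with 'meals'")
    kind = forms[0]
    try:
        if kind == "constant":
            rate = _as_number(raw["constant"], "input.constant")
            return InputSchedule.constant(rate, t_span[0], t_span[1])
        if kind == "segments":
            segs = []
            for i, seg in enumerate(raw["segments"]):
                if len(seg) != 3:
                    raise ConfigError(
                        f"input.segments[{i}] must be [start, end, rate]"
                    )
                segs.append(tuple(_as_number(v, f"input.segments[{i}]") for v in seg))
            return InputSchedule(tuple(segs))
        meals = []
        for i, meal in enumerate(raw["meals"]):
            if not isinstance(meal, dict):
                raise ConfigError(f"input.meals[{i}] must be a mapping")
            _check_keys(meal, {"start", "duration", "amplitude"}, f"input.meals[{i}]")
            for k in ("start", "duration", "amplitude"):
                if k not in meal:
                    raise ConfigError(f"input.meals[{i}] is missing key {k!r}")
            meals.append(
                (
                    _as_number(meal["start"], "start"),
                    _as_number(meal["duration"], "duration"),
                    _as_number(meal["amplitude"], "amplitude"),
                )
            )
        ramp = _as_number(raw.get("ramp", 0.0), "input.ramp")
        return meal_schedule(meals, ramp=ramp)
    except ConfigError:
        raise
    except ConfigurationError as exc:
        raise ConfigError(f"invalid input schedule: {exc}") from None


_IV_KINDS = {
    "diazinon": ({"kind", "time", "inhibition"}, lambda d: diazinon(d["time"], d.get("inhibition", 1.0))),
    "atropine": ({"kind", "time", "block"}, lambda d: atropine(d["time"], d.get("block", 1.0))),
    "damage": ({"kind", "time", "severity"}, lambda d: acinar_damage(d["time"], d["severity"])),
    "step": (
        {"kind", "time", "target", "multiplier"},
        lambda d: Intervention(time=d["time"], target=d["target"], multiplier=d["multiplier"]),
    ),
}


def _parse_interventions(raw) -> tuple[Intervention, ...]:
    if raw is None:
        return ()
    if not isinstance(raw, list):
        raise ConfigError("section 'interventions' must be a list")
    out = []
    for i, entry in enumerate(raw):
        where = f"interventions[{i}]"
        if not isinstance(entry, dict):
            raise ConfigError(f"{where} must be a mapping")
        kind = entry.get("kind")
        if kind not in _IV_KINDS:
            raise ConfigError(
                f"unknown key value {kind!r} for '{where}.kind'; "
                f"expected one of {sorted(_IV_KINDS)}"
            )
        allowed, builder = _IV_KINDS[kind]
        _check_keys(entry, allowed, where)
        if "time" not in entry:
            raise ConfigError(f"{where} is missing key 'time'")
        try:
            out.append(builder(entry))
        except KeyError as exc:
            raise ConfigError(f"{where} is missing key {exc.args[0]!r}") from None
        except ConfigurationError as exc:
            raise ConfigError(f"invalid {where}: {exc}") from None
    return tuple(out)


def parse_config(raw: dict, *, source: str = "<config>") -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<top level>")
    if "t_span" not in raw:
        raise ConfigError("missing required key 't_span'")
    t_span_raw = raw["t_span"]
    if not (isinstance(t_span_raw, (list, tuple)) and len(t_span_raw) == 2):
        raise ConfigError("key 't_span' must be a [t0, t1] pair")
    t_span = (_as_number(t_span_raw[0], "t_span[0]"), _as_number(t_span_raw[1], "t_span[1]"))
    if not t_span[1] > t_span[0]:
        raise ConfigError("key 't_span' must satisfy t1 > t0")

    params, preset = _parse_params(raw)
    schedule = _parse_input(raw.get("input"), t_span)
    interventions = _parse_interventions(raw.get("interventions"))

    solver_raw = raw.get("solver") or {}
    _check_keys(solver_raw, {"rtol", "atol", "grid_dt", "method"}, "solver")
    solver_kwargs = {
        k: (_as_number(v, f"solver.{k}") if k != "method" else str(v))
        for k, v in solver_raw.items()
    }
    solver = SolverOptions(**solver_kwargs)
    if solver.rtol <= 0 or solver.atol <= 0 or solver.grid_dt <= 0:
        raise ConfigError("solver tolerances and grid_dt must be > 0")

    thr_raw = raw.get("thresholds") or {}
    _check_keys(thr_raw, {"overflow_duration_min", "rest_tol", "serum_gain"}, "thresholds")
    try:
        thresholds = AssessmentThresholds(
            **{k: _as_number(v, f"thresholds.{k}") for k, v in thr_raw.items()}
        )
    except ConfigurationError as exc:
        raise ConfigError(f"invalid thresholds: {exc}") from None

    out_raw = raw.get("output") or {}
    _check_keys(out_raw, {"trajectory", "summary"}, "output")

    return RunConfig(
        params=params,
        schedule=schedule,
        t_span=t_span,
        interventions=interventions,
        solver=solver,
        thresholds=thresholds,
        preset=preset,
        trajectory_path=out_raw.get("trajectory"),
        summary_path=out_raw.get("summary"),
    )


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {p}: {exc}") from None
    return parse_config(raw, source=str(p))


def config_to_dict(cfg: RunConfig) -> dict:
    """Serializable mapping that round-trips through parse_config."""
    d: dict = {"t_span": [cfg.t_span[0], cfg.t_span[1]]}
    if cfg.preset is not None:
        d["preset"] = cfg.preset
        base = get_preset(cfg.preset)
    else:
        base = ModelParameters()
    overrides = {
        k: getattr(cfg.params, k)
        for k in _PARAM_FIELDS
        if getattr(cfg.params, k) != getattr(base, k)
    }
    if overrides:
        d["params"] = overrides
    if cfg.schedule.segments:
        d["input"] = {"segments": [list(s) for s in cfg.schedule.segments]}
    if cfg.interventions:
        d["interventions"] = [
            {"kind": "step", "time": iv.time, "target": iv.target, "multiplier": iv.multiplier}
            for iv in cfg.interventions
        ]
    d["solver"] = {
        "rtol": cfg.solver.rtol,
        "atol": cfg.solver.atol,
        "grid_dt": cfg.solver.grid_dt,
        "method": cfg.solver.method,
    }
    d["thresholds"] = {
        "overflow_duration_min": cfg.thresholds.overflow_duration_min,
        "rest_tol": cfg.thresholds.rest_tol,
        "serum_gain": cfg.thresholds.serum_gain,
    }
    output = {}
    if cfg.trajectory_path:
        output["trajectory"] = cfg.trajectory_path
    if cfg.summary_path:
        output["summary"] = cfg.summary_path
    if output:
        d["output"] = output
    return d


def save_config(cfg: RunConfig, path) -> None:
    """Write a config that load_config parses back to an equal RunConfig."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
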