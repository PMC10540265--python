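"""File formats and run configuration.

Tidy CSV throughout (UTF-8, header row, '.' decimal separator; times in
hours, concentrations in uM, stated in a comment header). Conditions,
constants and networks travel as YAML.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .simulate import (
    DEFAULT_WITHDRAWAL_TIMES,
    CalibrationModel,
    ExperimentCondition,
    SampledTransient,
    Trajectory,
)
from .synthetic import NoiseModel

_CSV_HEADER = "# fuelcircuits tidy CSV; time_h in hours, concentrations in uM\n"


# -- trajectories -----------------------------------------------------------

def trajectory_to_csv(trajectory: Trajectory, path) -> None:
    frames = []
    label = trajectory.condition.label if trajectory.condition else ""
    for j, sid in enumerate(trajectory.species_ids):
        frames.append(
            pd.DataFrame(
                {
                    "time_h": trajectory.times,
                    "species": sid,
                    "value_uM": trajectory.states[:, j],
                    "condition_label": label,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        df.to_csv(fh, index=False)


def trajectory_from_csv(path) -> Trajectory:
    df = pd.read_csv(path, comment="#")
    species = list(dict.fromkeys(df["species"]))
    times = np.array(sorted(df["time_h"].unique()))
    states = np.column_stack(
        [
            df[df["species"] == sid].sort_values("time_h")["value_uM"].to_numpy()
            for sid in species
        ]
    )
    label = str(df["condition_label"].iloc[0]) if len(df) else ""
    condition = None
    if label and label != "nan":
        condition = ExperimentCondition({}, t_end=float(times[-1]) or 1.0, label=label)
    return Trajectory(times=times, states=states, species_ids=species, condition=condition)


# -- sampled transients ------------------------------------------------------

def transients_to_csv(transients: list[SampledTransient], path) -> None:
    frames = []
    for tr in transients:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": tr.withdrawal_times,
                    "readout": tr.readouts,
                    "complex_uM": tr.complex_estimates,
                    "condition_label": tr.condition.label if tr.condition else "",
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        df.to_csv(fh, index=False)


def transients_from_csv(path, conditions: list[ExperimentCondition] | None = None):
    """Read sampled transients; attach matching conditions by label if given."""
    df = pd.read_csv(path, comment="#")
    by_label = {c.label: c for c in conditions or []}
    out = []
    for label, grp in df.groupby("condition_label", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            SampledTransient(
                withdrawal_times=grp["time_h"].to_numpy(),
                readouts=grp["readout"].to_numpy(),
                complex_estimates=grp["complex_uM"].to_numpy(),
                condition=by_label.get(str(label)),
            )
        )
    return out


# -- conditions and constants ------------------------------------------------

def conditions_to_yaml(conditions: list[ExperimentCondition], path) -> None:
    data = [
        {
            "label": c.label,
            "t_end": c.t_end,
            "initial_concentrations": dict(c.initial_concentrations),
        }
        for c in conditions
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def conditions_from_yaml(path) -> list[ExperimentCondition]:
    data = yaml.safe_load(Path(path).read_text())
    return [
        ExperimentCondition(
            {str(k): float(v) for k, v in c["initial_concentrations"].items()},
            t_end=float(c.get("t_end", 10.0)),
            label=str(c.get("label", "")),
        )
        for c in data
    ]


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration for one pipeline run (see docs for the schema)."""

    circuit: str
    options: dict = field(default_factory=dict)
    constants: dict | str = "default"  # inline mapping, path, or "default"
    conditions: str | list = "reference"  # "reference", path, or inline list
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    noise: NoiseModel | None = None
    withdrawal_times: tuple = DEFAULT_WITHDRAWAL_TIMES
    solver: dict = field(default_factory=lambda: {"rtol": 1e-8, "atol": 1e-12})
    seed: int = 0
    fit: dict = field(default_factory=dict)  # initial_guess / bounds / fixed / n_starts


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All violations are collected and reported in a single aggregated
    ConfigurationError naming every offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed YAML in {path}: {exc}")
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")

    errors: list[str] = []
    circuit = raw.get("circuit")
    if circuit not in ("nickase", "exoiii"):
        errors.append(f"circuit: expected 'nickase' or 'exoiii', got {circuit!r}")

    options = raw.get("options", {})
    if not isinstance(options, dict):
        errors.append("options: must be a mapping")
        options = {}

    constants = raw.get("constants", "default")
    if isinstance(constants, dict):
        for k, v in constants.items():
            try:
                if float(v) <= 0:
                    errors.append(f"constants.{k}: must be positive")
            except (TypeError, ValueError):
                errors.append(f"constants.{k}: not a number")
    elif isinstance(constants, str):
        if constants != "default":
            cpath = (path.parent / constants).resolve()
            if not cpath.exists():
                errors.append(f"constants: file not found: {constants}")
            else:
                constants = str(cpath)
    else:
        errors.append("constants: must be 'default', a path, or an inline mapping")

    conditions = raw.get("conditions", "reference")
    if isinstance(conditions, str) and conditions != "reference":
        cpath = (path.parent / conditions).resolve()
        if not cpath.exists():
            errors.append(f"conditions: file not found: {conditions}")
        else:
            conditions = str(cpath)
    elif isinstance(conditions, list):
        for i, c in enumerate(conditions):
            if not isinstance(c, dict) or "initial_concentrations" not in c:
                errors.append(f"conditions[{i}]: needs an initial_concentrations mapping")
    elif not isinstance(conditions, str):
        errors.append("conditions: must be 'reference', a path, or an inline list")

    cal_raw = raw.get("calibration", {}) or {}
    calibration = None
    try:
        calibration = CalibrationModel(
            slope=float(cal_raw.get("slope", 150.0)),
            background=float(cal_raw.get("background", 10.0)),
        )
    except (TypeError, ValueError) as exc:
        errors.append(f"calibration: {exc}")

    noise_raw = raw.get("noise")
    noise = None
    if noise_raw is not None:
        try:
            noise = NoiseModel(
                kind=noise_raw.get("kind", "proportional_gaussian"),
                sigma_add=float(noise_raw.get("sigma_add", 0.0)),
                sigma_prop=float(noise_raw.get("sigma_prop", 0.05)),
                seed=int(noise_raw.get("seed", raw.get("seed", 0))),
            )
        except (TypeError, ValueError, ConfigurationError) as exc:
            errors.append(f"noise: {exc}")

    solver = {"rtol": 1e-8, "atol": 1e-12}
    solver_raw = raw.get("solver", {}) or {}
    try:
        solver["rtol"] = float(solver_raw.get("rtol", solver["rtol"]))
        solver["atol"] = float(solver_raw.get("atol", solver["atol"]))
        if solver["rtol"] <= 0 or solver["atol"] <= 0:
            errors.append("solver: tolerances must be positive")
    except (TypeError, ValueError):
        errors.append("solver: tolerances must be numbers")

    withdrawal_times = tuple(raw.get("withdrawal_times", DEFAULT_WITHDRAWAL_TIMES))
    if sorted(withdrawal_times) != list(withdrawal_times) or len(withdrawal_times) < 1:
        errors.append("withdrawal_times: must be an ascending non-empty list")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    fit = raw.get("fit", {}) or {}
    if not isinstance(fit, dict):
        errors.append("fit: must be a mapping")
        fit = {}

    if errors:
        raise ConfigurationError(
            "invalid config %s:\n  - %s" % (path, "\n  - ".join(errors))
        )
    return RunConfig(
        circuit=circuit,
        options=options,
        constants=constants,
        conditions=conditions,
        calibration=calibration,
        noise=noise,
        withdrawal_times=withdrawal_times,
        solver=solver,
        seed=seed,
        fit=fit,
    )


def save_config(config: RunConfig, path) -> None:
    """Serialize a RunConfig back to YAML (round-trips through load_config)."""
    data = {
        "circuit": config.circuit,
        "options": dict(config.options),
        "constants": config.constants,
        "conditions": config.conditions,
        "calibration": {
            "slope": config.calibration.slope,
            "background": config.calibration.background,
        },
        "solver": dict(config.solver),
        "withdrawal_times": list(config.withdrawal_times),
        "seed": config.seed,
        "fit": dict(config.fit),
    }
    if config.noise is not None:
        data["noise"] = {
            "kind": config.noise.kind,
            "sigma_add": config.noise.sigma_add,
            "sigma_prop": config.noise.sigma_prop,
            "seed": config.noise.seed,
        }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
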