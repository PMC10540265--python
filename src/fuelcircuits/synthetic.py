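"""Synthetic noisy transients and the reference experimental conditions.

Every stage of the package is testable without any external data: this
module encodes the printed initial-concentration grids of both circuits,
provides documented default rate constants, and generates noisy sampled
transients with the statistical structure the inference stage assumes
(independent per-sample readout noise on the instrument scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .network import RateConstantSet, ReactionNetwork
from .simulate import (
    DEFAULT_WITHDRAWAL_TIMES,
    CalibrationModel,
    ExperimentCondition,
    SampledTransient,
    simulate,
    withdraw_samples,
)


@dataclass
class NoiseModel:
    """Per-sample measurement noise applied on the readout scale.

    kind: "none", "additive_gaussian" (sd = sigma_add reading units),
    "proportional_gaussian" (sd = sigma_prop * reading) or "mixed" (both).
    The seed fixes the full noise stream when no generator is supplied.
    """

    kind: str = "proportional_gaussian"
    sigma_add: float = 0.0
    sigma_prop: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "additive_gaussian", "proportional_gaussian", "mixed"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValidationError("noise sigmas must be nonnegative")

    def apply(self, readouts: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        readouts = np.asarray(readouts, dtype=float)
        if self.kind == "none":
            return readouts.copy()
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        out = readouts.copy()
        if self.kind in ("proportional_gaussian", "mixed"):
            out = out * (1.0 + self.sigma_prop * rng.standard_normal(out.shape))
        if self.kind in ("additive_gaussian", "mixed"):
            out = out + self.sigma_add * rng.standard_normal(out.shape)
        return np.maximum(out, 0.0)


# -- reference experimental conditions -------------------------------------

#: Strand concentrations (uM) of the resting modules.
_NICKASE_STRANDS = {"G": 1.0, "B": 1.0, "TL": 2.0}
_EXOIII_STRANDS = {"G": 1.0, "B": 1.0}

#: Base and auxiliary grids (uM): fuel varied at fixed enzyme and vice versa.
NICKASE_BASE = {"fuel": 3.0, "enzyme": 0.046}
NICKASE_FUEL_GRID = (2.0, 3.0, 4.0)
NICKASE_ENZYME_GRID = (0.023, 0.046, 0.069)
EXOIII_BASE = {"fuel": 3.0, "enzyme": 0.4}
EXOIII_FUEL_GRID = (2.0, 3.0, 4.0)
EXOIII_ENZYME_GRID = (0.2, 0.4, 0.6)

#: Simulation horizons (h), long enough to resolve the slowest depletion.
NICKASE_T_END = 24.0
EXOIII_T_END = 16.0


def _condition(circuit: str, fuel: float, enzyme: float, label: str) -> ExperimentCondition:
    if circuit == "nickase":
        init = dict(_NICKASE_STRANDS, F=fuel, N=enzyme)
        t_end = NICKASE_T_END
    else:
        init = dict(_EXOIII_STRANDS, F=fuel, E=enzyme)
        t_end = EXOIII_T_END
    return ExperimentCondition(init, t_end=t_end, label=label)


def reference_conditions(circuit: str) -> list[ExperimentCondition]:
    """Base condition plus the auxiliary fuel and enzyme grids (5 conditions).

    nickase: strands G/B/TL at 1/1/2 uM, fuel grid {2,3,4} uM at 0.046 uM
    nickase, enzyme grid {0.023,0.046,0.069} uM at 3 uM fuel.
    exoiii: strands G/B at 1/1 uM, fuel grid {2,3,4} uM at 0.4 uM Exo III,
    enzyme grid {0.2,0.4,0.6} uM at 3 uM fuel. The shared base condition is
    returned once, first.
    """
    if circuit == "nickase":
        base, fuel_grid, enzyme_grid = NICKASE_BASE, NICKASE_FUEL_GRID, NICKASE_ENZYME_GRID
    elif circuit == "exoiii":
        base, fuel_grid, enzyme_grid = EXOIII_BASE, EXOIII_FUEL_GRID, EXOIII_ENZYME_GRID
    else:
        raise ConfigurationError(f"unknown circuit {circuit!r}")
    conditions = [_condition(circuit, base["fuel"], base["enzyme"], "base")]
    for fuel in fuel_grid:
        if fuel != base["fuel"]:
            conditions.append(_condition(circuit, fuel, base["enzyme"], f"fuel_{fuel:g}uM"))
    for enzyme in enzyme_grid:
        if enzyme != base["enzyme"]:
            conditions.append(_condition(circuit, base["fuel"], enzyme, f"enzyme_{enzyme:g}uM"))
    return conditions


# -- default rate constants -------------------------------------------------

# Documented defaults (not fitted to any measurement): chosen once so that
# the base-condition transient of each circuit peaks near 2 h, the nickase
# complex depletes to 5% of peak around 10 h and the Exo III complex around
# 8 h, matching the qualitative shape the circuits are designed to show.
# Units: uM^-1 h^-1 for bimolecular and enzymatic-linear constants,
# uM^-2 h^-1 for the lumped termolecular assembly step, uM for Km.
_DEFAULT_CONSTANTS = {
    "nickase": {
        "k_displace": 0.6,
        "k_bind_tether": 6.0,
        "k_bind_quadruplex": 6.0,
        "k_assemble": 6.0,
        "k_nick": 18.0,
        "km_nick": 1.0,
        "k_disassemble": 22.0,
    },
    "exoiii": {
        "k_bind_tether": 12.0,
        "k_bind_quadruplex": 1.6,
        "k_assemble": 1.6,
        "k_digest": 3.2,
        "km_digest": 1.0,
        "k_digest_intermediate": 3.2,
    },
}


def default_true_constants(circuit: str, config_path=None) -> RateConstantSet:
    """Rate constants for a circuit: user-fitted values or built-in defaults.

    When ``config_path`` points to a YAML mapping of rate_constant_id to
    value (e.g. independently fitted constants), those are returned verbatim
    with source "config". Otherwise the documented built-in defaults are
    returned with source "builtin" — plausible values for testing and
    demonstration, not fitted to any measurement.
    """
    if config_path is not None:
        with open(config_path) as fh:
            values = yaml.safe_load(fh)
        if not isinstance(values, dict):
            raise ConfigurationError(f"constants file {config_path} must map ids to values")
        return RateConstantSet({str(k): float(v) for k, v in values.items()}, source="config")
    try:
        values = _DEFAULT_CONSTANTS[circuit]
    except KeyError:
        raise ConfigurationError(f"unknown circuit {circuit!r}")
    return RateConstantSet(dict(values), source="builtin")


def generate_transient_dataset(
    network: ReactionNetwork,
    constants: RateConstantSet,
    conditions: list[ExperimentCondition],
    withdrawal_times=DEFAULT_WITHDRAWAL_TIMES,
    calibration: CalibrationModel | None = None,
    noise: NoiseModel | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> list[SampledTransient]:
    """Simulate each condition, withdraw samples and apply measurement noise.

    Fully reproducible: one generator seeded from ``noise.seed`` drives the
    noise stream across all conditions in order.
    """
    calibration = calibration or CalibrationModel()
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    datasets = []
    for condition in conditions:
        traj = simulate(network, constants, condition, rtol=rtol, atol=atol)
        datasets.append(
            withdraw_samples(traj, withdrawal_times, calibration, noise=noise, rng=rng)
        )
    return datasets
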