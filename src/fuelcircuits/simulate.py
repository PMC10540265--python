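"""ODE integration, sample withdrawal and the linear readout calibration.

The measurement process being emulated: at discrete times an aliquot is
withdrawn from the running reaction module and its fluorescence (resorufin
channel) or chemiluminescence is read; the reading is proportional to the
concentration of the catalytically active complex, plus a constant
background contributed by the separated constituents. The full biocatalytic
cascade (glucose -> H2O2 -> DNAzyme -> reporter) is therefore lumped into a
linear calibration ``reading = slope * [complex] + background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ValidationError
from .network import RateConstantSet, ReactionNetwork, compile_rhs, conserved_totals

#: Sample-withdrawal grid used throughout: hours.
DEFAULT_WITHDRAWAL_TIMES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

#: Conservation drift considered acceptable (relative).
CONSERVATION_RTOL = 1e-6


@dataclass
class ExperimentCondition:
    """Initial concentrations (uM) for one run plus the simulation horizon (h)."""

    initial_concentrations: dict[str, float]
    t_end: float = 10.0
    label: str = ""

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValidationError(f"t_end must be positive, got {self.t_end}")
        for sid, c in self.initial_concentrations.items():
            if c < 0:
                raise ValidationError(f"negative initial concentration for {sid!r}: {c}")

    def state_vector(self, network: ReactionNetwork) -> np.ndarray:
        for sid in self.initial_concentrations:
            if sid not in network.catalog:
                raise ValidationError(f"condition {self.label!r}: unknown species {sid!r}")
        y0 = np.zeros(len(network.catalog))
        for sid, c in self.initial_concentrations.items():
            y0[network.catalog.index(sid)] = c
        return y0


@dataclass
class CalibrationModel:
    """Linear map between complex concentration (uM) and instrument reading.

    slope: reading units per uM of complex; background: reading at zero
    complex (signal of the separated constituents).
    """

    slope: float = 150.0
    background: float = 10.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValidationError("calibration slope must be positive")
        if self.background < 0:
            raise ValidationError("calibration background must be nonnegative")

    def forward(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.background

    def inverse(self, reading):
        """Concentration estimate, floored at zero."""
        c = (np.asarray(reading, dtype=float) - self.background) / self.slope
        return np.maximum(c, 0.0)


@dataclass
class Trajectory:
    """Dense ODE solution: times (h), states (uM, clipped at 0) and diagnostics."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species_ids: list[str]
    condition: ExperimentCondition | None = None
    diagnostics: dict = field(default_factory=dict)
    _interpolant: object = None

    def species(self, species_id: str) -> np.ndarray:
        return self.states[:, self.species_ids.index(species_id)]

    def at(self, times) -> np.ndarray:
        """States interpolated at arbitrary times within the span (clipped at 0)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if t.min() < self.times[0] - 1e-12 or t.max() > self.times[-1] + 1e-12:
            raise ValidationError(
                f"requested times outside trajectory span [{self.times[0]}, {self.times[-1]}]"
            )
        if self._interpolant is not None:
            vals = self._interpolant(np.clip(t, self.times[0], self.times[-1])).T
        else:
            vals = np.column_stack(
                [np.interp(t, self.times, self.states[:, j]) for j in range(self.states.shape[1])]
            )
        return np.maximum(vals, 0.0)

    def species_at(self, species_id: str, times) -> np.ndarray:
        return self.at(times)[:, self.species_ids.index(species_id)]


@dataclass
class SampledTransient:
    """Discrete withdrawals: readings plus calibrated complex estimates."""

    withdrawal_times: np.ndarray
    readouts: np.ndarray
    complex_estimates: np.ndarray
    condition: ExperimentCondition | None = None
    species_id: str = "C"

    def __post_init__(self):
        self.withdrawal_times = np.asarray(self.withdrawal_times, dtype=float)
        self.readouts = np.asarray(self.readouts, dtype=float)
        self.complex_estimates = np.asarray(self.complex_estimates, dtype=float)
        n = len(self.withdrawal_times)
        if len(self.readouts) != n or len(self.complex_estimates) != n:
            raise ValidationError("withdrawal_times, readouts, complex_estimates lengths differ")
        if n > 1 and not np.all(np.diff(self.withdrawal_times) > 0):
            raise ValidationError("withdrawal_times must be strictly increasing")


def simulate(
    network: ReactionNetwork,
    constants: RateConstantSet,
    condition: ExperimentCondition,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    n_grid: int = 601,
) -> Trajectory:
    """Integrate the circuit ODEs over [0, t_end] with a stiff-capable solver.

    Conservation drift of every strand/enzyme total is checked against
    ``CONSERVATION_RTOL``; a violation is recorded as a warning flag in the
    diagnostics (the run is not aborted). States are clipped to zero on
    output after verifying no excursion below -1e-9 uM.
    """
    y0 = condition.state_vector(network)
    # A loose negativity guard: the solver may probe slightly negative trial
    # states; a 1e-3 uM excursion means it is diverging and we abort.
    rhs = compile_rhs(network, constants, negative_tolerance=1e-3)
    t_eval = np.linspace(0.0, condition.t_end, n_grid)
    try:
        sol = solve_ivp(
            rhs,
            (0.0, condition.t_end),
            y0,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
            dense_output=True,
        )
    except ValidationError as exc:
        raise IntegrationError(
            f"solver diverged for condition {condition.label!r}: {exc}",
            diagnostics={"status": "diverged", "message": str(exc)},
        )
    if not sol.success:
        raise IntegrationError(
            f"solver failed for condition {condition.label!r}: {sol.message}",
            diagnostics={"status": sol.status, "message": sol.message, "nfev": sol.nfev},
        )

    states = sol.y.T
    min_state = float(states.min())
    totals0 = conserved_totals(network, y0)
    scale = max(abs(v) for v in totals0.values()) or 1.0
    drift = 0.0
    for label, vec in network.conserved_quantities:
        tot = states @ vec
        drift = max(drift, float(np.max(np.abs(tot - totals0[label]))) / scale)

    diagnostics = {
        "rtol": rtol,
        "atol": atol,
        "method": method,
        "nfev": int(sol.nfev),
        "n_steps": len(sol.t),
        "min_state": min_state,
        "conservation_drift": drift,
        "conservation_ok": drift < CONSERVATION_RTOL,
        "negativity_ok": min_state > -1e-9,
    }
    return Trajectory(
        times=sol.t,
        states=np.maximum(states, 0.0),
        species_ids=network.species_ids,
        condition=condition,
        diagnostics=diagnostics,
        _interpolant=sol.sol,
    )


def withdraw_samples(
    trajectory: Trajectory,
    times=DEFAULT_WITHDRAWAL_TIMES,
    calibration: CalibrationModel | None = None,
    noise=None,
    rng: np.random.Generator | None = None,
    species_id: str = "C",
) -> SampledTransient:
    """Emulate sample withdrawals: read out the complex through the calibration.

    ``noise`` is an optional NoiseModel applied on the readout scale; the
    complex estimate is the inverse calibration of the (noisy) reading,
    floored at zero.
    """
    calibration = calibration or CalibrationModel()
    times = np.asarray(times, dtype=float)
    conc = trajectory.species_at(species_id, times)
    readouts = calibration.forward(conc)
    if noise is not None:
        readouts = noise.apply(readouts, rng=rng)
    estimates = calibration.inverse(readouts)
    return SampledTransient(
        withdrawal_times=times,
        readouts=readouts,
        complex_estimates=estimates,
        condition=trajectory.condition,
        species_id=species_id,
    )


def transient_features(
    trajectory: Trajectory,
    species_id: str = "C",
    baseline_fraction: float = 0.05,
    n_fine: int = 4001,
) -> tuple[float, float, float | None]:
    """(peak_time h, peak_value uM, depletion_time h or None).

    peak_time is the argmax of the species over a fine resampling of the
    dense solution; depletion_time is the first time after the peak at which
    the concentration falls to ``baseline_fraction`` of the peak value, or
    None if that level is never reached within the horizon.
    """
    if not 0.0 < baseline_fraction < 1.0:
        raise ValidationError("baseline_fraction must lie in (0, 1)")
    t = np.linspace(trajectory.times[0], trajectory.times[-1], n_fine)
    c = trajectory.species_at(species_id, t)
    i_peak = int(np.argmax(c))
    peak_time, peak_value = float(t[i_peak]), float(c[i_peak])
    if peak_value <= 0.0:
        return peak_time, peak_value, None
    threshold = baseline_fraction * peak_value
    below = np.nonzero(c[i_peak:] <= threshold)[0]
    depletion_time = float(t[i_peak + below[0]]) if below.size else None
    return peak_time, peak_value, depletion_time
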