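"""Rate-constant estimation from sampled transients, and auxiliary prediction.

Workflow mirrored here: fit the circuit's rate constants to the sampled
transient(s) at a base condition by least squares on the complex-
concentration scale, then use the fitted constants to predict — purely by
simulation, no re-fitting — the transients at auxiliary fuel/enzyme
concentrations.

Fitting is performed in log10-parameter space (the constants are positive
and span decades) with a seeded multistart around the initial guess, using
lmfit's trust-region least-squares backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import ValidationError
from .network import RateConstantSet, ReactionNetwork
from .simulate import ExperimentCondition, SampledTransient, Trajectory, simulate

#: A parameter whose +/-50% perturbation moves the residual norm by less
#: than this fraction is flagged non-identifiable.
IDENTIFIABILITY_RTOL = 0.01


@dataclass
class FitResult:
    """Estimated rate constants with uncertainties and convergence metadata.

    standard_errors are on the natural (linear) scale, propagated from the
    log10-space covariance; None where the covariance is unavailable or
    singular. ``nonidentifiable`` lists parameters whose perturbation barely
    changes the objective — their point estimates carry no information.
    """

    estimates: RateConstantSet
    standard_errors: dict[str, float | None]
    residual_norm: float
    n_obs: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    nonidentifiable: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _as_list(observed) -> list[SampledTransient]:
    return list(observed) if isinstance(observed, (list, tuple)) else [observed]


def _predict_at(
    network: ReactionNetwork,
    constants: RateConstantSet,
    condition: ExperimentCondition,
    times: np.ndarray,
    species_id: str,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Lean integration evaluated only at the withdrawal times (fit hot path)."""
    from scipy.integrate import solve_ivp

    from .errors import IntegrationError
    from .network import compile_rhs

    rhs = compile_rhs(network, constants, negative_tolerance=1e-3)
    y0 = condition.state_vector(network)
    sol = solve_ivp(rhs, (0.0, float(times[-1])), y0, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=times)
    if not sol.success:
        raise IntegrationError(f"solver failed during fit: {sol.message}")
    return np.maximum(sol.y[network.catalog.index(species_id)], 0.0)


def _residuals(
    network: ReactionNetwork,
    constants: RateConstantSet,
    observations: list[SampledTransient],
    rtol: float,
    atol: float,
) -> np.ndarray:
    res = []
    for obs in observations:
        pred = _predict_at(network, constants, obs.condition, obs.withdrawal_times,
                           obs.species_id, rtol, atol)
        res.append(pred - obs.complex_estimates)
    return np.concatenate(res)


def fit_rate_constants(
    network: ReactionNetwork,
    observed,
    initial_guess: RateConstantSet,
    bounds: tuple[float, float] = (1e-4, 1e4),
    fixed: list[str] | None = None,
    *,
    n_starts: int = 8,
    seed: int = 0,
    start_spread: float = 0.5,
    sim_rtol: float = 1e-7,
    sim_atol: float = 1e-10,
    profile: str = "fast",
) -> FitResult:
    """Least-squares fit of the network's rate constants to sampled transients.

    Parameters are optimized as log10 values within ``bounds`` (a global
    (lo, hi) pair on the linear scale, or a per-id mapping). ``fixed`` names
    constants held at their initial-guess value. ``n_starts`` seeded starts
    are drawn log-normally around the initial guess (sd ``start_spread``
    decades); the best local optimum wins, making the result deterministic
    for identical inputs and seed.

    ``profile`` selects the identifiability check: "fast" perturbs each
    parameter +/-50% holding the others at the optimum; "full" is a genuine
    profile — each parameter is fixed at its perturbed value and the others
    re-optimized, which also exposes parameters identifiable only in
    combination (e.g. fast binding/unbinding pairs whose ratio alone is
    constrained); "none" skips the check.
    """
    observations = _as_list(observed)
    if not observations:
        raise ValidationError("no observations supplied")
    for obs in observations:
        if obs.condition is None:
            raise ValidationError("every observation needs its ExperimentCondition")
        if len(obs.withdrawal_times) < 2:
            raise ValidationError("degenerate data: need at least two time points")
    if max(float(np.max(obs.complex_estimates)) for obs in observations) <= 0.0:
        raise ValidationError(
            "observations carry no information: complex estimates are identically zero"
        )

    fixed = set(fixed or ())
    needed = network.rate_constant_ids()
    missing = [k for k in needed if k not in initial_guess.values]
    if missing:
        raise ValidationError(f"initial guess missing constants: {missing}")
    free = [k for k in needed if k not in fixed]
    n_obs = sum(len(obs.withdrawal_times) for obs in observations)
    if n_obs < len(free):
        raise ValidationError(f"{n_obs} observations cannot constrain {len(free)} parameters")

    if isinstance(bounds, dict):
        get_bounds = lambda k: bounds.get(k, (1e-4, 1e4))
    else:
        get_bounds = lambda k: bounds

    # lmfit parameter names must be identifiers; log10 scale throughout.
    def make_params(start_values: dict[str, float]) -> lmfit.Parameters:
        params = lmfit.Parameters()
        for k in needed:
            lo, hi = get_bounds(k)
            val = np.clip(np.log10(start_values[k]), np.log10(lo), np.log10(hi))
            params.add(f"log10_{k}", value=val, min=np.log10(lo), max=np.log10(hi),
                       vary=k not in fixed)
        return params

    def to_constants(params: lmfit.Parameters) -> RateConstantSet:
        return RateConstantSet(
            {k: 10.0 ** params[f"log10_{k}"].value for k in needed}, source="fit"
        )

    def objective(params: lmfit.Parameters) -> np.ndarray:
        return _residuals(network, to_constants(params), observations, sim_rtol, sim_atol)

    rng = np.random.default_rng(seed)
    trace: list[float] = []

    def iter_cb(params, iter_num, resid, *args, **kwargs):
        cost = float(np.dot(resid, resid))
        trace.append(min(cost, trace[-1]) if trace else cost)

    best = None
    n_local_failures = 0
    for start in range(max(n_starts, 1)):
        start_values = dict(initial_guess.values)
        if start > 0:
            for k in free:
                start_values[k] = start_values[k] * 10.0 ** (
                    start_spread * rng.standard_normal()
                )
        try:
            result = lmfit.minimize(
                objective, make_params(start_values), method="least_squares",
                iter_cb=iter_cb, xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            n_local_failures += 1
            continue
        cost = float(np.sum(result.residual**2))
        if best is None or cost < best[0]:
            best = (cost, result)

    if best is None:
        raise ValidationError("all optimization starts failed")
    cost, result = best
    estimates = to_constants(result.params)
    residual_norm = float(np.sqrt(cost))

    standard_errors: dict[str, float | None] = {}
    for k in needed:
        par = result.params[f"log10_{k}"]
        if par.vary and par.stderr is not None and np.isfinite(par.stderr):
            # d(k)/d(log10 k) = k ln 10
            standard_errors[k] = float(estimates[k] * np.log(10.0) * par.stderr)
        else:
            standard_errors[k] = None

    if profile == "none":
        nonidentifiable = []
    elif profile == "full":
        nonidentifiable = _flag_nonidentifiable_profile(
            network, estimates, free, fixed, observations, residual_norm,
            get_bounds, sim_rtol, sim_atol,
        )
    else:
        nonidentifiable = _flag_nonidentifiable(
            network, estimates, free, observations, residual_norm, sim_rtol, sim_atol
        )
    return FitResult(
        estimates=estimates,
        standard_errors=standard_errors,
        residual_norm=residual_norm,
        n_obs=n_obs,
        converged=bool(getattr(result, "success", True)),
        objective_trace=trace,
        nonidentifiable=nonidentifiable,
        diagnostics={
            "n_starts": n_starts,
            "n_local_failures": n_local_failures,
            "nfev": int(result.nfev),
            "seed": seed,
            "free_parameters": free,
        },
    )


def _flag_nonidentifiable(
    network, estimates, free, observations, residual_norm, rtol, atol
) -> list[str]:
    """Crude profile check: +/-50% perturbation must move the residual norm."""
    scale = np.sqrt(sum(float(np.sum(o.complex_estimates**2)) for o in observations))
    denom = max(residual_norm, 1e-6 * max(scale, 1e-12))
    flagged = []
    for k in free:
        changes = []
        for factor in (1.5, 1 / 1.5):
            norm = float(
                np.linalg.norm(
                    _residuals(network, estimates.replace(**{k: estimates[k] * factor}),
                               observations, rtol, atol)
                )
            )
            changes.append(abs(norm - residual_norm) / denom)
        if max(changes) < IDENTIFIABILITY_RTOL:
            flagged.append(k)
    return flagged


def _flag_nonidentifiable_profile(
    network, estimates, free, fixed, observations, residual_norm, get_bounds, rtol, atol
) -> list[str]:
    """Profile check: fix each parameter at +/-50%, re-optimize the rest.

    Exposes parameters that are individually unconstrained even though some
    combination of them is (sloppy directions); the fast single-axis check
    cannot see those.
    """
    needed = network.rate_constant_ids()
    scale = np.sqrt(sum(float(np.sum(o.complex_estimates**2)) for o in observations))
    denom = max(residual_norm, 1e-6 * max(scale, 1e-12))
    flagged = []
    for k in free:
        changes = []
        for factor in (1.5, 1 / 1.5):
            start = estimates.replace(**{k: estimates[k] * factor})
            params = lmfit.Parameters()
            for kk in needed:
                lo, hi = get_bounds(kk)
                val = np.clip(np.log10(start[kk]), np.log10(lo), np.log10(hi))
                params.add(
                    f"log10_{kk}", value=val, min=np.log10(lo), max=np.log10(hi),
                    vary=(kk in free and kk != k),
                )

            def obj(p):
                cs = RateConstantSet(
                    {kk: 10.0 ** p[f"log10_{kk}"].value for kk in needed}, source="fit"
                )
                return _residuals(network, cs, observations, rtol, atol)

            try:
                res = lmfit.minimize(
                    obj, params, method="least_squares",
                    xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=60,
                )
                norm = float(np.linalg.norm(res.residual))
            except Exception:
                norm = float(
                    np.linalg.norm(_residuals(network, start, observations, rtol, atol))
                )
            changes.append(abs(norm - residual_norm) / denom)
        if max(changes) < IDENTIFIABILITY_RTOL:
            flagged.append(k)
    return flagged


def predict_auxiliary(
    network: ReactionNetwork,
    fitted: RateConstantSet,
    conditions: list[ExperimentCondition],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> list[Trajectory]:
    """Pure simulation of the fitted model at each auxiliary condition."""
    return [simulate(network, fitted, c, rtol=rtol, atol=atol) for c in conditions]


@dataclass
class GoodnessOfFit:
    rmse: float  # uM, on the complex-estimate scale
    nrmse: float  # rmse normalized by the observation's peak value
    residuals: np.ndarray  # predicted - observed, per withdrawal time


def goodness_of_fit(
    observed: SampledTransient,
    predicted: Trajectory,
    calibration=None,  # accepted for interface symmetry; loss is on uM scale
) -> GoodnessOfFit:
    """RMSE between a sampled transient and a predicted trajectory.

    The predicted complex concentration is interpolated at the withdrawal
    times; nrmse divides by the peak of the observed estimates.
    """
    if len(observed.withdrawal_times) == 0:
        raise ValidationError("empty observation")
    pred = predicted.species_at(observed.species_id, observed.withdrawal_times)
    residuals = pred - observed.complex_estimates
    rmse = float(np.sqrt(np.mean(residuals**2)))
    peak = float(np.max(observed.complex_estimates))
    nrmse = rmse / peak if peak > 0 else np.inf
    return GoodnessOfFit(rmse=rmse, nrmse=nrmse, residuals=residuals)
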