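"""Sub-model fitting with a restart-capped multistart scheme, and
profile-likelihood confidence intervals.

Fitting one sub-model means minimising the user's cost function over
the *included* parameters only; excluded parameters are resolved to
their defaults on every evaluation, so the cost always sees a complete
global parameter vector.

The local search is deliberately humble: bounded Nelder-Mead, but run
as a sequence of capped *legs* — each leg is interrupted after a fixed
number of simplex iterations and restarted from its own endpoint, which
re-inflates the simplex and lets the search cover a broader region than
a single long run.  Legs stop once the between-leg decrease of the
objective falls below a convergence tolerance.  The whole chain is
repeated ``optim_runs`` times from independent random starting points
(the first chain may instead inherit estimates from a previously fitted
related model), and the best chain wins.

Identifiability of the fitted parameters is assessed by profile
likelihood: one parameter is walked away from its estimate while all
others are re-optimised; the 95% confidence bound sits where the
profiled -2 log-likelihood rises by the chi-square(1) quantile 3.841.
A profile that stays below the threshold all the way to the box bound
marks that side as non-identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .criteria import FitRecord, information_criterion
from .model_space import (
    ModelId,
    ModelSpaceError,
    ParameterSpace,
    make_resolver,
    resolve_parameters,
)

__all__ = ["FitOptions", "FitError", "fit_submodel", "ProfileResult", "profile_likelihood_ci"]

_PENALTY = 1e300  # stand-in for non-finite cost values inside the simplex


class FitError(RuntimeError):
    """Fitting could not be carried out (bad bounds, bad contract)."""


@dataclass(frozen=True)
class FitOptions:
    """Tunables of the restart-capped multistart fit.

    optim_runs:
        Independent multistart chains per sub-model (>= 1).
    iteration_cap:
        Simplex iterations per leg before the optimiser is interrupted
        and restarted from its endpoint.
    convergence_tol:
        Chain stops when the between-leg decrease of the objective
        falls below this value.
    max_legs:
        Safety cap on legs per chain.
    seed:
        Master seed; the RNG of each sub-model fit is derived from
        (seed, model identifier), so results do not depend on the order
        in which candidate models are evaluated.
    method:
        Local-search method label passed to scipy.optimize.minimize.
    """

    optim_runs: int = 2
    iteration_cap: int = 1000
    convergence_tol: float = 1e-3
    max_legs: int = 100
    seed: int = 0
    method: str = "Nelder-Mead"
    xatol: float = 1e-6
    fatol: float = 1e-8

    def __post_init__(self) -> None:
        if self.optim_runs < 1:
            raise FitError(f"optim_runs must be >= 1, got {self.optim_runs}")
        if self.iteration_cap < 1:
            raise FitError(f"iteration_cap must be >= 1, got {self.iteration_cap}")
        if not self.convergence_tol > 0:
            raise FitError(f"convergence_tol must be > 0, got {self.convergence_tol}")


def model_rng(options: FitOptions, alpha: ModelId) -> np.random.Generator:
    """Per-model RNG stream derived from (master seed, model bits)."""
    bits = int(str(alpha), 2) if len(alpha) else 0
    return np.random.default_rng([int(options.seed) & 0x7FFFFFFF, bits])


def _fit_bounds(names: Sequence[str], space: ParameterSpace) -> tuple[np.ndarray, np.ndarray]:
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for i, nm in enumerate(names):
        try:
            lo[i], hi[i] = space.bounds[nm]
        except KeyError:
            raise FitError(f"parameter {nm!r} has no bounds; fitting requires a finite box") from None
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise FitError("fitting requires finite bounds for every included parameter")
    return lo, hi


def _run_chain(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: optimize.Bounds,
    options: FitOptions,
) -> tuple[np.ndarray, float, bool, int]:
    """One restart-capped chain.  Returns (x, f, converged, nfev)."""
    x = np.asarray(x0, dtype=float)
    f_prev = objective(x)
    nfev = 1
    converged = False
    best_x, best_f = x, f_prev
    for _ in range(options.max_legs):
        res = optimize.minimize(
            objective,
            best_x,
            method=options.method,
            bounds=bounds,
            options={
                "maxiter": options.iteration_cap,
                "xatol": options.xatol,
                "fatol": options.fatol,
            },
        )
        nfev += int(res.nfev)
        if res.fun <= best_f:
            best_x, best_f = np.asarray(res.x, dtype=float), float(res.fun)
        if f_prev - best_f < options.convergence_tol:
            converged = True
            break
        f_prev = best_f
    return best_x, best_f, converged, nfev


def fit_submodel(
    alpha: ModelId,
    cost_fn: Callable[[np.ndarray], float],
    space: ParameterSpace,
    options: FitOptions,
    inherited_start: Mapping[str, float] | None = None,
    *,
    ic_type: str = "AICc",
    n_data: int | None = None,
    cost_returns: str = "minus2LL",
) -> FitRecord:
    """Fit one sub-model and score it with an information criterion.

    ``cost_fn`` receives the full resolved global parameter vector (in
    space order) and returns either a -2 log-likelihood
    (``cost_returns="minus2LL"``, requires ``n_data``) or the criterion
    value itself (``cost_returns="ic"``).

    ``inherited_start`` seeds the first chain with estimates from a
    related, previously fitted model: values for shared included
    parameters are reused (clipped into bounds), newly added parameters
    are sampled like any other start.

    A cost function that is non-finite at every attempted start yields
    a failed record (``ic_value = inf``, ``converged = False``) rather
    than an exception, so a search can log and move past pathological
    candidates.
    """
    if cost_returns not in ("minus2LL", "ic"):
        raise FitError(f"cost_returns must be 'minus2LL' or 'ic', got {cost_returns!r}")
    if cost_returns == "minus2LL" and n_data is None:
        raise FitError("n_data is required when the cost function returns -2 log L")
    names = alpha.included_names(space)
    k = len(names)
    if k == 0:
        raise ModelSpaceError("cannot fit the empty model")
    lo, hi = _fit_bounds(names, space)
    bounds = optimize.Bounds(lo, hi)
    rng = model_rng(options, alpha)
    resolver, _ = make_resolver(alpha, space)

    def objective(x: np.ndarray) -> float:
        v = cost_fn(resolver(x))
        return float(v) if np.isfinite(v) else _PENALTY

    starts = []
    for run in range(options.optim_runs):
        x0 = rng.uniform(lo, hi)
        if run == 0 and inherited_start is not None:
            for i, nm in enumerate(names):
                if nm in inherited_start:
                    x0[i] = np.clip(inherited_start[nm], lo[i], hi[i])
        starts.append(x0)

    best: tuple[np.ndarray, float, bool] | None = None
    nfev_total = 0
    any_finite_start = False
    for x0 in starts:
        if objective(x0) < _PENALTY:
            any_finite_start = True
        x, f, conv, nfev = _run_chain(objective, x0, bounds, options)
        nfev_total += nfev + 1
        if best is None or f < best[1] or (f == best[1] and conv and not best[2]):
            best = (x, f, conv)

    if not any_finite_start or best is None or best[1] >= _PENALTY:
        full = resolve_parameters(alpha, dict(zip(names, starts[0])), space)
        return FitRecord(
            model=alpha,
            parameters=full,
            minus2LL=np.inf,
            k=k,
            n=n_data,
            ic_value=np.inf,
            ic_type=ic_type,
            meta={"converged": False, "failed": True, "runs": options.optim_runs,
                  "nfev": nfev_total},
        )

    x_best, f_best, conv = best
    full = resolve_parameters(alpha, dict(zip(names, x_best)), space)
    if cost_returns == "minus2LL":
        minus2ll = f_best
        ic = information_criterion(minus2ll, k, n_data, ic_type)
    else:
        minus2ll = float("nan")
        ic = f_best
    return FitRecord(
        model=alpha,
        parameters=full,
        minus2LL=minus2ll,
        k=k,
        n=n_data,
        ic_value=ic,
        ic_type=ic_type,
        meta={"converged": conv, "runs": options.optim_runs, "nfev": nfev_total},
    )


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

@dataclass
class ProfileResult:
    """Profile-likelihood confidence interval for one parameter."""

    parameter: str
    estimate: float
    lower: float
    upper: float
    lower_identifiable: bool
    upper_identifiable: bool
    level: float
    threshold: float
    points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def identifiable(self) -> bool:
        return self.lower_identifiable and self.upper_identifiable


def profile_likelihood_ci(
    record: FitRecord,
    parameter_name: str,
    cost_fn: Callable[[np.ndarray], float],
    space: ParameterSpace,
    options: FitOptions,
    level: float = 0.95,
    *,
    max_steps: int = 30,
    n_bisect: int = 20,
    reopt_options: FitOptions | None = None,
) -> ProfileResult:
    """Walk one fitted parameter away from its estimate in both
    directions, re-optimising all other included parameters at each
    profile point.

    The confidence bound is located where the profiled objective
    crosses ``min + chi2(1, level)`` (bracketing followed by a few
    bisection refinements).  If the profile is still below the
    threshold when the walk reaches the parameter's box bound, that
    side is flagged non-identifiable and the bound itself is reported
    — the convention used to mark rates whose data carry no upper
    constraint.

    Steps are adaptive: they grow while the profile stays flat and a
    step that overshoots the threshold violently is retried at half
    size.  A failed re-optimisation at a profile point likewise halves
    the step.
    """
    alpha = record.model
    names = list(alpha.included_names(space))
    if parameter_name not in names:
        raise FitError(f"parameter {parameter_name!r} is not included in the fitted model")
    p = names.index(parameter_name)
    others = [nm for nm in names if nm != parameter_name]
    lo_all, hi_all = _fit_bounds(names, space)
    p_lo, p_hi = lo_all[p], hi_all[p]
    threshold = float(stats.chi2.ppf(level, df=1))
    base = float(record.minus2LL) if np.isfinite(record.minus2LL) else float(record.ic_value)
    estimate = float(record.parameters[space.index(parameter_name)])
    theta_hat = {nm: float(record.parameters[space.index(nm)]) for nm in names}
    ro = reopt_options or replace(options, optim_runs=1, max_legs=3, xatol=1e-5, fatol=1e-6)
    o_lo = np.array([lo_all[names.index(nm)] for nm in others])
    o_hi = np.array([hi_all[names.index(nm)] for nm in others])
    o_bounds = optimize.Bounds(o_lo, o_hi) if others else None

    resolver, _ = make_resolver(alpha, space)
    other_pos = [i for i in range(len(names)) if i != p]

    def profiled(value: float, warm: np.ndarray | None) -> tuple[float, np.ndarray]:
        """Objective minimised over the other parameters at fixed ``value``."""
        xfull = np.empty(len(names))
        xfull[p] = value

        if not others:
            v = cost_fn(resolver(xfull))
            return (float(v) if np.isfinite(v) else _PENALTY), np.empty(0)

        def obj(x: np.ndarray) -> float:
            xfull[other_pos] = x
            v = cost_fn(resolver(xfull))
            return float(v) if np.isfinite(v) else _PENALTY

        x0 = warm if warm is not None else np.array([theta_hat[nm] for nm in others])
        x0 = np.clip(x0, o_lo, o_hi)
        x, f, _, _ = _run_chain(obj, x0, o_bounds, ro)
        return f, x

    points: list[tuple[float, float]] = [(estimate, base)]
    span = p_hi - p_lo
    results: dict[int, tuple[float, bool]] = {}

    for direction in (-1, +1):
        bound = p_lo if direction < 0 else p_hi
        step = max(0.02 * span, 1e-12)
        pos, prof = estimate, base
        warm = np.array([theta_hat[nm] for nm in others]) if others else None
        ci_val, identifiable = float(bound), False
        below = (pos, prof, warm)
        steps = 0
        while steps < max_steps:
            steps += 1
            nxt = pos + direction * step
            clipped = max(p_lo, min(p_hi, nxt))
            f, x = profiled(clipped, warm)
            if f >= _PENALTY:  # failed re-optimisation: retry closer
                step /= 2
                if step < 1e-12 * max(1.0, span):
                    break
                continue
            points.append((clipped, f))
            rise = f - base
            if rise > threshold:
                if rise > 3 * threshold and step > 1e-9 * span:
                    step /= 2  # violent overshoot: resolve the crossing more finely
                    continue
                # bracket [below, clipped]; bisect then interpolate.
                # Resolution is relative to the interval's own width, so
                # sharply identified parameters get correspondingly fine
                # crossings.
                a_pos, a_f, a_warm = below
                b_pos, b_f = clipped, f
                wb = x
                for _ in range(n_bisect):
                    width_tol = max(0.005 * abs(a_pos - estimate), 1e-9 * span)
                    if abs(b_pos - a_pos) <= width_tol:
                        break
                    mid = 0.5 * (a_pos + b_pos)
                    fm, xm = profiled(mid, wb)
                    points.append((mid, fm))
                    if fm - base > threshold:
                        b_pos, b_f = mid, fm
                    else:
                        a_pos, a_f, wb = mid, fm, xm
                frac = (threshold - (a_f - base)) / ((b_f - a_f) or 1.0)
                ci_val = a_pos + frac * (b_pos - a_pos)
                identifiable = True
                break
            below = (clipped, f, x)
            pos, warm = clipped, x
            if clipped == bound:
                ci_val, identifiable = float(bound), False
                break
            if rise < threshold / 4:
                step = min(step * 1.8, 0.25 * span)
        else:
            # walk exhausted without crossing or reaching the bound
            ci_val, identifiable = pos, False
        results[direction] = (ci_val, identifiable)

    lower, lower_ok = results[-1]
    upper, upper_ok = results[+1]
    return ProfileResult(
        parameter=parameter_name,
        estimate=estimate,
        lower=min(lower, estimate),
        upper=max(upper, estimate),
        lower_identifiable=lower_ok,
        upper_identifiable=upper_ok,
        level=level,
        threshold=threshold,
        points=sorted(points),
    )
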