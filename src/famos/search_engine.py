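"""The model-selection loop: propose neighbours, fit them, accept strict
improvements, switch methods dynamically, and terminate.

The method automaton
--------------------
The search keeps one current method (forward, backward, or swap) and
one current best model.  Each iteration fits the method's full
neighbourhood of the current best and accepts the best candidate only
if its criterion value is *strictly* lower (strictness prevents cycling
among ties).  The next method follows a fixed automaton:

* improvement under forward or backward keeps the method;
* improvement under swap switches to forward (a successful exchange
  opens new territory for additions);
* failure under forward switches to backward and vice versa — unless
  both directions have now failed consecutively, in which case the
  search escalates to swap if any swap set is available, and otherwise
  terminates;
* failure under swap terminates.

Because acceptance requires a strict criterion decrease and the space
is finite, termination is guaranteed.

History and reproducibility
---------------------------
Every fitted model is memoised in a history map; previously tested
models proposed again are not refitted (their stored records still
compete in the iteration's comparison) unless refitting is explicitly
requested.  The first chain of every fit inherits parameter estimates
from the current best model.  Per-candidate RNG streams are derived
from (master seed, model identifier), so the result is identical
regardless of candidate evaluation order or parallelism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Mapping, Union

import numpy as np
from joblib import Parallel, delayed

from .criteria import FitRecord, akaike_weights
from .model_space import (
    ModelId,
    ModelSpaceError,
    ParameterSpace,
    most_distant_model,
    neighbors,
    random_model,
    validate_model,
)
from .optimizer import FitOptions, fit_submodel

__all__ = [
    "Method",
    "TERMINATE",
    "SearchOptions",
    "SearchState",
    "IterationRecord",
    "SearchResult",
    "next_method",
    "run_iteration",
    "run_famos",
]

logger = logging.getLogger(__name__)

Method = Literal["forward", "backward", "swap"]
TERMINATE = "terminate"
_METHODS = ("forward", "backward", "swap")


def next_method(
    current: Method,
    improved: bool,
    last_two_failed: bool,
    swap_available: bool,
) -> str:
    """Method automaton: the search method for the next iteration, or
    :data:`TERMINATE`.

    ``last_two_failed`` means the current iteration failed *and* the
    previous iteration used the opposite local direction and failed as
    well (forward then backward, or backward then forward).
    """
    if current not in _METHODS:
        raise ModelSpaceError(f"unknown method {current!r}")
    if improved:
        return "forward" if current == "swap" else current
    if current == "swap":
        return TERMINATE
    if last_two_failed:
        return "swap" if swap_available else TERMINATE
    return "backward" if current == "forward" else "forward"


@dataclass
class SearchOptions:
    """Configuration of one search run.

    ``start`` selects the starting model: ``"global"`` (all non-fixed
    parameters), ``"random"`` (uniform over admissible models, seeded
    by ``fit_options.seed``), ``"most_distant"`` (requires prior tested
    models, see :func:`run_famos`), or an explicit :class:`ModelId`.
    """

    ic_type: str = "AICc"
    n_data: int | None = None
    start: Union[str, ModelId] = "global"
    initial_method: Method = "forward"
    reuse_history: bool = True
    refit: bool = False
    fit_options: FitOptions = field(default_factory=FitOptions)
    max_iterations: int = 200
    n_jobs: int = 1
    auto_repair: bool = False
    cost_returns: str = "minus2LL"

    def __post_init__(self) -> None:
        if self.initial_method not in _METHODS:
            raise ModelSpaceError(f"initial_method must be one of {_METHODS}")


@dataclass
class IterationRecord:
    """Per-iteration log entry: what was proposed, fitted and accepted."""

    index: int
    method: str
    n_proposed: int
    n_fitted: int
    accepted: str | None
    best_ic: float


@dataclass
class SearchState:
    """Mutable state threaded through :func:`run_iteration`."""

    best: FitRecord
    method: Method
    history: dict[str, FitRecord]
    iterations: list[IterationRecord] = field(default_factory=list)
    prev_failed_direction: str | None = None
    terminated: bool = False


@dataclass
class SearchResult:
    """Outcome of a full search run."""

    best: FitRecord
    history: dict[str, FitRecord]
    iterations: list[IterationRecord]
    weights: dict[str, float]
    start: str
    meta: dict = field(default_factory=dict)

    @property
    def n_fitted(self) -> int:
        """Distinct models fitted during this run."""
        return len(self.history)


def _candidate_key(rec: FitRecord) -> tuple[float, int, str]:
    # lower criterion first; ties: fewer parameters, then canonical string
    return (rec.ic_value, rec.k, str(rec.model))


def _fit_one(
    model: ModelId,
    cost_fn,
    space: ParameterSpace,
    options: SearchOptions,
    inherited: Mapping[str, float] | None,
) -> FitRecord:
    return fit_submodel(
        model,
        cost_fn,
        space,
        options.fit_options,
        inherited_start=inherited,
        ic_type=options.ic_type,
        n_data=options.n_data,
        cost_returns=options.cost_returns,
    )


def run_iteration(
    state: SearchState,
    space: ParameterSpace,
    cost_fn: Callable[[np.ndarray], float],
    options: SearchOptions,
) -> SearchState:
    """Execute one iteration: propose, fit, compare, accept, switch.

    Mutates and returns ``state``.  An empty neighbourhood counts as
    "no improvement".  Results are independent of candidate evaluation
    order because every candidate's fit is seeded from (master seed,
    model identifier).
    """
    method = state.method
    proposals = neighbors(state.best.model, space, method)
    to_fit = []
    reused: list[FitRecord] = []
    for m in proposals:
        key = str(m)
        if options.reuse_history and not options.refit and key in state.history:
            reused.append(state.history[key])
        else:
            to_fit.append(m)

    inherited = {
        nm: float(state.best.parameters[space.index(nm)])
        for nm in state.best.model.included_names(space)
    }
    if options.n_jobs != 1 and len(to_fit) > 1:
        fitted = Parallel(n_jobs=options.n_jobs)(
            delayed(_fit_one)(m, cost_fn, space, options, inherited) for m in to_fit
        )
    else:
        fitted = [_fit_one(m, cost_fn, space, options, inherited) for m in to_fit]
    for rec in fitted:
        key = str(rec.model)
        prev = state.history.get(key)
        if prev is None or rec.ic_value < prev.ic_value:
            state.history[key] = rec

    candidates = reused + fitted
    accepted: FitRecord | None = None
    if candidates:
        top = min(candidates, key=_candidate_key)
        if np.isfinite(top.ic_value) and top.ic_value < state.best.ic_value:
            accepted = top

    improved = accepted is not None
    if improved:
        state.best = accepted
    last_two_failed = (
        not improved
        and method in ("forward", "backward")
        and state.prev_failed_direction == ("backward" if method == "forward" else "forward")
    )
    state.iterations.append(
        IterationRecord(
            index=len(state.iterations),
            method=method,
            n_proposed=len(proposals),
            n_fitted=len(fitted),
            accepted=str(accepted.model) if accepted else None,
            best_ic=float(state.best.ic_value),
        )
    )
    logger.info(
        "iteration %d [%s]: proposed=%d fitted=%d accepted=%s best_ic=%.6g",
        len(state.iterations) - 1, method, len(proposals), len(fitted),
        state.iterations[-1].accepted, state.best.ic_value,
    )
    nxt = next_method(method, improved, last_two_failed, space.swap_available)
    state.prev_failed_direction = method if (not improved and method != "swap") else None
    if nxt == TERMINATE:
        state.terminated = True
    else:
        state.method = nxt
    return state


def _repair(model: ModelId, space: ParameterSpace) -> ModelId:
    """Add the lowest-index member of each violated critical set."""
    included = set(model.included_names(space))
    add = []
    for cs in space.critical_sets:
        if not included & cs:
            add.append(min(space.index(nm) for nm in cs))
    repaired = model.with_bits(on=add)
    if not validate_model(repaired, space):
        raise ModelSpaceError(f"cannot repair starting model {model}")
    return repaired


def _starting_model(
    space: ParameterSpace,
    options: SearchOptions,
    prior_tested: Iterable[ModelId] | None,
) -> ModelId:
    start = options.start
    if isinstance(start, ModelId):
        if not validate_model(start, space):
            if options.auto_repair:
                return _repair(start, space)
            raise ModelSpaceError(
                f"starting model {start} is invalid for this space "
                "(set auto_repair=True to add critical-set members)"
            )
        return start
    if start == "global":
        return space.global_model()
    if start == "random":
        rng = np.random.default_rng([int(options.fit_options.seed) & 0x7FFFFFFF, 0x5747])
        return random_model(space, rng)
    if start == "most_distant":
        if not prior_tested:
            raise ModelSpaceError(
                "start='most_distant' requires prior tested models (prior_tested=...)"
            )
        return most_distant_model(prior_tested, space, seed=options.fit_options.seed)
    raise ModelSpaceError(f"unknown starting-model selector {start!r}")


def run_famos(
    space: ParameterSpace,
    cost_fn: Callable[[np.ndarray], float],
    options: SearchOptions | None = None,
    prior_tested: Iterable[ModelId] | None = None,
) -> SearchResult:
    """Run the full selection loop until termination.

    Returns the best model found, the complete evaluation history
    (every fitted model exactly once, with its best fit), the
    per-iteration log, and per-parameter Akaike support computed over
    the history.  Identical inputs and seed reproduce the identical
    trace.
    """
    options = options or SearchOptions()
    if options.initial_method == "swap" and not space.swap_available:
        raise ModelSpaceError("initial_method='swap' requires swap or critical sets")
    start_model = _starting_model(space, options, prior_tested)
    start_rec = _fit_one(start_model, cost_fn, space, options, None)
    if not np.isfinite(start_rec.ic_value):
        raise ModelSpaceError(
            f"cost function is not finite at any start for starting model {start_model}"
        )
    state = SearchState(
        best=start_rec,
        method=options.initial_method,
        history={str(start_model): start_rec},
    )
    while not state.terminated and len(state.iterations) < options.max_iterations:
        run_iteration(state, space, cost_fn, options)

    weights = akaike_weights(list(state.history.values()), space).support
    return SearchResult(
        best=state.best,
        history=state.history,
        iterations=state.iterations,
        weights=weights,
        start=str(start_model),
        meta={
            "seed": options.fit_options.seed,
            "ic_type": options.ic_type,
            "terminated": state.terminated,
        },
    )
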