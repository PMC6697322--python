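"""Search loop: method automaton, acceptance rules, memoisation, termination."""

from __future__ import annotations

import numpy as np
import pytest

import famos.search_engine as se
from famos.model_space import ModelId, ModelSpaceError, ParameterSpace
from famos.optimizer import FitOptions
from famos.search_engine import (
    TERMINATE,
    SearchOptions,
    next_method,
    run_famos,
)

from conftest import random_space


class TestNextMethod:
    @pytest.mark.parametrize(
        "current,improved,last_two_failed,swap_available,expected",
        [
            ("forward", True, False, True, "forward"),
            ("backward", True, False, False, "backward"),
            ("swap", True, False, True, "forward"),
            ("forward", False, False, True, "backward"),
            ("backward", False, False, True, "forward"),
            ("forward", False, True, True, "swap"),
            ("backward", False, True, True, "swap"),
            ("forward", False, True, False, TERMINATE),
            ("backward", False, True, False, TERMINATE),
            ("swap", False, False, True, TERMINATE),
        ],
    )
    def test_automaton(self, current, improved, last_two_failed, swap_available, expected):
        assert next_method(current, improved, last_two_failed, swap_available) == expected

    def test_unknown_method(self):
        with pytest.raises(ModelSpaceError):
            next_method("sideways", True, False, False)


def quad_separable(targets, scale=0.1):
    """Additively separable quadratic: excluded parameter i contributes
    (t_i/scale)^2 to the optimal -2 log L of any sub-model."""
    t = np.asarray(targets, dtype=float)

    def cost(theta):
        return float(np.sum(((theta - t) / scale) ** 2))

    return cost


def _space(n, **kw):
    return ParameterSpace(
        parameter_names=tuple(f"p{i}" for i in range(n)),
        bounds={f"p{i}": (-2.0, 2.0) for i in range(n)},
        **kw,
    )


def _options(start, **kw):
    return SearchOptions(
        ic_type="AIC",
        n_data=100,
        start=start,
        fit_options=FitOptions(seed=0, optim_runs=1),
        **kw,
    )


class TestRunFamosSeparable:
    """On a separable quadratic landscape the AIC-best model is known in
    closed form, so the whole trace is predictable."""

    def test_forward_then_stop_at_known_best(self):
        # contributions of excluding each parameter: 100, 25, 0.25, 0.01
        space = _space(4)
        cost = quad_separable([1.0, 0.5, 0.05, 0.01])
        res = run_famos(space, cost, _options(ModelId((1, 0, 0, 0))))
        assert str(res.best.model) == "1100"  # only gains > 2 AIC points included
        assert res.best.ic_value == pytest.approx(0.25 + 0.01 + 4.0, abs=1e-3)
        methods = [it.method for it in res.iterations]
        assert methods == ["forward", "forward", "backward"]
        assert res.meta["terminated"]
        # history: start + 3 forward + 2 forward + 1 new backward model
        assert res.n_fitted == 7

    def test_global_start_goes_backward_first(self):
        space = _space(3)
        cost = quad_separable([1.0, 0.5, 0.0])
        res = run_famos(space, cost, _options("global"))
        assert str(res.best.model) == "110"
        # forward neighbourhood of the global model is empty -> backward
        assert [it.method for it in res.iterations][:2] == ["forward", "backward"]
        assert res.iterations[0].n_proposed == 0

    def test_accepted_ic_strictly_decreases(self):
        space = _space(5)
        cost = quad_separable([1.0, 0.8, 0.6, 0.01, 0.005])
        res = run_famos(space, cost, _options("random"))
        accepted = [it.best_ic for it in res.iterations if it.accepted]
        assert all(b < a - 1e-12 for a, b in zip(accepted, accepted[1:]))
        finite = [r.ic_value for r in res.history.values() if np.isfinite(r.ic_value)]
        assert res.best.ic_value == min(finite)

    def test_tie_between_candidates_broken_canonically(self):
        # excluding p1 or p2 costs the same; both forward candidates
        # from {p0} tie, and the canonically smaller string must win
        space = _space(4)
        cost = quad_separable([1.0, 0.5, 0.5, 0.0])
        res = run_famos(space, cost, _options(ModelId((1, 0, 0, 0))))
        first_accept = next(it.accepted for it in res.iterations if it.accepted)
        assert first_accept == "1010"

    def test_ic_tie_with_current_best_not_accepted(self):
        # criterion({p0}) == criterion({p0,p1}): tie must not cycle
        space = ParameterSpace(
            parameter_names=("p0", "p1"),
            bounds={"p0": (1.0, 2.0), "p1": (1.0, 2.0)},
        )
        f = frozenset
        table = {f({"p0", "p1"}): 4.0, f({"p0"}): 4.0, f({"p1"}): 102.0}
        cost = table_cost_factory(table, space)
        opts = SearchOptions(
            start=ModelId((1, 1)),
            fit_options=FitOptions(seed=0, optim_runs=1, max_legs=1),
            cost_returns="ic",
        )
        res = run_famos(space, cost, opts)
        assert str(res.best.model) == "11"
        backward_iter = res.iterations[1]
        assert backward_iter.method == "backward"
        assert backward_iter.accepted is None


def table_cost_factory(table, space):
    """Criterion landscape fully specified by a lookup table.

    Bounds keep fitted values >= 1 while excluded parameters resolve to
    0, so the inclusion pattern is recoverable from the resolved vector
    and the cost is flat within each model.
    """
    names = space.parameter_names

    def cost(theta):
        included = frozenset(n for n, v in zip(names, theta) if v > 0.5)
        return float(table[included])

    return cost


class TestSwapEscapesLocalMinimum:
    def test_swap_rescue_and_trace(self):
        space = ParameterSpace(
            parameter_names=("p0", "p1", "p2"),
            swap_sets=[{"p0", "p1"}],
            bounds={n: (1.0, 2.0) for n in ("p0", "p1", "p2")},
        )
        f = frozenset
        table = {
            f({"p0"}): 10.0, f({"p1"}): 5.0, f({"p2"}): 30.0,
            f({"p0", "p1"}): 12.0, f({"p0", "p2"}): 11.0, f({"p1", "p2"}): 20.0,
            f({"p0", "p1", "p2"}): 25.0,
        }
        cost = table_cost_factory(table, space)
        opts = SearchOptions(
            start=ModelId((1, 0, 0)),
            fit_options=FitOptions(seed=0, optim_runs=1, max_legs=1),
            cost_returns="ic",
        )
        res = run_famos(space, cost, opts)
        # {p0} is a forward/backward local minimum; only the swap move
        # reaches the better singleton {p1}
        assert str(res.best.model) == "010"
        assert res.best.ic_value == 5.0
        methods = [it.method for it in res.iterations]
        assert methods == ["forward", "backward", "swap", "forward", "backward", "swap"]
        assert res.meta["terminated"]

    def test_without_swap_sets_stays_in_local_minimum(self):
        space = ParameterSpace(
            parameter_names=("p0", "p1", "p2"),
            bounds={n: (1.0, 2.0) for n in ("p0", "p1", "p2")},
        )
        f = frozenset
        table = {
            f({"p0"}): 10.0, f({"p1"}): 5.0, f({"p2"}): 30.0,
            f({"p0", "p1"}): 12.0, f({"p0", "p2"}): 11.0, f({"p1", "p2"}): 20.0,
            f({"p0", "p1", "p2"}): 25.0,
        }
        cost = table_cost_factory(table, space)
        opts = SearchOptions(
            start=ModelId((1, 0, 0)),
            fit_options=FitOptions(seed=0, optim_runs=1, max_legs=1),
            cost_returns="ic",
        )
        res = run_famos(space, cost, opts)
        assert str(res.best.model) == "100"


class TestHistoryAndDeterminism:
    def test_reuse_history_avoids_refits(self):
        calls = []
        space = _space(3)
        base = quad_separable([1.0, 0.5, 0.0])

        def counting_cost(theta):
            calls.append(tuple(np.round(theta, 6)))
            return base(theta)

        res = run_famos(space, counting_cost, _options(ModelId((1, 0, 0))))
        # every fitted model appears exactly once in history
        assert res.n_fitted == len({str(r.model) for r in res.history.values()})
        for key, rec in res.history.items():
            assert key == str(rec.model)
        # iterations whose proposals were all previously fitted do no new fits
        refit_free = [it for it in res.iterations if it.n_fitted == 0]
        assert all(it.accepted is None or it.n_proposed > 0 for it in refit_free)

    def test_identical_seed_reproduces_trace(self):
        space = _space(4)
        cost = quad_separable([0.9, 0.4, 0.2, 0.01])
        r1 = run_famos(space, cost, _options("random"))
        r2 = run_famos(space, cost, _options("random"))
        assert str(r1.best.model) == str(r2.best.model)
        assert [it.accepted for it in r1.iterations] == [it.accepted for it in r2.iterations]
        assert r1.best.ic_value == r2.best.ic_value
        np.testing.assert_array_equal(r1.best.parameters, r2.best.parameters)

    def test_candidate_order_does_not_change_result(self, monkeypatch):
        """Reversing every proposed neighbourhood must not change the
        outcome: per-candidate seeds are order-free and comparisons use
        a total order."""
        space = _space(4)
        cost = quad_separable([0.9, 0.4, 0.2, 0.01])
        ref = run_famos(space, cost, _options(ModelId((0, 0, 0, 1))))

        original = se.neighbors

        def reversed_neighbors(alpha, sp, method):
            return list(reversed(original(alpha, sp, method)))

        monkeypatch.setattr(se, "neighbors", reversed_neighbors)
        rev = run_famos(space, cost, _options(ModelId((0, 0, 0, 1))))
        assert str(rev.best.model) == str(ref.best.model)
        assert rev.best.ic_value == ref.best.ic_value
        assert {k: r.ic_value for k, r in rev.history.items()} == \
               {k: r.ic_value for k, r in ref.history.items()}

    @pytest.mark.parametrize("trial", range(4))
    def test_termination_and_monotonicity_on_random_spaces(self, trial):
        rng = np.random.default_rng(200 + trial)
        space = random_space(rng, int(rng.integers(3, 8)))
        targets = rng.uniform(-1, 1, size=space.n)
        cost = quad_separable(targets)
        opts = SearchOptions(
            ic_type="AIC", n_data=50, start="random",
            fit_options=FitOptions(seed=trial, optim_runs=1), max_iterations=60,
        )
        try:
            res = run_famos(space, cost, opts)
        except ModelSpaceError:
            pytest.skip("random space admits no valid model")
        assert res.meta["terminated"]
        accepted = [it.best_ic for it in res.iterations if it.accepted]
        assert all(b < a for a, b in zip(accepted, accepted[1:]))


class TestStartingModels:
    def test_invalid_user_start_rejected(self, critical_space):
        bad = ModelId.from_names(critical_space, ["rho_B"])
        cost = quad_separable([0.1, 0.1, 0.1, 0.1])
        with pytest.raises(ModelSpaceError, match="invalid"):
            run_famos(critical_space, cost, _options(bad))

    def test_auto_repair_adds_critical_member(self, critical_space):
        bad = ModelId.from_names(critical_space, ["rho_B"])
        cost = quad_separable([0.1, 0.1, 0.1, 0.1])
        opts = _options(bad, auto_repair=True)
        res = run_famos(critical_space, cost, opts)
        # repaired start includes the lowest-index member of the violated set
        assert res.start == str(ModelId.from_names(critical_space, ["mu_AB", "rho_B"]))

    def test_most_distant_requires_prior(self):
        space = _space(3)
        cost = quad_separable([0.1, 0.1, 0.1])
        with pytest.raises(ModelSpaceError, match="most_distant"):
            run_famos(space, cost, _options("most_distant"))

    def test_initial_swap_requires_sets(self):
        space = _space(3)
        cost = quad_separable([0.1, 0.1, 0.1])
        with pytest.raises(ModelSpaceError, match="swap"):
            run_famos(space, cost, _options("global", initial_method="swap"))
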