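"""Shared fixtures: small hand-made spaces and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from famos.model_space import ModelId, ParameterSpace, validate_model


@pytest.fixture
def simple_space() -> ParameterSpace:
    """Four free parameters, no critical or swap sets."""
    return ParameterSpace(
        parameter_names=("a", "b", "c", "d"),
        bounds={n: (0.0, 10.0) for n in "abcd"},
    )


@pytest.fixture
def critical_space() -> ParameterSpace:
    """Compartment-style space with one critical set {mu_AB, mu_CB}."""
    return ParameterSpace(
        parameter_names=("mu_AB", "mu_CB", "rho_B", "mu_BC"),
        critical_sets=[{"mu_AB", "mu_CB"}],
        bounds={n: (0.0, 1.0) for n in ("mu_AB", "mu_CB", "rho_B", "mu_BC")},
    )


def all_models(n: int):
    """Every 0/1 vector of length n (including the empty one)."""
    for bits in itertools.product((0, 1), repeat=n):
        yield ModelId(bits)


def all_valid_models(space: ParameterSpace):
    return [m for m in all_models(space.n) if validate_model(m, space)]


def brute_force_neighbors(alpha: ModelId, space: ParameterSpace, method: str):
    """Oracle: filter all 2^n vectors by validity and move geometry."""
    out = []
    for cand in all_models(space.n):
        if not validate_model(cand, space):
            continue
        d = alpha.hamming(cand)
        if method == "forward" and d == 1 and cand.k == alpha.k + 1:
            out.append(cand)
        elif method == "backward" and d == 1 and cand.k == alpha.k - 1:
            out.append(cand)
        elif method == "swap" and d == 2 and cand.k == alpha.k:
            # both flipped bits must share a swap (or critical) set
            added = set(cand.included) - set(alpha.included)
            removed = set(alpha.included) - set(cand.included)
            (i,) = added
            (j,) = removed
            ni, nj = space.parameter_names[i], space.parameter_names[j]
            if any(ni in s and nj in s for s in space.effective_swap_sets):
                out.append(cand)
    return out


def random_space(rng: np.random.Generator, n: int) -> ParameterSpace:
    """A random small space with random critical and swap sets."""
    names = tuple(f"p{i}" for i in range(n))
    n_crit = int(rng.integers(0, 3))
    crit = []
    for _ in range(n_crit):
        size = int(rng.integers(1, max(2, n // 2)))
        crit.append(set(rng.choice(names, size=size, replace=False)))
    n_swap = int(rng.integers(0, 3))
    swap = []
    for _ in range(n_swap):
        size = int(rng.integers(2, max(3, n // 2 + 1)))
        swap.append(set(rng.choice(names, size=size, replace=False)))
    return ParameterSpace(
        parameter_names=names,
        critical_sets=crit,
        swap_sets=swap,
        bounds={nm: (0.0, 1.0) for nm in names},
    )
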