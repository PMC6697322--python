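"""Combinatorial model spaces built on binary sub-model identifiers.

A *global model* collects every parameter (i.e. every candidate process)
that might matter for the dynamics under study.  Each sub-model is then
described by an ordered binary inclusion vector ``alpha`` over the global
parameter list: ``alpha[i] = 1`` means parameter ``i`` is estimated from
the data, ``alpha[i] = 0`` means the corresponding process is switched
off or pinned to a default value.  The model space is the set of all
admissible inclusion vectors, and search proceeds through three move
types over this space:

* **forward** — include one currently excluded parameter,
* **backward** — exclude one currently included parameter,
* **swap** — exchange an included for an excluded parameter, both drawn
  from the same *swap set* of structurally similar (mutually
  compensating) parameters.

*Critical sets* encode structural pre-knowledge: a model is admissible
only if it contains at least one member of every critical set.  The
empty model is never admissible.

This module owns the space definition (:class:`ParameterSpace`), the
identifier type (:class:`ModelId`), neighbourhood generation, model
counting, the "most distant model" heuristic used to restart searches in
unexplored regions, and the resolution of excluded parameters to
concrete default values (literals, inherited references, or guarded
references such as generation-wise rate inheritance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Union

import numpy as np

__all__ = [
    "ModelSpaceError",
    "ResolutionError",
    "DefaultRule",
    "ParameterSpace",
    "ModelId",
    "validate_model",
    "forward_neighbors",
    "backward_neighbors",
    "swap_neighbors",
    "count_models",
    "most_distant_model",
    "resolve_parameters",
    "make_resolver",
    "random_model",
]


class ModelSpaceError(ValueError):
    """A structurally invalid space, model, or configuration."""


class ResolutionError(ModelSpaceError):
    """Default-value resolution failed (cyclic reference or bad guard)."""


@dataclass(frozen=True)
class DefaultRule:
    """One fallback entry for an excluded parameter.

    ``target`` is either a literal number or the name of another
    parameter whose *resolved* value is inherited.  If ``only_if_any``
    is given, the rule applies only when at least one member of that
    guard set is included in the model being resolved; otherwise the
    next rule in the parameter's fallback list is tried.
    """

    target: Union[float, str]
    only_if_any: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.only_if_any is not None and not isinstance(self.only_if_any, frozenset):
            object.__setattr__(self, "only_if_any", frozenset(self.only_if_any))

    @property
    def is_reference(self) -> bool:
        return isinstance(self.target, str)


def _as_frozensets(sets: Iterable[Iterable[str]]) -> tuple[frozenset[str], ...]:
    return tuple(frozenset(s) for s in sets)


@dataclass(frozen=True)
class ParameterSpace:
    """Definition of a combinatorial model space.

    Parameters
    ----------
    parameter_names:
        Ordered, unique identifiers of all global-model parameters.
        The order fixes the bit order of every :class:`ModelId`.
    critical_sets:
        Subsets of parameter names of which at least one member must be
        included for a model to be admissible.
    swap_sets:
        Subsets of structurally similar parameters available to the
        swap move.  All critical sets are additionally treated as swap
        sets during neighbour generation.
    fixed_values:
        Parameters excluded from fitting altogether ("do not fit"),
        mapped to the value they always take.  Fixed parameters must
        have ``alpha = 0`` in every model.
    default_rules:
        Per-parameter ordered fallback lists of :class:`DefaultRule`
        used to resolve excluded parameters.  A parameter with no
        applicable rule (and no fixed value) resolves to ``0.0``:
        the process is off.
    bounds:
        Box bounds ``name -> (lower, upper)`` in natural units, used by
        the fitting layer for sampling and constraint enforcement.
    """

    parameter_names: tuple[str, ...]
    critical_sets: tuple[frozenset[str], ...] = ()
    swap_sets: tuple[frozenset[str], ...] = ()
    fixed_values: Mapping[str, float] = field(default_factory=dict)
    default_rules: Mapping[str, tuple[DefaultRule, ...]] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameter_names", tuple(self.parameter_names))
        object.__setattr__(self, "critical_sets", _as_frozensets(self.critical_sets))
        object.__setattr__(self, "swap_sets", _as_frozensets(self.swap_sets))
        object.__setattr__(self, "fixed_values", dict(self.fixed_values))
        object.__setattr__(
            self,
            "default_rules",
            {name: tuple(rules) for name, rules in dict(self.default_rules).items()},
        )
        object.__setattr__(
            self, "bounds", {k: (float(v[0]), float(v[1])) for k, v in dict(self.bounds).items()}
        )
        self._validate()

    # -- construction-time checks ------------------------------------------
    def _validate(self) -> None:
        names = self.parameter_names
        if len(names) == 0:
            raise ModelSpaceError("parameter space must contain at least one parameter")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelSpaceError(f"duplicate parameter names: {dupes}")
        known = set(names)

        def check_known(what: str, items: Iterable[str]) -> None:
            unknown = sorted(set(items) - known)
            if unknown:
                raise ModelSpaceError(f"{what} references unknown parameter(s): {unknown}")

        for cs in self.critical_sets:
            if not cs:
                raise ModelSpaceError("empty critical set")
            check_known("critical set", cs)
        for ss in self.swap_sets:
            check_known("swap set", ss)
        check_known("fixed_values", self.fixed_values)
        check_known("bounds", self.bounds)
        for name, rules in self.default_rules.items():
            check_known("default_rules key", [name])
            for rule in rules:
                if rule.is_reference:
                    check_known(f"default rule for {name!r}", [rule.target])
                if rule.only_if_any is not None:
                    check_known(f"default-rule guard for {name!r}", rule.only_if_any)

        fixed_in_critical = set(self.fixed_values) & set().union(*self.critical_sets) if self.critical_sets else set()
        if fixed_in_critical:
            raise ModelSpaceError(
                f"parameter(s) both fixed and critical: {sorted(fixed_in_critical)}"
            )
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ModelSpaceError(f"bounds for {name!r} must satisfy lower < upper, got {(lo, hi)}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Conservative static check: the graph of all reference edges
        # (guards ignored) must be acyclic; this guarantees acyclicity
        # under every possible model.
        edges: dict[str, list[str]] = {}
        for name, rules in self.default_rules.items():
            edges[name] = [r.target for r in rules if r.is_reference]
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {n: WHITE for n in edges}

        def visit(node: str, stack: list[str]) -> None:
            colour[node] = GREY
            for nxt in edges.get(node, ()):
                c = colour.get(nxt, BLACK if nxt not in edges else WHITE)
                if c == GREY:
                    raise ModelSpaceError(
                        f"cyclic default-rule references: {' -> '.join(stack + [node, nxt])}"
                    )
                if c == WHITE:
                    visit(nxt, stack + [node])
            colour[node] = BLACK

        for node in edges:
            if colour[node] == WHITE:
                visit(node, [])

    # -- convenience views --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.parameter_names)

    @cached_property
    def _index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.parameter_names)}

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelSpaceError(f"unknown parameter {name!r}") from None

    @cached_property
    def fixed_indices(self) -> frozenset[int]:
        return frozenset(self.index(n) for n in self.fixed_values)

    @cached_property
    def free_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n) if i not in self.fixed_indices)

    @property
    def n_free(self) -> int:
        return len(self.free_indices)

    @cached_property
    def effective_swap_sets(self) -> tuple[frozenset[str], ...]:
        """Swap sets actually used by the swap move: the declared swap
        sets plus every critical set (each admissible model already
        contains a member of each critical set, so members are mutually
        exchangeable)."""
        seen: list[frozenset[str]] = []
        for s in self.swap_sets + self.critical_sets:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    @property
    def swap_available(self) -> bool:
        return any(len(s) >= 2 for s in self.effective_swap_sets)

    def global_model(self) -> "ModelId":
        """The maximal admissible model: every non-fixed parameter included."""
        alpha = tuple(0 if i in self.fixed_indices else 1 for i in range(self.n))
        return ModelId(alpha)


@dataclass(frozen=True, order=True)
class ModelId:
    """Ordered binary inclusion vector; the unit of search.

    Ordering (and the canonical text form, the left-to-right 0/1
    string) is lexicographic on the bit tuple and is used for all
    deterministic tie-breaks.
    """

    alpha: tuple[int, ...]

    def __post_init__(self) -> None:
        alpha = tuple(int(a) for a in self.alpha)
        if any(a not in (0, 1) for a in alpha):
            raise ModelSpaceError(f"model identifier bits must be 0/1, got {alpha}")
        object.__setattr__(self, "alpha", alpha)

    @classmethod
    def from_string(cls, s: str) -> "ModelId":
        if not set(s) <= {"0", "1"}:
            raise ModelSpaceError(f"model string must contain only 0/1, got {s!r}")
        return cls(tuple(int(c) for c in s))

    @classmethod
    def from_names(cls, space: ParameterSpace, names: Iterable[str]) -> "ModelId":
        idx = {space.index(n) for n in names}
        return cls(tuple(1 if i in idx else 0 for i in range(space.n)))

    def __str__(self) -> str:
        return "".join(map(str, self.alpha))

    def __len__(self) -> int:
        return len(self.alpha)

    @property
    def k(self) -> int:
        """Number of included parameters."""
        return sum(self.alpha)

    @property
    def included(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.alpha) if a == 1)

    @property
    def excluded(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.alpha) if a == 0)

    def included_names(self, space: ParameterSpace) -> tuple[str, ...]:
        return tuple(space.parameter_names[i] for i in self.included)

    def with_bits(self, on: Iterable[int] = (), off: Iterable[int] = ()) -> "ModelId":
        alpha = list(self.alpha)
        for i in on:
            alpha[i] = 1
        for i in off:
            alpha[i] = 0
        return ModelId(tuple(alpha))

    def hamming(self, other: "ModelId") -> int:
        if len(other) != len(self):
            raise ModelSpaceError("cannot compare identifiers of different length")
        return sum(a != b for a, b in zip(self.alpha, other.alpha))


def _check_conforms(alpha: ModelId, space: ParameterSpace) -> None:
    if len(alpha) != space.n:
        raise ModelSpaceError(
            f"model identifier length {len(alpha)} does not match space size {space.n}"
        )


def validate_model(alpha: ModelId, space: ParameterSpace) -> bool:
    """True iff the model is admissible.

    Admissibility requires: at least one parameter included (the empty
    model is never evaluated), no fixed parameter included, and at
    least one member of every critical set included.
    """
    _check_conforms(alpha, space)
    if alpha.k == 0:
        return False
    if any(alpha.alpha[i] for i in space.fixed_indices):
        return False
    included = set(alpha.included_names(space))
    return all(included & cs for cs in space.critical_sets)


def forward_neighbors(alpha: ModelId, space: ParameterSpace) -> list[ModelId]:
    """All admissible models adding exactly one non-fixed excluded parameter.

    Supersets of an admissible model are admissible, so no filtering is
    needed; neighbours are emitted in order of the added parameter index.
    """
    _check_conforms(alpha, space)
    fixed = space.fixed_indices
    return [alpha.with_bits(on=[i]) for i in alpha.excluded if i not in fixed]


def backward_neighbors(alpha: ModelId, space: ParameterSpace) -> list[ModelId]:
    """All admissible models removing exactly one included parameter.

    Candidates that empty a critical set, or the empty model, are
    dropped; neighbours are ordered by the removed parameter index.
    """
    _check_conforms(alpha, space)
    out = []
    for i in alpha.included:
        cand = alpha.with_bits(off=[i])
        if validate_model(cand, space):
            out.append(cand)
    return out


def swap_neighbors(alpha: ModelId, space: ParameterSpace) -> list[ModelId]:
    """All admissible one-for-one exchanges within the swap sets.

    For every effective swap set (declared swap sets plus all critical
    sets) and every pair (included member j, excluded member i), a
    candidate with j switched off and i switched on is produced.
    Duplicates reachable through several sets are emitted once;
    inadmissible candidates are dropped.  Order is deterministic:
    sorted by (removed index, added index) of the first producing pair.
    """
    _check_conforms(alpha, space)
    included = set(alpha.included)
    fixed = space.fixed_indices
    seen: dict[ModelId, tuple[int, int]] = {}
    for pset in space.effective_swap_sets:
        indices = sorted(space.index(nm) for nm in pset)
        ins = [i for i in indices if i in included]
        outs = [i for i in indices if i not in included and i not in fixed]
        for j in ins:
            for i in outs:
                cand = alpha.with_bits(on=[i], off=[j])
                if cand not in seen and validate_model(cand, space):
                    seen[cand] = (j, i)
    return [m for m, _ in sorted(seen.items(), key=lambda kv: kv[1])]


def neighbors(alpha: ModelId, space: ParameterSpace, method: str) -> list[ModelId]:
    """Dispatch to the neighbourhood generator for ``method``."""
    try:
        fn = {
            "forward": forward_neighbors,
            "backward": backward_neighbors,
            "swap": swap_neighbors,
        }[method]
    except KeyError:
        raise ModelSpaceError(f"unknown search method {method!r}") from None
    return fn(alpha, space)


def count_models(n_parameters: int) -> int:
    """Number of non-empty sub-models of an ``n``-parameter global model.

    Exact integer arithmetic: ``2**n - 1`` (the empty model is excluded).
    """
    n = int(n_parameters)
    if n < 1:
        raise ModelSpaceError(f"need at least one parameter, got {n}")
    return 2**n - 1


# ---------------------------------------------------------------------------
# most-distant starting model
# ---------------------------------------------------------------------------

def _free_mask(alpha: ModelId, space: ParameterSpace) -> int:
    """Pack the free (non-fixed) bits of ``alpha`` into an int, first
    free parameter as most significant bit so that ascending ints match
    ascending canonical strings."""
    nf = space.n_free
    mask = 0
    for pos, i in enumerate(space.free_indices):
        if alpha.alpha[i]:
            mask |= 1 << (nf - 1 - pos)
    return mask


def _mask_to_model(mask: int, space: ParameterSpace) -> ModelId:
    nf = space.n_free
    alpha = [0] * space.n
    for pos, i in enumerate(space.free_indices):
        if mask >> (nf - 1 - pos) & 1:
            alpha[i] = 1
    return ModelId(tuple(alpha))


def _critical_masks(space: ParameterSpace) -> list[int]:
    nf = space.n_free
    pos_of = {i: pos for pos, i in enumerate(space.free_indices)}
    masks = []
    for cs in space.critical_sets:
        m = 0
        for nm in cs:
            m |= 1 << (nf - 1 - pos_of[space.index(nm)])
        masks.append(m)
    return masks


def most_distant_model(
    tested: Iterable[ModelId],
    space: ParameterSpace,
    *,
    seed: int = 0,
    exhaustive_limit: int = 20,
    n_restarts: int = 20,
) -> ModelId:
    """An admissible model maximising the minimum Hamming distance to
    all previously tested models (fixed parameters excluded from the
    distance).

    Used to restart searches in the least-explored region of the model
    space.  With at most ``exhaustive_limit`` free parameters the
    maximiser is found by exhaustive enumeration; above that a seeded
    multi-restart single-bit-flip hill climb is used (a documented
    heuristic).  Ties are broken by canonical 0/1-string order.
    """
    tested = list(tested)
    if not tested:
        raise ModelSpaceError("most_distant_model requires at least one tested model")
    for m in tested:
        _check_conforms(m, space)
    nf = space.n_free
    tested_masks = np.unique(
        np.array([_free_mask(m, space) for m in tested], dtype=np.uint64)
    )
    crit = _critical_masks(space)

    if nf <= exhaustive_limit:
        cands = np.arange(1, 2**nf, dtype=np.uint64)
        ok = np.ones(cands.shape, dtype=bool)
        for cm in crit:
            ok &= (cands & np.uint64(cm)) != 0
        cands = cands[ok]
        if cands.size == 0:
            raise ModelSpaceError("no admissible model exists (contradictory critical sets)")
        dmin = np.full(cands.shape, np.iinfo(np.int64).max, dtype=np.int64)
        for t in tested_masks:
            np.minimum(dmin, np.bitwise_count(cands ^ t).astype(np.int64), out=dmin)
        best = int(cands[int(np.argmax(dmin))])  # argmax returns first = lex smallest
        return _mask_to_model(best, space)

    # hill climb over single-bit flips
    rng = np.random.default_rng(seed)
    t_arr = tested_masks

    def min_dist(mask: int) -> int:
        return int(np.bitwise_count(np.uint64(mask) ^ t_arr).min())

    def admissible(mask: int) -> bool:
        return mask != 0 and all(mask & cm for cm in crit)

    def random_valid() -> int:
        while True:
            mask = int(rng.integers(0, 2**nf, dtype=np.uint64))
            for cm in crit:
                if not mask & cm:
                    # switch on a random member of the violated set
                    bits = [b for b in range(nf) if cm >> b & 1]
                    mask |= 1 << int(rng.choice(bits))
            if mask != 0:
                return mask

    best_mask, best_d = None, -1
    for _ in range(n_restarts):
        cur = random_valid()
        cur_d = min_dist(cur)
        visited = {cur}
        sideways_budget = 2 * nf  # plateau walks help escape distance ties
        while True:
            cand_best, cand_d = None, -1
            for b in range(nf):
                f = cur ^ (1 << b)
                if f in visited or not admissible(f):
                    continue
                d = min_dist(f)
                if d > cand_d or (d == cand_d and (cand_best is None or f < cand_best)):
                    cand_best, cand_d = f, d
            if cand_best is None or cand_d < cur_d:
                break
            if cand_d == cur_d:
                if sideways_budget <= 0:
                    break
                sideways_budget -= 1
            cur, cur_d = cand_best, cand_d
            visited.add(cur)
            if cur_d > best_d or (cur_d == best_d and (best_mask is None or cur < best_mask)):
                best_mask, best_d = cur, cur_d
        if cur_d > best_d or (cur_d == best_d and (best_mask is None or cur < best_mask)):
            best_mask, best_d = cur, cur_d
    return _mask_to_model(best_mask, space)


def random_model(space: ParameterSpace, rng: np.random.Generator) -> ModelId:
    """A model drawn uniformly from the admissible set (rejection sampling)."""
    n = space.n
    fixed = space.fixed_indices
    while True:
        bits = rng.integers(0, 2, size=n)
        for i in fixed:
            bits[i] = 0
        cand = ModelId(tuple(int(b) for b in bits))
        if validate_model(cand, space):
            return cand


# ---------------------------------------------------------------------------
# default-value resolution
# ---------------------------------------------------------------------------

def make_resolver(alpha: ModelId, space: ParameterSpace):
    """Precompile default-value resolution for one model.

    Guards and reference chains depend only on ``alpha``, so for a
    fixed model every parameter resolves either to a constant or to one
    of the fitted values.  The returned callable maps a vector of
    fitted values (in included-name order) to the full global parameter
    vector with a couple of array operations — this is the hot path of
    every cost evaluation during fitting.

    Returns ``(resolver, included_names)``.
    """
    _check_conforms(alpha, space)
    names = alpha.included_names(space)
    pos = {nm: i for i, nm in enumerate(names)}
    included_set = set(names)
    cache: dict[str, tuple[str, float | int]] = {}

    def sym(name: str, stack: tuple[str, ...]) -> tuple[str, float | int]:
        """('x', position-in-fitted-vector) or ('c', constant)."""
        if name in cache:
            return cache[name]
        if name in stack:
            raise ResolutionError(
                f"cyclic default-rule reference: {' -> '.join(stack + (name,))}"
            )
        if name in included_set:
            out: tuple[str, float | int] = ("x", pos[name])
        elif name in space.fixed_values:
            out = ("c", float(space.fixed_values[name]))
        else:
            out = ("c", 0.0)
            for rule in space.default_rules.get(name, ()):
                if rule.only_if_any is not None and not (rule.only_if_any & included_set):
                    continue
                if rule.is_reference:
                    out = sym(rule.target, stack + (name,))
                else:
                    out = ("c", float(rule.target))
                break
        cache[name] = out
        return out

    template = np.zeros(space.n)
    out_idx: list[int] = []
    x_pos: list[int] = []
    for j, nm in enumerate(space.parameter_names):
        tag, v = sym(nm, ())
        if tag == "x":
            out_idx.append(j)
            x_pos.append(int(v))
        else:
            template[j] = v
    out_arr = np.array(out_idx, dtype=np.intp)
    pos_arr = np.array(x_pos, dtype=np.intp)

    def resolver(x) -> np.ndarray:
        full = template.copy()
        full[out_arr] = np.asarray(x, dtype=float)[pos_arr]
        return full

    return resolver, names


def resolve_parameters(
    alpha: ModelId,
    fitted_values: Mapping[str, float],
    space: ParameterSpace,
) -> np.ndarray:
    """Expand fitted values of the included parameters into the full
    global parameter vector.

    Included parameters take their fitted values.  Excluded parameters
    take their fixed value if fixed, otherwise the first applicable
    entry of their default-rule list (guards evaluated against
    ``alpha``, references resolved recursively), otherwise ``0.0``.
    """
    resolver, names = make_resolver(alpha, space)
    missing = [n for n in names if n not in fitted_values]
    if missing:
        raise ModelSpaceError(f"fitted_values missing included parameter(s): {missing}")
    return resolver(np.array([float(fitted_values[n]) for n in names]))
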