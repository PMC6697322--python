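"""Configuration files, result tables, and serialization.

Space definitions travel as YAML: parameter order, critical/swap sets,
fixed values, default rules (literal, reference, or guarded reference)
and bounds.  Histories are CSV tables with one row per evaluated model
(model string, criterion, -2 log L, k, convergence flag, and one column
per parameter holding its resolved value); floats are written with
round-tripping precision so a re-read reproduces criterion values
bit-for-bit.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .criteria import FitRecord
from .model_space import DefaultRule, ModelSpaceError, ParameterSpace
from .search_engine import IterationRecord, SearchResult

__all__ = [
    "space_to_dict",
    "space_from_dict",
    "read_space_config",
    "write_space_config",
    "history_to_frame",
    "write_history",
    "read_history",
    "write_iterations",
    "write_best_model",
    "write_weights",
]


def _sorted_names(space: ParameterSpace, names: Iterable[str]) -> list[str]:
    return sorted(names, key=space.index)


def space_to_dict(space: ParameterSpace) -> dict:
    """Canonical plain-data form of a space (stable ordering throughout)."""
    rules = {}
    for name in space.parameter_names:
        if name not in space.default_rules:
            continue
        entries = []
        for rule in space.default_rules[name]:
            if rule.is_reference:
                e: dict = {"ref": rule.target}
            else:
                e = {"value": float(rule.target)}
            if rule.only_if_any is not None:
                e["only_if_any"] = _sorted_names(space, rule.only_if_any)
            entries.append(e)
        rules[name] = entries
    return {
        "parameters": list(space.parameter_names),
        "critical_sets": [_sorted_names(space, s) for s in space.critical_sets],
        "swap_sets": [_sorted_names(space, s) for s in space.swap_sets],
        "fixed": {n: float(space.fixed_values[n])
                  for n in _sorted_names(space, space.fixed_values)},
        "default_rules": rules,
        "bounds": {n: [float(b) for b in space.bounds[n]]
                   for n in _sorted_names(space, space.bounds)},
    }


def space_from_dict(data: Mapping) -> ParameterSpace:
    if "parameters" not in data:
        raise ModelSpaceError("space config must define 'parameters'")
    rules = {}
    for name, entries in (data.get("default_rules") or {}).items():
        parsed = []
        for e in entries:
            if "ref" in e and "value" in e:
                raise ModelSpaceError(
                    f"default rule for {name!r} has both 'ref' and 'value'"
                )
            if "ref" in e:
                target: float | str = e["ref"]
            elif "value" in e:
                target = float(e["value"])
            else:
                raise ModelSpaceError(
                    f"default rule for {name!r} needs 'ref' or 'value': {e}"
                )
            guard = e.get("only_if_any")
            parsed.append(
                DefaultRule(target, only_if_any=frozenset(guard) if guard else None)
            )
        rules[name] = tuple(parsed)
    return ParameterSpace(
        parameter_names=tuple(data["parameters"]),
        critical_sets=[set(s) for s in data.get("critical_sets") or []],
        swap_sets=[set(s) for s in data.get("swap_sets") or []],
        fixed_values=dict(data.get("fixed") or {}),
        default_rules=rules,
        bounds={k: tuple(v) for k, v in (data.get("bounds") or {}).items()},
    )


def write_space_config(space: ParameterSpace, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(space_to_dict(space), fh, sort_keys=False)


def read_space_config(path) -> ParameterSpace:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return space_from_dict(data)
    except ModelSpaceError as exc:
        raise ModelSpaceError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def history_to_frame(history: Mapping[str, FitRecord], space: ParameterSpace) -> pd.DataFrame:
    rows = []
    for key in sorted(history):
        rec = history[key]
        row = {
            "model": key,
            "ic_type": rec.ic_type,
            "ic_value": rec.ic_value,
            "minus2LL": rec.minus2LL,
            "k": rec.k,
            "n": rec.n,
            "converged": rec.converged,
        }
        for i, name in enumerate(space.parameter_names):
            row[name] = float(rec.parameters[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_history(history: Mapping[str, FitRecord], space: ParameterSpace, path) -> None:
    df = history_to_frame(history, space)
    # repr-precision floats so ic values survive a round trip bit-for-bit
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_history(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"model": str})


def write_iterations(iterations: list[IterationRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump([vars(it) for it in iterations], fh, indent=2)


def write_best_model(result: SearchResult, space: ParameterSpace, path) -> None:
    best = result.best
    payload = {
        "model": str(best.model),
        "ic_type": best.ic_type,
        "ic_value": best.ic_value,
        "minus2LL": None if not np.isfinite(best.minus2LL) else best.minus2LL,
        "k": best.k,
        "n": best.n,
        "estimates": {
            name: float(best.parameters[space.index(name)])
            for name in best.model.included_names(space)
        },
        "start": result.start,
        "meta": result.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_weights(weights: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"parameter": list(weights), "support": list(weights.values())}
    ).to_csv(path, index=False)
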