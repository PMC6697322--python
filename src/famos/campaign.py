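"""Multi-run driver: repeated searches restarted at the most distant model.

A single search is local, so its endpoint can depend on where it
started.  A *campaign* runs several searches in sequence, always
seeding the next run with the model most distant (in Hamming terms)
from everything any previous run has tested, merges the histories
(best fit per model), and pools the Akaike support across the whole
campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .criteria import FitRecord, akaike_weights
from .model_space import ModelId, ParameterSpace
from .search_engine import SearchOptions, SearchResult, run_famos

__all__ = ["CampaignResult", "run_campaign"]


@dataclass
class CampaignResult:
    """Pooled outcome of several sequential search runs."""

    best: FitRecord
    runs: list[SearchResult]
    history: dict[str, FitRecord]      # merged, best fit per model
    weights: dict[str, float]          # pooled per-parameter Akaike support
    meta: dict = field(default_factory=dict)


def run_campaign(
    space: ParameterSpace,
    cost_fn: Callable[[np.ndarray], float],
    options: SearchOptions,
    n_runs: int = 5,
) -> CampaignResult:
    """Execute ``n_runs`` sequential searches.

    Run 1 starts according to ``options.start``; every later run starts
    at the most distant model from the union of all previously tested
    models.  Per-run failures are surfaced in the run's metadata
    without aborting the remaining runs.  All randomness derives from
    ``options.fit_options.seed``.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    runs: list[SearchResult] = []
    merged: dict[str, FitRecord] = {}
    tested: list[ModelId] = []
    for k in range(n_runs):
        opts = replace(options, start=options.start if k == 0 else "most_distant")
        try:
            res = run_famos(space, cost_fn, opts, prior_tested=tested or None)
        except Exception as exc:  # surface, continue with remaining runs
            runs.append(
                SearchResult(
                    best=None, history={}, iterations=[], weights={},
                    start="", meta={"failed": True, "error": str(exc), "run": k},
                )
            )
            continue
        runs.append(res)
        for key, rec in res.history.items():
            prev = merged.get(key)
            if prev is None or rec.ic_value < prev.ic_value:
                merged[key] = rec
        tested = [rec.model for rec in merged.values()]
    if not merged:
        raise RuntimeError("every campaign run failed")
    best = min(merged.values(), key=lambda r: (r.ic_value, r.k, str(r.model)))
    weights = akaike_weights(list(merged.values()), space).support
    return CampaignResult(
        best=best,
        runs=runs,
        history=merged,
        weights=weights,
        meta={"n_runs": n_runs, "seed": options.fit_options.seed},
    )
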