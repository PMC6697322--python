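"""Information criteria, the dye-dilution cost function, and Akaike-weight
diagnostics.

Model comparison throughout the package is on the scale of an
information criterion (lower is better):

* ``AIC  = -2 ln L + 2k``
* ``AICc = AIC + 2k(k+1) / (n - k - 1)`` (small-sample correction;
  undefined for ``n <= k + 1``)
* ``BIC  = -2 ln L + k ln(n)``

where ``k`` counts the fitted parameters of the sub-model and ``n`` the
data points entering the likelihood.

Akaike weights turn criterion values of a collection of evaluated models
into relative evidence: ``w_m = exp(-Delta_m / 2) / sum exp(-Delta / 2)``
with ``Delta_m = IC_m - min IC``.  The per-parameter *support* sums the
weights of all models that include the parameter, giving an importance
measure in [0, 1] across everything the search evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model_space import ModelId, ParameterSpace

__all__ = [
    "CriterionError",
    "IC_TYPES",
    "information_criterion",
    "dye_dilution_cost",
    "FitRecord",
    "AkaikeWeights",
    "akaike_weights",
]

IC_TYPES = ("AIC", "AICc", "BIC")


class CriterionError(ValueError):
    """Invalid criterion request (e.g. AICc with too few data points)."""


def information_criterion(minus2ll: float, k: int, n: int, ic_type: str = "AICc") -> float:
    """Evaluate an information criterion from a -2 log-likelihood value.

    Raises :class:`CriterionError` for AICc when ``n <= k + 1`` (the
    correction term would blow up); the caller must handle this case
    explicitly rather than receive a silent infinity.
    """
    if ic_type not in IC_TYPES:
        raise CriterionError(f"unknown criterion {ic_type!r}; expected one of {IC_TYPES}")
    k = int(k)
    n = int(n)
    if n < 1:
        raise CriterionError(f"need n >= 1 data points, got {n}")
    if ic_type == "AIC":
        return minus2ll + 2.0 * k
    if ic_type == "BIC":
        return minus2ll + k * math.log(n)
    if n <= k + 1:
        raise CriterionError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return minus2ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def dye_dilution_cost(
    means: np.ndarray,
    sds: np.ndarray,
    predictions: np.ndarray,
    sigma_tilde: float,
) -> float:
    """Weighted least-squares cost for generation-frequency data.

    Twice the negative Gaussian log-likelihood of the replicate means
    (constant ``log(2 pi)`` terms dropped)::

        C = sum_t sum_i ((ybar_i(t) - m_i(t)) / (sigma_i(t) + stilde))^2
            + sum_t sum_i log((sigma_i(t) + stilde)^2)

    ``sigma_tilde`` floors the empirical standard deviations, guarding
    against cells where a handful of replicates happen to agree almost
    exactly; it is normally estimated alongside the model parameters.
    All three arrays must be aligned on the same (time, generation)
    grid; multiple environments are handled by summing this function
    over them.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if not (means.shape == sds.shape == predictions.shape):
        raise CriterionError(
            f"misaligned grids: means {means.shape}, sds {sds.shape}, "
            f"predictions {predictions.shape}"
        )
    denom = sds + sigma_tilde
    if np.any(denom <= 0):
        cell = tuple(int(c) for c in np.unravel_index(int(np.argmin(denom)), denom.shape))
        raise CriterionError(
            f"nonpositive sigma + sigma_tilde = {denom[cell]:g} at grid cell {cell}"
        )
    resid = (means - predictions) / denom
    return float(np.sum(resid**2) + np.sum(np.log(denom**2)))


@dataclass
class FitRecord:
    """Outcome of fitting one sub-model.

    ``parameters`` is the *full* resolved global parameter vector (in
    space order), so excluded parameters carry their default values.
    ``minus2LL`` is NaN when the cost function returns the criterion
    directly instead of a -2 log-likelihood.
    """

    model: "ModelId"
    parameters: np.ndarray
    minus2LL: float
    k: int
    n: int | None
    ic_value: float
    ic_type: str
    meta: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.meta.get("converged", False))


@dataclass
class AkaikeWeights:
    """Per-model Akaike weights and per-parameter support."""

    weights: dict[str, float]          # model string -> weight
    support: dict[str, float]          # parameter name -> summed weight
    deltas: dict[str, float]           # model string -> IC - min IC


def akaike_weights(
    records: Sequence[FitRecord],
    space: "ParameterSpace",
) -> AkaikeWeights:
    """Akaike weights across a collection of evaluated models.

    Only records with finite criterion values participate.  If several
    records share a model, the best (lowest IC) is kept.  Weights are
    invariant to adding a constant to every IC value and sum to one;
    support of a parameter included in every model is exactly one.
    """
    best: dict[str, FitRecord] = {}
    for rec in records:
        if not np.isfinite(rec.ic_value):
            continue
        key = str(rec.model)
        if key not in best or rec.ic_value < best[key].ic_value:
            best[key] = rec
    if not best:
        raise CriterionError("no finite criterion values to weight")
    keys = sorted(best)
    ic = np.array([best[k].ic_value for k in keys])
    delta = ic - ic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    weights = dict(zip(keys, map(float, w)))
    support = {}
    for j, name in enumerate(space.parameter_names):
        support[name] = float(
            sum(weights[k] for k in keys if best[k].model.alpha[j] == 1)
        )
    return AkaikeWeights(
        weights=weights,
        support=support,
        deltas=dict(zip(keys, map(float, delta))),
    )
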