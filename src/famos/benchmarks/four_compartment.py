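"""Four-compartment population benchmark.

Compartments A, B, C, D with multiplication rate ``rho_X`` inside
compartment X and transition rate ``mu_XY`` from X to Y, giving a
16-parameter global model (4 rho + 12 mu) whose sub-models form a
space of 2^16 - 1 = 65535 candidates.  The data-generating truth is
the 5-parameter chain::

    mu_AB = 0.1, rho_B = 0.1, mu_BC = 0.05, mu_BD = 0.2, rho_C = 0.1

started from A0 = 100 cells (arbitrary units of time and count).

Deterministic trajectories are the matrix-exponential solution of the
linear ODE system; synthetic data come from a stochastic Gillespie
simulation with adaptive tau-leaping, where each of 30 equidistant
time points is sampled from 10 *fresh, independent* trajectories so
measurement points are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .._linalg import expm_small
from ..model_space import ModelId, ParameterSpace

__all__ = [
    "COMPARTMENTS",
    "PARAM_NAMES",
    "TRUE_VALUES",
    "true_model",
    "rate_matrix",
    "solve",
    "build_space",
    "FourCompartmentDataset",
    "noiseless_dataset",
    "gillespie_dataset",
    "FourCompartmentCost",
]

COMPARTMENTS = ("A", "B", "C", "D")
RHO_NAMES = tuple(f"rho_{c}" for c in COMPARTMENTS)
MU_NAMES = tuple(
    f"mu_{x}{y}" for x in COMPARTMENTS for y in COMPARTMENTS if x != y
)
PARAM_NAMES = RHO_NAMES + MU_NAMES

TRUE_VALUES: dict[str, float] = {
    "mu_AB": 0.1,
    "rho_B": 0.1,
    "mu_BC": 0.05,
    "mu_BD": 0.2,
    "rho_C": 0.1,
}

X0 = np.array([100.0, 0.0, 0.0, 0.0])
DEFAULT_HORIZON = 10.0  # spans growth of B/C and near-depletion of A at the true rates
DEFAULT_N_TIME_POINTS = 30
DEFAULT_REPS = 10


def build_space(swap_mode: str = "none") -> ParameterSpace:
    """The 16-parameter benchmark space.

    ``swap_mode`` selects the swap sets: ``"none"`` (no swap move),
    ``"influx"`` (for each compartment X the structurally similar
    parameters that *increase* X: its own multiplication plus all
    inflows), ``"efflux"`` (multiplication plus all *outflows* — the
    deliberately mis-specified grouping), or ``"all"`` (one set of all
    16 parameters).
    """
    if swap_mode == "none":
        swap_sets: list[set[str]] = []
    elif swap_mode == "influx":
        swap_sets = [
            {f"rho_{x}"} | {f"mu_{y}{x}" for y in COMPARTMENTS if y != x}
            for x in COMPARTMENTS
        ]
    elif swap_mode == "efflux":
        swap_sets = [
            {f"rho_{x}"} | {f"mu_{x}{y}" for y in COMPARTMENTS if y != x}
            for x in COMPARTMENTS
        ]
    elif swap_mode == "all":
        swap_sets = [set(PARAM_NAMES)]
    else:
        raise ValueError(f"unknown swap_mode {swap_mode!r}")
    return ParameterSpace(
        parameter_names=PARAM_NAMES,
        swap_sets=swap_sets,
        bounds={name: (0.0, 10.0) for name in PARAM_NAMES},
    )


def true_model(space: ParameterSpace | None = None) -> ModelId:
    """The data-generating 5-parameter structure as a ModelId."""
    space = space or build_space()
    return ModelId.from_names(space, TRUE_VALUES)


def _theta_array(theta) -> np.ndarray:
    if isinstance(theta, Mapping):
        arr = np.zeros(len(PARAM_NAMES))
        idx = {n: i for i, n in enumerate(PARAM_NAMES)}
        for k, v in theta.items():
            arr[idx[k]] = float(v)
        return arr
    arr = np.asarray(theta, dtype=float)
    if arr.shape != (len(PARAM_NAMES),):
        raise ValueError(f"expected {len(PARAM_NAMES)} rates, got shape {arr.shape}")
    return arr


# source/destination compartment index of each mu_XY, in MU_NAMES order
_MU_SRC = np.array([COMPARTMENTS.index(n[3]) for n in MU_NAMES])
_MU_DST = np.array([COMPARTMENTS.index(n[4]) for n in MU_NAMES])
_MU_FLAT = _MU_DST * 4 + _MU_SRC              # unique off-diagonal slots
_SRC_ONEHOT = np.eye(4)[_MU_SRC]              # (12, 4): outflow bookkeeping


def rate_matrix(theta) -> np.ndarray:
    """4x4 generator of the linear system dx/dt = M x.

    ``theta`` is a mapping of rate names (missing rates are zero) or a
    full vector in :data:`PARAM_NAMES` order.
    """
    arr = _theta_array(theta)
    rho, mu = arr[:4], arr[4:]
    m = np.zeros(16)
    m[_MU_FLAT] = mu
    m[::5] = rho - mu @ _SRC_ONEHOT
    return m.reshape(4, 4)


def solve(theta, times, x0: np.ndarray = X0) -> np.ndarray:
    """Deterministic trajectories at the requested time points.

    The system is linear, so the solution is advanced exactly with the
    matrix exponential; repeated gaps (e.g. an equidistant grid) reuse
    a single ``expm`` evaluation.  ``times`` must be increasing and
    start at or after 0.  Returns an array of shape (len(times), 4).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0) or (times.size and times[0] < 0):
        raise ValueError("times must be a 1-D increasing grid starting at >= 0")
    m = rate_matrix(theta)
    out = np.empty((times.size, 4))
    x = np.asarray(x0, dtype=float)
    gaps = np.round(np.diff(times, prepend=0.0), 12)
    propagators = {gap: expm_small(m * gap) for gap in np.unique(gaps) if gap > 0}
    for i, gap in enumerate(gaps):
        if gap > 0:
            x = propagators[gap] @ x
        out[i] = x
    return out


# ---------------------------------------------------------------------------
# stochastic simulation (Gillespie with adaptive tau-leaping)
# ---------------------------------------------------------------------------

def _reaction_arrays(theta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(stoichiometry (R,4), rate constants (R,), source index (R,)).

    Reactions: X -> 2X with propensity rho_X * X, and X -> Y with
    propensity mu_XY * X.  Zero-rate reactions are dropped.
    """
    d = dict(zip(PARAM_NAMES, _theta_array(theta)))
    nu, c, src = [], [], []
    for i, x in enumerate(COMPARTMENTS):
        if d[f"rho_{x}"] > 0:
            v = np.zeros(4)
            v[i] = 1
            nu.append(v)
            c.append(d[f"rho_{x}"])
            src.append(i)
        for j, y in enumerate(COMPARTMENTS):
            if x != y and d[f"mu_{x}{y}"] > 0:
                v = np.zeros(4)
                v[i] = -1
                v[j] = 1
                nu.append(v)
                c.append(d[f"mu_{x}{y}"])
                src.append(i)
    if not nu:
        return np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=int)
    return np.array(nu), np.array(c), np.array(src, dtype=int)


def simulate_counts(
    theta,
    t_end: float,
    rng: np.random.Generator,
    x0: np.ndarray = X0,
    eps: float = 0.03,
    ssa_threshold: float = 10.0,
) -> np.ndarray:
    """One stochastic trajectory, returning the state at ``t_end``.

    Adaptive tau-leaping: the leap is bounded so that the expected
    relative change of every population stays around ``eps``; when the
    candidate leap is shorter than a few exact-SSA steps the simulator
    falls back to exact SSA, and a leap that would drive any count
    negative is halved and redrawn.  Counts can therefore never go
    negative.
    """
    nu, c, src = _reaction_arrays(theta)
    x = np.array(np.rint(x0), dtype=np.int64)
    if np.any(x < 0):
        raise ValueError("initial counts must be non-negative integers")
    t = 0.0
    nu_int = nu.astype(np.int64)
    nu_sq = nu**2
    while t < t_end and len(c):
        a = c * x[src]
        a0 = float(a.sum())
        if a0 == 0.0:
            break
        mu = a @ nu
        var = a @ nu_sq
        with np.errstate(divide="ignore", invalid="ignore"):
            bound = np.maximum(eps * x, 1.0)
            tau_mu = np.where(mu != 0, bound / np.abs(mu), np.inf)
            tau_var = np.where(var > 0, bound**2 / var, np.inf)
        tau = float(min(tau_mu.min(), tau_var.min(), t_end - t))
        if tau < ssa_threshold / a0:
            # exact SSA burst
            for _ in range(50):
                a = c * x[src]
                a0 = float(a.sum())
                if a0 == 0.0:
                    return x
                dt = rng.exponential(1.0 / a0)
                if t + dt > t_end:
                    return x
                t += dt
                j = int(rng.choice(len(a), p=a / a0))
                x += nu_int[j]
            continue
        while True:
            k = rng.poisson(a * tau)
            dx = k @ nu_int
            if np.all(x + dx >= 0):
                break
            tau /= 2.0  # retry with a smaller leap; never go negative
        x += dx
        t += tau
    return x


@dataclass
class FourCompartmentDataset:
    """Per-time-point means (and SDs) over replicate simulations."""

    times: np.ndarray
    means: np.ndarray  # (T, 4)
    sds: np.ndarray    # (T, 4)
    replicates: np.ndarray | None = None  # (T, reps, 4) raw samples
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        """Number of mean data cells entering the cost."""
        return int(self.means.size)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            for j, comp in enumerate(COMPARTMENTS):
                rows.append(
                    {"time": t, "compartment": comp,
                     "mean": self.means[i, j], "sd": self.sds[i, j]}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FourCompartmentDataset":
        df = pd.read_csv(path)
        times = np.sort(df["time"].unique())
        means = np.empty((times.size, 4))
        sds = np.empty((times.size, 4))
        for i, t in enumerate(times):
            sub = df[df["time"] == t].set_index("compartment")
            for j, comp in enumerate(COMPARTMENTS):
                means[i, j] = sub.loc[comp, "mean"]
                sds[i, j] = sub.loc[comp, "sd"]
        return cls(times=times, means=means, sds=sds)


def _time_grid(horizon: float, n_time_points: int) -> np.ndarray:
    # equidistant, excluding t=0 (the initial state carries no information)
    return np.linspace(0.0, horizon, n_time_points + 1)[1:]


def noiseless_dataset(
    theta: Mapping[str, float] | None = None,
    horizon: float = DEFAULT_HORIZON,
    n_time_points: int = DEFAULT_N_TIME_POINTS,
) -> FourCompartmentDataset:
    """ODE-exact means with zero SDs; the idealised-data benchmark."""
    theta = TRUE_VALUES if theta is None else theta
    times = _time_grid(horizon, n_time_points)
    means = solve(theta, times)
    return FourCompartmentDataset(
        times=times, means=means, sds=np.zeros_like(means),
        meta={"kind": "noiseless", "theta": dict(theta)},
    )


def gillespie_dataset(
    theta: Mapping[str, float] | None = None,
    horizon: float = DEFAULT_HORIZON,
    n_time_points: int = DEFAULT_N_TIME_POINTS,
    reps_per_point: int = DEFAULT_REPS,
    seed: int = 0,
) -> FourCompartmentDataset:
    """Stochastic benchmark dataset.

    For each of the equidistant time points, ``reps_per_point`` fresh
    trajectories are simulated from t = 0 and their states at that
    time are recorded, so the measurements at different time points
    are statistically independent.  Seed-reproducible.
    """
    theta = TRUE_VALUES if theta is None else theta
    times = _time_grid(horizon, n_time_points)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    raw = np.empty((times.size, reps_per_point, 4))
    for i, t in enumerate(times):
        for r in range(reps_per_point):
            raw[i, r] = simulate_counts(theta, float(t), rng)
    return FourCompartmentDataset(
        times=times,
        means=raw.mean(axis=1),
        sds=raw.std(axis=1, ddof=1),
        replicates=raw,
        meta={"kind": "gillespie", "seed": int(seed), "theta": dict(theta)},
    )


@dataclass
class FourCompartmentCost:
    """-2 log-likelihood of a candidate rate vector against a dataset.

    Gaussian likelihood of the per-time-point means with empirical SDs
    floored by a scale parameter ``sigma_tilde`` (count units)::

        sum ((mean - model) / (sd + st))^2 + sum log((sd + st)^2)

    ``sigma_tilde`` is profiled out exactly at every evaluation: for
    fixed predictions the expression is minimised over ``st`` within
    ``sigma_tilde_bounds`` by a bounded 1-D search on the log scale.
    The scale parameter is common to every candidate model, so it drops
    out of model comparisons and is not counted in ``k``.  The default
    lower bound of one count is the resolution of integer count data;
    it also keeps the likelihood proper on noiseless data (zero SDs and
    zero residuals would otherwise send it to -infinity).

    The object is picklable, so candidate fits can run in worker
    processes.
    """

    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    sigma_tilde_bounds: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        gaps = np.round(np.diff(self.times, prepend=0.0), 12)
        # single-propagator fast path for equidistant grids
        self._dt = float(gaps[0]) if gaps.size and np.all(gaps == gaps[0]) else None
        # The scale profile is evaluated on a fixed log grid whose
        # per-point weight vectors depend only on the dataset, so each
        # cost evaluation reduces to one matrix-vector product plus a
        # parabolic refinement between grid points.
        lo, hi = self.sigma_tilde_bounds
        ugrid = np.linspace(np.log(lo), np.log(hi), 65)
        denom = self.sds.ravel()[None, :] + np.exp(ugrid)[:, None]
        self._inv_denom2 = 1.0 / denom**2
        self._log_terms = 2.0 * np.sum(np.log(denom), axis=1)

    @classmethod
    def from_dataset(cls, ds: FourCompartmentDataset, **kw):
        return cls(times=ds.times, means=ds.means, sds=ds.sds, **kw)

    @property
    def n_data(self) -> int:
        return int(self.means.size)

    def _profiled_scale_cost(self, resid: np.ndarray) -> float:
        """min over sigma_tilde of the weighted cost, residuals fixed."""
        vals = self._inv_denom2 @ resid.ravel() ** 2 + self._log_terms
        i = int(np.argmin(vals))
        if i == 0 or i == vals.size - 1:
            return float(vals[i])
        a, b, c = vals[i - 1], vals[i], vals[i + 1]
        curv = a - 2 * b + c
        if curv <= 0:
            return float(b)
        return float(b - (c - a) ** 2 / (8 * curv))

    def predictions(self, theta_full: np.ndarray) -> np.ndarray:
        if self._dt is not None:
            p = expm_small(rate_matrix(theta_full) * self._dt)
            pred = np.empty_like(self.means)
            x = X0
            for i in range(pred.shape[0]):
                x = p @ x
                pred[i] = x
            return pred
        return solve(theta_full, self.times)

    def __call__(self, theta_full: np.ndarray) -> float:
        return self._profiled_scale_cost(self.means - self.predictions(theta_full))
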