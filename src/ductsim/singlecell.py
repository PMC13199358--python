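"""Single-cell (mean-field) approximation.

Under the symmetry assumption every cell carries the same marginal state
distribution; under the independence assumption correlations between cells
are dropped (interactions are kept).  One step propagates

    P_t(s) = sum_r P_{t-1}(r) * (u_s + rho[s, r] * v)

where, with per-neighbor takeover probability ``w_s = P_{t-1}(s) * tau_s``
and ``|B|`` neighbors,

    u_s = 1 - (1 - w_s)^|B|        (overgrown by some neighbor in state s)
    v   = (1 - sum_q w_q)^|B|      (overgrown by no neighbor at all)

applied only to overgrowable source states ``r``; cancerous and dead cells
follow the intrinsic column alone.  The u/v decomposition double-counts
simultaneous multi-state overgrowth events (an O(p_spr^2) effect), so the
output is renormalized each step; with ``p_spr = 0`` the recursion is the
exact single-cell Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .model import CellModel

__all__ = [
    "StateDistribution",
    "sc_step",
    "evolve_single_cell",
    "count_moments",
    "predicted_count_distribution",
]

_NORM_TOL = 1e-8


@dataclass
class StateDistribution:
    """Marginal distribution of one cell over the model states at time ``t``."""

    probs: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < -1e-12):
            raise ValueError("state distribution has negative entries")
        if abs(self.probs.sum() - 1.0) > _NORM_TOL:
            raise ValueError("state distribution is not normalized")


def _sc_step_probs(p: np.ndarray, model: CellModel, n_neighbors: int) -> np.ndarray:
    w = p * model.spread_weight
    u = 1.0 - (1.0 - w) ** n_neighbors
    v = (1.0 - w.sum()) ** n_neighbors
    og = model.overgrowable
    p_og = p * og
    new = model.intrinsic @ (p * ~og) + v * (model.intrinsic @ p_og) + p_og.sum() * u
    new = np.clip(new, 0.0, None)
    return new / new.sum()


def sc_step(
    dist: StateDistribution, model: CellModel, n_neighbors: int = 4
) -> StateDistribution:
    """Advance the mean-field marginal one timestep."""
    return StateDistribution(
        probs=_sc_step_probs(dist.probs, model, n_neighbors), t=dist.t + 1
    )


def evolve_single_cell(
    model: CellModel,
    t_max: int,
    n_neighbors: int = 4,
    *,
    init: np.ndarray | None = None,
    model_for_step: Callable[[int], CellModel] | None = None,
) -> np.ndarray:
    """Propagate the marginal to ``t_max``; returns ``(t_max+1, k)`` probabilities.

    Starts from all-healthy (point mass on state index 0) unless ``init`` is
    given.  ``model_for_step`` allows per-step parameter switching.
    """
    k = model.k
    p = np.zeros(k) if init is None else np.asarray(init, dtype=float).copy()
    if init is None:
        p[0] = 1.0
    out = np.empty((t_max + 1, k))
    out[0] = p
    for t in range(1, t_max + 1):
        m = model if model_for_step is None else model_for_step(t)
        p = _sc_step_probs(p, m, n_neighbors)
        out[t] = p
    return out


def count_moments(
    p_s: float | np.ndarray, n_cells: int
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Mean and variance of the count ``N_s(t)`` implied by independence.

    ``E[N_s] = N p_s`` and ``Var[N_s] = N p_s (1 - p_s)``: each of the ``N``
    exchangeable cells contributes an independent Bernoulli under the
    single-cell approximation.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    p = np.asarray(p_s, dtype=float)
    mean = n_cells * p
    var = n_cells * p * (1.0 - p)
    if np.ndim(p_s) == 0:
        return float(mean), float(var)
    return mean, var


def predicted_count_distribution(
    p_s: float,
    n_cells: int,
    family: str = "binomial",
    *,
    variance: float | None = None,
) -> np.ndarray:
    """Distribution of ``N_s`` over integer counts ``0..n_cells``.

    ``binomial`` is the exact consequence of the independence assumption.
    ``normal`` discretizes a Gaussian on the integer bins and renormalizes;
    pass ``variance`` to override the binomial variance (used by the pair
    approximation, which corrects the variance for neighbor correlations but
    only provides moments).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    support = np.arange(n_cells + 1)
    if family == "binomial":
        pmf = stats.binom.pmf(support, n_cells, p_s)
    elif family in ("normal", "discretized-normal"):
        mean = n_cells * p_s
        var = n_cells * p_s * (1.0 - p_s) if variance is None else float(variance)
        if var <= 1e-12:
            pmf = np.zeros(n_cells + 1)
            pmf[int(round(np.clip(mean, 0, n_cells)))] = 1.0
            return pmf
        pmf = stats.norm.pdf(support, loc=mean, scale=np.sqrt(var))
    else:
        raise ValueError(f"unknown count-distribution family {family!r}")
    total = pmf.sum()
    if total <= 0.0:
        raise ValueError("degenerate predicted count distribution")
    return pmf / total
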