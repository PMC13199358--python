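"""Neighboring-cells (pair) approximation with the decoherence closure.

The pair method keeps, besides the single-cell marginal, the joint
distribution of an ordered pair of adjacent cells.  Joints of longer chains
factor, by the decoherence assumption, as products of consecutive pair
probabilities over interior marginals (a Markov chain along the path):

    P(y_1, ..., y_m) = prod_i P(y_i, y_{i+1}) / prod_interior P(y_i)

One pair step updates each cell of the pair with a conditional kernel
``T(a | r; y)``: the partner's previous state ``y`` is known exactly, the
three remaining neighbors are drawn independently from the conditional
neighbor distribution ``P(z | center = r)`` implied by the pair table, and
the competing-rates local rule is averaged exactly over those neighbor
configurations (no independent-firing shortcut, so the kernel is the true
conditional expectation of the lattice update under the closure).  The
joint then updates as ``P'(a,b) = sum_{r,y} P(r,y) T(a|r;y) T(b|y;r)``,
which keeps the pair table symmetric and exactly marginal-consistent.  With
``p_spr = 0`` the method collapses to the exact single-cell Markov chain
with independent pairs.

The count variance uses chain correlations up to a truncation distance D
(default 4), with ``M_d = 4 d`` cells at lattice distance ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import CellModel

__all__ = [
    "PairDistribution",
    "VarianceConfig",
    "ClosureDegeneracyError",
    "initial_pair",
    "decoherence_join",
    "pair_step",
    "evolve_pair",
    "truncated_variance",
]

_MARGIN_TOL = 1e-8


class ClosureDegeneracyError(ZeroDivisionError):
    """A zero interior marginal carries nonzero adjacent pair mass."""


@dataclass
class PairDistribution:
    """Singles and ordered-neighbor-pair joints at time ``t``.

    Invariants: the pair table is symmetric (all cells are statistically
    identical), non-negative, sums to one, and both of its marginals equal
    ``singles``.
    """

    singles: np.ndarray
    pairs: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.singles = np.asarray(self.singles, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=float)
        k = self.singles.shape[0]
        if self.pairs.shape != (k, k):
            raise ValueError("pair table shape does not match singles")
        if np.any(self.pairs < -1e-12) or abs(self.pairs.sum() - 1.0) > _MARGIN_TOL:
            raise ValueError("pair table must be a normalized distribution")
        if not np.allclose(self.pairs, self.pairs.T, atol=_MARGIN_TOL):
            raise ValueError("pair table must be symmetric")
        if not np.allclose(self.pairs.sum(axis=1), self.singles, atol=_MARGIN_TOL):
            raise ValueError("pair marginals must match singles")

    @property
    def k(self) -> int:
        return self.singles.shape[0]


def initial_pair(model: CellModel, init_state: int | str = 0) -> PairDistribution:
    """All cells surely in ``init_state`` (all-healthy start)."""
    k = model.k
    i = model.index(init_state)
    singles = np.zeros(k)
    singles[i] = 1.0
    pairs = np.outer(singles, singles)
    return PairDistribution(singles=singles, pairs=pairs, t=0)


def decoherence_join(
    path: Sequence[int],
    pairs: np.ndarray,
    singles: np.ndarray,
    *,
    floor: float = 1e-15,
) -> float:
    """Joint probability of a chain of states under the decoherence closure.

    ``path`` lists state indices along consecutive neighboring cells; the
    joint is the product of consecutive pair probabilities divided by the
    interior singleton probabilities.
    """
    path = list(path)
    if len(path) < 2:
        raise ValueError("chain must contain at least two cells")
    num = 1.0
    for a, b in zip(path[:-1], path[1:]):
        num *= pairs[a, b]
    den = 1.0
    for y in path[1:-1]:
        m = singles[y]
        if m <= floor:
            if num > floor:
                raise ClosureDegeneracyError(
                    f"interior state {y} has zero marginal but nonzero pair mass"
                )
            return 0.0
        den *= m
    return num / den


def _conditional_neighbor(pd_pairs: np.ndarray, singles: np.ndarray, floor: float) -> np.ndarray:
    """``cond[r, z] = P(neighbor = z | center = r)``; degenerate rows fall back to singles."""
    cond = np.empty_like(pd_pairs)
    for r in range(pd_pairs.shape[0]):
        m = singles[r]
        if m > floor:
            cond[r] = pd_pairs[r] / m
        else:
            cond[r] = singles
    # guard tiny negative / renormalize rows
    cond = np.clip(cond, 0.0, None)
    rowsum = cond.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0.0] = 1.0
    return cond / rowsum


def _outer_multisets(k: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """All multisets of ``m`` neighbor states over ``k`` states.

    Returns the ``(n_ms, m)`` state combinations and their multinomial
    multiplicities.  Cached per ``(k, m)``.
    """
    key = (k, m)
    cached = _outer_multisets._cache.get(key)
    if cached is not None:
        return cached
    from itertools import combinations_with_replacement
    from math import factorial

    combos = list(combinations_with_replacement(range(k), m))
    states = np.array(combos, dtype=np.int64)
    mult = np.empty(len(combos))
    for i, c in enumerate(combos):
        denom = 1
        for s in set(c):
            denom *= factorial(c.count(s))
        mult[i] = factorial(m) // denom
    _outer_multisets._cache[key] = (states, mult)
    return states, mult


_outer_multisets._cache = {}


def _pair_kernel(
    pd: PairDistribution, model: CellModel, n_neighbors: int, floor: float
) -> np.ndarray:
    """Conditional update kernel ``T[a, r, y]`` for a cell in state ``r`` whose
    one known neighbor (the partner) is in state ``y``.

    Averages the competing-rates local rule exactly over the ``n_neighbors-1``
    outer neighbors, drawn iid from ``P(z | r)``: for an outer configuration
    with total spreading weight ``W_out`` the cell follows
    ``gamma * (intrinsic + outer takeovers + partner takeover)`` with
    ``gamma = 1 / (1 + W_out + tau_y)``.
    """
    k = model.k
    tau = model.spread_weight
    rho = model.intrinsic
    cond = _conditional_neighbor(pd.pairs, pd.singles, floor)

    m = n_neighbors - 1  # outer neighbors beyond the partner
    ms_states, ms_mult = _outer_multisets(k, m)       # (n_ms, m), (n_ms,)
    q = np.prod(cond[:, ms_states], axis=2) * ms_mult  # (r, n_ms)
    w_out = tau[ms_states].sum(axis=1)                 # (n_ms,)
    # counts[i, s] = number of outer neighbors in state s for multiset i
    counts = np.zeros((ms_states.shape[0], k))
    for col in range(m):
        np.add.at(counts, (np.arange(ms_states.shape[0]), ms_states[:, col]), 1.0)

    gamma = 1.0 / (1.0 + w_out[:, None] + tau[None, :])  # (n_ms, y)
    g = q @ gamma                                        # G[r, y]
    h = np.einsum("ri,iy,ia->ary", q, gamma, counts * tau[None, :])

    t_kern = rho[:, :, None] * g[None, :, :] + h
    # partner takeover: a == y picks up tau_y * G[r, y]
    idx = np.arange(k)
    t_kern[idx, :, idx] += (tau[:, None] * g.T)  # (y, r)
    # non-overgrowable current states follow the intrinsic column alone
    og = model.overgrowable
    t_kern[:, ~og, :] = rho[:, ~og][:, :, None]
    t_kern = np.clip(t_kern, 0.0, None)
    t_kern /= t_kern.sum(axis=0, keepdims=True)
    return t_kern


def _pair_step_table(
    pd: PairDistribution, model: CellModel, n_neighbors: int, floor: float
) -> np.ndarray:
    """One step on the raw pair table (hot path, no dataclass validation)."""
    t_kern = _pair_kernel(pd, model, n_neighbors, floor)
    new_pairs = np.einsum("ry,ary,byr->ab", pd.pairs, t_kern, t_kern)
    new_pairs = np.clip(new_pairs, 0.0, None)
    new_pairs = 0.5 * (new_pairs + new_pairs.T)
    return new_pairs / new_pairs.sum()


def _unchecked_pair(pairs: np.ndarray, t: int) -> PairDistribution:
    pd = object.__new__(PairDistribution)
    object.__setattr__(pd, "singles", pairs.sum(axis=1))
    object.__setattr__(pd, "pairs", pairs)
    object.__setattr__(pd, "t", t)
    return pd


def pair_step(
    pd: PairDistribution,
    model: CellModel,
    n_neighbors: int = 4,
    *,
    floor: float = 1e-15,
) -> PairDistribution:
    """Advance singles and neighbor-pair joints one timestep."""
    new_pairs = _pair_step_table(pd, model, n_neighbors, floor)
    return PairDistribution(
        singles=new_pairs.sum(axis=1), pairs=new_pairs, t=pd.t + 1
    )


def evolve_pair(
    model: CellModel,
    t_max: int,
    n_neighbors: int = 4,
    *,
    model_for_step: Callable[[int], CellModel] | None = None,
    floor: float = 1e-15,
) -> tuple[np.ndarray, PairDistribution]:
    """Propagate from the all-healthy start; returns the ``(t_max+1, k)``
    singles trajectory and the final :class:`PairDistribution`."""
    pd = initial_pair(model)
    out = np.empty((t_max + 1, model.k))
    out[0] = pd.singles
    for t in range(1, t_max + 1):
        m = model if model_for_step is None else model_for_step(t)
        pd = _unchecked_pair(_pair_step_table(pd, m, n_neighbors, floor), t)
        out[t] = pd.singles
    # re-validate the final state through the public constructor
    pd = PairDistribution(singles=pd.singles, pairs=pd.pairs, t=pd.t)
    return out, pd


@dataclass(frozen=True)
class VarianceConfig:
    """Truncation of the count-variance correlation sum.

    ``max_distance`` is the largest lattice distance D whose correlations are
    kept; on the four-neighbor cylinder there are ``M_d = 4 d`` cells at
    distance ``d``.
    """

    max_distance: int = 4

    def n_at_distance(self, d: int) -> int:
        return 4 * d

    def __post_init__(self) -> None:
        if self.max_distance < 1:
            raise ValueError("max_distance must be at least 1")


def truncated_variance(
    pd: PairDistribution,
    state: int | str,
    n_cells: int,
    cfg: VarianceConfig = VarianceConfig(),
    *,
    floor: float = 1e-15,
) -> float:
    """Variance of ``N_s(t)`` with chain correlations up to distance D.

    The independent-cells term ``N p_s (1 - p_s)`` is corrected by, for each
    distance ``d <= D``, ``M_d`` times the excess of the closed chain
    probability ``P(X_1 = s, X_{1+d} = s)`` (evaluated through the
    decoherence chain product) over ``p_s^2``.  With an independent pair
    table every correction vanishes exactly.
    """
    if isinstance(state, str):
        raise TypeError("pass a state index; labels belong to the calling model")
    s = int(state)
    p_s = pd.singles[s]
    base = p_s - p_s * p_s

    safe = np.where(pd.singles > floor, pd.singles, 1.0)
    bad = (pd.singles <= floor) & (pd.pairs.sum(axis=1) > floor)
    if np.any(bad):
        raise ClosureDegeneracyError("zero marginal with nonzero pair mass")
    kmat = pd.pairs / safe[:, None]  # kmat[y, y'] = P(y' | y)

    correction = 0.0
    acc = pd.pairs.copy()  # acc = pairs @ kmat^{d-1}
    for d in range(1, cfg.max_distance + 1):
        correction += cfg.n_at_distance(d) * (acc[s, s] - p_s * p_s)
        acc = acc @ kmat
    return float(max(n_cells * (base + correction), 0.0))
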