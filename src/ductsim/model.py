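"""Core lattice cell model: states, parameters, topology and the local update rule.

The milk duct is idealized as a single layer of epithelial cells on a
cylindrical square lattice (a ring of ``circumference`` cells stacked in
``n_rings`` layers).  Each cell is in one of nine states: healthy (``H``),
carrying 1..6 growth-relevant mutations (``M1``..``M6``), cancerous (``C``,
absorbing -- the seventh mutation), or dead (``D``, replaced by a healthy
cell at the next renewal step).

Two mechanisms drive the dynamics per (monthly) timestep:

* *intrinsic* transitions -- with probability ``p_mut`` a cell acquires the
  next growth-relevant mutation, with probability ``p_die`` it dies, and it
  keeps its state with probability ``s = 1 - (p_mut + p_die)``;
* *overgrowth* -- a mutated neighbor in state ``M_n`` replaces the cell with
  weight ``n * p_spr`` (growth-promoting mutations spread; cancerous cells do
  not spread since a single surviving cancerous cell already decides the
  outcome).

Competition between the intrinsic transition and overgrowth by the
neighborhood is resolved by competing-rates normalization: with total
spreading weight ``W`` from the neighbors, the intrinsic column is damped by
``gamma = 1 / (1 + W)`` and each neighbor takes the cell over with
probability ``gamma * n * p_spr``.  Cancerous and dead cells cannot be
overgrown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "STATE_LABELS",
    "ParameterError",
    "TopologyError",
    "ModelParams",
    "TransitionTables",
    "CellModel",
    "Lattice",
    "Exposure",
    "Scenario",
    "build_intrinsic",
    "nine_state_model",
    "local_update_distribution",
]

#: State labels of the nine-state model, in canonical order.
STATE_LABELS: tuple[str, ...] = ("H", "M1", "M2", "M3", "M4", "M5", "M6", "C", "D")


class ParameterError(ValueError):
    """A transition probability lies outside its admissible domain."""


class TopologyError(ValueError):
    """A neighborhood does not match the lattice topology."""


@dataclass(frozen=True)
class ModelParams:
    """Per-timestep transition probabilities of a single cell.

    Parameters
    ----------
    p_mut
        Probability per timestep that the next growth-relevant mutation
        occurs and is stable.
    p_die
        Probability per timestep that the cell dies (apoptosis, mitotic
        catastrophe, immune removal).
    p_spr
        Spreading probability per unit mutation count: a neighbor in state
        ``M_n`` overgrows the cell with weight ``n * p_spr``.
    """

    p_mut: float
    p_die: float
    p_spr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_mut", "p_die", "p_spr"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v!r} must lie in [0, 1]")
        if self.p_mut + self.p_die > 1.0 + 1e-12:
            raise ParameterError(
                f"p_mut + p_die = {self.p_mut + self.p_die} exceeds 1"
            )

    @property
    def s(self) -> float:
        """Stay probability ``1 - (p_mut + p_die)``; always derived, never stored."""
        return 1.0 - (self.p_mut + self.p_die)


@dataclass(frozen=True)
class TransitionTables:
    """Intrinsic transition matrix and per-state spreading weights.

    ``intrinsic[new, old]`` is column-stochastic; ``spreading_weight[s]`` is
    the per-neighbor takeover weight of a neighbor in state ``s`` (``n*p_spr``
    for ``M_n``, zero for ``H``, ``C`` and ``D``).
    """

    intrinsic: np.ndarray
    spreading_weight: np.ndarray


def build_intrinsic(params: ModelParams) -> TransitionTables:
    """Build the nine-state intrinsic transition table.

    Columns (old state) map as: ``H -> {H: s, M1: p_mut, D: p_die}``;
    ``M_n -> {M_n: s, M_{n+1}: p_mut, D: p_die}`` for n < 6;
    ``M6 -> {M6: s, C: p_mut, D: p_die}``; ``C -> {C: 1}`` (absorbing);
    ``D -> {H: 1}`` (renewal).
    """
    k = len(STATE_LABELS)
    rho = np.zeros((k, k))
    s = params.s
    for i in range(7):  # H, M1..M6
        rho[i, i] = s
        rho[i + 1, i] = params.p_mut  # next mutation stage (M6 -> C at i=6)
        rho[8, i] = params.p_die
    rho[7, 7] = 1.0  # C absorbing
    rho[0, 8] = 1.0  # D renews to H
    weight = np.zeros(k)
    weight[1:7] = params.p_spr * np.arange(1, 7)
    return TransitionTables(intrinsic=rho, spreading_weight=weight)


@dataclass(frozen=True)
class CellModel:
    """A state space with intrinsic transitions and spreading weights.

    Attributes
    ----------
    states
        State labels, index order fixed.
    intrinsic
        ``(k, k)`` column-stochastic matrix ``intrinsic[new, old]``.
    spread_weight
        ``(k,)`` per-neighbor takeover weight of each source state.
    overgrowable
        ``(k,)`` boolean; whether a cell currently in that state can be
        overgrown by a neighbor.
    """

    states: tuple[str, ...]
    intrinsic: np.ndarray
    spread_weight: np.ndarray
    overgrowable: np.ndarray
    # cumulative intrinsic indexed [old, new], filled in __post_init__
    cum_intrinsic: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        k = len(self.states)
        intr = np.asarray(self.intrinsic, dtype=float)
        if intr.shape != (k, k):
            raise ParameterError("intrinsic table shape does not match state count")
        if np.any(intr < -1e-12) or not np.allclose(intr.sum(axis=0), 1.0, atol=1e-9):
            raise ParameterError("intrinsic table must be column-stochastic")
        object.__setattr__(self, "intrinsic", intr)
        object.__setattr__(
            self, "spread_weight", np.asarray(self.spread_weight, dtype=float)
        )
        object.__setattr__(
            self, "overgrowable", np.asarray(self.overgrowable, dtype=bool)
        )
        object.__setattr__(self, "cum_intrinsic", np.cumsum(intr, axis=0).T.copy())

    @property
    def k(self) -> int:
        return len(self.states)

    def index(self, state: int | str) -> int:
        """Resolve a state label (or pass through an index)."""
        if isinstance(state, str):
            return self.states.index(state)
        return int(state)


def nine_state_model(params: ModelParams) -> CellModel:
    """The nine-state duct model: H/M1..M6 overgrowable, C and D are not."""
    tables = build_intrinsic(params)
    overgrowable = np.array([True] * 7 + [False, False])
    return CellModel(
        states=STATE_LABELS,
        intrinsic=tables.intrinsic,
        spread_weight=tables.spreading_weight,
        overgrowable=overgrowable,
    )


@dataclass(frozen=True)
class Lattice:
    """Cylindrical square lattice: rings of ``circumference`` cells.

    With ``n_rings > 1`` each cell has four neighbors (ring-left, ring-right,
    axial-up, axial-down); ``wrap_axial`` closes the cylinder into a torus so
    boundary rings keep four neighbors too.  A single ring (``n_rings == 1``)
    degenerates to a cycle where each cell has two neighbors.
    """

    circumference: int = 15
    n_rings: int = 1
    wrap_axial: bool = True

    def __post_init__(self) -> None:
        if self.circumference < 3:
            raise TopologyError("circumference must be at least 3")
        if self.n_rings < 1:
            raise TopologyError("n_rings must be at least 1")

    @property
    def n_cells(self) -> int:
        return self.circumference * self.n_rings

    @property
    def degree(self) -> int:
        """Maximum neighbor count (4, or 2 for a single ring)."""
        return 2 if self.n_rings == 1 else 4

    def index(self, ring: int, pos: int) -> int:
        return ring * self.circumference + pos

    def coords(self, i: int) -> tuple[int, int]:
        return divmod(i, self.circumference)

    def neighbors(self, i: int) -> tuple[int, ...]:
        """Neighbor indices of cell ``i``: ring-left, ring-right, axial-up, axial-down."""
        if not 0 <= i < self.n_cells:
            raise TopologyError(f"cell index {i} out of range")
        ring, pos = self.coords(i)
        c = self.circumference
        out = [self.index(ring, (pos - 1) % c), self.index(ring, (pos + 1) % c)]
        if self.n_rings > 1:
            if ring > 0:
                out.append(self.index(ring - 1, pos))
            elif self.wrap_axial:
                out.append(self.index(self.n_rings - 1, pos))
            if ring < self.n_rings - 1:
                out.append(self.index(ring + 1, pos))
            elif self.wrap_axial:
                out.append(self.index(0, pos))
        return tuple(out)

    def neighbor_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded neighbor table: ``(idx, mask)`` of shape ``(n_cells, degree)``.

        Cells with fewer neighbors (open axial ends) are padded with their own
        index and ``mask`` False.
        """
        n, deg = self.n_cells, self.degree
        idx = np.empty((n, deg), dtype=np.int64)
        mask = np.zeros((n, deg), dtype=bool)
        for i in range(n):
            nbs = self.neighbors(i)
            idx[i, : len(nbs)] = nbs
            idx[i, len(nbs):] = i
            mask[i, : len(nbs)] = True
        return idx, mask


def local_update_distribution(
    model: CellModel,
    current: int | str,
    neighbor_states: Sequence[int | str],
    *,
    degree: int = 4,
) -> np.ndarray:
    """One-cell one-step update distribution given the neighborhood.

    For an overgrowable current state with total neighbor spreading weight
    ``W = sum_j tau(neighbor_j)`` and ``gamma = 1/(1+W)``, the result is
    ``gamma * intrinsic_column + gamma * sum_j tau(neighbor_j) e_{state_j}``.
    Cancerous and dead cells return their intrinsic column unchanged.
    """
    cur = model.index(current)
    nbs = [model.index(s) for s in neighbor_states]
    if len(nbs) != degree:
        raise TopologyError(
            f"expected {degree} neighbor states, got {len(nbs)}"
        )
    col = model.intrinsic[:, cur].copy()
    if not model.overgrowable[cur]:
        return col
    w = model.spread_weight[np.asarray(nbs, dtype=np.int64)]
    gamma = 1.0 / (1.0 + w.sum())
    out = gamma * col
    np.add.at(out, np.asarray(nbs, dtype=np.int64), gamma * w)
    return out


@dataclass(frozen=True)
class Exposure:
    """A temporary radiation-exposure window with its own transition set."""

    params: ModelParams
    start_age: float  # years
    duration_steps: int
    dose_gy: float = 0.0


@dataclass(frozen=True)
class Scenario:
    """A full life-course simulation setting.

    ``baseline`` applies at all timesteps except inside the exposure window,
    where ``exposure.params`` applies.  Timesteps are months by default; the
    lattice/tissue size ``n_cells`` is carried here for count statistics.
    """

    baseline: ModelParams
    t_max: int
    n_cells: int = 1_000_000
    timestep_months: float = 1.0
    exposure: Exposure | None = None

    def __post_init__(self) -> None:
        if self.t_max < 0:
            raise ParameterError("t_max must be non-negative")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be positive")
        win = self.exposure_window()
        if win is not None and not (0 <= win[0] and win[1] <= self.t_max + 1):
            raise ParameterError(
                f"exposure window {win} lies outside [0, {self.t_max}]"
            )

    def exposure_window(self) -> tuple[int, int] | None:
        """Half-open step range ``[start, end)`` during which exposure applies."""
        if self.exposure is None:
            return None
        steps_per_year = 12.0 / self.timestep_months
        start = int(round(self.exposure.start_age * steps_per_year))
        return start, start + self.exposure.duration_steps

    def params_at(self, t: int) -> ModelParams:
        """Parameters governing the update into step ``t`` (1-based update index)."""
        win = self.exposure_window()
        if win is not None and win[0] < t <= win[1]:
            return self.exposure.params
        return self.baseline

    def model_for_step(self) -> Callable[[int], CellModel]:
        """A step-indexed nine-state model factory (baseline/exposure switching)."""
        base = nine_state_model(self.baseline)
        if self.exposure is None:
            return lambda t: base
        exposed = nine_state_model(self.exposure.params)
        win = self.exposure_window()
        return lambda t: exposed if win[0] < t <= win[1] else base
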