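"""Synchronous Monte Carlo simulation of the full lattice.

This is the ground-truth engine the approximations are judged against: all
cells draw their next state simultaneously from the local update
distribution applied to the previous configuration.  Each trial owns an
independent RNG stream spawned from the master seed, so trial ``i`` is
reproducible regardless of how many trials are run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import CellModel, Lattice, ParameterError, Scenario

__all__ = [
    "SimulationResult",
    "reduce_two_state",
    "simulate_model",
    "simulate",
    "count_histogram",
]


@dataclass
class SimulationResult:
    """Per-timestep per-state counts of independent lattice replicates.

    ``counts[trial, t, state]`` holds ``N_s(t)``; ``final_config`` (optional)
    keeps the terminal lattice configuration of every trial.
    """

    counts: np.ndarray
    states: tuple[str, ...]
    n_cells: int
    seed: int
    final_config: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def t_max(self) -> int:
        return self.counts.shape[1] - 1

    def state_index(self, state: int | str) -> int:
        if isinstance(state, str):
            return self.states.index(state)
        return int(state)


def reduce_two_state(rho_CH: float, tau_CH: float) -> CellModel:
    """Two-state demo model ``S = {H, C}``.

    ``H`` turns cancerous internally with probability ``rho_CH`` and can be
    overgrown by a cancerous neighbor with weight ``tau_CH``; ``C`` is
    absorbing.  Unlike the nine-state model, ``C`` spreads here -- the demo
    exists to stress the interaction term.
    """
    for name, v in (("rho_CH", rho_CH), ("tau_CH", tau_CH)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name}={v!r} must lie in [0, 1]")
    intrinsic = np.array([[1.0 - rho_CH, 0.0], [rho_CH, 1.0]])
    return CellModel(
        states=("H", "C"),
        intrinsic=intrinsic,
        spread_weight=np.array([0.0, tau_CH]),
        overgrowable=np.array([True, False]),
    )


def _step(
    states: np.ndarray,
    model: CellModel,
    nb_idx: np.ndarray,
    nb_mask: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Advance every cell of every trial one synchronous step.

    ``u`` is one uniform(0,1) draw per cell.  Scaling it to ``(0, 1+W)``
    realizes the competing-rates rule exactly: with probability
    ``gamma = 1/(1+W)`` the cell follows its intrinsic column (and the
    rescaled draw is again uniform), otherwise a neighbor takes over with
    probability proportional to its spreading weight.
    """
    k = model.k
    nbs = states[:, nb_idx]                       # (trials, n, deg)
    w = model.spread_weight[nbs] * nb_mask
    total_w = w.sum(axis=-1) * model.overgrowable[states]
    v = u * (1.0 + total_w)

    cum = model.cum_intrinsic[states]             # (trials, n, k)
    new_intr = np.minimum((v[..., None] > cum).sum(axis=-1), k - 1)

    r = (v - 1.0)[..., None]
    j = np.minimum((r >= np.cumsum(w, axis=-1)).sum(axis=-1), w.shape[-1] - 1)
    new_over = np.take_along_axis(nbs, j[..., None], axis=-1)[..., 0]
    return np.where(v < 1.0, new_intr, new_over)


def simulate_model(
    model: CellModel,
    lattice: Lattice,
    t_max: int,
    n_trials: int,
    seed: int,
    *,
    model_for_step: Callable[[int], CellModel] | None = None,
    record_final: bool = False,
) -> SimulationResult:
    """Simulate ``n_trials`` independent lattices for ``t_max`` steps.

    All cells start healthy (state index 0).  ``model_for_step`` may swap the
    model per step (exposure windows); otherwise ``model`` applies throughout.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be at least 1")
    n, k = lattice.n_cells, model.k
    nb_idx, nb_mask = lattice.neighbor_array()
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_trials)]

    states = np.zeros((n_trials, n), dtype=np.int64)
    counts = np.zeros((n_trials, t_max + 1, k), dtype=np.int64)
    counts[:, 0, 0] = n
    u = np.empty((n_trials, n))
    for t in range(1, t_max + 1):
        m = model if model_for_step is None else model_for_step(t)
        for i, rng in enumerate(rngs):
            u[i] = rng.random(n)
        states = _step(states, m, nb_idx, nb_mask, u)
        for s_idx in range(k):
            counts[:, t, s_idx] = (states == s_idx).sum(axis=1)
    return SimulationResult(
        counts=counts,
        states=model.states,
        n_cells=n,
        seed=seed,
        final_config=states.copy() if record_final else None,
    )


def simulate(
    lattice: Lattice,
    scenario: Scenario,
    n_trials: int,
    seed: int,
    *,
    record_final: bool = False,
) -> SimulationResult:
    """Nine-state life-course simulation with optional exposure window."""
    from .model import nine_state_model

    base = nine_state_model(scenario.baseline)
    return simulate_model(
        base,
        lattice,
        scenario.t_max,
        n_trials,
        seed,
        model_for_step=scenario.model_for_step() if scenario.exposure else None,
        record_final=record_final,
    )


def count_histogram(result: SimulationResult, state: int | str, t: int) -> np.ndarray:
    """Normalized histogram of ``N_state(t)`` over the counts ``0..n_cells``."""
    if not 0 <= t <= result.t_max:
        raise ValueError(f"t={t} outside simulated horizon 0..{result.t_max}")
    if result.n_trials == 0:
        raise ValueError("empty simulation result")
    c = result.counts[:, t, result.state_index(state)]
    hist = np.bincount(c, minlength=result.n_cells + 1).astype(float)
    return hist / hist.sum()
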