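"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's propagation engines: configuration
dynamics are enumerated exhaustively from the local update rule alone.
"""

import itertools

import numpy as np

import ductsim as d


def config_transition_matrix(model: d.CellModel, lattice: d.Lattice) -> tuple[np.ndarray, list]:
    """Exact transition matrix over all k^n lattice configurations.

    Synchronous update: the configuration transition probability is the
    product of the per-cell local update probabilities.
    """
    k, n = model.k, lattice.n_cells
    configs = list(itertools.product(range(k), repeat=n))
    q = np.zeros((len(configs), len(configs)))
    for j, old in enumerate(configs):
        per_cell = [
            d.local_update_distribution(
                model,
                old[i],
                [old[x] for x in lattice.neighbors(i)],
                degree=len(lattice.neighbors(i)),
            )
            for i in range(n)
        ]
        for a, new in enumerate(configs):
            q[a, j] = float(np.prod([per_cell[i][new[i]] for i in range(n)]))
    return q, configs


def exact_config_distribution(
    model: d.CellModel, lattice: d.Lattice, t: int
) -> tuple[np.ndarray, list]:
    """Exact distribution over configurations after ``t`` synchronous steps
    from the all-healthy start."""
    q, configs = config_transition_matrix(model, lattice)
    p0 = np.zeros(len(configs))
    p0[configs.index(tuple([0] * lattice.n_cells))] = 1.0
    return np.linalg.matrix_power(q, t) @ p0, configs
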