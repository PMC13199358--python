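"""Calibration of the transition probabilities to an incidence table.

The three free parameters (p_mut, p_die, p_spr) -- or, for the exposure
experiments, the alternate triple active inside the exposure window -- are
fitted by projected steepest descent on a squared-difference loss between
the predicted and the target incidence table.  The descent runs in
log-parameter space (probabilities span orders of magnitude, and the
boundary p_mut = 0 is a degenerate stationary point of the raw-space loss);
gradients come from central finite differences, a backtracking line search
keeps the loss trace monotone non-increasing, and box constraints (each
parameter in [0, 1], p_mut + p_die <= 1) are enforced by projection after
the exponential map.

The forward model runs one of the deterministic engines (pair approximation
by default) over the lifetime horizon at a 1-month timestep and converts the
per-cell cancer probability into annualized incidence per 100,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .incidence import IncidenceTable, model_to_incidence
from .model import Exposure, ModelParams, ParameterError, Scenario
from .pair import evolve_pair
from .singlecell import evolve_single_cell

__all__ = [
    "FitSpec",
    "FitResult",
    "loss",
    "predict_incidence",
    "steepest_descent_fit",
]


def loss(pred: IncidenceTable, data: IncidenceTable, mode: str = "relative") -> float:
    """Squared-difference loss summed over age groups.

    ``relative``: sum of ((pred - data) / data)^2 (requires positive data);
    ``per-100k``: sum of ((pred - data) / 100000)^2.
    """
    if not pred.same_groups(data):
        raise ValueError("prediction and data tables have different age groups")
    p, d = pred.rates, data.rates
    if mode == "relative":
        if np.any(d <= 0):
            raise ValueError("relative loss undefined for zero data rates")
        return float(np.sum(((p - d) / d) ** 2))
    if mode == "per-100k":
        return float(np.sum(((p - d) / 1e5) ** 2))
    raise ValueError(f"unknown loss mode {mode!r}")


def predict_incidence(
    params: ModelParams,
    groups: IncidenceTable | list[tuple[int, int]],
    *,
    n_cells: int = 1_000_000,
    engine: str = "pair",
    exposure: Exposure | None = None,
    lag: float = 5.0,
    timestep_months: float = 1.0,
    t_max: int | None = None,
) -> IncidenceTable:
    """Deterministic forward prediction of the incidence table.

    Runs the chosen approximation engine from birth (all cells healthy) over
    a horizon covering every age group, switching to the exposure parameter
    set inside the window if one is given.
    """
    bounds = groups.bounds() if isinstance(groups, IncidenceTable) else list(groups)
    max_age = max(hi for _, hi in bounds)
    steps_per_year = 12.0 / timestep_months
    if t_max is None:
        t_max = int(np.ceil((max_age - lag) * steps_per_year)) + 1
    scenario = Scenario(
        baseline=params,
        t_max=t_max,
        n_cells=n_cells,
        timestep_months=timestep_months,
        exposure=exposure,
    )
    model_for_step = scenario.model_for_step()
    model0 = model_for_step(0)
    c_idx = model0.index("C")
    if engine == "pair":
        probs, _ = evolve_pair(model0, t_max, model_for_step=model_for_step)
    elif engine in ("single-cell", "single_cell"):
        probs = evolve_single_cell(model0, t_max, model_for_step=model_for_step)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return model_to_incidence(
        probs[:, c_idx], n_cells, groups, lag=lag, timestep_months=timestep_months
    )


@dataclass
class FitSpec:
    """What to fit, against which table, with which optimizer settings."""

    target: IncidenceTable
    mode: str = "baseline"  # or "exposure"
    n_cells: int = 1_000_000
    engine: str = "pair"
    loss_mode: str = "relative"
    baseline_params: ModelParams | None = None  # required for exposure mode
    exposure_start_age: float = 30.0
    exposure_duration_steps: int = 6
    dose_gy: float = 0.1
    lag: float = 5.0
    timestep_months: float = 1.0
    x0: tuple[float, float, float] = (0.003, 0.3, 0.03)
    h_log: float = 1e-3
    step0: float = 0.15
    max_iter: int = 100
    tol: float = 1e-10
    n_starts: int = 1
    start_spread: float = 0.5  # log-space sd of the seeded restart perturbations
    seed: int = 0
    x_floor: float = 1e-8  # smallest representable probability in log space

    def __post_init__(self) -> None:
        if self.mode not in ("baseline", "exposure"):
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if self.mode == "exposure" and self.baseline_params is None:
            raise ValueError("exposure fits need the calibrated baseline_params")


@dataclass
class FitResult:
    """Fitted parameters with loss trace and the final prediction."""

    params: ModelParams
    loss: float
    predicted: IncidenceTable
    trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _project(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    if x[0] + x[1] > 1.0:
        x[:2] *= (1.0 - 1e-9) / (x[0] + x[1])
    return x


def _params_from_vector(x: np.ndarray) -> ModelParams:
    return ModelParams(p_mut=float(x[0]), p_die=float(x[1]), p_spr=float(x[2]))


def steepest_descent_fit(spec: FitSpec) -> FitResult:
    """Projected steepest descent with central differences and backtracking.

    With ``n_starts > 1`` the descent is repeated from seeded log-normal
    perturbations of ``x0`` (the loss surface has distinct local minima --
    notably a degenerate flat-prediction basin) and the best final loss wins.
    """

    def objective(x: np.ndarray) -> tuple[float, IncidenceTable]:
        params = _params_from_vector(_project(x.copy()))
        if spec.mode == "baseline":
            pred = predict_incidence(
                params,
                spec.target,
                n_cells=spec.n_cells,
                engine=spec.engine,
                lag=spec.lag,
                timestep_months=spec.timestep_months,
            )
        else:
            exposure = Exposure(
                params=params,
                start_age=spec.exposure_start_age,
                duration_steps=spec.exposure_duration_steps,
                dose_gy=spec.dose_gy,
            )
            pred = predict_incidence(
                spec.baseline_params,
                spec.target,
                n_cells=spec.n_cells,
                engine=spec.engine,
                exposure=exposure,
                lag=spec.lag,
                timestep_months=spec.timestep_months,
            )
        return loss(pred, spec.target, spec.loss_mode), pred

    def from_log(z: np.ndarray) -> np.ndarray:
        return _project(np.exp(z))

    def descend(z: np.ndarray) -> FitResult:
        return _descend(spec, objective, from_log, z)

    z0 = np.log(np.clip(np.asarray(spec.x0, dtype=float), spec.x_floor, 1.0))
    best = descend(z0)
    if spec.n_starts > 1:
        rng = np.random.default_rng(spec.seed)
        for _ in range(spec.n_starts - 1):
            z_start = z0 + spec.start_spread * rng.standard_normal(z0.size)
            candidate = descend(np.minimum(z_start, 0.0))
            if candidate.loss < best.loss:
                best = candidate
    return best


def _descend(spec: FitSpec, objective, from_log, z: np.ndarray) -> FitResult:
    x = from_log(z)
    f, pred = objective(x)
    if not np.isfinite(f):
        raise ParameterError("non-finite loss at the initial point")
    trace = [f]
    converged = False
    it = 0
    grad_prev: np.ndarray | None = None
    z_prev: np.ndarray | None = None
    alpha_prev = spec.step0
    for it in range(1, spec.max_iter + 1):
        # central-difference gradient in log space
        grad = np.zeros_like(z)
        for i in range(z.size):
            zp, zm = z.copy(), z.copy()
            zp[i] += spec.h_log
            zm[i] -= spec.h_log
            fp, _ = objective(from_log(zp))
            fm, _ = objective(from_log(zm))
            grad[i] = (fp - fm) / (2.0 * spec.h_log)
        gnorm = float(np.linalg.norm(grad))
        if not np.isfinite(gnorm):
            raise ParameterError("non-finite gradient encountered")
        if gnorm == 0.0:
            converged = True
            break
        # Barzilai-Borwein spectral step (the sloppy-valley loss makes plain
        # normalized descent zigzag); fall back to the warm-started step
        alpha = min(2.0 * alpha_prev, 4.0 * spec.step0)
        direction = -grad / gnorm
        if grad_prev is not None:
            dz = z - z_prev
            dg = grad - grad_prev
            denom = float(dg @ dg)
            if denom > 0.0:
                bb = abs(float(dz @ dg)) / denom  # step for the raw gradient
                if np.isfinite(bb) and bb > 0.0:
                    alpha = min(bb * gnorm, 10.0)  # rescale to unit direction
        z_prev, grad_prev = z.copy(), grad.copy()
        improved = False
        for _ in range(30):
            z_new = np.maximum(z + alpha * direction, np.log(spec.x_floor))
            f_new, pred_new = objective(from_log(z_new))
            if np.isfinite(f_new) and f_new < f:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            converged = True
            break
        alpha_prev = alpha
        df = f - f_new
        z, f, pred = z_new, f_new, pred_new
        trace.append(f)
        if df < spec.tol * max(1.0, f):
            converged = True
            break
    return FitResult(
        params=_params_from_vector(from_log(z)),
        loss=f,
        predicted=pred,
        trace=trace,
        n_iter=it,
        converged=converged,
    )
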