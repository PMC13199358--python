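"""Age-incidence layer: observed rate tables, lag shift, fitted baseline
hazard, excess relative risk, and the map from cell-model output to
predicted incidence per 100,000.

The observed reference is the 2018 Japanese breast-cancer registry rates by
5-year age group (cases per 100,000 per year).  A fixed 5-year lag separates
the first stable cancerous cell from a recorded diagnosis, so the observed
table is shifted down by the lag before it is used as a calibration target.

The smooth baseline hazard fitted to the lagged rates is

    lambda(a) = 300 * a^8 / (35^8 + a^8) * exp(-(a / 85)^6)

(a Hill-type rise to a mid-life plateau with a senescence decline), and
radiation exposure multiplies it by ``1 + R(a, d)`` with the dose-linear
excess relative risk

    R(a, d) = 5.2 * d * 25 / (a - 10)

applied only once the attained age reaches exposure age plus lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceTable",
    "ERRModel",
    "load_table",
    "lag_shift",
    "baseline_hazard",
    "excess_relative_risk",
    "exposed_rates",
    "model_to_incidence",
]

# baseline-hazard fit constants (cases per 100,000 per year)
HAZARD_SCALE = 300.0
HAZARD_MIDLIFE_AGE = 35.0
HAZARD_HILL_EXPONENT = 8
SENESCENCE_AGE = 85.0
SENESCENCE_EXPONENT = 6

# excess-relative-risk constants (age at menarche 12 scenario)
ERR_PER_GY = 5.2
ERR_AGE_SCALE = 25.0
ERR_AGE_OFFSET = 10.0

GROUP_WIDTH = 5  # years per age group

_FIXTURES = {
    "japan_breast_2018": "japan_breast_2018.csv",
    "baseline_rates_lagged": "baseline_rates_lagged.csv",
    "exposed_rates_0p1gy_age30": "exposed_rates_0p1gy_age30.csv",
}


@dataclass(frozen=True)
class IncidenceTable:
    """Rates per 100,000 by contiguous 5-year age group.

    ``df`` has columns ``age_low`` (int), ``age_high`` (float, NaN for an
    open-ended final group) and ``rate``.  Group bounds are inclusive as
    printed (e.g. 40-44); an open group is treated as 5 years wide.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"age_low", "age_high", "rate"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"incidence table needs columns {sorted(required)}")
        if (self.df["rate"] < 0).any():
            raise ValueError("rates must be non-negative")
        object.__setattr__(
            self, "df", self.df.reset_index(drop=True).astype({"age_low": int})
        )

    @classmethod
    def from_records(cls, rows: list[tuple[float, float | None, float]]) -> "IncidenceTable":
        return cls(
            pd.DataFrame(rows, columns=["age_low", "age_high", "rate"]).astype(
                {"age_high": float}
            )
        )

    @classmethod
    def read_csv(cls, path) -> "IncidenceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def rates(self) -> np.ndarray:
        return self.df["rate"].to_numpy(dtype=float)

    @property
    def age_low(self) -> np.ndarray:
        return self.df["age_low"].to_numpy(dtype=int)

    def bounds(self) -> list[tuple[int, int]]:
        """Half-open group bounds ``[low, high+1)`` in years; open groups span 5 years."""
        out = []
        for low, high in zip(self.df["age_low"], self.df["age_high"]):
            hi = int(high) + 1 if np.isfinite(high) else int(low) + GROUP_WIDTH
            out.append((int(low), hi))
        return out

    def midpoints(self) -> np.ndarray:
        """Integer evaluation age of each group (``age_low + 2``)."""
        return self.age_low + 2

    def with_rates(self, rates) -> "IncidenceTable":
        df = self.df.copy()
        df["rate"] = np.asarray(rates, dtype=float)
        return IncidenceTable(df)

    def same_groups(self, other: "IncidenceTable") -> bool:
        a, b = self.df, other.df
        return len(a) == len(b) and bool(
            (a["age_low"].to_numpy() == b["age_low"].to_numpy()).all()
        )


def load_table(name: str) -> IncidenceTable:
    """Load one of the embedded fixtures.

    ``japan_breast_2018``: observed rates; ``baseline_rates_lagged``: the
    same shifted by the 5-year lag (the calibration target);
    ``exposed_rates_0p1gy_age30``: the 0.1 Gy at age 30 scenario target.
    """
    fname = _FIXTURES[name]
    with resources.files("ductsim.data").joinpath(fname).open() as fh:
        return IncidenceTable.read_csv(fh)


def lag_shift(table: IncidenceTable, lag: int = 5) -> IncidenceTable:
    """Reassign group rates ``lag`` years earlier (diagnosis -> first cancer cell).

    A pure relabeling: the rate of group [n, n+4] moves to [n-lag, n+4-lag].
    """
    if lag % GROUP_WIDTH != 0:
        raise ValueError(f"lag must be a multiple of the {GROUP_WIDTH}-year group width")
    df = table.df.copy()
    df["age_low"] = df["age_low"] - lag
    df["age_high"] = df["age_high"] - lag
    return IncidenceTable(df)


def baseline_hazard(a):
    """Fitted baseline Poisson rate lambda(a), cases per 100,000 per year."""
    a = np.asarray(a, dtype=float)
    hill = a**HAZARD_HILL_EXPONENT / (
        HAZARD_MIDLIFE_AGE**HAZARD_HILL_EXPONENT + a**HAZARD_HILL_EXPONENT
    )
    lam = HAZARD_SCALE * hill * np.exp(-((a / SENESCENCE_AGE) ** SENESCENCE_EXPONENT))
    return float(lam) if lam.ndim == 0 else lam


@dataclass(frozen=True)
class ERRModel:
    """Dose-linear excess relative risk for the menarche-age-12 scenario."""

    dose_gy: float
    exposure_age: float = 30.0
    lag: float = 5.0
    coefficient: float = ERR_PER_GY
    age_scale: float = ERR_AGE_SCALE
    age_offset: float = ERR_AGE_OFFSET

    def at(self, a: float) -> float:
        return excess_relative_risk(
            a, self.dose_gy, exposure_age=self.exposure_age, lag=self.lag
        )


def excess_relative_risk(
    a: float, dose_gy: float, exposure_age: float = 30.0, lag: float = 5.0
) -> float:
    """R(a, d) = 5.2 * d * 25 / (a - 10), zero before exposure age + lag."""
    if a <= ERR_AGE_OFFSET:
        raise ValueError(f"attained age {a} must exceed {ERR_AGE_OFFSET} years")
    if a < exposure_age + lag:
        return 0.0
    return ERR_PER_GY * dose_gy * ERR_AGE_SCALE / (a - ERR_AGE_OFFSET)


def exposed_rates(
    base: IncidenceTable,
    dose_gy: float,
    exposure_age: float = 30.0,
    lag: float = 5.0,
    hazard=baseline_hazard,
) -> IncidenceTable:
    """Scenario rates per group: fitted hazard times ``1 + R``, rounded.

    Each group at or beyond the exposure age is evaluated at its integer
    midpoint ``age_low + 2``; groups entirely before the exposure age keep
    the observed rates from ``base`` (nothing has changed for them yet, and
    the smooth fit is not used there).
    """
    rates = []
    for low, rate in zip(base.age_low, base.rates):
        if low < exposure_age:
            rates.append(rate)
            continue
        a = low + 2
        r = excess_relative_risk(a, dose_gy, exposure_age=exposure_age, lag=lag)
        rates.append(round(hazard(a) * (1.0 + r)))
    return base.with_rates(rates)


def model_to_incidence(
    prob_c,
    n_cells: int,
    groups: IncidenceTable | list[tuple[int, int]],
    lag: float = 5.0,
    timestep_months: float = 1.0,
) -> IncidenceTable:
    """Annualized first-event incidence per 100,000 implied by the cell model.

    ``prob_c`` is the non-decreasing per-cell probability of being cancerous
    at each timestep.  The tissue-level CDF of the first cancerous cell is
    ``F(t) = 1 - (1 - P_C(t))^N``; diagnosis occurs ``lag`` years later, and
    a group's rate is ``100000 * (F(t_end) - F(t_start)) / width_years``.
    """
    p = np.asarray(prob_c, dtype=float)
    if np.any(np.diff(p) < -1e-10):
        raise ValueError("prob_c must be non-decreasing (C is absorbing)")
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        log_not = np.log1p(-p)  # -inf where p == 1, handled by expm1 below
    cdf = -np.expm1(n_cells * log_not)

    if isinstance(groups, IncidenceTable):
        bounds = groups.bounds()
        template = groups
    else:
        bounds = [(int(lo), int(hi)) for lo, hi in groups]
        template = IncidenceTable.from_records(
            [(lo, hi - 1, 0.0) for lo, hi in bounds]
        )

    steps_per_year = 12.0 / timestep_months
    t_grid = np.arange(p.shape[0])

    def cdf_at_age(age: float) -> float:
        t = (age - lag) * steps_per_year
        if t <= 0:
            return 0.0
        return float(np.interp(t, t_grid, cdf))

    rates = [
        1e5 * (cdf_at_age(hi) - cdf_at_age(lo)) / (hi - lo) for lo, hi in bounds
    ]
    return template.with_rates(rates)
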