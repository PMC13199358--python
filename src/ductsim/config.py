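"""YAML/JSON scenario configuration.

Keys: p_mut, p_die, p_spr, circumference, n_rings, wrap_axial,
timestep_months, t_max, n_cells, seed, and an optional exposure block
(start_age, duration_steps, p_mut, p_die, p_spr, dose_gy).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import Exposure, Lattice, ModelParams, Scenario

__all__ = ["load_config", "scenario_from_dict"]


def scenario_from_dict(cfg: dict) -> tuple[Scenario, Lattice, int]:
    """Build (scenario, lattice, seed) from a configuration mapping."""
    baseline = ModelParams(
        p_mut=float(cfg.get("p_mut", 0.0)),
        p_die=float(cfg.get("p_die", 0.0)),
        p_spr=float(cfg.get("p_spr", 0.0)),
    )
    exposure = None
    if "exposure" in cfg and cfg["exposure"]:
        e = cfg["exposure"]
        exposure = Exposure(
            params=ModelParams(
                p_mut=float(e.get("p_mut", baseline.p_mut)),
                p_die=float(e.get("p_die", baseline.p_die)),
                p_spr=float(e.get("p_spr", baseline.p_spr)),
            ),
            start_age=float(e.get("start_age", 30.0)),
            duration_steps=int(e.get("duration_steps", 6)),
            dose_gy=float(e.get("dose_gy", 0.0)),
        )
    scenario = Scenario(
        baseline=baseline,
        t_max=int(cfg.get("t_max", 1080)),
        n_cells=int(cfg.get("n_cells", 1_000_000)),
        timestep_months=float(cfg.get("timestep_months", 1.0)),
        exposure=exposure,
    )
    lattice = Lattice(
        circumference=int(cfg.get("circumference", 15)),
        n_rings=int(cfg.get("n_rings", 1)),
        wrap_axial=bool(cfg.get("wrap_axial", True)),
    )
    return scenario, lattice, int(cfg.get("seed", 0))


def load_config(path: str | Path) -> tuple[Scenario, Lattice, int]:
    """Read a YAML (or JSON) scenario file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return scenario_from_dict(cfg)
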