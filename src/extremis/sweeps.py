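"""f0 sweeps over many network realizations.

A sweep runs the relaxation for every initial positive fraction ``f0`` on a
grid, with a fresh Erdos-Renyi graph per realization, and aggregates the
final-state observables f, f_e, G1_e, G2_e.  Every (grid point, realization)
cell has its own deterministic seed, so any cell can be reproduced in
isolation:  ``cell_seed = base_seed + r * len(f0_grid) + i``.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams, _relax_arrays
from .networks import InitialCondition, generate_er, init_opinions
from .observables import e_clusters, fractions

__all__ = ["SweepConfig", "SweepResult", "run_sweep", "model_curve"]


@dataclasses.dataclass(frozen=True)
class SweepConfig:
    n: int
    k_mean: float
    a: float
    q_e: float
    f0_grid: tuple
    n_realizations: int
    base_seed: int
    tol: float = 1e-9
    max_steps: int = 10_000

    def __post_init__(self):
        grid = tuple(float(x) for x in self.f0_grid)
        object.__setattr__(self, "f0_grid", grid)
        if len(grid) == 0:
            raise ValueError("empty f0 grid")
        if any(not 0.0 <= x <= 1.0 for x in grid):
            raise ValueError("f0 values must lie in [0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("f0_grid must be strictly increasing (no duplicates)")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")

    @property
    def params(self) -> ModelParams:
        return ModelParams(a=self.a, q_e=self.q_e, tol=self.tol,
                           max_steps=self.max_steps)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["f0_grid"] = list(self.f0_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass
class SweepResult:
    """Raw per-cell table plus per-f0 mean/standard-error summary."""

    config: SweepConfig
    table: pd.DataFrame  # columns: f0, realization, seed, f, fe, g1, g2, converged, cycle

    @property
    def summary(self) -> pd.DataFrame:
        agg = self.table.groupby("f0")[["f", "fe", "g1", "g2"]].agg(["mean", "sem"])
        agg.columns = [f"{c}_{s}" for c, s in agg.columns]
        return agg.fillna(0.0).reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def cell_seed(config: SweepConfig, grid_index: int, realization: int) -> int:
    return config.base_seed + realization * len(config.f0_grid) + grid_index


def _cell_state(config: SweepConfig, grid_index: int, realization: int):
    """Graph + relaxed state for one sweep cell (independently reproducible)."""
    seed = cell_seed(config, grid_index, realization)
    ss = np.random.SeedSequence(seed)
    gseed, oseed = (int(s % 2**31) for s in ss.generate_state(2))
    g = generate_er(config.n, config.k_mean, gseed)
    st = init_opinions(g, InitialCondition(config.f0_grid[grid_index], oseed))
    q, steps, converged, cycle = _relax_arrays(st.opinions, g, config.params,
                                               accelerate=True)
    st.opinions = q
    st.step = steps
    st.converged = converged
    st.cycle_detected = cycle
    return g, st, seed


def run_sweep(config: SweepConfig) -> SweepResult:
    """Relax every (f0, realization) cell and collect final-state observables.

    Non-converged relaxations are flagged in the table but still included
    (period-2 cycles enter as the cycle-averaged state).
    """
    rows = []
    for i, f0 in enumerate(config.f0_grid):
        for r in range(config.n_realizations):
            g, st, seed = _cell_state(config, i, r)
            fr = fractions(st, config.q_e)
            ec = e_clusters(st, config.q_e)
            rows.append({
                "f0": f0, "realization": r, "seed": seed,
                "f": fr.f_pos, "fe": fr.fe_pos,
                "g1": ec.g1, "g2": ec.g2,
                "converged": st.converged, "cycle": st.cycle_detected,
            })
    return SweepResult(config=config, table=pd.DataFrame(rows))


def model_curve(result: SweepResult) -> np.ndarray:
    """(mean f, mean f_e) pairs ordered by f0, as an (n, 2) array."""
    s = result.summary.sort_values("f0")
    return np.column_stack([s["f_mean"].to_numpy(), s["fe_mean"].to_numpy()])
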