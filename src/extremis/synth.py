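"""Synthetic poll tables with planted (f, f_e) structure.

Real poll tables (one row per country-year or rated item) are emulated by
drawing, per unit, a latent moderate fraction f uniformly on a sub-interval
of (0, 1), placing the extreme fraction on a chosen latent curve
f_e = g(f), mirroring the negative side through the same curve applied to
1 - f, and sampling the four category counts multinomially.  This closes
the loop for every estimator in the empirical arm: LOESS/NW slope recovery,
departure-point detection and effective-degree fitting can all be tested
against known ground truth without downloading any survey.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .regression import PollRecord
from .sweeps import SweepResult, model_curve

__all__ = [
    "SyntheticPollSpec",
    "linear_curve",
    "piecewise_curve",
    "curve_from_sweep",
    "gen_polls",
    "gen_from_model",
]


def linear_curve(slope: float) -> Callable[[float], float]:
    """f_e = slope * f (the non-interacting, extensive expectation)."""
    if not 0.0 <= slope <= 1.0:
        raise ValueError("slope must lie in [0, 1] so that g(f) <= f")

    def g(f):
        return slope * np.asarray(f, dtype=float)

    g.name = f"linear(slope={slope})"
    return g


def piecewise_curve(changepoint: float, slope: float,
                    slope_after: float) -> Callable[[float], float]:
    """Linear up to the changepoint, then a steeper slope (clipped at f_e = f)."""
    if not 0.0 < changepoint < 1.0:
        raise ValueError("changepoint must lie in (0, 1)")
    if slope_after < slope:
        raise ValueError("slope_after must be >= slope (superlinear departure)")

    def g(f):
        f = np.asarray(f, dtype=float)
        out = np.where(f <= changepoint, slope * f,
                       slope * changepoint + slope_after * (f - changepoint))
        return np.minimum(out, f)

    g.name = f"piecewise(c={changepoint}, s1={slope}, s2={slope_after})"
    return g


def curve_from_sweep(sweep: SweepResult) -> Callable[[float], float]:
    """g(f) interpolating a simulated model (f, f_e) curve."""
    curve = model_curve(sweep)
    order = np.argsort(curve[:, 0])
    cf, cfe = curve[order, 0], curve[order, 1]

    def g(f):
        return np.minimum(np.interp(np.asarray(f, dtype=float), cf, cfe),
                          np.asarray(f, dtype=float))

    g.name = f"model(<k>={sweep.config.k_mean})"
    return g


@dataclasses.dataclass(frozen=True)
class SyntheticPollSpec:
    """Generator conditions for a synthetic poll table.

    ``respondents`` is either a fixed count per unit or an inclusive
    (low, high) range sampled uniformly.  ``overdispersion`` > 0 adds
    unit-level Dirichlet noise around the latent category probabilities
    (concentration = respondents/overdispersion scale); the default is pure
    multinomial sampling.
    """

    n_units: int
    respondents: Union[int, tuple]
    curve: Callable[[float], float]
    seed: int
    f_range: tuple = (0.05, 0.95)
    overdispersion: float = 0.0

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("need at least one unit")
        r = self.respondents
        if isinstance(r, int):
            if r < 1:
                raise ValueError("respondents must be positive")
        else:
            lo, hi = r
            if lo < 1 or hi < lo:
                raise ValueError("invalid respondents range")
        lo, hi = self.f_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("invalid f_range")


def _unit_probs(f: float, g: Callable, rng, overdispersion: float) -> np.ndarray:
    fe = float(np.clip(g(f), 0.0, f))
    f_neg = 1.0 - f
    fe_neg = float(np.clip(g(f_neg), 0.0, f_neg))
    p = np.array([fe, f - fe, f_neg - fe_neg, fe_neg])
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    if overdispersion > 0.0:
        conc = np.clip(p, 1e-9, None) / overdispersion
        p = rng.dirichlet(conc)
    return p


def gen_polls(spec: SyntheticPollSpec) -> list:
    """Draw the poll table: one PollRecord per unit, seeded and reproducible.

    Category order in the multinomial is (strong-pos, pos, neg, strong-neg);
    the negative side mirrors the positive one through the same latent
    curve, so points of both polarities fall on a single (f, f_e) trend.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    lo, hi = spec.f_range
    for u in range(spec.n_units):
        f = float(rng.uniform(lo, hi))
        if isinstance(spec.respondents, int):
            n = spec.respondents
        else:
            n = int(rng.integers(spec.respondents[0], spec.respondents[1] + 1))
        p = _unit_probs(f, spec.curve, rng, spec.overdispersion)
        c = rng.multinomial(n, p)
        records.append(PollRecord(unit=f"unit{u:04d}", strong_pos=int(c[0]),
                                  pos=int(c[1]), neg=int(c[2]),
                                  strong_neg=int(c[3]), total=n))
    return records


def gen_from_model(sweep: SweepResult, n_units: int, respondents: int,
                   seed: int) -> list:
    """Poll table whose latent (f, f_e) pairs lie on a simulated model curve.

    Units sample points of the sweep's (mean f, mean f_e) relation uniformly
    along the f0 grid and add multinomial respondent noise; feeding the
    result to the effective-degree fit closes the model-vs-poll loop.
    """
    if n_units < 1 or respondents < 1:
        raise ValueError("n_units and respondents must be positive")
    rng = np.random.default_rng(seed)
    curve = model_curve(sweep)
    records = []
    for u in range(n_units):
        f, fe = curve[rng.integers(curve.shape[0])]
        fe = float(min(fe, f))
        f = float(np.clip(f, 0.0, 1.0))
        f_neg = 1.0 - f
        # mirror the negative side through the same curve in f
        fe_neg = float(min(np.interp(f_neg, curve[:, 0], curve[:, 1]), f_neg))
        p = np.clip(np.array([fe, f - fe, f_neg - fe_neg, fe_neg]), 0.0, None)
        p /= p.sum()
        c = rng.multinomial(respondents, p)
        records.append(PollRecord(unit=f"munit{u:04d}", strong_pos=int(c[0]),
                                  pos=int(c[1]), neg=int(c[2]),
                                  strong_neg=int(c[3]), total=respondents))
    return records
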