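"""Converting categorical survey and rating data to (f, f_e) points and
smoothing them with LOESS and Nadaraya-Watson regression.

Four-category polls (e.g. "very favorable / somewhat favorable / somewhat
unfavorable / very unfavorable") map directly onto the model's opinion
fractions: with N the total surveyed population,

    f   = N+ / N   (moderate-or-extreme positive share),
    f_e = Ne+ / N  (extreme positive share),

and analogously for the negative polarity.  Star-rating histograms (movie
and book reviews) and party-orientation vote counts are reduced to the same
four categories through configurable level maps.  The trend of the
resulting point cloud is extracted without a parametric form by locally
weighted regression (LOESS, tricube weights, span h) or the Nadaraya-Watson
Gaussian-kernel smoother with leave-one-out cross-validated bandwidth; a
departure-from-linearity point operationalises the onset of the nonlinear
(interacting) regime.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PollRecord",
    "StarMap",
    "CurveEstimate",
    "IMDB_MAP",
    "AMAZON_MAP",
    "BRAZIL_ORIENTATION_MAP",
    "to_ffe",
    "stars_to_record",
    "shuffle_null",
    "loess_fit",
    "nw_fit",
    "departure_point",
    "points_from_records",
    "read_polls_csv",
    "write_polls_csv",
    "read_ratings_csv",
]


@dataclasses.dataclass(frozen=True)
class PollRecord:
    """Four exclusive ordered category counts for one survey unit.

    ``strong_pos``/``strong_neg`` are the extreme categories; ``pos``/``neg``
    the moderate ones.  ``total`` is the full surveyed population including
    any nonresponse, so the four categories may sum to less than ``total``.
    """

    unit: str
    strong_pos: int
    pos: int
    neg: int
    strong_neg: int
    total: int

    def __post_init__(self):
        counts = (self.strong_pos, self.pos, self.neg, self.strong_neg)
        if any(c < 0 for c in counts) or self.total < 0:
            raise ValueError("counts must be non-negative")
        if sum(counts) > self.total:
            raise ValueError("category counts exceed the surveyed total")


def to_ffe(record: PollRecord, include_nonresponse: bool = True) -> tuple:
    """Positive and negative (f, f_e) points of one record.

    The denominator defaults to the full surveyed total (nonresponse
    included); set ``include_nonresponse=False`` to divide by the sum of
    the four categories instead.
    """
    denom = record.total if include_nonresponse else (
        record.strong_pos + record.pos + record.neg + record.strong_neg)
    if denom == 0:
        raise ValueError("record has zero total")
    f_pos = (record.strong_pos + record.pos) / denom
    fe_pos = record.strong_pos / denom
    f_neg = (record.strong_neg + record.neg) / denom
    fe_neg = record.strong_neg / denom
    return (f_pos, fe_pos), (f_neg, fe_neg)


@dataclasses.dataclass(frozen=True)
class StarMap:
    """Mapping from rating levels to opinion categories.

    Polarity sets are *inclusive* (positive contains extreme-positive) and
    must be disjoint from each other; levels left out of both polarities
    count as neutral (they enter the total only).
    """

    n_levels: int
    extreme_pos: frozenset
    positive: frozenset
    negative: frozenset
    extreme_neg: frozenset

    def __post_init__(self):
        levels = set(range(1, self.n_levels + 1))
        for name, s in (("extreme_pos", self.extreme_pos),
                        ("positive", self.positive),
                        ("negative", self.negative),
                        ("extreme_neg", self.extreme_neg)):
            if not set(s) <= levels:
                raise ValueError(f"{name} contains levels outside 1..{self.n_levels}")
        if not set(self.extreme_pos) <= set(self.positive):
            raise ValueError("extreme_pos must be a subset of positive")
        if not set(self.extreme_neg) <= set(self.negative):
            raise ValueError("extreme_neg must be a subset of negative")
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative level sets overlap")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StarMap":
        return cls(n_levels=int(d["n_levels"]),
                   extreme_pos=frozenset(d["extreme_pos"]),
                   positive=frozenset(d["positive"]),
                   negative=frozenset(d["negative"]),
                   extreme_neg=frozenset(d["extreme_neg"]))

    @classmethod
    def from_yaml(cls, path) -> "StarMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# Published conversion conventions for 10-star movie ratings, 5-star book
# ratings, and the 6-level party-orientation scale (1 = extreme-left ...
# 6 = right; votes on the left half count as negative opinion).
IMDB_MAP = StarMap(10, frozenset({9, 10}), frozenset({7, 8, 9, 10}),
                   frozenset({1, 2, 3, 4}), frozenset({1, 2}))
AMAZON_MAP = StarMap(5, frozenset({5}), frozenset({4, 5}),
                     frozenset({1, 2}), frozenset({1}))
BRAZIL_ORIENTATION_MAP = StarMap(6, frozenset({5, 6}), frozenset({4, 5, 6}),
                                 frozenset({1, 2, 3}), frozenset({1, 2}))


def _as_level_array(histogram, n_levels: int) -> np.ndarray:
    """Histogram as an int array indexed by level-1; accepts dict or sequence."""
    if isinstance(histogram, Mapping):
        arr = np.zeros(n_levels, dtype=np.int64)
        for level, count in histogram.items():
            if not 1 <= int(level) <= n_levels:
                raise ValueError(f"level {level} outside 1..{n_levels}")
            arr[int(level) - 1] = int(count)
    else:
        arr = np.asarray(histogram, dtype=np.int64)
        if arr.shape != (n_levels,):
            raise ValueError(f"expected {n_levels} level counts, got {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative counts")
    return arr


def stars_to_record(histogram, star_map: StarMap, unit: str = "") -> PollRecord:
    """Reduce a star-rating histogram to a four-category PollRecord.

    The record stores exclusive categories: ``strong_pos`` sums the
    extreme-positive levels, ``pos`` the remaining positive levels, etc.
    The total counts every vote, including neutral levels.
    """
    arr = _as_level_array(histogram, star_map.n_levels)
    if arr.sum() == 0:
        raise ValueError("empty histogram")

    def _sum(levels) -> int:
        return int(sum(arr[l - 1] for l in levels))

    strong_pos = _sum(star_map.extreme_pos)
    strong_neg = _sum(star_map.extreme_neg)
    return PollRecord(
        unit=unit,
        strong_pos=strong_pos,
        pos=_sum(set(star_map.positive) - set(star_map.extreme_pos)),
        neg=_sum(set(star_map.negative) - set(star_map.extreme_neg)),
        strong_neg=strong_neg,
        total=int(arr.sum()),
    )


def shuffle_null(histogram, star_map: StarMap, seed: int):
    """Randomise votes within each polarity, destroying the extreme/moderate
    correlation while preserving polarity totals exactly.

    Each positive vote is independently reassigned uniformly among the
    positive star levels (likewise for negative votes); other levels are
    untouched.  Returns the shuffled histogram as an int array indexed by
    level-1.
    """
    arr = _as_level_array(histogram, star_map.n_levels).copy()
    rng = np.random.default_rng(seed)
    for levels in (sorted(star_map.positive), sorted(star_map.negative)):
        if not levels:
            continue
        total = int(sum(arr[l - 1] for l in levels))
        for l in levels:
            arr[l - 1] = 0
        if total:
            redistributed = rng.multinomial(total, np.full(len(levels), 1.0 / len(levels)))
            for l, c in zip(levels, redistributed):
                arr[l - 1] = c
    return arr


# --------------------------------------------------------------- smoothing
@dataclasses.dataclass
class CurveEstimate:
    """Fitted trend evaluated at ``x`` (sorted data abscissae)."""

    x: np.ndarray
    y: np.ndarray
    method: str  # "loess" | "nw"
    h: float  # span (loess) or bandwidth (nw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y_fit": self.y,
                             "method": self.method, "h": self.h})


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    w[inside] = (1.0 - np.abs(u[inside]) ** 3) ** 3
    return w


def loess_fit(x, y, span: float = 0.8, degree: int = 1) -> CurveEstimate:
    """Locally weighted polynomial regression (LOESS).

    At each data point x_i the ``r = ceil(span * n)`` nearest neighbors set
    the local scale h_i (distance to the r-th nearest neighbor); weights
    are tricube in the scaled distance, and a weighted least-squares
    polynomial of the given degree is evaluated at x_i.  Exactly reproduces
    polynomials up to ``degree`` by construction.  If h_i = 0 (at least r
    duplicated abscissae) the fit degenerates to the weighted mean of the
    exact ties, with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < max(degree + 2, 4):
        raise ValueError(f"need at least {max(degree + 2, 4)} points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    r = int(np.ceil(span * n))
    r = min(max(r, degree + 1), n)
    fitted = np.empty(n)
    warned = False
    for i in range(n):
        d = np.abs(xs - xs[i])
        h_i = np.partition(d, r - 1)[r - 1]
        if h_i == 0.0:
            if not warned:
                warnings.warn("duplicated abscissae: falling back to the "
                              "weighted mean of exact ties", stacklevel=2)
                warned = True
            fitted[i] = ys[d == 0.0].mean()
            continue
        w = _tricube(d / h_i)
        use = w > 0.0
        X = np.vander(xs[use] - xs[i], degree + 1, increasing=True)
        sw = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[use] * sw, rcond=None)
        fitted[i] = beta[0]
    return CurveEstimate(x=xs, y=fitted, method="loess", h=span)


def _nw_predict(x_train, y_train, x_eval, h: float) -> np.ndarray:
    d = x_eval[:, None] - x_train[None, :]
    k = np.exp(-0.5 * (d / h) ** 2)
    denom = k.sum(axis=1)
    bad = denom <= 1e-300
    if bad.any():
        warnings.warn("kernel weights underflow at some evaluation points; "
                      "widening the kernel locally", stacklevel=3)
        # widen until every evaluation point sees at least one observation
        hh = h
        while bad.any():
            hh *= 2.0
            k[bad] = np.exp(-0.5 * (d[bad] / hh) ** 2)
            denom = k.sum(axis=1)
            bad = denom <= 1e-300
    return (k @ y_train) / denom


def nw_fit(x, y, bandwidth="auto", n_grid: int = 30) -> CurveEstimate:
    """Nadaraya-Watson Gaussian-kernel smoother.

    With ``bandwidth="auto"`` the bandwidth minimises the leave-one-out
    squared prediction error over ``n_grid`` log-spaced values spanning
    0.01 to 1.0 times the abscissa range.  The fitted values are convex
    combinations of the observed y, hence bounded by their extremes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need 1-d x, y with at least 3 points")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if bandwidth == "auto":
        span = xs.max() - xs.min()
        if span == 0:
            raise ValueError("degenerate abscissae")
        grid = np.geomspace(0.01, 1.0, n_grid) * span
        best_h, best_err = None, np.inf
        for h in grid:
            err = _loo_error(xs, ys, h)
            if err < best_err:
                best_err, best_h = err, h
        h = float(best_h)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    fitted = _nw_predict(xs, ys, xs, h)
    return CurveEstimate(x=xs, y=fitted, method="nw", h=h)


def _loo_error(x: np.ndarray, y: np.ndarray, h: float) -> float:
    """Mean squared leave-one-out prediction error of the NW smoother."""
    d = x[:, None] - x[None, :]
    k = np.exp(-0.5 * (d / h) ** 2)
    np.fill_diagonal(k, 0.0)
    denom = k.sum(axis=1)
    ok = denom > 1e-300
    if not ok.any():
        return np.inf
    pred = (k[ok] @ y) / denom[ok]
    return float(np.mean((y[ok] - pred) ** 2))


def departure_point(curve: CurveEstimate,
                    slope_ref: Optional[float] = None,
                    low_cutoff: float = 0.3,
                    margin: float = 3.0) -> Optional[float]:
    """Smallest abscissa where the curve departs from its low-x linear trend.

    A through-the-origin reference line is fitted to the curve's points
    with x below ``low_cutoff`` (unless ``slope_ref`` is given); the
    departure point is the smallest x at or beyond the cutoff where the
    curve exceeds the line by more than ``margin`` times the residual
    standard deviation of the low-x fit.  Returns None when the curve
    never exceeds the band — i.e. it stays consistent with the linear,
    non-interacting expectation.
    """
    x, y = curve.x, curve.y
    low = x < low_cutoff
    if slope_ref is None:
        if low.sum() < 2:
            raise ValueError("too few points below low_cutoff to fit the "
                             "reference line")
        slope_ref = float(np.sum(x[low] * y[low]) / np.sum(x[low] ** 2))
    resid = y[low] - slope_ref * x[low]
    sd = float(resid.std(ddof=1)) if low.sum() >= 2 else 0.0
    threshold = margin * sd
    excess = y - slope_ref * x
    beyond = (x >= low_cutoff) & (excess > threshold)
    if not beyond.any():
        return None
    return float(x[np.argmax(beyond)])


# --------------------------------------------------------------------- I/O
def points_from_records(records: Sequence[PollRecord],
                        include_nonresponse: bool = True) -> pd.DataFrame:
    """Tidy (unit, polarity, f, fe) table from a list of records."""
    rows = []
    for rec in records:
        (fp, fep), (fn, fen) = to_ffe(rec, include_nonresponse)
        rows.append({"unit": rec.unit, "polarity": "positive", "f": fp, "fe": fep})
        rows.append({"unit": rec.unit, "polarity": "negative", "f": fn, "fe": fen})
    return pd.DataFrame(rows)


_POLL_COLUMNS = ["unit", "c_strong_pos", "c_pos", "c_neg", "c_strong_neg", "n_total"]


def read_polls_csv(path) -> list:
    df = pd.read_csv(path)
    missing = set(_POLL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"polls CSV missing columns: {sorted(missing)}")
    return [PollRecord(unit=str(r.unit), strong_pos=int(r.c_strong_pos),
                       pos=int(r.c_pos), neg=int(r.c_neg),
                       strong_neg=int(r.c_strong_neg), total=int(r.n_total))
            for r in df.itertuples()]


def write_polls_csv(records: Sequence[PollRecord], path) -> None:
    pd.DataFrame([{
        "unit": r.unit, "c_strong_pos": r.strong_pos, "c_pos": r.pos,
        "c_neg": r.neg, "c_strong_neg": r.strong_neg, "n_total": r.total,
    } for r in records]).to_csv(path, index=False)


def read_ratings_csv(path) -> tuple:
    """Ratings CSV with columns item, star_1..star_K -> (items, histograms)."""
    df = pd.read_csv(path)
    star_cols = sorted((c for c in df.columns if c.startswith("star_")),
                       key=lambda c: int(c.split("_")[1]))
    if not star_cols or "item" not in df.columns:
        raise ValueError("ratings CSV needs an 'item' column and star_K columns")
    hists = df[star_cols].to_numpy(dtype=np.int64)
    return df["item"].astype(str).tolist(), hists
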