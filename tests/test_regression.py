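"""Poll conversion, star maps, shuffle null, LOESS and NW smoothing."""
import numpy as np
import pytest

import extremis as ex
from extremis.regression import _loo_error


# ----------------------------------------------------------------- to_ffe
def test_to_ffe_basic_arithmetic():
    rec = ex.PollRecord("u", 200, 400, 300, 100, total=1000)
    (fp, fep), (fn, fen) = ex.to_ffe(rec)
    assert (fp, fep) == (0.6, 0.2)
    assert (fn, fen) == (0.4, 0.1)


def test_to_ffe_all_strong_positive():
    rec = ex.PollRecord("u", 50, 0, 0, 0, total=50)
    (fp, fep), _ = ex.to_ffe(rec)
    assert (fp, fep) == (1.0, 1.0)


def test_to_ffe_nonresponse_conventions():
    rec = ex.PollRecord("u", 200, 400, 200, 100, total=1000)  # 100 nonresponse
    (fp, _), _ = ex.to_ffe(rec)
    assert fp == pytest.approx(0.6)  # denominator is the full total
    (fp2, _), _ = ex.to_ffe(rec, include_nonresponse=False)
    assert fp2 == pytest.approx(600 / 900)


def test_to_ffe_invariants_and_errors():
    with pytest.raises(ValueError):
        ex.to_ffe(ex.PollRecord("u", 0, 0, 0, 0, total=0))
    with pytest.raises(ValueError):
        ex.PollRecord("u", 10, 10, 10, 10, total=30)  # categories exceed total
    rec = ex.PollRecord("u", 5, 10, 20, 3, total=40)
    (fp, fep), (fn, fen) = ex.to_ffe(rec)
    assert fep <= fp and fen <= fn and fp + fn <= 1.0


# --------------------------------------------------------------- star maps
def test_imdb_map_sums():
    hist = {9: 50, 10: 50, 7: 100}
    rec = ex.stars_to_record(hist, ex.IMDB_MAP)
    assert rec.strong_pos == 100          # 9-10 stars
    assert rec.strong_pos + rec.pos == 200  # positive = 7-10 stars
    assert rec.total == 200


def test_amazon_map_sums():
    rec = ex.stars_to_record([10, 10, 0, 30, 50], ex.AMAZON_MAP)
    assert rec.strong_pos == 50                  # 5 stars
    assert rec.strong_pos + rec.pos == 80        # 4-5 stars
    assert rec.neg + rec.strong_neg == 20        # 1-2 stars
    assert rec.strong_neg == 10                  # 1 star
    assert rec.total == 100


def test_orientation_map_polarity():
    # levels 1..6 run from extreme-left to right; left half is negative
    votes = [5, 10, 20, 30, 15, 20]
    rec = ex.stars_to_record(votes, ex.BRAZIL_ORIENTATION_MAP)
    assert rec.strong_neg == 15          # extreme-left + left
    assert rec.neg + rec.strong_neg == 35
    assert rec.strong_pos == 35          # center-right + right
    assert rec.pos + rec.strong_pos == 65


def test_star_map_validation():
    with pytest.raises(ValueError):
        ex.StarMap(5, frozenset({5}), frozenset({4, 5}),
                   frozenset({1, 2, 4}), frozenset({1}))  # polarities overlap
    with pytest.raises(ValueError):
        ex.StarMap(5, frozenset({3, 5}), frozenset({4, 5}),
                   frozenset({1}), frozenset({1}))  # extreme not subset
    with pytest.raises(ValueError):
        ex.stars_to_record([0, 0, 0, 0, 0], ex.AMAZON_MAP)  # empty histogram


def test_star_map_yaml_roundtrip(tmp_path):
    import yaml
    spec = {"n_levels": 6, "extreme_pos": [5, 6], "positive": [4, 5, 6],
            "negative": [1, 2, 3], "extreme_neg": [1, 2]}
    path = tmp_path / "map.yaml"
    path.write_text(yaml.safe_dump(spec))
    assert ex.StarMap.from_yaml(path) == ex.BRAZIL_ORIENTATION_MAP


# ------------------------------------------------------------ shuffle null
def test_shuffle_preserves_polarity_totals_exactly():
    rng = np.random.default_rng(0)
    hist = rng.integers(0, 200, size=5)
    out = ex.shuffle_null(hist, ex.AMAZON_MAP, seed=3)
    assert out[3] + out[4] == hist[3] + hist[4]  # positive votes (4-5 stars)
    assert out[0] + out[1] == hist[0] + hist[1]  # negative votes (1-2 stars)
    assert out[2] == hist[2]  # neutral level untouched


def test_shuffle_equalises_extreme_share():
    # 200 positive votes spread uniformly over levels {4, 5}
    out = ex.shuffle_null([0, 0, 0, 100, 100], ex.AMAZON_MAP, seed=5)
    frac_extreme = out[4] / 200
    assert abs(frac_extreme - 0.5) < 3 * np.sqrt(0.25 / 200)


def test_shuffle_seeded_and_handles_one_sided_votes():
    a = ex.shuffle_null([40, 10, 0, 0, 0], ex.AMAZON_MAP, seed=7)
    b = ex.shuffle_null([40, 10, 0, 0, 0], ex.AMAZON_MAP, seed=7)
    assert np.array_equal(a, b)
    assert a[3] + a[4] == 0  # negatives-only input stays negatives-only


# ------------------------------------------------------------------- LOESS
def test_loess_reproduces_straight_lines_exactly():
    rng = np.random.default_rng(1)
    x = np.sort(rng.uniform(0, 1, 60))
    y = 2 * x + 1
    for span in (0.3, 0.8, 1.0):
        curve = ex.loess_fit(x, y, span=span)
        assert np.allclose(curve.y, 2 * curve.x + 1, atol=1e-10)


def test_loess_matches_weighted_normal_equations_oracle():
    rng = np.random.default_rng(2)
    x = np.sort(rng.uniform(0, 1, 40))
    y = np.sin(3 * x) + rng.normal(0, 0.05, 40)
    span = 0.6
    curve = ex.loess_fit(x, y, span=span)
    n = x.size
    r = int(np.ceil(span * n))
    for i in (0, 7, 20, 39):
        d = np.abs(x - x[i])
        h = np.sort(d)[r - 1]
        w = np.where(d < h, (1 - (d / h) ** 3) ** 3, 0.0)
        X = np.column_stack([np.ones(n), x - x[i]])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert curve.y[i] == pytest.approx(beta[0], abs=1e-8)


def test_loess_agrees_with_statsmodels_lowess():
    from statsmodels.nonparametric.smoothers_lowess import lowess
    rng = np.random.default_rng(8)
    x = np.sort(rng.uniform(0, 1, 60))
    y = np.sin(3 * x) + rng.normal(0, 0.05, 60)
    for span in (0.4, 0.8):
        ours = ex.loess_fit(x, y, span=span)
        ref = lowess(y, x, frac=span, it=0, return_sorted=True)
        assert np.allclose(ours.y, ref[:, 1], atol=1e-10)


def test_loess_duplicate_abscissae_fall_back_to_tie_mean():
    x = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
    with pytest.warns(UserWarning):
        curve = ex.loess_fit(x, y, span=0.6)
    assert curve.y[0] == pytest.approx(2.5)


def test_loess_input_validation():
    with pytest.raises(ValueError):
        ex.loess_fit([0, 1], [0, 1])  # too few points
    with pytest.raises(ValueError):
        ex.loess_fit(np.arange(10.0), np.arange(10.0), span=1.5)


# ---------------------------------------------------------- Nadaraya-Watson
def test_nw_flat_kernel_limit_is_global_mean():
    rng = np.random.default_rng(3)
    x = np.sort(rng.uniform(0, 1, 30))
    y = rng.normal(0, 1, 30)
    curve = ex.nw_fit(x, y, bandwidth=1e4)
    assert np.allclose(curve.y, y.mean(), atol=1e-6)


def test_nw_delta_limit_interpolates():
    x = np.linspace(0, 1, 11)
    y = np.sin(2 * np.pi * x)
    curve = ex.nw_fit(x, y, bandwidth=1e-3)
    assert np.allclose(curve.y, y[np.argsort(x)], atol=1e-8)


def test_nw_output_is_convex_combination_of_y():
    rng = np.random.default_rng(4)
    x = np.sort(rng.uniform(0, 1, 50))
    y = rng.normal(0, 1, 50)
    curve = ex.nw_fit(x, y, bandwidth=0.1)
    assert curve.y.min() >= y.min() - 1e-12
    assert curve.y.max() <= y.max() + 1e-12


def test_nw_loocv_selects_interior_bandwidth():
    rng = np.random.default_rng(5)
    x = np.sort(rng.uniform(0, 1, 200))
    y = np.sin(2 * np.pi * x) + rng.normal(0, 0.1, 200)
    curve = ex.nw_fit(x, y, bandwidth="auto")
    span = x.max() - x.min()
    grid = np.geomspace(0.01, 1.0, 30) * span
    assert grid[0] < curve.h < grid[-1]
    err_sel = _loo_error(x, y, curve.h)
    assert err_sel <= _loo_error(x, y, grid[0])
    assert err_sel <= _loo_error(x, y, grid[-1])


# --------------------------------------------------------- departure point
def test_departure_none_for_linear_curve():
    x = np.linspace(0.05, 0.95, 50)
    curve = ex.CurveEstimate(x=x, y=0.33 * x, method="loess", h=0.8)
    assert ex.departure_point(curve) is None


def test_departure_detects_planted_changepoint():
    x = np.linspace(0.05, 0.95, 200)
    y = np.where(x <= 0.5, 0.3 * x, 0.15 + 0.9 * (x - 0.5))
    curve = ex.CurveEstimate(x=x, y=y, method="nw", h=0.05)
    dep = ex.departure_point(curve)
    assert dep is not None
    assert dep == pytest.approx(0.5, abs=0.05)


def test_departure_with_explicit_reference_slope():
    x = np.linspace(0.05, 0.95, 100)
    y = 0.5 * x
    curve = ex.CurveEstimate(x=x, y=y, method="loess", h=0.8)
    assert ex.departure_point(curve, slope_ref=0.5) is None
    dep = ex.departure_point(curve, slope_ref=0.2)
    assert dep is not None  # everything beyond the cutoff exceeds a 0.2 line


# --------------------------------------------------------------- poll I/O
def test_polls_csv_roundtrip(tmp_path):
    recs = [ex.PollRecord("ct-2010", 10, 20, 30, 5, 70),
            ex.PollRecord("ct-2012", 5, 25, 30, 10, 75)]
    path = tmp_path / "polls.csv"
    ex.write_polls_csv(recs, path)
    back = ex.read_polls_csv(path)
    assert back == recs
    pts = ex.points_from_records(back)
    assert len(pts) == 4
    assert set(pts.polarity) == {"positive", "negative"}
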