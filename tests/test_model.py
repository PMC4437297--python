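"""Update rules, synchronous stepping, and relaxation."""
import numpy as np
import pytest

import extremis as ex
from extremis.model import _relax_arrays, _relax_arrays_py, rule_branch

A08 = ex.ModelParams(a=0.8)
A0 = ex.ModelParams(a=0.0)
A1 = ex.ModelParams(a=1.0)


# ----------------------------------------------------------- single update
@pytest.mark.parametrize("q, qbar, params, expected", [
    (0.5, 0.8, A08, 0.8),     # rule (i): adopt the more extreme same-sign mean
    (0.5, 0.2, A08, 0.5),     # rule (ii): (1-a)q = 0.1 <= 0.2 <= 0.5
    (0.5, -0.5, A08, -0.5),   # rule (iii): opposite-sign mean is adopted
    (0.5, 0.05, A08, 0.05),   # rule (iii): much-weaker same-sign mean adopted
    (0.7, -0.2, A0, -0.2),    # a = 0 limit: plain averaging
    (0.5, -0.5, A1, -0.5),    # a = 1 still capitulates to an opposite mean
    (0.5, 0.1, A08, 0.5),     # boundary tie qbar = (1-a)q belongs to rule (ii)
    (0.5, 0.5, A08, 0.5),     # boundary tie qbar = q
    (-0.5, -0.8, A08, -0.8),  # mirror of rule (i)
    (-0.5, 0.4, A08, 0.4),    # mirror of rule (iii)
    (0.3, None, A08, 0.3),    # isolated node holds
])
def test_update_node_rules(q, qbar, params, expected):
    assert ex.update_node(q, qbar, params) == pytest.approx(expected, abs=1e-15)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(q=st.floats(-1.0, 1.0), qbar=st.floats(-1.0, 1.0), a=st.floats(0.0, 1.0))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_update_node_range_and_odd_symmetry(q, qbar, a):
    params = ex.ModelParams(a=a)
    out = ex.update_node(q, qbar, params)
    assert -1.0 <= out <= 1.0
    assert ex.update_node(-q, -qbar, params) == pytest.approx(-out, abs=1e-12)


def test_update_node_zero_conventions():
    assert ex.update_node(0.0, 0.4, A08) == pytest.approx(0.4)  # default adopt
    mix = ex.ModelParams(a=0.8, zero_opinion_rule="mix")
    assert ex.update_node(0.0, 0.4, mix) == pytest.approx(0.2 * 0.4)


@pytest.mark.parametrize("q, qbar", [(1.5, 0.0), (0.0, -1.2)])
def test_update_node_rejects_out_of_range(q, qbar):
    with pytest.raises(ValueError):
        ex.update_node(q, qbar, A08)


def test_params_validation():
    with pytest.raises(ValueError):
        ex.ModelParams(a=1.5)
    with pytest.raises(ValueError):
        ex.ModelParams(a=0.5, q_e=0.0)
    with pytest.raises(ValueError):
        ex.ModelParams(a=0.5, tol=0.0)
    with pytest.raises(ValueError):
        ex.ModelParams(a=0.5, zero_opinion_rule="bogus")


def test_rule_partition_is_complete_and_exclusive():
    """Exactly one branch fires everywhere on a dense (q, qbar, a) grid."""
    grid = np.linspace(-1.0, 1.0, 41)
    for a in (0.0, 0.25, 0.5, 0.8, 1.0):
        for q in grid:
            for qbar in grid:
                conds = {
                    "i": (q > 0 and qbar > q) or (q < 0 and qbar < q),
                    "ii": (q > 0 and (1 - a) * q <= qbar <= q)
                          or (q < 0 and q <= qbar <= (1 - a) * q),
                    "iii": (q > 0 and qbar < (1 - a) * q)
                           or (q < 0 and qbar > (1 - a) * q),
                    "zero": q == 0.0,
                }
                fired = [name for name, c in conds.items() if c]
                assert len(fired) == 1, (q, qbar, a, fired)
                assert rule_branch(q, qbar, a) == fired[0]


# ---------------------------------------------------------------- stepping
def test_neighbor_mean(k3_state):
    assert ex.neighbor_mean(k3_state, 2) == pytest.approx((0.9 + 0.8) / 2)
    g = ex.two_triangles()
    st = ex.OpinionState(np.full(7, 0.4), g)
    assert ex.neighbor_mean(st, 6) is None  # isolated node
    with pytest.raises(KeyError):
        ex.neighbor_mean(st, 99)


def test_step_k3_hand_derived(k3_state):
    # only node 2 sees a more extreme mean (0.85 > 0.1); others are in-band
    out = ex.step(k3_state, A1)
    assert np.allclose(out.opinions, [0.9, 0.8, 0.85])
    assert out.step == 1
    assert np.allclose(k3_state.opinions, [0.9, 0.8, 0.1])  # input untouched


def test_step_fixed_point_is_identity():
    g = ex.path_graph(3)
    st = ex.OpinionState(np.array([0.45, 0.45, 0.45]), g)
    out = ex.step(st, A1)
    assert np.array_equal(out.opinions, st.opinions)


def test_step_two_node_antagonists_swap():
    # opposite-sign means are adopted wholesale, so the pair oscillates
    g = ex.path_graph(2)
    st = ex.OpinionState(np.array([0.5, -0.5]), g)
    out = ex.step(st, A1)
    assert np.allclose(out.opinions, [-0.5, 0.5])


# -------------------------------------------------------------- relaxation
def test_relax_k3_stubborn_reaches_most_extreme(k3_state):
    out = ex.relax(k3_state, ex.ModelParams(a=1.0, tol=1e-6))
    assert np.allclose(out.opinions, 0.9, atol=1e-6)
    assert out.converged


def test_relax_k3_averaging_reaches_mean(k3_state):
    # complete-graph synchronous averaging conserves the opinion sum
    out = ex.relax(k3_state, A0)
    assert np.allclose(out.opinions, 0.6, atol=1e-6)


def test_relax_already_stable_returns_immediately():
    g = ex.path_graph(3)
    st = ex.OpinionState(np.array([0.45, 0.45, 0.45]), g)
    out = ex.relax(st, A1)
    assert out.converged and out.step <= 1
    assert np.array_equal(out.opinions, st.opinions)


def test_relax_detects_period_two_cycle():
    g = ex.path_graph(2)
    st = ex.OpinionState(np.array([0.5, -0.5]), g)
    out = ex.relax(st, A1)
    assert out.cycle_detected and not out.converged
    assert np.allclose(out.opinions, 0.0)  # cycle average


def test_relax_isolated_nodes_hold():
    g = ex.two_triangles()
    q = np.array([0.9, 0.8, 0.7, -0.2, -0.3, -0.4, 0.123])
    out = ex.relax(ex.OpinionState(q, g), A1)
    assert out.opinions[6] == 0.123


# ------------------------------------------------------------- invariants
def test_range_preserved_and_sign_symmetry():
    from tests.conftest import random_graph_and_opinions
    rng = np.random.default_rng(7)
    for _ in range(10):
        g, q = random_graph_and_opinions(rng)
        params = ex.ModelParams(a=float(rng.choice([0.0, 0.4, 1.0])))
        out = ex.relax(ex.OpinionState(q, g), params)
        assert np.all(np.abs(out.opinions) <= 1.0)
        flipped = ex.relax(ex.OpinionState(-q, g), params)
        assert np.allclose(flipped.opinions, -out.opinions, atol=1e-12)


def test_complete_graph_averaging_conserves_sum():
    rng = np.random.default_rng(3)
    g = ex.complete_graph(6)
    st = ex.OpinionState(rng.uniform(-1, 1, 6), g)
    total = st.opinions.sum()
    for _ in range(5):
        st = ex.step(st, A0)
        assert st.opinions.sum() == pytest.approx(total, abs=1e-12)


def test_all_positive_stays_all_positive_at_full_stubbornness():
    rng = np.random.default_rng(11)
    g = ex.generate_er(300, 4.0, 5)
    st = ex.OpinionState(rng.uniform(0.0, 1.0, 300) + 1e-9, g)
    out = ex.relax(st, A1)
    assert np.all(out.opinions[g.degrees > 0] > 0)


# --------------------------------------------------- independent oracles
def _oracle_relax(q0, edges, n, a, tol, max_steps, zero_mix=False):
    """Straight-line reimplementation: adjacency dict + textbook rules."""
    adj = {i: [] for i in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    q = list(map(float, q0))
    if not any(adj.values()):
        return q, 0, True, False  # nothing to update
    prev2 = None
    for steps in range(1, max_steps + 1):
        new = []
        for i in range(n):
            if not adj[i]:
                new.append(q[i])
                continue
            qbar = sum(q[j] for j in adj[i]) / len(adj[i])
            qi = q[i]
            if qi > 0:
                hold = (1 - a) * qi <= qbar <= qi
            elif qi < 0:
                hold = qi <= qbar <= (1 - a) * qi
            else:
                hold = False
            if hold:
                new.append(qi)
            elif qi == 0 and zero_mix:
                new.append((1 - a) * qbar)
            else:
                new.append(min(1.0, max(-1.0, qbar)))
        delta = max(abs(x - y) for x, y in zip(new, q))
        if prev2 is not None and max(abs(x - y) for x, y in zip(new, prev2)) < tol:
            return [0.5 * (x + y) for x, y in zip(new, q)], steps, False, True
        prev2 = q
        q = new
        if delta < tol:
            return q, steps, True, False
    return q, max_steps, False, False


def test_relax_matches_straight_line_oracle_on_tiny_graphs():
    rng = np.random.default_rng(19)
    for trial in range(40):
        n = int(rng.integers(2, 7))
        g = ex.generate_er(n, min(float(rng.uniform(1.0, 3.0)), n - 1),
                          int(rng.integers(1 << 30)))
        q0 = rng.uniform(-1, 1, n)
        a = float(rng.choice([0.0, 0.3, 0.7, 1.0]))
        params = ex.ModelParams(a=a, tol=1e-9, max_steps=500)
        got = ex.relax(ex.OpinionState(q0, g), params)
        want_q, want_steps, want_conv, want_cyc = _oracle_relax(
            q0, g.edges.tolist(), n, a, 1e-9, 500)
        assert np.allclose(got.opinions, want_q, atol=1e-12), trial
        assert got.step == want_steps
        assert got.converged == want_conv and got.cycle_detected == want_cyc


def test_compiled_and_numpy_engines_agree():
    from tests.conftest import random_graph_and_opinions
    rng = np.random.default_rng(23)
    for _ in range(15):
        g, q0 = random_graph_and_opinions(rng, n_max=60)
        params = ex.ModelParams(a=float(rng.choice([0.0, 0.5, 1.0])),
                                max_steps=2000)
        qa, sa, ca, ya = _relax_arrays(q0, g, params)
        qb, sb, cb, yb = _relax_arrays_py(q0, g, params)
        assert sa == sb and ca == cb and ya == yb
        assert np.allclose(qa, qb, atol=1e-12)


def test_accelerated_relax_matches_exact_observables():
    rng = np.random.default_rng(29)
    for _ in range(8):
        g = ex.generate_er(300, float(rng.uniform(3, 5.5)), int(rng.integers(1 << 30)))
        q0 = rng.uniform(-1, 1, 300)
        params = ex.ModelParams(a=float(rng.choice([0.0, 0.5, 1.0])))
        qe, _, ce, _ = _relax_arrays(q0, g, params)
        qa, _, ca, _ = _relax_arrays(q0, g, params, accelerate=True)
        fe_exact = (qe > 0.5).mean()
        fe_acc = (qa > 0.5).mean()
        assert fe_acc == pytest.approx(fe_exact, abs=0.01)


def test_state_csv_roundtrip(tmp_path):
    from extremis.model import read_state_csv, write_state_csv
    g = ex.path_graph(4)
    st = ex.OpinionState(np.array([0.25, -0.5, 1.0, 0.0]), g)
    path = tmp_path / "state.csv"
    write_state_csv(st, path)
    back = read_state_csv(path, g)
    assert np.array_equal(back.opinions, st.opinions)
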