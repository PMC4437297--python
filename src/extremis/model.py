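"""Opinion update rules and relaxation to a stable state.

Each agent holds a continuous opinion ``q`` in [-1, 1]; |q| > q_e marks an
extreme opinion.  At every time step all agents compare their opinion with
the arithmetic mean ``qbar`` of their network neighbors' opinions and update
synchronously according to three rules governed by a stubbornness parameter
``a`` in [0, 1] (stated here for q > 0; q < 0 is mirror-symmetric):

(i)   qbar > q              ->  q' = qbar   (adopt a more extreme mean)
(ii)  (1-a) q <= qbar <= q  ->  q' = q      (inflexibility range: ignore a
                                             weaker version of your own view)
(iii) qbar < (1-a) q        ->  q' = qbar   (adopt a mean that is opposite
                                             or much more moderate)

Stubbornness enters through the width of the inflexibility band: at a = 0
the band collapses and every rule reduces to plain neighbor averaging
(consensus dynamics, with possible period-2 oscillation on bipartite
structures); at a = 1 an agent ignores any same-sign mean weaker than its
own opinion, yet still capitulates wholesale to an opposite-signed
neighborhood — the ingredient behind cascades of extremization and the
abrupt takeover transitions at high connectivity.  Nodes with q = 0 carry
no polarity and adopt the mean by default (configurable).  Isolated nodes
have no social input and hold their opinion.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from numba import njit

from .networks import NetworkGraph

__all__ = [
    "ModelParams",
    "OpinionState",
    "neighbor_mean",
    "update_node",
    "rule_branch",
    "step",
    "relax",
    "write_state_csv",
    "read_state_csv",
]


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Model and convergence parameters.

    Parameters
    ----------
    a : float
        Stubbornness in [0, 1]: the fraction of an agent's own opinion
        magnitude below which a same-sign neighbor mean is ignored.
    q_e : float
        Extremism threshold in (0, 1); |q| > q_e counts as extreme.
        Four-category polls motivate the canonical value 0.5.
    tol : float
        Relaxation stops when no opinion moved by more than ``tol`` in a
        full synchronous sweep.
    max_steps : int
        Hard cap on the number of synchronous sweeps.
    zero_opinion_rule : {"adopt", "mix"}
        Convention for q = 0 nodes: "adopt" copies the neighbor mean (the
        rule-(iii) action), "mix" damps it to (1-a) qbar.
    isolated_rule : {"hold"}
        Degree-0 nodes keep their opinion.
    """

    a: float
    q_e: float = 0.5
    tol: float = 1e-9
    max_steps: int = 10_000
    zero_opinion_rule: str = "adopt"
    isolated_rule: str = "hold"

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("stubbornness a must lie in [0, 1]")
        if not 0.0 < self.q_e < 1.0:
            raise ValueError("q_e must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.zero_opinion_rule not in ("mix", "adopt"):
            raise ValueError("zero_opinion_rule must be 'mix' or 'adopt'")
        if self.isolated_rule != "hold":
            raise ValueError("isolated_rule must be 'hold'")


@dataclasses.dataclass
class OpinionState:
    """Per-node opinions on a fixed network, with bookkeeping flags."""

    opinions: np.ndarray
    network: NetworkGraph
    step: int = 0
    converged: bool = False
    cycle_detected: bool = False

    def __post_init__(self):
        self.opinions = np.asarray(self.opinions, dtype=np.float64)
        if self.opinions.shape != (self.network.n_nodes,):
            raise ValueError("opinions length must equal node count")
        if self.opinions.size and (np.abs(self.opinions) > 1.0).any():
            raise ValueError("opinions must lie in [-1, 1]")

    def copy(self) -> "OpinionState":
        return OpinionState(self.opinions.copy(), self.network, self.step,
                            self.converged, self.cycle_detected)


# --------------------------------------------------------------- rule logic
def rule_branch(q: float, qbar: Optional[float], a: float) -> str:
    """Which update branch fires for scalar inputs.

    Returns one of ``"i"``, ``"ii"``, ``"iii"``, ``"zero"`` (q = 0) or
    ``"hold"`` (no neighbors).  The branches partition the input space:
    boundary ties qbar = q and qbar = (1-a) q belong to rule (ii).
    """
    if qbar is None:
        return "hold"
    if q == 0.0:
        return "zero"
    if q > 0:
        if qbar > q:
            return "i"
        if (1.0 - a) * q <= qbar <= q:
            return "ii"
        return "iii"
    if qbar < q:
        return "i"
    if q <= qbar <= (1.0 - a) * q:
        return "ii"
    return "iii"


def update_node(q: float, qbar: Optional[float], params: ModelParams) -> float:
    """New opinion of a single node given its neighbor mean.

    ``qbar=None`` marks an isolated node (no neighbors), which holds.
    """
    if not -1.0 <= q <= 1.0:
        raise ValueError("q outside [-1, 1]")
    if qbar is not None and not -1.0 <= qbar <= 1.0:
        raise ValueError("qbar outside [-1, 1]")
    branch = rule_branch(q, qbar, params.a)
    if branch in ("hold", "ii"):
        return q
    if branch == "zero" and params.zero_opinion_rule == "mix":
        return (1.0 - params.a) * qbar
    return qbar  # rules (i), (iii) and the default zero convention


def _apply_rules(q: np.ndarray, qbar: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorised update for nodes that have at least one neighbor."""
    a = params.a
    thr = (1.0 - a) * q
    hold = (((q > 0.0) & (qbar >= thr) & (qbar <= q)) |
            ((q < 0.0) & (qbar <= thr) & (qbar >= q)))
    new = np.where(hold, q, qbar)
    if params.zero_opinion_rule == "mix":
        zero = q == 0.0
        if zero.any():
            new[zero] = (1.0 - a) * qbar[zero]
    return np.clip(new, -1.0, 1.0)


def neighbor_mean(state: OpinionState, node: int) -> Optional[float]:
    """Arithmetic mean opinion of a node's neighbors; None if degree 0."""
    nb = state.network.neighbors(node)  # raises KeyError for unknown ids
    if nb.size == 0:
        return None
    return float(state.opinions[nb].mean())


# ------------------------------------------------------------------ stepping
def step(state: OpinionState, params: ModelParams) -> OpinionState:
    """One full synchronous sweep; the input state is left unmodified."""
    g = state.network
    q = state.opinions
    deg = g.degrees
    new = q.copy()
    social = deg > 0
    if social.any():
        idx = np.flatnonzero(social)
        qbar = g.row_means(idx, q)
        new[idx] = _apply_rules(q[idx], qbar, params)
    return OpinionState(new, g, state.step + 1, False, False)


@njit(cache=False)
def _relax_kernel(indptr, indices, q, a, tol, max_steps, frontier, fcount,
                  zero_mix, check_cycle):
    """Frontier-accelerated synchronous relaxation (bit-identical to full
    sweeps: a node is recomputed only when its own value or a neighbor's
    changed, and unchanged inputs reproduce the same output exactly).

    ``frontier[:fcount]`` holds the nodes changed by the previous sweep and
    is updated in place, so the caller can resume in chunks.
    """
    n = q.size
    if check_cycle:
        qm1 = q.copy()
        qm2 = q.copy()
    else:  # monotone relaxations cannot cycle; skip the per-step snapshots
        qm1 = np.empty(0, dtype=np.float64)
        qm2 = np.empty(0, dtype=np.float64)
    seen = np.zeros(n, dtype=np.uint8)
    cand = np.empty(n, dtype=np.int64)
    newv = np.empty(n, dtype=np.float64)
    steps = 0
    converged = False
    cycle = False
    maxd = 0.0
    while steps < max_steps:
        if fcount == 0:
            converged = True
            break
        m = 0
        for fi in range(fcount):
            i = frontier[fi]
            if seen[i] == 0:
                seen[i] = 1
                cand[m] = i
                m += 1
            for jj in range(indptr[i], indptr[i + 1]):
                v = indices[jj]
                if seen[v] == 0:
                    seen[v] = 1
                    cand[m] = v
                    m += 1
        # synchronous: compute all candidate updates from the current state
        for ci in range(m):
            i = cand[ci]
            lo = indptr[i]
            hi = indptr[i + 1]
            if hi == lo:
                newv[ci] = q[i]
                continue
            s = 0.0
            for jj in range(lo, hi):
                s += q[indices[jj]]
            qbar = s / (hi - lo)
            qi = q[i]
            if qi > 0.0:
                if (1.0 - a) * qi <= qbar and qbar <= qi:
                    nv = qi
                else:
                    nv = qbar
            elif qi < 0.0:
                if qi <= qbar and qbar <= (1.0 - a) * qi:
                    nv = qi
                else:
                    nv = qbar
            else:
                nv = (1.0 - a) * qbar if zero_mix else qbar
            if nv > 1.0:
                nv = 1.0
            elif nv < -1.0:
                nv = -1.0
            newv[ci] = nv
        if check_cycle:
            for i in range(n):
                qm2[i] = qm1[i]
                qm1[i] = q[i]
        maxd = 0.0
        fcount = 0
        for ci in range(m):
            i = cand[ci]
            seen[i] = 0
            d = newv[ci] - q[i]
            if d != 0.0:
                ad = -d if d < 0.0 else d
                if ad > maxd:
                    maxd = ad
                q[i] = newv[ci]
                frontier[fcount] = i
                fcount += 1
        steps += 1
        if fcount == 0 or maxd < tol:
            converged = True
            break
        if check_cycle and steps >= 2:
            cd = 0.0
            for i in range(n):
                dd = q[i] - qm2[i]
                if dd < 0.0:
                    dd = -dd
                if dd > cd:
                    cd = dd
            if cd < tol:
                cycle = True
                for i in range(n):
                    q[i] = 0.5 * (q[i] + qm1[i])
                break
    return steps, converged, cycle, fcount, maxd


def _hold_pattern(q: np.ndarray, g: NetworkGraph, params: ModelParams) -> np.ndarray:
    """Boolean mask of nodes currently in the inflexibility band (rule ii)."""
    deg = g.degrees
    social = deg > 0
    qbar = np.zeros_like(q)
    idx = np.flatnonzero(social)
    qbar[idx] = g.row_means(idx, q)
    thr = (1.0 - params.a) * q
    hold = (((q > 0.0) & (qbar >= thr) & (qbar <= q)) |
            ((q < 0.0) & (qbar <= thr) & (qbar >= q)))
    return hold & social


def _steady_state_solve(q: np.ndarray, g: NetworkGraph,
                        params: ModelParams) -> tuple[Optional[np.ndarray], bool]:
    """Fixed point of the frozen branch pattern: (candidate, verified).

    When every remaining change is an adoption (rules i/iii) with a frozen
    set of holding nodes, the dynamics is a linear averaging flow whose
    stable state solves a Dirichlet problem: adopting nodes satisfy
    q_i = mean of neighbors, holding and isolated nodes are boundary
    values.  Closed adopting components (no boundary contact) conserve the
    degree-weighted opinion sum under synchronous averaging and settle at
    (or oscillate around, with the same time average) the degree-weighted
    mean of their current values.  The candidate state is verified against
    the full update rules; ``verified=False`` marks a candidate where some
    holding node's neighbor mean would exit its inflexibility band, so a
    few marginal nodes still need exact sweeps.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse.linalg import LinearOperator, bicgstab

    deg = g.degrees
    a = params.a
    n = g.n_nodes
    social = deg > 0
    idx = np.flatnonzero(social)
    hold = _hold_pattern(q, g, params)
    active = social & ~hold
    if not active.any():
        return q.copy(), True
    # row-normalised adjacency (neighbor-mean operator), built once
    inv_deg = np.zeros(n)
    inv_deg[social] = 1.0 / deg[social]
    P = sp.diags(inv_deg) @ g.adjacency
    c_full = np.ones(n)
    if params.zero_opinion_rule == "mix":
        c_full[(q == 0.0) & social] = 1.0 - a

    # Monotone active-set iteration: solve the frozen-pattern linear fixed
    # point; any holding node whose neighbor mean exits its band at the
    # solution would adopt under the true rules, so it joins the active set
    # and the system is re-solved.  Active nodes never need to leave the
    # set (they satisfy q = qbar exactly), so this terminates.
    for _ in range(40):
        act = np.flatnonzero(active)
        out = q.copy()
        qf = q.copy()
        qf[act] = 0.0
        rhs = (c_full * (P @ qf))[act]
        # components of the active subgraph, to isolate closed (boundary-
        # free, undamped) components where the system is singular
        keep = active[g.edges[:, 0]] & active[g.edges[:, 1]]
        relabel = -np.ones(n, dtype=np.int64)
        relabel[act] = np.arange(act.size)
        sub_edges = relabel[g.edges[keep]]
        sub = sp.coo_matrix(
            (np.ones(2 * sub_edges.shape[0]),
             (np.concatenate([sub_edges[:, 0], sub_edges[:, 1]]),
              np.concatenate([sub_edges[:, 1], sub_edges[:, 0]]))),
            shape=(act.size, act.size)).tocsr()
        n_comp, labels = connected_components(sub, directed=False)
        has_boundary = np.zeros(n_comp, dtype=bool)
        np.logical_or.at(has_boundary, labels, rhs != 0.0)
        damped = np.zeros(n_comp, dtype=bool)
        np.logical_or.at(damped, labels, c_full[act] < 1.0)
        open_rows = (has_boundary | damped)[labels]
        if open_rows.any():
            ro = act[open_rows]
            mask = np.zeros(n)

            def matvec(x, ro=ro, mask=mask):
                mask[ro] = x
                y = x - (c_full[ro] * (P @ mask)[ro])
                mask[ro] = 0.0
                return y

            op = LinearOperator((ro.size, ro.size), matvec=matvec)
            sol, info = bicgstab(op, rhs[open_rows], x0=q[ro],
                                 rtol=1e-12, atol=1e-13, maxiter=1000)
            if info != 0:
                return None, False
            out[ro] = sol
        for comp in np.flatnonzero(~(has_boundary | damped)):
            nodes = act[labels == comp]
            w = deg[nodes].astype(float)
            out[nodes] = float(np.dot(w, q[nodes]) / w.sum())
        if np.abs(out).max() > 1.0 + 1e-9:
            return None, False
        np.clip(out, -1.0, 1.0, out=out)
        qbar = g.row_means(idx, out)
        new = _apply_rules(out[idx], qbar, params)
        viol = np.abs(new - out[idx]) > 1e-8
        if not viol.any():
            return out, True
        grew = active.copy()
        grew[idx[viol]] = True
        if grew.sum() == active.sum():  # no growth yet inconsistent
            return out, False
        active = grew
    return out, False


_CHUNK_STEPS = 60
_SETTLE_DELTA = 0.02


def _relax_arrays(
    q0: np.ndarray,
    g: NetworkGraph,
    params: ModelParams,
    frontier: Optional[np.ndarray] = None,
    accelerate: bool = False,
    monotone: bool = False,
) -> tuple[np.ndarray, int, bool, bool]:
    """Iterate synchronous sweeps until stable (compiled engine).

    ``monotone=True`` marks a relaxation known to move opinions in one
    direction only (an upward perturbation of a stable state at a = 1),
    where period-2 cycles are impossible and their per-sweep bookkeeping
    can be skipped.

    Returns (opinions, steps, converged, cycle_detected).  A period-2
    cycle — possible wherever the map degenerates to plain averaging on a
    bipartite-like structure — is reported via the flag and resolved to the
    cycle average.  With ``accelerate=True`` the slow terminal phase (a
    frozen pattern of adoptions contracting toward its fixed point) is
    short-circuited by solving the linear stable state directly once the
    branch pattern has stopped changing; the solution is verified against
    the full rules and stepping resumes if it does not check out.
    """
    n = g.n_nodes
    q = np.array(q0, dtype=np.float64, copy=True)
    if frontier is None:
        frontier = np.flatnonzero(g.degrees > 0)
    else:
        frontier = np.asarray(frontier, dtype=np.int64)
        frontier = frontier[g.degrees[frontier] > 0]
    fio = np.empty(n, dtype=np.int64)
    fio[:frontier.size] = frontier
    fcount = frontier.size
    indptr, indices = g.csr64
    zero_mix = params.zero_opinion_rule == "mix"
    check_cycle = not (monotone and params.a == 1.0)
    if not accelerate:
        steps, converged, cycle, fcount, _ = _relax_kernel(
            indptr, indices, q, float(params.a), float(params.tol),
            int(params.max_steps), fio, fcount, zero_mix, check_cycle)
        return q, steps, converged, cycle
    total = 0
    converged = cycle = False
    injections = 0
    chunk_i = 0
    while total < params.max_steps:
        chunk = min(_CHUNK_STEPS, params.max_steps - total)
        steps, converged, cycle, fcount, maxd = _relax_kernel(
            indptr, indices, q, float(params.a), float(params.tol),
            chunk, fio, fcount, zero_mix, check_cycle)
        total += steps
        chunk_i += 1
        if converged or cycle:
            break
        # Try the projection once the flow has settled into small steps; a
        # persistent small oscillation can keep the step size up without
        # the pattern really evolving, so escalate after a long grind.
        settled = maxd < _SETTLE_DELTA or (chunk_i >= 10 and chunk_i % 5 == 0)
        if settled and injections <= 25:
            candidate, ok = _steady_state_solve(q, g, params)
            if candidate is not None and ok:
                return candidate, total, True, False
            if candidate is not None and injections < 25:
                # project onto the frozen-pattern fixed point and let exact
                # sweeps settle the marginal band nodes, then re-solve
                q = candidate
                frontier = np.flatnonzero(g.degrees > 0)
                fio[:frontier.size] = frontier
                fcount = frontier.size
            injections += 1
    return q, total, converged, cycle


def _relax_arrays_py(
    q0: np.ndarray,
    g: NetworkGraph,
    params: ModelParams,
    frontier: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, int, bool, bool]:
    """Pure-numpy engine with the same contract as :func:`_relax_arrays`;
    kept as an independent code path for cross-checking."""
    deg = g.degrees
    q = np.array(q0, dtype=np.float64, copy=True)
    if frontier is None:
        frontier = np.flatnonzero(deg > 0)
    else:
        frontier = np.asarray(frontier, dtype=np.int64)
        frontier = frontier[deg[frontier] > 0]
    qm1 = q.copy()
    qm2: Optional[np.ndarray] = None
    steps = 0
    converged = False
    cycle = False
    for _ in range(params.max_steps):
        if frontier.size == 0:
            converged = True
            break
        cand = g.neighborhood_closure(frontier)
        cand = cand[deg[cand] > 0]
        qbar = g.row_means(cand, q)
        new = _apply_rules(q[cand], qbar, params)
        delta = new - q[cand]
        changed = delta != 0.0
        qm2 = qm1
        qm1 = q
        q = q.copy()
        q[cand] = new
        steps += 1
        if not changed.any() or np.abs(delta).max() < params.tol:
            converged = True
            break
        if steps >= 2 and np.max(np.abs(q - qm2)) < params.tol:
            cycle = True
            q = 0.5 * (q + qm1)
            break
        frontier = cand[changed]
    return q, steps, converged, cycle


def relax(state: OpinionState, params: ModelParams) -> OpinionState:
    """Iterate :func:`step` until a stable state (or 2-cycle, or max_steps).

    The returned state carries ``converged`` / ``cycle_detected`` flags;
    non-convergence is never raised.  When a period-2 cycle is detected the
    reported opinions are the average over the two cycle phases.
    """
    q, steps, converged, cycle = _relax_arrays(state.opinions, state.network, params)
    return OpinionState(q, state.network, state.step + steps, converged, cycle)


def write_state_csv(state: OpinionState, path) -> None:
    """Two-column CSV (node_id, q); the network is stored separately."""
    with open(path, "w") as fh:
        fh.write("node_id,q\n")
        for i, q in enumerate(state.opinions):
            fh.write(f"{i},{float(q)!r}\n")


def read_state_csv(path, network: NetworkGraph) -> OpinionState:
    opinions = np.full(network.n_nodes, np.nan)
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "node_id,q":
            raise ValueError("expected a 'node_id,q' header")
        for line in fh:
            i, q = line.split(",")
            opinions[int(i)] = float(q)
    if np.isnan(opinions).any():
        raise ValueError("state file does not cover every node")
    return OpinionState(opinions, network)
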