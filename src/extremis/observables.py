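"""Opinion-fraction and extremist-cluster (e-cluster) statistics.

``f`` is the fraction of nodes with a given polarity (q > 0 or q < 0) and
``f_e`` the fraction holding the extreme version (|q| > q_e); both are
normalised by the total node count.  E-clusters are connected components of
the subgraph induced by extremists of one polarity; their sizes are
normalised by the size of the largest component of the *full* network.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse.csgraph import connected_components

from .model import OpinionState

__all__ = ["OpinionFractions", "EClusterStats", "fractions", "e_clusters"]


@dataclasses.dataclass(frozen=True)
class OpinionFractions:
    f_pos: float
    f_neg: float
    fe_pos: float
    fe_neg: float
    n_total: int


@dataclasses.dataclass(frozen=True)
class EClusterStats:
    """Largest (g1) and second-largest (g2) normalised e-cluster sizes."""

    g1: float
    g2: float
    n_clusters: int
    sizes: np.ndarray  # raw (unnormalised) cluster sizes, descending


def fractions(state: OpinionState, q_e: float) -> OpinionFractions:
    """Strict-inequality membership counts over the whole network."""
    q = state.opinions
    n = q.size
    if n == 0:
        return OpinionFractions(0.0, 0.0, 0.0, 0.0, 0)
    return OpinionFractions(
        f_pos=float((q > 0.0).sum()) / n,
        f_neg=float((q < 0.0).sum()) / n,
        fe_pos=float((q > q_e).sum()) / n,
        fe_neg=float((q < -q_e).sum()) / n,
        n_total=n,
    )


def e_clusters(state: OpinionState, q_e: float, polarity: str = "positive") -> EClusterStats:
    """Connected components of same-polarity extremists.

    Sizes are normalised by the largest-component size of the full network,
    so g1 = 1 means the extremists span the whole giant component.
    """
    q = state.opinions
    if polarity == "positive":
        members = np.flatnonzero(q > q_e)
    elif polarity == "negative":
        members = np.flatnonzero(q < -q_e)
    else:
        raise ValueError("polarity must be 'positive' or 'negative'")
    norm = state.network.largest_component_size
    if members.size == 0:
        return EClusterStats(0.0, 0.0, 0, np.empty(0, dtype=np.int64))
    sub = state.network.adjacency[members][:, members]
    n_comp, labels = connected_components(sub, directed=False)
    sizes = np.sort(np.bincount(labels))[::-1].astype(np.int64)
    g1 = sizes[0] / norm if norm else 0.0
    g2 = sizes[1] / norm if n_comp > 1 and norm else 0.0
    return EClusterStats(float(g1), float(g2), int(n_comp), sizes)
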