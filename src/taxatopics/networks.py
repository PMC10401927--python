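"""Within-topic rank-correlation co-occurrence networks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import CountTable
from .diff_abundance import benjamini_hochberg
from .preprocess import relative_abundance

__all__ = ["TopicNetwork", "spearman", "topic_network"]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p from
    the t approximation.  Constant input is an error (no rank order)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class TopicNetwork:
    """Undirected genus co-occurrence graph for one topic.

    Edges carry (genus, genus, rho, p, q); edge weight is |rho|.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float, float, float]]
    alpha: float
    adjust: str
    notes: list[str] = field(default_factory=list)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, rho, p, q in self.edges:
            g.add_edge(a, b, rho=rho, p=p, q=q, weight=abs(rho))
        return g

    def edge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.edges, columns=["genus_a", "genus_b", "rho", "p", "q"]
        )


def topic_network(
    table: CountTable,
    genera: list[str],
    alpha: float = 0.05,
    adjust: str = "none",
) -> TopicNetwork:
    """Pairwise Spearman tests among ``genera`` on relative abundances.

    Edges are kept where the significance rule passes: raw p <= alpha by
    default, or BH q <= alpha with ``adjust='BH'``.  Constant genera are
    skipped with a note.
    """
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    missing = [g for g in genera if g not in table.feature_ids]
    if missing:
        raise ValueError(f"genera not in table: {missing}")
    notes: list[str] = []
    if len(genera) < 2:
        warnings.warn("fewer than 2 genera: empty network", stacklevel=2)
        return TopicNetwork(list(genera), [], alpha, adjust, ["fewer than 2 genera"])
    rel = relative_abundance(table)
    cols = {g: rel[:, table.feature_ids.index(g)] for g in genera}
    tested: list[tuple[str, str, float, float]] = []
    for i, a in enumerate(genera):
        for b in genera[i + 1 :]:
            try:
                rho, p = spearman(cols[a], cols[b])
            except ValueError as exc:
                notes.append(f"skipped ({a}, {b}): {exc}")
                continue
            tested.append((a, b, rho, p))
    if not tested:
        return TopicNetwork(list(genera), [], alpha, adjust, notes)
    pvals = np.array([t[3] for t in tested])
    qvals = benjamini_hochberg(pvals)
    crit = qvals if adjust == "BH" else pvals
    edges = [
        (a, b, rho, p, float(q))
        for (a, b, rho, p), q, c in zip(tested, qvals, crit)
        if c <= alpha
    ]
    return TopicNetwork(list(genera), edges, alpha, adjust, notes)
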