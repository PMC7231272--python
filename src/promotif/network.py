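"""Differential expression, co-expression graphs, and MCODE complex detection.

The differential-expression caller applies a Welch two-sample test per gene on
log2 expression with an optional variance-shrinkage weight, then the standard
significance rule: BH-adjusted p < 0.05 and fold change strictly greater than
2 (|log2FC| > 1).

The network builder connects gene pairs whose absolute rank (Spearman)
correlation across samples reaches a threshold.  It deliberately replaces
composite meta-analysis networks (which need external association databases)
with a self-contained similarity graph; the clusters-out contract is the same.

MCODE: each node is weighted by ``k_max * density(N[v])`` where ``k_max`` is
the order of the highest k-core (k >= 2) of the node's closed neighbourhood
and the density is that of the closed-neighbourhood subgraph; nodes whose
neighbourhood has no 2-core weigh 0.  Complexes grow by BFS from unvisited
seeds in descending weight, admitting neighbours weighing at least
``(1 - node_score_cutoff) * seed_weight``; *haircut* iteratively prunes
members left with fewer than two in-complex neighbours, and *fluff* appends
unvisited neighbours whose closed-neighbourhood density exceeds a cutoff
(fluffed nodes stay available to later complexes).  All tie-breaks are
lexicographic on node id, so results are independent of edge-list order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

DE_MAX_ADJ_P = 0.05
DE_MIN_ABS_LOG2_FC = 1.0  # fold change strictly > 2


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def call_de(expr: pd.DataFrame, sample_groups: Sequence[str] | pd.Series,
            contrast: tuple[str, str], shrink: float = 0.0) -> pd.DataFrame:
    """Welch-test differential expression between two conditions.

    Parameters
    ----------
    expr : DataFrame
        log2 expression, genes x samples, no missing entries.
    sample_groups : sequence
        Condition label per sample (column order).
    contrast : (str, str)
        ``(test, control)`` condition names; log2FC is test minus control.
    shrink : float in [0, 1]
        Weight pulling each gene's per-group variance toward the mean variance
        of all genes in that group (0 = plain Welch).

    Returns a DataFrame with log2_fc, p, p_adj and the boolean ``de`` flag
    (p_adj < 0.05 and |log2FC| strictly > 1).
    """
    groups = np.asarray(sample_groups)
    if groups.shape[0] != expr.shape[1]:
        raise ValueError("sample_groups length must match expression columns")
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must be in [0, 1]")
    xa = expr.loc[:, groups == contrast[0]].to_numpy(dtype=float)
    xb = expr.loc[:, groups == contrast[1]].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(f"need >=2 replicates per condition, got {na} and {nb}")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    if shrink > 0:
        va = (1 - shrink) * va + shrink * va.mean()
        vb = (1 - shrink) * vb + shrink * vb.mean()
    lfc = ma - mb
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
        dof = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    # zero-variance genes: the difference is exact
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    p_adj = bh_fdr(p)
    out = pd.DataFrame({
        "log2_fc": lfc, "p": p, "p_adj": p_adj,
        "de": (p_adj < DE_MAX_ADJ_P) & (np.abs(lfc) > DE_MIN_ABS_LOG2_FC),
    }, index=expr.index)
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# Co-expression graph
# ---------------------------------------------------------------------------

def build_network(expr: pd.DataFrame, genes: Sequence[str] | None = None,
                  method: str = "spearman", min_similarity: float = 0.7) -> nx.Graph:
    """Similarity graph: edge (i, j) iff |correlation across samples| >= threshold."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to build a co-expression network")
    sub = expr.loc[list(genes)] if genes is not None else expr
    x = sub.to_numpy(dtype=float)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    g = nx.Graph()
    g.add_nodes_from(sub.index)
    ii, jj = np.nonzero(np.triu(np.abs(corr) >= min_similarity, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(sub.index[i], sub.index[j], weight=float(corr[i, j]))
    return g


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

@dataclass
class Complex:
    """An MCODE cluster: member nodes, the seed it grew from, and its density."""

    members: frozenset
    seed: Hashable
    density: float

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, node) -> bool:
        return node in self.members

    @property
    def score(self) -> float:
        return self.density * len(self.members)


def _closed_neighborhood_density(g: nx.Graph, node) -> float:
    nodes = set(g[node]) | {node}
    return nx.density(g.subgraph(nodes)) if len(nodes) > 1 else 0.0


def mcode_weights(g: nx.Graph) -> dict:
    """Deterministic MCODE node weights; isolated and tree-like nodes weigh 0."""
    weights = {}
    for node in g.nodes:
        nbhd = set(g[node]) | {node}
        sub = g.subgraph(nbhd)
        k_max = max(nx.core_number(sub).values(), default=0)
        if k_max < 2:
            weights[node] = 0.0
        else:
            weights[node] = float(k_max) * nx.density(sub)
    return weights


def _haircut(g: nx.Graph, members: set) -> set:
    """Iteratively drop members with fewer than two in-complex neighbours."""
    members = set(members)
    while True:
        drop = [n for n in members if sum(1 for m in g[n] if m in members) < 2]
        if not drop:
            return members
        members.difference_update(drop)


def mcode_complexes(g: nx.Graph, node_score_cutoff: float = 0.2,
                    haircut: bool = True, fluff: bool = True,
                    fluff_density: float = 0.5) -> list[Complex]:
    """Detect complexes by seeded BFS over MCODE node weights.

    Returned complexes are sorted by descending score (density x size); core
    members belong to one complex only, fluffed members may repeat.
    """
    weights = mcode_weights(g)
    order = sorted(g.nodes, key=lambda n: (-weights[n], str(n)))
    visited: set = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        cutoff = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        visited.add(seed)
        queue = [seed]
        while queue:
            u = queue.pop(0)
            for nb in sorted(g[u], key=str):
                if nb not in visited and weights[nb] >= cutoff:
                    visited.add(nb)
                    members.add(nb)
                    queue.append(nb)
        if haircut:
            members = _haircut(g, members)
        if len(members) < 2:
            continue
        if fluff:
            fluffed = set(members)
            for u in sorted(members, key=str):
                for nb in sorted(g[u], key=str):
                    if nb not in visited and nb not in fluffed and \
                            _closed_neighborhood_density(g, nb) > fluff_density:
                        fluffed.add(nb)
            members = fluffed
        complexes.append(Complex(frozenset(members), seed,
                                 nx.density(g.subgraph(members))))
    complexes.sort(key=lambda c: (-c.score, str(c.seed)))
    return complexes


def select_anchor_cluster(complexes: Iterable[Complex], anchor) -> Complex | None:
    """The highest-scoring complex containing the anchor gene, or None (warned)."""
    for cx in sorted(complexes, key=lambda c: (-c.score, str(c.seed))):
        if anchor in cx:
            return cx
    import logging
    logging.getLogger(__name__).warning("anchor %r is not in any complex", anchor)
    return None
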