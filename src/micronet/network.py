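"""Signed directed network construction and the comparison statistics.

Covers the community-level summaries used to contrast the benign and stress
conditions: directed connectance, signed degree/in-degree/out-degree,
classification of genus pairs into the five ecological states (mutualism,
commensalism, antagonism, amensalism, competition), common/specific node
partitions, rank and product-moment correlations between conditions, and
Wilcoxon rank-sum group tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SignedDirectedNetwork",
    "PairState",
    "NetworkComparison",
    "build_network",
    "connectance",
    "signed_degree",
    "classify_pair",
    "pair_state_table",
    "positive_link_proportion",
    "partition_nodes",
    "induced_subnetwork",
    "wilcoxon_degree_test",
    "spearman_degree_correlation",
    "graph_correlation",
    "percent_change",
]

_STATE_BY_PATTERN = {
    (1, 1): "mutualism",
    (1, 0): "commensalism",
    (0, 1): "commensalism",
    (1, -1): "antagonism",
    (-1, 1): "antagonism",
    (-1, 0): "amensalism",
    (0, -1): "amensalism",
    (-1, -1): "competition",
    (0, 0): "none",
}

STATE_ORDER = ("mutualism", "commensalism", "antagonism", "amensalism",
               "competition")

#: The nonstandard spelling used in some tabulations.
STATE_ALIASES = {"amenalism": "amensalism"}


@dataclass(frozen=True)
class SignedDirectedNetwork:
    """Genus nodes plus directed signed edges.

    ``edges`` maps ordered (source, target) pairs to (sign, strength); at
    most one edge per ordered pair, no self-edges, sign in {+1, -1}.
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[str, str], tuple[int, float]]
    condition: str = ""

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for (u, v), (s, _w) in self.edges.items():
            if u == v:
                raise ValueError(f"self-edge on {u!r} not allowed")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint missing from node set: {(u, v)}")
            if s not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {s}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sign(self, u: str, v: str) -> int:
        """Sign of the edge u -> v, 0 when absent."""
        e = self.edges.get((u, v))
        return e[0] if e is not None else 0

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(condition=self.condition)
        g.add_nodes_from(self.nodes)
        for (u, v), (s, w) in self.edges.items():
            g.add_edge(u, v, sign=s, strength=w)
        return g


@dataclass(frozen=True)
class PairState:
    """Classification of one unordered genus pair by its two directed signs."""

    pair: frozenset
    signs: tuple[int, int]
    state: str


@dataclass(frozen=True)
class NetworkComparison:
    """Node partition between two conditions plus attached test results."""

    common: tuple[str, ...]
    specific_a: tuple[str, ...]
    specific_b: tuple[str, ...]
    tests: dict = field(default_factory=dict)


def build_network(edges: Iterable[tuple], nodes: Sequence[str],
                  condition: str = "") -> SignedDirectedNetwork:
    """Assemble a network from (source, target, sign[, strength]) tuples.

    ``nodes`` is the full genus list surviving the prevalence filter;
    isolated genera stay as nodes.  Duplicate ordered pairs are rejected.
    """
    emap: dict[tuple[str, str], tuple[int, float]] = {}
    for e in edges:
        u, v, s = e[0], e[1], int(e[2])
        w = float(e[3]) if len(e) > 3 else float(s)
        if (u, v) in emap:
            raise ValueError(f"duplicate edge {u}->{v}")
        emap[(u, v)] = (s, w)
    return SignedDirectedNetwork(nodes=tuple(nodes), edges=emap,
                                 condition=condition)


def connectance(net: SignedDirectedNetwork) -> float:
    """Directed connectance L / (S(S-1)), self-edges excluded.

    The probability that an ordered pair of distinct genera carries an
    interaction.
    """
    s = net.n_nodes
    if s < 2:
        raise ValueError("connectance needs at least two nodes")
    return net.n_edges / (s * (s - 1))


def signed_degree(net: SignedDirectedNetwork, node: str, sign: int,
                  direction: str = "total") -> int:
    """Number of links of one sign touching a node.

    ``direction`` is "in" (incoming), "out" (outgoing) or "total"
    (in + out).
    """
    if node not in set(net.nodes):
        raise KeyError(f"unknown node {node!r}")
    if direction not in ("in", "out", "total"):
        raise ValueError("direction must be 'in', 'out' or 'total'")
    n_in = sum(1 for (u, v), (s, _) in net.edges.items()
               if v == node and s == sign)
    n_out = sum(1 for (u, v), (s, _) in net.edges.items()
                if u == node and s == sign)
    return {"in": n_in, "out": n_out, "total": n_in + n_out}[direction]


def classify_pair(s_ij: int, s_ji: int) -> str:
    """Ecological state of a genus pair from its two directed signs.

    (+,+) mutualism, (+,0) commensalism, (+,-) antagonism, (-,0)
    amensalism, (-,-) competition, (0,0) none.  Symmetric in argument
    order.
    """
    key = (int(np.sign(s_ij)), int(np.sign(s_ji)))
    if key not in _STATE_BY_PATTERN:
        raise ValueError(f"signs must be in {{-1, 0, +1}}, got {key}")
    return _STATE_BY_PATTERN[key]


def _interacting_pairs(net: SignedDirectedNetwork):
    seen = set()
    for (u, v) in net.edges:
        pair = frozenset((u, v))
        if pair in seen:
            continue
        seen.add(pair)
        yield tuple(sorted(pair))


def pair_state_table(net: SignedDirectedNetwork) -> dict[str, dict[str, float]]:
    """Counts and percentages of each pair state among interacting pairs.

    Only pairs with at least one edge enter the denominator; percentages
    sum to 100 up to rounding.
    """
    counts = {s: 0 for s in STATE_ORDER}
    for (u, v) in _interacting_pairs(net):
        state = classify_pair(net.sign(u, v), net.sign(v, u))
        counts[state] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("network has no interacting pairs")
    return {s: {"count": c, "percent": 100.0 * c / total}
            for s, c in counts.items()}


def positive_link_proportion(net: SignedDirectedNetwork) -> float:
    """Percentage of directed links that are positive."""
    if net.n_edges == 0:
        raise ValueError("positive-link proportion undefined on an "
                         "edgeless network")
    n_pos = sum(1 for (s, _) in net.edges.values() if s > 0)
    return 100.0 * n_pos / net.n_edges


def partition_nodes(net_a: SignedDirectedNetwork,
                    net_b: SignedDirectedNetwork) -> NetworkComparison:
    """Split nodes into common, A-specific and B-specific sets."""
    a, b = set(net_a.nodes), set(net_b.nodes)
    return NetworkComparison(
        common=tuple(sorted(a & b)),
        specific_a=tuple(sorted(a - b)),
        specific_b=tuple(sorted(b - a)),
    )


def induced_subnetwork(net: SignedDirectedNetwork,
                       subset: Iterable[str]) -> SignedDirectedNetwork:
    """Subnetwork on ``subset``: keeps edges with both endpoints inside."""
    keep = set(subset)
    unknown = keep - set(net.nodes)
    if unknown:
        raise KeyError(f"nodes not in network: {sorted(unknown)}")
    edges = {(u, v): e for (u, v), e in net.edges.items()
             if u in keep and v in keep}
    return SignedDirectedNetwork(nodes=tuple(n for n in net.nodes if n in keep),
                                 edges=edges, condition=net.condition)


def wilcoxon_degree_test(group1: Sequence[float],
                         group2: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two degree samples.

    Exact enumeration when both groups have <= 10 observations and no ties;
    otherwise the tie-corrected normal approximation (no continuity
    correction).  Returns (rank-sum statistic of group1, p).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and tie_free) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    # rank-sum statistic W = U + n1(n1+1)/2
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return w, float(res.pvalue)


def spearman_degree_correlation(net_a: SignedDirectedNetwork,
                                net_b: SignedDirectedNetwork,
                                common: Sequence[str],
                                direction: str = "total",
                                sign: int | None = None
                                ) -> tuple[float, float]:
    """Spearman rank correlation of common genera's degrees across conditions.

    ``sign=None`` counts links of both signs; otherwise only the requested
    sign.  Average ranks for ties.  Returns (rho, p).
    """
    def deg(net, node):
        if sign is None:
            return (signed_degree(net, node, 1, direction)
                    + signed_degree(net, node, -1, direction))
        return signed_degree(net, node, sign, direction)

    a = [deg(net_a, n) for n in common]
    b = [deg(net_b, n) for n in common]
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def graph_correlation(net_a: SignedDirectedNetwork,
                      net_b: SignedDirectedNetwork,
                      common: Sequence[str],
                      weighted: bool = False) -> float:
    """Product-moment correlation between two induced common subnetworks.

    The off-diagonal cells of the two adjacency matrices (binary edge
    presence by default; absolute strength when ``weighted``), aligned on
    the same node ordering, are vectorized and Pearson-correlated.  Sign
    information is not included.
    """
    common = list(common)
    if len(common) < 2:
        raise ValueError("need at least two common nodes")
    sub_a = induced_subnetwork(net_a, common)
    sub_b = induced_subnetwork(net_b, common)

    def adj(net):
        idx = {n: i for i, n in enumerate(common)}
        m = np.zeros((len(common), len(common)))
        for (u, v), (s, w) in net.edges.items():
            m[idx[u], idx[v]] = abs(w) if weighted else 1.0
        return m

    ma, mb = adj(sub_a), adj(sub_b)
    off = ~np.eye(len(common), dtype=bool)
    va, vb = ma[off], mb[off]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("degenerate adjacency (constant off-diagonal): "
                         "correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def percent_change(before: float, after: float) -> float:
    """Percentage decrease 100 * (before - after) / before."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (before - after) / before
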