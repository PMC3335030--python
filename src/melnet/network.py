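"""Desk-scale consensus directed gene-network inference.

The approach mirrors the architecture of subsample-and-combine Bayesian
network methods: many overlapping small subnetworks are fitted to
correlation neighbourhoods of the data, and directed edges appearing in a
sufficient fraction of the subnetworks containing both endpoints are
combined into a consensus network.  Hubs are consensus nodes with many
downstream children; the biological reading is that a hub summarises the
activity of its co-expressed module.

Subnetwork structure search is greedy hill climbing over single-edge
add/delete/reverse moves, maximising a decomposable Gaussian score with
acyclicity enforced at every move and a bounded number of parents per node.
The score is the extended BIC (EBIC, gamma = 1): ordinary BIC plus
``k log(p_candidates)`` for ``k`` parents, the standard correction for
structure recovery when the sample is small relative to the number of
candidate edges — plain BIC admits an edge for any |rho| above roughly
``sqrt(ln n / n)`` (~0.26 at n = 60), which at consensus scale floods the
network with chance edges.
Edge directionality in such networks is statistically underdetermined;
direction accuracy is reported by callers but never asserted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import CorrelationMatrix, spearman_matrix
from .dataio import CONTROL, DataFormatError, ExpressionMatrix, PerturbationDesign

__all__ = [
    "SubnetworkDAG",
    "ConsensusNetwork",
    "HubRecord",
    "sample_neighbourhoods",
    "fit_subnetwork",
    "consensus_network",
    "find_hubs",
    "hub_conservation",
    "parent_knockdown_consistency",
]

RIDGE = 1e-8  # stabiliser for singular local regressions
MAX_PARENTS = 3
EBIC_GAMMA = 1.0


@dataclass
class SubnetworkDAG:
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    score: float

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for p, c in self.edges:
            if p not in node_set or c not in node_set:
                raise DataFormatError("edge endpoint outside subnetwork nodes")
        g = nx.DiGraph(list(self.edges))
        if not nx.is_directed_acyclic_graph(g):
            raise DataFormatError("subnetwork contains a cycle")


@dataclass
class ConsensusNetwork:
    """Directed edges with consensus frequencies >= freq_threshold."""

    edges: dict[tuple[str, str], float]
    freq_threshold: float
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e, f in self.edges.items():
            if not 0 < f <= 1:
                raise DataFormatError(f"edge {e} frequency {f} outside (0, 1]")
            if f < self.freq_threshold - 1e-12:
                raise DataFormatError(f"edge {e} below freq_threshold")
        if not self.nodes:
            self.nodes = sorted({g for e in self.edges for g in e})

    @property
    def child_count(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for p, _c in self.edges:
            out[p] += 1
        return dict(out)

    def children_of(self, gene: str) -> list[str]:
        return sorted(c for p, c in self.edges if p == gene)

    def parents(self) -> list[str]:
        return sorted({p for p, _ in self.edges})


@dataclass
class HubRecord:
    gene: str
    n_children: int
    children: list[str]
    enriched_sets: list = field(default_factory=list)
    conserved: bool | None = None
    n_conserved_children: int | None = None
    measurable: bool = True


def sample_neighbourhoods(
    corr: CorrelationMatrix, n_subnets: int, subnet_size: int, seed: int
) -> list[tuple[str, ...]]:
    """Correlation neighbourhoods: a seed gene plus its top-|rho| neighbours.

    Seed genes cycle through a seeded permutation of all genes, so every
    gene appears in at least one subnetwork once ``n_subnets >= n_genes``.
    """
    n = len(corr.gene_ids)
    if subnet_size < 3:
        raise DataFormatError("subnet_size must be >= 3")
    if subnet_size > n:
        raise DataFormatError(f"subnet_size={subnet_size} exceeds n_genes={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    absrho = np.abs(corr.rho)
    out = []
    for s in range(n_subnets):
        i = int(order[s % n])
        # stable ranking: descending |rho|, gene index breaks ties
        pref = np.lexsort((np.arange(n), -absrho[i]))
        neigh = [j for j in pref if j != i][: subnet_size - 1]
        nodes = tuple(corr.gene_ids[j] for j in sorted([i, *neigh]))
        out.append(nodes)
    return out


def _local_score(
    Y: np.ndarray, child: int, parents: tuple[int, ...], n: int,
    gamma: float = EBIC_GAMMA,
) -> float:
    """Gaussian EBIC node score.

    -n/2 log(sigma^2) - (|P|+1)/2 log n - gamma |P| log(m-1), with m the
    number of candidate nodes.  Constant terms shared by every structure
    over the same nodes are dropped; regressions are ridge-stabilised with
    a documented constant.
    """
    y = Y[:, child]
    if parents:
        X = Y[:, list(parents)]
        XtX = X.T @ X + RIDGE * np.eye(len(parents))
        beta = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta
    else:
        resid = y
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    k = len(parents)
    m = Y.shape[1]
    return (
        -0.5 * n * np.log(sigma2)
        - 0.5 * (k + 1) * np.log(n)
        - gamma * k * np.log(max(m - 1, 1))
    )


def fit_subnetwork(
    expr: ExpressionMatrix,
    nodes,
    max_parents: int = MAX_PARENTS,
) -> SubnetworkDAG:
    """Greedy hill-climbing DAG search over the given nodes.

    Single-edge add/delete/reverse moves from the empty graph, deterministic
    scan order, terminating at a local optimum of the BIC score.
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise DataFormatError("need at least 2 nodes")
    if expr.n_samples < 10:
        raise DataFormatError("need >= 10 samples for subnetwork fitting")
    sub = expr.values.loc[nodes]
    Y = sub.to_numpy(dtype=float).T  # samples x nodes
    Y = Y - Y.mean(axis=0)
    n, m = Y.shape

    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def score(child: int, parents: frozenset[int]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in cache:
            cache[key] = _local_score(Y, child, key[1], n)
        return cache[key]

    parents: list[frozenset[int]] = [frozenset() for _ in range(m)]
    children: list[set[int]] = [set() for _ in range(m)]

    def creates_cycle(u: int, v: int) -> bool:
        # would u -> v close a cycle? i.e. is u reachable from v?
        stack, seen = [v], set()
        while stack:
            w = stack.pop()
            if w == u:
                return True
            if w in seen:
                continue
            seen.add(w)
            stack.extend(children[w])
        return False

    improved = True
    while improved:
        improved = False
        best_delta, best_move = 1e-9, None
        for u in range(m):
            for v in range(m):
                if u == v:
                    continue
                if u in parents[v]:
                    # delete u -> v
                    delta = score(v, parents[v] - {u}) - score(v, parents[v])
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", u, v)
                    # reverse to v -> u
                    if len(parents[u]) < max_parents:
                        # temporarily ignore u->v when checking reachability
                        children[u].discard(v)
                        cyc = creates_cycle(v, u)
                        children[u].add(v)
                        if not cyc:
                            delta = (
                                score(v, parents[v] - {u})
                                - score(v, parents[v])
                                + score(u, parents[u] | {v})
                                - score(u, parents[u])
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", u, v)
                else:
                    if len(parents[v]) < max_parents and not creates_cycle(u, v):
                        delta = score(v, parents[v] | {u}) - score(v, parents[v])
                        if delta > best_delta:
                            best_delta, best_move = delta, ("add", u, v)
        if best_move is not None:
            op, u, v = best_move
            if op == "add":
                parents[v] = parents[v] | {u}
                children[u].add(v)
            elif op == "del":
                parents[v] = parents[v] - {u}
                children[u].discard(v)
            else:  # reverse
                parents[v] = parents[v] - {u}
                children[u].discard(v)
                parents[u] = parents[u] | {v}
                children[v].add(u)
            improved = True

    total = sum(score(v, parents[v]) for v in range(m))
    edges = frozenset(
        (nodes[u], nodes[v]) for v in range(m) for u in parents[v]
    )
    return SubnetworkDAG(tuple(nodes), edges, float(total))


def consensus_network(
    subnets: list[SubnetworkDAG],
    freq_threshold: float = 0.2,
    denominator: str = "cooccurrence",
    directed: bool = True,
) -> ConsensusNetwork:
    """Combine subnetwork edges into a consensus network.

    The frequency of a directed edge a->b is the number of subnetworks
    containing the edge divided by the number containing both a and b
    (``denominator='cooccurrence'``; ``'all'`` divides by the total
    subnetwork count).  With ``directed=False`` the two directions are
    pooled into a single undirected edge (stored in lexicographic order).
    """
    if not subnets:
        raise DataFormatError("need at least one subnetwork")
    if not 0 < freq_threshold <= 1:
        raise DataFormatError("freq_threshold must lie in (0, 1]")
    if denominator not in ("cooccurrence", "all"):
        raise DataFormatError(f"unknown denominator {denominator!r}")

    edge_counts: Counter[tuple[str, str]] = Counter()
    pair_counts: Counter[frozenset[str]] = Counter()
    all_nodes: set[str] = set()
    for sn in subnets:
        all_nodes.update(sn.nodes)
        for e in sn.edges:
            key = e if directed else tuple(sorted(e))
            edge_counts[key] += 1
    if denominator == "cooccurrence":
        for sn in subnets:
            pairs = {
                frozenset((a, b))
                for e in edge_counts
                for a, b in [e]
                if a in set(sn.nodes) and b in set(sn.nodes)
            }
            for p in pairs:
                pair_counts[p] += 1

    edges = {}
    for (a, b), cnt in edge_counts.items():
        denom = (
            pair_counts[frozenset((a, b))]
            if denominator == "cooccurrence"
            else len(subnets)
        )
        freq = cnt / denom if denom else 0.0
        if freq >= freq_threshold:
            edges[(a, b)] = float(min(freq, 1.0))
    return ConsensusNetwork(edges, freq_threshold, sorted(all_nodes))


def find_hubs(net: ConsensusNetwork, min_children: int) -> list[HubRecord]:
    """Nodes with >= min_children consensus children, by descending degree.

    Ties are broken lexicographically by gene id.
    """
    counts = net.child_count
    hubs = [
        HubRecord(g, c, net.children_of(g))
        for g, c in counts.items()
        if c >= min_children
    ]
    hubs.sort(key=lambda h: (-h.n_children, h.gene))
    return hubs


def hub_conservation(
    net: ConsensusNetwork,
    other: ExpressionMatrix,
    rho_threshold: float = 0.4,
    min_conserved_children: int = 10,
    hubs: list[HubRecord] | None = None,
    min_children: int = 1,
) -> list[HubRecord]:
    """Count hub-child correlations conserved in another dataset.

    A hub is conserved when at least ``min_conserved_children`` of its
    children have |rho(hub, child)| >= ``rho_threshold`` across the other
    dataset's samples.  Hubs absent from the other dataset are flagged
    unmeasurable and not conserved.
    """
    if hubs is None:
        hubs = find_hubs(net, min_children)
    other_genes = set(other.gene_ids)
    out = []
    for h in hubs:
        if h.gene not in other_genes:
            out.append(
                HubRecord(h.gene, h.n_children, h.children, h.enriched_sets,
                          conserved=False, n_conserved_children=0, measurable=False)
            )
            continue
        kids = [c for c in h.children if c in other_genes]
        n_cons = 0
        if kids:
            sub = other.subset_genes([h.gene] + kids)
            corr = spearman_matrix(sub)
            hub_row = corr.rho[0, 1:]
            n_cons = int(np.sum(np.abs(hub_row) >= rho_threshold))
        out.append(
            HubRecord(h.gene, h.n_children, h.children, h.enriched_sets,
                      conserved=n_cons >= min_conserved_children,
                      n_conserved_children=n_cons, measurable=True)
        )
    return out


def parent_knockdown_consistency(
    net: ConsensusNetwork,
    expr: ExpressionMatrix,
    design: PerturbationDesign,
) -> pd.DataFrame:
    """Child response to knockdown of its consensus parent.

    For each consensus edge whose parent was siRNA-targeted, and each sample
    targeting that parent, compute on the linear scale the ratio of the
    child's expression in that sample to the child's median across all
    samples, reported with the fold-change sign convention (r if r >= 1,
    else -1/r, so the value is always <= -1 or >= 1), paired with the
    parent-child Spearman rho across the whole dataset.
    """
    targeted = [t for t in design.targets() if t in set(net.parents())]
    if not targeted:
        raise DataFormatError("no consensus parent was siRNA-targeted")
    linear = np.power(2.0, expr.values)
    medians = linear.median(axis=1)
    corr_cache: dict[tuple[str, str], float] = {}

    def pair_rho(a: str, b: str) -> float:
        if (a, b) not in corr_cache:
            sub = spearman_matrix(expr.subset_genes([a, b]))
            corr_cache[(a, b)] = float(sub.rho[0, 1])
        return corr_cache[(a, b)]

    rows = []
    for parent in targeted:
        for child in net.children_of(parent):
            if child not in linear.index:
                continue
            med = float(medians[child])
            if med == 0:
                raise DataFormatError(f"child {child!r} has zero median expression")
            for sample in design.samples_targeting(parent):
                r = float(linear.at[child, sample]) / med
                signed = r if r >= 1 else -1.0 / r
                rows.append(
                    {
                        "parent": parent,
                        "child": child,
                        "sample": sample,
                        "signed_ratio": signed,
                        "rho": pair_rho(parent, child),
                    }
                )
    return pd.DataFrame(rows)
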