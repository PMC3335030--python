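"""Rank correlations, Ward clustering on 1-|rho|, and cluster selection.

The dissimilarity between two genes is ``1 - |rho|`` where rho is Spearman's
rank correlation across samples, so positively and negatively correlated
genes can land in the same cluster.  The dendrogram is cut into *k* groups
and clusters are retained when they have more than 5 members, a minimum
pairwise |rho| of at least 0.4, and a median pairwise |rho| of at least 0.5.
Because the dissimilarity is built from |rho|, both retention rules are
applied to |rho|.

Ward linkage is computed "ward.D"-style: the Lance-Williams ward recurrence
applied to the raw 1-|rho| dissimilarities.  scipy's ``linkage`` applies
that recurrence to squared inputs, so feeding it ``sqrt(d)`` yields exactly
the ward.D tree on ``d`` (merge heights come back square-rooted; topology
and cut structure are what matter here and are identical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .dataio import DataFormatError, ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "Cluster",
    "ClusterSet",
    "spearman_matrix",
    "ward_linkage",
    "ward_cluster",
    "filter_clusters",
    "bootstrap_stability",
    "random_set_rho_null",
    "conserved_pair_check",
    "MIN_ABS_RHO",
    "MEDIAN_ABS_RHO",
    "MIN_CLUSTER_SIZE_EXCLUSIVE",
]

MIN_ABS_RHO = 0.4
MEDIAN_ABS_RHO = 0.5
MIN_CLUSTER_SIZE_EXCLUSIVE = 5  # retained clusters must have > 5 members


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix with unit diagonal."""

    gene_ids: list[str]
    rho: np.ndarray
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.rho.shape != (n, n):
            raise DataFormatError("rho shape does not match gene list")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise DataFormatError("rho must be symmetric")
        if np.nanmax(np.abs(self.rho)) > 1 + 1e-9:
            raise DataFormatError("|rho| entries must be <= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.gene_ids, columns=self.gene_ids)

    def submatrix(self, genes) -> "CorrelationMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return CorrelationMatrix(list(genes), self.rho[np.ix_(idx, idx)])

    def pair_rho(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.rho[i, j])


@dataclass
class Cluster:
    id: int
    members: list[str]
    min_abs_rho: float
    median_abs_rho: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    k_requested: int

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> pd.Series:
        """Gene -> cluster-id over clustered genes."""
        out = {}
        for c in self.clusters:
            for g in c.members:
                out[g] = c.id
        return pd.Series(out, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.id, g, c.min_abs_rho, c.median_abs_rho)
            for c in self.clusters
            for g in c.members
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "gene", "min_abs_rho", "median_abs_rho"]
        )


def spearman_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """All-pairs Spearman rank correlation across samples.

    Ranks use average tie handling, so rho is invariant to any strictly
    monotone per-gene transform.  Constant genes get rho 0 against every
    other gene (flagged), rather than propagating NaN.
    """
    if expr.n_samples < 3:
        raise DataFormatError("need >= 3 samples for rank correlations")
    X = expr.values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, X)
    sd = ranks.std(axis=1)
    constant = sd == 0
    safe = ranks.copy()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s); their correlations set to 0",
            stacklevel=2,
        )
        safe[constant] = np.arange(ranks.shape[1])  # placeholder, zeroed below
    rho = np.atleast_2d(np.corrcoef(safe))
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(
        expr.gene_ids, rho, [g for g, c in zip(expr.gene_ids, constant) if c]
    )


def _cluster_stats(members: list[str], corr: CorrelationMatrix) -> tuple[float, float]:
    sub = np.abs(corr.submatrix(members).rho)
    iu = np.triu_indices(len(members), k=1)
    vals = sub[iu]
    if vals.size == 0:
        return 1.0, 1.0
    return float(vals.min()), float(np.median(vals))


def ward_linkage(corr: CorrelationMatrix) -> np.ndarray:
    """Ward.D linkage on the 1-|rho| dissimilarity.

    Returned in scipy linkage format; the recorded merge heights are the
    square roots of the ward.D heights on 1-|rho| (monotone, so cutting is
    unaffected).
    """
    d = 1.0 - np.abs(corr.rho)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    condensed = squareform(d, checks=False)
    return linkage(np.sqrt(condensed), method="ward")


def ward_cluster(corr: CorrelationMatrix, k: int) -> ClusterSet:
    """Ward.D agglomeration on 1-|rho|, dendrogram cut into k groups."""
    n = len(corr.gene_ids)
    if k < 1:
        raise DataFormatError("k must be >= 1")
    if k > n:
        raise DataFormatError(f"k={k} exceeds number of genes {n}")
    Z = ward_linkage(corr)
    labels = fcluster(Z, t=k, criterion="maxclust")
    clusters = []
    for cid in sorted(set(labels)):
        members = [g for g, l in zip(corr.gene_ids, labels) if l == cid]
        mn, md = _cluster_stats(members, corr)
        clusters.append(Cluster(int(cid), members, mn, md))
    return ClusterSet(clusters, k_requested=k)


def filter_clusters(clusters: ClusterSet, corr: CorrelationMatrix) -> ClusterSet:
    """Retain clusters with size > 5, min |rho| >= 0.4, median |rho| >= 0.5.

    Statistics are recomputed from the correlation matrix so the recorded
    values are always self-consistent with it.
    """
    kept = []
    for c in clusters.clusters:
        mn, md = _cluster_stats(c.members, corr)
        if (
            c.size > MIN_CLUSTER_SIZE_EXCLUSIVE
            and mn >= MIN_ABS_RHO
            and md >= MEDIAN_ABS_RHO
        ):
            kept.append(Cluster(c.id, list(c.members), mn, md))
    return ClusterSet(kept, k_requested=clusters.k_requested)


def default_k(n_genes: int) -> int:
    """Dendrogram cut count: n_genes/10 with a floor of 10 (cap n_genes)."""
    return max(min(n_genes, 10), n_genes // 10)


def bootstrap_stability(
    expr: ExpressionMatrix,
    k: int,
    n_boot: int,
    seed: int,
    clusters: ClusterSet | None = None,
) -> dict[int, float]:
    """Sample-bootstrap co-clustering stability of the retained clusters.

    For each retained cluster, the fraction of bootstrap replicates (samples
    resampled with replacement, tree re-built and re-cut into k) in which at
    least 80% of its members co-occur inside a single bootstrap cluster.
    """
    if n_boot < 1:
        raise DataFormatError("n_boot must be >= 1")
    if clusters is None:
        corr = spearman_matrix(expr)
        clusters = filter_clusters(ward_cluster(corr, k), corr)
    rng = np.random.default_rng(seed)
    hits = {c.id: 0 for c in clusters.clusters}
    n = expr.n_samples
    for _ in range(n_boot):
        cols = rng.integers(0, n, size=n)
        boot = ExpressionMatrix(expr.values.iloc[:, cols].set_axis(
            [f"b{i}" for i in range(n)], axis=1
        ))
        bcorr = spearman_matrix(boot)
        blabels = ward_cluster(bcorr, k).membership()
        for c in clusters.clusters:
            counts = blabels[c.members].value_counts()
            if counts.iloc[0] >= 0.8 * c.size:
                hits[c.id] += 1
    return {cid: h / n_boot for cid, h in hits.items()}


def random_set_rho_null(
    expr: ExpressionMatrix, set_size: int, n_random: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Pairwise rho values for random gene sets of a given size.

    Serves as the null distribution against which a cluster's pairwise
    correlations are compared (density overlay).
    """
    if set_size > expr.n_genes:
        raise DataFormatError("set_size exceeds number of genes")
    rng = np.random.default_rng(seed)
    out = []
    genes = expr.gene_ids
    for _ in range(n_random):
        members = list(rng.choice(genes, size=set_size, replace=False))
        sub = spearman_matrix(expr.subset_genes(members))
        iu = np.triu_indices(set_size, k=1)
        out.append(sub.rho[iu])
    return out


def conserved_pair_check(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    rho_threshold: float = 0.8,
    conserved_abs_rho: float = 0.4,
) -> tuple[pd.DataFrame, float]:
    """Cross-dataset conservation of highly correlated gene pairs.

    Select all gene pairs with |rho| >= ``rho_threshold`` in dataset A and
    report their rho in dataset B, plus the fraction of selected pairs with
    |rho_B| >= ``conserved_abs_rho``.  If pair correlations reflect genuine
    co-regulation rather than a shared technical artefact, this fraction is
    high only when B shares A's active transcriptional modules.
    """
    shared = [g for g in exprA.gene_ids if g in set(exprB.gene_ids)]
    if not shared:
        raise DataFormatError("no shared genes between the two matrices")
    corrA = spearman_matrix(exprA.subset_genes(shared))
    corrB = spearman_matrix(exprB.subset_genes(shared))
    n = len(shared)
    iu = np.triu_indices(n, k=1)
    sel = np.abs(corrA.rho[iu]) >= rho_threshold
    rows = []
    for a, b, rA, rB in zip(
        iu[0][sel], iu[1][sel], corrA.rho[iu][sel], corrB.rho[iu][sel]
    ):
        rows.append((shared[a], shared[b], float(rA), float(rB)))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho_a", "rho_b"])
    frac = (
        float((df["rho_b"].abs() >= conserved_abs_rho).mean()) if len(df) else float("nan")
    )
    return df, frac
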