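"""Gene-set enrichment and the correlated-pair-fraction statistic.

Enrichment of a query gene list (a cluster, or a hub's children) for an
annotation gene set uses the hypergeometric upper tail as the strength
measure (reported as -log10 p) together with a seeded permutation p-value,
preserving the two-criterion structure (strength + permutation) of the
original screen.  Under the exchangeable null, the overlap of a random
same-size query with the set is exactly hypergeometric, so the permutation
draws overlap counts from that distribution directly.

The correlated-pair fraction of a gene set in a dataset is the proportion
of its unordered gene pairs with Spearman |rho| at or above a threshold
(default 0.5).  Comparing this fraction for the same set across an in-vitro
perturbation dataset and tumour cohorts distinguishes transcriptional
modules the cell-line model captures (shared-high) from those visible only
in tumours (tumour-only-high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dataio import DataFormatError, ExpressionMatrix, GeneSetCollection
from .coexpression import spearman_matrix

__all__ = [
    "EnrichmentResult",
    "PairFractionRecord",
    "enrich",
    "bh_fdr",
    "enrichment_table",
    "correlated_pair_fraction",
    "compare_fractions",
]

DEFAULT_SCORE_MIN = 1.3  # -log10 p >= 1.3, i.e. p_hyper <= 0.05
DEFAULT_N_PERM = 1000


@dataclass
class EnrichmentResult:
    query_id: str
    set_name: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p_hyper: float
    p_empirical: float
    enrichment_score: float  # -log10 p_hyper
    significant: bool

    def __post_init__(self) -> None:
        if self.overlap > min(self.query_size, self.set_size):
            raise DataFormatError("overlap exceeds query or set size")
        for p in (self.p_hyper, self.p_empirical):
            if not 0.0 <= p <= 1.0:
                raise DataFormatError("probabilities must lie in [0, 1]")


@dataclass
class PairFractionRecord:
    set_name: str
    dataset_label: str
    fraction: float
    n_pairs: int
    rho_threshold: float
    n_measured: int
    n_missing: int


def enrich(
    query_genes,
    gene_set,
    universe,
    query_id: str = "query",
    set_name: str = "set",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    score_min: float = DEFAULT_SCORE_MIN,
    p_empirical_max: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric + permutation enrichment of a query in a gene set.

    ``p_hyper`` is the upper tail P(X >= overlap) for drawing ``|query|``
    genes from the universe; ``p_empirical`` is the fraction of ``n_perm``
    random same-size queries whose overlap is at least the observed one
    (with the +1 small-sample correction).  The result is flagged
    significant when p_empirical <= ``p_empirical_max`` and the enrichment
    score (-log10 p_hyper) is >= ``score_min``.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise DataFormatError("empty universe")
    uni = set(universe)
    query = [g for g in dict.fromkeys(query_genes)]
    if not set(query) <= uni:
        raise DataFormatError("query genes must be a subset of the universe")
    members = set(gene_set) & uni
    if not members:
        raise DataFormatError(f"gene set {set_name!r} does not intersect the universe")

    N, K, n = len(universe), len(members), len(query)
    overlap = len(members & set(query))
    p_hyper = float(hypergeom.sf(overlap - 1, N, K, n))
    p_hyper = min(max(p_hyper, 0.0), 1.0)

    rng = np.random.default_rng(seed)
    # random same-size queries from an exchangeable universe produce exactly
    # hypergeometric overlaps; draw the counts directly
    sims = rng.hypergeometric(K, N - K, n, size=n_perm) if n > 0 else np.zeros(n_perm)
    p_emp = float((1 + np.sum(sims >= overlap)) / (n_perm + 1))

    score = float(-np.log10(max(p_hyper, 1e-300)))
    return EnrichmentResult(
        query_id=query_id,
        set_name=set_name,
        overlap=overlap,
        query_size=n,
        set_size=K,
        universe_size=N,
        p_hyper=p_hyper,
        p_empirical=p_emp,
        enrichment_score=score,
        significant=(p_emp <= p_empirical_max and score >= score_min),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrichment_table(
    queries: dict[str, list[str]],
    collection: GeneSetCollection,
    universe,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    score_min: float = DEFAULT_SCORE_MIN,
) -> pd.DataFrame:
    """Enrichment of every query against every set, with BH-FDR columns."""
    rows = []
    for qi, (qid, qgenes) in enumerate(queries.items()):
        for si, (sname, (_d, members)) in enumerate(collection.sets.items()):
            if not set(members) & set(universe):
                continue
            res = enrich(
                [g for g in qgenes if g in set(universe)],
                members,
                universe,
                query_id=qid,
                set_name=sname,
                n_perm=n_perm,
                seed=seed + 1000 * qi + si,
                score_min=score_min,
            )
            rows.append(res.__dict__)
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_hyper"] = bh_fdr(df["p_hyper"].to_numpy())
    return df


def correlated_pair_fraction(
    expr: ExpressionMatrix,
    gene_set,
    rho_threshold: float = 0.5,
    set_name: str = "set",
    dataset_label: str = "dataset",
) -> PairFractionRecord:
    """Fraction of a gene set's unordered pairs with |rho| >= threshold.

    Members absent from the matrix are dropped (and counted); at least two
    measured members are required.
    """
    members = [g for g in dict.fromkeys(gene_set)]
    measured = [g for g in members if g in set(expr.gene_ids)]
    n_missing = len(members) - len(measured)
    if len(measured) < 2:
        raise DataFormatError(
            f"gene set {set_name!r}: fewer than 2 members measured in {dataset_label!r}"
        )
    corr = spearman_matrix(expr.subset_genes(measured))
    s = len(measured)
    iu = np.triu_indices(s, k=1)
    vals = np.abs(corr.rho[iu])
    n_pairs = s * (s - 1) // 2
    fraction = float((vals >= rho_threshold).sum() / n_pairs)
    return PairFractionRecord(
        set_name=set_name,
        dataset_label=dataset_label,
        fraction=fraction,
        n_pairs=n_pairs,
        rho_threshold=rho_threshold,
        n_measured=s,
        n_missing=n_missing,
    )


def compare_fractions(
    gene_sets: GeneSetCollection,
    datasets: list[tuple[str, ExpressionMatrix]],
    rho_threshold: float = 0.5,
    invitro_label: str | None = None,
    high_cutoff: float = 0.5,
    low_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Correlated-pair fractions of every set in every dataset, classified.

    One record per (set, dataset).  Each set is additionally classified as
    ``shared-high`` (fraction >= high_cutoff in the in-vitro dataset and in
    at least one other dataset), ``tumour-only-high`` (>= high_cutoff in
    some non-in-vitro dataset while <= low_cutoff in vitro), or ``neither``.
    The in-vitro dataset defaults to the first label.
    """
    if not datasets:
        raise DataFormatError("need at least one dataset")
    labels = [lab for lab, _ in datasets]
    if invitro_label is None:
        invitro_label = labels[0]
    if invitro_label not in labels:
        raise DataFormatError(f"invitro_label {invitro_label!r} not among datasets")

    rows = []
    for sname, (_desc, members) in gene_sets.sets.items():
        per_ds: dict[str, float] = {}
        for lab, expr in datasets:
            try:
                rec = correlated_pair_fraction(
                    expr, members, rho_threshold, set_name=sname, dataset_label=lab
                )
            except DataFormatError:
                continue
            per_ds[lab] = rec.fraction
            rows.append(rec.__dict__)
        invitro = per_ds.get(invitro_label, float("nan"))
        others = [f for lab, f in per_ds.items() if lab != invitro_label]
        if others and invitro == invitro:  # invitro measured
            if invitro >= high_cutoff and max(others) >= high_cutoff:
                cls = "shared-high"
            elif max(others) >= high_cutoff and invitro <= low_cutoff:
                cls = "tumour-only-high"
            else:
                cls = "neither"
        else:
            cls = "neither"
        for r in rows:
            if r["set_name"] == sname:
                r["classification"] = cls
    return pd.DataFrame(rows)
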