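"""Nearest shrunken centroid prognosis classification over hub genes.

Two-class prognosis labels are derived from survival (event before an early
cutoff vs event-free beyond a late cutoff; samples in between excluded).
Candidate features are network hubs passing a child-count and Cox-p filter.
The classifier soft-thresholds standardized class-centroid offsets by a
shrinkage Delta, performing implicit gene selection, and assigns a sample
to the class with the smallest standardized squared distance to the
shrunken centroid minus twice the log prior.

Notation (per gene i, class k): d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0))
with m_k = sqrt(1/n_k - 1/n), pooled within-class sd s_i, fudge s0 = median
s_i; soft-thresholded offsets d'_ik = sign(d_ik) max(|d_ik| - Delta, 0);
shrunken centroids xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import DataFormatError, ExpressionMatrix, SurvivalTable
from .network import ConsensusNetwork

__all__ = [
    "ShrunkenCentroidModel",
    "CVResult",
    "hub_candidate_filter",
    "derive_outcome_classes",
    "train",
    "train_path",
    "cross_validate",
]


@dataclass
class ShrunkenCentroidModel:
    classes: list[str]
    genes: list[str]
    overall_centroid: np.ndarray  # (genes,)
    class_centroids: np.ndarray  # (genes, classes), unshrunken
    s: np.ndarray  # pooled within-class sd per gene
    s0: float
    m: np.ndarray  # (classes,)
    delta: float
    dprime: np.ndarray  # (genes, classes)
    shrunken_centroids: np.ndarray  # (genes, classes)
    priors: np.ndarray  # (classes,)
    m_convention: str = "minus"

    @property
    def selected_genes(self) -> list[str]:
        mask = (self.dprime != 0).any(axis=1)
        return [g for g, keep in zip(self.genes, mask) if keep]

    def discriminant(self, X: pd.DataFrame) -> pd.DataFrame:
        """Class scores delta_k(x) per sample (smaller is closer)."""
        mask = (self.dprime != 0).any(axis=1)
        x = X.loc[self.genes].to_numpy(dtype=float)
        denom = (self.s + self.s0) ** 2
        scores = np.zeros((X.shape[1], len(self.classes)))
        for k in range(len(self.classes)):
            if mask.any():
                diff = x[mask] - self.shrunken_centroids[mask, k][:, None]
                scores[:, k] = (diff**2 / denom[mask, None]).sum(axis=0)
            scores[:, k] -= 2.0 * np.log(self.priors[k])
        return pd.DataFrame(scores, index=X.columns, columns=self.classes)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Assign each sample (column) to its nearest shrunken centroid.

        Ties go to the class listed first.
        """
        scores = self.discriminant(X)
        # np.argmin returns the first index on ties -> class listed first
        idx = np.argmin(scores.to_numpy(), axis=1)
        return pd.Series([self.classes[i] for i in idx], index=X.columns)


@dataclass
class CVResult:
    delta_grid: list[float]
    errors: dict[float, float]
    confusions: dict[float, pd.DataFrame]
    chosen_delta: float
    model: ShrunkenCentroidModel
    selected_genes: list[str]
    per_class_sensitivity: dict[str, float]
    folds: list[list[str]] = field(default_factory=list)


def hub_candidate_filter(
    fits: pd.DataFrame,
    net: ConsensusNetwork,
    min_children: int,
    p_max: float,
) -> list[str]:
    """Hubs with >= min_children consensus children and Cox p <= p_max.

    ``fits`` is a cox_screen table (columns gene, p).
    """
    pmap = dict(zip(fits["gene"], fits["p"]))
    counts = net.child_count
    keep = sorted(
        g
        for g, c in counts.items()
        if c >= min_children and pmap.get(g, 1.0) <= p_max
    )
    if not keep:
        raise DataFormatError(
            "no hub passed the candidate filter; relax min_children or p_max"
        )
    return keep


def derive_outcome_classes(
    surv: SurvivalTable, t_early: float = 2.0, t_late: float = 3.0
) -> pd.Series:
    """Two-class prognosis labels from survival follow-up.

    ``died_early``: event observed at or before ``t_early``.
    ``survived_late``: event-free (at risk or censored) beyond ``t_late``.
    Samples in between carry no label and are excluded.
    """
    df = surv.records
    died = (df["event"] == 1) & (df["time"] <= t_early)
    alive = df["time"] > t_late
    labels = pd.Series(
        np.where(died, "died_early", np.where(alive, "survived_late", "")),
        index=df["sample"],
    )
    return labels[labels != ""]


def _fit_stats(X: np.ndarray, y: np.ndarray, classes: list[str], m_convention: str):
    n = X.shape[1]
    K = len(classes)
    overall = X.mean(axis=1)
    cents = np.zeros((X.shape[0], K))
    n_k = np.zeros(K)
    ss = np.zeros(X.shape[0])
    for k, c in enumerate(classes):
        cols = y == c
        n_k[k] = cols.sum()
        if n_k[k] < 2:
            raise DataFormatError(f"class {c!r} needs >= 2 samples")
        cents[:, k] = X[:, cols].mean(axis=1)
        ss += ((X[:, cols] - cents[:, k][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    if m_convention == "minus":
        m = np.sqrt(1.0 / n_k - 1.0 / n)
    elif m_convention == "plus":
        m = np.sqrt(1.0 / n_k + 1.0 / n)
    else:
        raise DataFormatError(f"unknown m convention {m_convention!r}")
    return overall, cents, s, s0, m, n_k


def train(
    expr: pd.DataFrame | ExpressionMatrix,
    labels: pd.Series,
    delta: float,
    priors: str = "proportional",
    m_convention: str = "minus",
) -> ShrunkenCentroidModel:
    """Fit a shrunken centroid model at a single shrinkage Delta.

    ``expr`` is genes x samples; ``labels`` maps sample -> class.  Class
    order is first-appearance order in ``labels`` (ties in prediction go to
    the first class).
    """
    X_df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    samples = [s for s in labels.index if s in set(X_df.columns)]
    if len(samples) < len(labels):
        raise DataFormatError("labelled samples missing from expression matrix")
    X = X_df[samples].to_numpy(dtype=float)
    y = labels.loc[samples].to_numpy()
    classes = list(dict.fromkeys(y))
    if len(classes) < 2:
        raise DataFormatError("need at least two classes")
    overall, cents, s, s0, m, n_k = _fit_stats(X, y, classes, m_convention)

    denom = np.outer(s + s0, m)
    d = (cents - overall[:, None]) / denom
    dprime = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * dprime
    if priors == "proportional":
        pi = n_k / n_k.sum()
    elif priors == "uniform":
        pi = np.full(len(classes), 1.0 / len(classes))
    else:
        raise DataFormatError(f"unknown priors {priors!r}")
    return ShrunkenCentroidModel(
        classes=classes,
        genes=list(X_df.index),
        overall_centroid=overall,
        class_centroids=cents,
        s=s,
        s0=s0,
        m=m,
        delta=float(delta),
        dprime=dprime,
        shrunken_centroids=shrunken,
        priors=pi,
        m_convention=m_convention,
    )


def train_path(expr, labels, delta_grid, **kwargs) -> list[ShrunkenCentroidModel]:
    """Fit the whole shrinkage path (one model per Delta)."""
    return [train(expr, labels, d, **kwargs) for d in delta_grid]


def _stratified_folds(labels: pd.Series, n_folds: int, seed: int) -> list[list[str]]:
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for c in dict.fromkeys(labels):
        samples = [s for s in labels.index if labels[s] == c]
        rng.shuffle(samples)
        for i, s in enumerate(samples):
            folds[i % n_folds].append(s)
    return [f for f in folds if f]


def cross_validate(
    expr: pd.DataFrame | ExpressionMatrix,
    labels: pd.Series,
    delta_grid,
    n_folds: int | None = None,
    seed: int = 0,
    **train_kwargs,
) -> CVResult:
    """Stratified cross-validation over a shrinkage grid.

    Folds are stratified and seeded; leave-one-out is used when the cohort
    has <= 30 samples (matching the scale at which such classifiers are
    typically piloted), else 10-fold.  The chosen Delta is the largest value
    attaining the minimal CV error, i.e. the fewest genes at equal error.
    """
    X_df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    delta_grid = [float(d) for d in delta_grid]
    n = len(labels)
    if n_folds is None:
        n_folds = n if n <= 30 else 10
    min_class = min(labels.value_counts())
    if n_folds > n:
        raise DataFormatError("more folds than samples")
    if n_folds < n and n_folds > min_class:
        raise DataFormatError("n_folds exceeds the smallest class size")

    folds = (
        [[s] for s in labels.index]
        if n_folds == n
        else _stratified_folds(labels, n_folds, seed)
    )
    classes = list(dict.fromkeys(labels))
    counts = {
        d: pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for d in delta_grid
    }
    for fold in folds:
        train_labels = labels.drop(fold)
        for d in delta_grid:
            model = train(X_df.drop(columns=fold), train_labels, d, **train_kwargs)
            pred = model.predict(X_df[fold])
            for s in fold:
                counts[d].loc[labels[s], pred[s]] += 1

    errors = {
        d: 1.0 - float(np.trace(counts[d].to_numpy())) / n for d in delta_grid
    }
    best = min(errors.values())
    chosen = max(d for d, e in errors.items() if e <= best + 1e-12)
    final = train(X_df, labels, chosen, **train_kwargs)
    conf = counts[chosen]
    sens = {
        c: (float(conf.loc[c, c]) / float(conf.loc[c].sum()) if conf.loc[c].sum() else float("nan"))
        for c in classes
    }
    return CVResult(
        delta_grid=delta_grid,
        errors=errors,
        confusions=counts,
        chosen_delta=chosen,
        model=final,
        selected_genes=final.selected_genes,
        per_class_sensitivity=sens,
        folds=folds,
    )
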