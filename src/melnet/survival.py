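"""Univariate Cox screening, category summaries and Kaplan-Meier splits.

Each gene's expression enters a univariate Cox proportional-hazards model as
a continuous covariate; the partial likelihood (Breslow tie handling) is
maximised by Newton-Raphson and the two-sided Wald p-value reported.  Gene
p-values are summarised per functional category on the -log2 scale, where
the significance threshold -log2(0.05) = 4.32 marks p = 0.05.  The
median-split Kaplan-Meier comparison (log-rank test on one degree of
freedom) is provided separately for individual genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .dataio import DataFormatError, ExpressionMatrix, SurvivalTable
from .genesets import bh_fdr

__all__ = [
    "CoxFit",
    "CategorySurvivalSummary",
    "cox_univariate",
    "cox_screen",
    "category_summary",
    "km_median_split",
    "kaplan_meier",
    "log_rank",
    "NEG_LOG2_P_THRESHOLD",
]

NEG_LOG2_P_THRESHOLD = -math.log2(0.05)  # 4.3219...


@dataclass
class CoxFit:
    gene: str
    beta: float
    se: float
    z: float
    p: float
    n_events: int
    converged: bool = True
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise DataFormatError("p must lie in (0, 1]")

    @property
    def neg_log2_p(self) -> float:
        return -math.log2(self.p)


@dataclass
class CategorySurvivalSummary:
    category: str
    genes: list[str]
    neg_log2_p: np.ndarray
    median: float
    iqr: tuple[float, float]
    fraction_significant: float
    threshold: float = NEG_LOG2_P_THRESHOLD


def _partial_likelihood_terms(beta: float, x: np.ndarray, time: np.ndarray,
                              event: np.ndarray):
    """Breslow log partial likelihood, gradient and Hessian at beta."""
    order = np.argsort(-time, kind="stable")  # descending time
    x_s, t_s, e_s = x[order], time[order], event[order]
    theta = np.exp(beta * x_s)
    c0 = np.cumsum(theta)
    c1 = np.cumsum(theta * x_s)
    c2 = np.cumsum(theta * x_s * x_s)
    ll = grad = hess = 0.0
    i = 0
    n = len(x_s)
    # walk event times from latest to earliest; risk set = prefix of sorted arr
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # samples i..j-1 share this time; risk set is everything with time >= t
        d = int(e_s[i:j].sum())
        if d > 0:
            s0, s1, s2 = c0[j - 1], c1[j - 1], c2[j - 1]
            xsum = float((x_s[i:j] * e_s[i:j]).sum())
            ll += beta * xsum - d * math.log(s0)
            grad += xsum - d * s1 / s0
            hess += -d * (s2 / s0 - (s1 / s0) ** 2)
        i = j
    return ll, grad, hess


def cox_univariate(
    values: pd.Series | np.ndarray,
    surv: SurvivalTable,
    gene: str = "gene",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a univariate Cox model by Newton-Raphson (Breslow ties).

    ``values`` is per-sample expression; a Series is aligned on the survival
    table's sample ids, a bare array is taken in table order.  Non-convergent
    or separation-prone fits are flagged with p = 1.
    """
    df = surv.records
    if isinstance(values, pd.Series):
        missing = [s for s in df["sample"] if s not in values.index]
        if missing:
            raise DataFormatError(f"expression missing for samples {missing[:5]}")
        x = values.loc[df["sample"]].to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if len(x) != len(df):
            raise DataFormatError("expression length does not match survival table")
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise DataFormatError("need >= 2 events for a Cox fit")
    if np.ptp(x) == 0:
        raise DataFormatError("constant expression: Cox model undefined")

    xc = x - x.mean()
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)

    beta, converged = 0.0, False
    for _ in range(max_iter):
        _ll, grad, hess = _partial_likelihood_terms(beta, xc, time, event)
        if hess >= -1e-300:
            break
        step = grad / hess
        # dampen huge steps (monotone-likelihood protection)
        step = float(np.clip(step, -5.0, 5.0))
        beta -= step
        if abs(step) < tol:
            converged = True
            break
    flagged = (not converged) or abs(beta) > 50
    _ll, _grad, hess = _partial_likelihood_terms(beta, xc, time, event)
    se = math.sqrt(-1.0 / hess) if hess < 0 else float("inf")
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = 1.0 if flagged else float(max(2.0 * norm.sf(abs(z)), 1e-300))
    return CoxFit(gene, float(beta), float(se), float(z), p, n_events,
                  converged=converged, flagged=flagged)


def cox_screen(expr: ExpressionMatrix, surv: SurvivalTable) -> pd.DataFrame:
    """Univariate Cox fit for every gene, with a BH-FDR column.

    Constant genes are skipped with a warning.
    """
    surv = surv.aligned([s for s in surv.samples if s in set(expr.sample_ids)])
    rows = []
    for g in expr.gene_ids:
        vals = expr.values.loc[g]
        try:
            fit = cox_univariate(vals, surv, gene=g)
        except DataFormatError:
            warnings.warn(f"skipping gene {g!r} (constant expression)", stacklevel=2)
            continue
        rows.append(
            {
                "gene": g,
                "beta": fit.beta,
                "se": fit.se,
                "z": fit.z,
                "p": fit.p,
                "neg_log2_p": fit.neg_log2_p,
                "n_events": fit.n_events,
                "flagged": fit.flagged,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def category_summary(
    fits: list[CoxFit] | pd.DataFrame,
    categories: dict[str, str],
    baseline_label: str = "ALL",
) -> list[CategorySurvivalSummary]:
    """Distribution of -log2 p per functional category, plus a baseline.

    ``categories`` maps gene -> category label; every fitted gene enters the
    baseline category regardless of annotation.  Empty categories are
    omitted with a warning.
    """
    if isinstance(fits, pd.DataFrame):
        recs = [(r.gene, r.p) for r in fits.itertuples(index=False)]
    else:
        recs = [(f.gene, f.p) for f in fits]
    by_cat: dict[str, list[tuple[str, float]]] = {baseline_label: list(recs)}
    for g, p in recs:
        cat = categories.get(g)
        if cat is not None:
            by_cat.setdefault(cat, []).append((g, p))
    wanted = set(categories.values())
    for cat in wanted - set(by_cat):
        warnings.warn(f"category {cat!r} has no fitted genes; omitted", stacklevel=2)

    out = []
    for cat, pairs in by_cat.items():
        genes = [g for g, _ in pairs]
        nl2 = np.array([-math.log2(p) for _, p in pairs])
        out.append(
            CategorySurvivalSummary(
                category=cat,
                genes=genes,
                neg_log2_p=nl2,
                median=float(np.median(nl2)),
                iqr=(float(np.percentile(nl2, 25)), float(np.percentile(nl2, 75))),
                fraction_significant=float((nl2 >= NEG_LOG2_P_THRESHOLD).mean()),
            )
        )
    return out


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate: step function over event times."""
    order = np.argsort(time, kind="stable")
    t_s, e_s = np.asarray(time)[order], np.asarray(event)[order]
    at_risk = len(t_s)
    surv = 1.0
    rows = [(0.0, 1.0)]
    i = 0
    while i < len(t_s):
        j = i
        while j < len(t_s) and t_s[j] == t_s[i]:
            j += 1
        d = int(e_s[i:j].sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append((float(t_s[i]), surv))
        at_risk -= j - i
        i = j
    return pd.DataFrame(rows, columns=["time", "survival"])


def log_rank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic on 1 df and p-value.

    The statistic is (O - E)^2 / V for group 1, with the hypergeometric
    variance accumulated over distinct event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & (group == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def km_median_split(
    values: pd.Series, surv: SurvivalTable
) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Kaplan-Meier curves for samples below/above the median expression.

    Ties at the median go to the low group.  Returns (low curve, high curve,
    log-rank statistic, p).
    """
    df = surv.records
    x = values.loc[df["sample"]].to_numpy(dtype=float)
    med = float(np.median(x))
    high = x > med
    if high.all() or not high.any():
        raise DataFormatError("median split left one group empty (constant values?)")
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    km_low = kaplan_meier(time[~high], event[~high])
    km_high = kaplan_meier(time[high], event[high])
    stat, p = log_rank(time, event, high.astype(int))
    return km_low, km_high, stat, p
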