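"""Batch scaling, noise-floor filtering and knockdown-efficacy summaries.

These are the steps applied to the perturbation expression matrix before any
correlation analysis: per-batch median centring of every gene (removing
additive batch offsets on the log2 scale), removal of genes whose median
signal sits below a noise floor, and per-target summaries of how effective
each siRNA knockdown was.

Knockdown efficacy follows the screen convention: the fold reduction is the
target's median abundance over all *other* arrays divided by its abundance
in its own array, on the linear scale, and the percent reduction is
``round(100 * (1 - 1/fold))`` with halves rounded away from zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CONTROL, ConfigError, DataFormatError, ExpressionMatrix, PerturbationDesign

__all__ = [
    "batch_median_scale",
    "noise_floor_filter",
    "knockdown_efficacy",
    "percent_from_fold",
    "KnockdownSummary",
    "SIRNA_KNOCKDOWN_REFERENCE",
]

# Published reference table from a 45-siRNA transcription-factor/signalling
# knockdown screen in a melanoma cell line: (target gene, fold reduction of
# the target relative to the median array, printed % reduction, batch).
# Used as a fixed oracle for the fold <-> percent identity.
SIRNA_KNOCKDOWN_REFERENCE: list[tuple[str, float, int, str]] = [
    ("ABL1", 2.01, 50, "KD2"),
    ("AKT1", 2.79, 64, "KD2"),
    ("CCNA2", 2.87, 65, "KD2"),
    ("CCNB1", 2.84, 65, "KD2"),
    ("CCNB2", 3.96, 75, "KD3"),
    ("CCND3", 2.91, 66, "KD2"),
    ("CDC16", 2.98, 66, "KD2"),
    ("CDC2", 2.72, 63, "KD1"),
    ("CDC25B", 2.08, 52, "KD1"),
    ("CDC37", 2.17, 54, "KD2"),
    ("CDK2", 2.60, 62, "KD2"),
    ("CDK4", 3.42, 71, "KD2"),
    ("CDK7", 2.53, 60, "KD1"),
    ("CDKN2C", 2.37, 58, "KD2"),
    ("CEBPD", 2.02, 50, "KD2"),
    ("CEBPZ", 2.96, 66, "KD2"),
    ("CHEK1", 2.80, 64, "KD2"),
    ("CTNNB1", 2.19, 54, "KD1"),
    ("ETS1", 1.98, 49, "KD3"),
    ("FOXM1", 2.69, 63, "KD2"),
    ("FOXO3A", 2.72, 63, "KD1"),
    ("GABARAP", 3.60, 72, "KD2"),
    ("HDAC2", 2.84, 65, "KD2"),
    ("HDAC3", 2.77, 64, "KD2"),
    ("HSF2", 4.62, 78, "KD1"),
    ("MAP2K1", 3.44, 71, "KD2"),
    ("MAPK1", 2.05, 51, "KD2"),
    ("MCM2", 5.96, 83, "KD3"),
    ("MITF", 14.51, 93, "KD3"),
    ("NCOR2", 2.32, 57, "KD2"),
    ("NMI", 4.77, 79, "KD2"),
    ("PCNA", 2.70, 63, "KD1"),
    ("PIAS1", 3.04, 67, "KD3"),
    ("PIK3CB", 2.15, 53, "KD2"),
    ("RB1", 4.34, 77, "KD1"),
    ("RBL2", 2.53, 60, "KD2"),
    ("RELA", 2.00, 50, "KD2"),
    ("SKP2", 3.40, 71, "KD2"),
    ("SP1", 1.99, 50, "KD3"),
    ("SP100", 3.06, 67, "KD2"),
    ("STAT1", 3.29, 70, "KD2"),
    ("STAT3", 5.75, 83, "KD3"),
    ("STAT6", 2.21, 55, "KD2"),
    ("TCEA1", 3.04, 67, "KD1"),
    ("TP53", 2.74, 64, "KD1"),
]


def percent_from_fold(fold: float) -> int:
    """Percent reduction implied by a fold reduction.

    ``percent = round(100 * (1 - 1/fold))``, halves rounded away from zero.
    """
    if fold == 0:
        raise ZeroDivisionError("fold reduction of 0 is undefined")
    value = 100.0 * (1.0 - 1.0 / fold)
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


@dataclass
class KnockdownSummary:
    """Per-knockdown-sample efficacy table.

    Columns: target, sample, fold_reduction (median-of-others / own, linear
    scale), percent_reduction, batch.
    """

    table: pd.DataFrame

    def per_target(self) -> pd.DataFrame:
        """Median fold per target (collapses replicate knockdowns)."""
        agg = self.table.groupby("target", sort=True)["fold_reduction"].median()
        out = agg.reset_index()
        out["percent_reduction"] = out["fold_reduction"].map(percent_from_fold)
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def batch_median_scale(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Centre every gene at zero median within each experimental batch.

    Subtraction on the log2 scale (division on the linear scale); rank
    preserving per gene within batch either way, so downstream Spearman
    statistics do not depend on the choice.
    """
    if expr.batch_of_sample is None:
        raise ConfigError("batch_median_scale requires batch labels")
    values = expr.values.copy()
    for batch, cols in expr.batch_of_sample.groupby(expr.batch_of_sample).groups.items():
        cols = list(cols)
        if len(cols) < 2:
            warnings.warn(
                f"batch {batch!r} has {len(cols)} sample(s); scaling anyway",
                stacklevel=2,
            )
        med = values[cols].median(axis=1)
        values[cols] = values[cols].sub(med, axis=0)
    return ExpressionMatrix(values, expr.batch_of_sample, expr.module_activity)


def noise_floor_filter(
    expr: ExpressionMatrix, floor_signal: float, factor: float = 1.5
) -> ExpressionMatrix:
    """Keep genes whose median signal is >= factor * floor_signal.

    ``floor_signal`` plays the role of a spiked-in noise-threshold control
    and must be on the same scale as the matrix values.  The boundary is
    inclusive.
    """
    med = expr.values.median(axis=1)
    keep = med >= factor * floor_signal
    if not keep.any():
        raise DataFormatError("noise floor filter removed every gene")
    return ExpressionMatrix(
        expr.values.loc[keep], expr.batch_of_sample, expr.module_activity
    )


def knockdown_efficacy(
    expr: ExpressionMatrix, design: PerturbationDesign
) -> KnockdownSummary:
    """Fold and percent reduction of each siRNA target in its own sample.

    Computed on the linear scale (2**log2 values): fold = (median abundance
    of the target over all other samples) / (abundance in the targeted
    sample).
    """
    design.validate_against(expr)
    linear = np.power(2.0, expr.values)
    rows = []
    for sample, target in design.target_of_sample.items():
        if target == CONTROL:
            continue
        own = float(linear.at[target, sample])
        if own == 0:
            raise DataFormatError(f"target {target!r} expressed at 0 in {sample!r}")
        others = linear.loc[target].drop(sample)
        fold = float(others.median()) / own
        batch = (
            expr.batch_of_sample[sample] if expr.batch_of_sample is not None else ""
        )
        rows.append(
            {
                "target": target,
                "sample": sample,
                "fold_reduction": fold,
                "percent_reduction": percent_from_fold(fold),
                "batch": batch,
            }
        )
    return KnockdownSummary(pd.DataFrame(rows))
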