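"""Data containers and flat-file IO for the pipeline.

The pipeline's universal carrier is a genes x samples matrix of log2
expression values (:class:`ExpressionMatrix`), accompanied by a perturbation
design table mapping each sample to its siRNA-targeted gene or control
status, gene-set collections in GMT format, and per-sample survival tables.

All readers are total over their error contracts: malformed input raises a
diagnosed :class:`DataFormatError`, never a silently truncated object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CONTROL = "CONTROL"

__all__ = [
    "CONTROL",
    "DataFormatError",
    "ConfigError",
    "ExpressionMatrix",
    "PerturbationDesign",
    "GeneSetCollection",
    "SurvivalTable",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_survival_csv",
    "write_survival_csv",
]


class DataFormatError(ValueError):
    """A file or in-memory object violates its format contract."""


class ConfigError(ValueError):
    """A configuration value is outside its allowed range."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with optional batch labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are gene identifiers, columns sample identifiers, entries
        finite log2-scale expression values.
    batch_of_sample : pandas.Series, optional
        Maps each sample id to an experimental-batch label.
    module_activity : pandas.DataFrame, optional
        Sidecar set by the synthetic generator: latent module activities
        (modules x samples) used to simulate the matrix.  Absent for real
        data; consumed by the survival simulator and by tests.
    """

    values: pd.DataFrame
    batch_of_sample: pd.Series | None = None
    module_activity: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise DataFormatError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise DataFormatError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            raise DataFormatError("expression values must all be finite")
        if self.batch_of_sample is not None:
            missing = set(v.columns) - set(self.batch_of_sample.index)
            if missing:
                raise DataFormatError(
                    f"samples without batch label: {sorted(missing)[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[genes], self.batch_of_sample, self.module_activity
        )


@dataclass
class PerturbationDesign:
    """Maps each sample to its knocked-down target gene or CONTROL."""

    target_of_sample: dict[str, str]

    def targets(self) -> list[str]:
        """Distinct non-control target genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.target_of_sample.values():
            if t != CONTROL:
                seen.setdefault(t, None)
        return list(seen)

    def samples_targeting(self, gene: str) -> list[str]:
        return [s for s, t in self.target_of_sample.items() if t == gene]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [t for t in self.targets() if t not in expr.values.index]
        if missing:
            raise DataFormatError(
                f"design targets absent from expression matrix: {missing[:5]}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member gene ids)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(members) != len(set(members)):
                raise DataFormatError(f"gene set {name!r} has duplicate members")
            if len(members) < 1:
                raise DataFormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def min_size_filter(self, min_size: int = 5) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: v for n, v in self.sets.items() if len(v[1]) >= min_size}
        )


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator.

    ``records`` has columns ``sample`` (unique), ``time`` (> 0) and
    ``event`` (0 = censored, 1 = event).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"sample", "time", "event"}
        if not required.issubset(df.columns):
            raise DataFormatError(
                f"survival table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        if df["sample"].duplicated().any():
            raise DataFormatError("duplicate sample ids in survival table")
        if (df["time"] <= 0).any():
            bad = df.loc[df["time"] <= 0, "sample"].iloc[0]
            raise DataFormatError(f"non-positive survival time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1])].iloc[0]
            raise DataFormatError(
                f"event indicator must be 0 or 1 (sample {bad['sample']!r} has {bad['event']!r})"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.records["sample"])

    @property
    def n_events(self) -> int:
        return int(self.records["event"].sum())

    def aligned(self, sample_ids) -> "SurvivalTable":
        """Restrict and order records to the given sample ids."""
        df = self.records.set_index("sample").loc[list(sample_ids)].reset_index()
        return SurvivalTable(df)


# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise DataFormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise DataFormatError(f"{path}: no sample columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataFormatError(f"{path}: duplicated gene row {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = df.index[(df[col].isna() | bad)][0]
            raise DataFormatError(
                f"{path}: non-numeric or missing cell at gene {row!r}, sample {col!r}"
            )
        df[col] = coerced
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.12g", index_label="gene")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member... per line."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, need >=3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(
                    f"{path}: line {lineno} ({name}): duplicate members collapsed",
                    stacklevel=2,
                )
            sets[name] = (desc, uniq)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# survival CSV


def read_survival_csv(path) -> SurvivalTable:
    """Read a survival CSV with header ``sample,time,event``."""
    df = pd.read_csv(path)
    expected = ["sample", "time", "event"]
    if list(df.columns[:3]) != expected:
        raise DataFormatError(f"{path}: header must be {','.join(expected)}")
    return SurvivalTable(df[expected])


def write_survival_csv(table: SurvivalTable, path) -> None:
    table.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# misc table IO used across stages


def write_edge_list_tsv(edges: Mapping[tuple[str, str], float], path) -> None:
    """Write a consensus-network edge list as parent/child/frequency TSV."""
    df = pd.DataFrame(
        [(p, c, f) for (p, c), f in edges.items()],
        columns=["parent", "child", "frequency"],
    )
    df.sort_values(["parent", "child"]).to_csv(path, sep="\t", index=False)


def read_edge_list_tsv(path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r.parent, r.child): float(r.frequency) for r in df.itertuples(index=False)
    }
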