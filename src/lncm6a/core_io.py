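"""Shared data model, tabular/sequence I/O and expression preprocessing.

Expression matrices are genes x samples on TPM scale until
:func:`log2_transform` is applied; every gene carries a molecular role
(m6A regulator, lncRNA, miRNA or mRNA) so downstream screens can select
the right strata without re-parsing annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLES = ("regulator", "lncRNA", "miRNA", "mRNA")

REGULATOR_CATEGORIES = ("reader", "writer", "eraser")

#: The 21 m6A regulators: 11 readers, 8 writers, 2 erasers.
DEFAULT_REGULATORS: tuple[tuple[str, str], ...] = (
    ("HNRNPA2B1", "reader"),
    ("HNRNPC", "reader"),
    ("IGF2BP1", "reader"),
    ("IGF2BP2", "reader"),
    ("IGF2BP3", "reader"),
    ("RBMX", "reader"),
    ("YTHDC1", "reader"),
    ("YTHDC2", "reader"),
    ("YTHDF1", "reader"),
    ("YTHDF2", "reader"),
    ("YTHDF3", "reader"),
    ("METTL14", "writer"),
    ("METTL16", "writer"),
    ("METTL3", "writer"),
    ("RBM15", "writer"),
    ("RBM15B", "writer"),
    ("VIRMA", "writer"),
    ("WTAP", "writer"),
    ("ZC3H13", "writer"),
    ("ALKBH5", "eraser"),
    ("FTO", "eraser"),
)


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


@dataclass(frozen=True)
class RegulatorCatalog:
    """Named m6A regulators with their writer/reader/eraser category."""

    entries: tuple[tuple[str, str], ...] = DEFAULT_REGULATORS

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate regulator names in catalog")
        bad = {c for _, c in self.entries} - set(REGULATOR_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown regulator categories: {sorted(bad)}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def category(self, name: str) -> str:
        for n, c in self.entries:
            if n == name:
                return c
        raise KeyError(name)

    def by_category(self, category: str) -> list[str]:
        return [n for n, c in self.entries if c == category]


@dataclass
class ExpressionMatrix:
    """Dense genes x samples abundance matrix with per-gene roles.

    ``values`` is indexed by gene id (rows) and sample id (columns);
    ``roles`` maps each gene id to one of :data:`ROLES`.  ``transformed``
    distinguishes the TPM scale from the log2(TPM + offset) scale.
    """

    values: pd.DataFrame
    roles: pd.Series
    transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if not self.transformed and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative TPM at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        missing = idx.difference(self.roles.index)
        if len(missing):
            raise ValidationError(f"gene without role: {missing[0]!r}")
        bad = set(self.roles.loc[idx]) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown role label(s): {sorted(bad)}")
        self.roles = self.roles.loc[idx]

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

    def genes_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return list(self.roles.index[self.roles == role])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        return ExpressionMatrix(
            self.values.loc[ids], self.roles.loc[ids], self.transformed
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.roles, self.transformed)


@dataclass(frozen=True)
class InteractionCatalog:
    """miRNA-target pairs with the target classed as lncRNA or mRNA."""

    pairs: pd.DataFrame  # columns mirna_id, target_id, target_class

    def __post_init__(self) -> None:
        required = ["mirna_id", "target_id", "target_class"]
        if list(self.pairs.columns) != required:
            raise ValidationError(f"interaction table must have columns {required}")
        bad = set(self.pairs["target_class"]) - {"lncRNA", "mRNA"}
        if bad:
            raise ValidationError(f"unknown target_class: {sorted(bad)}")
        if self.pairs.duplicated(["mirna_id", "target_id"]).any():
            dup = self.pairs[self.pairs.duplicated(["mirna_id", "target_id"])]
            raise ValidationError(
                f"duplicate interaction pair: {tuple(dup.iloc[0][:2])}"
            )

    def targets_of(self, mirna_id: str, target_class: str) -> list[str]:
        sel = (self.pairs["mirna_id"] == mirna_id) & (
            self.pairs["target_class"] == target_class
        )
        return list(self.pairs.loc[sel, "target_id"])

    @property
    def mirna_ids(self) -> list[str]:
        return list(pd.unique(self.pairs["mirna_id"]))


@dataclass
class DrugResponseTable:
    """Per-sample IC50 values, one row per drug; NaN marks missing assays."""

    ic50: pd.DataFrame  # drugs x samples
    scale: str = "ln_ic50"

    def __post_init__(self) -> None:
        if self.ic50.index.duplicated().any():
            raise ValidationError("duplicate drug id")
        if self.ic50.columns.duplicated().any():
            raise ValidationError("duplicate sample id in drug table")
        n_obs = self.ic50.notna().sum(axis=1)
        if (n_obs < 3).any():
            bad = n_obs.index[n_obs < 3][0]
            raise ValidationError(
                f"drug {bad!r} has fewer than 3 non-missing samples"
            )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.ic50.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ic50.columns)


@dataclass
class ClinicalTable:
    """Overall-survival follow-up: time in days and death/censor flag."""

    table: pd.DataFrame  # columns sample_id, time_days, event

    def __post_init__(self) -> None:
        required = ["sample_id", "time_days", "event"]
        if list(self.table.columns) != required:
            raise ValidationError(f"clinical table must have columns {required}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample id in clinical table")
        if (self.table["time_days"] <= 0).any():
            raise ValidationError("follow-up times must be positive")
        if not set(self.table["event"]).issubset({0, 1}):
            raise ValidationError("event must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse an expression TSV (gene_id, role, then one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3 or list(df.columns[:2]) != ["gene_id", "role"]:
        raise ValidationError(
            "expression TSV must start with columns gene_id, role"
        )
    body = df.iloc[:, 2:].copy()
    for j, col in enumerate(body.columns):
        numeric = pd.to_numeric(body[col], errors="coerce")
        bad = numeric.isna() & body[col].notna() | body[col].isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"non-numeric cell at row {i + 2} (gene {df.iloc[i, 0]!r}), "
                f"column {col!r}"
            )
        body[col] = numeric
    values = body.set_axis(df["gene_id"], axis=0)
    roles = pd.Series(df["role"].to_numpy(), index=df["gene_id"])
    return ExpressionMatrix(values=values, roles=roles, transformed=False)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.insert(0, "role", m.roles.loc[out.index])
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_interactions(path: str | Path) -> InteractionCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return InteractionCatalog(pairs=df)


def write_interactions(cat: InteractionCatalog, path: str | Path) -> None:
    cat.pairs.to_csv(path, sep="\t", index=False)


def read_drug_response(path: str | Path) -> DrugResponseTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DrugResponseTable(ic50=df)


def write_drug_response(t: DrugResponseTable, path: str | Path) -> None:
    out = t.ic50.copy()
    out.index.name = "drug_id"
    out.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(table=df)


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    t.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing


def filter_expressed(
    m: ExpressionMatrix, min_fraction: float = 0.7
) -> ExpressionMatrix:
    """Keep genes with TPM > 0 in at least ``min_fraction`` of samples."""
    if m.transformed:
        raise ValueError("expression filter is defined on the TPM scale")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = (m.values.to_numpy() > 0).mean(axis=1)
    keep = m.values.index[frac >= min_fraction]
    return ExpressionMatrix(m.values.loc[keep], m.roles.loc[keep], False)


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Replace every value v with log2(v + offset) and flag the new scale."""
    if m.transformed:
        raise ValueError("matrix is already log2 transformed")
    if offset <= 0:
        raise ValueError("offset must be positive")
    return ExpressionMatrix(
        np.log2(m.values + offset), m.roles.copy(), transformed=True
    )
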