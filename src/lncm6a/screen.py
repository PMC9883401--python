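"""Correlation screen linking lncRNAs to m6A regulators.

Every (lncRNA, regulator) pair within a cancer cohort is tested by Pearson
correlation on log2 expression; pairs with |r| above a magnitude threshold
and a BH-adjusted p below the FDR cutoff define the m6A-related lncRNAs of
that cancer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, RegulatorCatalog
from .stats import bh_adjust, pearson_matrix

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "cancer_id",
    "lncrna_id",
    "regulator_id",
    "category",
    "r",
    "p",
    "q",
    "sign",
]


def screen(
    expr: ExpressionMatrix,
    catalog: RegulatorCatalog | None = None,
    r_min: float = 0.3,
    q_max: float = 0.05,
    cancer_id: str = "cohort",
    candidates: set[str] | None = None,
    fdr_scope: str = "cancer",
) -> pd.DataFrame:
    """Return CorrelationRecord rows for pairs passing |r| > r_min, q < q_max.

    The BH family is, by default, every lncRNA x regulator test in the
    cohort (``fdr_scope="cancer"``); ``"regulator"`` adjusts within each
    regulator's column instead.  ``candidates`` optionally restricts the
    tested lncRNAs (e.g. to those with prior m6A evidence).
    """
    if catalog is None:
        catalog = RegulatorCatalog()
    if not expr.transformed:
        raise ValueError("screen requires log2-transformed expression")
    if fdr_scope not in ("cancer", "regulator"):
        raise ValueError("fdr_scope must be 'cancer' or 'regulator'")

    regs = [r for r in catalog.names if r in expr.values.index]
    missing = [r for r in catalog.names if r not in expr.values.index]
    if missing:
        log.warning("regulators absent from matrix, skipped: %s", missing)
    if not regs:
        raise ValueError("no catalog regulator present in the matrix")

    lncs = expr.genes_with_role("lncRNA")
    if candidates is not None:
        lncs = [l for l in lncs if l in candidates]
    if not lncs:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    lnc_vals = expr.values.loc[lncs].to_numpy()
    reg_vals = expr.values.loc[regs].to_numpy()
    r, p = pearson_matrix(lnc_vals, reg_vals)

    if fdr_scope == "cancer":
        q = bh_adjust(p.ravel()).reshape(p.shape)
    else:
        q = np.column_stack([bh_adjust(p[:, j]) for j in range(p.shape[1])])

    ii, jj = np.nonzero((np.abs(r) > r_min) & (q < q_max))
    records = pd.DataFrame(
        {
            "cancer_id": cancer_id,
            "lncrna_id": [lncs[i] for i in ii],
            "regulator_id": [regs[j] for j in jj],
            "category": [catalog.category(regs[j]) for j in jj],
            "r": r[ii, jj],
            "p": p[ii, jj],
            "q": q[ii, jj],
            "sign": np.where(r[ii, jj] > 0, "positive", "negative"),
        },
        columns=RECORD_COLUMNS,
    )
    return records.sort_values(["lncrna_id", "regulator_id"]).reset_index(drop=True)


@dataclass
class ScreenSummary:
    """Landscape counts over one or more per-cancer screens."""

    per_cancer: pd.DataFrame  # cancer_id, n_positive, n_negative
    per_regulator: pd.DataFrame  # regulator_id, n_lncrnas
    per_lncrna: pd.DataFrame  # lncrna_id, n_regulators
    median_regulators_per_lncrna: float
    category_proportions: pd.DataFrame  # category, proportion of lncRNAs


def summarize(
    records: pd.DataFrame, catalog: RegulatorCatalog | None = None
) -> ScreenSummary:
    """Count positive/negative links per cancer, per regulator and per lncRNA."""
    if catalog is None:
        catalog = RegulatorCatalog()
    if records.empty:
        empty = pd.DataFrame
        return ScreenSummary(
            per_cancer=empty(columns=["cancer_id", "n_positive", "n_negative"]),
            per_regulator=empty(columns=["regulator_id", "n_lncrnas"]),
            per_lncrna=empty(columns=["lncrna_id", "n_regulators"]),
            median_regulators_per_lncrna=float("nan"),
            category_proportions=empty(columns=["category", "proportion"]),
        )
    per_cancer = (
        records.groupby("cancer_id")["sign"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["positive", "negative"], fill_value=0)
        .rename(columns={"positive": "n_positive", "negative": "n_negative"})
        .reset_index()
    )
    per_regulator = (
        records.groupby("regulator_id")["lncrna_id"]
        .nunique()
        .rename("n_lncrnas")
        .reset_index()
    )
    per_lncrna = (
        records.groupby("lncrna_id")["regulator_id"]
        .nunique()
        .rename("n_regulators")
        .reset_index()
    )
    n_lnc = per_lncrna.shape[0]
    # a lncRNA linked to both a reader and a writer counts once per category
    props = []
    for cat in ("reader", "writer", "eraser"):
        linked = records.loc[records["category"] == cat, "lncrna_id"].nunique()
        props.append({"category": cat, "proportion": linked / n_lnc})
    return ScreenSummary(
        per_cancer=per_cancer,
        per_regulator=per_regulator,
        per_lncrna=per_lncrna,
        median_regulators_per_lncrna=float(per_lncrna["n_regulators"].median()),
        category_proportions=pd.DataFrame(props),
    )
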