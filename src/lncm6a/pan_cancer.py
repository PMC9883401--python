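"""Cancer-common vs cancer-specific classification of m6A-related lncRNAs.

A lncRNA significant in (essentially) all analysed cancers is
cancer-common; one significant in exactly one cancer is cancer-specific;
the rest are intermediate.  Expression deviation quantifies how stable a
lncRNA's mean expression is across cancer cohorts, and a hypergeometric
upper-tail test checks whether cancer-specific lncRNAs are enriched among
tissue-elevated (TE) lncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .stats import hypergeom_upper_tail

CLASSIFICATION_COLUMNS = [
    "lncrna_id", "n_cancers_significant", "label",
    "specific_cancer", "n_regulators",
]


def classify(
    records: pd.DataFrame,
    cancer_ids: list[str],
    common_min_fraction: float = 1.0,
) -> pd.DataFrame:
    """Label each lncRNA common / specific / intermediate across cancers.

    ``records`` concatenates per-cancer screen outputs.  A lncRNA is common
    when significant in >= common_min_fraction of the analysed cancers
    (default: all of them), specific when significant in exactly one.
    """
    if len(cancer_ids) < 2:
        raise ValueError("classification needs at least 2 cancers")
    extra = set(records["cancer_id"]) - set(cancer_ids)
    if extra:
        raise ValueError(f"records mention cancers not analysed: {sorted(extra)}")
    n_total = len(cancer_ids)
    need_common = max(2, int(np.ceil(common_min_fraction * n_total)))
    rows = []
    for lnc, grp in records.groupby("lncrna_id"):
        cancers = set(grp["cancer_id"])
        k = len(cancers)
        if k >= need_common:
            label, specific = "common", ""
        elif k == 1:
            label, specific = "specific", next(iter(cancers))
        else:
            label, specific = "intermediate", ""
        rows.append(
            dict(
                lncrna_id=lnc,
                n_cancers_significant=k,
                label=label,
                specific_cancer=specific,
                n_regulators=grp["regulator_id"].nunique(),
            )
        )
    return pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS).sort_values(
        "lncrna_id"
    ).reset_index(drop=True)


def expression_deviation(
    cohorts: dict[str, ExpressionMatrix], lncrna_id: str, mode: str = "sd"
) -> float:
    """Between-cancer dispersion of a lncRNA's expression.

    ``"sd"`` (default): sample standard deviation across cancers of the
    per-cancer mean log2 expression.  ``"cv"``: coefficient of variation of
    the pooled per-sample values across all cohorts.
    """
    if mode not in ("sd", "cv"):
        raise ValueError("mode must be 'sd' or 'cv'")
    present = {
        c: m for c, m in cohorts.items() if lncrna_id in m.values.index
    }
    if len(present) < 2:
        raise ValueError(
            f"{lncrna_id!r} expressed in fewer than 2 cancers; deviation undefined"
        )
    if mode == "sd":
        means = [
            float(m.values.loc[lncrna_id].mean()) for m in present.values()
        ]
        return float(np.std(means, ddof=1))
    pooled = np.concatenate(
        [m.values.loc[lncrna_id].to_numpy(dtype=float) for m in present.values()]
    )
    mean = pooled.mean()
    if mean == 0:
        raise ValueError("pooled mean is zero; CV undefined")
    return float(pooled.std(ddof=1) / mean)


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int
    n_set_a: int
    n_set_b: int
    universe: int
    p: float


def hypergeom_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= |a ∩ b|) for overlap of two sets."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = hypergeom_upper_tail(k, len(universe), len(set_b), len(set_a))
    return EnrichmentResult(
        overlap=k, n_set_a=len(set_a), n_set_b=len(set_b),
        universe=len(universe), p=p,
    )
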