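"""m6A-mediated ceRNA (competing endogenous RNA) network construction.

Candidate lncRNA-miRNA-mRNA axes come from experimentally supported miRNA
interactions (the miRNA must target both the lncRNA and the mRNA); an axis
becomes a ceRNA triple when the expression correlations show the sponging
signature: lncRNA-mRNA positively correlated, and the shared miRNA
negatively correlated with both, each passing magnitude and FDR thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, InteractionCatalog
from .stats import bh_adjust, pearson_matrix

log = logging.getLogger(__name__)

TRIPLE_COLUMNS = [
    "cancer_id",
    "lncrna_id",
    "mirna_id",
    "mrna_id",
    "r_lnc_mrna",
    "q_lnc_mrna",
    "r_mir_lnc",
    "q_mir_lnc",
    "r_mir_mrna",
    "q_mir_mrna",
]


def candidate_axes(
    cat: InteractionCatalog, related_lncrnas: set[str]
) -> list[tuple[str, str, str]]:
    """All (lncRNA, miRNA, mRNA) with the miRNA targeting both ends."""
    axes = []
    for mirna in cat.mirna_ids:
        lncs = [t for t in cat.targets_of(mirna, "lncRNA") if t in related_lncrnas]
        if not lncs:
            continue
        mrnas = cat.targets_of(mirna, "mRNA")
        axes.extend((l, mirna, g) for l in lncs for g in mrnas)
    return axes


@dataclass
class CeRNANetwork:
    """Filtered triples plus the per-lncRNA mRNA target-set index."""

    triples: pd.DataFrame

    index: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {
            lnc: set(grp["mrna_id"])
            for lnc, grp in self.triples.groupby("lncrna_id")
        }

    def target_set(self, lncrna_id: str) -> set[str]:
        if lncrna_id not in self.index:
            raise KeyError(f"lncRNA {lncrna_id!r} not in network")
        return set(self.index[lncrna_id])

    @property
    def lncrna_ids(self) -> list[str]:
        return sorted(self.index)


def filter_triples(
    axes: list[tuple[str, str, str]],
    expr: ExpressionMatrix,
    r_min: float = 0.3,
    q_max: float = 0.05,
    cancer_id: str = "cohort",
) -> CeRNANetwork:
    """Keep axes whose three correlations satisfy the ceRNA sign pattern.

    lncRNA-mRNA must have r > r_min; miRNA-lncRNA and miRNA-mRNA must have
    r < -r_min; all three with BH q < q_max.  The lncRNA-mRNA correlations
    form one BH family and the miRNA-target correlations another, each over
    the distinct pairs tested in this cohort.
    """
    if not expr.transformed:
        raise ValueError("triple filtering requires log2-transformed expression")
    axes = [
        ax
        for ax in axes
        if all(g in expr.values.index for g in ax)
        or _warn_missing(ax, expr)
    ]
    if not axes:
        return CeRNANetwork(pd.DataFrame(columns=TRIPLE_COLUMNS))

    lnc_mrna = sorted({(l, g) for l, _, g in axes})
    mir_tgt = sorted({(m, l) for l, m, _ in axes} | {(m, g) for _, m, g in axes})

    def _pair_stats(pairs: list[tuple[str, str]]) -> dict:
        rows = sorted({a for a, _ in pairs})
        cols = sorted({b for _, b in pairs})
        r, p = pearson_matrix(
            expr.values.loc[rows].to_numpy(), expr.values.loc[cols].to_numpy()
        )
        ri = {g: i for i, g in enumerate(rows)}
        ci = {g: j for j, g in enumerate(cols)}
        idx = np.array([(ri[a], ci[b]) for a, b in pairs])
        rv = r[idx[:, 0], idx[:, 1]]
        pv = p[idx[:, 0], idx[:, 1]]
        qv = bh_adjust(pv)
        return {pair: (rv[k], qv[k]) for k, pair in enumerate(pairs)}

    lm_stats = _pair_stats(lnc_mrna)
    mt_stats = _pair_stats(mir_tgt)

    rows = []
    for l, m, g in axes:
        r_lg, q_lg = lm_stats[(l, g)]
        r_ml, q_ml = mt_stats[(m, l)]
        r_mg, q_mg = mt_stats[(m, g)]
        if (
            r_lg > r_min
            and q_lg < q_max
            and r_ml < -r_min
            and q_ml < q_max
            and r_mg < -r_min
            and q_mg < q_max
        ):
            rows.append(
                dict(
                    cancer_id=cancer_id,
                    lncrna_id=l,
                    mirna_id=m,
                    mrna_id=g,
                    r_lnc_mrna=r_lg,
                    q_lnc_mrna=q_lg,
                    r_mir_lnc=r_ml,
                    q_mir_lnc=q_ml,
                    r_mir_mrna=r_mg,
                    q_mir_mrna=q_mg,
                )
            )
    return CeRNANetwork(pd.DataFrame(rows, columns=TRIPLE_COLUMNS))


def _warn_missing(ax, expr) -> bool:
    missing = [g for g in ax if g not in expr.values.index]
    log.warning("axis %s skipped: %s absent from expression matrix", ax, missing)
    return False


def write_target_sets(net: CeRNANetwork, path) -> None:
    """GMT-style file: lncRNA id, then its target mRNAs, tab-separated."""
    with open(path, "w") as fh:
        for lnc in net.lncrna_ids:
            members = "\t".join(sorted(net.index[lnc]))
            fh.write(f"{lnc}\t{members}\n")
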