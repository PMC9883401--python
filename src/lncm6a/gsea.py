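"""Drug-resistance scoring of lncRNAs via a weighted enrichment walk.

mRNAs are ranked by the Pearson correlation between their expression and a
drug's per-sample IC50.  A lncRNA's ceRNA target set S is then scored by a
weighted Kolmogorov-Smirnov running sum over the ranked list L = g1...gN:
hits accumulate |r_j|^p / N_R (N_R = sum of hit weights), misses accumulate
1/(N - N_H), and the enrichment score ES is the value of the running sum at
its maximum absolute deviation from zero.  Positive ES means the target set
concentrates among resistance-correlated genes; significance comes from a
permutation null of random equal-size gene sets, with BH correction across
all (lncRNA, drug) pairs of a screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DrugResponseTable, ExpressionMatrix
from .stats import bh_adjust, pearson_r

RESULT_COLUMNS = [
    "lncrna_id", "drug_id", "es", "n_hits", "p_perm", "q", "call",
]


@dataclass(frozen=True)
class RankedGeneList:
    """Genes in descending order of the IC50-correlation metric."""

    genes: tuple[str, ...]
    metric: np.ndarray  # aligned with genes, descending
    drug_id: str

    @property
    def n(self) -> int:
        return len(self.genes)


def rank_by_drug(
    expr_mrna: ExpressionMatrix, ic50: pd.Series, drug_id: str = ""
) -> RankedGeneList:
    """Rank mRNAs by Pearson r(expression, IC50), pairwise-complete.

    Ties in the metric break lexicographically on gene id so the order is
    deterministic regardless of input gene order.
    """
    common = [s for s in expr_mrna.sample_ids if s in ic50.index]
    y = ic50.loc[common]
    mask = y.notna()
    samples = list(y.index[mask])
    if len(samples) < 3:
        raise ValueError("fewer than 3 samples with both expression and IC50")
    yv = y.loc[samples].to_numpy(dtype=float)
    genes = expr_mrna.genes_with_role("mRNA")
    metrics = {}
    for g in genes:
        xv = expr_mrna.values.loc[g, samples].to_numpy(dtype=float)
        if np.std(xv) == 0 or np.std(yv) == 0:
            metrics[g] = 0.0
        else:
            metrics[g], _ = pearson_r(xv, yv)
    order = sorted(genes, key=lambda g: (-metrics[g], g))
    return RankedGeneList(
        genes=tuple(order),
        metric=np.array([metrics[g] for g in order]),
        drug_id=drug_id,
    )


def _walk(
    weights: np.ndarray, hit: np.ndarray
) -> np.ndarray:
    """Running sum P_hit - P_miss for one hit-indicator over the list."""
    n = weights.size
    nh = int(hit.sum())
    nr = weights[hit].sum()
    p_hit = np.cumsum(np.where(hit, weights, 0.0)) / nr
    p_miss = np.cumsum(np.where(hit, 0.0, 1.0)) / (n - nh)
    return p_hit - p_miss


def enrichment_score(
    L: RankedGeneList, S: set[str], weight_p: float = 1.0, use_abs: bool = True
) -> tuple[float, np.ndarray]:
    """ES and the full running walk for gene set S against ranked list L.

    Requires 0 < |S ∩ L| < N and a positive total hit weight N_R.  The walk
    always returns to zero at position N.
    """
    hit = np.fromiter((g in S for g in L.genes), dtype=bool, count=L.n)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no member in the ranked list")
    if nh == L.n:
        raise ValueError("gene set covers the whole list; misses undefined")
    base = np.abs(L.metric) if use_abs else L.metric
    weights = base**weight_p
    if weights[hit].sum() <= 0:
        raise ValueError("total hit weight N_R is not positive")
    walk = _walk(weights, hit)
    es = float(walk[_peak_index(np.abs(walk))])
    return es, walk


def _peak_index(absd: np.ndarray) -> int:
    # earliest position within rounding noise of the maximal deviation,
    # so numerically tied +/- peaks resolve deterministically
    return int(np.argmax(absd >= absd.max() - 1e-9))


def _es_many(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Vectorised ES for many hit-indicator rows over one ranked list."""
    n = weights.size
    nh = hits.sum(axis=1, keepdims=True)
    w = np.where(hits, weights, 0.0)
    p_hit = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~hits, axis=1) / (n - nh)
    d = p_hit - p_miss
    absd = np.abs(d)
    peak = np.argmax(absd >= absd.max(axis=1, keepdims=True) - 1e-9, axis=1)
    return np.take_along_axis(d, peak[:, None], axis=1)[:, 0]


def permutation_p(
    L: RankedGeneList,
    S: set[str],
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    weight_p: float = 1.0,
    use_abs: bool = True,
) -> tuple[float, float]:
    """Split-null permutation p for the ES of S against L.

    Draws B uniform gene sets of size |S ∩ L| and, following the sign-
    specific GSEA convention, compares the observed ES only against the
    same-signed part of the null with add-one smoothing:
    p = (1 + #{es_b >= es_obs}) / (1 + #{es_b >= 0}) for positive ES and
    the mirror image for negative ES.  p is never zero, is bounded below
    by 1/(B+1), and is approximately uniform for random sets.
    Returns (es_obs, p_perm).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    es_obs, _ = enrichment_score(L, S, weight_p=weight_p, use_abs=use_abs)
    nh = sum(g in S for g in L.genes)
    base = np.abs(L.metric) if use_abs else L.metric
    weights = base**weight_p
    # uniform random nh-subsets: smallest nh of B x n iid uniforms
    ranks = np.argpartition(rng.random((B, L.n)), nh - 1, axis=1)[:, :nh]
    hits = np.zeros((B, L.n), dtype=bool)
    np.put_along_axis(hits, ranks, True, axis=1)
    es_null = _es_many(weights, hits)
    if es_obs > 0:
        p = (1 + int(np.sum(es_null >= es_obs))) / (
            1 + int(np.sum(es_null >= 0))
        )
    elif es_obs < 0:
        p = (1 + int(np.sum(es_null <= es_obs))) / (
            1 + int(np.sum(es_null <= 0))
        )
    else:
        p = 1.0
    return es_obs, min(p, 1.0)


def call_associations(results: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """BH-adjust permutation p over the screen and call each pair.

    resistant: es > 0 and q < q_max; sensitive: es < 0 and q < q_max;
    otherwise ns.
    """
    out = results.copy()
    if out.empty:
        out["q"] = []
        out["call"] = []
        return out
    out["q"] = bh_adjust(out["p_perm"].to_numpy())
    out["call"] = np.where(
        (out["es"] > 0) & (out["q"] < q_max),
        "resistant",
        np.where((out["es"] < 0) & (out["q"] < q_max), "sensitive", "ns"),
    )
    return out


def drug_screen(
    expr: ExpressionMatrix,
    drugs: DrugResponseTable,
    target_sets: dict[str, set[str]],
    B: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Score every (lncRNA target set, drug) pair and call associations."""
    rng = np.random.default_rng(seed)
    mrna_ids = set(expr.genes_with_role("mRNA"))
    rows = []
    for drug_id in drugs.drug_ids:
        ic50 = drugs.ic50.loc[drug_id]
        L = rank_by_drug(expr, ic50, drug_id=drug_id)
        for lnc, S in sorted(target_sets.items()):
            hits = S & mrna_ids
            if not hits or len(hits) >= L.n:
                continue
            es, p = permutation_p(L, hits, B=B, seed=rng, weight_p=weight_p)
            rows.append(
                dict(lncrna_id=lnc, drug_id=drug_id, es=es,
                     n_hits=len(hits), p_perm=p)
            )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS[:5])
    return call_associations(results, q_max=q_max)
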