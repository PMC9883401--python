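"""Synthetic multi-omic cohorts with planted, fully-known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real tumor cohorts:

* regulator-lncRNA correlation at a tunable planted magnitude rho,
* ceRNA sponging triples — a miRNA negatively loaded on both a lncRNA and
  its target mRNAs, which share a positive latent term,
* drug IC50 linearly coupled to the expression of resistance genes,
* exponential survival with a group-dependent hazard and uniform censoring,
* lncRNA sequences with tunable GC/CpG composition and planted DRACH motifs.

Gaussian latents are mapped to a positive TPM scale by exponentiation
(TPM = 2^(loc + scale*z)), so the downstream log2 transform approximately
recovers the latent correlation structure.  Every emitted id appears in
the truth tables; one master seed drives per-component child generators so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import seqfeat
from .core_io import (
    DEFAULT_REGULATORS,
    ClinicalTable,
    DrugResponseTable,
    ExpressionMatrix,
    InteractionCatalog,
)

LATENT_LOC = 5.0  # log2-TPM location of the latent-to-TPM map
LATENT_SCALE = 1.5  # log2-TPM spread per latent unit

_COMPONENT = {"expression": 0, "interactions": 1, "drugs": 2,
              "survival": 3, "sequences": 4}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults define the study conditions."""

    n_samples: int = 500
    n_cancers: int = 3
    n_regulators: int = 21
    n_lncrnas: int = 200
    n_mirnas: int = 20
    n_mrnas: int = 300
    # regulator-lncRNA planting
    rho_signal: float = 0.6
    frac_related: float = 0.1
    frac_negative: float = 0.3
    # ceRNA triples
    n_triple_lncrnas: int = 4
    n_targets_per_lncrna: int = 8
    triple_mirna_loading: float = 0.6
    triple_shared_loading: float = 0.6
    triple_regulator_loading: float = 0.4
    n_decoy_axes: int = 20
    # drugs
    n_drugs: int = 4
    n_signal_drugs: int = 2
    n_effect_genes: int = 8
    drug_effect_size: float = 1.0
    drug_noise_sd: float = 2.0
    # survival
    baseline_hazard: float = 1.0 / 1000.0  # per day
    survival_beta: float = float(np.log(2))
    n_survival_lncrnas: int = 1
    censoring_fraction: float = 0.3
    # cancer-specific planting (one disjoint block of lncRNAs per cancer)
    n_specific_lncrnas: int = 0
    specific_block: int = 0
    # sequences
    seq_length: int = 2000
    gc_target: float = 0.5
    cpg_enrichment: float = 4.0
    cpg_core_fraction: float = 0.4
    n_drach_planted: int = 30
    # zero-inflated low-expression genes exercising the 70% filter
    frac_low_expressed: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_regulators", "n_lncrnas", "n_mirnas",
                     "n_mrnas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not abs(self.rho_signal) < 1:
            raise ValueError("|rho_signal| must be < 1")
        for name in ("frac_related", "frac_negative", "censoring_fraction",
                     "frac_low_expressed", "cpg_core_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        a, b, r = (self.triple_mirna_loading, self.triple_shared_loading,
                   self.triple_regulator_loading)
        if a * a + b * b + r * r >= 1:
            raise ValueError("triple loadings imply variance > 1")
        if self.n_regulators > len(DEFAULT_REGULATORS):
            raise ValueError("at most 21 regulators available")

    @property
    def n_related(self) -> int:
        return int(round(self.frac_related * self.n_lncrnas))


@dataclass
class SyntheticTruth:
    """Exhaustive ground truth: any discovery not listed here is false."""

    related_pairs: set[tuple[str, str, str]] = field(default_factory=set)
    true_triples: set[tuple[str, str, str]] = field(default_factory=set)
    drug_effect_genes: dict[str, list[tuple[str, str]]] = field(
        default_factory=dict
    )
    drug_target_lncrna: dict[str, str] = field(default_factory=dict)
    survival_beta: dict[str, float] = field(default_factory=dict)
    sequence_truth: pd.DataFrame | None = None

    @property
    def related_lncrnas(self) -> set[str]:
        return {l for l, _, _ in self.related_pairs}


def _rng(cfg: SimulationConfig, component: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _COMPONENT[component]])


def _ids(cfg: SimulationConfig) -> dict[str, list[str]]:
    return {
        "regulator": [n for n, _ in DEFAULT_REGULATORS[: cfg.n_regulators]],
        "lncRNA": [f"LNC{i:04d}" for i in range(cfg.n_lncrnas)],
        "miRNA": [f"MIR{i:03d}" for i in range(cfg.n_mirnas)],
        "mRNA": [f"MRNA{i:04d}" for i in range(cfg.n_mrnas)],
    }


def _to_tpm(latent: np.ndarray) -> np.ndarray:
    return np.exp2(LATENT_LOC + LATENT_SCALE * latent)


def triple_lncrna_ids(cfg: SimulationConfig) -> list[str]:
    """The lncRNAs carrying planted sponging triples (ids are deterministic)."""
    start = cfg.n_related
    return [f"LNC{start + k:04d}" for k in range(cfg.n_triple_lncrnas)]


def specific_lncrna_ids(cfg: SimulationConfig, block: int | None = None) -> list[str]:
    """The cancer-specific planted lncRNAs of one cancer's block."""
    if block is None:
        block = cfg.specific_block
    start = (
        cfg.n_related
        + cfg.n_triple_lncrnas
        + block * cfg.n_specific_lncrnas
    )
    return [f"LNC{start + k:04d}" for k in range(cfg.n_specific_lncrnas)]


def simulate_cohort(
    cfg: SimulationConfig, cancer_id: str = "cohort"
) -> tuple[ExpressionMatrix, InteractionCatalog, SyntheticTruth]:
    """Emit a TPM-scale expression matrix, interaction catalog and truth.

    Layout: lncRNAs [0, n_related) carry the regulator correlation at
    rho_signal (a frac_negative share with negative sign); the next
    n_triple_lncrnas lncRNAs anchor sponging triples and carry a weaker
    regulator loading so they are m6A-related too; everything else is
    independent background.  Identical config and seed give byte-identical
    outputs.
    """
    ids = _ids(cfg)
    n_planted_lnc = (
        cfg.n_related
        + cfg.n_triple_lncrnas
        + (cfg.specific_block + 1) * cfg.n_specific_lncrnas
    )
    if n_planted_lnc > cfg.n_lncrnas:
        raise ValueError("more planted lncRNAs than n_lncrnas")
    if cfg.n_triple_lncrnas > cfg.n_mirnas:
        raise ValueError("more planted triples than available miRNAs")
    n_target_total = cfg.n_triple_lncrnas * cfg.n_targets_per_lncrna
    if n_target_total > cfg.n_mrnas:
        raise ValueError("more planted target mRNAs than n_mrnas")

    rng = _rng(cfg, "expression")
    n = cfg.n_samples
    truth = SyntheticTruth()
    samples = [f"{cancer_id}_S{i:04d}" for i in range(n)]

    reg_latent = rng.standard_normal((cfg.n_regulators, n))
    lnc_latent = rng.standard_normal((cfg.n_lncrnas, n))
    mir_latent = rng.standard_normal((cfg.n_mirnas, n))
    mrna_latent = rng.standard_normal((cfg.n_mrnas, n))

    # regulator-correlated lncRNAs
    rho = cfg.rho_signal
    n_neg = int(round(cfg.frac_negative * cfg.n_related))
    for i in range(cfg.n_related):
        j = i % cfg.n_regulators
        sign = -1.0 if i < n_neg else 1.0
        lnc_latent[i] = (
            sign * rho * reg_latent[j]
            + np.sqrt(1 - rho * rho) * lnc_latent[i]
        )
        truth.related_pairs.add(
            (ids["lncRNA"][i], ids["regulator"][j],
             "negative" if sign < 0 else "positive")
        )

    # cancer-specific lncRNAs: same loading, but only this cohort's block
    for k, lnc in enumerate(specific_lncrna_ids(cfg)):
        li = int(lnc[3:])
        j = (cfg.n_related + k) % cfg.n_regulators
        lnc_latent[li] = (
            rho * reg_latent[j] + np.sqrt(1 - rho * rho) * lnc_latent[li]
        )
        truth.related_pairs.add((lnc, ids["regulator"][j], "positive"))

    # sponging triples: miRNA negatively loaded on lncRNA and targets,
    # which share a positive latent; the lncRNA keeps a regulator loading
    a = cfg.triple_mirna_loading
    b = cfg.triple_shared_loading
    rl = cfg.triple_regulator_loading
    c_lnc = np.sqrt(1 - a * a - b * b - rl * rl)
    c_tgt = np.sqrt(1 - a * a - b * b)
    for k in range(cfg.n_triple_lncrnas):
        li = cfg.n_related + k
        j = li % cfg.n_regulators
        shared = rng.standard_normal(n)
        lnc_latent[li] = (
            rl * reg_latent[j] - a * mir_latent[k] + b * shared
            + c_lnc * lnc_latent[li]
        )
        truth.related_pairs.add(
            (ids["lncRNA"][li], ids["regulator"][j], "positive")
        )
        for t in range(cfg.n_targets_per_lncrna):
            gi = k * cfg.n_targets_per_lncrna + t
            mrna_latent[gi] = (
                -a * mir_latent[k] + b * shared + c_tgt * mrna_latent[gi]
            )
            truth.true_triples.add(
                (ids["lncRNA"][li], ids["miRNA"][k], ids["mRNA"][gi])
            )

    values = pd.DataFrame(
        _to_tpm(
            np.vstack([reg_latent, lnc_latent, mir_latent, mrna_latent])
        ),
        index=ids["regulator"] + ids["lncRNA"] + ids["miRNA"] + ids["mRNA"],
        columns=samples,
    )

    # zero-inflate some background genes so the expression filter is live
    background = [
        g
        for role in ("lncRNA", "mRNA")
        for g in ids[role]
        if g not in {x for tup in truth.true_triples for x in tup}
        and g not in truth.related_lncrnas
    ]
    n_low = int(round(cfg.frac_low_expressed * len(background)))
    low_genes = list(rng.choice(background, size=n_low, replace=False))
    for g in low_genes:
        drop = rng.random(n) < 0.5
        values.loc[g, values.columns[drop]] = 0.0

    roles = pd.Series(
        {g: role for role in ids for g in ids[role]}, name="role"
    ).loc[values.index]
    expr = ExpressionMatrix(values=values, roles=roles, transformed=False)

    # interaction catalog: planted triple edges plus decoy axes
    irng = _rng(cfg, "interactions")
    pairs: list[tuple[str, str, str]] = []
    for l, m, g in sorted(truth.true_triples):
        pairs.append((m, l, "lncRNA"))
        pairs.append((m, g, "mRNA"))
    related_sorted = sorted(truth.related_lncrnas)
    for _ in range(cfg.n_decoy_axes if related_sorted else 0):
        m = ids["miRNA"][int(irng.integers(cfg.n_mirnas))]
        l = related_sorted[int(irng.integers(len(related_sorted)))]
        g = ids["mRNA"][int(irng.integers(cfg.n_mrnas))]
        pairs.append((m, l, "lncRNA"))
        pairs.append((m, g, "mRNA"))
    cat_df = (
        pd.DataFrame(pairs, columns=["mirna_id", "target_id", "target_class"])
        .drop_duplicates(["mirna_id", "target_id"])
        .sort_values(["mirna_id", "target_id"])
        .reset_index(drop=True)
    )
    return expr, InteractionCatalog(pairs=cat_df), truth


def simulate_drug_response(
    cfg: SimulationConfig, expr: ExpressionMatrix, truth: SyntheticTruth
) -> DrugResponseTable:
    """IC50 = effect_size * sum of effect-gene log2 expression + noise.

    Signal drugs take their effect genes (positive weight = resistance-
    associated) from a planted triple lncRNA's target set; the remaining
    drugs are pure noise.  Records the gene-direction map in the truth.
    """
    if not expr.transformed:
        raise ValueError("drug simulation couples IC50 to log2 expression")
    rng = _rng(cfg, "drugs")
    tl = triple_lncrna_ids(cfg)
    targets_of = {
        l: sorted(g for ll, _, g in truth.true_triples if ll == l) for l in tl
    }
    n = expr.n_samples
    rows = {}
    for d in range(cfg.n_drugs):
        drug_id = f"DRUG{d:02d}"
        ic50 = rng.standard_normal(n) * cfg.drug_noise_sd
        if d < cfg.n_signal_drugs and tl:
            lnc = tl[d % len(tl)]
            genes = targets_of[lnc][: cfg.n_effect_genes]
            missing = [g for g in genes if g not in expr.values.index]
            if missing:
                raise ValueError(f"effect gene absent from matrix: {missing[0]}")
            for g in genes:
                ic50 = ic50 + cfg.drug_effect_size * expr.values.loc[g].to_numpy()
            truth.drug_effect_genes[drug_id] = [(g, "resistance") for g in genes]
            truth.drug_target_lncrna[drug_id] = lnc
        else:
            truth.drug_effect_genes[drug_id] = []
        rows[drug_id] = ic50
    ic50_df = pd.DataFrame(rows, index=expr.sample_ids).T
    return DrugResponseTable(ic50=ic50_df)


def _solve_censor_horizon(lam: np.ndarray, target: float) -> float:
    """Uniform-censoring horizon c with P(C < T) equal to the target."""

    def censored_fraction(c: float) -> float:
        x = lam * c
        return float(np.mean((1 - np.exp(-x)) / x))

    lo, hi = 1e-9 / lam.mean(), 1e9 / lam.mean()
    return brentq(lambda c: censored_fraction(c) - target, lo, hi)


def simulate_survival(
    cfg: SimulationConfig, expr: ExpressionMatrix, truth: SyntheticTruth
) -> ClinicalTable:
    """Exponential survival with hazard h0*exp(beta * above-median indicator).

    Censoring is independent Uniform(0, c) with c solved numerically for
    the requested censoring fraction; censoring_fraction = 0 disables it.
    """
    if not expr.transformed:
        raise ValueError("survival simulation uses log2 expression")
    rng = _rng(cfg, "survival")
    planted = [f"LNC{i:04d}" for i in range(cfg.n_survival_lncrnas)]
    missing = [l for l in planted if l not in expr.values.index]
    if missing:
        raise ValueError(f"survival lncRNA absent from matrix: {missing[0]}")
    n = expr.n_samples
    log_hr = np.zeros(n)
    for l in planted:
        x = expr.values.loc[l].to_numpy(dtype=float)
        high = x > np.median(x)
        log_hr = log_hr + cfg.survival_beta * high
        truth.survival_beta[l] = cfg.survival_beta
    lam = cfg.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / lam)
    if cfg.censoring_fraction > 0:
        c = _solve_censor_horizon(lam, cfg.censoring_fraction)
        t_cens = rng.uniform(0, c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    table = pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "time_days": np.maximum(time, 1e-9),
            "event": event,
        }
    )
    return ClinicalTable(table=table)


_DRACH_CHOICES = ("AGT", "AG", "A", "C", "ACT")  # D, R, A, C, H


def simulate_sequences(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Per-lncRNA sequences, a TSS BED table and the exact sequence truth.

    Sequences follow a first-order composition model at the GC target; for
    m6A-related lncRNAs (the planted ones) the C->G transition is boosted
    by the CpG enrichment factor within a core window (``cpg_core_fraction``
    of the length, centred on the TSS at the midpoint, giving the
    CpG-island-like promoter peak) and DRACH 5-mers are spliced in at
    non-overlapping positions.  Truth values (gc, cpg_count, drach_count)
    are recomputed on the emitted string, so they are exact by construction.
    """
    if cfg.seq_length < 10:
        raise ValueError("sequences must be at least 10 nt")
    if cfg.n_drach_planted * 5 > cfg.seq_length:
        raise ValueError("planted motifs do not fit in the sequence")
    rng = _rng(cfg, "sequences")
    ids = _ids(cfg)["lncRNA"]
    related = {f"LNC{i:04d}" for i in range(cfg.n_related)} | set(
        triple_lncrna_ids(cfg)
    )
    bases = np.array(list("ACGT"))
    gc = cfg.gc_target
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    sequences: dict[str, str] = {}
    bed_rows = []
    truth_rows = []
    core_half = int(cfg.seq_length * cfg.cpg_core_fraction / 2)
    core_lo = cfg.seq_length // 2 - core_half
    core_hi = cfg.seq_length // 2 + core_half
    for idx, seq_id in enumerate(ids):
        enrich = cfg.cpg_enrichment if seq_id in related else 1.0
        from_c = base_p.copy()
        from_c[2] *= enrich
        from_c = from_c / from_c.sum()
        draws_base = rng.choice(4, size=cfg.seq_length, p=base_p)
        draws_cpg = rng.choice(4, size=cfg.seq_length, p=from_c)
        out = np.empty(cfg.seq_length, dtype=int)
        out[0] = draws_base[0]
        for i in range(1, cfg.seq_length):
            in_core = core_lo <= i < core_hi
            out[i] = (
                draws_cpg[i]
                if (out[i - 1] == 1 and in_core)
                else draws_base[i]
            )
        seq = "".join(bases[out])
        n_plant = cfg.n_drach_planted if seq_id in related else 0
        placed: list[int] = []
        attempts = 0
        while len(placed) < n_plant and attempts < 1000 * max(n_plant, 1):
            pos = int(rng.integers(0, cfg.seq_length - 4))
            if all(abs(pos - q) >= 5 for q in placed):
                motif = "".join(
                    rng.choice(list(choice)) for choice in _DRACH_CHOICES
                )
                seq = seq[:pos] + motif + seq[pos + 5 :]
                placed.append(pos)
            attempts += 1
        sequences[seq_id] = seq
        mid = cfg.seq_length // 2
        strand = "+" if idx % 2 == 0 else "-"
        bed_rows.append((seq_id, mid, mid + 1, f"{seq_id}_tss", 0, strand))
        truth_rows.append(
            {
                "seq_id": seq_id,
                "length": len(seq),
                "gc": seqfeat.gc_content(seq),
                "cpg_count": seqfeat.cpg_count(seq),
                "drach_count": seqfeat.motif_count(seq, "DRACH"),
                "n_planted": n_plant,
                "is_related": seq_id in related,
            }
        )
    bed = pd.DataFrame(
        bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return sequences, bed, pd.DataFrame(truth_rows)


def simulate_multi_cancer(
    cfg: SimulationConfig,
) -> dict[str, tuple[ExpressionMatrix, InteractionCatalog, SyntheticTruth]]:
    """One cohort per cancer, same planted structure, independent noise."""
    out = {}
    for c in range(cfg.n_cancers):
        cancer_id = f"C{c + 1:02d}"
        sub = replace(
            cfg,
            seed=(cfg.seed * 1009 + c + 1) % (2**31 - 1),
            specific_block=c,
        )
        out[cancer_id] = simulate_cohort(sub, cancer_id=cancer_id)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in sequences.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
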