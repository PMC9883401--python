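# lncm6a

Pan-cancer identification and functional profiling of **m6A-regulator-related
lncRNAs** from expression matrices, with a fully synthetic, ground-truthed
cohort generator so that every stage of the analysis is verifiable by
parameter recovery.

N6-methyladenosine (m6A) is the most abundant internal RNA modification; it
is written, erased and read by a dedicated set of 21 regulator proteins
(11 readers, 8 writers, 2 erasers — METTL3, FTO, YTHDF1, ...). Long
noncoding RNAs are heavily m6A-modified, and lncRNAs whose expression tracks
the regulators across tumor cohorts are candidate substrates and effectors
of the modification. This package implements the downstream inference chain
a computational-oncology group would run over such cohorts:

1. **Correlation screen** — for each cancer cohort, every (lncRNA,
   regulator) pair is tested by Pearson correlation on log2(TPM + 1)
   expression; pairs with |r| > 0.3 and Benjamini–Hochberg q < 0.05 define
   the *m6A-related lncRNAs*.
2. **ceRNA networks** — candidate lncRNA–miRNA–mRNA axes (one miRNA
   targeting both ends) are kept as competing-endogenous-RNA triples when
   the correlations show the sponging signature:
   r(lncRNA, mRNA) > 0.3, r(miRNA, lncRNA) < −0.3, r(miRNA, mRNA) < −0.3,
   all at q < 0.05.
3. **Drug-resistance score** — mRNAs are ranked by the correlation of their
   expression with a drug's per-sample IC50 (higher IC50 = more resistant);
   a lncRNA's ceRNA target set *S* is scored on the ranked list
   L = g₁g₂…g_N with the weighted running sum

   P_hit(S, i) = Σ_{gⱼ∈S, j≤i} |rⱼ|ᵖ / N_R,  N_R = Σ_{gⱼ∈S} |rⱼ|ᵖ
   P_miss(S, i) = Σ_{gⱼ∉S, j≤i} 1 / (N − N_H)

   The enrichment score ES is the maximum deviation from zero of
   P_hit − P_miss; significance comes from a permutation null of random
   equal-size gene sets, and BH-significant positive/negative ES yields a
   *drug-resistant* / *drug-sensitive* call.
4. **Survival** — patients are split at each lncRNA's median expression;
   groups are compared by the log-rank test and a univariate Cox
   proportional-hazards model (hazard ratio of high vs low).
5. **Sequence features** — GC content, CpG counts, normalized CpG
   (observed CpG / expected CpG with expected = (GC/2)²), DRACH-motif
   (D=[AGT] R=[AG] A C H=[ACT]) consensus counts and TSS-window CpG
   profiles, compared between lncRNA groups by Student's t or
   Kolmogorov–Smirnov tests.
6. **Pan-cancer classification** — lncRNAs significant in all cancers are
   *cancer-common*, in exactly one *cancer-specific*; expression deviation
   and hypergeometric enrichment against a tissue-elevated lncRNA set
   characterize the two classes.

Because the original tumor compendia (TCGA, GDSC, GENCODE annotations,
miRNA-interaction databases) cannot ship with code, the
`lncm6a.simulate` module generates self-contained cohorts with planted
ground truth for every layer — regulator-correlated lncRNAs at a chosen ρ,
sponging triples with the correct sign pattern, IC50 linearly coupled to
resistance genes, exponential survival with a planted hazard ratio, and
sequences with tunable GC/CpG composition and planted DRACH motifs — so
recovery, false-discovery control and calibration are all testable.

## Worked example

```python
import lncm6a as L

cfg = L.SimulationConfig(n_samples=300, n_lncrnas=60, n_mirnas=10,
                         n_mrnas=80, seed=1)
expr, interactions, truth = L.simulate_cohort(cfg)
logged = L.log2_transform(L.filter_expressed(expr))

records = L.screen(logged)          # m6A-related lncRNA screen
planted = {(l, r) for l, r, _ in truth.related_pairs}
found = set(zip(records.lncrna_id, records.regulator_id))
print(len(records), len(planted & found) / len(planted))
# 10 1.0        <- all 10 planted pairs recovered, no false pairs

net = L.filter_triples(L.candidate_axes(interactions,
                                        truth.related_lncrnas), logged)
print(len(net.triples))             # 32  <- all planted ceRNA triples

drugs = L.simulate_drug_response(cfg, logged, truth)
calls = L.drug_screen(logged, drugs, net.index, B=1000, seed=1)
print(calls.loc[calls.call == "resistant",
                ["lncrna_id", "drug_id", "es", "q"]].head(2).to_string())
#   lncrna_id drug_id   es         q
# 0   LNC0006  DRUG00  1.0  0.012759   <- the drugs whose IC50 was coupled
# 5   LNC0007  DRUG01  1.0  0.012759      to each lncRNA's planted targets
```

The printed enrichment score 1.0 means the lncRNA's entire ceRNA target set
sits at the very top of the resistance-correlation ranking — exactly the
planted coupling — and q < 0.05 turns it into a *resistant* call.

The same steps are available as a CLI (`lncm6a simulate | screen |
features | cerna | drug-gsea | survival | classify | all`), and the
`analysis/` directory holds the numbered study drivers
(`01_simulate_cohorts.py` … `07_pan_cancer.py`) that chain them over a
three-cancer synthetic study and write their tables under `results/`.

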