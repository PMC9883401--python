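# Methods

## Expression model and preprocessing

All screens operate on genes × samples matrices carrying a molecular role
per gene (m6A regulator, lncRNA, miRNA, mRNA). Raw abundances are on the
TPM scale; preprocessing keeps genes with TPM > 0 in at least 70% of
samples (inclusive boundary, configurable `min_fraction`) and then applies
log2(TPM + offset) with a pseudocount offset of 1. The pseudocount is a
convention rather than a derived quantity — retained genes can still hold
zeros in up to 30% of samples — and is exposed as a parameter. The filter
is defined only on the TPM scale and the transform is one-shot; both
conditions are enforced by a `transformed` flag, so a double transform or a
post-transform filter is an error rather than a silent distortion.

## Correlation screen

For every (lncRNA, regulator) pair the sample Pearson coefficient is
computed on the log2 scale, with the two-sided p-value from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. Multiple testing is
corrected by Benjamini–Hochberg; the FDR family is all lncRNA × regulator
tests within one cancer cohort by default (`fdr_scope="regulator"` adjusts
per regulator column instead — the choice is a genuine analysis decision,
since landscape counts are reported per cancer while regulator-centric
summaries argue for per-regulator families). Pairs pass with |r| > 0.3
(strict) and q < 0.05 (strict). An optional candidate whitelist restricts
the tested lncRNAs to those with prior m6A evidence when such an annotation
is available; without it, all lncRNAs are tested. Zero-variance genes
yield r = 0, p = 1 inside the vectorised screen (they can never pass), while
the scalar `pearson_r` treats them as errors.

## ceRNA triples

Candidate axes require experimental support: a miRNA must target both the
lncRNA and the mRNA in the interaction catalog before any correlation is
computed (the "axis" reading — correlation alone never creates an edge).
An axis becomes a triple when r(lncRNA, mRNA) > 0.3, r(miRNA, lncRNA) <
−0.3 and r(miRNA, mRNA) < −0.3, each with BH q < 0.05. Two FDR families
are used: all distinct lncRNA–mRNA pairs tested in the cohort form one,
all distinct miRNA–target pairs the other, mirroring the two kinds of
hypotheses. Axes touching genes absent from the (filtered) matrix are
skipped with a warning, since catalog/matrix mismatches are the norm with
real annotations. The per-lncRNA union of partner mRNAs — the "target
set" — is the gene set handed to the drug-resistance score.

## Drug-resistance enrichment score

mRNAs are ranked by Pearson correlation between expression and per-sample
IC50 (pairwise-complete over non-missing assays; ties in the metric break
lexicographically on gene id so ranking is deterministic). The target set
S is scored with the weighted Kolmogorov–Smirnov running sum: hits add
|r_j|^p / N_R (weight exponent p = 1 by default), misses add 1/(N − N_H),
and ES is the running sum's value at its maximum absolute deviation. The
absolute value in the hit weight is deliberate: with signed weights N_R
could vanish or change sign for sets concentrated among negative
correlations, making the score ill-defined; |r_j| matches the canonical
weighted-GSEA definition. Both p and the use of |·| are configurable.
Numerically, the walk is a single vectorised cumulative sum; its endpoint
is identically zero (asserted to 1e−12 in tests), and when two walk
positions tie in |D| to within 1e−9 the earliest position wins, which keeps
the vectorised implementation, a naive per-position reference and the
permutation null mutually consistent.

Significance uses a gene-set permutation null: B random sets of size |S|
(B = 1000 by default) drawn uniformly from the ranked genes. The p-value
follows the sign-conditional convention of weighted-GSEA tooling,
p = (1 + #{es_b ≥ es_obs}) / (1 + #{es_b ≥ 0}) for positive observed ES
and the mirror for negative: because resistant and sensitive calls are
sign-specific, each sign is judged against its own half of the null. This
estimator is bounded below by 1/(B+1), never zero, and approximately
uniform for signal-free sets (the package's calibration study measures the
fraction of null p below 0.05 at ≈ 0.05; a same-sign count over the full
B+1 denominator would instead concentrate half the mass of each sign's
tail and double that fraction). Calls are made after BH adjustment across
all (lncRNA, drug) pairs of a screen: resistant if ES > 0 and q < 0.05,
sensitive if ES < 0 and q < 0.05, otherwise ns.

A caveat worth knowing: with gene-set permutation, target sets of strongly
co-expressed genes (exactly what ceRNA sets are) have heavier-tailed null
ES than random sets, so occasional significant calls on signal-free drugs
are expected. Phenotype permutation with per-permutation re-ranking would
absorb that correlation at ~N-fold cost; the set-permutation null is the
default here, as it is in the preranked variant of GSEA tools.

## Survival

Patients split at the median of the lncRNA's log2 expression, strictly
above going high — the tie rule guarantees the median value itself lands
consistently in the low group. The two-group log-rank test and the
univariate Cox proportional-hazards fit (on the high/low indicator by
default, continuous expression optional) come from lifelines; the Cox fit
uses Efron's tie correction, which coincides with Breslow's on the
continuous simulated times where ties have probability zero. Groups
without any observed event, constant covariates, and diverging fits
(|β| > 20, the signature of perfect separation) raise errors instead of
returning unstable numbers. Panels of lncRNAs get BH q-values separately
for the log-rank and Cox p families.

## Sequence features

GC content excludes N bases from numerator and denominator. Normalized CpG
is the observed CpG dinucleotide frequency, #CG/(length − 1) (the number
of dinucleotide positions, making observed and expected commensurate
per-position frequencies), over the expected (GC/2)²; a GC-free or
sub-2-nt sequence raises a dedicated `UndefinedRatio` instead of returning
0 or infinity, and aggregations count excluded windows explicitly. Motif
counting is an IUPAC consensus scan (default DRACH = [AGT][AG]AC[ACT], U
read as T) counting all overlapping matches. TSS profiles slide a 200-nt
window at 100-nt steps across ±2 kb (all configurable), clip at sequence
bounds, and mirror offsets on the minus strand so positive offsets are
always downstream. Group comparisons use the equal-variance Student's t
test for counts and scores and the two-sample Kolmogorov–Smirnov test for
normalized CpG distributions. Whether the sequences fed in are transcript
bodies or promoter regions is the caller's choice of FASTA — both usages
are legitimate and the functions are agnostic.

## Pan-cancer classification

A lncRNA significant in at least `common_min_fraction` (default 1.0, i.e.
all) of the analysed cancers is cancer-common, in exactly one
cancer-specific, otherwise intermediate; the three labels partition the
lncRNAs with at least one record. Demanding literally every cohort is
fragile when only a handful of cancers are analysed, hence the
configurable fraction. Expression deviation defaults to the
between-cancer standard deviation of per-cancer mean log2 expression
(sample sd, n−1), with a pooled coefficient-of-variation alternative.
Tissue-elevation enrichment is the exact hypergeometric upper tail
P(X ≥ k) on the overlap between the cancer-specific set and a supplied
tissue-elevated set within a stated universe.

## Synthetic cohorts

The generator maps Gaussian latent variables to TPM via
TPM = 2^(5 + 1.5·z), so the log2(TPM+1) transform approximately recovers
latent correlations (the +1 distorts only the low tail). Planted
structure, all recorded in an exhaustive truth object:

- **Regulator-related lncRNAs** (`frac_related`, default 10%):
  z = ±ρ·z_reg + √(1−ρ²)·ε at ρ = 0.6, a 30% share negative — strong but
  realistic co-expression, comfortably above the 0.3 screen threshold at
  the default n = 500 so that recovery failures indicate bugs, not power.
- **Sponging triples**: for each of 4 triple-anchor lncRNAs, one miRNA m
  and 8 target mRNAs with loadings lncRNA = 0.4·z_reg − 0.6·m + 0.6·u + ε′,
  mRNA = −0.6·m + 0.6·u + ε″ (u a shared latent), giving population
  correlations −0.6 (both miRNA arms) and +0.72 (lncRNA–mRNA). The anchor
  lncRNAs carry a weaker regulator loading so they are m6A-related by
  construction, as ceRNA lncRNAs are in the motivating biology. Decoy
  catalog edges create candidate axes with no planted signal, so
  false-triple rates are measurable.
- **Drugs**: IC50 = effect·Σ expression over a triple lncRNA's target
  mRNAs + N(0, 2²) noise for signal drugs (positive weight =
  resistance-associated), pure noise otherwise.
- **Survival**: exponential times with hazard h₀·exp(β·1[x > median]),
  h₀ = 1/1000 per day and β = log 2 by default; censoring is independent
  Uniform(0, c) with the horizon c solved by root-finding so the expected
  censored fraction hits the requested value (default 0.3).
- **Sequences**: first-order composition model at the GC target, with the
  C→G transition multiplied by the CpG enrichment factor inside a core
  window (40% of the length, centred on the midpoint TSS) for m6A-related
  lncRNAs — yielding the CpG-island-like promoter peak — plus 30
  non-overlapping DRACH 5-mers spliced in per related sequence (enough to
  dominate the compositional shift in background motif frequency the CpG
  boost induces). Truth values are recomputed on the emitted string, so
  they are exact by definition.
- **Multi-cancer studies** re-plant the same related pairs and triples in
  every cohort with independent noise, plus optionally one disjoint block
  of cancer-specific related lncRNAs per cohort, making the
  common/specific classification testable end to end.

One master seed drives named child generators (expression, interactions,
drugs, survival, sequences), so any stage regenerates independently and
identical configs give byte-identical files.

What the simulator does *not* emulate: batch effects, count noise and
library-size variation, miRNA-family redundancy, correlated regulators
(each planted lncRNA tracks a single regulator, so "regulators per lncRNA"
statistics are trivial here), expression-stability differences between
common and specific lncRNAs (the deviation comparison is null on synthetic
data), dropout beyond simple zero-inflation, and any sequence homology.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the assumed statistical structure, not robustness to the
full messiness of tumor compendia.

## Study sizes

The shipped studies use cohorts of 300–500 samples, 60–1050 lncRNAs and
80–300 mRNAs, with 20-seed triple studies, 100-seed drug studies, 200
replicates for type-I-error calibration and 2000 draws (B = 200) for
permutation calibration — sizes at which the binomial noise on every
reported rate is well inside the asserted bands while a full run stays in
the tens of seconds.

## Known limitations

- Gene-set permutation (not phenotype permutation) for the ES null; see
  the caveat above.
- The Cox implementation is univariate by design; no covariate adjustment.
- Conservation scores are consumed as an optional input column, never
  computed (they require whole-genome alignments).
- The DRACH scan is a consensus count, not a trained site predictor; it
  counts motif occurrences, not predicted methylation sites.
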