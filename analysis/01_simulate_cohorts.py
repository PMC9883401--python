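"""Generate the three-cancer synthetic study and write all raw inputs.

Each cancer cohort shares the same planted structure (regulator-correlated
lncRNAs, sponging triples, drug-coupled target sets, one prognostic
lncRNA) with independent noise, mimicking a recurrent pan-cancer signal.
"""

import pandas as pd

from common import STUDY, load_study, outdir
from lncm6a import core_io, simulate


def main() -> None:
    data = outdir("data")
    cohorts = simulate.simulate_multi_cancer(STUDY)
    for cancer_id, (expr, cat, truth) in cohorts.items():
        core_io.write_expression_matrix(expr, data / f"expression_{cancer_id}.tsv")
        core_io.write_interactions(cat, data / f"interactions_{cancer_id}.tsv")
        print(
            f"{cancer_id}: {expr.n_genes} genes x {expr.n_samples} samples, "
            f"{len(truth.related_pairs)} planted regulator-lncRNA pairs, "
            f"{len(truth.true_triples)} planted ceRNA triples"
        )
    sequences, bed, seq_truth = simulate.simulate_sequences(STUDY)
    simulate.write_fasta(sequences, data / "lncrna.fa")
    bed.to_csv(data / "tss.bed", sep="\t", header=False, index=False)
    seq_truth.to_csv(data / "sequence_truth.tsv", sep="\t", index=False)
    print(
        f"sequences: {len(sequences)} lncRNAs of {STUDY.seq_length} nt, "
        f"{int(seq_truth['is_related'].sum())} with CpG/DRACH enrichment"
    )


if __name__ == "__main__":
    main()
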