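"""Score each lncRNA's ceRNA target set against drug IC50 rankings with
the weighted enrichment walk and permutation null, then check the
resistant/sensitive calls against the drugs' planted target lncRNAs."""

from common import STUDY, load_study, outdir
from lncm6a import candidate_axes, drug_screen, filter_triples, screen
from lncm6a.core_io import write_drug_response
from lncm6a.simulate import simulate_drug_response


def main() -> None:
    out = outdir("drug")
    for cancer_id, (logged, cat, truth) in load_study().items():
        drugs = simulate_drug_response(STUDY, logged, truth)
        write_drug_response(drugs, out / f"ic50_{cancer_id}.tsv")
        records = screen(logged, cancer_id=cancer_id)
        net = filter_triples(
            candidate_axes(cat, set(records["lncrna_id"])), logged,
            cancer_id=cancer_id,
        )
        results = drug_screen(logged, drugs, net.index, B=1000,
                              seed=STUDY.seed)
        results.to_csv(out / f"drug_associations_{cancer_id}.tsv", sep="\t",
                       index=False)
        called = results[results["call"] == "resistant"]
        recovered = sum(
            ((called["drug_id"] == d) & (called["lncrna_id"] == l)).any()
            for d, l in truth.drug_target_lncrna.items()
        )
        print(
            f"{cancer_id}: {len(results)} lncRNA-drug pairs scored, "
            f"{len(called)} resistant calls | planted associations "
            f"recovered {recovered}/{len(truth.drug_target_lncrna)}"
        )


if __name__ == "__main__":
    main()
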