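"""Build the m6A-mediated ceRNA network per cancer from the screened
lncRNAs and the interaction catalog, and audit recovery against the
planted sponging triples."""

from common import load_study, outdir
from lncm6a import candidate_axes, filter_triples, screen
from lncm6a.cerna import write_target_sets


def main() -> None:
    out = outdir("cerna")
    for cancer_id, (logged, cat, truth) in load_study().items():
        records = screen(logged, cancer_id=cancer_id)
        related = set(records["lncrna_id"])
        axes = candidate_axes(cat, related)
        net = filter_triples(axes, logged, cancer_id=cancer_id)
        net.triples.to_csv(out / f"cerna_triples_{cancer_id}.tsv", sep="\t",
                           index=False)
        write_target_sets(net, out / f"cerna_sets_{cancer_id}.gmt")
        got = set(zip(net.triples["lncrna_id"], net.triples["mirna_id"],
                      net.triples["mrna_id"]))
        tp = len(truth.true_triples & got)
        print(
            f"{cancer_id}: {len(axes)} candidate axes -> {len(got)} triples "
            f"over {len(net.index)} lncRNAs | planted recovered "
            f"{tp}/{len(truth.true_triples)}, false {len(got) - tp}"
        )


if __name__ == "__main__":
    main()
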