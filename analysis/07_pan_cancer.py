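"""Aggregate the per-cancer screens: classify lncRNAs as cancer-common /
specific / intermediate, compare expression deviation between the groups,
and test whether cancer-specific lncRNAs are enriched in a (synthetic)
tissue-elevated set."""

import numpy as np
import pandas as pd

from common import load_study, outdir
from lncm6a import (
    classify,
    compare_groups,
    expression_deviation,
    hypergeom_enrichment,
    screen,
)


def main() -> None:
    out = outdir("pan_cancer")
    study = load_study()
    cohorts = {c: logged for c, (logged, _, _) in study.items()}
    records = pd.concat(
        [screen(logged, cancer_id=c) for c, (logged, _, _) in study.items()],
        ignore_index=True,
    )
    table = classify(records, sorted(study))
    devs = []
    for lnc in table["lncrna_id"]:
        try:
            devs.append(expression_deviation(cohorts, lnc))
        except ValueError:
            devs.append(np.nan)
    table["expression_deviation"] = devs
    table.to_csv(out / "classification.tsv", sep="\t", index=False)
    counts = table["label"].value_counts().to_dict()
    print(f"classification: {counts}")

    common = table[table["label"] == "common"].dropna(
        subset=["expression_deviation"]
    )
    specific = table[table["label"] != "common"].dropna(
        subset=["expression_deviation"]
    )
    if len(common) >= 2 and len(specific) >= 2:
        res = compare_groups(
            common["expression_deviation"], specific["expression_deviation"],
            test="student_t", feature="expression_deviation",
        )
        print(
            f"expression deviation, common {common['expression_deviation'].mean():.3f} "
            f"vs non-common {specific['expression_deviation'].mean():.3f} "
            f"(t {res.statistic:.2f}, p {res.p:.2e})"
        )
        pd.DataFrame([vars(res)]).to_csv(
            out / "group_comparisons.tsv", sep="\t", index=False
        )

    # synthetic tissue-elevated set: the per-cancer planted specific
    # lncRNAs stand in for a tissue atlas annotation
    from lncm6a.simulate import specific_lncrna_ids
    from common import STUDY

    universe = set(study[sorted(study)[0]][0].genes_with_role("lncRNA"))
    te_set = {
        l
        for c in range(STUDY.n_cancers)
        for l in specific_lncrna_ids(STUDY, block=c)
    } & universe
    query = set(table.loc[table["label"] == "specific", "lncrna_id"])
    enr = hypergeom_enrichment(query & universe, te_set, universe)
    pd.DataFrame([vars(enr)]).to_csv(out / "enrichment.tsv", sep="\t",
                                     index=False)
    print(
        f"TE enrichment: overlap {enr.overlap} of query {enr.n_set_a} vs "
        f"TE {enr.n_set_b} in universe {enr.universe} "
        f"(hypergeometric p {enr.p:.3g})"
    )


if __name__ == "__main__":
    main()
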