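"""Screen each cancer cohort for m6A-related lncRNAs and summarize the
landscape: positive/negative correlation counts, per-regulator reach and
regulators-per-lncRNA, checked against the planted truth."""

import pandas as pd

from common import load_study, outdir
from lncm6a import screen, summarize


def main() -> None:
    out = outdir("screen")
    all_records = []
    for cancer_id, (logged, _, truth) in load_study().items():
        records = screen(logged, cancer_id=cancer_id)
        records.to_csv(out / f"m6a_related_{cancer_id}.tsv", sep="\t",
                       index=False)
        all_records.append(records)
        planted = {(l, r) for l, r, _ in truth.related_pairs}
        found = set(zip(records["lncrna_id"], records["regulator_id"]))
        tp = len(planted & found)
        print(
            f"{cancer_id}: {len(records)} significant pairs over "
            f"{records['lncrna_id'].nunique()} lncRNAs | sensitivity "
            f"{tp / len(planted):.2f}, false pairs {len(found) - tp}"
        )
    records = pd.concat(all_records, ignore_index=True)
    s = summarize(records)
    s.per_cancer.to_csv(out / "per_cancer_counts.tsv", sep="\t", index=False)
    s.per_regulator.to_csv(out / "per_regulator_counts.tsv", sep="\t",
                           index=False)
    s.per_lncrna.to_csv(out / "regulators_per_lncrna.tsv", sep="\t",
                        index=False)
    s.category_proportions.to_csv(out / "category_proportions.tsv", sep="\t",
                                  index=False)
    print(
        f"median regulators per lncRNA: {s.median_regulators_per_lncrna:.0f}; "
        f"category proportions: "
        + ", ".join(
            f"{r.category} {r.proportion:.2f}"
            for r in s.category_proportions.itertuples()
        )
    )


if __name__ == "__main__":
    main()
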