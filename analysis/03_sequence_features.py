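"""Profile lncRNA sequence features and compare m6A-related vs other
lncRNAs: GC, CpG count and DRACH motifs by Student's t, normalized CpG by
Kolmogorov-Smirnov, plus the TSS-window normalized-CpG profile."""

import pandas as pd

from common import STUDY, outdir
from lncm6a import compare_groups, feature_table, simulate_sequences, windowed_norm_cpg


def main() -> None:
    out = outdir("features")
    sequences, bed, truth = simulate_sequences(STUDY)
    feats = feature_table(sequences).merge(
        truth[["seq_id", "is_related"]], on="seq_id"
    )
    feats.to_csv(out / "seq_features.tsv", sep="\t", index=False)

    rows = []
    rel = feats[feats["is_related"]]
    oth = feats[~feats["is_related"]]
    for feature, test in (
        ("gc", "student_t"),
        ("cpg_count", "student_t"),
        ("drach_count", "student_t"),
        ("norm_cpg", "ks"),
    ):
        a = rel[feature].dropna()
        b = oth[feature].dropna()
        res = compare_groups(a, b, test=test, feature=feature)
        rows.append(vars(res))
        print(
            f"{feature}: related mean {a.mean():.3f} vs other {b.mean():.3f} "
            f"({res.test}, stat {res.statistic:.2f}, p {res.p:.2e})"
        )
    pd.DataFrame(rows).to_csv(out / "group_comparisons.tsv", sep="\t",
                              index=False)

    related_ids = set(truth.loc[truth["is_related"], "seq_id"])
    profiles = []
    for group, ids in (
        ("m6a_related", related_ids),
        ("other", set(sequences) - related_ids),
    ):
        prof = windowed_norm_cpg(
            sequences, bed[bed["chrom"].isin(ids)],
            flank=800, window=200, step=100,
        )
        prof.insert(0, "group", group)
        profiles.append(prof)
        peak = prof.loc[prof["mean_norm_cpg"].idxmax()]
        print(
            f"TSS profile [{group}]: peak mean norm CpG "
            f"{peak['mean_norm_cpg']:.2f} at offset {int(peak['offset'])} nt"
        )
    pd.concat(profiles).to_csv(out / "tss_profile.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
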