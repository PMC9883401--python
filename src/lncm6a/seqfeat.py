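"""Sequence-derived features of lncRNAs.

GC content, CpG dinucleotide counts, the observed/expected normalized CpG
ratio (expected = (GC/2)^2, the classic CpG-island statistic), DRACH-motif
consensus scanning, TSS-window CpG profiles and two-group feature
comparisons (Student's t or Kolmogorov-Smirnov).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats as sps

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


class UndefinedRatio(ValueError):
    """Normalized CpG is undefined (GC content zero or sequence too short)."""


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def gc_content(seq: str) -> float:
    """(#G + #C) / (length excluding N); errors on empty or all-N input."""
    s = _clean(seq)
    if not s:
        raise ValueError("empty sequence")
    counted = len(s) - s.count("N")
    if counted == 0:
        raise ValueError("all-N sequence has no defined GC content")
    return (s.count("G") + s.count("C")) / counted


def cpg_count(seq: str) -> int:
    return _clean(seq).count("CG")


def normalized_cpg(seq: str) -> float:
    """Observed CpG frequency over expected (GC/2)^2.

    Observed = #CG dinucleotides / (length - 1).  Raises
    :class:`UndefinedRatio` when GC content is zero (expected = 0) or the
    sequence is shorter than one dinucleotide.
    """
    s = _clean(seq)
    if len(s) < 2:
        raise UndefinedRatio("sequence shorter than 2 nt")
    gc = gc_content(s)
    if gc == 0:
        raise UndefinedRatio("GC content is zero; expected CpG is zero")
    observed = s.count("CG") / (len(s) - 1)
    expected = (gc / 2.0) ** 2
    return observed / expected


def motif_count(seq: str, pattern: str = "DRACH") -> int:
    """Count overlapping occurrences of an IUPAC consensus (U treated as T)."""
    s = _clean(seq)
    pat = _clean(pattern)
    if len(pat) > len(s):
        return 0
    try:
        regex = "".join(IUPAC[c] for c in pat)
    except KeyError as e:
        raise ValueError(f"unknown IUPAC code {e.args[0]!r}") from None
    return sum(1 for _ in re.finditer(f"(?={regex})", s))


def feature_table(
    sequences: Mapping[str, str],
    pattern: str = "DRACH",
    conservation: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sequence feature rows; norm_cpg is NaN where undefined."""
    rows = []
    for seq_id, seq in sequences.items():
        s = _clean(seq)
        try:
            ncpg = normalized_cpg(s)
        except UndefinedRatio:
            ncpg = np.nan
        rows.append(
            {
                "seq_id": seq_id,
                "length": len(s),
                "gc": gc_content(s),
                "cpg_count": cpg_count(s),
                "norm_cpg": ncpg,
                "drach_count": motif_count(s, pattern),
                "conservation": (
                    conservation.get(seq_id, np.nan) if conservation else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse BED (0-based, half-open); needs >= 3 columns, strand optional."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("BED needs at least chrom, start, end")
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    for col in ("start", "end"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as e:
            raise ValueError(f"malformed BED {col} column: {e}") from None
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy 0 <= start < end")
    if "name" not in df:
        df["name"] = [f"region{i}" for i in range(len(df))]
    if "strand" not in df:
        df["strand"] = "+"
    return df


def windowed_norm_cpg(
    sequences: Mapping[str, str],
    tss: pd.DataFrame,
    flank: int = 2000,
    window: int = 200,
    step: int = 100,
) -> pd.DataFrame:
    """Mean normalized CpG in sliding windows around each TSS.

    Offsets run from -flank to +flank in ``step`` increments; each window of
    ``window`` nt is centred on the offset, clipped at sequence bounds, and
    mirrored on the minus strand so positive offsets always point downstream.
    Windows with an undefined ratio are excluded from the mean but counted.
    """
    if flank < window:
        raise ValueError("flank must be at least one window wide")
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 nt and step >= 1 nt")
    offsets = np.arange(-flank, flank + 1, step)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=int)
    undefined = np.zeros(offsets.size, dtype=int)
    for row in tss.itertuples(index=False):
        seq = sequences.get(row.chrom)
        if seq is None:
            raise ValueError(f"TSS chrom {row.chrom!r} absent from sequences")
        strand = getattr(row, "strand", "+")
        pos = row.start if strand != "-" else row.end - 1
        for k, off in enumerate(offsets):
            center = pos + off if strand != "-" else pos - off
            lo = max(0, center - window // 2)
            hi = min(len(seq), center + window - window // 2)
            if hi - lo < 2:
                continue
            try:
                sums[k] += normalized_cpg(seq[lo:hi])
                counts[k] += 1
            except UndefinedRatio:
                undefined[k] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "offset": offsets,
            "mean_norm_cpg": mean,
            "n_windows": counts,
            "n_undefined": undefined,
        }
    )


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    test: str  # "student_t" or "ks"
    statistic: float
    p: float
    n_a: int
    n_b: int


def compare_groups(
    values_a, values_b, test: str = "student_t", feature: str = ""
) -> GroupComparison:
    """Two-sided equal-variance t test or two-sample KS between groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups contain non-finite values; drop them first")
    if test == "student_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t test needs at least 2 values per group")
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    elif test == "ks":
        if a.size < 1 or b.size < 1:
            raise ValueError("KS test needs at least 1 value per group")
        stat, p = sps.ks_2samp(a, b)
    else:
        raise ValueError("test must be 'student_t' or 'ks'")
    return GroupComparison(
        feature=feature, test=test, statistic=float(stat), p=float(p),
        n_a=a.size, n_b=b.size,
    )
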