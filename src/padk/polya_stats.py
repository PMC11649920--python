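"""Per-read poly(A) tail aggregation and statistics.

Input tables mirror nanopolish ``polya`` output after annotation: one row
per read with the estimated tail length, a QC tag, and condition/replicate
labels.  Only reads tagged ``PASS`` are used; per-transcript medians are
computed per replicate, a transcript is reported only with at least 20
reads in each of two replicates, and condition shifts are tested with a
paired Wilcoxon signed-rank test with continuity correction.  Tail-change
versus level-change relationships use the Pearson correlation with a
Fisher-z 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "qc_filter",
    "summarize_transcripts",
    "compare_conditions",
    "delta_correlation",
    "MIN_READS",
    "MIN_REPLICATES",
]

MIN_READS = 20
MIN_REPLICATES = 2

READ_COLUMNS = ("read_id", "transcript_id", "condition", "replicate",
                "polya_length", "qc_tag")


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in READ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"poly(A) read table missing columns: {missing}")
    if not np.isfinite(table["polya_length"].to_numpy(float)).all():
        raise ValueError("poly(A) lengths must be finite")


def qc_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Keep PASS reads only; returns (filtered table, per-tag counts)."""
    _validate(table)
    tag_counts = table["qc_tag"].value_counts()
    kept = table.loc[table["qc_tag"] == "PASS"].reset_index(drop=True)
    return kept, tag_counts


def summarize_transcripts(
    table: pd.DataFrame,
    min_reads: int = MIN_READS,
    min_replicates: int = MIN_REPLICATES,
) -> pd.DataFrame:
    """Per-transcript tail summaries with the replicate read threshold.

    Within each (transcript, condition): the tail median is computed per
    replicate; the transcript is retained only if at least ``min_replicates``
    replicates each have ≥ ``min_reads`` reads.  The reported
    ``median_tail`` is the mean of the qualifying replicates' medians (each
    replicate is one experiment; averaging their medians weights experiments
    equally).  ``pooled_median_tail`` pools qualifying replicates' reads.
    ``mean_log2_level`` is the replicate mean of log2 depth-normalized read
    counts (fraction of the replicate's reads assigned to the transcript).
    """
    _validate(table)
    # depth normalization is per sequencing library = (condition, replicate)
    lib_sizes = table.groupby(["condition", "replicate"])["read_id"].count()

    per_rep = (
        table.groupby(["transcript_id", "condition", "replicate"])["polya_length"]
        .agg(median_tail="median", n_reads="count")
        .reset_index()
    )
    per_rep["lib_size"] = per_rep.set_index(["condition", "replicate"]).index.map(
        lib_sizes
    )
    per_rep["log2_level"] = np.log2(per_rep["n_reads"] / per_rep["lib_size"])
    per_rep["qualifies"] = per_rep["n_reads"] >= min_reads

    rows = []
    for (tid, cond), grp in table.groupby(["transcript_id", "condition"], sort=True):
        reps = per_rep.loc[
            (per_rep["transcript_id"] == tid) & (per_rep["condition"] == cond)
        ]
        good = reps.loc[reps["qualifies"]]
        if len(good) < min_replicates:
            continue
        pooled = grp.loc[
            grp["replicate"].isin(good["replicate"]), "polya_length"
        ].median()
        rows.append(
            {
                "transcript_id": tid,
                "condition": cond,
                "median_tail": good["median_tail"].mean(),
                "pooled_median_tail": float(pooled),
                "n_replicates": len(good),
                "n_reads_total": int(good["n_reads"].sum()),
                "mean_log2_level": good["log2_level"].mean(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "condition", "median_tail", "pooled_median_tail",
            "n_replicates", "n_reads_total", "mean_log2_level",
        ],
    )


@dataclass
class ConditionComparison:
    """Paired comparison of per-transcript median tails."""

    n_transcripts: int
    n_zero_dropped: int
    median_a: float
    median_b: float
    q1_a: float
    q3_a: float
    q1_b: float
    q3_b: float
    median_shift: float
    statistic: float
    p_value: float


def compare_conditions(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame
) -> ConditionComparison:
    """Paired Wilcoxon signed-rank test on matched transcript median tails.

    Transcripts are matched by id (intersection of the two summaries).
    Zero differences are dropped (the standard signed-rank convention) and
    the normal approximation with continuity correction is used.  When every
    difference is zero the distributions are identical and p = 1.
    """
    merged = summary_a.merge(
        summary_b, on="transcript_id", suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("no transcripts shared between the two conditions")
    a = merged["median_tail_a"].to_numpy(float)
    b = merged["median_tail_b"].to_numpy(float)
    diffs = b - a
    nonzero = diffs != 0
    if nonzero.sum() == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic, p = stats.wilcoxon(
            b[nonzero], a[nonzero], zero_method="wilcox",
            correction=True, method="approx",
        )
    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return ConditionComparison(
        n_transcripts=len(merged),
        n_zero_dropped=int((~nonzero).sum()),
        median_a=float(qa[1]),
        median_b=float(qb[1]),
        q1_a=float(qa[0]),
        q3_a=float(qa[2]),
        q1_b=float(qb[0]),
        q3_b=float(qb[2]),
        median_shift=float(qb[1] - qa[1]),
        statistic=float(statistic),
        p_value=float(p),
    )


def delta_correlation(
    delta_tail: np.ndarray, delta_level: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pearson r between tail changes and level changes, with Fisher-z CI.

    The confidence interval is tanh(atanh(r) ± z/√(n−3)); it degenerates to
    the point r when |r| = 1 (atanh infinite — perfectly linear data).
    """
    x = np.asarray(delta_tail, dtype=float)
    y = np.asarray(delta_level, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matching 1-D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return r, (r, r)
    z = stats.norm.ppf(0.5 + level / 2.0)
    zr = math.atanh(r)
    half = z / math.sqrt(n - 3)
    return r, (math.tanh(zr - half), math.tanh(zr + half))
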