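"""RIP-seq enrichment from feature × sample count matrices.

Input is a counts table (features in rows, one column per sequencing
sample) plus a sample sheet declaring, for each sample, its condition
(purification target or input), replicate number, and whether it is an
input (total RNA) library.  The enrichment pipeline is:

1. drop features with fewer than 10 reads in any sample used;
2. divide each sample by its total read count (library-size fractions);
3. log2;
4. average replicates within each condition;
5. subtract the input condition from each purification;
6. center each feature by subtracting its median across purifications.

A per-replicate "raw" enrichment (IP log2 fraction − input log2 fraction,
no averaging or centering) is kept for comparison against RT-qPCR-style
measurements, and purification-level category contrasts use a Welch
two-sample t-test on the log2 enrichments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MIN_READS",
    "EnrichmentResult",
    "compute_enrichment",
    "raw_enrichment",
    "category_test",
]

MIN_READS = 10

SAMPLE_COLUMNS = ("sample", "condition", "replicate", "is_input")


def _check_samples(counts: pd.DataFrame, samples: pd.DataFrame) -> str:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    unknown = set(samples["sample"]) - set(counts.columns)
    if unknown:
        raise ValueError(f"samples absent from the count matrix: {sorted(unknown)}")
    if (counts[samples["sample"]].to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    input_conditions = samples.loc[samples["is_input"], "condition"].unique()
    if len(input_conditions) != 1:
        raise ValueError("exactly one input condition is required")
    return str(input_conditions[0])


@dataclass
class EnrichmentResult:
    """Centered log2 enrichments plus intermediates and an audit."""

    enrichment: pd.DataFrame          # feature × purification, median-centered
    uncentered: pd.DataFrame          # feature × purification, before step 6
    log2_means: pd.DataFrame          # feature × condition after steps 1-4
    n_features_in: int
    n_features_filtered: int

    def to_long(self) -> pd.DataFrame:
        long = self.enrichment.reset_index().melt(
            id_vars="feature_id",
            var_name="purification",
            value_name="log2_enrichment",
        )
        return long


def compute_enrichment(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_reads: int = MIN_READS,
) -> EnrichmentResult:
    """Run the six-step enrichment pipeline.

    ``counts`` must be indexed by feature id (or carry a ``feature_id``
    column).  A feature is kept only if it has at least ``min_reads`` reads
    in every sample of the sheet, which also guarantees log2 never sees a
    zero; no pseudocounts are needed.
    """
    counts = _indexed(counts)
    input_condition = _check_samples(counts, samples)

    used = counts[list(samples["sample"])]
    keep = (used >= min_reads).all(axis=1)
    filtered = used.loc[keep]

    fractions = filtered / filtered.sum(axis=0)
    log2 = np.log2(fractions)

    cond_of = dict(zip(samples["sample"], samples["condition"]))
    log2_means = log2.T.groupby(lambda s: cond_of[s]).mean().T

    purifications = [c for c in log2_means.columns if c != input_condition]
    uncentered = log2_means[purifications].sub(log2_means[input_condition], axis=0)

    if len(purifications) > 1:
        centered = uncentered.sub(uncentered.median(axis=1), axis=0)
    else:
        # median of a single value is itself: centering makes it all zero
        centered = uncentered - uncentered
    centered.index.name = uncentered.index.name = "feature_id"

    return EnrichmentResult(
        enrichment=centered,
        uncentered=uncentered,
        log2_means=log2_means,
        n_features_in=len(counts),
        n_features_filtered=int((~keep).sum()),
    )


def raw_enrichment(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate log2 fraction difference between IP and paired input.

    Replicates are paired by their replicate label.  Feature/replicate pairs
    with a zero count in either library are skipped (NaN) and counted in the
    ``n_skipped_zero`` attribute.
    """
    counts = _indexed(counts)
    input_condition = _check_samples(counts, samples)

    fractions = counts[list(samples["sample"])] / counts[list(samples["sample"])].sum(axis=0)
    inputs = samples.loc[samples["is_input"]].set_index("replicate")["sample"]

    records = []
    n_skipped = 0
    for _, row in samples.loc[~samples["is_input"]].iterrows():
        if row["replicate"] not in inputs.index:
            raise ValueError(f"no input sample paired with replicate {row['replicate']}")
        ip = fractions[row["sample"]]
        inp = fractions[inputs[row["replicate"]]]
        valid = (ip > 0) & (inp > 0)
        n_skipped += int((~valid).sum())
        value = pd.Series(np.nan, index=fractions.index)
        value[valid] = np.log2(ip[valid]) - np.log2(inp[valid])
        rec = value.rename("raw_log2_enrichment").reset_index()
        rec.insert(1, "purification", row["condition"])
        rec.insert(2, "replicate", row["replicate"])
        records.append(rec)
    out = pd.concat(records, ignore_index=True)
    out = out.rename(columns={out.columns[0]: "feature_id"})
    out.attrs["n_skipped_zero"] = n_skipped
    return out


def category_test(
    long_enrichment: pd.DataFrame,
    categories: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Welch t-test of log2 enrichment between two feature categories.

    ``categories`` maps feature_id → label.  One row per purification with
    group medians, quartiles, sizes, the Welch t statistic and its p-value.
    Degenerate groups (fewer than 2 features) get summaries but no test.
    """
    df = long_enrichment.copy()
    df["category"] = df["feature_id"].map(categories)
    rows = []
    for purification, grp in df.groupby("purification", sort=True):
        a = grp.loc[grp["category"] == group_a, "log2_enrichment"].dropna()
        b = grp.loc[grp["category"] == group_b, "log2_enrichment"].dropna()
        row: dict = {"purification": purification}
        for label, values in ((group_a, a), (group_b, b)):
            q1, med, q3 = (
                values.quantile([0.25, 0.5, 0.75]) if len(values) else (np.nan,) * 3
            )
            row.update(
                {
                    f"n_{label}": len(values),
                    f"median_{label}": med,
                    f"q1_{label}": q1,
                    f"q3_{label}": q3,
                }
            )
        if len(a) >= 2 and len(b) >= 2:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
            row.update(t_statistic=float(t_stat), p_value=float(p))
        else:
            row.update(t_statistic=np.nan, p_value=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _indexed(counts: pd.DataFrame) -> pd.DataFrame:
    if "feature_id" in counts.columns:
        counts = counts.set_index("feature_id")
    return counts
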