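"""SLAM-seq half-life pipeline.

Works on conversion tables with one row per (transcript, condition,
replicate, time point) holding a read count and a T→C conversion rate —
the structure of SLAM-DUNK "tcount" summaries after per-transcript
aggregation.  The pipeline is:

1. drop observations with fewer than 20 reads or conversion rate below 1e-4
   (a transcript run losing its t=0 observation is dropped entirely);
2. normalize each run's conversion rates to 1 at t=0;
3. fit A₀·exp(−k·t) per run, half-life = ln(2)/k, gate on pseudo-R² > 0.8;
4. compare conditions as Δlog2(half-life) against the mean log2 half-life of
   control runs.

No correction is applied for dilution of labeled molecules by growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decay_fit

__all__ = [
    "REQUIRED_COLUMNS",
    "FilterAudit",
    "filter_observations",
    "normalize_t0",
    "estimate_half_lives",
    "compare_conditions",
    "run_pipeline",
]

REQUIRED_COLUMNS = (
    "transcript_id",
    "condition",
    "replicate",
    "time_min",
    "read_count",
    "conversion_rate",
)

_GROUP = ["transcript_id", "condition", "replicate"]

MIN_READS = 20
MIN_CONVERSION = 1e-4
MIN_PSEUDO_R2 = 0.8


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"conversion table missing columns: {missing}")
    if (table["read_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    if ((table["conversion_rate"] < 0) | (table["conversion_rate"] > 1)).any():
        raise ValueError("conversion rates must be in [0, 1]")
    keys = _GROUP + ["time_min"]
    if table.duplicated(subset=keys).any():
        raise ValueError("duplicate (transcript, condition, replicate, time) rows")
    return table


@dataclass
class FilterAudit:
    """Bookkeeping of what the observation filters removed."""

    n_input: int = 0
    n_low_reads: int = 0
    n_low_conversion: int = 0
    n_dropped_with_group: int = 0  # surviving rows removed because t=0 was lost
    groups_lost_t0: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_low_reads
            - self.n_low_conversion
            - self.n_dropped_with_group
        )


def filter_observations(
    table: pd.DataFrame,
    min_reads: int = MIN_READS,
    min_conversion: float = MIN_CONVERSION,
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the read-count and conversion-rate observation filters.

    Filters act per observation (one sample × transcript row).  A run
    (transcript, condition, replicate) whose t=0 observation is removed can
    no longer be normalized and is excluded entirely; the audit lists those
    runs.
    """
    _validate(table)
    audit = FilterAudit(n_input=len(table))

    low_reads = table["read_count"] < min_reads
    low_conv = table["conversion_rate"] < min_conversion
    audit.n_low_reads = int(low_reads.sum())
    audit.n_low_conversion = int((low_conv & ~low_reads).sum())

    kept = table.loc[~(low_reads | low_conv)].copy()

    # runs whose t=0 row fell to a filter are removed wholly
    had_t0 = set(map(tuple, table.loc[table["time_min"] == 0, _GROUP].to_numpy()))
    has_t0 = set(map(tuple, kept.loc[kept["time_min"] == 0, _GROUP].to_numpy()))
    lost = had_t0 - has_t0
    if lost:
        audit.groups_lost_t0 = sorted(lost)
        mask = kept[_GROUP].apply(tuple, axis=1).isin(lost)
        audit.n_dropped_with_group = int(mask.sum())
        kept = kept.loc[~mask]

    return kept.reset_index(drop=True), audit


def normalize_t0(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize conversion rates to 1 at t=0 within each run.

    Returns a long table with a ``value`` column; runs without a usable t=0
    observation (missing, zero rate) or with fewer than 3 time points are
    excluded and flagged in the ``excluded`` attribute of the result
    (``result.attrs["excluded"]``).
    """
    _validate(table)
    out = []
    excluded: list[tuple] = []
    for key, grp in table.groupby(_GROUP, sort=True):
        t0 = grp.loc[grp["time_min"] == 0, "conversion_rate"]
        if len(t0) == 0 or float(t0.iloc[0]) <= 0 or grp["time_min"].nunique() < 3:
            excluded.append(key)
            continue
        g = grp.sort_values("time_min").copy()
        g["value"] = g["conversion_rate"] / float(t0.iloc[0])
        out.append(g)
    if not out:
        result = table.iloc[0:0].copy()
        result["value"] = []
    else:
        result = pd.concat(out, ignore_index=True)
    result.attrs["excluded"] = excluded
    return result


def estimate_half_lives(
    normalized: pd.DataFrame, min_pseudo_r2: float = MIN_PSEUDO_R2
) -> pd.DataFrame:
    """Per-run exponential fits with the pseudo-R² quality gate.

    Returns one row per (transcript, condition, replicate) with the fit
    fields and a ``status`` of ``ok``, ``filtered_r2`` or ``fit_failed``.
    """
    rows = []
    for (tid, cond, rep), grp in normalized.groupby(_GROUP, sort=True):
        g = grp.sort_values("time_min")
        row = {
            "transcript_id": tid,
            "condition": cond,
            "replicate": rep,
            "n_timepoints_used": g["time_min"].nunique(),
        }
        try:
            series = decay_fit.DecaySeries(
                g["time_min"].to_numpy(float), g["value"].to_numpy(float)
            )
            fit = decay_fit.fit_exponential(series)
        except ValueError as exc:
            fit = None
            row.update(status="fit_failed", message=str(exc))
        if fit is not None:
            if not fit.success:
                row.update(status="fit_failed", message=fit.message)
            else:
                row.update(
                    k=fit.k,
                    a0=fit.a0,
                    half_life=fit.half_life,
                    pseudo_r2=fit.pseudo_r2,
                    k_ci_low=fit.k_ci_low,
                    k_ci_high=fit.k_ci_high,
                    status="ok" if fit.pseudo_r2 > min_pseudo_r2 else "filtered_r2",
                    message="",
                )
        rows.append(row)
    cols = [
        "transcript_id", "condition", "replicate", "n_timepoints_used",
        "k", "a0", "half_life", "pseudo_r2", "k_ci_low", "k_ci_high",
        "status", "message",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


def compare_conditions(
    results: pd.DataFrame,
    control_runs: list[tuple],
    treatment_runs: list[tuple],
) -> pd.DataFrame:
    """Δlog2 half-life of treatment runs against the control baseline.

    ``control_runs`` and ``treatment_runs`` are (condition, replicate)
    pairs.  Per transcript the baseline is the mean of log2(half-life) over
    the control runs with ``ok`` status (typically four undepleted
    experiments); Δ = mean log2 half-life of ok treatment runs − baseline.
    Transcripts lacking an ok control or treatment run are skipped; the
    number of contributing controls is reported.
    """
    ok = results.loc[results["status"] == "ok"].copy()
    ok["run"] = list(zip(ok["condition"], ok["replicate"]))
    ctrl = ok.loc[ok["run"].isin(set(control_runs))]
    trt = ok.loc[ok["run"].isin(set(treatment_runs))]

    base = (
        ctrl.assign(log2_hl=np.log2(ctrl["half_life"]))
        .groupby("transcript_id")["log2_hl"]
        .agg(baseline_log2_hl="mean", n_controls="count")
    )
    test = (
        trt.assign(log2_hl=np.log2(trt["half_life"]))
        .groupby("transcript_id")["log2_hl"]
        .agg(treatment_log2_hl="mean", n_treatment="count")
    )
    merged = base.join(test, how="inner").reset_index()
    merged["delta_log2_half_life"] = (
        merged["treatment_log2_hl"] - merged["baseline_log2_hl"]
    )
    return merged


def run_pipeline(
    table: pd.DataFrame,
    min_reads: int = MIN_READS,
    min_conversion: float = MIN_CONVERSION,
    min_pseudo_r2: float = MIN_PSEUDO_R2,
) -> tuple[pd.DataFrame, FilterAudit]:
    """filter → normalize → fit, returning per-run results and the audit."""
    filtered, audit = filter_observations(table, min_reads, min_conversion)
    if filtered.empty:
        return estimate_half_lives(filtered.assign(value=[])), audit
    normalized = normalize_t0(filtered)
    return estimate_half_lives(normalized, min_pseudo_r2), audit
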