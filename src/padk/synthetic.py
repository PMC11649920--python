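"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes —
first-order decay with multiplicative lognormal noise for chase curves,
binomial sampling of T→C conversions for SLAM-seq tables, steady-state
species mixtures with truncated-normal tail lengths for per-read poly(A)
tables, and negative-binomial libraries for RIP-seq count matrices.  All
randomness flows through a single integer seed; fixed seed means
byte-identical output.

Deterministic mini-fixtures used by the filter-bookkeeping tests
(:func:`slam_filter_fixture`, :func:`polya_replicate_fixture`,
:func:`ripseq_toy_matrix`) live here too.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import kinetic_core
from .decay_fit import DecaySeries
from .kinetic_core import ModelSpec, TailProfile

__all__ = [
    "gen_chase",
    "gen_slam",
    "gen_polya_reads",
    "gen_ripseq",
    "slam_filter_fixture",
    "polya_replicate_fixture",
    "ripseq_toy_matrix",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def gen_chase(
    spec: ModelSpec,
    times,
    cv: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> DecaySeries:
    """Noisy normalized chase total from the analytic model solution.

    The chase starts at the model steady state; each sampled point is
    multiplied by lognormal noise with coefficient of variation ``cv`` and
    the series is renormalized to exactly 1 at t=0.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = _rng(seed)
    t = np.asarray(times, dtype=float)
    curve = kinetic_core.analytic_chase(spec, kinetic_core.steady_state(spec), t)
    values = curve.normalized_total() * _lognormal_factor(rng, cv, len(t))
    values = values / values[t == 0][0]
    return DecaySeries(t, values)


def gen_decay_series(
    k: float,
    lag: float,
    times,
    cv: float,
    seed: int | np.random.Generator = 0,
) -> DecaySeries:
    """Noisy single-exponential series with lag (reporter-style data)."""
    rng = _rng(seed)
    t = np.asarray(times, dtype=float)
    clean = np.exp(-k * np.clip(t - lag, 0.0, None))
    values = clean * _lognormal_factor(rng, cv, len(t))
    values = values / values[t == 0][0]
    return DecaySeries(t, values)


def gen_slam(
    true_half_lives: dict[str, float],
    times,
    depth: int = 100,
    r0: float = 0.05,
    positions_per_read: int = 25,
    condition: str = "control",
    replicate: int = 1,
    seed: int | np.random.Generator = 0,
    plant_low_count: bool = False,
    plant_low_conversion: bool = False,
) -> pd.DataFrame:
    """Conversion table with binomial sampling noise around exponential decay.

    Per transcript and time point: the true conversion rate is
    r₀·2^(−t/half-life); the observed rate is Binomial(N, rate)/N with
    N = read_count × positions_per_read convertible positions, and the read
    count itself is Poisson around ``depth``.  The defaults model a ~100 nt
    3'-end read at ~25% T content and a t=0 conversion rate of 5%, in the
    2–6% range reported for 4-thiouracil labeling in yeast.  Optional planted rows carry a
    19-read count or a 5e-5 conversion rate at the largest time point to
    exercise the observation filters (never at t=0, so only those rows are
    removed).
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    rng = _rng(seed)
    t = np.asarray(times, dtype=float)
    rows = []
    planted: list[dict] = []
    for tid in sorted(true_half_lives):
        hl = true_half_lives[tid]
        for ti in t:
            rate = r0 * 2.0 ** (-ti / hl)
            reads = max(int(rng.poisson(depth)), 20)
            n_pos = reads * positions_per_read
            observed = rng.binomial(n_pos, rate) / n_pos
            rows.append(
                {
                    "transcript_id": tid,
                    "condition": condition,
                    "replicate": replicate,
                    "time_min": ti,
                    "read_count": reads,
                    "conversion_rate": observed,
                }
            )
    t_last = float(t.max())
    if plant_low_count:
        planted.append(
            {
                "transcript_id": "planted_low_count",
                "condition": condition,
                "replicate": replicate,
                "time_min": t_last,
                "read_count": 19,
                "conversion_rate": r0,
            }
        )
    if plant_low_conversion:
        planted.append(
            {
                "transcript_id": "planted_low_conversion",
                "condition": condition,
                "replicate": replicate,
                "time_min": t_last,
                "read_count": depth,
                "conversion_rate": 5e-5,
            }
        )
    table = pd.DataFrame(rows + planted)
    table.attrs["planted_rows"] = len(planted)
    return table


def gen_polya_reads(
    specs: dict[str, ModelSpec] | ModelSpec,
    tails: TailProfile = TailProfile(),
    n_reads: int = 1000,
    tail_sd: tuple[float, float, float] = (5.0, 5.0, 3.0),
    pass_rate: float = 1.0,
    condition: str = "control",
    replicates: int = 2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-read poly(A) table sampled from steady-state species mixtures.

    For each transcript, reads are assigned to the long/medium/short species
    with the steady-state proportions of its kinetic model, then given a
    tail length from a Normal(L_species, sd_species) truncated at 0 (by
    resampling).  QC tags are ``PASS`` with probability ``pass_rate`` and
    ``SUFFCLIP`` otherwise.  Passing per-transcript models with different
    (ka, kd) creates stable and unstable transcript classes.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be at least 1")
    if not (0 < pass_rate <= 1):
        raise ValueError("pass_rate must be in (0, 1]")
    if isinstance(specs, ModelSpec):
        specs = {"tx_0": specs}
    rng = _rng(seed)
    lengths = tails.as_array()
    sds = np.asarray(tail_sd, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        for tid in sorted(specs):
            ss = kinetic_core.steady_state(specs[tid])
            probs = ss.as_array() / ss.total
            species = rng.choice(3, size=n_reads, p=probs)
            tail = rng.normal(lengths[species], sds[species])
            # truncate at zero by resampling the negative draws
            while np.any(tail < 0):
                bad = tail < 0
                tail[bad] = rng.normal(lengths[species[bad]], sds[species[bad]])
            tags = np.where(rng.random(n_reads) < pass_rate, "PASS", "SUFFCLIP")
            for i in range(n_reads):
                rows.append(
                    {
                        "read_id": f"{condition}_r{rep}_{tid}_{i}",
                        "transcript_id": tid,
                        "condition": condition,
                        "replicate": rep,
                        "polya_length": tail[i],
                        "qc_tag": tags[i],
                    }
                )
    return pd.DataFrame(rows)


def gen_ripseq(
    n_features: int = 200,
    enriched: set[int] | frozenset[int] = frozenset(),
    effect_log2: float = 1.0,
    depth: int = 200,
    dispersion: float = 0.05,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial RIP-seq counts with planted enrichment.

    Feature abundances are lognormal across features; IP abundances equal
    input × 2^effect for the ``enriched`` feature indices.  Three input and
    three IP replicates with unequal library sizes are produced.  Returns
    (counts, sample sheet, truth table).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = _rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_features)
    base = base / base.sum()
    effect = np.array(
        [effect_log2 if i in enriched else 0.0 for i in range(n_features)]
    )
    ip_abund = base * 2.0**effect
    ip_abund = ip_abund / ip_abund.sum()

    features = [f"feat_{i:04d}" for i in range(n_features)]
    counts = pd.DataFrame(index=pd.Index(features, name="feature_id"))
    sheet_rows = []
    for rep in range(1, n_replicates + 1):
        for cond, abund, is_input in (("input", base, True), ("IP", ip_abund, False)):
            lib = depth * n_features * rng.uniform(0.7, 1.3)
            mu = abund * lib
            if dispersion == 0:
                sample_counts = rng.poisson(mu)
            else:
                r = 1.0 / dispersion
                sample_counts = rng.negative_binomial(r, r / (r + mu))
            name = f"{cond}_rep{rep}"
            counts[name] = sample_counts
            sheet_rows.append(
                {
                    "sample": name,
                    "condition": cond,
                    "replicate": rep,
                    "is_input": is_input,
                }
            )
    samples = pd.DataFrame(sheet_rows)
    truth = pd.DataFrame(
        {"feature_id": features, "true_log2_effect": effect}
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# deterministic mini-fixtures for filter bookkeeping
# ---------------------------------------------------------------------------

def slam_filter_fixture() -> tuple[pd.DataFrame, int]:
    """Ten-observation conversion table with planted sub-threshold rows.

    Two transcripts with five time points each; transcript ``tx_a`` carries
    three rows with 19 reads and transcript ``tx_b`` one row with a 5e-5
    conversion rate, none of them at t=0.  Returns (table, expected number
    of retained observations) — 10 − 3 − 1 = 6.
    """
    rows = [
        # tx_a: 19-read observations at t = 10, 20, 30
        ("tx_a", 0, 150, 2.0e-2),
        ("tx_a", 5, 140, 1.4e-2),
        ("tx_a", 10, 19, 1.0e-2),
        ("tx_a", 20, 19, 5.0e-3),
        ("tx_a", 30, 19, 2.5e-3),
        # tx_b: low-conversion observation at t = 30
        ("tx_b", 0, 200, 1.0e-2),
        ("tx_b", 5, 210, 5.0e-3),
        ("tx_b", 10, 190, 2.5e-3),
        ("tx_b", 20, 180, 6.0e-4),
        ("tx_b", 30, 170, 5.0e-5),
    ]
    table = pd.DataFrame(
        rows, columns=["transcript_id", "time_min", "read_count", "conversion_rate"]
    )
    table.insert(1, "condition", "control")
    table.insert(2, "replicate", 1)
    return table, 6


def polya_replicate_fixture() -> tuple[pd.DataFrame, dict]:
    """Small per-read poly(A) table exercising QC and replicate thresholds.

    100 reads total, 80 of them PASS.  Among PASS reads: ``tx_keep`` has
    20 and 21 reads in the two replicates (retained); ``tx_drop`` has 20
    reads in replicate 1 but only 19 in replicate 2 (excluded by the
    ≥20-in-each-of-two-replicates rule).  Returns (table, expectations).
    """
    rows = []

    def add(tid: str, rep: int, n: int, tag: str, base_len: float) -> None:
        start = len(rows)
        for i in range(n):
            rows.append(
                {
                    "read_id": f"read_{start + i:03d}",
                    "transcript_id": tid,
                    "condition": "control",
                    "replicate": rep,
                    "polya_length": base_len + (i % 7),
                    "qc_tag": tag,
                }
            )

    add("tx_keep", 1, 20, "PASS", 40.0)
    add("tx_keep", 2, 21, "PASS", 42.0)
    add("tx_drop", 1, 20, "PASS", 30.0)
    add("tx_drop", 2, 19, "PASS", 31.0)   # one read short of the threshold
    add("tx_keep", 1, 12, "SUFFCLIP", 40.0)
    add("tx_drop", 2, 8, "ADAPTER", 30.0)
    table = pd.DataFrame(rows)
    expected = {
        "n_reads": 100,
        "n_pass": 80,
        "retained_transcripts": ["tx_keep"],
        "excluded_transcripts": ["tx_drop"],
    }
    return table, expected


def ripseq_toy_matrix() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Six-feature, six-sample count matrix with hand-checkable enrichments.

    Three input and three IP replicates; counts are exact multiples across
    replicates so the expected log2 enrichments can be computed by direct
    arithmetic in the tests.
    """
    counts = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(1, 7)],
            "input_rep1": [100, 200, 400, 100, 50, 150],
            "input_rep2": [200, 400, 800, 200, 100, 300],
            "input_rep3": [100, 200, 400, 100, 50, 150],
            "IP_rep1": [400, 200, 400, 100, 50, 150],
            "IP_rep2": [800, 400, 800, 200, 100, 300],
            "IP_rep3": [400, 200, 400, 100, 50, 150],
        }
    )
    samples = pd.DataFrame(
        {
            "sample": [
                "input_rep1", "input_rep2", "input_rep3",
                "IP_rep1", "IP_rep2", "IP_rep3",
            ],
            "condition": ["input"] * 3 + ["IP"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
            "is_input": [True, True, True, False, False, False],
        }
    )
    return counts, samples
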