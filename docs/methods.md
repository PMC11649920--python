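# Methods

## Kinetic models

Two mass-action models describe a homogeneous mRNA population split into
three poly(A)-tail classes, long (PA_l), medium (PA_m) and short (PA_s).
Production feeds PA_l at constant rate P (abundance·min⁻¹); deadenylation
converts long → medium → short at rate k_A (min⁻¹, pseudo-first-order).

Serial (deadenylation-dependent):

    dPA_l/dt = P − k_A·PA_l
    dPA_m/dt = k_A·PA_l − k_A·PA_m
    dPA_s/dt = k_A·PA_m − k_D·PA_s

Parallel (deadenylation-independent): identical, with an extra −k_D·PA_x
degradation term on each of the three species.

Assumptions worth stating: tail shortening is discretized into three
classes only (no per-nucleotide resolution); rates are time-invariant and
identical across molecules; production is constant (no transcriptional
feedback); chase experiments are modeled by setting P = 0 with the steady
state as initial condition. The steady states are `(P/k_A, P/k_A, P/k_D)`
(serial) and `(P/s, P·k_A/s², P·k_A²/(k_D·s²))` with `s = k_A + k_D`
(parallel). All tail averages and half-lives are invariant to P (asserted
in tests), so P = 1 is the fixed default.

In a chase both models are the same linear cascade: the long/medium block
decays at r (= k_A serial, k_A + k_D parallel) with transitions at k_A, and
the short species decays at k_D. The closed form mixes `e^(−rt)` and
`e^(−k_D t)`; when the two eigenvalues coincide (serial with k_A = k_D) the
implementation switches to the exact repeated-eigenvalue
polynomial×exponential form rather than perturbing a rate (relative
eigenvalue gap below 1e−9 triggers the switch). A stiff LSODA integration
(rtol 1e−9, atol 1e−12 by default) of the same ODEs serves as an
independent oracle; agreement is held to 1e−6 relative over ten half-decay
times, with the comparison floored at e^(−10) of the initial total because
totals below the window's decay bound are not meaningfully resolvable in
relative terms.

**Half-life estimators.** The primary estimator is the 50%-crossing time of
total RNA, found by Brent root search on the analytic total (bracket grown
geometrically from 2·(2/k_A + 1/k_D), tolerance 1e−9 min); it is unique
because the total is strictly decreasing. A second estimator fits a single
exponential to the sampled total, as bench chase data are processed; it is
window-dependent and deliberately reported alongside the crossing. For a
fast serial RNA the log-total is concave, so the fit comes out *below* the
crossing (5.4 → 4.7 min at k_A = 0.25, k_D = 0.5 on a 0–60-min grid); for
slow deadenylation on a short window it comes out above (115 → 124 min at
k_A = 0.01, k_D = 0.5). Integer half-lives quoted in the worked examples sit
between the two. The crossing for (k_A, k_D) = (0.25, 0.02) is
35.5735 min — verified against an independent symbolic solution — which
rounds to 36; the fit estimator gives 35.1 on any reasonable grid.

**Rate grid.** The default serial grid is k_A ∈ {0.25, 0.05, 0.01} and
k_D ∈ {0.5, 0.1, 0.02} min⁻¹: a geometric factor-5 grid around the
published intermediate values, spanning the 25-fold range over which the
steady-state mean tail runs 16–55 nt. Species tails default to 70/40/10 nt
(long/mid/short), the conventional arbitrary assignment; the serial
half-life is provably independent of them.

## Decay fitting

Series are normalized to 1 at t = 0. The models are `A₀·e^(−kt)` and the
lag form `A₀·e^(−k(t−l))`, with the value held at A₀ for t < l: the lag
represents the delay between the shut-off drug entering the cell and decay
actually starting, during which the level is taken as flat. l defaults to
1.2 min (the wild-type reporter estimate) and is applied uniformly across
conditions unless freed. Half-life is `ln2/k + l`. Fitting is unweighted
nonlinear least squares (trust-region reflective, non-negative bounds),
initialized from a log-linear regression; the reported fit therefore never
has a larger SSE than that initialization. Failures (non-convergence,
k ≤ 0, zero-variance input) are returned as flagged records, not raised,
so batch pipelines can audit them.

Confidence intervals on k invert the profile likelihood: with k fixed, A₀
is profiled out in closed form and the interval is the set where
`SSE(k) ≤ SSE_min·(1 + F₀.₉₅(1, n−p)/(n−p))` (profile-t construction),
with roots found by bracketed Brent search. If bracketing fails, a Wald
interval from the numerical curvature of the profile SSE is substituted
and the method is recorded on the fit. Numerically perfect fits
(SSE ≤ 1e−24) return a degenerate interval at k. Goodness of fit is the
pseudo-R² `1 − SSres/SStot`, which can be negative for bad fits; it is
undefined (error) for zero-variance series.

## SLAM-seq pipeline

Inputs are per-(transcript, condition, replicate, time) rows with a read
count and a T→C conversion rate. Observation filters: read count < 20, or
conversion rate < 1e−4 (applied to raw, pre-normalization rates). The
read filter is interpreted per observation because the table is
per-sample; a run is dropped wholly only when its t = 0 observation is
lost, since it can then no longer be normalized. Rates are normalized to
1 at t = 0, fitted per run with the plain exponential (no lag, and no
correction for growth dilution of the label), gated at pseudo-R² > 0.8 per
replicate, and half-life is `ln2/k`. Condition effects are
`Δlog2(half-life)` against the mean log2 half-life of the (typically four)
control runs; replicates are fitted separately and combined on the log2
scale. No per-transcript hypothesis tests or multiple-testing machinery
are attached: the quantity of interest is the Δlog2 table itself.

## RIP-seq enrichment

Pipeline order: (1) drop features with fewer than 10 reads — applied per
feature within *every* sample used, so a contrast never sees a zero and no
pseudocounts are needed; (2) divide by per-sample totals; (3) log2;
(4) average replicates within conditions; (5) subtract the input
condition; (6) subtract each feature's median across purification columns.
Step 6 makes enrichments comparable across purifications; with a single
purification it zeroes the table (median of one value), so single-IP
analyses should read the pre-centering values, which are also returned.
"Raw" per-replicate enrichments (log2 fraction IP − log2 fraction input,
paired by replicate label) are kept for comparison against qPCR-style
measurements; zero counts there skip the feature-replicate pair and are
counted. Category contrasts use Welch's unequal-variance t-test with
group medians and quartiles reported alongside.

## Poly(A) tail statistics

Only reads QC-tagged `PASS` are used (tag counts audited). A transcript is
reported per condition only with ≥ 20 reads in each of at least two
replicates — the conservative reading of a reads-in-replicates rule. The
transcript-level tail statistic is the mean of the qualifying replicates'
medians (each replicate is one experiment and gets equal weight); the
pooled-read median is computed alongside. Condition shifts use the paired
Wilcoxon signed-rank test on matched transcripts, normal approximation
with continuity correction, zero differences dropped (n adjusted and
reported); identical inputs short-circuit to p = 1. Tail-change vs
level-change association is the Pearson correlation with a Fisher-z 95%
interval (`tanh(atanh r ± 1.96/√(n−3))`), degenerate at |r| = 1. Levels
are log2 fractions of per-library read counts averaged over replicates.

## Synthetic data

The generators emulate the statistical structure each consumer assumes,
not the raw instruments:

* **Chase curves** — analytic model total × lognormal multiplicative noise
  with mean 1 and chosen CV (default 5–10%), renormalized at t = 0.
* **SLAM tables** — true conversion `r₀·2^(−t/hl)` observed through
  Binomial(N) sampling with N = reads × convertible positions; reads are
  Poisson around the nominal depth. Defaults r₀ = 0.05 and 25 positions
  per read model a ~100-nt 3′-end read at ~25% T with a t = 0 conversion
  rate in the 2–6% range reported for 4-thiouracil labeling in yeast.
  Optional planted rows (19 reads; 5e−5 conversion) exercise the filters.
* **Poly(A) reads** — species drawn from the steady-state proportions of a
  per-transcript kinetic model; tail ~ Normal(L_species, sd) truncated at
  0 by resampling (default sd 5/5/3 nt); QC tag PASS with a set
  probability. Depletions are emulated by scaling k_A or k_D.
* **RIP-seq counts** — lognormal feature abundances, planted 2^effect
  enrichment on a chosen feature set, negative-binomial sampling
  (dispersion 0.05) at unequal library sizes, three replicates each.

Noise families (lognormal for abundances, binomial for conversions,
negative binomial for counts, truncated normal for tails) are the minimal
standard choices matching each data type's support. What passing tests do
*not* show about real data: no alignment or conversion-calling artifacts,
no SNP masking, no transcript-length or 3′-bias effects, no basecalling
error structure in tail estimates, and no biological covariation between
level, tail and stability beyond what the kinetic model induces.

## Problem sizes and known limits

The simulation studies use 150–200 transcripts, 100–1000 reads or
100–500× depth, and 200-seed replications — sizes at which every
stochastic check (interval coverage, null-calibration KS, direction
tests) is stable while the whole suite stays fast.

Two limits are worth knowing. First, the rounded 50%-crossing at
(k_A, k_D) = (0.25, 0.02) is 36 min while the fit estimator gives 35; any
integer-rounded comparison of the two estimators can disagree by one
minute near a rounding boundary. Second, SLAM-seq half-life recovery at
depth 100 with a 30-min window is information-limited for slow
transcripts: the binomial delta-method bound puts sd(k)/k at ~10% for a
10-min half-life but ~31% at 60 min, so averaging two replicates still
leaves roughly 11% of quality-gated transcripts outside a 15% error band.
Longer chases or deeper sequencing, not better fitting, are what would
tighten the slow end.
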