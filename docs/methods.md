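# Methods

## The measurement problem

Two birds of a pair call repeatedly; each may answer the other within a
short window. Treating each bird's call onsets as a point process, the
package measures (i) whether answers occur above chance, (ii) how
*asymmetric* the answering relationship is, and (iii) how that asymmetry
relates to behaviour and develops over days. The female's calls define time
zero throughout; "answer" means a male call 0–0.5 s **after** a female
call, "answered" a male call 0–0.5 s **before** one.

## Exchange statistics

**Cross-correlogram.** For every focal call at time *t*, each partner onset
*u* with *u − t* ∈ [−2, 2) s increments the bin containing the lag; 100
bins of 40 ms, half-open [left, right) so a lag of exactly +2 s is
excluded and −2 s included. Lags are rounded to 10⁻⁹ s before binning so
that exact-width lags land on their nominal edge despite floating-point
cancellation. Counts are reported both raw and per focal call (density).

**Baseline and Poisson limits.** Lags in [−4, −2) ∪ (2, 4] s, binned at
the same width, estimate the uncoupled calling rate λ per bin. Under a
homogeneous Poisson null the upper confidence limit is the smallest integer
U with P(X ≤ U) ≥ 1 − α/2, the lower the α/2 quantile; a bin outside
[L, U] is significant at level α. α defaults to 0.05 with 0.01 routinely
reported as well (the appropriate level is a user decision; both are
computed because the discreteness of the Poisson quantile makes the
realised error rate slightly conservative). λ = 0 with nonzero observed
bins yields limits (0, 0) and a warning: exceedance is then trivially
significant.

**Answer counting.** The naive reading — count every partner call within
0.5 s on either side — double-counts a partner call that falls within the
window of two focal calls. By default each partner call is therefore
assigned to its **nearest** focal call only (ties to the earlier one; a lag
of exactly 0 counts as answered), which guarantees
n_answers + n_answered ≤ n_partner. The literal all-pairs count remains
available (`dedupe=False`); exact antisymmetry of the two roles holds in
that mode, and to Monte-Carlo accuracy in the default mode.

**Directionality index.** D = (answers − answered)/(answers + answered),
in [−1, 1]; 0/0 is reported as missing (NaN), never as 0, so silent
pair-days cannot masquerade as symmetric. Reports additionally carry
D × 100, the scale used in the source literature's figures. Antiphony is
flagged when at least one bin with center in (0, 0.5] exceeds the upper
limit; the peak latency is the center of the maximal such bin.

**Overlap.** The proportion of focal calls whose [onset, onset+duration)
interval intersects any partner call interval; computed by a sorted sweep
with a prefix-maximum of interval ends and verified against the quadratic
oracle in tests. Durations are required — overlap is undefined on onsets.

## Audio features

Calls are segmented where the RMS envelope (5 ms window) exceeds a dBFS
threshold; runs closer than `min_gap_s` merge, shorter than `min_dur_s`
drop. The ten per-call parameters use a 512-point Hann STFT with 75%
overlap (≈86 Hz × 2.9 ms hop at 44.1 kHz): amplitude-weighted spectral
centroid (mean frequency), arg-max bin (mode frequency) and the
lowest-frequency prominent local spectral maximum ("first peak", a
fundamental proxy — an interpretation, configurable via the prominence
floor), each averaged over frames with across-frame SDs; zero crossings
are reported as a rate so the feature is duration-free (the raw count is
kept). Frequency features of a constant signal are reported as 0 with a
`degenerate` flag.

Automatic sorting is a full-covariance Gaussian mixture on per-column
z-scored features with a fixed seed and k chosen by the user; segments
whose maximum posterior falls below 0.6 are labelled Unassigned. The hard
labels and posteriors are exported so a human can refine them in a label
file that re-enters the pipeline verbatim — replacing by-eye cluster
refinement with an auditable artifact. Partner-leak detections are removed
by amplitude: the backpack channel records its carrier at a characteristic
level, so detections more than `intensity_margin_db` (default 10 dB) below
the mode of the peak-amplitude distribution (1-dB bins) are dropped.

## Behaviour integration

Behaviour tracks are non-overlapping labelled intervals from a scored
window (default 3600 s: two 30-min sessions). The video clock maps onto the
audio clock by least squares through matched anchor events — one anchor
gives a pure offset, two or more also estimate drift; residuals above 0.5 s
warn. An event belongs to the interval whose half-open [start, stop) range
contains its onset; events in no scored interval are counted and excluded.
Per-state rates are events/duration, with zero-duration states missing
(never 0), so Σ rate × duration recovers the in-window event count
exactly. Calling rates enter the mixed models square-root transformed; the
stored quantity is always the raw rate.

## Inference

Models are fitted by maximum likelihood (not REML — the focus is
fixed-effect estimation and model comparison on a common likelihood).
A single un-nested random intercept uses the grouping-factor
parameterisation; crossed terms (day and pair) and nesting (pair within
experience) are variance components over one all-encompassing group.
Uncertainty is propagated by drawing fixed-effect parameter sets from
N(β̂, Côv(β̂)) — the asymptotic sampling distribution, which is the
approximate posterior under flat priors; variance components stay at their
ML estimates. 10 000 draws by default, seeded; a numerically non-PSD
covariance is repaired by clipping negative eigenvalues, with a warning.
Equal-tailed 95% credible intervals come from draw quantiles and converge
to Wald intervals (checked at 2×10⁵ draws in the tests).

**Derived p** for a contrast is the fraction of paired draws in which the
first group's estimate exceeds the second's; 0.05/0.95 play the role of a
two-tailed 5% threshold. **Repeatability** is the intraclass correlation
from one-way ANOVA variance components with the Lessells–Boag n₀ for
unequal group sizes; a negative among-group component is truncated to 0
and flagged. Its SE uses the standard large-sample approximation
Var(r) ≈ 2(1−r)²[1+(n₀−1)r]² / [n₀(n₀−1)(a−1)]. **Marginal/conditional
r²** are var(fixed predictor) over, respectively without and with the
random-intercept variances in the numerator, against the total
fixed + random + residual variance.

The packaged model set (`run_paper_models`) fits: clumping seconds and
|D|×100 each on experience × day (categorical, 4 levels) with a pair
intercept; √(stack rate) on relative position with crossed day and pair
intercepts; male on female stack totals and answer counts with day crossed
and pair nested in experience; and z-scored answer proportion on z-scored
clumping per sex, plus a rerun excluding zero-clumping days (singletons or
single-level factors degrade gracefully: the factor is dropped from the
formula and its contrasts skipped). Group contrasts are evaluated through
design rows at the relevant covariate combinations.

## Synthetic generator

Each bird calls as a homogeneous Poisson baseline; every baseline call of
bird *i* is independently answered by bird *j* with probability
`p_answer_j` at a latency drawn from Gamma(4, 0.05 s) truncated to
(0, 0.5] by inverse-CDF sampling (mode ≈ 0.15 s — any unimodal sub-half-
second latency serves the purpose; answer peaks in real exchanges sit in
this range). Answers do not themselves trigger answers by default, keeping
the closed-form count expectations exact (a chaining flag relaxes this).
Calls violating a 0.1 s refractory gap are dropped front-to-back, not
shifted. One master seed drives all sub-streams through
`numpy.random.SeedSequence` spawning. Call types are drawn i.i.d. from a
stack-dominated repertoire (stack 0.84, unassigned 0.026, remainder spread
over the other five types), and durations are type-typical constants.

Defaults are calibrated to the magnitudes reported for isolated
non-breeding zebra finch pairs: a baseline of 0.17 calls/s per bird
(≈476 000 vocalisations over 96 bird-days of 8 h) and `p_answer` 0.2,
which yields answer shares near the reported 15–18%. The generator makes
no attempt at song syntax, circadian rate variation, or acoustic realism
beyond distinguishable tonal templates; passing tests therefore certify
the measurement chain's arithmetic and statistical behaviour on processes
with the right first-order structure, not its performance on real
recordings (real calls overlap spectrally, amplitudes fluctuate, and
answer latencies need not be Gamma).

Behaviour tracks are semi-Markov (exponential dwells, uniform switching
among the other states); the cohort fixtures choose dwell parameters so
expected clumping time matches each scenario. Rendered audio places one
tonal template per call type at event onsets (own calls at unit gain,
partner leak attenuated, optional white noise) and peak-normalises only
when clipping would occur, preserving gain ratios.

### Cohort presets

`new_pair_convergence`: 8 new pairs whose answer-probability asymmetry
(±0.25 around a base of 0.3 on day 1) decays to ±0.02 by day 7, with
clumping growing from ≈29 s to ≈600 s, plus 4 established pairs symmetric
throughout with high clumping; the male's answer probability co-varies
with clumping. `established_pair`: the 4 symmetric pairs alone.
`uncoupled_null`: 12 pairs with p_answer = 0 and no group differences —
all downstream structure is chance.

## Problem sizes and numerical choices

Test and validation runs use scaled-down problem sizes chosen for tight
Monte-Carlo error at desk scale: coverage of the Poisson limits uses 500
uncoupled 8-h pair-days at the default rates (baseline λ ≈ 33 per bin,
where the discrete quantiles make the realised two-sided error ≈ 0.042 at
α = 0.05); parameter recovery uses a sparse-calling regime (0.015 calls/s
over 12 000 s, 10 replicates per grid point) because the closed-form index
expectation holds in the limit where chance coincidences
(base_rate × 0.5 s per call) are negligible next to the answer
probabilities; the null-inference sweep uses 100 cohorts of 1800 s
pair-days. Cohort fixtures default to 3600 s pair-days — one scored hour —
rather than full recording days, which changes count magnitudes but none
of the contrasts being tested.

Known limitations: feature SDs are across spectrogram frames (the only
axis available to a frame-wise definition); the "first peak" definition is
one defensible reading of a fundamental-proxy feature; the Poisson limits
assume a homogeneous baseline, so slow rate drift inflates exceedances;
MixedLM boundary fits (zero variance components) are flagged as singular
rather than refused, and their derived p's should be read with care.
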