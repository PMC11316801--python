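# Methods

`driftdecode` quantifies the day-to-day stability of task-variable
coding in longitudinally imaged cortical populations. This note
documents the models and procedures, the synthetic world used for
validation, the numerical choices, and what a passing test does and
does not establish.

## Task and trial structure

Trials of the two-context T-maze last 9 s at 10 Hz: 3 s from trial
start to the decision point, 3 s from decision to trial end, and a 3 s
post-trial (reward/timeout) period, modeled as contiguous 90-frame
blocks. The four non-aborted trial types are CL/IR/IL/CR
(correct-left, incorrect-right, incorrect-left, correct-right); CL and
IR belong to context 1, IL and CR to context 2, so the three binary
task partitions are

* context: {CL, IR} vs {IL, CR}
* motor choice: {CL, IL} vs {IR, CR}
* outcome: {CL, CR} vs {IR, IL}, evaluated separately before
  (post-decision) and after (post-trial) trial end.

Aborted trials (no choice within the decision window) are excluded by
every downstream operation.

## Preprocessing

Per neuron and session: `F_corrected(n) = F_soma(n) − α(F_neuropil(n)
− F̄_neuropil)`, with α ∈ [0, 1] minimizing the absolute Pearson
correlation between the corrected trace and the neuropil trace. The
objective is evaluated *exactly* on the full 0.001-resolution grid via
moment algebra (cov/var expansions), so the estimator and the
exhaustive grid search coincide by construction; an undefined
correlation (zero-variance corrected trace) counts as 0, and a
zero-variance neuropil trace returns α = 0 with a warning. ΔF/F(%) =
100(F − F₀)/F₀ with F₀ the mode of the corrected-fluorescence density:
Gaussian KDE, Silverman bandwidth, 512 grid points over the data range
(a histogram-mode alternative is available for sensitivity checks; the
bandwidth choice is ours — only "mode of the density" is dictated by
the procedure being reproduced). Each day is treated as one
concatenated trace; block-level registration is upstream of this
package. An optional precomputed deconvolved-spike channel is carried
through untouched.

## Inclusion gates

1. **Session behavior**: performance strictly above 0.5 and at least 2
   trials of each of the four types.
2. **Activity reliability**: Pearson correlation between odd- and
   even-trial mean timecourses (correct trials) must exceed the 95th
   percentile of 100 null iterations in which every trial's series is
   circularly shifted by an independent uniform offset in [1, bins−1].
   By construction this retains ~5% of exchangeable-null cells
   (measured 4.5–6% in simulation).
3. **ROI stability**: SSIM between the 30×30 µm windows on day 1 and
   day k (Gaussian window σ = 1.5, K₁ = 0.01, K₂ = 0.03, dynamic range
   from the pooled pair) must exceed the 95th percentile of ≥ 50 null
   SSIMs against random windows of the comparison day's field, sampled
   at least one window-width away from the true ROI (100 windows by
   default; count and exclusion zone are our choices). A 2-D
   correlation metric is provided as a switch and agrees with SSIM on
   clear cases.

For a (day 1, day k) comparison a cell must be reliable on both days,
ROI-stable for the pair, and both sessions must pass the behavioral
gate; the strict all-days intersection is also exposed.

## Trial-balanced response analyses

Balancing draws the minimum per-group trial count without replacement
(100 iterations). The preference test resamples the two classes with
replacement to the smaller class size and compares activity bin-by-bin
with a two-sided Wilcoxon signed-rank test, pairing resampled trials
within each iteration; iterations are combined by the **median**
p-value per bin, and a cell is called significant when p < 0.05 for at
least 5 consecutive 0.1-s bins. Rationale: pairing iteration *means*
across iterations is grossly anticonservative (resampling noise is far
smaller than the class-mean gap under the null), while the mean-p
combination is conservative (measured bin-level level 0.9%); the
median-p rule tracks the typical resample and holds the bin-level 5%
level (measured 4.5%). The 5-bin run rule then makes the cell-level
call conservative. The signed-rank p-values are computed vectorized,
with the exact no-tie null distribution for n ≤ 25 pairs and a
tie-corrected normal approximation beyond; zeros are rank-split.

Cross-day response stability is the Pearson correlation between
odd-trial means on day 1 and even-trial means on day k, concatenated
over the grouping's classes ("odd" = 0-based even indices, i.e. the
1st, 3rd, ... kept trials). Population-vector correlation matrices
resample cells to a fixed count and trials within condition (100
iterations); within day 1 the two vectors come from disjoint trial
halves. Latency sorting orders cells by the arg-max bin of the
odd-trial mean with ties broken by cell id.

## Decoding

Per-timebin binary linear SVMs (scikit-learn `SVC(kernel="linear",
C=1.0)`; C exposed in config; features are raw ΔF/F without scaling —
a documented choice, switchable upstream by the caller). Trials are
homogenized per bootstrap iteration: each type's trials are first
split into two disjoint halves, and each half is resampled with
replacement to the session's minimum per-type count, so train and test
never share an underlying trial and all types contribute equally.
Within-day testing uses the held-out half; cross-day testing uses
homogenized trials of the test day. Curves carry the mean and 5th/95th
percentiles over 100 iterations (25 in the pipeline's window-only
mode). A variable is significantly encoded when the lower 5th CI
exceeds 0.5 for ≥ 5 consecutive bins; outcome runs at bins up to the
trial-end bin are assigned to post-decision outcome and later runs to
post-trial outcome (a cell may receive both). Pseudo-populations pool
cells across experiments by sampling, independently per cell, one of
that cell's trials of the required type per pseudo-trial. Controls:
fixed-size random subsets, and smallest subsets reaching 90% day-1
window performance (doubling-then-bisection over nested random
subsets).

## Stability quantification

Decoding above chance is integrated over each variable's 1.5-s window
(context 1.5–3 s, motor and post-decision outcome 3–4.5 s, post-trial
outcome 6–7.5 s) by the trapezoid rule over bins sampling the window
inclusively at both ends, signed (dips below chance subtract; a
clip-at-zero switch exists). For every (day 1, day k) pair the day-1
reference area is computed from the *same* pair-selected cells as the
day-k test; normalizing a large day-1 population by a small selected
day-k set biases τ̂ low (observed: motor τ̂ 0.72 vs true 1.9 under the
naive contract).

Decay models, fitted by bounded nonlinear least squares (τ ∈ (0.05,
100], amplitude ∈ [0, 2] where free, multistart from τ ∈ {0.5, 2, 8,
32}, best SSE kept):

* `normalized`: NP = e^((1−day)/τ) — one parameter; NP(1) = 1 exactly
  and NP(1 + τ) = 1/e exactly.
* `perf_baseline`: P = P_day1·e^((1−day)/τ) + 0.5 — the 0.5 is the
  chance baseline of a binary decoder.
* `cc_decay`: CC = CC_day1·e^((1−day)/τ).

Fits are retained only if SSE ≤ 1.6 and R² > 0 (R² relative to the
mean-only model). The SSE cutoff is inherited from the procedure being
reproduced and is data-scale-dependent; on synthetic data it is kept
as the default but should be revisited for other scales. Fit
parameters are rankit-transformed (invnormal((rank − 0.5)/n), ties
averaged) before group comparisons with linear mixed-effects models:
response ~ group with random intercepts for mouse and experiment
(variance component), REML estimation, two-sided Wald tests per level
pair (with a single contrast, F = t²), p-values floored at 1e−5. A
singular experiment component is dropped with a flag.

## The synthetic world

The generator emulates: 10 Hz imaging; the 3+3+3 s trial; ~74% correct
behavior via an agent choosing the rewarded side with probability
`target_performance`, under the task program's anti-repeat ramp
(repeat probability falling 0.45 → 0 over 10 consecutive repeats) and
bias gate (one side exceeding double the other over a 10-trial window
forces the counter-context); 2% aborted trials. Tuned cells emit
transients — a boxcar on the variable's canonical window (context
0–6 s, motor and post-decision outcome 3–4.5 s, post-trial outcome
6–7.5 s) convolved with a 0.7-s single-exponential calcium kernel
(GCaMP6s-like) and peak-normalized — on trials of their preferred
class, with lognormal-free multiplicative trial gain (sd 0.3).
Amplitudes decay as e^((1−day)/τ_v); with probability `turnover_prob`
(default 0.1) per day a cell is re-assigned fresh tuning, emulating
turnover. Neuropil is a shared low-pass-filtered Gaussian field signal
(sd 0.08·baseline) added to soma with weight `neuropil_alpha_true`;
white per-frame noise has sd 15 ΔF/F%.

Default single-cell amplitudes are gamma-distributed (mean 8 ΔF/F%,
shape 6). These values were set by a signal-to-noise argument, not by
realism alone: per-bin single-cell d′ ≈ 0.5 lets cells clear the
reliability gate at realistic rates (~30–50%/day) while keeping the
QC-selected population's day-1 decoding near 0.8 — the near-linear
range of the performance-vs-amplitude map, which is the regime in
which NP decay mirrors the generator's amplitude decay. Saturated
decoding (day-1 performance near 1) provably flattens NP and inflates
τ̂; heavy-tailed (exponential) amplitudes reintroduce saturation
through the selected tail, which is why the gamma shape is moderate.

What the generator does **not** emulate: motion artifacts and
registration error, block seams within a day, spiking dynamics or
deconvolution, correlated noise beyond the shared neuropil, reward
licking artifacts, slow drift of baseline fluorescence. A green
recovery test therefore establishes that the pipeline's estimators are
consistent for data obeying the stated drift law at realistic SNR — it
does not certify behavior under imaging pathologies the world omits.

## Numerical and degenerate-input conventions

* α grid resolution 0.001; ties resolved to the smallest α.
* Constant traces: F₀ = the constant; reliability and preference on
  degenerate (zero-variance) inputs return "not significant" with a
  flag rather than raising.
* Undefined correlations (zero variance) propagate as NaN and exclude
  the cell from CC summaries, flagged.
* Window integration samples t₀..t₁ inclusive so a constant curve
  integrates to exactly width × height.
* Identical constant patches have SSIM 1 (zero dynamic range is
  special-cased).
* Pipeline stage seeds are spawned as `SeedSequence([master, stage])`;
  a fixed master seed makes the full run byte-deterministic.

## Known limitations

* LME comparisons on very few entities (e.g. 3 experiments) are
  reported but underpowered; the pipeline flags fallback fits.
* The per-experiment decoding in the default pipeline restricts bins
  to each variable's 1.5-s window (the only bins NP uses) with 25
  bootstrap iterations to keep end-to-end runs fast; full-trial curves
  with 100 iterations are available through `decode_across_days`
  directly.
* Single-cell encoding calls in the pipeline run on a capped subset of
  cells by default (`decoding.max_encoding_cells`) for the same
  reason.
* The SSE ≤ 1.6 fit filter presumes NP-scale residuals; rescaled
  responses need a rescaled threshold.
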