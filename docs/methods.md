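# Methods notes

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `pupiltrace`. Empirical claims below are the
ones the test suite and `scripts/acceptance.py` themselves compute.

## Data model and conventions

Missing pupil samples are NaN in memory and empty fields on disk; sample
indices are 0-based and every window is half-open `[start, end)`. Each
recording starts at 0 s and trial event times share that clock (only
relative timings matter to the analysis). Event times are snapped to the
nearest analysis-rate sample when epoching, bounding alignment jitter by
10 ms at 50 Hz; sub-sample interpolation of event offsets was deliberately
not implemented, as pupil responses evolve over hundreds of milliseconds.

Tabular I/O auto-detects tab vs comma from the header line and writes
floats with 10 significant digits, so reader/writer round-trips preserve
values to well beyond 6 significant digits and missingness exactly.

## Preprocessing

The cleaning chain is mask → interpolate → filter → decimate → trial
outlier removal, applied in exactly that order.

- **Gap interpolation** fills maximal missing runs *strictly* shorter than
  500 ms by linear interpolation between the flanking valid samples; runs of
  500 ms or longer, and runs touching either end of the recording (no
  anchor on one side), stay missing. Interpolation is idempotent.
- **Savitzky–Golay filter** (order 2, frame 501 samples): the frame is
  defined at the input rate, i.e. a 1.002 s window at 500 Hz, and the
  filter runs *before* decimation, acting as the low-pass stage. The filter
  never fits across a missing run: each contiguous valid segment is
  smoothed independently. Segments longer than the frame use the standard
  moving-window fit with edge samples evaluated from the polynomial of the
  nearest full window (`scipy.signal.savgol_filter(mode="interp")`, which
  avoids inventing data across blink boundaries); segments up to the frame
  length get a single whole-segment polynomial fit. Tests verify exact
  reproduction of constants and quadratics (an order-2 filter reproduces
  polynomials up to degree 2) and pointwise agreement with an explicit
  per-window least-squares oracle to 1e−9.
- **Decimation** keeps every 10th sample (500 → 50 Hz). Block averaging
  would double-smooth given the SG stage.
- **Trial outlier removal** works on the analysis-rate track over the
  window [fixation onset, stimulus onset + 5 s) — the maximal extent the
  epochs use. Samples deviating from the window mean of non-missing samples
  by more than 3 SD are replaced by linear interpolation between the
  nearest surviving neighbors inside the window (held constant beyond the
  outermost survivors). Windows with zero SD have no outliers by
  definition (the criterion is a strict inequality).
- **Cohort screening**: a participant whose pre-interpolation missing
  fraction exceeds the cohort mean by more than 3 cohort SDs is flagged;
  the rule is computed across the whole cohort, never per file.

## Epoching and averaging

Stimulus-aligned epochs are 400 samples over [−3, +5) s; response-aligned
epochs are 300 samples over [−3, +3) s with the keypress at index 150, and
may extend past stimulus offset (samples come from the continuous
recording; missing if it ended). For *both* alignments the baseline is the
mean over non-missing samples in [−0.5, 0) s before stimulus onset — never
the pre-keypress window — subtracted from every sample of the segment. An
epoch whose baseline window has under 50% usable samples is flagged
excluded rather than corrected (the 50% floor is this package's choice; the
excluded counts are logged). Trials are labelled from design cell ×
response (hit/miss per strength, correct rejection, false alarm; correct
recall per strength), and only correct-response labels enter the primary
averages. Averages are pointwise means over non-missing entries. A
participant needs ≥ 2 trials in each condition of a contrast to enter it;
the same floor is applied to secondary labels (misses, false alarms) for
symmetry, and dropped participants are reported.

## Cluster-based permutation inference

Pointwise statistic: Wilcoxon signed-rank on per-participant condition
differences, two-sided, every 20 ms. Conventions: zero differences are
discarded (Wilcoxon's original rule); tied magnitudes get midranks with the
variance tie-correction Σ(t³−t)/48; z = (W₊ − n(n+1)/4)/σ with no
continuity correction. Points are untestable (z = 0, p = 1, clusters break)
when fewer than 90% of participants have both curves non-missing there,
when fewer than 5 non-zero differences remain, or when the variance
degenerates — this prevents n from collapsing silently mid-cluster.

Inside the cluster pipeline the p value always comes from the normal
approximation: z is the currency of cluster mass, and the approximation is
what the field's standard toolkits use. An exact-enumeration path
(dynamic programming over the 2ⁿ sign assignments) exists for small
tie-free samples and is what small-sample reports should use; it matches
brute-force enumeration exactly and scipy's exact method to machine
precision. The two paths agree within 0.01 in p wherever p < 0.1 for
n ≥ 12; mid-distribution their gap is bounded by the lattice spacing of the
discrete W statistic (~0.04 at n = 12), which is irrelevant to cluster
formation at α = .05.

Clusters are maximal runs of consecutive pointwise-significant timepoints
with constant z sign, scored by summed z. The permutation scheme flips each
participant's condition assignment independently with probability 1/2 (the
standard exchangeability argument for paired designs; for paired curves a
label swap is a sign flip of the difference curve). Per permutation the
*maximum* |mass| is recorded (0 if no cluster forms) — the max-statistic
variant that controls family-wise error; pooling all permutation clusters
is not implemented. Significance: |mass| strictly above the empirical 95th
percentile (linear-interpolation quantile) of the null maxima; reported
p_perm uses the add-one estimator (1 + #{null ≥ |mass|})/(N + 1), so the
smallest attainable p with 500 permutations is 1/501 ≈ 0.002. Cluster
windows are reported in milliseconds relative to the alignment event with
half-open ends (a cluster reaching the last sample of the 5 s window ends
at 5000 ms).

A key implementation fact: because |differences| are invariant under sign
flips, the per-point ranks and null variances are computed once and every
permutation's z-series is a single matrix product over the signed ranks.
This makes the calibration studies below cheap and is tested against an
exhaustive enumeration of all flip patterns on a small design.

Permutation draws come from a counter-based Philox stream keyed by the
config seed, so null distributions reproduce bit-identically across runs
and platforms.

**Calibration.** The sign-flip test's validity rests only on the
exchangeability of each participant's paired curves under the null, so
family-wise error is calibrated at curve level, where many replicates are
feasible: across 200 null datasets (20 participants × 250 timepoints of
temporally smoothed noise, 200 permutations each) the any-significant-
cluster rate must fall inside the exact binomial 95% band around 0.05.
Power and localization are checked end-to-end instead (below).

## Behavioral tests

Per-participant condition summaries (accuracy, mean RT over correct
trials) are compared pairwise; Shapiro–Wilk on the differences at α = .05
selects a paired t-test (pass) or a Wilcoxon signed-rank test (fail),
reported with the positive-rank-sum V convention. Constant difference
vectors yield an explicit degenerate report.

## Synthetic study generator

The generator's defaults *are* the study conditions the analysis targets:

- Design: 3 s fixation + 5 s stimulus per trial; 30 weak / 15 strong
  targets (plus 45 foils in recognition); 1 s inter-trial interval and a
  fixed 2 s verbal-report period after successful recall trials (the real
  procedure's report period is open-ended; a fixed value keeps sessions
  reproducible).
- Behavioral calibration: correct-response probabilities 0.2911 / 0.5126
  (cued recall weak/strong) and 0.7214 / 0.8666 (recognition hits
  weak/strong), with 0.885 correct rejection of foils chosen as a realistic
  value. RTs are lognormal with medians at the condition means the
  accuracies pair with (2.37 / 2.07 s recall, 1.74 / 1.51 s hits, 1.84 s
  correct rejections; σ = 0.2) and are clipped to the 5 s response window.
- Pupil signal, per participant: baseline diameter ~ N(3.5, 0.3) mm; slow
  drift (random walk low-passed at 0.1 Hz, SD 0.1 mm) that baseline
  correction must absorb; white measurement noise SD 0.1 mm at 500 Hz; a
  lognormal participant gain (σ = 0.15) multiplying all evoked amplitudes.
- Evoked response: the Erlang-form pupil response function
  h(t) = (t/t_max)ⁿ·exp(n(1 − t/t_max)) with n = 10.1, t_max = 930 ms
  (standard pupillometry practice), convolved with a 5 s boxcar spanning the
  stimulus period and peak-normalized. The sustained input makes the
  response plateau through the late stimulus window, so condition amplitude
  gaps live over roughly 1–5 s post-onset — matching where retrieval-effort
  effects appear — rather than decaying by 2 s as a pure transient would.
  Setting `sustain_s: 0` recovers the pure kernel (peak exactly at
  onset + t_max), and an optional response-locked transient is available
  (off by default). Amplitudes: recall 0.45 / 0.30 mm (weak/strong — the
  retrieval-effort pattern, gap 0.15 mm), hits 0.40 mm in both strengths,
  correct rejections 0.25 mm, false alarms 0.40 mm (the old/new effect
  follows subjective oldness, not veridicality), misses 0.30 mm.
- Blinks: Poisson arrivals at 0.6 Hz with lognormal durations
  (median 0.15 s, σ = 0.6) — about 10% missing data overall, and a
  P(dur > 0.5 s) ≈ 6% tail that exercises the retained-gap path.

Everything derives from `(config, seed)` via spawned seed sequences; ground
truth (per-trial amplitudes, RTs, blink intervals, per-participant
baselines and gains) is emitted for recovery tests.

**What the generator does not emulate**: luminance effects and gaze-angle
foreshortening, biophysical iris dynamics, saccade/fixation structure,
non-stationary blink rates, serial dependence between trials, and any
latency shift of the evoked response with condition beyond what RT coupling
produces. Passing the recovery tests therefore shows the *pipeline* is
correct and calibrated under realistic noise, blinks and drift — not that
real recordings satisfy the generator's assumptions.

## Validation studies and problem sizes

- Exact Wilcoxon vs brute-force 2ⁿ enumeration: 200 random tie-free
  vectors, n ∈ [5, 10], exact equality.
- Type-I calibration: 200 curve-level null datasets, 20 participants,
  250 timepoints, 200 permutations; acceptance is the exact binomial 95%
  band around 0.05.
- Power/localization: 50 independently seeded full studies (500 Hz
  generation with blinks and drift, 40 participants, default 0.15 mm
  weak-vs-strong gap); a significant positive cluster overlapping
  [2, 5] s post-onset must appear in ≥ 90% of seeds. Observed rates sit at
  ceiling with the default noise levels.
- Amplitude recovery: with noise, drift, blinks and gain spread disabled,
  the grand-average peak must land within 20% of the injected amplitude.
- Behavioral calibration: rates pooled over 100 seeds must bracket the
  configured condition means within binomial sampling error.

These sizes were chosen as the smallest designs at which the binomial
acceptance bands are informative while keeping each study desk-scale.

## Known limitations

- The outlier rule uses the trial window's own mean/SD at 50 Hz; extremely
  short windows or pathologically bimodal trials could over-trigger it.
- The 90% pairwise-completeness rule for testable points is a hard
  threshold; gradual missingness near it can shorten clusters.
- `reproduce` assumes per-participant tabular text; binary vendor formats
  must be exported to text first, and published comparison values come from
  the user's config (`reference_values`), not from the package.
- With very small cohorts (n < 5 participants) no point is testable by
  design; the pipeline then reports no clusters rather than failing.
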