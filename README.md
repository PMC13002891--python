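# pupiltrace

Analysis pipeline for task-evoked pupillometry in memory-retrieval
experiments: preprocessing of raw pupil-diameter recordings, stimulus- and
response-aligned epoching with baseline correction, per-participant
condition averaging, and cluster-based permutation inference on the
pupil-dilation time course — plus a synthetic-data generator that emulates
a two-task (cued recall / recognition), two-strength (weak = one study
presentation, strong = two) paired-associate design, so the whole chain can
be exercised with no external data.

It is written for psychophysiology researchers who record pupil diameter
with a remote eye-tracker (500 Hz, millimeters) while participants retrieve
studied material, and who want a tested, reproducible path from raw samples
to "significant cluster from X to Y ms, p = .002".

## The method

**Preprocessing** (per participant, in order): samples the tracker flagged
as blinks or detection failures are masked; missing runs shorter than
500 ms are linearly interpolated (longer runs stay missing); the series is
low-pass filtered with a second-order Savitzky–Golay filter (frame 501
samples at 500 Hz); the data are decimated 500 → 50 Hz; finally, samples
deviating from their trial-window mean by more than 3 SD are replaced by
linear interpolation within the window.

**Epoching**: stimulus-aligned segments span −3 … +5 s around stimulus
onset (400 samples at 50 Hz; the 3 s fixation cross precedes the 5 s
stimulus), response-aligned segments span ±3 s around the keypress
(300 samples, keypress at sample 150). Both are baseline-corrected by
subtracting the mean pupil size over the final 500 ms of fixation,
[−0.5, 0) s relative to *stimulus* onset. Only correct trials enter the
per-participant condition averages, and a participant needs at least two
trials in every condition of a contrast to enter it.

**Inference**: at every 20 ms step of the analysis window (the 5 s after
onset for stimulus-aligned data; all 6 s for response-aligned data) the two
condition curves are compared across participants with a Wilcoxon
signed-rank test. Maximal runs of consecutive pointwise-significant
(p < .05) timepoints with a consistent sign form clusters scored by their
summed z ("cluster mass"). A null distribution of the maximum |mass| is
built from 500 permutations that randomly flip each participant's condition
assignment; an observed cluster is significant when its |mass| exceeds the
95th percentile of that null. Behavioral summaries (accuracy, RT) are
compared with a paired t-test or a Wilcoxon signed-rank test, chosen by a
Shapiro–Wilk normality check on the differences.

The Wilcoxon machinery is implemented in full (midranks, tie-corrected
variance, zero-discard, and an exact-enumeration path for small samples)
and is cross-checked against `scipy.stats.wilcoxon` and brute-force
2ⁿ enumeration in the test suite.

## Worked example

Write a config and run the synthetic demo:

```yaml
# demo_config.yaml
input_dir: demo_dataset
output_dir: demo_results
synth:
  n_participants: 12
  task: cued_recall
  seed: 7
perm:
  n_permutations: 500
  seed: 7
contrast:
  label_a: recall_weak
  label_b: recall_strong
  alignment: stimulus
```

```bash
pupiltrace simulate --config demo_config.yaml
pupiltrace run --config demo_config.yaml
pupiltrace plot --config demo_config.yaml
```

which prints

```
simulated 12 participants, 540 trials, task=cued_recall, seed=7 -> demo_dataset
Cluster permutation test: recall_weak vs recall_strong (stimulus-aligned, n=12, 500 permutations, seed=7)
  cluster 640 to 5000 ms, sign +, mass 664.36, p_perm = 0.002 [SIGNIFICANT]
```

Reading the output: recalling weakly encoded associates evoked a larger
pupil dilation than recalling strongly encoded ones, and the difference
forms one continuous cluster from 640 ms to the end of the stimulus window;
its mass (summed Wilcoxon z) exceeded every one of the 500 permutation
maxima, giving the smallest p the permutation scheme can produce,
(1 + 0)/(500 + 1) ≈ 0.002. The accompanying `behavioral_tests.json` shows
the generator's behavioral structure recovered from the simulated events
(mean recall rate 0.306 weak vs 0.506 strong; mean RT 2.43 s weak vs
2.16 s strong, paired t-test p < .001). `demo_results/` also contains the
per-participant quality reports, condition-average curves, the full cluster
JSON report, and the grand-average figure.

Applying the pipeline to your own recordings only requires two tabular text
files per participant (continuous samples: `time`, `diameter`, `valid`;
trial events: design cell, event times, response, correctness) — see
`pupiltrace reproduce --help` and the `column_mapping` config key for
adapting foreign column names.

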