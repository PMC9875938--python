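# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user should know before trusting or changing
the defaults.

## Task and behaviour generator

`TaskDesign` encodes the session structure: 720 trials, 70 % Go / 30 %
Nogo, 50 % congruent, 6 blocks of 120 with the four trial-type ×
congruency cells exactly balanced within every block.  Letter identity
("A" → left hand, "B" → right hand) is balanced within cells, and stimulus
side follows from congruency through the letter→hand map, which encodes
both Go congruency (stimulus side = responding-hand side) and Nogo
congruency (left-"A" / right-"B").  Designs whose cell counts are not
integral are rejected rather than rounded.

Go RTs are log-normal — right-skewed with positive support, the standard
minimal RT phenomenology — with group means 539.18 / 549.63 ms (congruent /
incongruent), SD 80 ms, truncated by the 1700 ms deadline (slower draws
become misses).  Nogo outcomes are Bernoulli false alarms at 6.1 %
(congruent) vs. 4.7 % (incongruent), putting expected Nogo accuracies at
93.9 % and 95.3 %; false-alarm RTs are drawn from the same log-normal
truncated at the deadline via its inverse CDF.  `sample_subject_behaviour`
adds between-subject heterogeneity — a common RT shift (SD 15 ms), a
per-subject congruency effect (SD 12 ms, floored at 0.5 ms so the
direction is preserved), and a mean-one log-normal multiplier on the
false-alarm rates (log-SD 0.4) — so that group-level paired effect sizes
are finite and of realistic magnitude rather than inflated by identical
subjects.

## EEG generator

Each trial is

x_i(t) = a_S · s_topo ⊗ s(t − τ_S) + a_C · c_topo ⊗ c(t − τ_C,i) + noise,

with unit-norm Gaussian-blob topographies (vertex-centred for S,
fronto-central for C), Gaussian-windowed half-cycle waveforms (S: centre
200 ms, width 150 ms; C: width 200 ms), and C latency
τ_C,i = 150 + 0.55·RT_i + N(0, 25 ms).  Nogo trials carry no response, so
their latencies use a pseudo-RT from the same log-normal family — the
total C-latency jitter SD is ≈ 50 ms either way.  Condition effects enter
as amplitude scale factors per congruency (default: C amplitude +15 % on
incongruent trials) and, optionally, a box-car topography difference inside
a configurable window for sensitivity analyses with a known effect window.

Noise is spatially correlated 1/f ("pink") noise — ten random smooth scalp
patterns driving independent 1/f-amplitude time series — plus white sensor
noise.  Defaults are a_S = 35 µV, a_C = 30 µV, pink SD 1.5 µV, white SD
1.0 µV per channel.  These place the single-trial matched-filter SNR in
the regime where iterative latency estimation is informative (an
oracle-template matcher reaches r ≳ 0.95 against the true latencies); at
substantially lower SNR even the oracle bound collapses and latency
recovery measures the noise floor, not the algorithm.  The generator
emulates the statistical structure the analysis relies on — two sources
with distinct latency behaviour, RT coupling, condition amplitude effects,
structured background — but not volume-conducted physiology, ocular or
muscle artifacts, alpha rhythms, or channel-specific drifts.  Passing
tests therefore certify the machinery, not performance on any particular
real recording.

## Preprocessing

Fixed order: band-pass → resample → artifact rejection → CSD → baseline.
The band-pass is a 4th-order Butterworth (0.5–40 Hz) applied
forward-backward (zero phase, as ERP timing analysis requires); the filter
order is a conventional default.  Resampling (500 → 256 Hz when the data
rate is higher than the target) is polyphase with anti-aliasing.  The time
axis is half-open — sample k at `times[0] + k/srate`, window end excluded —
which fixes all off-by-one questions (a 4 s epoch at 256 Hz has exactly
1024 samples).

Rejection drops trials with any sample beyond ±100 µV, or any channel
whose peak-to-peak activity within a sliding 100 ms window falls below
0.5 µV (dead-channel signature).  Thresholds are read in µV.  Against this
generator's modest noise floor the flatline detector has a small
false-positive rate (a few percent of trials); with real EEG backgrounds
it effectively never fires on healthy channels, and the thresholds are
parameters.

The CSD transform is the spherical-spline surface Laplacian (MNE
implementation) with stiffness m = 4, λ = 1e−5, 50 Legendre terms —
canonical surface-Laplacian defaults — on a 9.5 cm sphere; its output is
reference-free by construction.  Baseline correction subtracts the
−300–0 ms mean per trial and channel.

## RIDE

Only S- and C-clusters are estimated; one latency per trial (shared across
channels), waveforms channel-wise, medians throughout for robustness to
residual artifact trials.  Windows: S −200–600 ms, C 150–800 ms; the C
search window defaults to the C window; both cluster waveforms are tapered
by a Tukey window with 10 % cosine edges to avoid boundary discontinuities.

Three numerical choices matter at single-trial SNR and were validated
against ground truth during development:

* **Initialization.**  Latencies start from matching each raw trial
  against the trial-median waveform tapered to the *late half* of the C
  window.  The late window is past the stimulus-locked cluster's support,
  so this template is C-shaped; a full-window average template is
  dominated by S and pins every trial's match to a constant, and per-trial
  peak picking on the residual envelope is noise at realistic SNR.
* **Inner decomposition loop.**  Given latencies, the S/C median updates
  are alternated 10 times before latencies are re-estimated, letting the
  two clusters separate within their overlapping windows.  A single update
  leaves the C template contaminated by the residual of the S estimate and
  the iteration then drifts.
* **Smoothed scores and a shrinking trust region.**  The template-matching
  score is smoothed over candidate shifts (Gaussian, 30 ms) and each
  iteration's latency update is confined to a trust region around the
  current estimate that shrinks geometrically from 80 ms to 25 ms.  Both
  suppress a positive feedback loop in which individual trials jump to
  distant noise peaks and the template is rebuilt around those errors.

Convergence is a median absolute latency change ≤ 1 sample (after at
least 3 iterations), capped at 20 iterations.  Ties in template matching
break toward the smallest absolute shift.  An all-zero C template (e.g. a
pure-S dataset) returns a flagged, converged result with C ≡ 0.  With the
generator defaults (216 trials, 60 channels, ≈ 50 ms latency jitter),
recovered latencies correlate r ≈ 0.86–0.99 with truth across seeds and
the S waveform correlates ≥ 0.97 at its peak channel.  The S/C split of
*shared* stimulus-locked variance inside the overlap of the two windows is
only identified through latency variance and remains imperfect — a known
property of window-based decompositions, which is why recovery is scored
on latencies and waveform shape rather than exact amplitude attribution.

## Group ICA

All subjects share the montage, so group aggregation is channel-space
concatenation of every subject's (trials × time) samples followed by one
group PCA and FastICA (tanh contrast, deflation, up to 5 seeded restarts
with a symmetric-scheme fallback).  Per-subject retained variance under
the group PCA basis is checked against a threshold; the module default is
98 % with 20 components, the pipeline default relaxes the threshold to
90 % because the generator's white sensor noise is spectrally flatter than
real EEG (where 20 PCs retain 98 %).  Scale/sign indeterminacy is fixed by
storing unit-norm topographies with the maximal-|loading| channel positive
(the unmixing rows carry the compensating factors, so mixing·unmixing is
unchanged, equal to the projector onto the retained PCA subspace).
Back-reconstruction applies the group unmixing to one subject's data;
back-projection re-expands a single component to rank-1 channel data — the
decoding input, keeping all 60 channels as features.

## Topography matching

Components are compared by |Pearson r| across channels (sign-invariant,
since ICA polarity is arbitrary).  Every component of either decomposition
seeds a cluster of above-threshold matches from the other, capped at 3 per
condition; reported pairs are reciprocal best matches, deduplicated so a
component appears in at most one pair (largest |r| wins, then the lowest
index — the published pair tables are disjoint).  Specificity at the 0.85
threshold is extreme by construction: for 60-channel random topographies
P(|r| ≥ 0.85) is ≪ 10⁻⁶ per comparison, and 1000 replicate runs of 20 × 20
random components produce zero matches.

## Decoding and cluster statistics

Per subject and component pair, classes are balanced by random
undersampling, then a linear SVM (C = 1, the only sensible kernel choice
at 60 features and ≈ 100–200 trials) is trained per time point on
channel amplitudes z-scored with training-fold statistics, scored by AUC
from decision values on held-out folds of a 5-fold × 2 stratified CV, and
averaged over folds.  Temporal generalization evaluates each trained
hyperplane at every test time; its diagonal equals the time course exactly
because both come from the same folds.  AUC is computed by the
Mann–Whitney rank formula, vectorized over test times.

Group inference: per map point, a Wilcoxon signed-rank test of
(score − 0.5), one-sided above chance; cluster-forming at p < 0.05
(exact enumeration of the signed-rank null below 12 subjects, tie-corrected
normal approximation otherwise); cluster statistic = sum of signed-rank z;
null distribution = maximum cluster statistic under 1000 random
per-subject sign flips (ranks of |d| are flip-invariant, so the whole
permutation ensemble is computed with one matrix product); cluster
p = (1 + #{null ≥ observed})/(1 + n_perm).  Contiguity is 1-D adjacency
for time courses and 4-connectivity for generalization matrices.  Under
null scores the family-wise error rate is calibrated (measured ≈ 0.05 in
[0.03, 0.07] at α = 0.05 over 500 replicates).

## Source localization

The lead field is simulated: `three-sphere-approx` uses a monopole-style
1/distance potential kernel from sources in the upper unit half-ball to
scalp electrodes (smooth, with the depth bias of real gain matrices);
`random-smooth` draws Gaussian gains smoothed across sources by a spatial
kernel.  Both are average-referenced.  This stands in for a realistic
head model: anatomical claims are out of scope, the inverse machinery is
the object under test.

sLORETA: minimum-norm kernel T = Gᵀ(GGᵀ + αH)⁺ with H the average-reference
projector and α scaled by trace(GGᵀ)/n (default 1e−2, configurable), then
per-source standardization by the resolution-matrix diagonal,
power_j = (Tx)_j² / (TG)_jj.  Source orientations are fixed (scalar gain
per source), which keeps the standardization a scalar division and makes
the zero-localization-error property exactly testable: for every noiseless
single-source input the standardized power peaks at the true source, which
plain minimum norm fails for deep sources (verified exhaustively).  Power
is left untransformed (no log) by default.

The condition contrast is a paired t per source on (congruent −
incongruent) maps — time-window averages of standardized power over the
MVPA-significant window — corrected by the permutation distribution of the
maximum |t| under per-subject sign flips (2000 flips at study scale;
smaller where runtime matters, as the n_perm used is always reported).

## Behavioural statistics

Summaries per trial-type × congruency: mean/SE of correct-Go RT, Go
accuracy excluding misses (correct / responded), Nogo accuracy as the
correct-omission rate, false-alarm percentage.  The paired t reports
dz = mean(d)/SD(d) = t/√n, the convention consistent with the published
(t, n, d) triplets it is checked against.  The Wilcoxon signed-rank test
drops zero differences, enumerates all 2ⁿ sign assignments exactly for
n ≤ 12, and otherwise uses the tie-corrected normal approximation.

## Pipeline and problem sizes

`run_all` chains simulate → preprocess → RIDE (per condition) → group ICA
(per cluster × condition) → matching → per-pair MVPA → source contrast →
behaviour for the Nogo (primary) or Go arm, with every stage seeded
deterministically from one master seed; identical configurations produce
byte-identical JSON reports.  Default problem sizes — 8 subjects, epochs
−500–1200 ms at 250 Hz, decoding on a 4-fold-decimated grid, MVPA on the
2 strongest pairs per cluster, 1000 permutations — were chosen so a full
run completes in minutes on a single core; each knob scales up directly
(e.g. 40 subjects, −2000–2000 ms at 500 Hz, 2000 SnPM permutations) when
study-scale runs are wanted.  `scripts/acceptance.py` uses reduced sizes
of the same kind (500 calibration replicates, 1000 permutations, 40-point
time grids) and reports the n it used alongside every value.

## Known limitations

* The generator omits ocular/muscle artifacts and rhythmic background, so
  the rejection and CSD stages are exercised only against amplitude and
  flatline pathologies, and ICA never sees artifact components.
* S/C amplitude attribution inside the window overlap is only partially
  identified (see RIDE above).
* The C amplitude condition effect is spatially fixed; real
  congruency effects may move or reshape sources across conditions, which
  the topography-matching stage would then (correctly) fail to pair.
* The lead field is generic; localization results validate the estimator's
  properties, not anatomy.
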