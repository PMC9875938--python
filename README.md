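# ridemvpa

A concatenated EEG analysis pipeline for studying how response-selection
mode (automatic vs. controlled) shapes response inhibition in a hybrid
Simon Go/Nogo task — built as a tested, reusable re-implementation of the
full method chain, exercised end-to-end on simulated data with known ground
truth.

The chain decomposes epoched EEG **in time** before decomposing it **in
space**, then asks **when** condition information is present and **where**
it comes from:

1. **RIDE** (residue iteration decomposition) splits single-trial epochs
   into a stimulus-locked *S-cluster* and a latency-variable *C-cluster*.
   With per-trial C latencies τᵢ it alternates

   S = median_i [ xᵢ(t) − Ĉ(t − τᵢ) ],  C = median_i [ (xᵢ − Ŝ)(t + τᵢ) ],

   re-estimating each τᵢ by cross-covariance template matching inside a
   search window, until the latencies stabilize.  No response-locked
   R-cluster is estimated (responses are absent on Nogo trials).
2. **Group spatial ICA** (`C = WX`): subjects' single-trial cluster data are
   concatenated in channel space, reduced by PCA and unmixed with FastICA;
   subject activations are recovered by back-reconstruction, and any
   component can be back-projected to rank-1 channel data.
3. **Topography matching** pairs components across the congruent and
   incongruent decompositions by |Pearson r| of their scalp maps
   (threshold 0.85, at most 3 cluster members per condition, reciprocal
   best pairs).
4. **MVPA** decodes congruent vs. incongruent trials from the back-projected
   pair data: a linear SVM per time point (fivefold cross-validation, run
   twice, AUC scoring) plus temporal generalization (train at t, test at
   t′).  Group inference uses Wilcoxon signed-rank tests against chance
   (AUC = 0.5) with cluster-based sign-flip permutation correction, the
   cluster statistic being the summed signed-rank z.
5. **Source contrast**: sLORETA-standardized minimum-norm power on a
   simulated lead field, compared between conditions with a max-|t|
   sign-flip randomization test (SnPM).

A synthetic Simon Go/Nogo generator (720 trials, 70/30 Go/Nogo, 50/50
congruency, 6 blocks; log-normal RTs; an S source with fixed latency and a
C source whose latency is coupled to RT; 1/f + white noise on a 60-channel
montage) provides ground truth for every stage.

## Test

```bash
python -m pytest -q tests/
```

## Worked example

```python
import numpy as np
import ridemvpa as rm

# one subject's Nogo session with ground truth
design = rm.TaskDesign(n_trials=216, go_proportion=0.0, n_blocks=6)
trials = rm.generate_trial_table(design, seed=0)
trials = rm.simulate_behaviour(trials, seed=1)
params = rm.TruthParams(srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0))
epochs, truth = rm.simulate_epochs(trials, params, seed=2)

result = rm.ride_decompose(epochs, rm.RideConfig())
true_idx = np.searchsorted(epochs.times_ms, truth.c_latency_ms)
r = np.corrcoef(result.c_latency_samples, true_idx)[0, 1]
print(f"converged after {result.n_iterations} iterations; latency r = {r:.3f}")
```

prints

```
converged after 3 iterations; latency r = 0.981
```

i.e. the decomposition stabilized in three latency iterations and the
estimated single-trial C latencies correlate r = 0.98 with the simulated
ones (their jitter SD is ≈ 50 ms).  The full multi-subject chain is one
call — `rm.run_all(rm.PipelineConfig(n_subjects=8, base_seed=0))` — or, from
a shell, `ridemvpa run-all --seed 0 --subjects 8 --out report.json`.

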