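# fearscope

Analysis pipeline for one-photon Miniscope calcium imaging recorded during
restraint stress (IMO), auditory fear conditioning (FC) and fear extinction
(FE) in mice. The package consumes already-deconvolved fluorescence traces
(neurons × frames at 30 fps), behavioral video of the restrained animal, and
1 Hz freezing traces, and provides the bespoke analysis stages that sit
between source extraction and group statistics:

- **ΔF/F0 normalization** with a median baseline: `ΔF/F0 = (F − F0)/F0`,
  `F0 = median(F)` over the complete session trace — the median because
  sparse, large calcium transients make the mean a poor baseline.
- **Calcium events** as local maxima of the normalized trace, with
  epoch-wise frequency (events/s) and amplitude (peak ΔF/F0) summaries.
- **Video movement scoring**: per-frame Sobel edge masks (thresholded at a
  fudge factor × an automatic canny-style high threshold); the score for
  frame *n* is `|edges(n) \ edges(n−1)| / |edges(n)|`. Scores are shifted to
  median 0, scaled by the central 95% interpercentile range, fitted with a
  two-component Gaussian mixture, and frames above the density intersection
  are classified high movement; bout percentage, mean length and frequency
  summarize each epoch.
- **Tone responsiveness** per neuron via the phi coefficient φ of the 2×2
  contingency of event × tone frames, a 1000-shuffle null (event count
  preserved), the Z distance `(φ_obs − mean(R))/sd(R)` from the null matrix
  R, and excited/inhibited labels where φ_obs leaves the null's central 95%
  interval.
- **Correlation classes**: per-neuron Pearson r against movement (frame
  rate) or freezing (1 Hz, traces averaged within each second); positive if
  p < 0.05 and r > 0, negative if p < 0.05 and r < 0, else uncorrelated.
- **Group statistics**: Shapiro–Wilk and Levene checks, recurrent two-sided
  Grubbs outlier removal, mixed-design repeated-measures ANOVA (one between-
  and one within-subjects factor, Mauchly sphericity reported), and Tukey
  HSD multiple comparisons.

Because in-vivo recordings of this kind are rarely shareable, the package
ships a first-class synthetic-data module that generates schedules, traces,
restraint video and freezing series with known ground truth (neuron classes,
spike frames, hidden movement states), so every stage can be validated by
parameter recovery.

## Worked example

```python
import numpy as np
import fearscope as fs

schedule = fs.make_fc_schedule()          # 1350 s: hab + 5 tones/shocks + tail
coupling = fs.CouplingSpec.from_fractions(
    100, {"excited": 0.2, "inhibited": 0.1, "null": 0.7})
traces, truth = fs.simulate_traces(schedule, 100, coupling=coupling, seed=11)

raster = fs.detect_events(fs.normalize_dff(traces))
result = fs.tone_responsiveness(raster, schedule.tone_mask(),
                                n_shuffles=1000, seed=12)
labels = np.array(result.labels)
print((labels == "excited").sum(), (labels == "inhibited").sum())
```

This prints `20 14`: of 100 simulated neurons (20 truly tone-excited, 10
truly tone-inhibited), the phi permutation test recovers all 20 excited
neurons and calls 14 inhibited — the per-class error stays within a few
neurons of the ground truth. Each neuron's `result.z` is its Z distance from
the shuffle null; for a recovered excited neuron it is on the order of 20.

More narrative walk-throughs live in `examples/` (schedules and synthetic
sessions, movement scoring, event/phi analysis, correlation classes, group
statistics); each prints the numbers it computes and what they mean. A thin
CLI mirrors the stages: `fearscope simulate|movement|events|phi|correlate|
stats|run`.

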