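# Methods

This note documents the models, defaults and numerical choices behind
fearscope, and what the synthetic tests do and do not establish about real
recordings.

## Session model

Sessions are laid out in 0-based frames with half-open `[start, end)`
intervals at a fixed frame rate (default 30 fps, the Miniscope acquisition
rate). The conditioning (FC) protocol is 300 s habituation, five 30 s tones
each co-terminated by a 1 s footshock, 180 s inter-trial intervals and a
180 s tail (1350 s in total); extinction (FE) is 300 s habituation, fifteen
unshocked 30 s tones at 30 s intervals and a 30 s tail (1200 s). The
restraint (IMO) fixture holds the two recorded epochs — the first and last
10 minutes of the two-hour restraint — back to back, since the unrecorded
middle carries no data. Freezing is sampled at 1 Hz as a percent-immobility
value per second and binarized downstream (default threshold 50%), mirroring
the granularity mismatch the pipeline must handle between 30 fps traces and
1 Hz behavior.

## Trace processing

ΔF/F0 uses the median of the complete session trace as F0, per neuron. A
zero median raises an explicit error naming the neuron rather than emitting
infinities. Events are local maxima of the normalized trace; plateau maxima
are assigned to the first frame of the plateau (deterministic tie-break).
The event threshold is peak prominence ≥ 2× the per-neuron median absolute
deviation of the ΔF/F0 trace — scale-free and robust; no fixed amplitude
cut-off is assumed. Event amplitude is the peak ΔF/F0 value itself, not
peak-minus-trough. Epoch statistics use half-open frame intervals; an event
belongs to the epoch containing its peak, neurons without events contribute
frequency 0 and are excluded from amplitude means.

## Movement scoring

Frames are converted to grayscale (standard luminance weights for RGB) and
reduced to binary edge masks: Sobel gradient magnitude above `fudge` (0.5) ×
an automatic high threshold. The automatic threshold is the 70th percentile
of the frame's nonzero gradient magnitudes — the conventional canny-style
choice of retaining the strongest 30% — and both the percentile and the
fudge factor are configurable, since different cameras and scenes warrant
different operating points. The movement score for frame *n* is the count of
edge pixels present at *n* but not at *n−1*, divided by the edge count at
*n*; an edge-free frame scores 0 (no motion evidence). There is no score for
the first frame, so a session of N frames yields N−1 scores.

Normalization reads the "95% confidence interval" scale as the central 95%
interpercentile range (q97.5 − q2.5) of the empirical score distribution —
the only scale-free reading that needs no distributional assumption — after
shifting the median to 0. No smoothing is applied to raw scores.

The high-movement classifier fits a two-component univariate Gaussian
mixture by EM (scikit-learn, k-means initialization with a fixed seed,
tolerance 1e-6, up to 500 iterations; non-convergence raises an error
carrying the final lower bound and iteration count). The threshold is the
root of `w1·N(x|μ1,σ1) = w2·N(x|μ2,σ2)` between the ordered means, solved
from the quadratic in x given by the log-density equality; with equal
variances the equation is linear, and with equal weights too the root is
exactly the midpoint of the means. If no root lies strictly between the
means (nested components), the midpoint is used and flagged. High-movement
bouts are maximal runs of frames above the threshold; percent of frames,
mean bout length (s) and bout frequency (per s) summarize an epoch.

## Tone responsiveness

The phi coefficient is computed from the 2×2 contingency of the Boolean
event and tone vectors, with TP = event during tone and FN = tone frame
without an event. Degenerate margins (no events at all) return φ = 0 with a
flag. The null randomizes each neuron's event vector 1000 times preserving
the event count. A key identity makes this exact and fast: under a uniform
permutation of a binary vector, both margins of the table are fixed, so the
TP cell is Hypergeometric(N, n_tone, k) and φ is a deterministic function of
TP — the default null draws TP directly from that distribution, which is the
same distribution the literal permutation produces (a goodness-of-fit test
in the suite verifies this). A literal-permutation method and a circular-
shift method are also available; circular shifting preserves within-event
autocorrelation and is the conservative choice for multi-frame transients,
but plain randomization remains the default. The Z distance is
`(φ_obs − mean(null))/sd(null)`; labels use the null's empirical central 95%
interval by default (excited above, inhibited below), with an equivalent
|Z| ≥ 1.96 rule exposed. No multiple-testing correction is applied across
neurons — the labels are per-neuron descriptive calls.

Per-tone-block classification restricts the stimulus vector to the block's
tones plus, for each tone, an equal-duration off-tone window immediately
after tone offset (clipped at the next tone). This keeps the stimulus
marginals comparable across blocks; the off-tone reference window is
otherwise underdetermined.

## Correlation classes

Neurons are correlated with movement (1:1 at the frame rate, traces offset
by one frame to pair with transition scores) or freezing (ΔF/F0 averaged
within each behavior second — averaging the faster series is the
information-preserving direction, unlike interpolating the slower one).
Labels follow the fixed rule: positive (p < 0.05, r > 0), negative
(p < 0.05, r < 0), uncorrelated otherwise; constant traces are flagged and
counted uncorrelated. The scatter binning sometimes used to display these
relationships is presentation-only and deliberately absent from the
statistics path.

## Group statistics

The recurrent Grubbs test repeatedly removes the single most extreme value
while `G = max|x−x̄|/s` exceeds the two-sided critical value
`((n−1)/√n)·√(t²/(n−2+t²))` with `t = t_{α/(2n), n−2}`, at α = 0.05 by
default (configurable; no convention is universal). The mixed-design ANOVA
(one between-, one within-subjects factor) is computed by the standard
sums-of-squares decomposition via pingouin; a hand-worked decomposition on a
2×2 fixture serves as the test oracle. Subjects missing a within level are
dropped with a warning so the design stays complete. Mauchly sphericity is
reported for within factors with more than two levels but no epsilon
correction is applied by default (a corrected p is available from the
underlying fit). Tukey HSD uses the studentized-range distribution
(scipy; Tukey–Kramer for unequal n) and reports the unadjusted pooled-
variance pairwise p alongside — the adjusted p can never be smaller.

## Synthetic data: what it emulates and what it does not

The trace simulator draws spikes as one Bernoulli trial per frame at
`rate/fps` (exact expected counts for rates well below the frame rate), with
per-class rate multipliers on designated frames: ×8 during tones for excited
neurons, ×0.05 for inhibited, and the same factors on high-behavior frames
for behavior-coupled classes. Draws within 0.2 s of the previous kept spike
are discarded: distinct calcium transients are not resolvable below the
indicator rise time, so ground-truth events carry that minimum spacing, and
a transient that would peak after the recording ends is likewise not
counted. Spike trains are convolved with a peak-normalized difference of
exponentials (rise 0.05 s, decay 0.4 s — fast-indicator kinetics). The noise
term emulates what survives deconvolution: slow baseline wander (Gaussian
process with a 90 s correlation scale, SD 0.05 of the transient peak)
representing bleaching/focus drift, not white sensor noise — deconvolved
traces have essentially noiseless baselines. White noise is available by
setting the correlation scale to zero.

The video simulator hides a two-state Markov chain (enter-high 0.05,
exit-high 0.15 per frame, stationary occupancy 0.25) driving a bounded
integer random walk of a smoothly textured body over a static textured
background. Low-state frames are integer-still (sub-pixel tremor); high-
state steps are uniform in ±4 px per axis with a minimum Chebyshev size of
half the amplitude, reflecting that struggle bouts are large-amplitude.
Mild per-pixel sensor noise (SD 0.003) makes edge masks flicker so that
low-movement scores form a smooth distribution rather than an atom at zero —
which is exactly why a two-normal description fits real score distributions.
The freezing simulator draws each second frozen at the tone or off-tone
probability and reports an immobility percentage (70–100 for frozen seconds,
0–30 otherwise) so default binarization recovers the drawn state.

Passing the recovery tests therefore shows the pipeline is correct under
plausible generative conditions with exact ground truth. It does not show
robustness to what the generators omit: photon noise and bleaching dynamics,
non-rigid body deformation, camera shake, segmentation cross-talk between
neurons, or spike-rate nonstationarity unrelated to the modeled factors.

Two honest caveats surface directly in the synthetic results. First, with
autocorrelated traces and autocorrelated behavior the per-frame Pearson test
is anticonservative: neurons with no built-in coupling are flagged well
above the nominal 5% (the calibration tests use white-noise traces, where
the 5% holds exactly). Second, event detection slightly undercounts at high
rates when transients merge within the kernel rise; at the default 0.2
events/s the bias is far below sampling error.

## Determinism and sizes

All randomness flows through explicit integer seeds (numpy Generator); every
simulator, the EM fit, and the shuffle null are bit-reproducible for a given
seed. Pipeline outputs are stamped with the seed and a hash of the full
configuration, and identical runs are byte-identical. The test-suite and
acceptance problem sizes — 300-neuron cohorts on the full 1350 s
conditioning schedule, 1000 shuffles, 20 000 mixture draws, 3000-frame
videos, 200–1000-neuron correlation cohorts — were chosen so the whole
validation runs in about a minute on a single CPU while keeping Monte-Carlo
bands (3 binomial SEs) tight enough to detect real miscalibration.
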