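# Methods

`mngpipe` covers two linked problems: (i) analysing efferent
microneurography (MNG) sessions — sorting motoneuron spikes out of a
single-channel nerve recording, relating their firing to grasp force and
finger-flexion velocity, and decoding those movement parameters — and
(ii) simulating a small spinal motoneuron circuit to ask whether the firing
features the decoder relies on survive the loss of proprioceptive feedback.
Because raw human recordings of this kind are not publicly available, the
package also contains a first-class synthetic-session generator with exact
ground truth; every analysis stage is validated against it.

## Synthetic sessions

A session emulates one experimental block: a 10 kHz single-channel MNG,
one to four 10 kHz surface-EMG channels, a 10 Hz pressure readout, and a
cue timeline. Two task protocols are generated:

* **isotonic** grasps at 1/2/4/6 kPa — 11 s repetitions, each preceded by
  2 s of rest, three repetitions per level (a full session spans
  12 × (2 + 11) = 156 s);
* **isokinetic** finger flexions at 17/26/47 deg/s — repetition duration
  is a fixed 160 degree flexion path divided by the speed, clipped to the
  4–10 s protocol range.

Motoneuron spike trains are inhomogeneous Poisson processes. During
isotonic repetitions the underlying rate rises over 0.8 s to a peak set by
the saturating rate–force law (below), then relaxes exponentially
(τ = 0.8 s) to a plateau at 60 % of the peak — the "reaching" and
"holding" phases. During isokinetic repetitions the rate ramps linearly to
a speed-independent peak, so the rate slope is proportional to velocity.
Per-unit rate scales are jittered by ±15 % to emulate across-unit
heterogeneity; background rest discharge defaults to 1 Hz. Default
generating law parameters are (A, B, C, D) = (0.5, 1, 1, 0.2) with a 25 Hz
per-unit peak.

Each fiber contributes a zero-mean bi-/triphasic template (~1–2.4 ms,
Gaussian-lobe construction); five mutually distinguishable shapes are
provided (pairwise shift-maximized normalized cross-correlation < 0.9),
and larger pools reuse them cyclically. The MNG is the sum of all
templated trains plus Gaussian noise band-limited to 300–3000 Hz (the
amplifier band). The sEMG is an envelope-times-carrier construction: the
target envelope mixes the MNG envelope with an independent envelope so the
envelope–envelope Pearson correlation hits a target (default 0.6, the
average observed between the most-correlated muscle and the nerve); the
carrier is 100–1000 Hz band-limited noise. Because rectification and
clipping re-correlate the channels, the mixing weight is corrected by a
few secant iterations on the measured correlation, and a target that
remains unreachable raises an error rather than being silently clipped.
Pressure follows the commanded profile with a 1 s rise and 10 %
multiplicative hold noise. One session seed deterministically spawns all
sub-streams; identical (config, seed) reproduces the session bit for bit.

What the generator does **not** emulate: electrode drift and motion
artifacts, non-stationary noise, bursting or doublet discharge,
correlated (common-drive) motoneuron inputs, amplitude variability of a
unit's successive spikes, and EMG cross-talk structure beyond a single
correlation number. Passing tests on these sessions therefore demonstrate
algorithmic correctness under the stated statistical assumptions, not
performance on real recordings.

## Preprocessing

* Band-pass: zero-phase (forward–backward) third-order Butterworth,
  700–2000 Hz.
* Artifact blanking: samples within a centered 4 ms window around
  supra-threshold events are zeroed; overlapping windows merge. Zeroing
  (not interpolation) is the artifact-neutral choice.
* Detection: threshold at `detection_k` (default 4) times the robust noise
  SD (median(|x|)/0.6745), alignment to the local trough, 1 ms dead time.
  Detections dwarfed by a >2× larger event within ±3 ms are discarded —
  they are threshold re-crossings of the filter's ringing lobes.
* Sorting: 1.6 ms snippets, top-3 principal components, k-means over
  k = 2..5 with silhouette model selection (k = 1 when the best silhouette
  is below 0.5). Clusters whose templates have shift-maximized correlation
  ≥ 0.8 **and** median trough depths within 1.25× are merged (alignment
  jitter splits one unit into subclusters whose mean templates differ
  mostly by dilution); clusters under 2 % of detections are dropped as
  collision residue. This is a deliberately standard, reproducible stand-in
  for more elaborate wavelet-based sorters.
* Firing rate: centered 100 ms boxcar, FR(t) = count in [t−50 ms, t+50 ms)
  / 0.1 s, on an arbitrary grid (1 ms for decoding).
* SNR: the trace is fragmented into 100 ms intervals labelled
  activity/rest from the cue timeline; SNR = mean of activity-interval
  |x| maxima over the same mean for rest intervals.
* Trial selection: a repetition is analysed iff SNR > 1 and the task was
  executed correctly — mean held pressure within ±10 % of the request
  (isotonic), or the sEMG-envelope maximum within ±10 % of the repetition
  duration from the flexion-end cue (isokinetic). Tolerance boundaries are
  inclusive. Envelopes are rectification followed by a zero-phase 2 Hz
  second-order Butterworth low-pass.

## Rate–force and slope–velocity characterization

The saturating rate–force law is

    FR(f) = B / (C + exp(-f / D)) - A,

with force and rate normalized to their maxima; A, B, C set the
**saturation value** B/C − A and D is the characteristic force. Fitting is
bounded nonlinear least squares (A, B, C ∈ [0, 10], D ∈ (10⁻³, 10]) from
20 Latin-hypercube starts, keeping the lowest-cost solution; constant-rate
input is flagged degenerate with R² = 0. The reaching-phase statistic is
the repetition maximum of the boxcar average firing rate; the holding-phase
statistic is the stationary-interval mean, which at three repetitions per
level is the much better-determined of the two (an 8 s average versus the
maximum of a noisy trace).

The rate slope of a flexion is (FR_max − FR(onset)) / (t_max − onset) on
the max-normalized series, and the slope–velocity relation is ordinary
least squares. Group comparisons are distribution-gated: Lilliefors
normality on every group and Bartlett homoscedasticity at α = 0.05 route
to one-way ANOVA when all pass and Kruskal–Wallis otherwise, with
Tukey–Kramer post-hoc pairs on request. Case-resampling bootstrap
utilities are seeded and deterministic.

## Decoding

The average firing rate (AFR) is the pointwise mean of the sorted units'
boxcar rates, normalized to its maximum over the training trials (frozen
for held-out prediction) and resampled to 1 ms. Features:

* force:    Feat1(t) = −1 + 1/(AFR(t) − 1.5)², a monotone transform that
  linearizes the quasi-logarithmic rate–force relation;
* velocity: Feat1(t) = (AFR(t) − AFR(t_min)) / (t − t_min) with t_min the
  pre-activity AFR minimum. The magnitude-positive sign convention is
  used. Inside the decoder a 1 s guard after t_min zeroes the feature —
  the vanishing denominator would otherwise turn boxcar quantization noise
  into rest-period feature spikes that inflate the gate thresholds;
* Feat2/Feat3: binary activity/rest flags from a hysteresis threshold pair,
  calibrated from the rest-period Feat1 distribution (T_l1 = mean + 1 SD,
  T_u1 = mean + 3 SD; initial state rest). No level prediction is emitted
  while gated to rest.

The custom classifier assigns the level of the nearest Feat1 centroid
(absolute distance, ties to the lowest level); centroids are class means of
gated-active training samples under leave-one-trial-out folding. Linear
discriminant comparators run per 1 ms gated sample on three feature sets:
the custom features, single-unit rates, or multi-unit activity (MNG
envelope + AFR); singular within-class scatter triggers Ledoit–Wolf
shrinkage, which is reported. Accuracy is balanced accuracy — the mean
over classes (rest included) of per-class recall — and one event is one
1 ms gated sample. Both chance conventions (with and without the rest
class) are reported because the field uses both. Per-subject confusion
matrices aggregate as sums of row-normalized matrices.

## Spinal circuit model

Five Izhikevich neurons (a = 0.02, b = 0.2, c = −65, d = 16; the reset
increment raised from the canonical 8 to make the cells slowly adapting)
integrate with forward Euler at 0.1 ms inside a 1 ms control loop. Input
is central drive + feedback + noise. Drives: isotonic — a square wave of
4 s period with amplitude proportional to desired force; isokinetic — a
sawtooth β·v̄·t over a fixed path x̄ (= 60 model degrees), so the peak
β·x̄ is speed-independent; both smoothed by a 20 ms Gaussian window
(σ = width/4). Noise is per-neuron Poisson with a common mean (default
0.3 events/ms at gain 4.0): sparse, high-variance kicks that desynchronize
the pool and dither the 10 Hz-per-spike quantization of the 100 ms boxcar.

Each spike contributes a bi-exponential twitch e^(−t/τ₂) − e^(−t/τ₁).
The printed calibration pair — 60 ms rise, 80 ms half-relaxation — is
over-determined for this family if the half-relaxation is read as the
peak-to-half interval: that interval can never be shorter than ~1.68× the
time to peak (minimum ≈ 100.8 ms for a 60 ms peak, verified by scanning
τ₂/τ₁). The calibration therefore sets τ₂ = 80/ln 2 ≈ 115.4 ms (an 80 ms
half-life of the relaxation exponential) and root-finds τ₁ ≈ 35.1 ms for
an exact 60 ms time-to-peak; the measured peak-to-half interval of the
resulting twitch is ≈ 118.5 ms. Total force is superlinear in the pooled
rate, F = A_tot·(ΣFRᵢ ∗ twitch)^k with k = 1.5. Inside the closed loop
FRᵢ is a **trailing** 100 ms boxcar — a centered one would need 50 ms of
future spikes — which amounts to a fixed 50 ms extra latency in the
twitch path; reported rate series use the centered analysis boxcar.

Feedback currents are delayed, linearly-weighted window sums: inhibitory
force feedback (Ib-like) of the force history and excitatory movement
feedback (Ia/II-like) of velocity × position, the latter identically zero
for grasps (fingers quasi-steady) and computed open-loop from the
commanded kinematics for flexions. Window weights are
1 + α(t′/W − ½), t′ = 0..W inclusive.

### Calibration of the free amplitudes

None of A_tot, k, the noise statistics, the drive gain or the feedback
amplitudes are observable from recordings; they were fixed once by a
calibration pass targeting the published summary values of the isotonic
experiment (saturation 0.63 without and 0.34 with force feedback at
normalized strength 0.4) and recorded as the defaults above. Two findings
shaped the design:

* a short-delay closed force loop cannot reduce the measured rate peak:
  the loop lags the onset transient by boxcar + twitch + delay ≈ 150 ms,
  and raising its gain only produces relaxation oscillations whose rebound
  bursts restore the peak;
* the pool's own adaptation (d = 16) produces the no-feedback saturation
  of peak rate versus drive, matching the observation that a purely
  feed-forward pool already shows the saturating relation.

The isotonic experiment therefore runs two-cycle trials: a warm-up grasp
charges a slow Ib-like integrator (Δ = W = 2000 ms = half a drive period,
α = 0), so the measured second grasp starts against an inhibition
proportional to the previous grasp's force. Feedback strength s maps to
the window amplitude as f_coeff = s / (W_samples · F_REF) with
F_REF = 1.1. Rates are normalized — jointly across the pooled feedback
conditions — to the pool's maximal discharge rate, defined as the peak
inverse ISI of a deterministic reference run (mean noise as constant
current, no feedback) at a supramaximal probe drive of 13.0; forces to the
largest group-averaged trial peak force. The rate peak is taken from the
first second of the measured grasp, the trial force from the whole
on-phase (by which time the integrator has drained).

With these defaults the experiment (8 drive amplitudes, 3 repetitions)
yields saturation ≈ 0.62 without and ≈ 0.34 with force feedback, with the
with-feedback value below the without-feedback value in every seed tested.
The isokinetic experiment reproduces a speed-independent peak rate
(distribution-gated test, p > 0.1) and a positive, linear slope–velocity
relation in all feedback configurations, including the "amputee" (no
feedback) case.

## Numerical and problem-size choices

* Simulation grids: neurons 0.1 ms, force/feedback/rates 1 ms; halving the
  neuron step changes on-phase mean rates by < 5 %.
* The closed-loop core is compiled with numba when available and falls
  back to the identical pure-Python loop otherwise.
* Test-suite problem sizes: pipeline checks run 10 seeds of full
  156 s/117 s sessions with 10 units; the model experiments run
  scaled-down (2 repetitions / 4 seeds isotonic; 5 repetitions / 2
  conditions isokinetic). The acceptance script runs the isotonic
  experiment at 3 repetitions over 10 seeds and reports min/max-trimmed
  means, because the bounded fit occasionally lands on a runaway-asymptote
  solution for the flatter with-feedback curves.
* Ties and degenerate inputs: equidistant centroids resolve to the lowest
  level; all-zero AFR is flagged and left at zero; zero-variance groups
  are rejected by the gated test; an all-zero rest trace makes the SNR
  undefined and raises.

## Known limitations

* Single-channel threshold sorting cannot resolve near-coincident spikes;
  at ten units and grasp-peak rates the pooled train loses a
  rate-dependent few percent of spikes, which slightly compresses
  reaching-phase rate–force curves. The holding-phase fit is unaffected in
  practice and is the recommended saturation estimator.
* The Ib-like cycle-memory feedback is phenomenological: its seconds-long
  integration window stands in for slower, possibly supraspinal loops and
  should not be read as an afferent conduction delay.
* The decoder's velocity feature needs ≥ ~10 units before the AFR is
  smooth enough for slope gating; small pools leave it near chance.
* No fatigue, no recruitment-order dynamics within the pool, and no
  spiking afferent models.
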