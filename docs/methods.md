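# Methods

This note documents the models, parameter choices and limitations of the
`graspsource` pipeline: synthetic reach-and-grasp EEG → event detection →
MRCP preprocessing → sLORETA source imaging → sliding-window sLDA decoding
→ PLV networks and graph metrics → statistics.

## Synthetic experiment

The generator emulates a cue-based protocol: per 12-s trial, an attention
beep at 0 s, a task cue at 3 s, a "go" cue at 5 s, and a movement (reach,
grasp, return) completed within 5 s of "go". Defaults mirror the full
design — 40 channels at 1000 Hz, 8 sessions × 10 trials per condition × 6
conditions = 480 trials, plus a 10-s rest block — with per-session balanced
randomised task order derived from one master seed (bit-identical reruns).

**Sources and forward model.** Each of `n_sources` (default 48) scalar
sources is assigned to one of the 24 ROIs round-robin. The default
leadfield has random Gaussian unit-norm columns; a `dipole` option places
electrodes on a hemisphere and oriented current dipoles inside it using the
infinite-homogeneous-medium dipole potential for spatially structured
columns, and an `identity` option supports analytic tests. No anatomical
head model is used: realistic geometry is irrelevant to the recovery
properties under test, and the random-leadfield setting is the harder case
for localization.

**MRCP templates.** Movement conditions carry a negative deflection in left
BA4a (peak amplitudes 6–10 a.u., latencies 1.2–1.85 s after onset,
condition-specific) with a 0.8× copy in BA6 led by 150 ms, a 35% attenuated
right-hemisphere mirror (contralateral control of the right hand), a smaller
somatosensory (BA2) response, and a visual (V1/V2) response during the reach
(0–1 s). No-movement has exactly zero motor templates and a weak visual
response. Inter-trial amplitude variability is a free parameter
(`amplitude_sd_frac`, default 0.2 — a value the protocol leaves unspecified,
so it is exposed rather than fixed).

**Oscillatory coupling.** For connectivity recovery, ground truth lists
coupled ROI pairs (default: left BA4a–BA6) that share one random-phase 2-Hz
sinusoid per trial (amplitude 2.0); every other ROI receives an independent
random-phase 1–3 Hz sinusoid (amplitude 0.7). These amplitudes live in the
ground-truth object so an all-zero truth yields exactly zero EEG at
infinite SNR.

**Sensor signal and noise.** Source activity is projected through the
leadfield and scaled at 2 μV per source unit, so the ±100 μV rejection rule
operates on realistic magnitudes. Noise is spatially mixed 1/f Gaussian
with RMS set by `snr`, defined as the amplitude ratio between the
projection of a reference-amplitude (5 a.u.) source and the noise
(`snr = inf` disables noise). A contamination map plants fractions of
movement trials violating each behavioural discard rule, and an artifact
fraction injects >100 μV spikes.

What the generator does **not** emulate: ocular/muscle artifacts (hence no
ICA stage), 50-Hz line noise (an optional notch could be added trivially),
anatomical source geometry, or non-stationary noise. Passing tests
therefore demonstrate algorithmic correctness and recovery under the stated
model, not robustness to real-world artifact structure.

## Event detection

Movement onset is the button rising edge, movement end its falling edge,
the grasp interval the force-channel edges. Edges are detected at half the
channel's dynamic range with a 10-ms debounce (the protocol does not state
thresholds; these are package choices). Discard rules: R1 release before
"go"; R2 no return within 5 s of "go" (also applied when button edges are
missing entirely, since no onset exists); R3 reaction time > 1.5 s; R4
wrong movement, decidable only from simulation truth and a no-op on real
data. Each trial carries exactly one flag and re-flagging is idempotent.
No-movement trials get a pseudo-onset: "go" plus the subject's mean
reaction time over valid movement trials.

## Preprocessing

Order: 0.1–40 Hz zero-phase 4th-order Butterworth ("zero-phase 4th order"
is read as an order-4 design applied forward–backward, i.e. effective
magnitude order 8) → polyphase downsampling to 100 Hz (Kaiser β=14 design,
passband ripple ~1e-7) → epochs cut at [−3, 3.5) s around onset → trial
rejection → common average reference → 0.1–3 Hz MRCP band.

All intervals are half-open: [a, b) at rate r holds round((b−a)·r) samples.
This makes the arithmetic self-consistent: the [−2, 3.5) tROI at 16 Hz has
exactly 88 samples, hence 88 sliding-window models. Epochs are cut one
second wider than the tROI on the left so that a causal 1-s feature window
exists for the earliest tROI time point.

Rejection: AMP if any sample exceeds ±100 μV (applied before re-referencing,
so the threshold refers to recorded amplitudes); JP if the trial's mean
negative log-likelihood under per-channel empirical Gaussians deviates more
than 5 SD from the trial population; KURT likewise for mean channel
kurtosis (flag precedence AMP > KURT > JP; zero spread flags nothing).
An optional robust channel screen replaces by-eye bad-channel removal and
is off by default.

## Source imaging

Noise covariance: sample covariance of the identically preprocessed 10-s
rest block plus diagonal loading ε·tr(C)/n with ε = 1e−6 (guarantees
positive definiteness under rank deficiency). Inverse: sLORETA — the
regularised minimum-norm kernel standardised by the diagonal of the
resolution matrix, with λ = tr(LLᵀ)/(n_channels·snr²) at the conventional
snr = 3 (the regularisation the original analysis used is unreported).
Sources are scalar (fixed orientation); no depth weighting, since sLORETA
standardisation compensates. ROI traces are signed arithmetic means over
the ROI's sources, preserving MRCP polarity; the output always has exactly
24 ROI rows.

## Decoding

Features: sMRCP resampled to 16 Hz; per window position (end time `t`), the
causal [t−1, t) s window sampled every 125 ms → 8 amplitudes × 24 ROIs =
192 features; 88 positions tile the tROI. Classifier: a single six-class
linear discriminant with Ledoit–Wolf analytic shrinkage of the pooled
covariance (one multiclass model, not one-vs-rest), invertible even with
more features than trials. Evaluation: stratified 5-fold CV repeated 10
times from one master seed (stratification is a package choice); accuracy
and per-class precision per window; confusion matrices summed over the
folds of one repeat and averaged across repeats, so row sums equal class
counts. Peak time is the argmax of the mean curve with ties to the
earliest window. Chance level is the smallest k/n whose exact binomial
upper tail at p = 1/6 is ≤ α = 0.05; at 480 trials this gives 95/480 ≈
19.8%. (A grand-average significance level quoted for this design differs
between 17.95% and 17.75% in different places and cannot be reconstructed
without per-subject retained-trial counts; the exact binomial bound is used
throughout.) The window-size experiment repeats the CV for 1-sample, 0.5,
1.0 and 1.5-s windows; positions whose window lacks support in the padded
epoch are skipped, and the single-sample window uses one amplitude per ROI.

## Connectivity and graph metrics

Instantaneous phases come from the Hilbert analytic signal computed over
the whole padded epoch, with analysis windows drawn from the interior so
transform edge effects (first/last 5% of samples) stay outside. Single-trial
PLV matrices over 1-s windows stepped by 0.1 s are averaged across the
trials of a condition (computing PLV on trial-averaged traces is exposed as
an alternative by passing a single-trial container). Matrices are
symmetrised to numerical precision with unit diagonal. Thresholding keeps
edges with PLV ≥ 0.65 and retains isolated nodes.

Metrics are computed on the weighted supra-threshold graph (a `binary`
switch gives unweighted variants): DE = mean over nodes of summed incident
weights; DS = edges/276; CC = mean weighted geometric-mean triangle
clustering (weights rescaled by the graph maximum; degree-<2 nodes
contribute 0); CPL = mean shortest-path length over connected pairs with
distances 1/weight (disconnected pairs excluded; an edgeless graph yields
NaN); M = weighted Newman modularity of the best Louvain partition at
resolution 1 with seeded tie-breaking. Weighted-versus-binary is genuinely
underdetermined in the source design; weighted is the default because the
degree definition is explicitly weight-based, and consistency favours
weights throughout.

## Statistics

Rank-sum tracks: two-sided Wilcoxon rank-sum per time point between a
movement condition and no-movement within one ROI, exact enumeration for
pooled tie-free samples ≤ 20 and the tie-corrected normal approximation
otherwise; uncorrected p < 0.05 masks (an FDR option exists but is off, as
the comparison of record is uncorrected). The window-size comparison is a
one-way repeated-measures ANOVA computed by direct sums-of-squares
(all-equal cells → F = 0, p = 1; zero within-cell error with a nonzero
effect → F = ∞, p = 0), cross-checked against statsmodels' AnovaRM in the
test suite; no sphericity correction by default.

## Problem sizes

The test suite and the acceptance script run desk-scale instances chosen as
representative rather than exhaustive: one session of 60 trials at the
native 1 kHz rate and 10:1 SNR for the shared end-to-end fixture; CV with
2–3 repeats over every 2nd–8th window position where full resolution adds
nothing to the property under test; 100 random leadfields for the
localization sweep; 10⁴ Monte-Carlo draws for PLV calibration; the complete
graph atlas (every connected graph on ≤ 6 nodes) plus 100 random 24-node
graphs for the metric oracles; and a 24-trial, 500-Hz two-run comparison
for byte-level determinism.

## Known limitations

Artifact-light synthetic data means the ICA cleaning stage of real-EEG
practice is intentionally absent; the ±100 μV/JP/KURT screens are the only
cleaning. The forward models are geometrically unrealistic by design.
Single-trial PLV on 1-s windows of 0.1–3 Hz signals spans at most a few
cycles, so absolute PLV values are upward-biased (the Rayleigh floor
√(π/4N) is ~0.09 at N=100); the 0.65 threshold should be read relative to
that floor. Louvain is stochastic: module maps are reproducible only at a
fixed seed. The decoder assumes class-conditional Gaussian features with a
shared covariance; no nonlinear classifiers or feature selection are
provided.
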