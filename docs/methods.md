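# Methods

This note documents the models, algorithms, and parameter choices behind
`metamerlab`, the reasoning at the points where the design was genuinely
open, and what the synthetic test conditions do and do not establish.

## Staged models and the cut-point contract

A `StagedModel` is an ordered sequence of named, deterministic layers with a
declared subset of *stages*.  Stages are cut points: the model output depends
on the input only through the activations there, which is what makes an
activation match meaningful — matching a stage pins down every downstream
computation, including the classifier decision.  In architectures with
parallel branches only merge points qualify; the toy zoo is purely
sequential, so every declared stage is post-nonlinearity or post-pooling.

Dataset normalization (channel mean/std) is a differentiable layer *inside*
the graph, so synthesis gradients flow through it and regularizers can be
computed on the normalized signal.

The layer library (`metamerlab.nn`) is a compact reverse-mode implementation
(conv 1-D/2-D, linear, rectifier, average pooling, normalization, power-law
compression) written against two requirements that shaped its design: exact
input gradients for synthesis, and parameter gradients sufficient to briefly
train the toy classifiers.  Gradients are verified against central finite
differences in the test suite.

## Toy models, stimuli and the auditory front end

Images are 16×16×1 in [0, 1]; audio is 1,600 samples of mono waveform at
20,000 Hz (the rate all auditory processing assumes).  Stimulus classes are
parametric: shape silhouettes with positional jitter and additive noise
(disk, square, cross, stripes, …), and tone/chirp/AM-noise/harmonic tokens
with frequency jitter.  `briefly_trained` models reach >80% held-out
accuracy after a short SGD pass; `random_weights` models sit at chance.

The auditory front end is a fixed differentiable filterbank: 32 FIR bandpass
channels with log-spaced centers (200 Hz–8 kHz, half-octave bandwidth),
half-wave rectification, a 400 Hz envelope lowpass, 8× downsampling, and
power-law compression with exponent 0.3.  The channel count and compression
exponent are configuration constants; this is a deliberately simplified
time–frequency front end, not a faithful cochlear model.

## Synthesis

The optimizer is projected steepest descent on the input:

* loss ‖A−A′‖/‖A‖ on flattened stage activations.  The un-squared norm
  ratio is the default; a squared variant is a config flag
  (`squared_loss`).  The denominator is the reference activations by
  default; `denominator_mode="synthetic"` uses ‖A′‖, which is the form the
  regularized preset adopts.
* step constraint: each update Δ = −g is rescaled to ‖Δ‖₂ = η exactly
  (`rescale_always`); `clamp_only` instead caps the norm at η, leaving
  small gradients untouched.  `rescale_always` is the default because the
  optimizer has no inner learning rate — the schedule *is* the step size.
* schedule: η(t) = η₀·0.5^⌊t/3000⌋ with η₀ = 1 over 24,000 steps, giving
  eight plateaus ending at 0.5⁷ ≈ 0.0078.  `SynthesisConfig.scaled(k)`
  shrinks both the step count and the decay interval k-fold, preserving the
  plateau ladder — the 2,000-step preset used in fast runs is `scaled(12)`.
* initialization: images start at N(0.5, 0.05) i.i.d. per pixel, audio at
  N(0, 10⁻⁷) — faint gray noise and near-silence respectively.
* rectifier handling: a rectifier *at the matched stage* propagates
  gradients as identity during synthesis (all other rectifiers behave
  normally).  Without this, the near-zero initialization leaves most
  units inactive and the gradient dies at the very layer being matched.
* divergence to non-finite values raises an error carrying the partial
  trace.  The trace records per-step loss, η, and realized step norms, so
  schedule exactness and the step-norm bound are checkable after the fact.

### Regularized preset

`SynthesisConfig.regularized(tier)` minimizes
‖A−A′‖/‖A′‖ + λ_α‖x−x̄‖₆ + λ_TV·R_TV(x) on the model-normalized signal x,
with λ_α = 0.005, λ_TV ∈ {5·10⁻⁶, 5·10⁻⁵, 5·10⁻⁴} (tiers 1×/10×/100×),
a 16× initial step size, and clipping to the image range after each step.
R_TV sums squared horizontal and vertical neighbor differences; boundary
terms whose neighbor falls outside the image are omitted (the sum is
otherwise undefined at edges).  Mean subtraction leaves the TV differences
unchanged algebraically but is retained for fidelity to the α-norm term,
which genuinely needs it.  Regularization trades match fidelity for
natural-signal statistics; certification thresholds apply unchanged.

## Certification criteria

A candidate passes if (1) each required match metric — Spearman ρ (average
ranks for ties), Pearson R², SNR_dB = 10·log₁₀(Σx²/Σ(x−y)²) — strictly
exceeds its threshold from a null distribution of the same metrics over
random distinct-index stimulus pairs, and (2) the model's argmax label for
the candidate equals that for its reference.  Defaults: 10⁶ null pairs
(10⁴ in test presets), threshold = null sample maximum; a quantile rule is
configurable.  Pairs are sampled with replacement across pairs, never
pairing an item with itself; same-class pairs are not excluded.

Two exact-perfect sentinel values always satisfy their criterion: SNR = +∞
(zero error energy) and Spearman ρ = 1.  The ρ sentinel matters on
low-dimensional stages: an 8-logit vector has few rank orderings, so both a
numerically perfect candidate and some same-class null pairs sit exactly at
ρ = 1, making "strictly greater than the null maximum" unsatisfiable there
despite a perfect match.  R² has no sentinel; it never hits 1 exactly in
floating point, and the strict rule applies.

Models without a classifier head get one attached by training a linear
readout on frozen stage activations, so the label criterion is applied
uniformly.

## Transfer

Metamer recognition by other models is stored as a tidy
(generation model, stage, recognition model) accuracy table.  Self-cells are
*missing*, never zero, and zero-trial cells likewise — treating them as 0
would bias group means.  Aggregation averages per recognition model over the
group's generation models first, then across recognition models (s.e.m.
across recognition models).  The group-difference statistic averages over
stages and recognition models; its null permutes generation-model labels
independently within each recognition model, with missing self-cells
traveling with their labels.  Default p-value convention is
(1 + #{null ≥ obs})/(1 + n_perm); the alternative 1 − rank/n_perm is
available (`convention="rank"`, floored at 1/n_perm) since the rank
direction of that formula is ambiguous.

## Behavioral statistics

The analysis unit is proportion correct per participant × condition; model
observers enter as pseudo-participants, one per matched human stimulus set.
The mixed-design F (between: observer; within: stage) uses the standard
sums-of-squares decomposition, validated cell-by-cell against an independent
oracle and against `pingouin.mixed_anova`.  Inference is by permutation:
observer labels for the main effect; observer labels *and* per-participant
stage labels for the interaction; per-participant stage labels for the
single-factor repeated-measures design.

Split-half analyses halve participants at random per split (an odd
participant joins the first half at random).  The confusion-matrix analysis
row-normalizes each half's class×class matrix and Spearman-correlates all
cells (an off-diagonal-only mode exists, since diagonal inclusion is a free
choice); a response-shuffled control is drawn fresh per split, and
p = (1 + n_overlap)/n_splits where n_overlap counts splits with
true − shuffled ≤ 0.  Per-stimulus reliability computes each half's
per-item proportion correct from exactly `min_trials` (default 4)
subsampled trials, excluding items below the minimum in either half, so no
item carries extra weight.  Extreme-item consistency selects the k most and
least recognizable items on one half and scores them on the other,
reporting the proportion of splits where most > least and its complement
as p.

### Calibration of the split-half p-value

The overlap-count p is a *consistency* measure, not a calibrated
permutation rank: the splits are halvings of the same dataset and their
true-minus-shuffled differences are strongly positively correlated, so
under a true null n_overlap concentrates near n_splits/2 rather than being
uniform.  Measured over 500 simulated unstructured-response datasets, the
mean p is ≈ 0.50 but its 5th percentile is ≈ 0.17, and the rejection rate
at α = 0.05 is ≈ 0.004 — far below nominal.  The test is therefore valid
but conservative; small p-values remain strong evidence of consistent
error structure.  The ANOVA and transfer permutation tests, which permute
genuinely exchangeable units, calibrate at the nominal rate (measured
0.046–0.060 under the same protocol), and the suite asserts that
distinction: nominal calibration for the permutation tests,
never-anticonservative behavior for the split-half p.

## Encoding and RSA

Features are stage activations, time-averaged where a temporal axis exists;
voxel responses are (stimuli × voxels × scans), scan-averaged for fitting.
Per train/test split (10 random splits; train fraction 83/165 ≈ 50.3%,
scaled proportionally for other stimulus counts):

* ridge λ per voxel by exact leave-one-out CV over 81 penalties (powers of
  ten, 10⁻⁴⁰–10⁴⁰), features mean-centered on the training set, intercept
  unpenalized.  The closed form uses one SVD and the e/(1−h_ii) identity
  and is tested to equal explicit refits to 1e−8; numerically null singular
  directions are truncated so that interpolating fits register unbounded
  LOO error instead of spuriously winning.
* test fidelity is squared Pearson r; voxel reliability r′_v is the median
  Spearman–Brown-corrected (n = 3) Pearson correlation between scan pairs
  on the test stimuli; prediction reliability r′_v̂ repeats the fit per
  scan and correlates the three predicted test vectors.  Non-positive split
  correlations map to reliability 0 — the prophecy formula has a pole at
  r = −1/(n−1) and a negative split correlation means no measurable
  reliability.  Both reliabilities are floored at the one-tailed P<0.05
  critical Pearson correlation for their sample sizes (0.182 at n = 83,
  0.183 at n = 82, recomputed from the configured split sizes rather than
  hard-coded); r²* = r²/(r′_v·r′_v̂), median over splits.
* best-stage selection is leave-one-participant-out: each participant is
  scored at the stage maximizing the *other* participants' mean summary;
  the modal chosen stage is reported.
* RDMs are 1 − Pearson r between stimulus patterns after z-scoring each
  unit across stimuli (the per-stimulus axis is a config flag; the choice
  is free and the unit axis is the field's common default).  Comparisons
  use upper-triangle entries only.  Cross-validated RDM similarity picks
  the stage on train-stimulus RDMs and scores test-stimulus RDMs
  (Spearman), median over splits; the noise ceiling correlates each
  participant's RDM with the average of the others'.

## Synthetic data

Simulated observers: trial correct with probability
sigmoid(logit(p_c) + item effect), item effects Gaussian on the logit scale
(shared across participants — the ground truth for per-stimulus
reliability), errors drawn from a row-stochastic confusion kernel over
wrong classes.  Simulated voxels: sparse non-negative linear readout of a
known stage's time-averaged features, standardized to unit signal s.d.,
plus i.i.d. Gaussian scan noise, so the expected inter-scan correlation is
1/(1 + σ²_noise) and the generating stage is identifiable.  Defaults used
in parameter-recovery runs: 60 stimuli, 20 voxels, 25% weight support,
σ_noise = 0.4, 3 scans, 3 simulated participants, 20 replicates — sizes at
which one CPU completes the full recovery study in well under a minute
while leaving the generating stage's corrected variance within 0.1 of 1.

What these fixtures do *not* establish: human lapse behavior, realistic
fMRI noise spectra or voxel correlation structure, and real-model feature
geometry.  Passing recovery and calibration tests show the estimators are
correct under their own assumptions, not that real data meet those
assumptions.

## Numerical choices and edge cases

* match-loss gradient at A′ = A is defined as 0 (the norm is not
  differentiable there; the fixed point should stay fixed).
* zero-norm loss denominators raise; all-zero reference activations make
  SNR undefined and raise; zero-variance arrays flag the correlation
  metrics as undefined rather than raising, so null construction can
  resample and log.
* degenerate ANOVA cells (zero denominator mean square) yield F = 0 when
  the numerator is also zero, +∞ otherwise.
* argmax ties (classifier decisions, best-stage selection) resolve to the
  first index, making reruns bit-reproducible.
* every stochastic component takes an explicit seed; identical
  (inputs, seed) give identical outputs, which the workbench uses to make
  whole-experiment reruns reproduce verdicts exactly.

## Known limitations

* The toy zoo's stages are few and low-dimensional; final-stage nulls
  saturate rank metrics (hence the ρ sentinel) in a way high-dimensional
  stages of large models would not.
* The auditory front end is a stand-in with free parameters, not a
  validated cochlear model; audio synthesis through it is markedly slower
  than image synthesis and test presets keep audio runs short.
* The transfer permutation test is slightly conservative when group sizes
  are small (within-group label swaps tie the observed statistic); with
  groups of three or more generation models it calibrates at the nominal
  rate.
* `run_experiment` executes sequentially; stage-wise caching keyed by
  config/model/stimulus hashes is the intended extension point for larger
  sweeps, which a single process handles poorly today.
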