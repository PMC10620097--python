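# metamerlab

Model metamers are stimuli synthesized so that their activations at a chosen
stage of a sensory model match the activations of a natural reference
stimulus, while being otherwise unconstrained.  Because everything a model
computes downstream of a stage depends on the input only through that stage,
two stimuli with matched stage activations are — for the model — the same
stimulus.  Whether *other* observers (humans, other models, brains) also
treat them as the same is a direct probe of the model's invariances: a deep
stage with human-like invariances should produce metamers humans still
recognize, while idiosyncratic invariances produce metamers that look or
sound like noise to everyone but the generating model.

`metamerlab` implements this methodology end to end for staged differentiable
models, for researchers in computational sensory neuroscience who want to
probe model invariances without committing to a specific deep-learning
framework:

* **Synthesis** — gradient descent on the input signal minimizing the
  normalized activation distance ‖A−A′‖/‖A‖, with an L2 step-norm constraint
  η(t) = η₀·0.5^⌊t/3000⌋ over 24,000 steps, per-modality noise
  initialization, identity gradients through the rectifier at the matched
  stage, and optional α-norm/total-variation regularization
  (‖A−A′‖/‖A′‖ + λ_α‖x−x̄‖₆ + λ_TV·R_TV(x), with a 16× initial step size).
* **Certification** — a synthesized candidate counts as a metamer only if its
  Spearman ρ, Pearson R² and SNR (10·log₁₀ Σx²/Σ(x−y)²) at the matched stage
  all fall outside a null distribution over random stimulus pairs, *and* the
  model assigns it the same label as its reference.
* **Transfer** — recognition of one model's metamers by other models,
  aggregated over recognition models (self excluded) with permutation tests
  that shuffle generation-model labels independently per recognition model.
* **Behavioral statistics** — permutation-based mixed repeated-measures
  ANOVA (observer × stage), split-half confusion-matrix reliability,
  per-stimulus reliability, and most/least-recognizable-item consistency.
* **Encoding & RSA** — ridge-regression voxel-wise encoding with exact
  leave-one-out λ selection over 81 log-spaced penalties, noise-ceiling
  corrected variance r²\* = r²/(r′_v·r′_v̂) with reliability floors at the
  one-tailed P<0.05 critical correlation, cross-validated best-stage
  selection, and RDM-based representational similarity.
* **Toy model zoo & synthetic data** — small image/audio convolutional
  staged models (with a filterbank–envelope–compression auditory front end),
  parametric stimulus sets, simulated observers and simulated voxels with
  known ground truth, so the entire pipeline is testable on a laptop.

The staged models run on a compact numpy reverse-mode layer library
(`metamerlab.nn`); any user model exposing the `StagedModel` contract
(ordered named stages, deterministic forward, input gradients) plugs into
the same machinery.

## Worked example

Synthesize a metamer at the final (logit) stage of a briefly trained 8-class
toy image model, and certify it:

```python
import numpy as np
import metamerlab as ml

model = ml.make_toy_model("image", n_classes=8, variant="briefly_trained", seed=0)
train = ml.generate_stimuli("image", n_per_class=20, seed=1)
null = ml.build_null_distribution(model, "final", train, n_pairs=10_000, seed=2)

ref = ml.generate_stimuli("image", n_per_class=1, seed=3).signals[0]
config = ml.SynthesisConfig(seed=0).scaled(12)   # 2,000 steps, same eta ladder
cand = ml.synthesize_metamer(model, "final", ref, config)
verdict = ml.evaluate_metamer(model, cand, null)

print(f"final match loss: {cand.trace.loss[-1]:.2e}")
print(f"metrics: rho={verdict.metrics.spearman_rho:.4f} "
      f"R2={verdict.metrics.pearson_r2:.6f} SNR={verdict.metrics.snr_db:.1f} dB")
print("null thresholds:", {k: round(v, 4) for k, v in verdict.thresholds.items()})
print(f"label match: {verdict.label_match}, overall pass: {verdict.overall}")
r = np.corrcoef(cand.signal.values.ravel(), ref.values.ravel())[0, 1]
print(f"signal-space correlation with reference: {r:.3f}")
```

Output:

```
final match loss: 2.45e-03
metrics: rho=1.0000 R2=0.999998 SNR=60.0 dB
null thresholds: {'spearman_rho': 1.0, 'pearson_r2': 0.9993, 'snr_db': 28.8441}
label match: True, overall pass: True
signal-space correlation with reference: 0.025
```

Read: after 2,000 constrained steps the candidate's logit-stage activations
match the reference far better than any of 10,000 random stimulus pairs
(60 dB vs a 28.8 dB null maximum), and the model gives both the same label —
a certified metamer — yet in pixel space it is uncorrelated with its
reference (r = 0.025).  The model cannot tell them apart; anything else can.

A thin CLI wraps the same functions (`metamerlab synthesize | null |
evaluate | run ...`); `metamerlab run --config exp.yaml` executes the whole
synthesize → certify → transfer → simulate-observers pipeline and writes a
report bundle with provenance.

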