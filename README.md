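# perhar — personalized human activity recognition from inertial sensors

`perhar` implements a personalization framework for wearable-sensor activity
recognition. Impersonal classifiers trained across a population of subjects
degrade on individuals whose sensor placement, body mechanics, or movement
cadence differ from the training population. This package addresses that by
learning a metric embedding of inertial time-series segments and classifying
each subject's segments against that *same subject's* small set of labeled
reference embeddings, rather than against a fixed softmax head.

It is aimed at researchers and engineers working with labeled IMU
(accelerometer/gyroscope/magnetometer) recordings — digital-health,
physiotherapy-monitoring, and HAR-benchmark settings — who want a complete,
desk-scale-testable reference implementation of personalized embedding
inference, including its evaluation protocols and a synthetic data generator
that reproduces the inter-subject-heterogeneity regime the method targets.

## The model

A 1D fully-convolutional core maps a fixed-length window
`x ∈ R^{C×W}` to a unit-norm embedding `f(x) ∈ R^d`:

    [conv1d(f_i, k_i) → batch norm → ReLU → dropout] × 3
      → global average pooling over time
      → (dense projection to d, when d ≠ f_3)
      → L2 normalization onto the unit hypersphere

Default kernels (7, 5, 3) give the last convolutional layer a receptive
field of 13 samples (260 ms at 50 Hz). The core is trained either

* with **categorical cross-entropy** through a softmax head (the impersonal
  FCN classifier; its penultimate embeddings give the *personalized deep
  feature* model, PDF), or
* with **triplet loss** (the *personalized triplet network*, PTN):

      L_T = Σ_i max( ‖f(x_i^a) − f(x_i^p)‖² − ‖f(x_i^a) − f(x_i^n)‖² + α, 0 )

  where anchor `x^a` and positive `x^p` share an activity class, the
  negative `x^n` does not, and α = 0.3 is the margin. The *subject triplet*
  variant additionally draws all three members from a single subject,

      L_S = Σ_s Σ_i max( ‖f(x_{s,i}^a) − f(x_{s,i}^p)‖² − ‖f(x_{s,i}^a) − f(x_{s,i}^n)‖² + α, 0 ),

  which shrinks the triplet universe from O(N³) to O(N) and concentrates
  training on within-subject class separation — exactly the property that
  per-subject nearest-neighbor inference relies on. Mixed sampling (half
  subject, half random triplets) is the default.

At test time each subject's recordings are split along the temporal axis
*before* windowing (first 50% reference, rest test, so no window ever spans
both), reference windows are embedded into a per-subject store, and test
windows are classified by 3-nearest-neighbor majority vote under the
Euclidean metric (nearest-centroid is available as an O(#classes)
alternative). Out-of-distribution activities are flagged by the mean
distance to the 3 nearest reference embeddings; an engineered-feature
baseline (PEF: 11 statistics per channel, standardized) uses the same
machinery.

The network, its manual backpropagation, Adam, and gradient-norm clipping
are implemented in numpy (`perhar._nn`) — compact, seeded, and exactly
reproducible.

## Worked example

```python
from dataclasses import replace
from perhar import (
    EvalConfig, FCNConfig, TripletSamplerConfig,
    grouped_kfold, make_benchmark_fixture, run_classification_experiment,
)

recs, manifest = make_benchmark_fixture(
    "heterogeneous", n_subjects=6, n_classes=4, seconds_per_class=30, seed=0
)
plan = grouped_kfold([r.subject_id for r in recs], n_folds=2, seed=0)
cfg = EvalConfig(
    fcn=FCNConfig(conv_filters=(32, 64, 32), embedding_dim=32, epochs=20),
    sampler=TripletSamplerConfig(mode="mixed", triplets_per_epoch=128),
    epochs=20,
)
for kind in ("FCN", "PTN"):
    res = run_classification_experiment(recs, kind, plan, cfg, folds=[0])
    print(kind, round(res.mean, 3), {s: round(a, 3) for s, a in res.per_subject.items()})
```

prints (seeds fixed, so exactly this):

```
FCN 0.655 {'S02': 1.0, 'S03': 0.5, 'S05': 0.464}
PTN 1.0 {'S02': 1.0, 'S03': 1.0, 'S05': 1.0}
```

The fixture gives every subject a random sensor-placement rotation, amplitude
scale, and baseline offset. The impersonal FCN, trained on the other three
subjects, collapses on the two test subjects whose transforms it never saw
(0.46–0.50 accuracy; per-subject spread 0.54), while the personalized
triplet network classifies every subject perfectly from 3-NN search over
that subject's own reference embeddings.

The same machinery drives the CLI:

```bash
har synth --level heterogeneous --seed 7 --out data/
har segment --in data/ --out segments.npz --window-s 4 --overlap 0.8
har train-ptn --in segments.npz --out ptn.npz --epochs 20
har evaluate --experiment classification --config exp.yaml
```

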