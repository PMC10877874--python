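# ovadx

Tools for two computational problems in ovarian-cancer diagnosis, built
to be runnable end to end on synthetic data:

1. **Tumor segmentation on T2-weighted-MRI-like 2D slices.** An
   edge-output fully-convolutional network: a truncated residual
   backbone with side branches at three depths, each reduced to a fixed
   channel width and upsampled back to input resolution by a learned
   (bilinear-initialized) transposed convolution, fused by two
   convolutions into a per-pixel tumor probability map. Training uses a
   class-balanced cross-entropy loss
   `L = −β Σ_{Y+} log p − (1−β) Σ_{Y−} log(1−p)`, `β = |Y−|/|Y|`, which
   counters the heavy tumor/background imbalance; plain cross-entropy
   and soft Dice loss are available for comparison. Evaluation reports
   DSC, sensitivity, specificity and the boundary Hausdorff distance.
2. **Multi-indicator diagnosis from routine laboratory panels.** A
   pipeline over 25 blood indicators plus 3 demographic fields: z-score
   standardization → correlation-matrix PCA keeping the top 3 components
   → a one-hidden-layer back-propagation classifier whose hidden size,
   weights and thresholds are selected by a genetic algorithm, emitting
   a continuous score in [0,1] per subject. Performance is read off the
   ROC curve (Mann–Whitney AUC, Youden-index operating point) and model
   comparisons use the paired DeLong test.

Because no clinical data ship with the package, a first-class synthetic
module generates (a) phantom slice/mask datasets with elliptical,
ring-shaped and fuzzy-boundary tumors on textured backgrounds, and (b)
case/control cohorts with a 3-latent-factor indicator structure and the
documented group-mean directions (E2, P, AGR, PA, TC lower in cases).
The audiences are method developers who need a fully reproducible
segmentation/diagnosis testbed, and readers who want every formula in
the pipeline exercised by runnable code.

## Worked example

Train the reduced-backbone network on easy phantoms and evaluate the
held-out slices:

```python
import ovadx as ox
from dataclasses import replace
from ovadx.harness import (easy_phantom_spec, easy_train_config,
                           split_dataset, train_model, evaluate_model)

data = ox.generate_phantom_dataset(easy_phantom_spec(), 40)
cfg = easy_train_config(seed=0)
train, test = split_dataset(data, cfg.split_fraction, cfg.seed)
net = train_model(replace(cfg, split_fraction=1.0), train)
table, _ = evaluate_model(net, test)
print(table.round(2))
```

```
        mean    sd
DSC/%  95.33  2.10
Se/%   99.97  0.09
Sp/%   99.20  0.25
HD      1.05  0.15
```

Held-out Dice overlap is ~95%: the network recovers almost the entire
tumor (sensitivity 99.97%) with pixel-scale boundary error (mean
Hausdorff distance ~1 px). Fit the diagnostic pipeline on a synthetic
cohort of the default size (185 cases, 569 controls) and score its
held-out third:

```python
table = ox.generate_cohort(ox.CohortSpec(seed=8))
model = ox.fit_diagnostic_model(table, seed=1,
                                ga=ox.GAConfig(seed=1, fine_tune=True))
test = table.loc[model.split.test_ids]
scores = model.predict(test)
labels = (test.label == "case").astype(int)
curve = ox.roc_curve(scores, labels)
print(f"AUC {curve.auc:.3f}; Youden Se {curve.youden_point[1]:.1%}, "
      f"Sp {curve.youden_point[2]:.1%}")
print(f"CA125 alone: AUC {ox.roc_curve(test.CA125, labels).auc:.3f}")
```

```
AUC 0.899; Youden Se 77.4%, Sp 87.4%
CA125 alone: AUC 0.697
```

The multi-indicator model separates cases from the pooled controls far
better than the single marker CA125 (an unsupervised PCA keeps only the
dominant-variance directions, so some of the case/control shift is
deliberately sacrificed — see `docs/methods.md`), and the paired DeLong test
(`ox.delong_test(scores, test.CA125, labels)`) quantifies that
difference with a two-sided p-value.

Everything is also scriptable from the shell: `ovadx synth phantoms`,
`ovadx synth cohort`, `ovadx seg train|evaluate|grid|compare`,
`ovadx dx fit|predict|profile` (see `--help`).

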