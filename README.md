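# ttafoods

Robust test-time inference for single-cell image classifiers under
acquisition-domain shift. The pipeline has three stages:

1. **Deterministic test-time augmentation** — a fixed, ordered set of 14
   transforms (7 center crops with margins 5–20 px, horizontal/vertical
   flips, 5°/10°/20° rotations, Gaussian blur, color jitter) produces 15
   versions of each test image (original included).
2. **Feature-space OOD filtering** — per layer ("low"/"mid"/"high"), the
   average Euclidean distance of each augmented sample to its k=5 nearest
   training features is compared against a threshold fitted as the 95th
   percentile of the training set's own self-excluded k-NN distances. A
   sample is kept only if it is within threshold on *all* layers; kept
   samples are weighted inversely to their mean threshold-normalized
   distance, discarded ones get weight 0. The original is never filtered.
3. **Weighted soft-vote fusion** — class-probability vectors of the kept
   samples are accumulated with their weights and divided by the number of
   versions; argmax (lowest index on ties) gives the final label.

The library is model-agnostic: anything implementing the small
`ClassifierAdapter` contract (class probabilities + three tagged feature
layers) plugs in. A fully deterministic synthetic benchmark is included: a
5-class cell-like image generator with controllable domain shift
(tint/hue/brightness/blur/noise) and a nearest-centroid toy adapter, so the
whole pipeline is testable on CPU with no downloads.

## Library quick start

```python
import ttafoods as tf

train = tf.generate_dataset(20, tf.DOMAINS["identity"], image_size=64, seed=1)
adapter = tf.make_toy_adapter(train)
feats = tf.extract_layer_features(adapter, train.images)
model = tf.fit_foods(feats, k=5, percentile=95)
augset = tf.build_default_augmentations(64)

test = tf.generate_dataset(4, tf.DOMAINS["stain_shift"], image_size=64, seed=2)
pred = tf.predict_pipeline(adapter, model, augset, test.images[0])
print(pred.label, pred.n_contributing, pred.weights_used)
```

## CLI

```sh
# 1. generate a synthetic dataset (class-per-subdirectory PNG layout)
ttafoods fixtures generate --out data/train --n-per-class 20 --domain identity --seed 1

# 2. fit the toy adapter + OOD filter into one model bundle
ttafoods foods fit --train data/train --k 5 --percentile 95 --out model.foods.npz

# 3. predict a single image (JSON report on stdout)
ttafoods predict --model model.foods.npz --image data/train/a_round/a_round_0000.png
ttafoods predict --model model.foods.npz --image ... --no-filter   # keep all samples
ttafoods predict --model model.foods.npz --image ... --baseline    # no augmentation

# 4. run the cross-domain benchmark + 8-row ablation grid
ttafoods evaluate cross-domain --out results/ --seed 0
```

`evaluate cross-domain` fits on each of the 4 packaged domains and tests on
every other (12 ordered source→target pairs), evaluates the baseline plus
all 8 ablation variants (filter on/off × soft/hard voting × uniform/weighted
weights), and writes `scores.csv`, `ablation.csv` (mean paired difference vs
baseline + Wilcoxon signed-rank p-value per variant), `distances.csv` /
`distance_summary.csv` (threshold-normalized distance distributions of kept
vs discarded augmentations) and a run manifest. An optional YAML config
(`--config`) overrides domains, sample counts, seeds and filter settings.

## Layout

```
src/ttafoods/
  augment.py    deterministic augmentation set + TTA application
  features.py   ClassifierAdapter contract, pooled layer-feature extraction
  foods.py      k-NN OOD filter: fitting, thresholds, retention, weights
  sec.py        weighted soft-vote fusion and the end-to-end pipeline
  fixtures.py   synthetic 5-class image generator + toy adapter
  evaluate.py   weighted metrics, cross-domain runner, ablation, Wilcoxon
  cli_io.py     dataset I/O, config, model bundles, the `ttafoods` CLI
tests/          pytest suite incl. acceptance criteria (tests/test_acceptance.py)
scripts/acceptance.py   standalone acceptance report
```
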