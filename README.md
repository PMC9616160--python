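# octaline

A-line-wise identification of lipid-laden plaque in intravascular
optical coherence tomography (IV-OCT), for researchers building or
evaluating automated plaque-assessment pipelines.

During percutaneous coronary intervention, an IV-OCT pullback produces
hundreds of cross-sectional B-scans (1024 A-lines × 1024 depth pixels
each) that cardiologists must read visually. Lipid-rich plaque — the
vulnerable kind — betrays itself in a single A-line: its signal decays
with depth much faster (attenuation coefficient µ ≈ 6 mm⁻¹) than
fibrous or intimal tissue (µ ≈ 2 mm⁻¹). `octaline` classifies each
A-line independently with a 1-D convolutional network that treats the
depth profile as a sequence:

    input (512 px)
      → 3 × [Conv1D(48, k=21, same, ReLU) → MaxPool(2) → Dropout(0.5)]
      → Flatten (3072)
      → Dense(16, ReLU, no bias) → BatchNorm → Dropout(0.5)
      → Dense(8,  ReLU, no bias) → BatchNorm → Dropout(0.5)
      → Dense(2, sigmoid)          # argmax: 0 = other, 1 = lipid

trained with class-balanced binary cross-entropy (w_c = n/(2·n_c))
under Adamax, with early stopping and learning-rate reduction on
plateau. Preprocessing is minimal: log compression to dB, 2×2 block
averaging to 512×512, and feature standardization fitted on the
training split only.

Because no public per-A-line annotated IV-OCT corpus exists, the
package includes a physics-based simulator (`octaline.simdata`):
single-scattering decay I(z) = b·exp(−2µzΔz) with unit-mean
exponential speckle, class-specific attenuation, bright intimal
layers, guidewire shadow, arc-shaped plaques and the ~20% lipid class
imbalance. It provides seeded, bit-reproducible ground truth for every
stage. See `docs/methods.md` for the model, its assumptions and
limitations.

## Worked example

```python
import octaline as oc
from octaline.train import prepare_features, split_train_test

# 10 synthetic B-scans: lipid mu=6, other tissue mu=2 beneath a
# bright intimal layer, exponential speckle, ~20% lipid A-lines
pullback = oc.simulate_dataset(oc.SimConfig(n_bscans=10, seed=7),
                               oc.simdata.contrast_optics())

split = split_train_test(range(10), test_fraction=0.2, seed=1)   # 8 / 2
inner = split_train_test(split.train_bscan_ids, 0.2, seed=2)     # 6 / 2
X_tr, y_tr, _, std = prepare_features(pullback, inner.train_bscan_ids)
X_va, y_va, _, _ = prepare_features(pullback, inner.test_bscan_ids, std)
X_te, y_te, _, _ = prepare_features(pullback, split.test_bscan_ids, std)

clf = oc.build_classifier(oc.ModelConfig(max_epochs=6,
                                         early_stop_patience=3, seed=3))
clf.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)

report = oc.classification_metrics(
    oc.confusion_from_predictions(clf.predict(X_te), y_te))
print(f"accuracy    {report.accuracy:.3f}")
print(f"sensitivity {report.sensitivity:.3f}")
print(f"specificity {report.specificity:.3f}")
```

prints

```
accuracy    0.972
sensitivity 0.996
specificity 0.964
```

per held-out A-line, with lipid as the positive class: 97% of the
1024 held-out A-lines are labelled correctly, virtually every true
lipid A-line is found (sensitivity), and 3.6% of non-lipid A-lines are
falsely flagged (1 − specificity). `ALineCNNClassifier` follows the
scikit-learn estimator API (`fit` / `predict` / `predict_proba` /
`get_params`), so it composes with sklearn model-selection tooling.

The same stages are available from the shell:

```
octaline simulate --config sim.yaml --out pullback/ --seed 1
octaline train    --data pullback/ --out run/ --seed 1
octaline predict  --data pullback/ --weights run/weights.npz \
                  --standardizer run/standardizer.json --out pred.csv
octaline evaluate --data pullback/ --predictions pred.csv --out report.json
octaline render   --data pullback/ --predictions pred.csv --bscan 0 --out map.png
```

`render` draws the cross-section as a disk with two annuli — outer:
ground truth, inner: prediction; orange = lipid, blue = other.

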