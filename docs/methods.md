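# Methods

## Problem and approach

Intravascular OCT (IV-OCT) renders a coronary artery cross-section as
a polar B-scan: 1024 depth profiles (A-lines, 0.35° apart, 1024 pixels
at 4.8 µm axial step) per catheter rotation. Lipid-laden plaque
attenuates the OCT signal much faster with depth than fibrous or
intimal tissue, so each A-line carries enough information to decide
lipid vs. other on its own. The package classifies A-lines with a 1-D
convolutional network that treats the depth axis the way time-series
classifiers treat time, avoiding lumen segmentation, attenuation-map
estimation, speckle filtering, data augmentation, and hand-crafted
features.

## Synthetic pullback simulator

No public IV-OCT corpus with per-A-line histology-confirmed labels
exists, so every stage is exercised against a physics-based simulator
(`octaline.simdata`). Its signal model is first-order single
scattering: below the lumen surface at depth index `z0`,

    I(z) = b · exp(−2 µ (z − z0) Δz) · S + N,

with `µ` the tissue attenuation coefficient (mm⁻¹), `Δz` the axial
step (mm), `b` the mean linear backscatter, `S` unit-mean multiplicative
speckle and `N` an additive detection-noise floor (exponential with
scale `noise_floor`). Fully developed speckle is exponential on
intensity; a Rayleigh-amplitude dialect (identical intensity statistics,
sampled in the amplitude domain) and a `"none"` setting for
deterministic limits are also available.

Per-class defaults: lipid µ = 6 mm⁻¹ (diffuse border, no superficial
layer); intimal-thickening and fibrous tissue µ = 2 mm⁻¹ beneath a
bright superficial intimal layer (20 px, 3× backscatter); calcium
µ = 3 mm⁻¹ with a sharp border and slightly lower backscatter; the
guidewire is a saturated 4-px surface reflection followed by a
noise-floor shadow. The values sit inside ranges commonly reported for
coronary tissue; the single property downstream stages rely on is the
lipid > fibrous attenuation contrast. The expected log₁₀-intensity
decay slope, −2µΔz·log₁₀e per pixel (≈ −0.0250 at µ = 6 mm⁻¹,
Δz = 4.8 µm), is asserted against simulation in the test suite.

Plaques occupy contiguous angular arcs (annotation in this field is
arc-based): each B-scan gets one lipid arc whose extent is drawn
uniformly from `plaque_arc_deg_range` (default centred so that the
pooled lipid A-line fraction converges to `class_mix` ≈ 0.2, the
imbalance typical of such corpora), exactly one guidewire arc (10°),
and the remainder split among the other tissue classes. The lumen
offset is constant per B-scan, drawn from `lumen_radius_px_range`.
Everything is reproducible bit-for-bit from `SimConfig.seed` via
per-B-scan rng substreams.

What the simulator does **not** emulate: catheter non-uniform rotation
distortion, residual-blood scattering, polarization channels, depth-
dependent focus/roll-off, mixed-tissue A-lines, or inter-observer
label noise. Passing the synthetic end-to-end experiment therefore
shows that the pipeline recovers a known attenuation contrast under
speckle and class imbalance — not that the published clinical accuracy
transfers to real cadaveric data.

## Preprocessing

`log_compress` maps linear intensity to 10·log₁₀(I + ε) dB with
ε = 10⁻¹² so zeros stay finite; any monotone log is equivalent up to
the later standardization. `downsample_bscan` averages non-overlapping
2×2 blocks (1024×1024 → 512×512): block averaging is chosen over
decimation because its purpose is speckle-noise suppression (variance
of unit-mean exponential speckle drops ≈ 4×, asserted by simulation);
decimation remains available behind `downsample_mode`. Feature-wise
standardization uses population statistics (zero-variance features get
unit scale), is **fitted on the training split only**, and is frozen
and persisted for validation/test/inference — the only leakage-free
protocol; per-batch rescaling at inference would leak test statistics
into the features. Output row `i` of a B-scan maps to native A-lines
`2i` and `2i+1`; predictions are duplicated back to native resolution
for rendering and native-A-line scoring.

## Classifier

A sequential 1-D CNN (`octaline.model`, numpy engine in
`octaline._nn`): three blocks of Conv1D(48 filters, kernel 21,
stride 1, length-preserving padding, ReLU) → MaxPool1D(2) →
Dropout(0.5), then Flatten (64·48 = 3072), Dense(16, ReLU, no bias) →
BatchNorm → Dropout(0.5), Dense(8, ReLU, no bias) → BatchNorm →
Dropout(0.5), and a biased Dense(2) with sigmoid outputs. The two
sigmoid units are independent scores trained against one-hot targets
with binary cross-entropy (they need not sum to one); the hard label
is their argmax. Totals: 147 266 trainable parameters, audited
layer-by-layer against the closed-form formulas in the tests.

Design choices where the design was open:

* **Two dense hidden layers (16 then 8)**, each followed by batch-norm
  and dropout. A single-hidden-layer variant remains available via
  `dense_units=(16,)`.
* **Weight initialization**: Glorot-uniform with an explicit seed;
  builds are bit-reproducible.
* **Dropout rates above 0.5** are accepted (with a warning) so the
  instability above 0.5 can be demonstrated in cross-validation, but
  0.5 is the recommended ceiling and the default.
* Optimizer default is **Adamax with step size 0.002** (its canonical
  value), β₁ = 0.9, β₂ = 0.999; Adam, Adagrad, SGD and RMSprop are
  available for the tuning sweep. The step size in force is recorded
  in the run manifest.

## Training protocol

Splits are always by whole B-scan — A-lines from one B-scan never
straddle a train/test or CV boundary. The outer split holds out
round(n·0.2) B-scans (98 → 78/20); five-fold tuning partitions the
training B-scans into folds differing by at most one (78 → validation
folds 16/16/16/15/15, remainders ≈ 62). Class imbalance is handled by
balanced weights w_c = n_total/(2·n_c) applied as per-sample loss
multipliers (not resampling), so the weighted class totals are equal.

Fitting uses shuffled mini-batches of 256, early stopping on
validation loss (default patience 10, best weights restored),
learning-rate halving after 5 stagnant epochs down to 10⁻⁵, and a hard
cap of 100 epochs. Validation loss is monitored unweighted. Every fit
returns a manifest (seed, config snapshot, epochs run, stopping
reason, final learning rate, loss curves). Hyperparameter tuning is a
coordinate-wise sweep (one parameter at a time from the default
configuration), each cell scored by the mean validation accuracy over
five freshly built models — no state carries over between folds. The
repeated-shuffle experiment reshuffles, resplits and retrains from
scratch with seed base+i and reports per-repeat and aggregate
accuracy/sensitivity/specificity; the dispersion is reported as
observed, never asserted.

## Evaluation and rendering

Lipid is the positive class; guidewire A-lines count as "other"
(the binary grouping keeps all four non-lipid categories together).
Accuracy, sensitivity and specificity follow the standard confusion-
matrix identities; a class absent from the truth marks the affected
metric as undefined (with a warning) rather than propagating NaN.
Throughput is measured (median B-scans/s over repeats, prediction
only, hardware descriptor attached) and never asserted against any
reference number — it is hardware-dependent. Ring overlays draw the
B-scan as a disk (angle 0 at 12 o'clock, clockwise; the native
358.4° span is preserved, not rescaled), the outer annulus colored by
ground truth and the inner by prediction — orange lipid, blue other.

## Problem sizes of the shipped experiments

The surrogate end-to-end experiment in `scripts/acceptance.py` uses
40 native-geometry B-scans (seeded), lipid µ = 6 vs other µ = 2 mm⁻¹,
exponential speckle, ~20% lipid A-lines, an 80/20 outer split, an
inner 80/20 validation split for callbacks, and a training budget of
at most 12 epochs with early-stopping patience 5 — sizes chosen so the
whole run completes on a single CPU while the strong-contrast task
converges well within the budget. The test suite runs the same
experiment at reduced scale (10 native B-scans) plus a null-contrast
control on a class-balanced reduced-geometry corpus (identical optics
for every class, lipid arc ≈ 179°): with no contrast to learn, a
near-converged balanced-weight model collapses toward a constant or
noise-driven prediction, and only on a balanced corpus does raw
held-out accuracy then sit at chance (0.5) — on an imbalanced corpus
it would sit at the majority fraction, making 0.5 the wrong null
reference. Any leakage or simulator artifact still pushes accuracy
above the 3-binomial-SE band.

## Known limitations

* Single-scattering, noise-floor-additive signal model; no
  depth-dependent beam profile.
* The classifier is trained and validated on synthetic contrast only;
  clinical performance claims require real annotated IV-OCT data.
* Training the full-size model in numpy on one CPU is minutes, not
  seconds; GPU-class throughput applies to inference-scale batches
  only.
* `sensitivity`/`specificity` are single-operating-point numbers
  (argmax decision); no ROC analysis is provided.
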