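"""Training protocol: B-scan-level splits, balanced class weights,
five-fold hyperparameter tuning, and the repeated-shuffle experiment.

All randomized steps are seeded and all splits operate on whole
B-scans: A-lines from one B-scan never straddle a train/test or CV
boundary, and standardization statistics are always fitted on the
training side only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.utils.class_weight import compute_class_weight

from .evaluate import classification_metrics, confusion_from_predictions
from .model import ALineCNNClassifier, ModelConfig, build_classifier
from .preprocess import Standardizer, bscan_features, downsample_labels
from .simdata import SimulatedPullback


class DataSplitError(ValueError):
    pass


@dataclass
class DatasetSplit:
    train_bscan_ids: list
    test_bscan_ids: list
    seed: int
    fold_assignments: dict | None = None

    def __post_init__(self):
        overlap = set(self.train_bscan_ids) & set(self.test_bscan_ids)
        if overlap:
            raise DataSplitError(f"B-scans on both sides of the split: {sorted(overlap)}")


@dataclass(frozen=True)
class ClassWeights:
    weight_other: float
    weight_lipid: float


@dataclass
class RunManifest:
    seed: int
    config: dict
    epochs_run: int
    stopping_reason: str
    final_lr: float
    loss_curve: list
    val_loss_curve: list


@dataclass
class TuningCell:
    param: str
    value: object
    fold_scores: list
    mean_accuracy: float
    std_accuracy: float


@dataclass
class TuningGrid:
    """Coordinate-wise candidate lists plus per-cell CV results."""

    axes: dict  # param name -> candidate list
    cells: list = field(default_factory=list)


def split_train_test(bscan_ids, test_fraction: float, seed: int) -> DatasetSplit:
    """Shuffled B-scan-level split; 98 ids at 0.2 -> 78 train / 20 test."""
    ids = list(bscan_ids)
    if not 0 < test_fraction < 1:
        raise DataSplitError("test_fraction must lie in (0, 1)")
    if len(ids) < 2:
        raise DataSplitError("need at least 2 B-scans to split")
    n_test = int(round(len(ids) * test_fraction))
    if n_test == 0 or n_test == len(ids):
        raise DataSplitError("split leaves one side empty")
    order = np.random.default_rng(seed).permutation(len(ids))
    test = [ids[i] for i in order[:n_test]]
    train = [ids[i] for i in order[n_test:]]
    return DatasetSplit(train, test, seed)


def make_cv_folds(train_ids, k: int = 5, seed: int = 0) -> dict:
    """Map each B-scan id to a fold in 1..k; fold sizes differ by <= 1."""
    ids = list(train_ids)
    if k < 2:
        raise DataSplitError("k must be >= 2")
    if k > len(ids):
        raise DataSplitError(f"k={k} exceeds the {len(ids)} training B-scans")
    order = np.random.default_rng(seed).permutation(len(ids))
    chunks = np.array_split(order, k)
    return {ids[i]: fold + 1 for fold, chunk in enumerate(chunks) for i in chunk}


def compute_class_weights(binary_labels) -> ClassWeights:
    """Balanced heuristic: w_c = n_total / (2 * n_c)."""
    y = np.asarray(binary_labels).astype(int).ravel()
    present = np.unique(y)
    if not np.array_equal(present, [0, 1]):
        raise DataSplitError(f"both classes must be present, found labels {present}")
    w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
    return ClassWeights(weight_other=float(w[0]), weight_lipid=float(w[1]))


def prepare_features(pullback: SimulatedPullback, bscan_ids,
                     std: Standardizer | None = None):
    """Stack preprocessed features for the given B-scans.

    Fits the standardizer on these B-scans when none is supplied (the
    caller passes a frozen one for validation/test data).  Returns
    (X, y_binary, row_bscan_ids, standardizer).
    """
    feats, labels, rows = [], [], []
    for bid in bscan_ids:
        f = bscan_features(pullback.bscans[bid])
        feats.append(f)
        labels.append(downsample_labels(pullback.labels[bid].binary))
        rows.append(np.full(len(f), bid))
    X_raw = np.concatenate(feats)
    y = np.concatenate(labels)
    row_ids = np.concatenate(rows)
    if std is None:
        std = Standardizer().fit(X_raw)
    return std.transform(X_raw), y, row_ids, std


def train_classifier(clf: ALineCNNClassifier, X_train, y_train, X_val, y_val,
                     weights: ClassWeights | None = None,
                     config: ModelConfig | None = None
                     ) -> tuple[ALineCNNClassifier, RunManifest]:
    """Fit with class-weighted BCE and the callback-controlled loop."""
    if config is not None:
        clf.set_params(**{k: v for k, v in config.to_dict().items()
                          if k in clf.get_params()})
        clf.dense_units = tuple(config.dense_units)
    cw = "balanced" if weights is None else (weights.weight_other, weights.weight_lipid)
    clf.fit(X_train, y_train, X_val=X_val, y_val=y_val, class_weight=cw)
    h = clf.history_
    manifest = RunManifest(
        seed=clf.seed, config=clf.model_config().to_dict(),
        epochs_run=h.epochs_run, stopping_reason=h.stopping_reason,
        final_lr=h.final_lr, loss_curve=list(h.loss),
        val_loss_curve=list(h.val_loss),
    )
    return clf, manifest


def _cv_accuracy(pullback: SimulatedPullback, train_ids, folds: dict,
                 config: ModelConfig) -> list[float]:
    """Validation accuracy per fold; a fresh model is built every fold."""
    scores = []
    for fold in sorted(set(folds.values())):
        val_ids = [i for i in train_ids if folds[i] == fold]
        fit_ids = [i for i in train_ids if folds[i] != fold]
        X_fit, y_fit, _, std = prepare_features(pullback, fit_ids)
        X_val, y_val, _, _ = prepare_features(pullback, val_ids, std)
        clf = build_classifier(config)  # fresh weights: no state carryover
        clf.fit(X_fit, y_fit, X_val=X_val, y_val=y_val)
        scores.append(float((clf.predict(X_val) == y_val).mean()))
    return scores


def tune_hyperparameters(pullback: SimulatedPullback, train_ids, grid: TuningGrid,
                         k: int = 5, seed: int = 0,
                         base_config: ModelConfig | None = None
                         ) -> tuple[ModelConfig, TuningGrid]:
    """Coordinate-wise sweep: vary one hyperparameter at a time from the
    default config; each cell's score is the mean validation accuracy
    over k freshly-trained folds.  Returns the argmax config."""
    base = base_config or ModelConfig()
    folds = make_cv_folds(train_ids, k=k, seed=seed)
    best = {}
    for param, candidates in grid.axes.items():
        results = []
        for value in candidates:
            cfg = dataclasses.replace(base, **{param: value})
            fold_scores = _cv_accuracy(pullback, train_ids, folds, cfg)
            cell = TuningCell(param, value, fold_scores,
                              float(np.mean(fold_scores)), float(np.std(fold_scores)))
            grid.cells.append(cell)
            results.append(cell)
        best[param] = max(results, key=lambda c: c.mean_accuracy).value
    return dataclasses.replace(base, **best), grid


def repeat_experiment(pullback: SimulatedPullback, n_repeats: int = 10,
                      base_seed: int = 0, config: ModelConfig | None = None,
                      test_fraction: float = 0.2, val_fraction: float = 0.2):
    """Reshuffle / resplit / retrain n times; report per-repeat metrics.

    Each repeat i uses seed base_seed + i for the split and the model,
    reserves val_fraction of the training B-scans for the callbacks,
    and evaluates pooled per-A-line metrics on the held-out test
    B-scans.  Returns (per-repeat list of dicts, aggregate dict with
    mean and std for each metric).
    """
    if n_repeats < 1:
        raise DataSplitError("n_repeats must be >= 1")
    config = config or ModelConfig()
    rows = []
    for i in range(n_repeats):
        seed = base_seed + i
        split = split_train_test(range(len(pullback)), test_fraction, seed)
        inner = split_train_test(split.train_bscan_ids, val_fraction, seed + 1)
        X_tr, y_tr, _, std = prepare_features(pullback, inner.train_bscan_ids)
        X_va, y_va, _, _ = prepare_features(pullback, inner.test_bscan_ids, std)
        X_te, y_te, _, _ = prepare_features(pullback, split.test_bscan_ids, std)
        clf = build_classifier(dataclasses.replace(config, seed=seed))
        clf, _ = train_classifier(clf, X_tr, y_tr, X_va, y_va)
        report = classification_metrics(
            confusion_from_predictions(clf.predict(X_te), y_te))
        rows.append({"repeat": i, "seed": seed,
                     "accuracy": report.accuracy,
                     "sensitivity": report.sensitivity,
                     "specificity": report.specificity})
    agg = {}
    for key in ("accuracy", "sensitivity", "specificity"):
        vals = np.array([r[key] for r in rows], dtype=float)
        agg[f"{key}_mean"] = float(vals.mean())
        agg[f"{key}_std"] = float(vals.std()) if n_repeats > 1 else 0.0
    return rows, agg
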