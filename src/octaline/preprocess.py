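"""Raw polar B-scan -> standardized A-line feature batches.

The chain is deliberately minimal: log compression to dB, 2x2 block
downsampling of the 1024x1024 native geometry to 512x512 (averaging
trades resolution for speckle-noise suppression), and feature-wise
standardization with statistics fitted on the training split only.
Each output row is one downsampled A-line of 512 depth features and
maps back to native A-lines 2i and 2i+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler

from .simdata import PolarBScan

FEATURE_LEN = 512
DEFAULT_LOG_FLOOR = 1e-12


class NotFittedError(RuntimeError):
    pass


def log_compress(linear: np.ndarray, floor_eps: float = DEFAULT_LOG_FLOOR) -> np.ndarray:
    """10*log10(I + eps): linear detector intensity to dB."""
    linear = np.asarray(linear)
    if (linear < 0).any():
        raise ValueError("linear intensity must be non-negative")
    if floor_eps <= 0:
        raise ValueError("floor_eps must be positive")
    return 10.0 * np.log10(linear + floor_eps)


def downsample_bscan(bscan: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Halve both axes; 'mean' averages 2x2 blocks, 'decimate' subsamples."""
    bscan = np.asarray(bscan)
    h, w = bscan.shape
    if h % 2 or w % 2:
        raise ValueError(f"both dimensions must be even, got {bscan.shape}")
    if mode == "mean":
        return bscan.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
    if mode == "decimate":
        return bscan[::2, ::2]
    raise ValueError("mode must be 'mean' or 'decimate'")


@dataclass
class ALineBatch:
    """Rows of standardized 512-feature A-lines with provenance.

    source_index has one (bscan_index, row_index) pair per row; output
    row i of a B-scan covers native A-lines 2i and 2i+1.
    """

    data: np.ndarray
    source_index: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.source_index = np.asarray(self.source_index)
        if self.data.ndim != 2 or self.data.shape[1] != FEATURE_LEN:
            raise ValueError(f"batch features must have length {FEATURE_LEN}")
        if len(self.source_index) != len(self.data):
            raise ValueError("one provenance record per row required")

    def __len__(self) -> int:
        return len(self.data)

    def native_alines(self, row: int) -> tuple[int, int]:
        i = int(self.source_index[row, 1])
        return 2 * i, 2 * i + 1


class Standardizer:
    """Feature-wise centering/scaling (population std, zero-var guard).

    Thin stateful wrapper over scikit-learn's StandardScaler so the
    fitted statistics can be frozen at train time, persisted, and
    re-applied verbatim at validation/test/inference time.
    """

    def __init__(self):
        self._scaler = StandardScaler()
        self.fitted = False

    @property
    def mean_(self) -> np.ndarray:
        self._require_fitted()
        return self._scaler.mean_

    @property
    def scale_(self) -> np.ndarray:
        self._require_fitted()
        return self._scaler.scale_

    def _require_fitted(self):
        if not self.fitted:
            raise NotFittedError("standardizer has not been fitted")

    def fit(self, batch: np.ndarray) -> "Standardizer":
        batch = np.asarray(batch)
        if batch.ndim != 2:
            raise ValueError("expected a 2-D (samples x features) array")
        if batch.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit a standardizer")
        self._scaler.fit(batch)
        self.fitted = True
        return self

    def transform(self, batch: np.ndarray) -> np.ndarray:
        self._require_fitted()
        batch = np.asarray(batch)
        if batch.shape[1] != self._scaler.mean_.shape[0]:
            raise ValueError(
                f"feature length {batch.shape[1]} != fitted {self._scaler.mean_.shape[0]}")
        return self._scaler.transform(batch)

    def inverse_transform(self, batch: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return self._scaler.inverse_transform(np.asarray(batch))

    def to_dict(self) -> dict:
        self._require_fitted()
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        std = cls()
        mean = np.asarray(d["mean"], dtype=float)
        scale = np.asarray(d["scale"], dtype=float)
        std._scaler.mean_ = mean
        std._scaler.scale_ = scale
        std._scaler.var_ = scale ** 2
        std._scaler.n_features_in_ = mean.shape[0]
        std._scaler.with_mean = True
        std._scaler.with_std = True
        std.fitted = True
        return std


def fit_standardizer(train_batch: np.ndarray) -> Standardizer:
    return Standardizer().fit(train_batch)


def apply_standardizer(std: Standardizer, batch: np.ndarray,
                       source_index: np.ndarray | None = None) -> ALineBatch:
    data = std.transform(batch)
    if source_index is None:
        source_index = np.stack([np.zeros(len(data), dtype=int),
                                 np.arange(len(data))], axis=1)
    return ALineBatch(data, source_index)


def bscan_features(bscan: PolarBScan, *, floor_eps: float = DEFAULT_LOG_FLOOR,
                   downsample_mode: str = "mean") -> np.ndarray:
    """Log-compress + 2x downsample one B-scan (1024x1024 -> 512x512)."""
    return downsample_bscan(log_compress(bscan.intensity, floor_eps), downsample_mode)


def bscan_to_aline_batch(bscan: PolarBScan, std: Standardizer,
                         bscan_index: int = 0, *,
                         floor_eps: float = DEFAULT_LOG_FLOOR,
                         downsample_mode: str = "mean") -> ALineBatch:
    if bscan.n_alines != 1024 or bscan.depth_px != 1024:
        raise ValueError(
            f"expected native 1024x1024 geometry, got {bscan.intensity.shape}")
    feats = bscan_features(bscan, floor_eps=floor_eps, downsample_mode=downsample_mode)
    source = np.stack([np.full(len(feats), bscan_index, dtype=int),
                       np.arange(len(feats))], axis=1)
    return apply_standardizer(std, feats, source)


def downsample_labels(binary_labels: np.ndarray) -> np.ndarray:
    """Label for each pair of native A-lines: lipid if either member is.

    Keeps labels aligned with the 2x downsampled feature rows; the
    lipid-dominant rule errs toward sensitivity at arc borders.
    """
    lab = np.asarray(binary_labels)
    if lab.ndim != 1 or len(lab) % 2:
        raise ValueError("need an even-length 1-D label vector")
    pairs = lab.reshape(-1, 2)
    return pairs.max(axis=1)


def upsample_predictions(pred: np.ndarray) -> np.ndarray:
    """Duplicate each downsampled-row prediction to its two native A-lines."""
    return np.repeat(np.asarray(pred), 2)
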