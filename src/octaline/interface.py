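"""Pullback I/O and classification-map rendering.

On disk a pullback is a directory with:

* ``bscans.tif``   — multi-page 32-bit float TIFF, one page per B-scan
                     (A-lines x depth, linear intensity),
* ``manifest.json``— geometry, seed, simulation config,
* ``labels.csv``   — bscan_index, aline_index, class5, class2[, mu].

Rendering follows the ring-overlay convention for cross-sectional
views: the B-scan is shown as a disk (angle 0 at 12 o'clock, running
clockwise), the outer annulus is colored by the visual ground truth
and the inner annulus by the automated prediction — orange for lipid,
blue for other.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .simdata import (
    CLASS_NAMES,
    ALineLabels,
    PolarBScan,
    SimulatedPullback,
    sim_config_to_dict,
)

ORANGE = np.array([1.0, 0.55, 0.0])  # lipid
BLUE = np.array([0.12, 0.35, 0.80])  # other


class FormatError(ValueError):
    pass


class VocabularyError(ValueError):
    pass


def write_pullback(pullback: SimulatedPullback, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.stack([b.intensity.astype(np.float32) for b in pullback.bscans])
    tifffile.imwrite(out / "bscans.tif", stack)
    manifest = {
        "n_bscans": len(pullback),
        "alines_per_bscan": pullback.bscans[0].n_alines,
        "depth_px": pullback.bscans[0].depth_px,
        "axial_step_um": pullback.bscans[0].axial_step_um,
        "angular_step_deg": pullback.bscans[0].angular_step_deg,
        "seed": pullback.config.seed,
        "sim_config": sim_config_to_dict(pullback.config),
        "class_names": list(CLASS_NAMES),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bscan_index", "aline_index", "class5", "class2", "mu"])
        for bi, (lab, mu) in enumerate(zip(pullback.labels, pullback.truth_mu)):
            binary = lab.binary
            for ai, (c5, c2) in enumerate(zip(lab.class5, binary)):
                writer.writerow([bi, ai, c5, "lipid" if c2 else "other", mu[ai]])
    return out


def read_pullback(path) -> tuple[list[PolarBScan], list[ALineLabels], dict]:
    """Load and cross-validate a pullback directory."""
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    stack = tifffile.imread(root / "bscans.tif")
    if stack.ndim == 2:
        stack = stack[None]
    n, a, d = stack.shape
    if n != manifest["n_bscans"] or a != manifest["alines_per_bscan"] \
            or d != manifest["depth_px"]:
        raise FormatError(
            f"TIFF geometry {stack.shape} does not match manifest "
            f"({manifest['n_bscans']}, {manifest['alines_per_bscan']}, "
            f"{manifest['depth_px']})")
    name_to_code = {name: i for i, name in enumerate(CLASS_NAMES)}
    codes = np.zeros((n, a), dtype=np.int64)
    seen = np.zeros((n, a), dtype=bool)
    with open(root / "labels.csv", newline="") as fh:
        for row_no, row in enumerate(csv.DictReader(fh), start=2):
            token = row["class5"]
            if token not in name_to_code:
                raise VocabularyError(
                    f"labels.csv row {row_no}: unknown class token {token!r}")
            bi, ai = int(row["bscan_index"]), int(row["aline_index"])
            if not (0 <= bi < n and 0 <= ai < a):
                raise FormatError(f"labels.csv row {row_no}: index out of range")
            codes[bi, ai] = name_to_code[token]
            seen[bi, ai] = True
    if not seen.all():
        raise FormatError("labels.csv does not cover every A-line")
    bscans = [PolarBScan(stack[i], axial_step_um=manifest["axial_step_um"],
                         angular_step_deg=manifest["angular_step_deg"])
              for i in range(n)]
    labels = [ALineLabels(codes[i]) for i in range(n)]
    return bscans, labels, manifest


@dataclass
class ClassificationMap:
    """Per-native-A-line truth and prediction for one B-scan."""

    bscan_id: int
    truth: np.ndarray
    prediction: np.ndarray
    angular_step_deg: float = 0.35

    def __post_init__(self):
        self.truth = np.asarray(self.truth).astype(int)
        self.prediction = np.asarray(self.prediction).astype(int)
        if self.truth.shape != self.prediction.shape or self.truth.ndim != 1:
            raise ValueError("truth and prediction must be equal-length 1-D arrays")


def _polar_lookup(shape_out: int, n_alines: int, depth_px: int,
                  angular_step_deg: float):
    """Per-Cartesian-pixel (aline, radius) indices; -1 marks background."""
    c = (shape_out - 1) / 2.0
    yy, xx = np.mgrid[0:shape_out, 0:shape_out]
    dx, dy = xx - c, yy - c
    r = np.hypot(dx, dy) / (shape_out / 2.0) * depth_px
    # angle 0 at 12 o'clock, clockwise
    theta = np.degrees(np.arctan2(dx, -dy)) % 360.0
    aline = np.rint(theta / angular_step_deg).astype(int)
    radius = np.rint(r).astype(int)
    valid = (radius < depth_px) & (aline < n_alines)
    aline[~valid] = -1
    return aline, radius, valid


def polar_to_cartesian(bscan: PolarBScan | np.ndarray, out_size: int = 512,
                       background: float = 0.0,
                       angular_step_deg: float | None = None) -> np.ndarray:
    """Nearest-neighbour disk view of a polar B-scan.

    Accepts a PolarBScan or a plain 2-D display array (A-lines x depth,
    e.g. log-compressed dB values) with an explicit angular step.  The
    native angular span (n_alines * angular_step, slightly under
    360 deg) is preserved: uncovered sectors render as background.
    """
    if out_size < 2:
        raise ValueError("out_size must be >= 2")
    if isinstance(bscan, PolarBScan):
        image = bscan.intensity
        step = bscan.angular_step_deg
    else:
        image = np.asarray(bscan)
        step = angular_step_deg if angular_step_deg is not None else 360.0 / len(image)
    n_alines, depth_px = image.shape
    aline, radius, valid = _polar_lookup(out_size, n_alines, depth_px, step)
    out = np.full((out_size, out_size), background, dtype=float)
    out[valid] = image[aline[valid], np.minimum(radius[valid], depth_px - 1)]
    return out


def render_classification_rings(cmap: ClassificationMap, base_image: np.ndarray,
                                *, outer=(0.92, 1.0), inner=(0.82, 0.90)
                                ) -> np.ndarray:
    """Overlay truth (outer annulus) and prediction (inner annulus).

    base_image is a square grayscale disk view; the result is RGB in
    [0, 1].  Ring radii are fractions of the image half-width.
    """
    img = np.asarray(base_image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("base_image must be a square 2-D array")
    n = len(cmap.truth)
    if n * cmap.angular_step_deg < 350.0:
        raise ValueError("classification map does not cover the B-scan")
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    size = img.shape[0]
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - c, yy - c
    rfrac = np.hypot(dx, dy) / (size / 2.0)
    theta = np.degrees(np.arctan2(dx, -dy)) % 360.0
    sector = np.minimum(np.rint(theta / cmap.angular_step_deg).astype(int), n - 1)
    for (r0, r1), values in ((outer, cmap.truth), (inner, cmap.prediction)):
        band = (rfrac >= r0) & (rfrac < r1)
        colors = np.where(values[sector][:, :, None] == 1, ORANGE, BLUE)
        rgb[band] = colors[band]
    return rgb
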