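"""Class-weighted binary cross-entropy on multi-unit sigmoid outputs."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


class WeightedBinaryCrossEntropy:
    """Mean over samples of w_s * mean over output units of BCE.

    Targets are one-hot rows; outputs are independent sigmoid scores
    (the two units are not constrained to sum to 1).  `sample_weight`
    carries the per-class balancing weights as per-sample multipliers.
    """

    def value(self, probs: np.ndarray, targets: np.ndarray,
              sample_weight: np.ndarray | None = None) -> float:
        p = np.clip(probs, _EPS, 1.0 - _EPS)
        per_unit = -(targets * np.log(p) + (1.0 - targets) * np.log(1.0 - p))
        per_sample = per_unit.mean(axis=1)
        if sample_weight is not None:
            per_sample = per_sample * sample_weight
        return float(per_sample.mean())

    def grad(self, probs: np.ndarray, targets: np.ndarray,
             sample_weight: np.ndarray | None = None) -> np.ndarray:
        """Gradient w.r.t. the sigmoid *probabilities*.

        Composed with the Sigmoid layer's backward pass this yields the
        usual stable (p - y) logit gradient.
        """
        p = np.clip(probs, _EPS, 1.0 - _EPS)
        n, k = probs.shape
        g = (p - targets) / (p * (1.0 - p)) / (n * k)
        if sample_weight is not None:
            g = g * sample_weight[:, None]
        return g.astype(np.float32)
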