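"""Quantitative surrogates for visual judgments: PSNR, boundary F1,
brightness statistics.

Edge quality is scored against a phantom's analytic edge mask with a pixel
tolerance: a predicted pixel counts as a true positive iff an unmatched
ground-truth pixel lies within Chebyshev distance ``tolerance_px`` (greedy
one-to-one matching without replacement, scan order, nearest candidate
first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["EdgeScore", "psnr", "edge_f1", "mean_brightness"]

#: PSNR reported for identical images (zero MSE).
PSNR_CAP_DB = 99.0


@dataclass(frozen=True)
class EdgeScore:
    precision: float
    recall: float
    f1: float
    tolerance_px: int


def psnr(reference, test) -> float:
    """Peak signal-to-noise ratio in dB for [0, 1]-range images.

    ``10 * log10(1 / MSE)``; identical images return the 99 dB cap.
    """
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(1.0 / mse), PSNR_CAP_DB)


def edge_f1(predicted, truth, tolerance_px: int = 1) -> EdgeScore:
    """Boundary precision/recall/F1 with a Chebyshev pixel tolerance.

    Matching is greedy without replacement: predicted pixels are visited in
    scan order and each claims its nearest still-unmatched truth pixel
    within the tolerance.  Conventions: two empty masks score 1.0; one empty
    mask scores 0.0 (and F1 is 0 whenever precision + recall is 0).
    At ``tolerance_px = 0`` the score is symmetric in its arguments.
    """
    if tolerance_px < 0:
        raise ValueError(f"tolerance_px must be >= 0, got {tolerance_px}")
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if pred.shape != tru.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {tru.shape}")
    p_coords = np.argwhere(pred)
    t_coords = np.argwhere(tru)
    n_pred, n_true = len(p_coords), len(t_coords)
    if n_pred == 0 and n_true == 0:
        return EdgeScore(1.0, 1.0, 1.0, tolerance_px)
    if n_pred == 0 or n_true == 0:
        return EdgeScore(0.0, 0.0, 0.0, tolerance_px)

    if tolerance_px == 0:
        tp = int(np.count_nonzero(pred & tru))
    else:
        tree = cKDTree(t_coords)
        neighborhoods = tree.query_ball_point(
            p_coords, r=tolerance_px, p=np.inf, return_sorted=True
        )
        claimed = np.zeros(n_true, dtype=bool)
        tp = 0
        for p, cand in zip(p_coords, neighborhoods):
            if not cand:
                continue
            open_cand = [i for i in cand if not claimed[i]]
            if not open_cand:
                continue
            d = np.abs(t_coords[open_cand] - p).max(axis=1)
            claimed[open_cand[int(np.argmin(d))]] = True
            tp += 1

    precision = tp / n_pred
    recall = tp / n_true
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EdgeScore(precision, recall, f1, tolerance_px)


def mean_brightness(img) -> float:
    """Arithmetic mean of all pixels — the statistic behind the parity
    (odd/even exponent) brightness comparisons."""
    return float(np.mean(np.asarray(img, dtype=np.float64)))
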