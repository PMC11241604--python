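"""Evaluation metrics: confusion-matrix rates, Dice overlap, MSE/PSNR, SSIM.

All classification rates derive from a :class:`ConfusionCounts` four-tuple;
image-quality metrics operate on equal-shape float rasters. Degenerate
denominators yield 0 with a warning rather than NaN, so downstream reports
stay finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "dice",
    "mse_psnr",
    "ssim",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification outcome counts (positive class = Abnormal)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("at least one count must be positive")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """All scalar rates derived from a binary confusion matrix.

    Returns accuracy, precision, recall (= sensitivity), specificity,
    f_score, fnr, fpr, frr and error_rate. FRR is reported as an alias of
    FNR: for a binary screen a false rejection is a missed abnormal case.
    """
    n = c.total
    accuracy = (c.tp + c.tn) / n
    precision = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    recall = _safe_ratio(c.tp, c.tp + c.fn, "recall")
    specificity = _safe_ratio(c.tn, c.tn + c.fp, "specificity")
    f_score = _safe_ratio(2 * precision * recall, precision + recall, "f_score")
    fnr = _safe_ratio(c.fn, c.fn + c.tp, "fnr")
    fpr = _safe_ratio(c.fp, c.fp + c.tn, "fpr")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "specificity": specificity,
        "f_score": f_score,
        "fnr": fnr,
        "fpr": fpr,
        "frr": fnr,
        "error_rate": 1.0 - accuracy,
    }


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean masks.

    Two empty masks are defined to agree perfectly (returns 1).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def mse_psnr(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> tuple[float, float]:
    """Mean squared error and peak signal-to-noise ratio (dB).

    ``peak`` sets the signal scale (1.0 for normalised rasters, 255 for
    8-bit). Identical images yield MSE 0 and PSNR ``math.inf``.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return 0.0, math.inf
    return mse, 10.0 * math.log10(peak * peak / mse)


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    peak: float = 1.0,
) -> float:
    """Mean structural similarity index over local windows.

    Standard luminance-contrast-structure product with Gaussian-free uniform
    windows of odd side ``window``; value in [-1, 1], 1 for identical images.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if min(ref.shape) < window:
        raise ValueError(f"image smaller than SSIM window ({window})")
    return float(
        structural_similarity(
            ref, test, win_size=window, K1=k1, K2=k2, data_range=peak,
            gaussian_weights=False,
        )
    )
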