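"""Image-fidelity metrics: IOU, MSE/PSNR, SSIM, and Betti comparison.

Conventions follow the evaluation used for the denoiser: IOU is the
Jaccard index of *black* pixel sets of binary images; PSNR uses the maximum
value of the reference image as the peak (so doubling both images leaves
the score unchanged, unlike toolboxes that fix a nominal 255); SSIM uses
Gaussian-weighted 11x11 windows with sigma 1.5 and constants
C1 = (0.01 L)^2, C2 = (0.03 L)^2 where L is the reference dynamic range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .morphology import as_image, is_binary
from .persistence import betti

__all__ = ["iou", "mse", "psnr", "ssim", "betti_compare", "ScoreReport"]

log = logging.getLogger(__name__)


def _pair(f, fhat):
    f, fhat = as_image(f), as_image(fhat)
    if f.shape != fhat.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {fhat.shape}")
    return f, fhat


def iou(f, fhat) -> float:
    """Jaccard index |A n B| / |A u B| of the black sets of two binary
    images; 1 exactly when the black sets coincide.  Two empty black sets
    are identical, so the score is defined as 1 (and logged)."""
    f, fhat = _pair(f, fhat)
    if not (is_binary(f) and is_binary(fhat)):
        raise ValueError("iou expects binary images")
    a, b = f == 0, fhat == 0
    union = np.logical_or(a, b).sum()
    if union == 0:
        log.info("iou: both black sets empty; returning 1.0")
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def mse(f, fhat) -> float:
    """Mean squared error over the pixel domain."""
    f, fhat = _pair(f, fhat)
    return float(np.mean((f.astype(float) - fhat.astype(float)) ** 2))


def psnr(f, fhat) -> float:
    """Peak signal-to-noise ratio in dB, peak = max of the reference f.

    Identical images give ``math.inf``.
    """
    f, fhat = _pair(f, fhat)
    peak = float(f.max(initial=0))
    if peak == 0:
        raise ValueError("psnr needs a reference image that is not identically zero")
    err = mse(f, fhat)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err)


def ssim(f, fhat, data_range=None) -> float:
    """Mean structural similarity over Gaussian 11x11 windows (sigma 1.5).

    ``data_range`` defaults to the dynamic range of the reference f (1.0
    for a constant reference).  Absolute values may differ slightly from
    other toolboxes with different window choices.
    """
    f, fhat = _pair(f, fhat)
    if min(f.shape) < 11:
        raise ValueError("images must be at least 11 pixels along each side")
    if data_range is None:
        data_range = float(f.max() - f.min())
        if data_range == 0:
            data_range = 1.0
    return float(
        structural_similarity(
            f.astype(np.float64),
            fhat.astype(np.float64),
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def betti_compare(f, fhat) -> tuple:
    """((beta_0, beta_1) of f, (beta_0, beta_1) of fhat)."""
    return betti(f), betti(fhat)


@dataclass(frozen=True)
class ScoreReport:
    """Bundle of scores for an (image, reference) pair."""

    iou: float
    mse: float
    psnr: float
    ssim: float
    betti_ref: tuple
    betti_out: tuple

    @classmethod
    def compute(cls, reference, output) -> "ScoreReport":
        reference, output = _pair(reference, output)
        binary = is_binary(reference) and is_binary(output)
        return cls(
            iou=iou(reference, output) if binary else float("nan"),
            mse=mse(reference, output),
            psnr=psnr(reference, output),
            ssim=ssim(reference, output),
            betti_ref=betti(reference) if binary else (None, None),
            betti_out=betti(output) if binary else (None, None),
        )

    def to_dict(self) -> dict:
        return {
            "iou": self.iou,
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "betti_ref": list(self.betti_ref),
            "betti_out": list(self.betti_out),
        }
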