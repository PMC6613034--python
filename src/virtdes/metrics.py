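"""Quantitative evaluation of decompositions.

rmse measures reconstruction error against the (normalized) ground-truth
layer; the bone suppression ratio bsr = 1 - sum((S_hat-S)^2)/sum((Y-S)^2)
equals 1 at perfect suppression and 0 when the radiograph is returned
unchanged; ssim follows the reference protocol (images rescaled to
[0, 255], 11x11 Gaussian window with sigma 1.5, K1 = 0.01, K2 = 0.03).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["EvalResult", "rmse", "bsr", "ssim", "evaluate_decomposition"]


@dataclass
class EvalResult:
    rmse_S: float
    rmse_B: float
    bsr: float
    ssim_S: float
    ssim_B: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_shapes(*imgs: np.ndarray) -> None:
    shapes = {i.shape for i in imgs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {shapes}")


def rmse(Z_hat: np.ndarray, Z: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((Z_hat - Z)^2))."""
    _check_shapes(Z_hat, Z)
    d = np.asarray(Z_hat, dtype=np.float64) - Z
    return float(np.sqrt((d * d).mean()))


def bsr(S_hat: np.ndarray, S: np.ndarray, Y: np.ndarray) -> float:
    """Bone suppression ratio 1 - sum((S_hat-S)^2)/sum((Y-S)^2)."""
    _check_shapes(S_hat, S, Y)
    den = float(((Y - S) ** 2).sum())
    if den <= 0:
        raise ValueError("no bone content: sum((Y - S)^2) is zero")
    num = float(((S_hat - S) ** 2).sum())
    return 1.0 - num / den


def _rescale255(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float64)
    return (img - lo) / (hi - lo) * 255.0


def ssim(A: np.ndarray, B: np.ndarray) -> float:
    """Mean structural similarity after per-image min-max rescale to
    [0, 255]; Gaussian-weighted 11x11 window, sigma 1.5, L = 255."""
    _check_shapes(A, B)
    return float(structural_similarity(
        _rescale255(A), _rescale255(B), gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=255.0))


def evaluate_decomposition(S_hat: np.ndarray, B_hat: np.ndarray,
                           S: np.ndarray, B: np.ndarray,
                           Y: Optional[np.ndarray] = None) -> EvalResult:
    """Bundle of all measures; Y defaults to S + B (the additive model)."""
    if Y is None:
        Y = S + B
    return EvalResult(rmse_S=rmse(S_hat, S), rmse_B=rmse(B_hat, B),
                      bsr=bsr(S_hat, S, Y), ssim_S=ssim(S_hat, S),
                      ssim_B=ssim(B_hat, B))
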