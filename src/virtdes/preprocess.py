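"""Guided-filter base/detail decomposition and contrast normalization.

Radiographs from different machines and patients differ in density and
contrast.  Each image is split into a smooth base layer (self-guided filter
with a large radius) and a detail layer, and the detail layer is
standardized to zero mean / unit variance.  The soft-tissue and bone ground
truths are normalized with the *same* base layer and detail statistics, so
the additive relation Y = S + B carries over exactly to the normalized
domain, and the decomposition can later be mapped back by compensating the
base layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "NormalizationContext", "guided_filter", "default_radius",
    "normalize_radiograph", "normalize_targets", "denormalize",
]


@dataclass
class NormalizationContext:
    """Base layer and detail statistics needed to normalize and to invert."""

    Y0: np.ndarray      # base layer of the radiograph
    mu_d: float         # mean of the detail layer Y - Y0
    sigma_d: float      # std of the detail layer

    def validate(self) -> None:
        if not self.sigma_d > 0:
            raise ValueError("sigma_d must be positive")

    def to_dict(self) -> dict:
        return {"mu_d": self.mu_d, "sigma_d": self.sigma_d}


def _box(img: np.ndarray, radius: int) -> np.ndarray:
    # box mean over windows of side 2r+1 with replicate padding
    return uniform_filter(img, size=2 * radius + 1, mode="nearest")


def guided_filter(inp: np.ndarray, guide: np.ndarray, radius: int,
                  eps: float) -> np.ndarray:
    """Edge-preserving smoothing of ``inp`` steered by ``guide``.

    In every box window w of side 2*radius+1 a linear model
    q = a*guide + b is fitted: a = cov_w(guide, inp) / (var_w(guide) + eps),
    b = mean_w(inp) - a*mean_w(guide); the output at a pixel averages the
    (a, b) of all windows containing it.
    """
    if inp.shape != guide.shape:
        raise ValueError("input and guide must share a shape")
    if radius < 1 or eps <= 0:
        raise ValueError("radius must be >= 1 and eps > 0")
    inp = np.asarray(inp, dtype=np.float64)
    guide = np.asarray(guide, dtype=np.float64)
    mI = _box(guide, radius)
    mP = _box(inp, radius)
    corr_II = _box(guide * guide, radius)
    corr_IP = _box(guide * inp, radius)
    var_I = corr_II - mI * mI
    cov_IP = corr_IP - mI * mP
    a = cov_IP / (var_I + eps)
    b = mP - a * mI
    return _box(a, radius) * guide + _box(b, radius)


def default_radius(image_size: int, radius_at_512: int = 40) -> int:
    """Base-layer filter radius, proportional to the working image size
    (the reference radius is stated for 512 x 512 images)."""
    return max(1, round(radius_at_512 * image_size / 512))


def normalize_radiograph(Y: np.ndarray, radius: int, eps: float
                         ) -> Tuple[np.ndarray, NormalizationContext]:
    """Split Y into base + detail and standardize the detail layer.

    Returns (Y_n, ctx) with mean(Y_n) = 0, std(Y_n) = 1.  A constant detail
    layer (sigma_d = 0) is a degenerate input and raises.
    """
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    Y0 = guided_filter(Y, Y, radius, eps)
    Yd = Y - Y0
    mu_d = float(Yd.mean())
    sigma_d = float(Yd.std())
    if sigma_d <= 0:
        raise ValueError("degenerate input: constant detail layer")
    return (Yd - mu_d) / sigma_d, NormalizationContext(Y0=Y0, mu_d=mu_d,
                                                       sigma_d=sigma_d)


def normalize_targets(S: np.ndarray, B: np.ndarray,
                      ctx: NormalizationContext
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Normalize ground-truth layers consistently with the radiograph:
    S_n = (S - Y0 - mu_S)/sigma_d, B_n = (B - mu_B)/sigma_d.  When
    Y = S + B, additivity is preserved (mu_d = mu_S + mu_B)."""
    ctx.validate()
    if S.shape != ctx.Y0.shape or B.shape != ctx.Y0.shape:
        raise ValueError("shape mismatch with normalization context")
    mu_S = float((S - ctx.Y0).mean())
    mu_B = float(B.mean())
    S_n = (S - ctx.Y0 - mu_S) / ctx.sigma_d
    B_n = (B - mu_B) / ctx.sigma_d
    return S_n, B_n


def denormalize(S_n: np.ndarray, B_n: np.ndarray,
                ctx: NormalizationContext
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Invert the normalization: S = sigma_d*S_n + Y0 + mu_d,
    B = sigma_d*B_n.  Whenever S_n + B_n = Y_n the outputs sum to Y
    exactly (the bone DC offset, unobservable from Y alone, is folded into
    the soft-tissue image)."""
    ctx.validate()
    S = ctx.sigma_d * S_n + ctx.Y0 + ctx.mu_d
    B = ctx.sigma_d * B_n
    return S, B
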