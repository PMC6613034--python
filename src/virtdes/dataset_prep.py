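"""Preparation of raw DES outputs into additive training triplets.

The soft-tissue and bone images produced by a two-exposure DES system go
through vendor postprocessing, so the raw trio (Y, S0, B0) does not satisfy
Y = S0 + B0.  The bone component actually present in Y is recovered by
transferring Y's gradients along the bone image's gradient directions
(a cross projection tensor) and integrating the resulting field in the
least-squares sense; the soft tissue is then Y - B, making the triplet
additive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn

from .phantom import DesTriplet

__all__ = [
    "GradientField", "image_gradient", "cross_projection_transfer",
    "integrate_gradient", "build_training_triplet", "standardize_geometry",
]


@dataclass
class GradientField:
    gx: np.ndarray   # horizontal derivative (along columns)
    gy: np.ndarray   # vertical derivative (along rows)

    def validate(self) -> None:
        if self.gx.shape != self.gy.shape:
            raise ValueError("gx and gy must share a shape")
        if not (np.all(np.isfinite(self.gx)) and np.all(np.isfinite(self.gy))):
            raise ValueError("gradient field contains non-finite values")


def image_gradient(img: np.ndarray) -> GradientField:
    """Central-difference gradient with replicated borders."""
    p = np.pad(img, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return GradientField(gx=gx, gy=gy)


def cross_projection_transfer(Y: np.ndarray, B0: np.ndarray,
                              eps: float = 1e-3) -> GradientField:
    """Project Y's gradient onto the local gradient direction of the guide B0.

    With u = grad(B0) / (|grad(B0)| + eps), returns G = (u . grad Y) u.
    Where the guide is flat (|grad B0| below a floor tau = 1e-3 of its 99th
    percentile) G is zeroed, suppressing noise amplification.
    """
    if Y.shape != B0.shape:
        raise ValueError("Y and B0 must share a shape")
    if eps <= 0:
        raise ValueError("eps must be positive")
    gY = image_gradient(Y)
    gB = image_gradient(B0)
    mag = np.hypot(gB.gx, gB.gy)
    ux = gB.gx / (mag + eps)
    uy = gB.gy / (mag + eps)
    dot = ux * gY.gx + uy * gY.gy
    tau = 1e-3 * np.percentile(mag, 99)
    keep = mag >= max(tau, np.finfo(float).tiny)
    return GradientField(gx=np.where(keep, dot * ux, 0.0),
                         gy=np.where(keep, dot * uy, 0.0))


def integrate_gradient(G: GradientField, mean: float = 0.0) -> np.ndarray:
    """Least-squares 2D integration of a (possibly non-integrable) field.

    Minimizes ||D B - G||^2 where D is the forward-difference gradient with
    Neumann boundaries, i.e. solves the Poisson equation lap B = div G; the
    free constant is fixed so that mean(B) equals ``mean``.  The normal
    equations are diagonalized by a type-II DCT.
    """
    G.validate()
    H, W = G.gx.shape
    gx = G.gx[:, : W - 1]
    gy = G.gy[: H - 1, :]
    rhs = np.zeros((H, W))
    rhs[:, :-1] -= gx
    rhs[:, 1:] += gx
    rhs[:-1, :] -= gy
    rhs[1:, :] += gy          # rhs = D^T g; normal eqs: (D^T D) B = D^T g
    coef = dctn(rhs, type=2, norm="ortho")
    ky = 2.0 - 2.0 * np.cos(np.pi * np.arange(H) / H)
    kx = 2.0 - 2.0 * np.cos(np.pi * np.arange(W) / W)
    denom = ky[:, None] + kx[None, :]
    denom[0, 0] = 1.0
    coef = coef / denom
    coef[0, 0] = 0.0
    B = idctn(coef, type=2, norm="ortho")
    return B + (mean - B.mean())


def build_training_triplet(Y: np.ndarray, S0: np.ndarray,
                           B0: np.ndarray, eps: float = 1e-3,
                           trip_id: str = "prepared") -> DesTriplet:
    """Build an additive (Y, S, B) triplet from a raw DES trio.

    B is the 2D integral of Y's gradients projected along B0's gradient
    directions, offset so its 1st percentile is zero (bone attenuation is
    physically non-negative); S = Y - B, so Y = S + B exactly.  S0 is
    accepted for interface completeness: the bone estimate depends only on
    Y and the bone guide.
    """
    if not (Y.shape == S0.shape == B0.shape):
        raise ValueError("Y, S0, B0 must be co-registered with equal shapes")
    G = cross_projection_transfer(Y, B0, eps=eps)
    B = integrate_gradient(G, mean=0.0)
    B = B - np.percentile(B, 1)
    S = Y - B
    trip = DesTriplet(Y=Y.astype(np.float64), S=S, B=B, id=trip_id)
    trip.validate()
    return trip


def standardize_geometry(img: np.ndarray, scale: float, crop: int) -> np.ndarray:
    """Bilinear rescale by ``scale`` then center-crop to ``crop`` x ``crop``."""
    from skimage.transform import rescale

    if scale != 1.0:
        img = rescale(img, scale, order=1, anti_aliasing=scale < 1.0,
                      preserve_range=True)
    h, w = img.shape
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} exceeds scaled size {img.shape}")
    y0 = (h - crop) // 2
    x0 = (w - crop) // 2
    return np.ascontiguousarray(img[y0: y0 + crop, x0: x0 + crop])
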