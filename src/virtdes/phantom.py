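"""Synthetic DES phantom generator.

Real dual-energy subtraction (DES) training data are triplets (Y, S, B):
a chest radiograph Y, a soft-tissue image S and a bone image B, prepared so
that Y = S + B holds exactly.  This module emulates such triplets: S is a
smooth positive lung-field/mediastinum profile with a low-frequency random
texture (and an optional bright nodule disc), B is a sum of anti-aliased
curved bands emulating posterior ribs (and optionally clavicles), and
Y = S + B by construction.  Inter-subject variation is produced by jittering
the geometric parameters.

Everything is generated in a normalized float range [0, 1] before any
intensity scaling, which decouples geometry from the 16-bit I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import List, Optional

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .config import PhantomParams

__all__ = ["DesTriplet", "generate_phantom_triplet", "generate_phantom_database"]


@dataclass
class DesTriplet:
    """Co-registered (Y, S, B) image trio with the additive constraint."""

    Y: np.ndarray
    S: np.ndarray
    B: np.ndarray
    pixel_spacing: float = 0.7   # mm/px at the working scale (metadata only)
    id: str = "phantom"
    params: Optional[dict] = None
    # optional motion-artifact pair: bone layer translated, S_art = Y - B_art
    S_art: Optional[np.ndarray] = None
    B_art: Optional[np.ndarray] = None

    def validate(self) -> None:
        if not (self.Y.shape == self.S.shape == self.B.shape):
            raise ValueError("Y, S, B must share a shape")
        for name in ("Y", "S", "B"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")


def _soft_tissue(params: PhantomParams, rng: np.random.Generator,
                 yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    n = params.image_size
    g = params.gain
    w = 0.16 * n * params.width_factor
    cy, cx_l, cx_r = 0.50 * n, 0.30 * n, 0.70 * n
    wy = 0.26 * n

    S = np.full((n, n), 0.45, dtype=np.float64)
    # mediastinum ridge
    S += 0.25 * np.exp(-((xx - 0.5 * n) ** 2) / (2 * (0.08 * n) ** 2))
    # lung-field depressions (radiolucent lungs)
    for cx in (cx_l, cx_r):
        S -= 0.18 * np.exp(-((xx - cx) ** 2 / (2 * w ** 2)
                             + (yy - cy) ** 2 / (2 * wy ** 2)))
    # diaphragm brightening toward the bottom
    S += 0.10 / (1.0 + np.exp(-(yy - 0.85 * n) / (0.03 * n)))
    # smooth stochastic texture of the stated correlation length
    tex = rng.standard_normal((n, n))
    tex = gaussian_filter(tex, params.soft_texture_scale, mode="nearest")
    sd = tex.std()
    if sd > 0:
        S += 0.03 * tex / sd
    if params.nodule_spec is not None:
        (ny, nx), rad, contrast = params.nodule_spec
        r2 = (yy - ny) ** 2 + (xx - nx) ** 2
        S += contrast * np.exp(-2.0 * r2 / (rad ** 2 + 1e-12))
    return np.clip(S * g, 1e-3, None)


def _band(B: np.ndarray, xs: np.ndarray, ycurve: np.ndarray,
          yy_col: np.ndarray, sigma: float, amp: float) -> None:
    """Accumulate a curved band with a Gaussian vertical cross-profile.

    For shallow arcs the vertical distance to the center-line is a good
    proxy for the perpendicular distance; it keeps rasterization exact and
    parallel ribs exactly non-merging.
    """
    prof = amp * np.exp(-((yy_col[:, None] - ycurve[None, :]) ** 2)
                        / (2.0 * sigma ** 2))
    B[:, xs] += prof


def _bone(params: PhantomParams, yy_col: np.ndarray) -> np.ndarray:
    n = params.image_size
    B = np.zeros((n, n), dtype=np.float64)
    if params.rib_contrast <= 0:
        return B
    sigma = params.rib_thickness / 2.0
    amp = params.rib_contrast * params.gain
    w = 0.16 * n * params.width_factor
    top, bot = 0.18 * n, 0.80 * n
    spacing = (bot - top) / max(params.n_ribs, 1) * params.spacing_factor
    sag = params.rib_curvature * params.curvature_factor * spacing

    for cx in (0.30 * n, 0.70 * n):
        x0 = int(max(np.ceil(cx - w), 0))
        x1 = int(min(np.floor(cx + w), n - 1))
        xs = np.arange(x0, x1 + 1)
        u = (xs - cx) / w                      # in [-1, 1]
        for k in range(params.n_ribs):
            yk = top + spacing * (k + 0.5)
            ycurve = yk + sag * u ** 2         # downward-bowed posterior rib
            _band(B, xs, ycurve, yy_col, sigma, amp)
        if params.clavicle:
            yk = 0.12 * n
            ycurve = yk - 0.5 * sag * u ** 2   # upward-bowed clavicle
            _band(B, xs, ycurve, yy_col, 1.3 * sigma, 1.2 * amp)
    return B


def generate_phantom_triplet(params: PhantomParams) -> DesTriplet:
    """Generate one synthetic DES triplet; deterministic given ``params.seed``.

    Noise (if any) is split 70/30 in amplitude between the soft-tissue and
    bone layers *before* summation, so Y = S + B stays exact.  If
    ``motion_shift`` > 0 an auxiliary pair (S_art, B_art) with the bone layer
    translated is attached while Y remains the sum of the unshifted layers.
    """
    params.validate()
    n = params.image_size
    rng = np.random.default_rng(params.seed)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    S = _soft_tissue(params, rng, yy, xx)
    B = _bone(params, yy[:, 0])

    if params.noise_sigma > 0:
        S = S + 0.7 * params.noise_sigma * rng.standard_normal((n, n))
        B = B + 0.3 * params.noise_sigma * rng.standard_normal((n, n))

    Y = S + B
    trip = DesTriplet(Y=Y, S=S, B=B, id=f"phantom_{params.seed}",
                      params=asdict(params))
    if params.motion_shift > 0:
        B_art = nd_shift(B, (params.motion_shift, 0.0), order=1,
                         mode="nearest")
        trip.B_art = B_art
        trip.S_art = Y - B_art
    trip.validate()
    return trip


def generate_phantom_database(n: int, base_params: PhantomParams,
                              variation: float, seed: int) -> List[DesTriplet]:
    """Generate ``n`` triplets with geometric jitter of relative amplitude
    ``variation`` (rib spacing, lung-field width, curvature, global gain
    each scaled by an independent factor ~ U[1-variation, 1+variation]).

    Per-case seeds are derived from ``seed``, so the database is fully
    reproducible and each case is itself reproducible from its stored params.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= variation < 1.0):
        raise ValueError("variation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    out: List[DesTriplet] = []
    for i in range(n):
        if variation > 0:
            f = rng.uniform(1.0 - variation, 1.0 + variation, size=4)
        else:
            f = np.ones(4)
        p = replace(base_params, seed=int(case_seeds[i]),
                    spacing_factor=base_params.spacing_factor * float(f[0]),
                    width_factor=base_params.width_factor * float(f[1]),
                    curvature_factor=base_params.curvature_factor * float(f[2]),
                    gain=base_params.gain * float(f[3]))
        trip = generate_phantom_triplet(p)
        trip.id = f"case_{i:04d}"
        out.append(trip)
    return out
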