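"""Dense local descriptors of normalized radiographs.

Every pixel is described by the concatenation of three blocks:

* the raw 7x7 patch around it (49 dims) — normalized intensity context;
* the responses of a 50-filter bank (first/second oriented Gaussian
  derivatives at 6 orientations x 4 scales, plus a Laplacian of Gaussian
  and a Gaussian), jointly Weber-normalized per pixel — texture at small
  and large scales;
* a dense SIFT descriptor over the 16x16 neighborhood (4x4 cells, 8
  orientation bins, 128 dims) — local structure and context.

The combined 227-dim (49 + 50 + 128) descriptors are balanced block-wise
to equal mean per-dimension variance and reduced (default to 60 dims) by
PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import correlate1d
from scipy.signal import fftconvolve

BLOCK_LAYOUT = (49, 50, 128)   # raw patch, filter bank, dense SIFT
COMBINED_DIM = sum(BLOCK_LAYOUT)

__all__ = [
    "FilterBank", "DescriptorField", "PcaProjection", "build_filter_bank",
    "compute_dense_descriptors", "fit_block_weights", "fit_descriptor_pca",
    "project_descriptors", "sample_vectors", "BLOCK_LAYOUT", "COMBINED_DIM",
]


@dataclass
class FilterBank:
    kernels: List[np.ndarray]
    scales: np.ndarray

    def validate(self) -> None:
        assert len(self.kernels) == 50


@dataclass
class DescriptorField:
    """Per-pixel descriptors, shape (H, W, d)."""

    vectors: np.ndarray
    block_layout: Optional[Tuple[int, int, int]] = None

    @property
    def dim(self) -> int:
        return self.vectors.shape[-1]


@dataclass
class PcaProjection:
    mean_vector: np.ndarray          # (d,)
    basis: np.ndarray                # (d, k), orthonormal columns
    explained_variance_fraction: float


# ---------------------------------------------------------------- filter bank

def _aniso_gauss_deriv(scale: float, theta: float, order: int) -> np.ndarray:
    """Oriented anisotropic Gaussian derivative kernel.

    The long (smoothing) axis has sigma = scale, the derivative axis
    sigma = scale/3 (3:1 elongation); support truncated at 2.5 sigma,
    capped at a 129x129 kernel.
    """
    sl = scale
    ss = scale / 3.0
    r = int(min(np.ceil(2.5 * sl), 64))
    y, x = np.mgrid[-r: r + 1, -r: r + 1].astype(np.float64)
    xl = x * np.cos(theta) + y * np.sin(theta)    # long axis
    xs = -x * np.sin(theta) + y * np.cos(theta)   # derivative axis
    g = np.exp(-(xl ** 2) / (2 * sl ** 2) - (xs ** 2) / (2 * ss ** 2))
    if order == 1:
        k = -xs / ss ** 2 * g
    else:
        k = (xs ** 2 - ss ** 2) / ss ** 4 * g
    k = k - k.mean()                               # exact zero mean
    return k / np.abs(k).sum()


def build_filter_bank() -> FilterBank:
    """48 oriented derivative filters (6 orientations x 4 scales x 2 orders)
    plus one Laplacian of Gaussian and one Gaussian; scales geometrically
    spaced in [1, 32] pixels."""
    scales = np.geomspace(1.0, 32.0, 4)
    kernels: List[np.ndarray] = []
    for order in (1, 2):
        for s in scales:
            for k in range(6):
                kernels.append(_aniso_gauss_deriv(s, k * np.pi / 6.0, order))
    s = scales[1]
    r = int(np.ceil(3 * s))
    y, x = np.mgrid[-r: r + 1, -r: r + 1].astype(np.float64)
    g = np.exp(-(x ** 2 + y ** 2) / (2 * s ** 2))
    log = (x ** 2 + y ** 2 - 2 * s ** 2) / s ** 4 * g
    log = log - log.mean()
    kernels.append(log / np.abs(log).sum())
    kernels.append(g / g.sum())                    # unit-sum Gaussian
    bank = FilterBank(kernels=kernels, scales=scales)
    bank.validate()
    return bank


def _correlate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    r = kernel.shape[0] // 2
    padded = np.pad(img, r, mode="edge")
    return fftconvolve(padded, kernel[::-1, ::-1], mode="valid")


def _bank_ffts(bank: FilterBank, shape, pad: int, fshape):
    """Per-shape cache of the kernels' FFTs (kernels are image-independent,
    so the bank is applied with one forward FFT per image)."""
    cache = getattr(bank, "_fft_cache", None)
    key = (shape, fshape)
    if cache is not None and cache[0] == key:
        return cache[1]
    from scipy.fft import rfft2

    ffts = []
    for k in bank.kernels:
        buf = np.zeros(fshape)
        kf = k[::-1, ::-1]
        buf[: kf.shape[0], : kf.shape[1]] = kf
        ffts.append(rfft2(buf))
    bank._fft_cache = (key, ffts)
    return ffts


def _filter_bank_block(I: np.ndarray, bank: FilterBank,
                       weber_const: float) -> np.ndarray:
    from scipy.fft import irfft2, next_fast_len, rfft2

    H, W = I.shape
    radii = [k.shape[0] // 2 for k in bank.kernels]
    pad = max(radii)
    fshape = (next_fast_len(H + 4 * pad), next_fast_len(W + 4 * pad))
    ffts = _bank_ffts(bank, (H, W), pad, fshape)
    Af = rfft2(np.pad(I, pad, mode="edge"), s=fshape)
    resp = np.empty((H, W, len(bank.kernels)))
    for i, (kf, r) in enumerate(zip(ffts, radii)):
        full = irfft2(Af * kf, s=fshape)
        resp[:, :, i] = full[pad + r: pad + r + H, pad + r: pad + r + W]
    norm = np.linalg.norm(resp, axis=-1)
    factor = np.where(norm > 0, np.log1p(norm / weber_const)
                      / np.where(norm > 0, norm, 1.0), 0.0)
    return resp * factor[..., None]


# ----------------------------------------------------------------- dense SIFT

_SIFT_CELLS = (-6, -2, 2, 6)     # cell-center offsets in the 16x16 block
_SIFT_BINS = 8


def _dense_sift(I: np.ndarray) -> np.ndarray:
    H, W = I.shape
    p = np.pad(I, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)

    # soft orientation binning
    b = ang / (2 * np.pi / _SIFT_BINS)
    b0 = np.floor(b).astype(np.intp) % _SIFT_BINS
    f = b - np.floor(b)
    bins = np.zeros((_SIFT_BINS, H, W))
    for k in range(_SIFT_BINS):
        bins[k][b0 == k] += (mag * (1 - f))[b0 == k]
        k1 = (k - 1) % _SIFT_BINS
        bins[k][b0 == k1] += (mag * f)[b0 == k1]

    # spatial pooling: triangular (bilinear) kernel of the 4-px cell width
    tri = np.array([1, 2, 3, 4, 3, 2, 1], dtype=np.float64) / 4.0
    pooled = correlate1d(bins, tri, axis=1, mode="nearest")
    pooled = correlate1d(pooled, tri, axis=2, mode="nearest")

    pad = 8
    pooled = np.pad(pooled, ((0, 0), (pad, pad), (pad, pad)), mode="edge")
    desc = np.empty((H, W, 16, _SIFT_BINS))
    idx = 0
    sigma_block = 8.0
    for cy in _SIFT_CELLS:
        for cx in _SIFT_CELLS:
            gw = np.exp(-(cy ** 2 + cx ** 2) / (2 * sigma_block ** 2))
            sl = pooled[:, pad + cy: pad + cy + H, pad + cx: pad + cx + W]
            desc[:, :, idx, :] = gw * np.moveaxis(sl, 0, -1)
            idx += 1
    desc = desc.reshape(H, W, 16 * _SIFT_BINS)
    nrm = np.linalg.norm(desc, axis=-1, keepdims=True)
    desc = np.where(nrm > 1e-12, desc / np.where(nrm > 0, nrm, 1.0), 0.0)
    desc = np.minimum(desc, 0.2)
    nrm = np.linalg.norm(desc, axis=-1, keepdims=True)
    return np.where(nrm > 1e-12, desc / np.where(nrm > 0, nrm, 1.0), 0.0)


# ------------------------------------------------------------------- combined

def compute_dense_descriptors(I: np.ndarray,
                              bank: Optional[FilterBank] = None,
                              weights: Sequence[float] = (1.0, 1.0, 1.0),
                              raw_patch: int = 7,
                              weber_const: float = 0.03) -> DescriptorField:
    """Combined 277-dim per-pixel descriptor of a normalized image, with
    the three blocks scaled by ``weights`` before concatenation."""
    I = np.asarray(I, dtype=np.float64)
    if not np.all(np.isfinite(I)):
        raise ValueError("input image contains non-finite values")
    if bank is None:
        bank = build_filter_bank()
    r = raw_patch // 2
    padded = np.pad(I, r, mode="edge")
    raw = sliding_window_view(padded, (raw_patch, raw_patch))
    raw = raw.reshape(I.shape[0], I.shape[1], raw_patch * raw_patch)
    fb = _filter_bank_block(I, bank, weber_const)
    sift = _dense_sift(I)
    vec = np.concatenate([weights[0] * raw, weights[1] * fb,
                          weights[2] * sift], axis=-1)
    return DescriptorField(vectors=vec, block_layout=BLOCK_LAYOUT)


def sample_vectors(field: DescriptorField, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` random pixel descriptors (with replacement-free draw)."""
    H, W, d = field.vectors.shape
    idx = rng.choice(H * W, size=min(n, H * W), replace=False)
    return field.vectors.reshape(H * W, d)[idx]


def fit_block_weights(samples: Union[np.ndarray, List[DescriptorField]],
                      min_samples: int = 1000) -> np.ndarray:
    """Per-block scale factors equalizing mean per-dimension variance.

    ``samples`` is an (n, 277) array of unweighted descriptors (or a list
    of fields, which are flattened).  Returns factors proportional to
    1/sqrt(mean variance of the block), normalized so their product-free
    reference (the first block) has weight relative to the common target
    variance (the mean of the three block variances).
    """
    if isinstance(samples, list):
        samples = np.concatenate(
            [f.vectors.reshape(-1, f.dim) for f in samples], axis=0)
    samples = np.asarray(samples, dtype=np.float64)
    if samples.shape[0] < min_samples:
        raise ValueError(f"need >= {min_samples} sampled vectors")
    splits = np.cumsum(BLOCK_LAYOUT)[:-1]
    blocks = np.split(samples, splits, axis=1)
    v = np.array([b.var(axis=0).mean() for b in blocks])
    if np.any(v <= 0):
        raise ValueError("zero-variance descriptor block")
    target = v.mean()
    return np.sqrt(target / v)


def fit_descriptor_pca(samples: np.ndarray,
                       target_dim: int = 60) -> PcaProjection:
    """Mean-centered PCA of (block-weighted) descriptor samples."""
    from sklearn.decomposition import PCA

    samples = np.asarray(samples, dtype=np.float64)
    n, d = samples.shape
    if n < target_dim:
        raise ValueError("need at least target_dim samples")
    k = min(target_dim, n, d)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(samples)
    frac = float(pca.explained_variance_ratio_.sum())
    return PcaProjection(mean_vector=pca.mean_,
                         basis=pca.components_.T.copy(),
                         explained_variance_fraction=frac)


def project_descriptors(field: DescriptorField,
                        proj: PcaProjection) -> DescriptorField:
    if field.dim != proj.mean_vector.shape[0]:
        raise ValueError("descriptor/projection dimension mismatch")
    H, W, d = field.vectors.shape
    flat = field.vectors.reshape(H * W, d) - proj.mean_vector
    out = flat @ proj.basis
    return DescriptorField(vectors=out.reshape(H, W, -1))
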