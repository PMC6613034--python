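"""Bag-of-words retrieval of exemplar radiographs.

Projected dense descriptors are vector-quantized against a k-means
codebook; an image is represented by the concatenated visual-word count
histograms of the whole image (level 0) and its four quadrants (level 1),
and images are compared by histogram intersection — an approximate number
of descriptor matches at the two spatial levels.  The top-M most similar
database radiographs become the exemplars for decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .descriptors import DescriptorField

__all__ = [
    "Codebook", "SpatialPyramidHist", "fit_codebook", "quantize_field",
    "spatial_pyramid_rep", "histogram_intersection", "select_exemplars",
]


@dataclass
class Codebook:
    centers: np.ndarray    # (K, d)

    @property
    def K(self) -> int:
        return self.centers.shape[0]


@dataclass
class SpatialPyramidHist:
    """Concatenated counts of length 5K: level 0 then the four quadrants
    (top-left, top-right, bottom-left, bottom-right)."""

    H: np.ndarray
    region_layout: Tuple[Tuple[int, int, int, int], ...] = ()


def fit_codebook(samples: np.ndarray, K: int, seed: int = 0) -> Codebook:
    """k-means visual-word codebook; deterministic given ``seed``."""
    from sklearn.cluster import KMeans

    samples = np.asarray(samples, dtype=np.float64)
    if K > samples.shape[0]:
        raise ValueError("K exceeds the number of samples")
    if K < 2:
        raise ValueError("K must be >= 2")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    km.fit(samples)
    return Codebook(centers=km.cluster_centers_.copy())


def quantize_field(field: DescriptorField, codebook: Codebook) -> np.ndarray:
    """Per-pixel nearest center (Euclidean; ties -> lowest index)."""
    if field.dim != codebook.centers.shape[1]:
        raise ValueError("descriptor/codebook dimension mismatch")
    H, W, d = field.vectors.shape
    X = field.vectors.reshape(H * W, d)
    C = codebook.centers
    d2 = (X * X).sum(1)[:, None] - 2.0 * X @ C.T + (C * C).sum(1)[None, :]
    return np.argmin(d2, axis=1).reshape(H, W).astype(np.int32)


def _hist(words: np.ndarray, K: int) -> np.ndarray:
    return np.bincount(words.ravel(), minlength=K).astype(np.float64)


def spatial_pyramid_rep(words: np.ndarray, K: int) -> SpatialPyramidHist:
    """Level-0 + four-quadrant word histograms (quadrants split at
    floor(h/2), floor(w/2))."""
    if words.min() < 0 or words.max() >= K:
        raise ValueError("word index out of range")
    h, w = words.shape
    hy, hx = h // 2, w // 2
    regions = ((0, 0, h, w), (0, 0, hy, hx), (0, hx, hy, w),
               (hy, 0, h, hx), (hy, hx, h, w))
    parts = [_hist(words[y0:y1, x0:x1], K) for (y0, x0, y1, x1) in regions]
    return SpatialPyramidHist(H=np.concatenate(parts), region_layout=regions)


def histogram_intersection(HA: SpatialPyramidHist,
                           HB: SpatialPyramidHist) -> float:
    if HA.H.shape != HB.H.shape:
        raise ValueError("histogram length mismatch")
    return float(np.minimum(HA.H, HB.H).sum())


def select_exemplars(query: SpatialPyramidHist,
                     database: Sequence[Tuple[str, SpatialPyramidHist]],
                     M: int) -> List[str]:
    """Ids of the M most similar database images, descending similarity
    (ties broken by lexicographic id)."""
    if len(database) == 0:
        raise ValueError("empty database")
    if M > len(database):
        raise ValueError("M exceeds database size")
    sims = [(-histogram_intersection(query, h), tid) for tid, h in database]
    sims.sort()
    return [tid for _, tid in sims[:M]]
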