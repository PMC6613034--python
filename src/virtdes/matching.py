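"""Hierarchical dense matching between a radiograph and an exemplar.

Correspondences are solved coarse-to-fine: nonoverlapping source grid
cells are matched to overlapping target cells by bag-of-words histogram
intersection inside a spatial window (chest radiographs share a spatial
layout, so anatomically corresponding content stays nearby), and the
broadcast cell field — randomly perturbed per pixel — seeds PatchMatch-style
refinement: alternating forward/backward propagation scans with locally
randomized search, accepting candidates only if they strictly lower the
per-pixel descriptor distance.  Total matching cost is therefore
non-increasing and the result is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import GridMatchConfig
from .descriptors import DescriptorField

__all__ = [
    "CorrespondenceField", "grid_match", "refine_field",
    "hierarchical_dense_match", "field_total_variation", "random_field",
    "flow_to_rgb", "export_field",
]


@dataclass
class CorrespondenceField:
    """Per-pixel displacement T (dy, dx): source pixel x matches target
    pixel x + T(x); ``cost`` is the descriptor distance of that match."""

    T: np.ndarray                   # (H, W, 2) int32
    cost: np.ndarray                # (H, W) float64

    def validate(self, shape=None) -> None:
        H, W = self.T.shape[:2]
        ys = np.arange(H)[:, None] + self.T[:, :, 0]
        xs = np.arange(W)[None, :] + self.T[:, :, 1]
        th, tw = (H, W) if shape is None else shape
        if ys.min() < 0 or xs.min() < 0 or ys.max() >= th or xs.max() >= tw:
            raise ValueError("correspondence field maps out of bounds")


def _window_half(shape, window_fraction: float) -> int:
    H, W = shape
    return max(1, int(round(np.sqrt(window_fraction * H * W) / 2.0)))


def _cell_hist(words: np.ndarray, K: int) -> np.ndarray:
    return np.bincount(words.ravel(), minlength=K)


def grid_match(src_words: np.ndarray, tgt_words: np.ndarray,
               cfg: GridMatchConfig, K: int = 0) -> CorrespondenceField:
    """Coarse cell-level matching by BoW histogram intersection.

    Each nonoverlapping source cell is matched to the overlapping target
    cell (stride ``target_step``) of maximal intersection among cells whose
    centers lie in the spatial window; ties prefer the smallest displacement
    magnitude, then row-major target order.  The cell displacement is
    broadcast to the cell's pixels.
    """
    cfg.validate()
    if src_words.shape != tgt_words.shape:
        raise ValueError("word maps must share a shape")
    H, W = src_words.shape
    if K <= 0:
        K = int(max(src_words.max(), tgt_words.max())) + 1
    cs, step = cfg.cell_size, cfg.target_step
    hw = _window_half((H, W), cfg.window_fraction)

    t_pos = [(ty, tx)
             for ty in range(0, H - cs + 1, step)
             for tx in range(0, W - cs + 1, step)]
    t_hist = np.stack([_cell_hist(tgt_words[ty:ty + cs, tx:tx + cs], K)
                       for ty, tx in t_pos])
    t_pos_arr = np.asarray(t_pos)
    t_centers = t_pos_arr + cs / 2.0

    T = np.zeros((H, W, 2), dtype=np.int32)
    for sy in range(0, H, cs):
        for sx in range(0, W, cs):
            sh = min(cs, H - sy)
            sw = min(cs, W - sx)
            s_hist = _cell_hist(src_words[sy:sy + sh, sx:sx + sw], K)
            sc = np.array([sy + sh / 2.0, sx + sw / 2.0])
            inwin = np.all(np.abs(t_centers - sc) <= hw, axis=1)
            cand = np.nonzero(inwin)[0]
            if cand.size == 0:
                raise ValueError("spatial window excludes all target cells")
            sims = np.minimum(t_hist[cand], s_hist).sum(axis=1)
            disp = t_pos_arr[cand] - np.array([sy, sx])
            mag2 = (disp ** 2).sum(axis=1)
            order = np.lexsort((cand, mag2, -sims))
            best = order[0]
            T[sy:sy + sh, sx:sx + sw] = disp[best]
    fld = CorrespondenceField(T=T, cost=np.zeros((H, W)))
    fld.validate()
    return fld


@njit(cache=True)
def _patch_cost(src, tgt, y, x, ty, tx):
    d = 0.0
    for k in range(src.shape[2]):
        diff = src[y, x, k] - tgt[ty, tx, k]
        d += diff * diff
    return d


@njit(cache=True)
def _refine_kernel(src, tgt, T, iters, hw, jitter, seed):   # pragma: no cover
    H, W = src.shape[0], src.shape[1]
    np.random.seed(seed)
    cost = np.empty((H, W))
    # initialization: jitter the coarse field inside the window
    for y in range(H):
        for x in range(W):
            dy, dx = T[y, x, 0], T[y, x, 1]
            if jitter > 0:
                dy += np.random.randint(-jitter, jitter + 1)
                dx += np.random.randint(-jitter, jitter + 1)
            dy = min(max(dy, max(-hw, -y)), min(hw, H - 1 - y))
            dx = min(max(dx, max(-hw, -x)), min(hw, W - 1 - x))
            T[y, x, 0], T[y, x, 1] = dy, dx
            cost[y, x] = _patch_cost(src, tgt, y, x, y + dy, x + dx)

    for it in range(iters):
        fwd = it % 2 == 0
        ys = range(H) if fwd else range(H - 1, -1, -1)
        for y in ys:
            xs = range(W) if fwd else range(W - 1, -1, -1)
            for x in xs:
                # propagation from already-visited neighbors
                for n in range(2):
                    if fwd:
                        ny, nx = (y - 1, x) if n == 0 else (y, x - 1)
                    else:
                        ny, nx = (y + 1, x) if n == 0 else (y, x + 1)
                    if ny < 0 or nx < 0 or ny >= H or nx >= W:
                        continue
                    dy, dx = T[ny, nx, 0], T[ny, nx, 1]
                    if (abs(dy) > hw or abs(dx) > hw or y + dy < 0 or
                            x + dx < 0 or y + dy >= H or x + dx >= W):
                        continue
                    c = _patch_cost(src, tgt, y, x, y + dy, x + dx)
                    if c < cost[y, x]:
                        cost[y, x] = c
                        T[y, x, 0], T[y, x, 1] = dy, dx
                # locally randomized search, exponentially shrinking radius
                r = hw
                while r >= 1:
                    dy = T[y, x, 0] + np.random.randint(-r, r + 1)
                    dx = T[y, x, 1] + np.random.randint(-r, r + 1)
                    dy = min(max(dy, max(-hw, -y)), min(hw, H - 1 - y))
                    dx = min(max(dx, max(-hw, -x)), min(hw, W - 1 - x))
                    c = _patch_cost(src, tgt, y, x, y + dy, x + dx)
                    if c < cost[y, x]:
                        cost[y, x] = c
                        T[y, x, 0], T[y, x, 1] = dy, dx
                    r //= 2
    return cost


def refine_field(src_desc: DescriptorField, tgt_desc: DescriptorField,
                 init: CorrespondenceField, cfg: GridMatchConfig,
                 jitter: int | None = None) -> CorrespondenceField:
    """PatchMatch-style refinement of an initial field (see module doc).

    ``jitter`` is the half-range of the uniform per-pixel perturbation of
    the initial field (default: ``cfg.target_step``); pass 0 to refine the
    initial field as-is.
    """
    cfg.validate()
    if src_desc.dim != tgt_desc.dim:
        raise ValueError("descriptor dimension mismatch")
    src = np.ascontiguousarray(src_desc.vectors, dtype=np.float32)
    tgt = np.ascontiguousarray(tgt_desc.vectors, dtype=np.float32)
    hw = _window_half(src.shape[:2], cfg.window_fraction)
    T = np.ascontiguousarray(init.T.copy(), dtype=np.int32)
    j = cfg.target_step if jitter is None else int(jitter)
    cost = _refine_kernel(src, tgt, T, cfg.iters, hw, j,
                          cfg.seed % (2 ** 31))
    fld = CorrespondenceField(T=T, cost=cost)
    fld.validate()
    return fld


def hierarchical_dense_match(src_desc: DescriptorField, src_words: np.ndarray,
                             tgt_desc: DescriptorField, tgt_words: np.ndarray,
                             cfg: GridMatchConfig,
                             K: int = 0) -> CorrespondenceField:
    """Coarse grid matching followed by PatchMatch refinement."""
    coarse = grid_match(src_words, tgt_words, cfg, K=K)
    return refine_field(src_desc, tgt_desc, coarse, cfg)


def flow_to_rgb(fld: CorrespondenceField) -> np.ndarray:
    """Color-wheel visualization of a displacement field: hue encodes the
    displacement direction, saturation the magnitude (uint8 RGB)."""
    from matplotlib.colors import hsv_to_rgb

    dy = fld.T[:, :, 0].astype(np.float64)
    dx = fld.T[:, :, 1].astype(np.float64)
    mag = np.hypot(dy, dx)
    hsv = np.stack([
        (np.arctan2(dy, dx) / (2 * np.pi)) % 1.0,
        mag / max(mag.max(), 1e-12),
        np.ones_like(mag),
    ], axis=-1)
    return (hsv_to_rgb(hsv) * 255).astype(np.uint8)


def export_field(fld: CorrespondenceField, prefix: str) -> None:
    """Write the field as a 2-channel float array (``<prefix>_flow.npy``)
    and a color-wheel PNG (``<prefix>_flow.png``) for inspection."""
    import imageio.v3 as iio

    np.save(f"{prefix}_flow.npy", fld.T.astype(np.float32))
    iio.imwrite(f"{prefix}_flow.png", flow_to_rgb(fld))


def field_total_variation(fld: CorrespondenceField) -> float:
    """Anisotropic total variation of the displacement field: the sum of
    absolute neighbor differences of both components (a smoothness score)."""
    T = fld.T.astype(np.int64)
    tv = np.abs(np.diff(T, axis=0)).sum() + np.abs(np.diff(T, axis=1)).sum()
    return float(tv)


def random_field(shape, cfg: GridMatchConfig, seed: int) -> CorrespondenceField:
    """Uniform random in-window field (the PatchMatch-baseline init)."""
    H, W = shape
    hw = _window_half(shape, cfg.window_fraction)
    rng = np.random.default_rng(seed)
    ys = np.arange(H)[:, None]
    xs = np.arange(W)[None, :]
    dy = rng.integers(-hw, hw + 1, size=(H, W))
    dx = rng.integers(-hw, hw + 1, size=(H, W))
    dy = np.clip(dy, -ys, H - 1 - ys)
    dx = np.clip(dx, -xs, W - 1 - xs)
    T = np.stack([dy, dx], axis=-1).astype(np.int32)
    return CorrespondenceField(T=T, cost=np.zeros((H, W)))
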