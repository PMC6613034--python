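"""MAP decomposition of a normalized radiograph into soft tissue and bone.

The model maximizes the posterior p(S, B | Y) ∝ p(Y | S, B) p(S) p(B) with
a Gaussian data term lam*||Y - S - B||^2 and nonparametric patch priors:
for every patch center x, exemplar patches are sampled through the dense
correspondence fields and the prior energy is the patch-level
log-sum-exp  -sum_x log sum_i exp(-eta * ||R_x S - R_{x+T_i(x)} S_i||^2).

The energy is minimized by an iteratively reweighted least-squares (IRLS)
scheme: the log-sum-exp is majorized at the current iterate by its Jensen
bound with softmax weights, and the resulting quadratic surrogate decouples
into an independent 2x2 linear system per pixel.  Each step therefore
descends the true energy (majorize-minimize).  The iteration is started
from the symmetric Jensen bound (uniform weights 1/M).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .config import DecompositionConfig
from .matching import CorrespondenceField

__all__ = [
    "ExemplarSet", "EnergyBreakdown", "compute_prior_weights", "energy",
    "irls_step", "initialize_solution", "map_decompose",
    "weighted_regression_baseline", "decompose_radiograph",
]


@dataclass
class ExemplarSet:
    """Normalized exemplar layers and their correspondence fields
    (input pixel x -> exemplar pixel x + T_i(x))."""

    S: List[np.ndarray]
    B: List[np.ndarray]
    fields: List[CorrespondenceField]
    Y: Optional[List[np.ndarray]] = None
    ids: Optional[List[str]] = None
    _cache: Dict[int, Tuple[np.ndarray, np.ndarray]] = dc_field(
        default_factory=dict, repr=False)

    @property
    def M(self) -> int:
        return len(self.S)

    def gathered(self, patch_size: int) -> Tuple[np.ndarray, np.ndarray]:
        """Exemplar patches pulled through the fields: arrays of shape
        (M, Hc, Wc, p, p) for the S and B layers (cached)."""
        if patch_size not in self._cache:
            GS = np.stack([_gather(self.S[i], self.fields[i], patch_size)
                           for i in range(self.M)])
            GB = np.stack([_gather(self.B[i], self.fields[i], patch_size)
                           for i in range(self.M)])
            self._cache[patch_size] = (GS, GB)
        return self._cache[patch_size]


@dataclass
class EnergyBreakdown:
    E_total: float
    E_data: float
    E_prior_S: float
    E_prior_B: float


def _centers(shape: Tuple[int, int], p: int) -> Tuple[int, int]:
    p2 = p // 2
    return shape[0] - 2 * p2, shape[1] - 2 * p2


def _gather(img: np.ndarray, fld: CorrespondenceField, p: int) -> np.ndarray:
    """Exemplar patches at the matched centers of all interior patch
    centers; matched centers are clamped so the patch fits in the image."""
    p2 = p // 2
    H, W = img.shape
    Hc, Wc = _centers((H, W), p)
    cy = np.arange(p2, p2 + Hc)[:, None]
    cx = np.arange(p2, p2 + Wc)[None, :]
    my = np.clip(cy + fld.T[p2: p2 + Hc, p2: p2 + Wc, 0], p2, H - 1 - p2)
    mx = np.clip(cx + fld.T[p2: p2 + Hc, p2: p2 + Wc, 1], p2, W - 1 - p2)
    win = sliding_window_view(img, (p, p))
    return win[my - p2, mx - p2]


def _patch_errors(cur: np.ndarray, G: np.ndarray, p: int) -> np.ndarray:
    """e_i(x) = ||R_x cur - gathered exemplar patch||^2, shape (M, Hc, Wc)."""
    sw = sliding_window_view(cur, (p, p))
    d = sw[None] - G
    return np.einsum("mijkl,mijkl->mij", d, d)


def _softmax_weights(e: np.ndarray, eta: float) -> np.ndarray:
    """w_i(x) = exp(-eta e_i) / sum_j exp(-eta e_j), max-stabilized;
    e has shape (M, Hc, Wc)."""
    z = -eta * e
    z = z - z.max(axis=0, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=0, keepdims=True)


def compute_prior_weights(current: np.ndarray,
                          exemplar_imgs: Sequence[np.ndarray],
                          fields: Sequence[CorrespondenceField],
                          eta: float, patch_size: int) -> np.ndarray:
    """Per-center softmax weights over exemplars (shape (M, Hc, Wc));
    sums to 1 over the exemplar axis at every center."""
    G = np.stack([_gather(img, fld, patch_size)
                  for img, fld in zip(exemplar_imgs, fields)])
    e = _patch_errors(current, G, patch_size)
    return _softmax_weights(e, eta)


def _coverage(shape: Tuple[int, int], p: int) -> np.ndarray:
    Hc, Wc = _centers(shape, p)
    C = np.zeros(shape)
    for oy in range(p):
        for ox in range(p):
            C[oy: oy + Hc, ox: ox + Wc] += 1.0
    return C


def _scatter(w: np.ndarray, G: np.ndarray, shape: Tuple[int, int],
             p: int) -> np.ndarray:
    """A(x) = sum_i sum_{patches P containing x} w_{P,i} * (exemplar value
    matched to the position of x within P)."""
    A = np.zeros(shape)
    M, Hc, Wc = w.shape
    for oy in range(p):
        for ox in range(p):
            A[oy: oy + Hc, ox: ox + Wc] += np.einsum(
                "mij,mij->ij", w, G[:, :, :, oy, ox])
    return A


def energy(S: np.ndarray, B: np.ndarray, Y_n: np.ndarray,
           ex: ExemplarSet, cfg: DecompositionConfig) -> EnergyBreakdown:
    """Total decomposition energy (data + patch-level log-sum-exp priors)."""
    cfg.validate()
    p = cfg.patch_size
    GS, GB = ex.gathered(p)
    r = Y_n - S - B
    E_data = cfg.lambda_ * float((r * r).sum())
    eS = _patch_errors(S, GS, p)
    eB = _patch_errors(B, GB, p)
    E_pS = -float(logsumexp(-cfg.eta_S * eS, axis=0).sum())
    E_pB = -float(logsumexp(-cfg.eta_B_ * eB, axis=0).sum())
    return EnergyBreakdown(E_total=E_data + E_pS + E_pB, E_data=E_data,
                           E_prior_S=E_pS, E_prior_B=E_pB)


def _solve_surrogate(wS: np.ndarray, wB: np.ndarray, Y_n: np.ndarray,
                     ex: ExemplarSet, cfg: DecompositionConfig
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Exact minimizer of the quadratic surrogate for given weights.

    The surrogate decouples per pixel into
      (lam + etaS*C) S + lam B = lam Y + etaS A_S
      lam S + (lam + etaB*C) B = lam Y + etaB A_B
    with coverage count C(x) and weighted rearrangement aggregates A.
    """
    p = cfg.patch_size
    lam, aS, aB = cfg.lambda_, cfg.eta_S, cfg.eta_B_
    GS, GB = ex.gathered(p)
    A_S = _scatter(wS, GS, Y_n.shape, p)
    A_B = _scatter(wB, GB, Y_n.shape, p)
    C = _coverage(Y_n.shape, p)
    a11 = lam + aS * C
    a22 = lam + aB * C
    b1 = lam * Y_n + aS * A_S
    b2 = lam * Y_n + aB * A_B
    det = a11 * a22 - lam * lam
    S = (a22 * b1 - lam * b2) / det
    B = (a11 * b2 - lam * b1) / det
    return S, B


def irls_step(S_t: np.ndarray, B_t: np.ndarray, Y_n: np.ndarray,
              ex: ExemplarSet, cfg: DecompositionConfig
              ) -> Tuple[np.ndarray, np.ndarray]:
    """One majorize-minimize step: softmax weights at (S_t, B_t), then the
    element-wise 2x2 linear solve of the surrogate."""
    cfg.validate()
    p = cfg.patch_size
    GS, GB = ex.gathered(p)
    wS = _softmax_weights(_patch_errors(S_t, GS, p), cfg.eta_S)
    wB = _softmax_weights(_patch_errors(B_t, GB, p), cfg.eta_B_)
    return _solve_surrogate(wS, wB, Y_n, ex, cfg)


def initialize_solution(Y_n: np.ndarray, ex: ExemplarSet,
                        cfg: DecompositionConfig
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Jensen-bound initialization: the surrogate with uniform weights 1/M
    (the quadratic upper bound of the log-sum-exp at the symmetric point)."""
    cfg.validate()
    Hc, Wc = _centers(Y_n.shape, cfg.patch_size)
    w = np.full((ex.M, Hc, Wc), 1.0 / ex.M)
    return _solve_surrogate(w, w, Y_n, ex, cfg)


def map_decompose(Y_n: np.ndarray, ex: ExemplarSet,
                  cfg: DecompositionConfig
                  ) -> Tuple[np.ndarray, np.ndarray, List[EnergyBreakdown]]:
    """Full MAP solve: initialization then IRLS until the relative energy
    change drops below ``cfg.tol`` or ``cfg.irls_iters`` is reached.  The
    energy trace is non-increasing (majorize-minimize)."""
    cfg.validate()
    S, B = initialize_solution(Y_n, ex, cfg)
    trace = [energy(S, B, Y_n, ex, cfg)]
    for _ in range(cfg.irls_iters):
        S, B = irls_step(S, B, Y_n, ex, cfg)
        trace.append(energy(S, B, Y_n, ex, cfg))
        prev, cur = trace[-2].E_total, trace[-1].E_total
        if abs(prev - cur) <= cfg.tol * (abs(prev) + 1e-30):
            break
    return S, B, trace


def weighted_regression_baseline(Y_n: np.ndarray, ex: ExemplarSet,
                                 cfg: DecompositionConfig
                                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Locally weighted regression baseline: each output patch is the
    weighted mean of the matched exemplar patches, with weights given by a
    softmax of the descriptor matching cost (no data term, no iteration);
    overlapping patch estimates are averaged by coverage."""
    cfg.validate()
    p = cfg.patch_size
    p2 = p // 2
    Hc, Wc = _centers(Y_n.shape, p)
    GS, GB = ex.gathered(p)
    cost = np.stack([f.cost[p2: p2 + Hc, p2: p2 + Wc] for f in ex.fields])
    w = _softmax_weights(cost, cfg.eta_S)
    C = _coverage(Y_n.shape, p)
    S = _scatter(w, GS, Y_n.shape, p) / C
    B = _scatter(w, GB, Y_n.shape, p) / C
    return S, B


def decompose_radiograph(Y, database, cfg=None, ground_truth=None):
    """End-to-end decomposition of a raw radiograph against a prepared
    database (normalize, descriptors, retrieval, matching, MAP solve,
    base-layer compensation).  See :func:`virtdes.pipeline.decompose_radiograph`."""
    from . import pipeline

    return pipeline.decompose_radiograph(Y, database, cfg=cfg,
                                         ground_truth=ground_truth)
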