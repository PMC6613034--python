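# Methods

## Model

A chest radiograph is modeled as the exact sum of a soft-tissue component
and a bone component, `Y = S + B`, in a normalized detail domain. Given a
database of DES triplets `{(Yᵢ, Sᵢ, Bᵢ)}`, the decomposition of a new
radiograph maximizes the posterior `p(S,B|Y) ∝ p(Y|S,B) p(S) p(B)` with

- a Gaussian likelihood `p(Y|S,B) ∝ exp(−λ‖Y−S−B‖²)`, and
- nonparametric patch priors: for each patch center x, the exemplar patch
  sampled through the dense correspondence field Tᵢ serves as a kernel
  center, `E_p(S) = −Σₓ log Σᵢ exp(−η_S ‖RₓS − R_{x+Tᵢ(x)}Sᵢ‖²)` (the
  patch-level log-sum-exp form; analogously for B with η_B).

Both priors assume that radiographs whose local appearance matches at
corresponding anatomical sites have matching soft-tissue and bone content —
the core transferability assumption of exemplar-based decomposition.
S and B are treated as a priori independent.

### Optimization

The energy is minimized by IRLS/majorize-minimize. At the current iterate,
softmax weights `w_{x,i} ∝ exp(−η e_{x,i})` (computed with max
subtraction) turn the log-sum-exp into a quadratic surrogate that touches
the energy at the iterate; because `Σᵢ w_{x,i} = 1`, the surrogate's normal
equations decouple into one 2×2 system per pixel,

```
(λ + η_S C) S + λ B = λ Y + η_S A_S
λ S + (λ + η_B C) B = λ Y + η_B A_B
```

with `C(x)` the number of patches covering x and `A(x)` the weighted
rearrangement of matched exemplar patches. The determinant
`λ(η_S+η_B)C + η_S η_B C²` is strictly positive, so the solve is exact and
every step lowers the true energy (asserted to 1e-9 relative in tests).
The iteration starts from the Jensen bound of the log-sum-exp at the
symmetric point, i.e. the surrogate with uniform weights 1/M, and stops at
relative energy change 1e-4 or 10 iterations — descent is fast because each
step is a full linear solve; with the default small bandwidths the energy
typically converges in 1–3 steps.

Patches are fully contained in the image, so border pixels are covered by
fewer patches (corner coverage is 1); matched patch centers are clamped so
the exemplar patch also fits. One weight per (center, exemplar) pair is
shared by all pixels of the patch during rearrangement.

### Parameters

| parameter | default | meaning |
|---|---|---|
| λ | 100 | data-term weight; larger values force Y = S + B harder |
| η_S | 1e-5 | soft-tissue kernel bandwidth (usable range ~1e-6 … 0.5) |
| η_B | 2·η_S | bone kernel bandwidth |
| M | 5 | exemplar count (diminishing returns beyond 5) |
| patch | 5×5 | prior sampling patch |
| codebook K | 5000 full-scale / 128 desk-scale | BoW visual words |
| grid cell / step | 32 / 16 px | coarse matching cells |
| window | ¼ image area | spatial search window (shared layout assumption) |
| iterations | 5 | PatchMatch propagation + random-search sweeps |

Small bandwidths put the prior in an *averaging* regime (the log-sum-exp
approaches the mean of matched patch errors); large bandwidths approach a
min-operation and sharpen results but risk artifacts. λ and the bandwidths
reproduce the tuned full-scale values; at these settings the data term
dominates the 2×2 solve, so the additive constraint is conserved to
numerical precision while the prior decides how detail is split between
S and B.

## Normalization

The base layer Y₀ is the self-guided filter output with radius 40 px at the
512-px scale (scaled proportionally for other sizes) and
`eps = (0.2 · dynamic range)²`. The eps default was calibrated once on a
phantom against the defining property of the base layer — it must follow
the smooth lung-field profile while leaving rib detail in the detail layer;
at much smaller eps the self-guided filter approaches the identity and the
normalization degenerates (σ_d → 0). μ_d and σ_d are computed over the
whole image (no body mask). Ground-truth layers are normalized with the
same Y₀ and σ_d, which preserves additivity exactly; the inverse (Step 8)
uses μ_d rather than μ_S, so the bone image's mean — unobservable from a
single radiograph — is folded into the soft-tissue image. Evaluation
therefore runs in the normalized domain (rmse on normalized layers, as in
the full-scale protocol).

## Descriptors

Per pixel: the raw 7×7 patch (49 dims); 50 filter-bank responses — first
and second anisotropic Gaussian derivatives at 6 orientations × 4 scales
geometrically spaced in [1, 32] px (3:1 elongation, truncated at 2.5σ,
capped at 129×129), plus a Laplacian of Gaussian and a Gaussian at the
second scale — jointly Weber-normalized, `r ← r·log(1+‖r‖/0.03)/‖r‖`; and a
dense SIFT over the 16×16 neighborhood (4×4 cells, 8 signed-orientation
bins, Gaussian block weight σ = 8, bilinear spatial pooling, 0.2 clipping
and renormalization). The combined descriptor is 227-dimensional
(49 + 50 + 128). Blocks are scaled to equal mean per-dimension variance
(fitted on 500 sampled pixels per training image) and then reduced to 60
dims by PCA; on the phantom database ~98 % of the variance is retained.
Weighting precedes PCA, matching its purpose of balancing the blocks before
reduction. Descriptors are shift-equivariant in the interior and are reused
by both retrieval and matching (one shared codebook).

## Matching

Source images are split into nonoverlapping 32×32 cells, targets into
overlapping cells at stride 16; cells match by BoW histogram intersection
within a square window of ¼ image area (chest radiographs share a spatial
layout, so correct matches are nearby). Ties prefer the smallest
displacement, then row-major order. The broadcast coarse field, perturbed
per pixel by a uniform jitter of ± one step (the "random permutation"), is
refined by PatchMatch: alternating forward/backward scans propagate
neighbor displacements and a local randomized search with exponentially
shrinking radius proposes alternatives; candidates are accepted only when
they strictly lower the squared descriptor distance and stay inside the
window. Total cost is therefore non-increasing, and results are
deterministic given the seed (scan-order independence is *not* claimed).
Against a per-pixel exhaustive window search the refined costs are bounded
below by the optimum and stay at the optimum when started there.

The smoothness comparison baseline is PatchMatch proper — totally random
initialization and *no* spatial-layout prior (whole-image search window) —
since the windowed refinement already embodies half of the hierarchical
scheme's anchoring. On ambiguous inter-subject phantom pairs the
hierarchical field's total variation is consistently 50–85 % of the
baseline's; on same-subject textured pairs both converge to the same
(unique) optimum and the comparison is uninformative.

## Synthetic phantom

Each phantom triplet emulates a posterior-anterior chest radiograph in
[0, 1] float range: S is a smooth positive field (mediastinum ridge, two
lung-field depressions, diaphragm edge, a Gaussian-correlated random
texture of 32 px correlation length and 0.03 amplitude, optional nodule
disc); B is a sum of parallel quadratic rib arcs per lung (default 8, peak
contrast 0.18, Gaussian cross-profile σ = thickness/2 — smooth edges
resembling radiographic bone, and parallel arcs never merge), plus optional
clavicle arcs. Gaussian noise is split 70/30 in amplitude between S and B
*before* summing, so Y = S + B holds exactly; a motion-artifact pair
translates the bone layer and defines S_art = Y − B_art, mimicking
two-exposure misregistration. Databases jitter rib spacing, lung width,
curvature and global gain by independent U[1−v, 1+v] factors (default
v = 0.2) with per-case derived seeds.

What the phantom does **not** emulate: real anatomy (vessels, scapulae,
heart border), scatter and beam hardening, vendor postprocessing,
non-additive raw DES, detector noise correlations. Passing tests therefore
demonstrate the machinery's correctness and the model's behavior under its
own assumptions — not clinical performance.

## Problem sizes

The test and reproduction benchmark uses a 30-case phantom database at
256×256 px with a K = 128 codebook and 6 held-out queries (seed 7) — a
documented scaled-down regime of the full-scale setting (hundreds of
512-px clinical cases, K = 5000). Unit oracles run on ≤16×16 instances
where brute-force references (dense least squares, triple-loop energies,
exhaustive matching) are exact.

## Numerical choices

- Log-sum-exp and softmax with max subtraction throughout.
- Least-squares gradient integration via a type-II DCT diagonalization of
  the Neumann normal equations; the free constant fixes the bone image's
  1st percentile at zero (bone attenuation is non-negative).
- Cross projection tensors: rank-1 projection onto the guide gradient
  direction, with a flat-guide floor τ = 1e-3 of the 99th percentile of the
  guide's gradient magnitude. Integration of the (non-integrable) projected
  field leaves a smooth low-frequency drift in the reconstructed bone
  image; the rib structure itself is recovered almost perfectly (high-pass
  correlation ≈ 0.96 on phantoms).
- Word quantization ties break to the lowest index; retrieval ties break
  lexicographically by id; histograms are raw counts (images share a size,
  so counts are comparable and intersection reads as a match count).
- 16-bit I/O quantizes layers independently; loaded training triplets
  re-derive Y as S + B (deviation from the stored Y ≤ 1e-4 of range) so the
  additive model is exact after a round trip.

## Known limitations

- The low-bandwidth (averaging) regime makes the estimate a data-term-
  corrected average of matched exemplar patches; block artifacts appear
  when exemplars are few or dissimilar.
- The bone image inherits any low-frequency error of the prior average
  since only S + B is pinned by the data term.
- PatchMatch refinement is sequential; results depend on the seed and scan
  order (deterministically), and only local optimality is guaranteed.
- Retrieval with raw-count intersection assumes equal image sizes across
  the database and query.
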