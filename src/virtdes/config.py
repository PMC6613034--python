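"""Configuration dataclasses shared across the pipeline.

All hyperparameters of the decomposition model live here so that a single
YAML file (or CLI flags) fully determines a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import yaml


@dataclass
class PhantomParams:
    """Parameters of the synthetic DES triplet generator.

    The phantom emulates a posterior-anterior chest radiograph as the exact
    sum of a smooth soft-tissue field and a curvilinear bone layer
    (rib/clavicle-like bands).  All intensities are in a normalized float
    range [0, 1] before 16-bit I/O scaling.
    """

    image_size: int = 256
    n_ribs: int = 8
    rib_curvature: float = 0.35        # dimensionless sag of the rib arc
    rib_thickness: float = 3.0         # pixels (Gaussian cross-profile sigma = thickness/2)
    rib_contrast: float = 0.18         # intensity units in [0,1]
    clavicle: bool = False
    soft_texture_scale: float = 32.0   # px, correlation length of the smooth soft-tissue field
    noise_sigma: float = 0.0           # intensity units
    motion_shift: float = 0.0          # px, bone-layer shift for DES motion-artifact pairs
    nodule_spec: Optional[Tuple[Tuple[float, float], float, float]] = None  # (center(y,x), radius, contrast)
    seed: int = 0
    # multiplicative jitter factors used by the database generator
    spacing_factor: float = 1.0        # rib spacing
    width_factor: float = 1.0          # lung-field width
    curvature_factor: float = 1.0
    gain: float = 1.0                  # global intensity

    def validate(self) -> None:
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if self.rib_thickness < 1:
            raise ValueError(f"rib_thickness must be >= 1, got {self.rib_thickness}")
        if self.n_ribs < 0:
            raise ValueError("n_ribs must be >= 0")
        for name in ("rib_contrast", "noise_sigma", "motion_shift"):
            v = float(getattr(self, name))
            if not (v >= 0.0) or v != v or v in (float("inf"),):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class GridMatchConfig:
    """Hierarchical dense-matching parameters.

    ``cell_size`` is the side of the nonoverlapping source grid cells;
    target cells overlap with stride ``target_step``.  The search window is
    a square of area ``window_fraction`` times the image area, centered on
    the source position.
    """

    cell_size: int = 32
    target_step: int = 16
    window_fraction: float = 0.25
    iters: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.cell_size < 8:
            raise ValueError("cell_size must be >= 8")
        if self.target_step > self.cell_size:
            raise ValueError("target_step must be <= cell_size")
        if not (0.0 < self.window_fraction <= 1.0):
            raise ValueError("window_fraction must be in (0, 1]")


@dataclass
class DecompositionConfig:
    """MAP decomposition hyperparameters.

    ``lambda_`` weighs the data term lam*||Y - S - B||^2; ``eta_S`` and
    ``eta_B`` are the Gaussian-kernel bandwidths of the soft-tissue and bone
    patch priors (eta_B defaults to 2*eta_S).
    """

    lambda_: float = 100.0
    eta_S: float = 1e-5
    eta_B: Optional[float] = None      # None -> 2 * eta_S
    M: int = 5
    patch_size: int = 5
    irls_iters: int = 10
    tol: float = 1e-4
    seed: int = 0

    @property
    def eta_B_(self) -> float:
        return 2.0 * self.eta_S if self.eta_B is None else self.eta_B

    def validate(self) -> None:
        if self.lambda_ <= 0 or self.eta_S <= 0 or self.eta_B_ <= 0:
            raise ValueError("lambda_, eta_S, eta_B must be positive")
        if self.patch_size % 2 != 1 or self.patch_size < 1:
            raise ValueError("patch_size must be odd and >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclass
class PipelineConfig:
    """Full pipeline configuration (preprocessing, descriptors, retrieval,
    matching, decomposition)."""

    # preprocessing: guided-filter radius is specified at the 512x512 scale
    # and scaled proportionally to the working image size
    gf_radius_at_512: int = 40
    gf_eps_frac: float = 0.2           # eps = (frac * dynamic range)^2
    # descriptors
    raw_patch: int = 7
    sift_block: int = 16
    weber_const: float = 0.03
    pca_dim: int = 60
    sample_per_image: int = 500
    # retrieval
    codebook_size: int = 128           # 5000 in the full-scale regime; desk-scale default
    # matching / decomposition
    match: GridMatchConfig = field(default_factory=GridMatchConfig)
    decomp: DecompositionConfig = field(default_factory=DecompositionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        match = GridMatchConfig(**d.pop("match", {}))
        decomp = DecompositionConfig(**d.pop("decomp", {}))
        return cls(match=match, decomp=decomp, **d)

    def dump_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
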