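"""End-to-end orchestration: database preparation, decomposition, sweeps.

A *prepared database* is a directory of DES triplets plus cached models
(block weights, PCA projection, BoW codebook) and per-image word maps and
spatial-pyramid histograms.  Preparation is idempotent: a manifest records
a hash of the preprocessing/descriptor/retrieval configuration, and entries
whose caches exist are not recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import decompose as dc
from . import descriptors as ds
from . import imgio, matching, metrics, preprocess, retrieval
from .config import DecompositionConfig, PipelineConfig
from .phantom import DesTriplet

log = logging.getLogger("virtdes")

__all__ = ["Database", "build_database", "decompose_radiograph", "sweep"]


def _cfg_hash(cfg: PipelineConfig, ids: Sequence[str]) -> str:
    payload = yaml.safe_dump({"cfg": cfg.to_dict(), "ids": list(ids)},
                             sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _arr_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


class Database:
    """Prepared exemplar database (see module docstring)."""

    def __init__(self, db_dir: str, cfg: PipelineConfig):
        self.dir = db_dir
        self.cfg = cfg
        self.ids: List[str] = imgio.load_database_ids(db_dir)
        self.bank = ds.build_filter_bank()
        self.weights: Optional[np.ndarray] = None
        self.pca: Optional[ds.PcaProjection] = None
        self.codebook: Optional[retrieval.Codebook] = None
        self.hists: Dict[str, retrieval.SpatialPyramidHist] = {}
        self._norm_cache: Dict[str, tuple] = {}
        self._field_cache: Dict[str, ds.DescriptorField] = {}
        self._field_cache_max = 12

    # ------------------------------------------------------------- caching
    @property
    def cache_dir(self) -> str:
        d = os.path.join(self.dir, "cache")
        os.makedirs(d, exist_ok=True)
        return d

    def _record(self, tid: str) -> dict:
        with open(os.path.join(self.dir, f"{tid}.json")) as fh:
            return json.load(fh)

    def triplet(self, tid: str) -> DesTriplet:
        return imgio.load_triplet(self.dir, self._record(tid))

    def normalized(self, tid: str):
        """(Y_n, S_n, B_n, ctx) for a database case (memoized)."""
        if tid not in self._norm_cache:
            trip = self.triplet(tid)
            Y_n, ctx = self.normalize(trip.Y)
            S_n, B_n = preprocess.normalize_targets(trip.S, trip.B, ctx)
            self._norm_cache[tid] = (Y_n, S_n, B_n, ctx)
        return self._norm_cache[tid]

    def normalize(self, Y: np.ndarray):
        radius = preprocess.default_radius(Y.shape[0],
                                           self.cfg.gf_radius_at_512)
        dyn = float(Y.max() - Y.min())
        eps = (self.cfg.gf_eps_frac * max(dyn, 1e-12)) ** 2
        return preprocess.normalize_radiograph(Y, radius, eps)

    def descriptor_field(self, Y_n: np.ndarray) -> ds.DescriptorField:
        """Weighted, PCA-projected descriptor field of a normalized image."""
        raw = ds.compute_dense_descriptors(
            Y_n, bank=self.bank, weights=self.weights,
            raw_patch=self.cfg.raw_patch, weber_const=self.cfg.weber_const)
        return ds.project_descriptors(raw, self.pca)

    def projected_field(self, tid: str) -> ds.DescriptorField:
        if tid not in self._field_cache:
            if len(self._field_cache) >= self._field_cache_max:
                self._field_cache.pop(next(iter(self._field_cache)))
            Y_n = self.normalized(tid)[0]
            self._field_cache[tid] = self.descriptor_field(Y_n)
        return self._field_cache[tid]

    def words(self, tid: str) -> np.ndarray:
        return np.load(os.path.join(self.cache_dir, f"{tid}_words.npy"))

    def hist(self, tid: str) -> retrieval.SpatialPyramidHist:
        if tid not in self.hists:
            H = np.load(os.path.join(self.cache_dir, f"{tid}_hist.npy"))
            self.hists[tid] = retrieval.SpatialPyramidHist(H=H)
        return self.hists[tid]


def build_database(db_dir: str, cfg: Optional[PipelineConfig] = None
                   ) -> Database:
    """Prepare (or reload) a triplet directory: fit block weights, PCA and
    codebook on sampled descriptors, and cache per-image word maps and
    spatial-pyramid histograms.  Idempotent by config hash."""
    cfg = cfg or PipelineConfig()
    db = Database(db_dir, cfg)
    if len(db.ids) < 2:
        raise ValueError("database needs >= 2 triplets")
    man_path = os.path.join(db.cache_dir, "db_manifest.json")
    model_path = os.path.join(db.cache_dir, "models.npz")
    want_hash = _cfg_hash(cfg, db.ids)

    manifest = None
    if os.path.exists(man_path):
        with open(man_path) as fh:
            manifest = json.load(fh)
        if manifest.get("config_hash") != want_hash:
            manifest = None

    if manifest is not None and os.path.exists(model_path):
        mdl = np.load(model_path)
        db.weights = mdl["weights"]
        db.pca = ds.PcaProjection(mean_vector=mdl["pca_mean"],
                                  basis=mdl["pca_basis"],
                                  explained_variance_fraction=float(
                                      mdl["pca_evf"]))
        db.codebook = retrieval.Codebook(centers=mdl["centers"])
    else:
        t0 = time.time()
        rng = np.random.default_rng(cfg.seed)
        samples = []
        for tid in db.ids:
            Y_n = db.normalized(tid)[0]
            f = ds.compute_dense_descriptors(Y_n, bank=db.bank,
                                             raw_patch=cfg.raw_patch,
                                             weber_const=cfg.weber_const)
            samples.append(ds.sample_vectors(f, cfg.sample_per_image, rng))
        samples = np.concatenate(samples)
        db.weights = ds.fit_block_weights(samples)
        splits = np.cumsum(ds.BLOCK_LAYOUT)[:-1]
        blocks = np.split(samples, splits, axis=1)
        weighted = np.concatenate(
            [w * b for w, b in zip(db.weights, blocks)], axis=1)
        db.pca = ds.fit_descriptor_pca(weighted, cfg.pca_dim)
        projected = (weighted - db.pca.mean_vector) @ db.pca.basis
        db.codebook = retrieval.fit_codebook(projected, cfg.codebook_size,
                                             seed=cfg.seed)
        np.savez(model_path, weights=db.weights, pca_mean=db.pca.mean_vector,
                 pca_basis=db.pca.basis,
                 pca_evf=db.pca.explained_variance_fraction,
                 centers=db.codebook.centers)
        manifest = None
        log.info("models fitted in %.1fs (pca evf %.3f)", time.time() - t0,
                 db.pca.explained_variance_fraction)

    # per-image caches
    for tid in db.ids:
        wp = os.path.join(db.cache_dir, f"{tid}_words.npy")
        hp = os.path.join(db.cache_dir, f"{tid}_hist.npy")
        if manifest is not None and os.path.exists(wp) and os.path.exists(hp):
            continue
        field = db.projected_field(tid)
        words = retrieval.quantize_field(field, db.codebook)
        hist = retrieval.spatial_pyramid_rep(words, db.codebook.K)
        np.save(wp, words)
        np.save(hp, hist.H)

    with open(man_path, "w") as fh:
        json.dump({"config_hash": want_hash, "ids": db.ids,
                   "codebook_hash": _arr_hash(db.codebook.centers),
                   "pca_hash": _arr_hash(db.pca.basis),
                   "entries": {tid: {"words": f"{tid}_words.npy",
                                     "hist": f"{tid}_hist.npy"}
                               for tid in db.ids}}, fh, indent=1)
    return db


# ------------------------------------------------------------------ querying

class QueryContext:
    """Prepared query: normalized image, descriptors, words, histogram."""

    def __init__(self, Y: np.ndarray, db: Database):
        t0 = time.time()
        self.Y = np.asarray(Y, dtype=np.float64)
        self.Y_n, self.ctx = db.normalize(self.Y)
        self.field = db.descriptor_field(self.Y_n)
        self.words = retrieval.quantize_field(self.field, db.codebook)
        self.hist = retrieval.spatial_pyramid_rep(self.words, db.codebook.K)
        log.info("query prepared in %.1fs", time.time() - t0)


def match_exemplars(qc: QueryContext, db: Database, M: int) -> dc.ExemplarSet:
    """Retrieve the top-M exemplars and solve their dense correspondence
    fields (query -> exemplar radiograph)."""
    if M > len(db.ids):
        raise ValueError("database smaller than M")
    entries = [(tid, db.hist(tid)) for tid in db.ids]
    top = retrieval.select_exemplars(qc.hist, entries, M)
    S_list, B_list, Y_list, fields = [], [], [], []
    for tid in top:
        t0 = time.time()
        Y_n, S_n, B_n, _ = db.normalized(tid)
        fld = matching.hierarchical_dense_match(
            qc.field, qc.words, db.projected_field(tid), db.words(tid),
            db.cfg.match, K=db.codebook.K)
        S_list.append(S_n)
        B_list.append(B_n)
        Y_list.append(Y_n)
        fields.append(fld)
        log.info("matched exemplar %s in %.1fs (mean cost %.3g)", tid,
                 time.time() - t0, fld.cost.mean())
    return dc.ExemplarSet(S=S_list, B=B_list, Y=Y_list, fields=fields,
                          ids=top)


def decompose_radiograph(Y: np.ndarray, database: Database,
                         cfg: Optional[DecompositionConfig] = None,
                         ground_truth: Optional[Tuple[np.ndarray, np.ndarray]]
                         = None):
    """Decompose a raw radiograph against a prepared database.

    Returns (S, B, report): the soft-tissue and bone images in the input's
    intensity domain (base layer compensated into S) and a report with the
    exemplar ids, the energy trace, the effective configuration, and — if
    ``ground_truth`` = (S_true, B_true) is given — normalized-domain
    rmse/bsr plus ssim.
    """
    cfg = cfg or database.cfg.decomp
    qc = QueryContext(Y, database)
    ex = match_exemplars(qc, database, cfg.M)
    S_n, B_n, trace = dc.map_decompose(qc.Y_n, ex, cfg)
    S, B = preprocess.denormalize(S_n, B_n, qc.ctx)
    report = {
        "exemplars": ex.ids,
        "energy_trace": [t.E_total for t in trace],
        "config": {"lambda_": cfg.lambda_, "eta_S": cfg.eta_S,
                   "eta_B": cfg.eta_B_, "M": cfg.M,
                   "patch_size": cfg.patch_size},
        "residual_mean_abs": float(np.abs(Y - S - B).mean()),
    }
    if ground_truth is not None:
        St, Bt = ground_truth
        St_n, Bt_n = preprocess.normalize_targets(St, Bt, qc.ctx)
        report["metrics"] = metrics.EvalResult(
            rmse_S=metrics.rmse(S_n, St_n), rmse_B=metrics.rmse(B_n, Bt_n),
            bsr=metrics.bsr(S_n, St_n, qc.Y_n),
            ssim_S=metrics.ssim(S_n, St_n),
            ssim_B=metrics.ssim(B_n, Bt_n)).to_dict()
    return S, B, report


# --------------------------------------------------------------------- sweep

def sweep(param: str, values: Sequence, db: Database,
          queries: Sequence[DesTriplet],
          base_cfg: Optional[DecompositionConfig] = None) -> List[dict]:
    """Decomposition performance across a hyperparameter sweep.

    ``param`` is one of ``lambda_``, ``eta_S``, ``M``.  Queries are matched
    once at the largest M needed and exemplar subsets are reused, so the
    sweep isolates the effect of the parameter.  Returns one row per value
    with mean/median/std of rmse_S, bsr, ssim_S and the additive residual.
    """
    if param not in ("lambda_", "eta_S", "M"):
        raise ValueError(f"unknown sweep parameter {param!r}")
    base_cfg = base_cfg or db.cfg.decomp
    max_m = max(values) if param == "M" else base_cfg.M
    prepared = []
    for trip in queries:
        qc = QueryContext(trip.Y, db)
        ex = match_exemplars(qc, db, int(max_m))
        prepared.append((trip, qc, ex))

    rows = []
    for v in values:
        cfg = replace(base_cfg, **{param: v}) if param != "M" \
            else replace(base_cfg, M=int(v))
        per_q = []
        for trip, qc, ex in prepared:
            sub = ex if param != "M" else dc.ExemplarSet(
                S=ex.S[: cfg.M], B=ex.B[: cfg.M], fields=ex.fields[: cfg.M],
                Y=ex.Y[: cfg.M] if ex.Y else None,
                ids=ex.ids[: cfg.M] if ex.ids else None)
            S_n, B_n, _ = dc.map_decompose(qc.Y_n, sub, cfg)
            St_n, Bt_n = preprocess.normalize_targets(trip.S, trip.B, qc.ctx)
            res = metrics.EvalResult(
                rmse_S=metrics.rmse(S_n, St_n),
                rmse_B=metrics.rmse(B_n, Bt_n),
                bsr=metrics.bsr(S_n, St_n, qc.Y_n),
                ssim_S=metrics.ssim(S_n, St_n),
                ssim_B=metrics.ssim(B_n, Bt_n)).to_dict()
            res["residual"] = float(np.abs(qc.Y_n - S_n - B_n).mean())
            per_q.append(res)
        row = {"param": param, "value": v}
        for k in per_q[0]:
            vals = np.array([q[k] for q in per_q])
            row[f"{k}_mean"] = float(vals.mean())
            row[f"{k}_median"] = float(np.median(vals))
            row[f"{k}_std"] = float(vals.std())
        rows.append(row)
    return rows
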