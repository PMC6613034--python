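"""Image and database I/O.

Radiographs are exchanged as 16-bit monochrome DICOM or 16-bit PNG/TIFF and
handled internally as float64 arrays.  A DES triplet is stored as three
16-bit PNGs ``<id>_Y.png``, ``<id>_S.png``, ``<id>_B.png`` plus a JSON
sidecar recording the float-to-integer scaling (per image) and the
generator parameters; a database directory carries a ``manifest.json``.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np

from .phantom import DesTriplet

__all__ = [
    "read_image", "write_image16", "save_triplet", "load_triplet",
    "save_database", "load_database_ids", "load_database",
]

_U16 = 65535.0


def read_image(path: str) -> np.ndarray:
    """Read a 16-bit DICOM / PNG / TIFF (or 8-bit) image as float64."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
    else:
        arr = np.asarray(iio.imread(path)).astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr


def write_image16(path: str, img: np.ndarray,
                  vmin: Optional[float] = None,
                  vmax: Optional[float] = None) -> Tuple[float, float]:
    """Write ``img`` as 16-bit PNG/TIFF; returns the (vmin, vmax) scaling
    used so the float image can be recovered as vmin + u16/65535*(vmax-vmin)."""
    img = np.asarray(img, dtype=np.float64)
    lo = float(img.min()) if vmin is None else float(vmin)
    hi = float(img.max()) if vmax is None else float(vmax)
    if hi <= lo:
        hi = lo + 1.0
    q = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(path, np.round(q * _U16).astype(np.uint16))
    return lo, hi


def _restore(path: str, lo: float, hi: float) -> np.ndarray:
    return read_image(path) / _U16 * (hi - lo) + lo


def save_triplet(trip: DesTriplet, out_dir: str) -> dict:
    """Save a triplet; returns its sidecar record (also written to disk)."""
    os.makedirs(out_dir, exist_ok=True)
    rec = {"id": trip.id, "pixel_spacing": trip.pixel_spacing,
           "params": trip.params, "files": {}, "scale": {}}
    for name in ("Y", "S", "B"):
        fn = f"{trip.id}_{name}.png"
        lo, hi = write_image16(os.path.join(out_dir, fn), getattr(trip, name))
        rec["files"][name] = fn
        rec["scale"][name] = [lo, hi]
    with open(os.path.join(out_dir, f"{trip.id}.json"), "w") as fh:
        json.dump(rec, fh, indent=1)
    return rec


def load_triplet(db_dir: str, rec: dict) -> DesTriplet:
    """Load a triplet from its sidecar record.

    16-bit quantization breaks exact additivity by up to one quantization
    step; the radiograph is re-derived as Y = S + B so that loaded training
    triplets satisfy the additive model exactly (the deviation from the
    stored Y is below 1e-4 of the dynamic range).
    """
    imgs = {}
    for name in ("Y", "S", "B"):
        lo, hi = rec["scale"][name]
        imgs[name] = _restore(os.path.join(db_dir, rec["files"][name]), lo, hi)
    trip = DesTriplet(Y=imgs["S"] + imgs["B"], S=imgs["S"], B=imgs["B"],
                      pixel_spacing=rec.get("pixel_spacing", 0.7),
                      id=rec["id"], params=rec.get("params"))
    trip.validate()
    return trip


def save_database(triplets: List[DesTriplet], out_dir: str) -> str:
    os.makedirs(out_dir, exist_ok=True)
    entries = [save_triplet(t, out_dir) for t in triplets]
    manifest = {"n": len(entries), "ids": [e["id"] for e in entries]}
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def load_database_ids(db_dir: str) -> List[str]:
    with open(os.path.join(db_dir, "manifest.json")) as fh:
        return list(json.load(fh)["ids"])


def load_database(db_dir: str) -> List[DesTriplet]:
    out = []
    for tid in load_database_ids(db_dir):
        with open(os.path.join(db_dir, f"{tid}.json")) as fh:
            rec = json.load(fh)
        out.append(load_triplet(db_dir, rec))
    return out
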