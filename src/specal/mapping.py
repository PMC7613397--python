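"""Per-pixel trait mapping with uncertainty.

A trained model bundle (PCA + GPR + trait metadata) is applied to every
valid pixel of a hyperspectral cube, producing three co-registered rasters:
the trait estimate, its predictive standard deviation (SD, absolute
uncertainty) and the coefficient of variation CV = 100 * SD / estimate
(relative uncertainty, in percent — deliberately not clipped at 100%, since
near-zero estimates over non-vegetated surfaces legitimately push CV beyond
it).  Pixels are processed in chunks; results are bitwise identical
regardless of chunk size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from .dimred import PCAModel
from .regression import GPRModel
from .spectral_io import RasterCube, read_envi, write_envi

__all__ = ["ModelBundle", "TraitMap", "apply_model", "cv_map",
           "write_maps", "read_maps"]


@dataclass
class ModelBundle:
    """Everything needed to map one trait: PCA, GP and the band grid."""

    pca: PCAModel
    gpr: GPRModel
    trait: str
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        """Short provenance hash of the bundle's numeric content."""
        h = hashlib.sha256()
        for arr in (self.pca.mean, self.pca.components, self.gpr.X,
                    self.gpr.alpha,
                    np.array([self.gpr.sigma_f2, self.gpr.lengthscale,
                              self.gpr.sigma_n2, self.gpr.y_mean,
                              self.gpr.y_std])):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        h.update(self.trait.encode())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        bundle = joblib.load(Path(path))
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


@dataclass
class TraitMap:
    """Estimate, SD and CV rasters with a shared validity mask."""

    estimate: np.ndarray     # (rows, cols), trait units
    sd: np.ndarray           # (rows, cols), trait units
    cv: np.ndarray           # (rows, cols), percent
    valid: np.ndarray        # (rows, cols) bool
    trait: str
    provenance: str = ""

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.estimate, self.sd, self.cv, self.valid)}
        if len(shapes) != 1:
            raise ValueError("all rasters must share one shape")


def cv_map(estimate: np.ndarray, sd: np.ndarray,
           epsilon: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """CV = 100 * sd / estimate (%), masked (NaN) where estimate <= epsilon.

    Values above 100% are kept: over non-vegetated surfaces, near-zero
    estimates with finite SD genuinely exceed that bound.
    """
    estimate = np.asarray(estimate, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if estimate.shape != sd.shape:
        raise ValueError("estimate and sd shapes differ")
    if np.any(sd[np.isfinite(sd)] < 0):
        raise ValueError("negative standard deviation")
    ok = np.isfinite(estimate) & (estimate > epsilon)
    cv = np.full(estimate.shape, np.nan)
    cv[ok] = 100.0 * sd[ok] / estimate[ok]
    return cv, ok


def apply_model(cube: RasterCube, bundle: ModelBundle,
                chunk: int = 4096, epsilon: float = 1e-6) -> TraitMap:
    """Predict the bundle's trait for every valid pixel of ``cube``.

    The cube's band grid must match the bundle's (resample first if not).
    Nodata or non-finite pixels propagate to the validity mask.  Chunking
    only batches memory; the numerical path is per-pixel deterministic, so
    outputs are bitwise identical for any chunk size.
    """
    if cube.wavelengths.size != bundle.wavelengths.size or not np.allclose(
        cube.wavelengths, bundle.wavelengths
    ):
        raise ValueError(
            "cube band grid does not match the model bundle; resample the "
            "cube to the bundle's sensor configuration first"
        )
    if chunk < 1:
        raise ValueError("chunk must be positive")
    rows, cols, bands = cube.shape
    flat = cube.data.reshape(-1, bands).astype(float)
    valid = np.isfinite(flat).all(axis=1)
    if np.isfinite(cube.nodata):
        valid &= ~np.any(flat == cube.nodata, axis=1)

    est = np.full(rows * cols, np.nan)
    sd = np.full(rows * cols, np.nan)
    idx = np.where(valid)[0]
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        feats = bundle.pca.transform(flat[sel])
        mean, std = bundle.gpr.predict(feats, return_std=True)
        est[sel] = mean
        sd[sel] = std

    est = est.reshape(rows, cols)
    sd = sd.reshape(rows, cols)
    cv, cv_ok = cv_map(est, sd, epsilon=epsilon)
    return TraitMap(
        estimate=est, sd=sd, cv=cv, valid=valid.reshape(rows, cols),
        trait=bundle.trait, provenance=bundle.content_hash(),
    )


def write_maps(tmap: TraitMap, path: str | Path) -> list[Path]:
    """Write estimate/SD/CV (+ mask) as co-registered ENVI rasters.

    Files are ``<path>_est``, ``<path>_sd``, ``<path>_cv`` and
    ``<path>_mask`` (.hdr/.img pairs); the provenance hash goes into each
    header description.
    """
    base = Path(path)
    meta = {"trait": tmap.trait, "bundle_hash": tmap.provenance}
    written = []
    layers = {
        "est": tmap.estimate, "sd": tmap.sd, "cv": tmap.cv,
        "mask": tmap.valid.astype(np.float32),
    }
    for suffix, layer in layers.items():
        out = Path(f"{base}_{suffix}")
        arr = np.asarray(layer, dtype=np.float32)[:, :, None]
        data = np.where(np.isfinite(arr), arr, np.float32(-9999.0))
        cube = RasterCube(data=data, wavelengths=np.array([0.0]),
                          nodata=-9999.0, meta={**meta, "layer": suffix})
        write_envi(cube, out)
        written.append(out.with_suffix(".hdr"))
    return written


def read_maps(path: str | Path) -> TraitMap:
    """Read a trait map written by :func:`write_maps`."""
    base = Path(path)
    layers = {}
    meta = {}
    for suffix in ("est", "sd", "cv", "mask"):
        cube = read_envi(Path(f"{base}_{suffix}"))
        arr = cube.data[:, :, 0].astype(float)
        arr[arr == cube.nodata] = np.nan
        layers[suffix] = arr
        desc = _description_meta(Path(f"{base}_{suffix}").with_suffix(".hdr"))
        meta.update(desc)
    return TraitMap(
        estimate=layers["est"], sd=layers["sd"], cv=layers["cv"],
        valid=layers["mask"] > 0.5,
        trait=meta.get("trait", "unknown"),
        provenance=meta.get("bundle_hash", ""),
    )


def _description_meta(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    start = text.find("{specal raster; ")
    if start == -1:
        return {}
    end = text.find("}}", start)   # JSON closing brace + description brace
    if end == -1:
        return {}
    try:
        return json.loads(text[start + len("{specal raster; ") : end + 1])
    except json.JSONDecodeError:
        return {}
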