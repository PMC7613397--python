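"""LUT and image-cube I/O plus sensor band convolution.

LUTs are stored as CSV: trait columns first, then one column per band named
by its wavelength in nm (``R0420.000``).  Image cubes use the minimal ENVI
dialect — a text ``.hdr`` with ``key = value`` lines next to a flat
little-endian float32 binary in BSQ, BIL or BIP interleave.  Spectral
resampling between sensors uses Gaussian spectral response functions defined
by band centers and FWHM.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth_lut import TRAIT_NAMES

__all__ = [
    "LUT",
    "SensorSRF",
    "RasterCube",
    "read_lut",
    "write_lut",
    "read_envi",
    "write_envi",
    "gaussian_srf_weights",
    "convolve_to_sensor",
    "enmap_like_srf",
]

_BAND_PREFIX = "R"
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2 sqrt(2 ln 2))


@dataclass
class LUT:
    """Aligned trait table + reflectance spectra; the AL candidate pool.

    ``is_vegetation`` flags rows generated by the canopy model; soil-library
    rows are False and carry NaN traits so they never enter trait metrics.
    """

    traits: pd.DataFrame
    spectra: np.ndarray
    wavelengths: np.ndarray
    is_vegetation: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.traits) != self.spectra.shape[0]:
            raise ValueError("trait table and spectra row counts differ")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra band count does not match wavelength grid")
        if self.is_vegetation is None:
            self.is_vegetation = np.ones(len(self.traits), dtype=bool)
        else:
            self.is_vegetation = np.asarray(self.is_vegetation, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]


def _band_col(wl: float) -> str:
    return f"{_BAND_PREFIX}{wl:09.3f}"


def write_lut(lut: LUT, path: str | Path) -> None:
    """Write a LUT as CSV with a one-line JSON metadata header comment."""
    path = Path(path)
    df = lut.traits.copy()
    df["is_vegetation"] = lut.is_vegetation.astype(int)
    band_cols = [_band_col(w) for w in lut.wavelengths]
    spec = pd.DataFrame(
        np.asarray(lut.spectra, dtype=np.float32), columns=band_cols, index=df.index
    )
    out = pd.concat([df, spec], axis=1)
    with open(path, "w") as fh:
        fh.write("# specal-lut " + json.dumps(lut.meta) + "\n")
        # %.9g round-trips float32 exactly
        out.to_csv(fh, index=False, float_format="%.9g")


def read_lut(path: str | Path) -> LUT:
    """Read a LUT CSV written by :func:`write_lut` (or a compatible file)."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# specal-lut"):
            meta = json.loads(first[len("# specal-lut") :])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)

    band_cols = [c for c in df.columns if c.startswith(_BAND_PREFIX) and
                 c[len(_BAND_PREFIX):].replace(".", "", 1).isdigit()]
    if not band_cols:
        raise ValueError(f"{path}: no band columns (expected '{_BAND_PREFIX}<wavelength>')")
    wavelengths = np.array([float(c[len(_BAND_PREFIX):]) for c in band_cols])
    order = np.argsort(wavelengths)
    band_cols = [band_cols[i] for i in order]
    wavelengths = wavelengths[order]
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError(f"{path}: duplicate band wavelengths")

    spectra = df[band_cols].to_numpy(dtype=np.float32)
    bad = np.where(~np.isfinite(spectra).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: non-finite spectra at row {bad[0]}")

    trait_cols = [c for c in TRAIT_NAMES if c in df.columns]
    missing = [c for c in TRAIT_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trait column(s) {missing}")
    traits = df[trait_cols]
    veg = (
        df["is_vegetation"].to_numpy(dtype=bool)
        if "is_vegetation" in df.columns
        else None
    )
    return LUT(traits=traits, spectra=spectra, wavelengths=wavelengths,
               is_vegetation=veg, meta=meta)


# ---------------------------------------------------------------------------
# ENVI raster cubes
# ---------------------------------------------------------------------------

@dataclass
class RasterCube:
    """(rows, cols, bands) reflectance cube with a band wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray
    nodata: float = -9999.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube must be (rows, cols, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength list")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


_ENVI_INTERLEAVES = ("bsq", "bil", "bip")


def write_envi(cube: RasterCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write an ENVI header (.hdr) + flat float32 binary (.img)."""
    interleave = interleave.lower()
    if interleave not in _ENVI_INTERLEAVES:
        raise ValueError(f"interleave must be one of {_ENVI_INTERLEAVES}")
    base = Path(path)
    if base.suffix == ".hdr":
        base = base.with_suffix("")
    rows, cols, bands = cube.shape
    arr = cube.data
    if interleave == "bsq":
        payload = np.transpose(arr, (2, 0, 1))
    elif interleave == "bil":
        payload = np.transpose(arr, (0, 2, 1))
    else:  # bip
        payload = arr
    payload = np.ascontiguousarray(payload, dtype="<f4")
    payload.tofile(base.with_suffix(".img"))

    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {specal raster" +
        ("; " + json.dumps(cube.meta) if cube.meta else "") + "}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        f"interleave = {interleave}",
        "byte order = 0",
        f"data ignore value = {cube.nodata:.6g}",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
    ]
    base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")


def _parse_hdr(text: str) -> dict:
    # collapse {...} blocks spanning multiple lines, then split on key = value
    entries: dict[str, str] = {}
    buf = ""
    for raw in text.splitlines():
        buf += raw.strip() + " "
        if buf.count("{") > buf.count("}"):
            continue
        line = buf.strip()
        buf = ""
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, val = line.split("=", 1)
        entries[key.strip().lower()] = val.strip()
    return entries


def read_envi(path: str | Path) -> RasterCube:
    """Read an ENVI cube; the array is identical regardless of interleave."""
    base = Path(path)
    if base.suffix == ".hdr":
        base = base.with_suffix("")
    hdr_path = base.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    entries = _parse_hdr(hdr_path.read_text())
    try:
        cols = int(entries["samples"])
        rows = int(entries["lines"])
        bands = int(entries["bands"])
        interleave = entries["interleave"].lower()
        dtype_code = int(entries["data type"])
    except KeyError as exc:
        raise ValueError(f"{hdr_path}: missing required header field {exc}") from exc
    if dtype_code != 4:
        raise ValueError(f"{hdr_path}: only float32 (data type 4) is supported")
    if interleave not in _ENVI_INTERLEAVES:
        raise ValueError(f"{hdr_path}: unknown interleave {interleave!r}")

    wl_field = entries.get("wavelength", "")
    wl = np.array(
        [float(v) for v in wl_field.strip("{} ").split(",") if v.strip()], dtype=float
    )
    if wl.size and wl.size != bands:
        raise ValueError(f"{hdr_path}: wavelength list length != bands")
    if not wl.size:
        wl = np.arange(bands, dtype=float)

    raw = np.fromfile(base.with_suffix(".img"), dtype="<f4")
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"{base}: data size {raw.size} does not match header "
            f"{rows}x{cols}x{bands}"
        )
    if interleave == "bsq":
        arr = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        arr = raw.reshape(rows, cols, bands)

    nodata = float(entries.get("data ignore value", -9999.0))
    return RasterCube(data=np.ascontiguousarray(arr), wavelengths=wl, nodata=nodata)


# ---------------------------------------------------------------------------
# sensor spectral response functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorSRF:
    """Gaussian band model of a sensor: centers and FWHM, both in nm."""

    centers: np.ndarray
    fwhm: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "fwhm", np.asarray(self.fwhm, dtype=float))
        if self.centers.size != self.fwhm.size:
            raise ValueError("centers and fwhm must have equal length")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(self.fwhm <= 0):
            raise ValueError("FWHM must be positive")

    @property
    def n_bands(self) -> int:
        return self.centers.size

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "SensorSRF":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "center" not in cols or "fwhm" not in cols:
            raise ValueError(f"{path}: SRF CSV needs 'center' and 'fwhm' columns")
        return cls(df[cols["center"]].to_numpy(), df[cols["fwhm"]].to_numpy(),
                   name=name or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"center": self.centers, "fwhm": self.fwhm}).to_csv(
            path, index=False
        )


def enmap_like_srf() -> SensorSRF:
    """A plausible 242-band EnMAP-like SRF (no official table is bundled).

    88 VNIR bands at 6.5 nm spacing (FWHM 8 nm) and 154 SWIR bands at
    ~9.5 nm spacing (FWHM 11 nm), spanning 420-2450 nm.
    """
    from .synth_lut import default_wavelengths

    centers = default_wavelengths()
    fwhm = np.where(centers < 990.0, 8.0, 11.0)
    return SensorSRF(centers=centers, fwhm=fwhm, name="enmap-like")


def gaussian_srf_weights(
    source_wavelengths: np.ndarray, srf: SensorSRF
) -> np.ndarray:
    """Weight matrix (target bands x source bands) of normalized Gaussians.

    Each row is a Gaussian with sigma = FWHM/2.3548 centered on the band,
    truncated at +-3 sigma and renormalized to unit sum.
    """
    src = np.asarray(source_wavelengths, dtype=float)
    if np.any(np.diff(src) <= 0):
        raise ValueError("source wavelengths must be strictly increasing")
    if np.any(srf.centers < src[0]) or np.any(srf.centers > src[-1]):
        bad = int(np.where((srf.centers < src[0]) | (srf.centers > src[-1]))[0][0])
        raise ValueError(
            f"target band {bad} ({srf.centers[bad]:.1f} nm) outside source range"
        )
    sigma = srf.fwhm * FWHM_TO_SIGMA
    lo = srf.centers - 2.0 * srf.fwhm
    hi = srf.centers + 2.0 * srf.fwhm
    if np.any(lo < src[0] - 1e-9) or np.any(hi > src[-1] + 1e-9):
        warnings.warn(
            "source grid does not span +-2 FWHM of every target band; "
            "edge bands are truncated", RuntimeWarning, stacklevel=2,
        )
    d = src[None, :] - srf.centers[:, None]
    w = np.exp(-0.5 * (d / sigma[:, None]) ** 2)
    w[np.abs(d) > 3.0 * sigma[:, None]] = 0.0
    # a 3-sigma window always contains at least the nearest source band when
    # sigma is tiny; fall back to the nearest band if numerically empty
    empty = w.sum(axis=1) == 0
    if np.any(empty):
        nearest = np.argmin(np.abs(d[empty]), axis=1)
        w[np.where(empty)[0], nearest] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def convolve_to_sensor(
    spectra: np.ndarray,
    source_wavelengths: np.ndarray,
    srf: SensorSRF,
) -> np.ndarray:
    """Resample spectra (n x source_bands) onto the sensor's band centers."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    src = np.asarray(source_wavelengths, dtype=float)
    if spectra.shape[1] != src.size:
        raise ValueError("spectra band count does not match source grid")
    w = gaussian_srf_weights(src, srf)
    return spectra @ w.T
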