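"""Synthetic PROSAIL-PRO-like lookup tables, soil spectra and image scenes.

Real hybrid-retrieval workflows couple a leaf radiative-transfer model
(PROSPECT-PRO) with a canopy model (4SAIL) to simulate top-of-canopy
reflectance for random trait combinations.  This module provides a
lightweight *surrogate* forward model with the same structure — Beer–Lambert
leaf absorption with Gaussian specific-absorption features for each
biochemical, and gap-fraction mixing of the leaf term with a soil background
— so that the whole retrieval stack (PCA, GPR, active learning, mapping) can
be exercised end to end without the external RTM code.

The surrogate is deterministic given the trait table, produces reflectances
in [0, 1], and is monotone in each absorber at that absorber's feature
wavelength.  It is *not* radiometrically accurate and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_NAMES",
    "TraitRanges",
    "SceneField",
    "SceneLayout",
    "default_wavelengths",
    "sample_traits",
    "surrogate_forward",
    "add_noise",
    "soil_library",
    "make_scene",
]

#: canonical trait column order used everywhere in the package
TRAIT_NAMES = (
    "N",            # leaf structure parameter (unitless)
    "Cab",          # chlorophyll a+b content (ug/cm^2)
    "Cxc",          # total carotenoid content (ug/cm^2)
    "Cw",           # equivalent water thickness (cm)
    "Cant",         # anthocyanin content (ug/cm^2)
    "Cp",           # protein content (g/cm^2)
    "CBC",          # carbon-based constituents (g/cm^2)
    "LAI",          # leaf area index (m^2/m^2)
    "ALIA",         # average leaf inclination angle (degrees)
    "hotspot",      # hot-spot size parameter (m/m)
    "soil_brightness",  # scales between a dark wet and bright dry soil (0-1)
)

#: fixed acquisition geometry: sun zenith 30 deg, nadir view
SUN_ZENITH_DEG = 30.0
VIEW_ZENITH_DEG = 0.0

GENERATOR_VERSION = "1.0"


@dataclass(frozen=True)
class TraitRanges:
    """Uniform sampling bounds per trait.

    Defaults are the canopy-RTM parameterisation used for the 1k-sample
    training database: leaf structure 1-2, Cab 0-80 ug/cm2, Cxc 0-15 ug/cm2,
    Cw 0.001-0.03 cm, Cant 0-2 ug/cm2, Cp 0.001-0.0025 g/cm2,
    CBC 0.001-0.01 g/cm2, LAI 0-7, ALIA 30-70 deg, hotspot 0.01-0.5,
    soil brightness 0-1.
    """

    N: tuple[float, float] = (1.0, 2.0)
    Cab: tuple[float, float] = (0.0, 80.0)
    Cxc: tuple[float, float] = (0.0, 15.0)
    Cw: tuple[float, float] = (0.001, 0.03)
    Cant: tuple[float, float] = (0.0, 2.0)
    Cp: tuple[float, float] = (0.001, 0.0025)
    CBC: tuple[float, float] = (0.001, 0.01)
    LAI: tuple[float, float] = (0.0, 7.0)
    ALIA: tuple[float, float] = (30.0, 70.0)
    hotspot: tuple[float, float] = (0.01, 0.5)
    soil_brightness: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            lo, hi = getattr(self, f.name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"non-finite bounds for trait {f.name!r}")
            if hi < lo:
                raise ValueError(f"lower bound exceeds upper for trait {f.name!r}")

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


def default_wavelengths() -> np.ndarray:
    """EnMAP-like 242-band grid, 420-2450 nm (88 VNIR + 154 SWIR bands)."""
    vnir = 420.0 + 6.5 * np.arange(88)
    swir = np.linspace(995.0, 2450.0, 154)
    return np.concatenate([vnir, swir])


def sample_traits(ranges: TraitRanges, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` i.i.d. uniform trait vectors within ``ranges``.

    Identical ``(ranges, n, seed)`` always yield an identical table.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    data = {}
    for name in TRAIT_NAMES:
        lo, hi = ranges.bounds(name)
        if hi <= lo:
            raise ValueError(f"trait {name!r} has non-positive range width")
        data[name] = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(data, columns=list(TRAIT_NAMES))


# ---------------------------------------------------------------------------
# surrogate forward model
# ---------------------------------------------------------------------------

def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _leaf_envelope(wl: np.ndarray) -> np.ndarray:
    # bright "albino leaf" scattering envelope: ~0.46 plateau with a gentle
    # decline towards the SWIR
    return 0.46 * (1.0 - 0.10 * (wl - 420.0) / 2030.0)


def _absorption_depth(traits: pd.DataFrame, wl: np.ndarray) -> np.ndarray:
    """Total Beer-Lambert optical depth per (sample, band).

    Each biochemical contributes Gaussian specific-absorption features at its
    field-known wavelengths; coefficients are scaled so that the upper end of
    each trait range reaches an optical depth of roughly 2-4 (saturating but
    not flat), mimicking the nonlinearity of the real leaf model.
    """
    k_cab = 0.040 * (_gauss(wl, 430.0, 20.0) + 0.9 * _gauss(wl, 662.0, 24.0))
    k_cxc = 0.20 * (
        0.6 * _gauss(wl, 455.0, 15.0)
        + _gauss(wl, 480.0, 15.0)
        + 0.7 * _gauss(wl, 505.0, 15.0)
    )
    k_ant = 0.40 * _gauss(wl, 550.0, 35.0)
    k_cw = 80.0 * (
        0.12 * _gauss(wl, 970.0, 45.0)
        + 0.35 * _gauss(wl, 1200.0, 55.0)
        + 1.00 * _gauss(wl, 1450.0, 75.0)
        + 1.60 * _gauss(wl, 1940.0, 90.0)
    )
    k_cp = 200.0 * (_gauss(wl, 2180.0, 120.0) + 0.4 * _gauss(wl, 1730.0, 80.0))
    k_cbc = 80.0 * (_gauss(wl, 2300.0, 140.0) + 0.6 * _gauss(wl, 1720.0, 90.0))

    c = {name: traits[name].to_numpy()[:, None] for name in
         ("Cab", "Cxc", "Cant", "Cw", "Cp", "CBC")}
    return (
        c["Cab"] * k_cab[None, :]
        + c["Cxc"] * k_cxc[None, :]
        + c["Cant"] * k_ant[None, :]
        + c["Cw"] * k_cw[None, :]
        + c["Cp"] * k_cp[None, :]
        + c["CBC"] * k_cbc[None, :]
    )


def soil_spectrum(wl: np.ndarray, brightness: float | np.ndarray) -> np.ndarray:
    """Smooth bare-soil reflectance: monotone VIS slope, broad SWIR curvature.

    ``brightness`` in [0, 1] scales between the implemented wet (dark) and
    dry (bright) soil; no pigment or liquid-water features are present.
    """
    b = np.atleast_1d(np.asarray(brightness, dtype=float))[:, None]
    base = 0.08 + 0.30 * (wl - 400.0) / 2100.0 - 0.05 * _gauss(wl, 2200.0, 180.0)
    out = (0.4 + 0.8 * b) * base[None, :]
    return np.clip(out, 0.0, 1.0)


def _projection_factor(alia_deg: np.ndarray) -> np.ndarray:
    """Leaf projection factor G(ALIA): cos-weighted approximation.

    Planophile canopies (small ALIA) intercept more light per unit LAI than
    erectophile ones; only the relative attenuation matters here.
    """
    return 0.5 * (0.6 + 0.8 * np.cos(np.deg2rad(alia_deg)))


def surrogate_forward(
    traits: pd.DataFrame,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate canopy reflectance for each trait row.

    reflectance = gap * soil + (1 - gap) * leaf, with
    gap = exp(-G(ALIA) * LAI) and leaf = envelope(N) * exp(-absorption).
    Deterministic; all outputs in [0, 1].
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be a strictly increasing 1-d grid")
    if wl.min() < 400.0 or wl.max() > 2500.0:
        raise ValueError("wavelengths must lie within 400-2500 nm")
    missing = [t for t in TRAIT_NAMES if t not in traits.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")

    tau = _absorption_depth(traits, wl)
    n_struct = traits["N"].to_numpy()[:, None]
    leaf = (0.88 + 0.12 * (n_struct - 1.0)) * _leaf_envelope(wl)[None, :] * np.exp(-tau)

    lai = traits["LAI"].to_numpy()[:, None]
    g = _projection_factor(traits["ALIA"].to_numpy())[:, None]
    # beam path length through the canopy scales with 1/cos(sun zenith)
    gap = np.exp(-g * lai / np.cos(np.deg2rad(SUN_ZENITH_DEG)))

    soil = soil_spectrum(wl, traits["soil_brightness"].to_numpy())
    hot = traits["hotspot"].to_numpy()[:, None]
    # small hot-spot brightening of the canopy term; vanishes at LAI=0
    refl = gap * soil + (1.0 - gap) * leaf * (1.0 + 0.05 * hot)
    return np.clip(refl, 0.0, 1.0)


def add_noise(spectra: np.ndarray, percent: float, seed: int) -> np.ndarray:
    """Inject multiplicative Gaussian noise r -> r * (1 + eps), eps ~ N(0, percent).

    ``percent`` is a fraction (0.05 for 5% noise). Output clipped to [0, 1].
    """
    if percent < 0:
        raise ValueError("noise percent must be non-negative")
    spectra = np.asarray(spectra, dtype=float)
    if percent == 0:
        return spectra.copy()
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, percent, size=spectra.shape)
    return np.clip(spectra * (1.0 + eps), 0.0, 1.0)


def soil_library(
    n: int,
    seed: int,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Generate ``n`` distinct bare-soil / crop-residue-like spectra.

    Spectra are smooth, vegetation-feature-free (no chlorophyll trough at
    662 nm, no water bands), with varying brightness, VIS slope and SWIR
    curvature.  They emulate the non-vegetated samples added to a training
    set so the regressor behaves sanely over bare surfaces; callers flag the
    matching trait rows as non-vegetation rather than assigning zeros.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)
    brightness = rng.uniform(0.15, 1.0, size=n)
    slope = rng.uniform(0.7, 1.3, size=n)
    curvature = rng.uniform(0.5, 1.5, size=n)
    out = np.empty((n, wl.size))
    for i in range(n):
        base = (
            0.08
            + 0.30 * slope[i] * (wl - 400.0) / 2100.0
            - 0.05 * curvature[i] * _gauss(wl, 2200.0, 180.0)
            - 0.02 * curvature[i] * _gauss(wl, 1650.0, 250.0)
        )
        out[i] = (0.4 + 0.8 * brightness[i]) * base
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# synthetic scene
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneField:
    """One circular pivot-irrigated field: center (row, col) and radius in pixels."""

    row: float
    col: float
    radius: float


@dataclass
class SceneLayout:
    """Geometry of a synthetic scene: raster size and circular fields."""

    rows: int
    cols: int
    fields: Sequence[SceneField] = field(default_factory=tuple)
    noise_percent: float = 0.05

    def validate(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("raster dimensions must be positive")
        for f in self.fields:
            if (
                f.row - f.radius < 0
                or f.col - f.radius < 0
                or f.row + f.radius > self.rows
                or f.col + f.radius > self.cols
            ):
                raise ValueError(f"field {f} exceeds raster bounds")


def make_scene(
    layout: SceneLayout,
    ranges: TraitRanges | None = None,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, np.ndarray]:
    """Build a synthetic image cube of circular vegetated fields on bare soil.

    Each field has a single uniform trait vector (pivot irrigation produces
    homogeneous growth); the background is bare soil of spatially constant
    brightness.  Returns ``(cube, wavelengths, field_traits, truth)`` where
    ``cube`` is (rows, cols, bands), ``field_traits`` has one row per field,
    and ``truth`` is a (rows, cols, n_traits) raster that is NaN outside the
    vegetated disks.
    """
    layout.validate()
    ranges = ranges or TraitRanges()
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)

    n_fields = len(layout.fields)
    traits = sample_traits(ranges, n_fields, seed=int(rng.integers(2**31)))
    if n_fields:
        # pivot fields are actively cropped: keep them clearly vegetated
        lo, hi = ranges.bounds("LAI")
        traits["LAI"] = np.maximum(traits["LAI"].to_numpy(), lo + 0.3 * (hi - lo))

    soil_b = float(rng.uniform(0.3, 0.9))
    background = soil_spectrum(wl, soil_b)[0]

    cube = np.broadcast_to(background, (layout.rows, layout.cols, wl.size)).copy()
    truth = np.full((layout.rows, layout.cols, len(TRAIT_NAMES)), np.nan)

    if n_fields:
        spectra = surrogate_forward(traits, wl)
        rr, cc = np.mgrid[0 : layout.rows, 0 : layout.cols]
        for i, f in enumerate(layout.fields):
            mask = (rr - f.row) ** 2 + (cc - f.col) ** 2 <= f.radius**2
            cube[mask] = spectra[i]
            truth[mask] = traits.iloc[i].to_numpy()

    if layout.noise_percent > 0:
        cube = add_noise(cube, layout.noise_percent, seed=int(rng.integers(2**31)))
    return cube.astype(np.float32), wl, traits, truth
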