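"""End-to-end helpers: simulate a benchmark, train an AL-optimized bundle.

These functions wire the pipeline in its canonical order — LUT simulation,
PCA compression of the spectra, active-learning selection in feature space,
and packaging of the final PCA+GPR pair as a mappable bundle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .active_learning import ALOptions, ALResult, al_loop, rmse
from .dimred import PCAModel, fit_pca
from .mapping import ModelBundle
from .regression import GPROptions, fit_gpr, refit
from .spectral_io import LUT
from .synth_lut import (
    TraitRanges,
    add_noise,
    sample_traits,
    soil_library,
    surrogate_forward,
    default_wavelengths,
)

__all__ = ["Benchmark", "make_benchmark", "train_al_bundle", "train_full_bundle"]


@dataclass
class Benchmark:
    """A simulated pool + held-out noisy validation set for one experiment."""

    pool: LUT
    val_spectra: np.ndarray
    val_traits: pd.DataFrame
    wavelengths: np.ndarray
    seed: int


def make_benchmark(
    n_pool: int = 1000,
    n_val: int = 200,
    seed: int = 0,
    noise_percent: float = 0.05,
    n_soil: int = 0,
    ranges: TraitRanges | None = None,
) -> Benchmark:
    """Simulate the standard experiment: a 1k pool and noisy validation set.

    The pool spectra are noise-free RTM-surrogate output; the validation
    spectra receive multiplicative Gaussian noise (default 5%) to emulate
    measured data.  ``n_soil`` appends that many bare-soil spectra to the
    pool with NaN trait rows flagged as non-vegetation.
    """
    ranges = ranges or TraitRanges()
    wl = default_wavelengths()
    traits = sample_traits(ranges, n_pool, seed=seed)
    spectra = surrogate_forward(traits, wl)
    veg = np.ones(n_pool, dtype=bool)
    if n_soil > 0:
        soil = soil_library(n_soil, seed=seed + 101, wavelengths=wl)
        soil_traits = pd.DataFrame(
            np.nan, index=range(n_soil), columns=traits.columns
        )
        traits = pd.concat([traits, soil_traits], ignore_index=True)
        spectra = np.vstack([spectra, soil])
        veg = np.concatenate([veg, np.zeros(n_soil, dtype=bool)])
    pool = LUT(
        traits=traits, spectra=spectra, wavelengths=wl, is_vegetation=veg,
        meta={"seed": seed, "n_pool": n_pool, "n_soil": n_soil},
    )

    val_traits = sample_traits(ranges, n_val, seed=seed + 1)
    val_clean = surrogate_forward(val_traits, wl)
    val_spectra = add_noise(val_clean, noise_percent, seed=seed + 2)
    return Benchmark(pool=pool, val_spectra=val_spectra, val_traits=val_traits,
                     wavelengths=wl, seed=seed)


def _features(pool: LUT, val_spectra: np.ndarray,
              n_components: int) -> tuple[PCAModel, np.ndarray, np.ndarray]:
    pca = fit_pca(pool.spectra, n_components=n_components,
                  wavelengths=pool.wavelengths)
    return pca, pca.transform(pool.spectra), pca.transform(val_spectra)


def train_al_bundle(
    pool: LUT,
    val_spectra: np.ndarray,
    val_traits: pd.DataFrame,
    trait: str = "Cw",
    strategy: str = "ebd",
    n_components: int = 20,
    al_opts: ALOptions | None = None,
    include_soil: bool = False,
    soil_trait_value: float = 0.0,
) -> tuple[ModelBundle, ALResult]:
    """AL-optimize a training set for one trait and package the final model.

    Soil rows (non-vegetation, NaN traits) stay out of the candidate pool but
    the PCA is fit on all pool spectra so image pixels project consistently.
    With ``include_soil`` the pool's soil spectra are appended to the final
    training set, labeled ``soil_trait_value`` (bare surfaces carry none of
    the leaf trait), before mapping — this tames uncertainty over
    non-vegetated pixels.
    """
    pca, pool_f, val_f = _features(pool, val_spectra, n_components)
    veg = pool.is_vegetation
    result = al_loop(
        pool_f[veg], pool.traits.loc[veg, trait].to_numpy(),
        val_f, val_traits[trait].to_numpy(),
        strategy=strategy, opts=al_opts or ALOptions(),
    )
    model = result.model
    if include_soil and np.any(~veg):
        soil_f = pool_f[~veg]
        model = refit(model, np.vstack([model.X, soil_f]),
                      np.concatenate([model.y,
                                      np.full(soil_f.shape[0], soil_trait_value)]),
                      keep_scaling=True)
    bundle = ModelBundle(
        pca=pca, gpr=model, trait=trait, wavelengths=pool.wavelengths,
        meta={"strategy": strategy, "n_accepted": result.n_accepted,
              "final_rmse": result.final_rmse},
    )
    return bundle, result


def train_full_bundle(
    pool: LUT,
    trait: str = "Cw",
    n_components: int = 20,
    gpr_opts: GPROptions | None = None,
    val_spectra: np.ndarray | None = None,
    val_traits: pd.DataFrame | None = None,
    include_soil: bool = False,
    soil_trait_value: float = 0.0,
) -> tuple[ModelBundle, float]:
    """Train on the full pool (no AL); returns the bundle and val RMSE (or nan).

    ``include_soil`` appends the pool's bare-soil spectra to the training set
    labeled ``soil_trait_value``.
    """
    pca = fit_pca(pool.spectra, n_components=n_components,
                  wavelengths=pool.wavelengths)
    veg = pool.is_vegetation
    X = pca.transform(pool.spectra[veg])
    y = pool.traits.loc[veg, trait].to_numpy()
    model = fit_gpr(X, y, gpr_opts or GPROptions())
    if include_soil and np.any(~veg):
        # augment the already-trained model: keep its hyperparameters, add
        # the soil spectra as extra (zero-labeled) training points
        soil_f = pca.transform(pool.spectra[~veg])
        model = refit(model, np.vstack([X, soil_f]),
                      np.concatenate([y, np.full(soil_f.shape[0],
                                                 soil_trait_value)]),
                      keep_scaling=True)
    score = np.nan
    if val_spectra is not None and val_traits is not None:
        score = rmse(model.predict(pca.transform(val_spectra)),
                     val_traits[trait].to_numpy())
    bundle = ModelBundle(pca=pca, gpr=model, trait=trait,
                         wavelengths=pool.wavelengths,
                         meta={"strategy": "full", "final_rmse": score})
    return bundle, score
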