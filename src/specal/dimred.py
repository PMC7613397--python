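"""PCA compression of spectra, fit once on the training pool.

Hyperspectral bands are strongly collinear; compressing to a small number of
principal components (default 20) removes redundancy before kernel
regression.  The model is fit on the training pool only and then applied
unchanged to validation spectra and image pixels.  Scores are used raw by
default: their variance ordering carries the signal scale, and z-scoring
them was found to inflate near-noise tail components and degrade isotropic
kernels downstream (available via ``standardize=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PCAModel", "fit_pca"]


@dataclass
class PCAModel:
    """Trained PCA: band mean, orthonormal loadings and score scaling.

    ``band_scale`` is all-ones for covariance PCA; for correlation PCA it
    holds the per-band standard deviation, applied before centering, so the
    loadings remain orthonormal in the scaled space.
    """

    mean: np.ndarray                 # (bands,), in scaled band space
    components: np.ndarray           # (bands, k), orthonormal columns
    explained_variance: np.ndarray   # (k,), non-increasing
    band_scale: np.ndarray           # (bands,)
    wavelengths: np.ndarray | None
    standardize: bool
    score_mean: np.ndarray           # (k,) training-score mean (~0)
    score_std: np.ndarray            # (k,)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def _check_bands(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        if spectra.shape[1] != self.mean.size:
            raise ValueError(
                f"band grid mismatch: model has {self.mean.size} bands, "
                f"input has {spectra.shape[1]}"
            )
        return spectra

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        """Project spectra onto the components (z-scored if standardize).

        The projection uses a fixed per-element summation order (not BLAS),
        so results are bitwise identical however the input is chunked.
        """
        spectra = self._check_bands(spectra)
        centered = spectra / self.band_scale - self.mean
        scores = np.einsum("ij,jk->ik", centered, self.components, optimize=False)
        if self.standardize:
            scores = (scores - self.score_mean) / self.score_std
        return scores

    def inverse_transform(self, features: np.ndarray) -> np.ndarray:
        """Map component scores back to band space (lossy off-subspace)."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.n_components:
            raise ValueError("feature dimension does not match n_components")
        scores = features
        if self.standardize:
            scores = scores * self.score_std + self.score_mean
        return (scores @ self.components.T + self.mean) * self.band_scale


def fit_pca(
    spectra: np.ndarray,
    n_components: int = 20,
    wavelengths: np.ndarray | None = None,
    standardize: bool = False,
    correlation: bool = False,
) -> PCAModel:
    """Fit PCA on (n_samples x n_bands) spectra.

    ``correlation=True`` z-scores the bands first (correlation-matrix PCA);
    the default operates on raw reflectance covariance.  The loading sign is
    fixed so the largest-magnitude element of each component is positive,
    making results reproducible across runs.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    n, p = spectra.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds achievable rank {max_rank}"
        )
    band_scale = np.ones(p)
    if correlation:
        band_scale = spectra.std(axis=0, ddof=1)
        band_scale[band_scale == 0] = 1.0
    work = spectra / band_scale

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(work)
    components = pca.components_.T.copy()   # (bands, k)
    flip = np.sign(components[np.argmax(np.abs(components), axis=0),
                              np.arange(n_components)])
    flip[flip == 0] = 1.0
    components *= flip
    scores *= flip

    score_std = scores.std(axis=0, ddof=1)
    score_std[score_std == 0] = 1.0
    return PCAModel(
        mean=pca.mean_,
        components=components,
        explained_variance=pca.explained_variance_.copy(),
        band_scale=band_scale,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        standardize=standardize,
        score_mean=scores.mean(axis=0),
        score_std=score_std,
    )
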