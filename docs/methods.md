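# Methods

## Workflow

The package implements a hybrid retrieval chain: simulate a lookup table
(trait vectors → canopy reflectance), compress the spectra with PCA, select
an informative training subset by pool-based active learning around a
Gaussian-process regressor, and apply the final PCA+GPR bundle per pixel of
a hyperspectral cube, reporting the predictive mean, standard deviation and
coefficient of variation.

## Surrogate forward model

True leaf/canopy radiative transfer (PROSPECT-PRO coupled to 4SAIL) requires
external coefficient tables; `specal` ships a structurally analogous
surrogate instead:

* **Leaf term.** A bright scattering envelope (~0.46, gently declining into
  the SWIR, scaled by the leaf structure parameter N) attenuated as
  `exp(-Σ kᵢ(λ)·Cᵢ)`. Each biochemical has Gaussian specific-absorption
  features at its field-known wavelengths: chlorophyll at 430/662 nm,
  carotenoids at 455/480/505 nm, anthocyanins at 550 nm, water at
  970/1200/1450/1940 nm, protein at 1730/2180 nm, carbon-based constituents
  at 1720/2300 nm. Peak optical depths at the top of each trait range are
  2–4, so the trait–reflectance relation saturates nonlinearly as in the
  real models.
* **Canopy mixing.** `R = gap·soil + (1-gap)·leaf`, with
  `gap = exp(-G(ALIA)·LAI / cos θ_s)`, θ_s = 30° sun zenith, nadir view, and
  `G(ALIA) = 0.5·(0.6 + 0.8·cos ALIA)` a cosine-weighted projection
  approximation — planophile canopies intercept more per unit LAI. The
  hot-spot parameter adds a small brightening of the canopy term that
  vanishes as LAI → 0.
* **Soil.** A smooth, monotone-sloped spectrum with broad SWIR curvature,
  scaled between a dark wet and bright dry end member by the brightness
  factor. The soil library varies brightness, slope and curvature; soil
  spectra contain no pigment or liquid-water features.

Trait sampling is i.i.d. uniform within the standard ranges (N 1–2,
C_ab 0–80 µg/cm², C_xc 0–15 µg/cm², C_w 0.001–0.03 cm, C_ant 0–2 µg/cm²,
C_p 0.001–0.0025 g/cm², CBC 0.001–0.01 g/cm², LAI 0–7, ALIA 30–70°,
hotspot 0.01–0.5, soil brightness 0–1); the default band grid is an
EnMAP-like 242-band configuration, 420–2450 nm. Noise is multiplicative
relative Gaussian, `r → r·(1+ε)`, ε ~ N(0, 0.05) by default — the common
convention for reflectance noise, chosen because additive noise of that
magnitude would be unphysical in dark absorption bands. All generators are
pure functions of (configuration, seed); pre-noise reflectance is in [0, 1]
by construction and post-noise values are clipped.

**What the surrogate does and does not emulate.** It reproduces the features
the retrieval stack exercises: smooth band-correlated spectra, nonlinear
saturating trait response, soil/vegetation mixing, near-total loss of leaf
information as LAI → 0, and out-of-domain bare-soil spectra. It is not
radiometrically accurate, has no BRDF geometry beyond the fixed 30°/0°, no
atmosphere, and no trait correlations. Passing tests therefore demonstrate
correctness and the qualitative behaviour of the workflow on data with this
structure — not accuracy claims transferable to field spectra.

## Gaussian-process regressor

Isotropic RBF kernel plus noise on the PCA scores:
`k(x,x') = σ_f² exp(-‖x-x'‖²/2ℓ²) + σ_n² δ`. Targets are centered and
scaled to unit variance internally; hyperparameters (σ_f², ℓ, σ_n²) maximize
the log marginal likelihood by L-BFGS-B in log space with analytic
gradients, one median-heuristic start plus 4 seeded random restarts, bounds
σ_f² ∈ [1e-4, 1e3], ℓ within e^±5 of the median heuristic,
σ_n² ∈ [1e-8, 10]. A jitter of 1e-8 is added to the kernel diagonal and
floors the predictive variance; the reported variance includes σ_n². For
pools larger than `max_opt_n = 400` the likelihood search runs on a seeded
subsample (the optimum is stable under subsampling and the full-pool search
is an order of magnitude slower); the final weights always solve on all
rows. Constant targets short-circuit to a constant predictor.

PCA scores are used **unstandardized** by default: their variance ordering
carries the signal scale, and z-scoring was measured to inflate near-noise
tail components and cost ~0.02–0.05 held-out R² with the isotropic kernel
(`standardize=True` remains available, as does correlation-matrix PCA).
Sign conventions are fixed (largest-magnitude loading element positive) so
results are reproducible across runs. All heavy projections and kernel
reductions use fixed per-element summation (cdist + non-optimized einsum),
which makes predictions bitwise independent of chunking.

## Active-learning loop

From `init_n = 10` seeded random labeled samples (1% of the default 1k
pool): rank the remaining pool with the chosen heuristic, test the best
candidate by refitting the GP with it included, and accept only if the
validation RMSE strictly improves (optionally by at least
`min_improvement`); rejected candidates are removed permanently, and the
pool is re-ranked after each acceptance (re-ranking after every rejection is
available but changes nothing for model-independent diversity scores). The
loop ends when the pool is exhausted or `stop` acceptances are reached
(default: none). Tentative refits reuse the current hyperparameters (one
Cholesky each); the hyperparameters are re-optimized every `reopt_every = 10`
acceptances and the better of the two fits on validation is kept. Multiple
traits are independent single-output runs.

Heuristic details and defaults:

* **EBD** — min squared Euclidean distance to the labeled set (max–min
  rule); mean aggregation available.
* **ABD** — min angle to any labeled vector.
* **CBD** — k-means (k = 5, seeded) on the pool; score 1/(1+m) with m the
  labeled members of the candidate's cluster, ties broken by centroid
  proximity.
* **PAL** — population variance of k = 5 GP members, each trained on a
  seeded 75% subset without replacement, hyperparameters inherited from the
  current model.
* **EQB** — Shannon entropy of the 5 member predictions histogrammed into 5
  equal-width bins over each candidate's own prediction range.
* **RSAL** — posterior mean of an auxiliary GP fit to |training residuals|.
* **random** — seeded uniform scores.

k, the subset fraction and the bin count are package defaults (documented,
configurable), not values asserted from prior work. Diversity scores are
computed in a z-scored copy of the feature space (per-feature statistics
over the pool) so the first component's large variance does not dominate the
geometry; the regressor itself consumes raw scores.

**The random baseline.** In benchmark comparisons "random sampling" means
training on an equal-sized *ungated* random subset. Running random ranking
through the improvement-gated loop is itself a strong selector on clean
synthetic pools — the gate, not the ranking, does most of the work there —
so gating the baseline would compare two AL methods. On the surrogate
benchmark (1k pool, 10 initial, 200 noisy validation spectra) the
EBD-optimized model beats both the full-pool model and the ungated
equal-budget random baseline in mean final RMSE while keeping ≤ 30% of the
pool; gated-random is competitive with EBD under these clean conditions.

## Mapping

Valid pixels (finite, not nodata) are PCA-projected and predicted in chunks;
chunk size only batches memory. CV = 100·SD/estimate is masked where the
estimate ≤ ε = 1e-6 (trait units) and deliberately not clipped at 100%:
near-zero estimates over bare surfaces genuinely exceed it. Adding the
bare-soil library to a trained model (zero-labeled, keeping the model's
hyperparameters and target scaling — i.e., the same GP prior with more data)
provably never increases predictive variance and measurably lowers it over
bare-soil pixels; re-tuning hyperparameters after augmentation would change
the variance scale and is not done.

## Problem sizes and numerical choices

Experiments use the 1000-sample pool / 200-sample validation configuration
of the core study design; loop-soundness checks run a 500-sample pool with
stop = 20 over all seven strategies and five seeds, and recovery checks use
500 noiseless training samples against 300 held-out samples. Synthetic
scenes in tests are 40–50 px across with two pivot fields; the generators
and ENVI I/O handle 700×700 cubes. Ties in acceptance reject the candidate;
degenerate inputs (constant targets, zero-width prediction ranges in EQB,
all-zero residuals in RSAL) short-circuit to exact answers rather than
relying on the optimizer.

## Known limitations

* The low-LAI corner of the trait space is intrinsically unidentifiable
  (a sparse canopy is nearly bare soil); held-out R² for leaf traits is
  dominated by those samples and a particularly unlucky draw can push
  carotenoid recovery slightly below 0.95.
* The EBD-vs-random advantage is configuration-dependent: with a clean,
  same-distribution validation set the improvement gate alone is powerful,
  and gated-random matches gated-EBD; the advantage over ungated random
  subsets is robust.
* The GP is exact (dense); pools beyond ~5000 samples would need sparse
  approximations, which are out of scope.
* ENVI support is the minimal interoperable subset: float32, BSQ/BIL/BIP,
  `key = value` headers with a wavelength list; no georeferencing,
  compression or tiling.
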