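# Methods

## Problem and model

Given a segmented 3D tumor (CT volume plus binary mask, with voxel spacing
in mm) and right-censored outcomes (time T > 0, event flag E ∈ {0,1}), the
package estimates a scalar log-risk h(x) under the proportional-hazards
model

    λ(t | x) = λ₀(t) · exp(h(x)),

where λ₀ is an unspecified baseline hazard.  Classical Cox regression takes
h(x) = βᵀx linear in covariates; here h is a spherical convolutional
network applied to spherical projections of the tumor, trained with the
same objective as the linear model — the average negative log partial
likelihood over subjects with observed events,

    L(θ) = −(1/N_E) Σ_{i: E_i=1} [ h_θ(x_i) − log Σ_{j: T_j ≥ T_i} exp(h_θ(x_j)) ],

with Breslow handling of tied event times and each subject included in its
own risk set.  The partial likelihood eliminates λ₀, so only the risk
*ranking* is learned; scores are shift-invariant (asserted by a property
test).  Log-sum-exp terms are computed with a max shift and are stable for
scores of several hundred in magnitude.

## Spherical projections

All geometry is in physical mm; voxel (i,j,k) has its center at
origin + (i+½, j+½, k+½)·spacing.

An enclosing sphere of radius R (max in-mask voxel-center distance from the
tumor center of mass, plus one voxel diagonal) is centred on the unweighted
center of mass of the mask.  Three channels are computed on an equiangular
2B×2B grid (colatitudes θ_j = π(2j+1)/4B, longitudes φ_k = πk/B):

* **depth** — a ray is marched from the sphere surface toward the centroid
  in steps of half the minimum spacing, interpolating the mask trilinearly;
  the 0.5-crossing (refined by linear interpolation between the bracketing
  samples) at distance d from the sphere gives depth = R − d, the radial
  extent in mm.  Rays that never intersect the mask map to 0.  Values are
  kept in mm so that tumor size — a strongly prognostic trait — is
  preserved; an optional flag divides by R for a scale-free variant.  R is
  per-tumor.
* **intensity** — the image is affinely windowed from [−1000, 400] HU to
  [0, 1] (configurable), masked, and summed along the same rays times the
  step length (units: windowed HU·mm).
* **egi** — the mask (Gaussian-smoothed by σ = 1 voxel by default; raw
  voxel faces would collapse all normals onto six directions) is
  triangulated at the 0.5 isosurface (marching cubes, after 2-voxel
  zero-padding so border-touching masks stay closed); each triangle adds
  its area to the grid cell containing its outward normal, and cell totals
  are divided by cell solid angles.  Binning conserves total surface area
  exactly; the map is a density on S² (mm² per steradian).

Input configurations: `sphcnn1` = {depth}, `sphcnn2` = {egi, intensity}.
Channels are z-scored with mean/sd computed on the training split only; the
statistics are stored inside the model checkpoint and re-used verbatim for
any external cohort.

The equiangular grid oversamples the polar caps relative to the equator.
This is accepted (and inherited by everything downstream); area-uniform
sampling schemes exist but are out of scope.

## Harmonic analysis

Orthonormal complex spherical harmonics with Condon–Shortley phase; packed
coefficient index l(l+1)+m; real signals satisfy f_{l,−m} = (−1)^m conj(f_{lm}).
Colatitude quadrature weights are the classical equiangular weights
(closed form with the sin((2k+1)θ)/(2k+1) kernel); they integrate every
Legendre polynomial below degree 2B exactly, so the forward transform is
exact for band-limited signals and the round trip is the identity to
~1e−14.  Wigner-d matrices are obtained per degree as the exact matrix
exponential of −iβJ_y via diagonalization of J_y (cross-checked against a
symbolic implementation in the tests).  SO(3) signals live on 2B×2B×2B ZYZ
Euler grids (α, β, γ), expanded in E^l_mn = conj(D^l_mn); the same
colatitude weights make the SO(3) analysis/synthesis pair exact for
band-limited signals.

## Network

    input (C_in × 2B × 2B)
      → SHT → S² correlation with learned spectral filters (C₁ channels)
      → SO(3) grid at bandwidth B/2 → +bias, ReLU
      → spherical pool (spectral truncation to B/4)
      → SO(3) correlation (Wigner block products, C₂ channels) → +bias, ReLU
      → spherical pool (to B/8)
      → invariant readout (group mean + RMS per channel)
      → dense(40) → ReLU → linear(1) = h_θ

Correlations are computed spectrally: the S² correlation produces Wigner
blocks G^l = f̂ ψ̂^H per degree, and the SO(3) correlation multiplies blocks
O^l = 8π²/(2l+1) · G^l Ψ^l^H.  Filters are parameterized directly by their
spectral coefficients (real and imaginary parts, projected onto the
real-signal subspace), with He-style fan-in scaling per degree at
initialization, all seed-controlled.

Defaults: C₁ = 16, C₂ = 32, bandwidths B → B/2 → B/4 across layers, dense
width fixed at 40, library default B = 32; training experiments use B = 16.
These widths are the package's choice (deliberately small — deeper or wider
spherical networks were not needed for shape-driven risk and train
comfortably on one CPU).  The pointwise ReLU between convolutions is
standard practice; it acts on grid samples and mildly leaks energy above
the band limit.  The readout's RMS statistic supplements the group mean
(which a linear layer alone would reduce to a single spectral coefficient);
a flag disables it.  Whether a nonlinearity follows the dense layer is
configurable (`dense_relu`, on by default).

The training loop is pure numpy.  Every layer has a hand-written adjoint
(vector–Jacobian product); the composite gradient is verified against
central finite differences at step 1e−5 to better than 1e−4 relative
(coordinates where the perturbation flips a ReLU activation pattern are
excluded from the comparison — the loss is not differentiable there, so a
two-sided difference is not comparable to the one-sided analytic gradient).
Inside the model, synthesize→analyze round trips between band-limited
stages are algebraically collapsed and the readout is evaluated via
Parseval; a test asserts equality with the literal op-by-op composition to
1e−8.  The spectral path optionally runs in single precision (used by the
training configuration; double precision is the library default and is used
in all oracle tests).

### Rotation invariance

A rotation of the input map multiplies its harmonic coefficients by Wigner
matrices; both correlation layers are equivariant (the SO(3) signal is left
translated) and the readout integrates over the group, so h_θ is invariant
by construction.  On sampled grids the statement is exact for polar
rotations on the lattice of the *coarsest* internal grid (stride B/L₂ input
columns; the rectified signals are not band-limited, so only lattice
translations commute with ReLU + analysis).  Off-lattice grid rotations and
arbitrary rotations of the underlying solid (voxelized after rotating the
analytic phantom, which is exact) change h by on the order of 1–2.5% of the
cohort score spread — the spread (standard deviation of scores across the
phantom cohort) is the meaningful scale for a ranking score, since the
C-index only reads score differences.  This residual is input-discretization
noise, not network non-invariance: sub-voxel *translations* of the same
solids — to which the continuum pipeline is exactly invariant — shift the
scores slightly more (up to ~3.5% of the spread) than rotations do, because
each re-voxelization perturbs the depth map by up to half a voxel pointwise.

## Phantom generator

The generator emulates the statistical structure of an imaging–survival
cohort, not CT physics.  Solids are star-shaped about the grid center:
r(ω) = r₀(1 + Σ_{1≤l≤4} a_lm Ȳ_lm(ω)) with real orthonormal harmonics,
r₀ ~ U(6, 14) mm, coefficients i.i.d. normal with 1/l damping and a
per-subject overall scale.  Two clamps enforce the generator's contract:
the summed amplitude bound stays below 0.8 (positivity and
star-shapedness), and the worst-case radial slope |∇r|/r is clamped to
0.35 (via the Bernstein bound sup|∇Y_l| ≤ l·sup|Y_l|).  The slope clamp is
what guarantees the *depth oracle*: a voxelized mask's surface is only
known to half a voxel in the normal direction, and that uncertainty is
amplified radially by 1/cos(obliquity); at 0.35 the ray-marched depth map
agrees with the analytic r(ω) to well within half a voxel diagonal at
every grid node (worst 0.74 mm over 240 characterization draws against the
0.87 mm bound; 0.45 was found to violate the bound in the tail and was
rejected).  The band limit (l ≤ 4) is far below the mapping bandwidth, so
phantoms are representable without aliasing.

Interior texture: base 40 HU, six smooth blobs (σ = 4 mm, amplitude scaled
to ±half the nominal 60 HU), i.i.d. noise σ = 15 HU; background −1000 HU
(air).  Default voxel grid 48³ at 1 mm.

Survival: constant baseline hazard λ₀ = 0.05 events/month, so latent times
are exponential and simulated exactly by inverse transform,
T* = −log U / (λ₀ e^{βᵀx}); censoring C ~ U(0, 60) months independent of
covariates (the standard non-informative assumption), T = min(T*, C),
E = [T* ≤ C].  This yields roughly 55–65% events at the default risk
levels, a realistic censoring fraction for oncology cohorts.  Default
covariates are the z-scored log tumor volume and the z-scored asphericity
(the L2 norm of the perturbation coefficients), so β is the
per-standard-deviation log hazard of each shape trait and the risk is a
pure function of shape — learnable, in principle, from the spherical maps
alone.

What passing phantom tests does **not** show: robustness to real CT
texture, imaging artefacts, segmentation error, lesion attachment to
anatomy, or non-proportional hazards.  The phantoms certify the machinery
(projections, transforms, training, evaluation), not clinical performance.

## Survival statistics

* **C-index** (Harrell): pair (i, j) is comparable when the earlier subject
  has an event (or at tied times exactly one is an event); concordant means
  the earlier subject has the higher score; tied scores count ½.
  Implementations differ in these edge rules, so they are fixed here and
  checked pairwise against brute-force enumeration and against an
  independent library implementation.
* **Kaplan–Meier**: product-limit estimate over distinct event times;
  censored subjects leave the risk set just after their time.  With no
  censoring it reduces exactly to the empirical survival function.
* **Median stratification**: scores strictly above the cohort median are
  "high" risk; scores equal to the median go to "low" (deterministic tie
  rule), so distinct scores with even n split the cohort in half.
* **Linear CoxPH** (Newton on the Breslow partial likelihood, gradient
  ∞-norm < 1e−8, ≤100 iterations) is retained as the reference fitter
  connecting the loss to the classical model; it raises on separation or
  non-convergence and matches an independent implementation to ~1e−3.

## Training protocol

Adam (β = 0.9/0.999, lr 1e−3) with decoupled weight decay 1e−4 on weights
(not biases), 60 epochs, batch size 64 with risk sets formed within each
mini-batch; batches are reshuffled until each contains an event, and a
`full_batch` flag restores the exact full-cohort loss.  Model selection
keeps the checkpoint with the best validation loss (smoother than
validation C-index, which is reported alongside); the validation split is
event-stratified, as are cross-validation folds (so no fold is left without
events).  All splits, batches and initializations derive from the
experiment seed; two runs with the same inputs and seed are bit-identical.

The reference experiment (also run by `scripts/acceptance.py`) trains
`sphcnn1` at B = 16 on a 120-subject phantom cohort whose hazard is pure
volume (β = 1.5 per SD of log volume), holding out 20% for model selection,
and evaluates on an independent 120-subject cohort drawn with the same
generative parameters from a shifted seed — held-out in the strict sense
that neither training nor model selection ever saw it, and large enough
(n = 120) for a stable C-index.  The trained model reaches the C-index of
the true log-risk to within a few thousandths (≈0.79–0.80 under the default
censoring), and the β = 0 variant of the same protocol lands near 0.5.

## Numerical choices and degenerate inputs

* Depth rays that miss map to 0; empty masks raise (never a silent origin).
* Masks with values outside [0, 1] raise; images must share the mask grid.
* EGI falls back to the unsmoothed mask when smoothing pushes a tiny object
  below the 0.5 iso-level; degenerate (zero-area) triangles are dropped.
* The readout RMS uses a 1e−24 floor inside the square root; its gradient
  is well-defined at (numerically) zero signals.
* The Cox loss requires at least one event; the C-index requires at least
  one comparable pair; both raise informative errors otherwise.
* Serialization: models round-trip through HDF5 with predictions stable to
  1e−7; experiment configs round-trip through JSON bit-exactly.

## Limitations

* Bandwidths are powers-of-two multiples of 8 and capped by CPU budget
  (≤64); no GPU path.
* Multi-lesion masks are not split; the projections assume one connected,
  roughly star-shaped object.  Strongly non-star-shaped tumors alias in the
  depth map (the first crossing is taken).
* The equiangular grid's polar oversampling slightly over-weights polar
  structure in the standardization statistics.
* Phantom realism is deliberately limited (see above); clinical validation
  requires real cohorts, which this package reads (NIfTI + CSV) but does
  not provide.
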