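"""Synthetic tumor phantoms with known shape and survival ground truth.

Real cohorts for image-based survival prediction couple a CT volume, a tumor
segmentation and a right-censored outcome per subject.  This module emulates
that statistical structure with star-shaped solids: the radial function

    r(omega) = r0 * (1 + sum_{1 <= l <= L, |m| <= l} a_lm Ybar_lm(omega))

(real spherical harmonics Ybar_lm) gives every phantom a closed-form depth
map, which serves as the analytic oracle for the spherical projection code.
Interiors receive a smooth blob texture plus i.i.d. noise on a soft-tissue
baseline; the surrounding background is air (-1000 HU).

Survival times follow a proportional-hazards law with constant baseline
hazard lambda0 (exponential baseline, so simulation is exact by inverse
transform): T* = -log(U) / (lambda0 * exp(beta^T x)), censored at
C ~ Uniform(0, c_max).  Default covariates are the z-scored log tumor volume
and a perturbation-magnitude "asphericity" score, so the simulated risk is a
pure function of shape and therefore learnable from spherical projections.

The generator does not attempt realistic CT physics or lung anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .survival_stats import SurvivalCohort
from .volume import VoxelVolume

__all__ = [
    "StarShapedSolid",
    "PhantomCohortSpec",
    "TextureParams",
    "generate_solid",
    "generate_mask",
    "voxelize_solid",
    "generate_intensity",
    "simulate_survival",
    "generate_cohort",
    "real_sph_basis",
]


def real_sph_basis(max_degree: int, directions: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics for degrees 1..max_degree.

    directions: (..., 3) unit vectors.  Returns (n_basis, ...) with
    n_basis = (max_degree + 1)^2 - 1 (the constant l=0 term is excluded; the
    base radius plays that role).  Basis: Ybar_l0 = Y_l0,
    Ybar_lm = sqrt(2) Re Y_lm (m > 0), Ybar_l,-m = sqrt(2) Im Y_lm.
    """
    from scipy.special import sph_harm_y

    d = np.asarray(directions, dtype=float)
    shp = d.shape[:-1]
    d = d.reshape(-1, 3)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    rows = []
    for l in range(1, max_degree + 1):
        rows.append(sph_harm_y(l, 0, theta, phi).real)
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            rows.append(np.sqrt(2.0) * y.real)
            rows.append(np.sqrt(2.0) * y.imag)
    return np.stack(rows).reshape(len(rows), *shp)


@dataclass
class StarShapedSolid:
    """Solid that is star-shaped about ``center``: every ray from the center
    exits the solid exactly once, at radius r(omega)."""

    center: np.ndarray
    r0: float
    coefficients: np.ndarray  # real-harmonic perturbation coefficients, l >= 1
    max_degree: int
    rotation: np.ndarray | None = None  # applied rotation matrix (world <- body)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n_expected = (self.max_degree + 1) ** 2 - 1
        if self.coefficients.shape != (n_expected,):
            raise ValueError(
                f"expected {n_expected} coefficients for max_degree={self.max_degree}"
            )
        if self.r0 <= 0:
            raise ValueError("base radius must be positive")

    def radius(self, directions: np.ndarray) -> np.ndarray:
        """Analytic radial function r(omega) in mm for unit directions (..., 3)."""
        d = np.asarray(directions, dtype=float)
        if self.rotation is not None:
            # rotated solid: r'(w) = r(R^-1 w); row-vector form w @ R
            d = d @ self.rotation
        basis = real_sph_basis(self.max_degree, d)
        pert = np.tensordot(self.coefficients, basis, axes=(0, 0))
        return self.r0 * (1.0 + pert)

    def rotated(self, rotation_matrix: np.ndarray) -> "StarShapedSolid":
        """The same solid rotated about its center by ``rotation_matrix``."""
        R = np.asarray(rotation_matrix, dtype=float)
        base = self.rotation if self.rotation is not None else np.eye(3)
        return StarShapedSolid(
            center=self.center.copy(),
            r0=self.r0,
            coefficients=self.coefficients.copy(),
            max_degree=self.max_degree,
            rotation=R @ base,
        )

    def max_radius_bound(self) -> float:
        """Upper bound on r(omega) from |Ybar_lm| <= sqrt((2l+1)/(4 pi))."""
        bound = 1.0 + np.abs(self.coefficients) @ _amplitude_bounds(self.max_degree)
        return self.r0 * bound

    @property
    def asphericity(self) -> float:
        """Relative perturbation magnitude: L2 norm of the coefficients
        (equals the rms of r/r0 - 1 over the sphere, by orthonormality)."""
        return float(np.linalg.norm(self.coefficients) / np.sqrt(4 * np.pi))


def _amplitude_bounds(max_degree: int) -> np.ndarray:
    out = []
    for l in range(1, max_degree + 1):
        out.extend([np.sqrt((2 * l + 1) / (4 * np.pi))] * (2 * l + 1))
    return np.asarray(out)


@dataclass
class TextureParams:
    """Interior texture: ``base_hu`` plus smooth random blobs plus i.i.d.
    Gaussian noise; background (outside the mask) is air at -1000 HU."""

    base_hu: float = 40.0
    blob_count: int = 6
    blob_amplitude: float = 60.0
    blob_sigma_mm: float = 4.0
    noise_sd: float = 15.0
    background_hu: float = -1000.0


@dataclass
class PhantomCohortSpec:
    """Generative settings for a phantom cohort; identical spec + seed yields
    a bit-identical cohort."""

    n_subjects: int = 50
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    r0_range: tuple[float, float] = (6.0, 14.0)
    perturbation_scale: float = 0.35
    max_slope: float = 0.35  # bound on |grad r| / r (tan of surface obliquity)
    max_degree: int = 4
    texture: TextureParams = field(default_factory=TextureParams)
    beta_true: tuple[float, ...] = (1.0, 0.5)  # (log-volume, asphericity)
    lambda0: float = 0.05  # events per month
    c_max: float = 60.0  # censoring horizon, months
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.lambda0 <= 0:
            raise ValueError("baseline hazard lambda0 must be > 0")
        if self.c_max <= 0:
            raise ValueError("censoring horizon c_max must be > 0")
        if isinstance(self.texture, dict):
            self.texture = TextureParams(**self.texture)

    def subject_rng(self, subject_index: int, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, subject_index])


def generate_solid(spec: PhantomCohortSpec, subject_index: int) -> StarShapedSolid:
    """Draw the analytic star-shaped solid of one subject.

    Coefficients are drawn i.i.d. normal per harmonic with 1/l damping.  Two
    clamps keep the solid within the generator's contract: the summed
    amplitude bound stays below 0.8 (so r(omega) > 0 and the solid is
    star-shaped) and the worst-case radial slope |grad r| / r stays below
    ``spec.max_slope`` (Bernstein bound sup|grad Y_l| <= l sup|Y_l|).  The
    slope clamp is what guarantees that a voxelized mask's ray-marched depth
    matches the analytic r(omega) within half a voxel diagonal: the
    voxelization error normal to the surface is ~half a voxel and is
    amplified radially by 1/cos of the surface obliquity.
    """
    rng = spec.subject_rng(subject_index, stream=0)
    r0 = rng.uniform(*spec.r0_range)
    n_coef = (spec.max_degree + 1) ** 2 - 1
    raw = rng.normal(size=n_coef)
    degrees = np.concatenate(
        [np.full(2 * l + 1, l) for l in range(1, spec.max_degree + 1)]
    )
    coefs = spec.perturbation_scale * rng.uniform(0.2, 1.0) * raw / (
        degrees * np.sqrt(n_coef)
    )
    amp = _amplitude_bounds(spec.max_degree)
    bound = np.abs(coefs) @ amp
    if bound > 0.8:
        coefs *= 0.8 / bound
        bound = 0.8
    slope = (np.abs(coefs) * degrees) @ amp / (1.0 - bound)
    if slope > spec.max_slope:
        coefs *= spec.max_slope / slope
    center = _grid_center(spec)
    return StarShapedSolid(
        center=center, r0=r0, coefficients=coefs, max_degree=spec.max_degree
    )


def _grid_center(spec: PhantomCohortSpec) -> np.ndarray:
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    return shape * spacing / 2.0


def voxelize_solid(
    solid: StarShapedSolid,
    grid_shape,
    spacing,
    context: str = "solid",
) -> VoxelVolume:
    """Binary mask whose voxels are 1 iff their centers lie inside ``solid``.

    Raises if the solid cannot fit in the grid with a 2-voxel margin.
    """
    spacing = np.asarray(spacing, dtype=float)
    shape = np.asarray(grid_shape)
    half_extent = shape * spacing / 2.0
    needed = solid.max_radius_bound() + 2 * spacing.max()
    if np.any(needed > half_extent):
        need_vox = np.ceil(2 * needed / spacing).astype(int)
        raise ValueError(
            f"{context}: solid (radius bound {solid.max_radius_bound():.1f} mm) "
            f"exceeds grid; need grid_shape >= {tuple(need_vox)} at spacing "
            f"{tuple(spacing)}"
        )
    vol = VoxelVolume(np.zeros(tuple(grid_shape), dtype=np.uint8), spacing=spacing)
    xs, ys, zs = vol.voxel_centers_1d()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) - solid.center
    dist = np.linalg.norm(pts, axis=-1)
    inside_ball = dist <= solid.max_radius_bound()
    dirs = np.zeros_like(pts)
    nz = dist > 0
    dirs[nz] = pts[nz] / dist[nz, None]
    mask = np.zeros(tuple(grid_shape), dtype=np.uint8)
    sel = inside_ball & nz
    mask[sel] = (dist[sel] <= solid.radius(dirs[sel])).astype(np.uint8)
    mask[~nz] = 1  # the exact center is always interior
    vol.values = mask
    return vol


def generate_mask(
    spec: PhantomCohortSpec, subject_index: int
) -> tuple[VoxelVolume, StarShapedSolid]:
    """Voxelize one subject's solid: voxel is 1 iff its center lies inside.

    Returns the binary mask together with the analytic solid (the oracle for
    depth-projection tests).  Raises if the solid cannot fit with a 2-voxel
    margin.
    """
    solid = generate_solid(spec, subject_index)
    vol = voxelize_solid(
        solid, spec.grid_shape, spec.spacing, context=f"subject {subject_index}"
    )
    return vol, solid


def generate_intensity(
    mask: VoxelVolume,
    texture: TextureParams | None = None,
    seed: int | np.random.Generator = 0,
) -> VoxelVolume:
    """Fill the mask interior with textured intensities (HU).

    Inside: base_hu + smooth random blobs + i.i.d. Gaussian noise; outside:
    background_hu.  All values finite.
    """
    if not mask.is_binary():
        raise ValueError("mask must be binary")
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    texture = texture or TextureParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = np.full(mask.shape, texture.background_hu, dtype=float)
    interior = np.full(mask.shape, texture.base_hu, dtype=float)
    if texture.blob_count > 0 and texture.blob_amplitude != 0:
        idx = np.argwhere(m)
        pick = rng.integers(0, len(idx), size=texture.blob_count)
        amp = rng.normal(0.0, texture.blob_amplitude, size=texture.blob_count)
        field_ = np.zeros(mask.shape)
        field_[tuple(idx[pick].T)] += amp
        sigma_vox = texture.blob_sigma_mm / mask.spacing
        smooth = gaussian_filter(field_, sigma=sigma_vox)
        # renormalize so blob peaks are on the amplitude scale
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth *= texture.blob_amplitude / (2 * peak)
        interior += smooth
    if texture.noise_sd > 0:
        interior += rng.normal(0.0, texture.noise_sd, size=mask.shape)
    out[m] = interior[m]
    return VoxelVolume(out, spacing=mask.spacing.copy(), origin=mask.origin.copy())


def simulate_survival(
    spec: PhantomCohortSpec,
    covariates: np.ndarray,
    covariate_names: list[str] | None = None,
) -> SurvivalCohort:
    """Draw right-censored outcomes from the proportional-hazards law with
    constant baseline hazard.

    Latent event time T* = -log(U) / (lambda0 * exp(beta^T x)) with
    U ~ Uniform(0, 1); censoring time C ~ Uniform(0, c_max); observed
    T = min(T*, C), E = [T* <= C].  Returns times, events, covariates and the
    true log-risk h = beta^T x per subject.
    """
    if spec.lambda0 <= 0:
        raise ValueError("baseline hazard lambda0 must be > 0")
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != spec.n_subjects and X.shape[1] == spec.n_subjects:
        X = X.T
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    beta = np.asarray(spec.beta_true, dtype=float)[: X.shape[1]]
    h = X @ beta
    rng = np.random.default_rng([spec.seed, 2, 0])
    U = rng.uniform(size=len(h))
    t_star = -np.log(U) / (spec.lambda0 * np.exp(h))
    C = rng.uniform(0.0, spec.c_max, size=len(h))
    T = np.minimum(t_star, C)
    E = (t_star <= C).astype(int)
    # observation times of exactly zero are not representable; clip tiny values
    T = np.maximum(T, 1e-9)
    return SurvivalCohort(
        time=T,
        event=E,
        covariates=X,
        covariate_names=covariate_names,
        true_log_risk=h,
    )


@dataclass
class PhantomSubject:
    image: VoxelVolume
    mask: VoxelVolume
    solid: StarShapedSolid


def generate_cohort(
    spec: PhantomCohortSpec, with_images: bool = True
) -> tuple[list[PhantomSubject], SurvivalCohort]:
    """Generate the full phantom cohort: per-subject (image, mask, solid) and
    the survival table.

    Default covariates are the z-scored log tumor volume (mm^3, from the
    voxelized mask) and the z-scored asphericity score, so beta_true is the
    per-standard-deviation log-hazard of each shape trait.
    """
    subjects: list[PhantomSubject] = []
    logvol = np.empty(spec.n_subjects)
    asph = np.empty(spec.n_subjects)
    for i in range(spec.n_subjects):
        mask, solid = generate_mask(spec, i)
        image = (
            generate_intensity(mask, spec.texture, spec.subject_rng(i, stream=1))
            if with_images
            else None
        )
        vol_mm3 = float(mask.values.sum() * np.prod(mask.spacing))
        logvol[i] = np.log(vol_mm3)
        asph[i] = solid.asphericity
        subjects.append(PhantomSubject(image=image, mask=mask, solid=solid))

    def zscore(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    X = np.column_stack([zscore(logvol), zscore(asph)])
    cohort = simulate_survival(spec, X, covariate_names=["log_volume", "asphericity"])
    return subjects, cohort
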