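"""Projection of a segmented tumor onto spherical signals.

Three channels are supported, mirroring the three mappings used as spherical
CNN inputs:

``depth``
    An enclosing sphere of radius R is centred at the tumor's center of
    mass.  Along each grid direction omega a ray is marched from the sphere
    surface toward the centroid; the first intersection with the mask at
    distance d from the sphere gives depth(omega) = R - d, i.e. the radial
    extent of the tumor in mm (size-preserving; divide by R via
    ``normalize=True`` for a scale-free variant).  Rays that never hit the
    mask map to 0.

``intensity``
    The line integral (HU-windowed intensity x mm) of the masked image along
    the same rays, from sphere surface to centroid.

``egi``
    The extended Gaussian image: the distribution on the unit sphere of the
    outward surface-normal directions of the mask's 0.5-isosurface, weighted
    by triangle area (mm^2) and normalised per grid cell by the cell's solid
    angle, so the total integral equals the surface area.

All maps live on the equiangular 2B x 2B grid of :class:`SphericalGrid`;
note the polar rows of that grid oversample the sphere relative to the
equator (accepted and documented; see harmonics module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .harmonics import SphericalGrid
from .volume import VoxelVolume

__all__ = [
    "SphericalMap",
    "ChannelStats",
    "center_of_mass",
    "enclosing_radius",
    "depth_projection",
    "intensity_projection",
    "egi",
    "make_input",
    "cell_solid_angles",
    "INPUT_CONFIGS",
]

INPUT_CONFIGS = {
    "sphcnn1": ("depth",),
    "sphcnn2": ("egi", "intensity"),
}

DEFAULT_WINDOW = (-1000.0, 400.0)


@dataclass
class SphericalMap:
    """Named real channels sampled on a spherical grid."""

    grid: SphericalGrid
    channels: list[str]
    values: np.ndarray  # (n_channels, 2B, 2B)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.atleast_3d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 3 or self.values.shape[0] != len(self.channels):
            raise ValueError("values must be (n_channels, 2B, 2B)")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("values do not match grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spherical map contains non-finite values")

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channels.index(name)]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["bandwidth"] = self.grid.bandwidth
            f.attrs["channels"] = [c.encode() for c in self.channels]
            for key, val in self.metadata.items():
                f.attrs[key] = val
            for name in self.channels:
                f.create_dataset(f"/{name}", data=self.channel(name))

    @classmethod
    def from_hdf5(cls, path) -> "SphericalMap":
        with h5py.File(path, "r") as f:
            B = int(f.attrs["bandwidth"])
            channels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f.attrs["channels"]
            ]
            values = np.stack([f[f"/{name}"][()] for name in channels])
            meta = {
                k: f.attrs[k]
                for k in f.attrs
                if k not in ("bandwidth", "channels")
            }
        return cls(grid=SphericalGrid(B), channels=channels, values=values, metadata=meta)


def _require_mask(mask: VoxelVolume) -> np.ndarray:
    m = np.asarray(mask.values, dtype=float)
    if m.min() < 0 or m.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    if not (m >= 0.5).any():
        raise ValueError("mask is empty; cannot project an empty segmentation")
    return m


def center_of_mass(mask: VoxelVolume) -> np.ndarray:
    """Unweighted mean of in-mask voxel-center physical coordinates (mm)."""
    m = _require_mask(mask)
    idx = np.argwhere(m >= 0.5)
    return mask.index_to_physical(idx).mean(axis=0)


def enclosing_radius(mask: VoxelVolume, center: np.ndarray) -> float:
    """Radius (mm) of a sphere about ``center`` that strictly contains every
    mask voxel: the max voxel-center distance plus one voxel-diagonal."""
    m = _require_mask(mask)
    idx = np.argwhere(m >= 0.5)
    pts = mask.index_to_physical(idx)
    dmax = np.linalg.norm(pts - np.asarray(center), axis=1).max()
    return float(dmax + np.linalg.norm(mask.spacing))


def _ray_samples(mask: VoxelVolume, center: np.ndarray, grid: SphericalGrid, radius: float):
    """Fractional voxel indices of ray samples, sphere surface -> centroid.

    Returns (indices (ndir, nstep, 3), radii (nstep,), step length mm)."""
    step = float(mask.spacing.min()) / 2.0
    nstep = int(np.ceil(radius / step)) + 1
    radii = radius - step * np.arange(nstep)
    radii = np.clip(radii, 0.0, None)
    dirs = grid.directions().reshape(-1, 3)
    pts = center[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    return mask.physical_to_index(pts), radii, step


def _interp(volume_values: np.ndarray, frac_idx: np.ndarray) -> np.ndarray:
    flat = frac_idx.reshape(-1, 3).T
    out = map_coordinates(
        np.asarray(volume_values, dtype=float), flat, order=1, mode="constant", cval=0.0
    )
    return out.reshape(frac_idx.shape[:-1])


def depth_projection(
    mask: VoxelVolume,
    grid: SphericalGrid,
    center: np.ndarray | None = None,
    radius: float | None = None,
    normalize: bool = False,
) -> SphericalMap:
    """Depth map of the mask: radial extent of the tumor along each grid
    direction (mm; divided by R when ``normalize``).

    Rays are marched inward in steps of half the minimum spacing with
    trilinear mask interpolation; the first sample >= 0.5 defines the hit.
    """
    m = _require_mask(mask)
    c = center_of_mass(mask) if center is None else np.asarray(center, dtype=float)
    R = enclosing_radius(mask, c) if radius is None else float(radius)
    idx, radii, step = _ray_samples(mask, c, grid, R)
    samples = _interp(m, idx)  # (ndir, nstep)
    hit = samples >= 0.5
    first = np.argmax(hit, axis=1)
    rows = np.arange(samples.shape[0])
    depth = radii[first].astype(float)
    # refine the crossing radius by linear interpolation between the last
    # sample below threshold and the first at/above it
    refinable = hit.any(axis=1) & (first > 0)
    prev = samples[rows, np.maximum(first - 1, 0)]
    cur = samples[rows, first]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cur > prev, (0.5 - prev) / (cur - prev), 1.0)
    adj = radii[np.maximum(first - 1, 0)] - np.clip(frac, 0.0, 1.0) * step
    depth[refinable] = adj[refinable]
    depth = np.where(hit.any(axis=1), depth, 0.0)
    if normalize:
        depth = depth / R
    values = depth.reshape(1, *grid.shape)
    return SphericalMap(
        grid=grid,
        channels=["depth"],
        values=values,
        metadata={"centroid": c, "radius": R, "depth_normalized": normalize},
    )


def intensity_projection(
    image: VoxelVolume,
    mask: VoxelVolume,
    grid: SphericalGrid,
    center: np.ndarray | None = None,
    radius: float | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> SphericalMap:
    """Accumulated windowed intensity along each ray (units: windowed HU x mm).

    The image is affinely windowed from ``window`` to [0, 1] and masked
    (trilinear mask weight thresholded at 0.5); samples are summed times the
    step length, approximating the line integral from sphere to centroid.
    """
    if not image.same_geometry(mask):
        raise ValueError("image and mask must share grid geometry")
    m = _require_mask(mask)
    lo, hi = window
    if not hi > lo:
        raise ValueError("invalid intensity window")
    win = np.clip((np.asarray(image.values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    c = center_of_mass(mask) if center is None else np.asarray(center, dtype=float)
    R = enclosing_radius(mask, c) if radius is None else float(radius)
    idx, radii, step = _ray_samples(mask, c, grid, R)
    inside = _interp(m, idx) >= 0.5
    vals = _interp(win, idx)
    acc = (vals * inside).sum(axis=1) * step
    return SphericalMap(
        grid=grid,
        channels=["intensity"],
        values=acc.reshape(1, *grid.shape),
        metadata={"centroid": c, "radius": R, "window": np.asarray(window)},
    )


def cell_solid_angles(grid: SphericalGrid) -> np.ndarray:
    """Solid angle of each grid row's cell, shape (2B,).

    Cells are the equiangular Voronoi boxes [pi j / 2B, pi (j+1) / 2B) x
    [phi_k - pi/2B, phi_k + pi/2B); their solid angles sum to 4 pi."""
    B = grid.bandwidth
    edges = np.pi * np.arange(2 * B + 1) / (2 * B)
    return (np.cos(edges[:-1]) - np.cos(edges[1:])) * (np.pi / B)


def egi(
    mask: VoxelVolume,
    grid: SphericalGrid,
    smoothing_sigma: float = 1.0,
) -> SphericalMap:
    """Extended Gaussian image of the mask.

    The 0.5-isosurface of the (optionally Gaussian-smoothed, sigma in voxels)
    mask is triangulated; each triangle contributes its area (mm^2) to the
    grid cell containing its outward unit normal.  The returned map is an
    area density (mm^2 per steradian): cell totals divided by cell solid
    angles, so integrating the map over the sphere with the exact cell solid
    angles recovers the total triangulated surface area.
    """
    from skimage.measure import marching_cubes

    m = _require_mask(mask)
    # zero-pad so surfaces of masks touching the border stay closed
    pad = 2
    mp = np.pad(m, pad)
    if smoothing_sigma > 0:
        mp = gaussian_filter(mp, sigma=smoothing_sigma)
        if mp.max() < 0.5:
            # tiny object smoothed below threshold: fall back to raw mask
            mp = np.pad(m, pad)
    try:
        verts, faces, vnormals, _ = marching_cubes(
            mp, level=0.5, spacing=tuple(mask.spacing)
        )
    except (ValueError, RuntimeError) as exc:
        raise ValueError(
            "surface extraction failed; if the mask touches the volume "
            "border, pad the volume before computing the EGI"
        ) from exc
    tri = verts[faces]  # (ntri, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    ok = areas > 0
    tri_n = np.zeros_like(cross)
    tri_n[ok] = cross[ok] / (2 * areas[ok, None])
    # orient along the outward vertex normals supplied by marching_cubes
    ref = vnormals[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", tri_n, ref) < 0
    tri_n[flip] *= -1.0

    B = grid.bandwidth
    theta = np.arccos(np.clip(tri_n[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(tri_n[:, 1], tri_n[:, 0]), 2 * np.pi)
    j = np.clip((theta / (np.pi / (2 * B))).astype(int), 0, 2 * B - 1)
    k = np.mod(np.round(phi / (np.pi / B)).astype(int), 2 * B)
    hist = np.zeros(grid.shape)
    np.add.at(hist, (j[ok], k[ok]), areas[ok])
    density = hist / cell_solid_angles(grid)[:, None]
    return SphericalMap(
        grid=grid,
        channels=["egi"],
        values=density.reshape(1, *grid.shape),
        metadata={
            "surface_area": float(areas[ok].sum()),
            "smoothing_sigma": smoothing_sigma,
        },
    )


def make_input(
    config: str,
    image: VoxelVolume | None,
    mask: VoxelVolume,
    grid: SphericalGrid,
    window: tuple[float, float] = DEFAULT_WINDOW,
    egi_sigma: float = 1.0,
    normalize_depth: bool = False,
) -> SphericalMap:
    """Assemble the network input channels for one subject.

    ``sphcnn1`` uses only the segmentation's depth projection (one channel);
    ``sphcnn2`` uses the EGI plus the intensity projection from the image
    (two channels).  Per-channel cohort standardization is a separate,
    training-split-only step (:class:`ChannelStats`).
    """
    key = config.lower()
    if key not in INPUT_CONFIGS:
        raise ValueError(
            f"unknown input config {config!r}; choose from {sorted(INPUT_CONFIGS)}"
        )
    c = center_of_mass(mask)
    R = enclosing_radius(mask, c)
    parts = []
    meta = {"centroid": c, "radius": R, "config": key}
    for name in INPUT_CONFIGS[key]:
        if name == "depth":
            sm = depth_projection(mask, grid, center=c, radius=R, normalize=normalize_depth)
        elif name == "intensity":
            if image is None:
                raise ValueError("config sphcnn2 requires an intensity image")
            sm = intensity_projection(image, mask, grid, center=c, radius=R, window=window)
        else:
            sm = egi(mask, grid, smoothing_sigma=egi_sigma)
        parts.append(sm.channel(name))
        meta.update({k: v for k, v in sm.metadata.items() if k not in meta})
    return SphericalMap(
        grid=grid,
        channels=list(INPUT_CONFIGS[key]),
        values=np.stack(parts),
        metadata=meta,
    )


@dataclass
class ChannelStats:
    """Per-channel standardization statistics (training split only)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, maps: list[SphericalMap]) -> "ChannelStats":
        stack = np.stack([m.values for m in maps])  # (n, C, 2B, 2B)
        mean = stack.mean(axis=(0, 2, 3))
        sd = stack.std(axis=(0, 2, 3))
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd)

    def apply(self, m: SphericalMap) -> SphericalMap:
        vals = (m.values - self.mean[:, None, None]) / self.sd[:, None, None]
        meta = dict(m.metadata)
        meta["standardized"] = True
        return SphericalMap(grid=m.grid, channels=list(m.channels), values=vals, metadata=meta)
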