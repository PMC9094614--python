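"""Spherical and rotation-group harmonic analysis on equiangular grids.

This module provides the numerical backbone for the spherical network:

* an equiangular 2B x 2B sampling of the sphere (colatitudes strictly inside
  the poles) with quadrature weights that integrate every spherical harmonic
  of degree < 2B exactly,
* the forward/inverse spherical-harmonic transform (SHT), exact for signals
  band-limited below the bandwidth B,
* Wigner-d matrices on the same colatitude nodes and the corresponding
  synthesis/analysis pair for signals on the rotation group SO(3), sampled on
  a 2B x 2B x 2B ZYZ Euler-angle grid.

Conventions
-----------
Orthonormal complex spherical harmonics Y_lm with Condon-Shortley phase
(scipy's convention).  Real signals satisfy f_{l,-m} = (-1)^m conj(f_{lm}).
Coefficients are packed in a flat array of length B**2 with index
``l*(l+1) + m``.

SO(3) signals are expanded in the functions

    E^l_mn(alpha, beta, gamma) = e^{i m alpha} d^l_mn(beta) e^{i n gamma},

which are the complex conjugates of the Wigner-D matrix elements
D^l_mn = e^{-i m alpha} d^l_mn(beta) e^{-i n gamma}.  The E basis is
orthogonal with ||E^l_mn||^2 = 8 pi^2 / (2l+1).  Blocks are stored as
``(..., L, 2L-1, 2L-1)`` arrays with m, n offset by L-1; entries outside
|m|,|n| <= l are zero.

The grid oversamples the polar caps relative to the equator; this is the
usual trade-off of equiangular sampling and is accepted here (area-uniform
sampling schemes exist but are not used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "SphericalGrid",
    "lm_index",
    "num_coeffs",
    "sht_forward",
    "sht_inverse",
    "spherical_harmonic_values",
    "parseval_norm",
    "wigner_d_matrices",
    "wigner_d_table",
    "so3_synthesize",
    "so3_analyze",
    "so3_weights",
    "so3_integral",
    "block_degree_mask",
    "real_symmetrize",
    "so3_real_symmetrize",
]


# ---------------------------------------------------------------------------
# Sphere grid and quadrature
# ---------------------------------------------------------------------------

def _theta_weights(bandwidth: int) -> np.ndarray:
    """Colatitude quadrature weights a_j with sum_j a_j P_l(cos theta_j) =
    2 delta_{l0} for all l < 2B (exact; Driscoll-Healy style)."""
    B = bandwidth
    j = np.arange(2 * B)
    theta = np.pi * (2 * j + 1) / (4 * B)
    k = np.arange(B)[:, None]
    s = np.sum(np.sin((2 * k + 1) * theta[None, :]) / (2 * k + 1), axis=0)
    return (2.0 / B) * np.sin(theta) * s


@dataclass(frozen=True)
class SphericalGrid:
    """Equiangular 2B x 2B sampling of the unit sphere.

    Colatitudes theta_j = pi (2j+1) / (4B), longitudes phi_k = pi k / B.
    ``weights[j]`` is the full per-point quadrature weight (including the
    longitude spacing pi/B), so ``sum_j weights[j] * 2B == 4 pi``.
    """

    bandwidth: int
    thetas: np.ndarray = field(repr=False, default=None)
    phis: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        B = int(self.bandwidth)
        if B < 1:
            raise ValueError(f"bandwidth must be >= 1, got {B}")
        j = np.arange(2 * B)
        object.__setattr__(self, "thetas", np.pi * (2 * j + 1) / (4 * B))
        object.__setattr__(self, "phis", np.pi * j / B)
        object.__setattr__(self, "weights", _theta_weights(B) * np.pi / B)

    @property
    def shape(self) -> tuple[int, int]:
        return (2 * self.bandwidth, 2 * self.bandwidth)

    def directions(self) -> np.ndarray:
        """Unit vectors for every grid node, shape (2B, 2B, 3)."""
        th = self.thetas[:, None]
        ph = self.phis[None, :]
        return np.stack(
            [
                np.sin(th) * np.cos(ph) * np.ones_like(ph),
                np.sin(th) * np.sin(ph) * np.ones_like(ph),
                np.cos(th) * np.ones_like(ph),
            ],
            axis=-1,
        )

    def integrate(self, values: np.ndarray) -> np.ndarray:
        """Quadrature integral over the sphere of grid samples (last two axes)."""
        return np.einsum("...jk,j->...", values, self.weights)


def lm_index(l, m):
    """Flat coefficient index of (l, m): l*(l+1)+m."""
    l = np.asarray(l)
    m = np.asarray(m)
    return l * (l + 1) + m


def num_coeffs(bandwidth: int) -> int:
    return bandwidth * bandwidth


@lru_cache(maxsize=16)
def _lm_arrays(bandwidth: int) -> tuple[np.ndarray, np.ndarray]:
    ls = np.concatenate([np.full(2 * l + 1, l) for l in range(bandwidth)])
    ms = np.concatenate([np.arange(-l, l + 1) for l in range(bandwidth)])
    return ls, ms


@lru_cache(maxsize=8)
def _legendre_table(bandwidth: int) -> np.ndarray:
    """Y_lm(theta_j, 0) for the grid colatitudes: real array (B^2, 2B)."""
    from scipy.special import sph_harm_y

    grid = SphericalGrid(bandwidth)
    ls, ms = _lm_arrays(bandwidth)
    tab = sph_harm_y(
        ls[:, None], ms[:, None], grid.thetas[None, :], 0.0
    )
    return np.ascontiguousarray(tab.real)


def spherical_harmonic_values(bandwidth: int, thetas, phis) -> np.ndarray:
    """Y_lm at arbitrary points; returns complex array (B^2, npts)."""
    from scipy.special import sph_harm_y

    ls, ms = _lm_arrays(bandwidth)
    th = np.asarray(thetas, dtype=float).ravel()
    ph = np.asarray(phis, dtype=float).ravel()
    return sph_harm_y(ls[:, None], ms[:, None], th[None, :], ph[None, :])


# ---------------------------------------------------------------------------
# Spherical harmonic transform
# ---------------------------------------------------------------------------

def sht_forward(values: np.ndarray, grid: SphericalGrid) -> np.ndarray:
    """Forward SHT of grid samples (..., 2B, 2B) -> packed coefficients (..., B^2).

    f_lm = sum_{jk} w_j f(theta_j, phi_k) conj(Y_lm(theta_j, phi_k)); exact for
    band-limited input of degree < B.
    """
    B = grid.bandwidth
    values = np.asarray(values)
    if values.shape[-2:] != (2 * B, 2 * B):
        raise ValueError(
            f"grid/values mismatch: expected trailing shape {(2*B, 2*B)}, "
            f"got {values.shape[-2:]}"
        )
    ls, ms = _lm_arrays(B)
    # DFT over longitude: F[..., j, m_bin] with bin m mod 2B
    F = np.fft.fft(values, axis=-1)
    Fg = F[..., :, ms % (2 * B)]  # (..., 2B, B^2)
    tab = _legendre_table(B)  # (B^2, 2B)
    wtab = tab * grid.weights[None, :]
    return np.einsum("...ji,ij->...i", Fg, wtab)


def sht_inverse(coeffs: np.ndarray, grid: SphericalGrid, real: bool = True) -> np.ndarray:
    """Inverse SHT: packed coefficients (..., B^2) -> grid samples (..., 2B, 2B)."""
    B = grid.bandwidth
    coeffs = np.asarray(coeffs)
    if coeffs.shape[-1] != B * B:
        raise ValueError(
            f"bandwidth mismatch: expected {B*B} coefficients, got {coeffs.shape[-1]}"
        )
    ls, ms = _lm_arrays(B)
    tab = _legendre_table(B)  # (B^2, 2B)
    # aggregate coefficients sharing a longitude frequency bin
    agg = np.zeros((2 * B, B * B))
    agg[ms % (2 * B), np.arange(B * B)] = 1.0
    # spec[..., j, mbin] = sum_i coeffs_i Y-profile_i(j) [m_i -> mbin]
    spec = np.einsum("...i,ij,mi->...jm", coeffs, tab, agg)
    # synthesize sum_m spec e^{i m phi_k} = 2B * ifft over the frequency axis
    out = np.fft.ifft(spec, axis=-1) * (2 * B)
    return out.real if real else out


def parseval_norm(values: np.ndarray, grid: SphericalGrid) -> np.ndarray:
    """Weighted L2 norm on the grid: sqrt(integral |f|^2 d omega)."""
    return np.sqrt(grid.integrate(np.abs(values) ** 2))


# ---------------------------------------------------------------------------
# Wigner-d and SO(3) transforms
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _jy_eig(l: int):
    dim = 2 * l + 1
    Jp = np.zeros((dim, dim))
    ns = np.arange(-l, l)
    for i, n in enumerate(ns):
        Jp[i + 1, i] = np.sqrt(l * (l + 1) - n * (n + 1))
    Jy = (Jp - Jp.T) / 2j
    w, V = np.linalg.eigh(Jy)
    return w, V


def wigner_d_matrices(l: int, betas) -> np.ndarray:
    """d^l_mn(beta) for each beta; shape (len(betas), 2l+1, 2l+1).

    Computed as the matrix exponential exp(-i beta J_y) via exact
    diagonalization of J_y; rows/columns ordered m, n = -l .. l.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    w, V = _jy_eig(l)
    phase = np.exp(-1j * betas[:, None] * w[None, :])
    out = np.einsum("mk,bk,nk->bmn", V, phase, V.conj())
    return np.ascontiguousarray(out.real)


@lru_cache(maxsize=8)
def _wigner_table_cached(L: int, grid_B: int) -> np.ndarray:
    grid = SphericalGrid(grid_B)
    tab = np.zeros((L, 2 * grid_B, 2 * L - 1, 2 * L - 1))
    c = L - 1
    for l in range(L):
        d = wigner_d_matrices(l, grid.thetas)
        tab[l, :, c - l : c + l + 1, c - l : c + l + 1] = d
    return tab


def wigner_d_table(L: int, grid_B: int | None = None, single: bool = False) -> np.ndarray:
    """Padded Wigner-d table (L, 2B, 2L-1, 2L-1) on the grid colatitudes.

    ``tab[l, j, m + L - 1, n + L - 1] = d^l_mn(theta_j)``; zero outside
    |m|, |n| <= l.  ``grid_B`` defaults to L (matching 2L x 2L x 2L grids).
    """
    if grid_B is None:
        grid_B = L
    if single:
        return _wigner_table_f32(int(L), int(grid_B))
    return _wigner_table_cached(int(L), int(grid_B))


@lru_cache(maxsize=8)
def _wigner_table_f32(L: int, grid_B: int) -> np.ndarray:
    return _wigner_table_cached(L, grid_B).astype(np.float32)


def block_degree_mask(L: int) -> np.ndarray:
    """Boolean (L, 2L-1, 2L-1) mask of valid (l, m, n) block entries."""
    c = L - 1
    mask = np.zeros((L, 2 * L - 1, 2 * L - 1), dtype=bool)
    for l in range(L):
        mask[l, c - l : c + l + 1, c - l : c + l + 1] = True
    return mask


def so3_weights(grid_B: int) -> np.ndarray:
    """Per-point SO(3) quadrature weights over beta rows; the full weight of
    node (alpha_a, beta_j, gamma_c) is ``weights[j]``.  Normalized so the
    total over the 2B x 2B x 2B grid is 8 pi^2 (the group volume)."""
    return _theta_weights(grid_B) * (np.pi / grid_B) ** 2


@lru_cache(maxsize=32)
def _dft_matrix(nB: int, L: int, sign: int, single: bool) -> np.ndarray:
    """(nB, 2L-1) matrix e^{sign * i * angle_a * m} for the frequency bins
    m = -(L-1) .. L-1 on the 2B-point uniform angle grid."""
    a = 2 * np.pi * np.arange(nB) / nB
    m = np.arange(-(L - 1), L)
    W = np.exp(sign * 1j * np.outer(a, m))
    return W.astype(np.complex64) if single else W


def _freq_synth(A: np.ndarray, nB: int) -> np.ndarray:
    """(..., j, m, n) frequency-bin array -> (..., j, a, c) grid samples via
    sum_{mn} A e^{+i(m alpha_a + n gamma_c)} (batched matmuls, no padding)."""
    L = (A.shape[-1] + 1) // 2
    single = A.dtype == np.complex64
    W = _dft_matrix(nB, L, +1, single)
    T = A @ W.T  # (..., j, m, c)
    T = np.swapaxes(T, -2, -1) @ W.T  # (..., j, c, a)
    return np.swapaxes(T, -2, -1)  # (..., j, a, c)


def _freq_gather(X: np.ndarray, L: int) -> np.ndarray:
    """(..., a, j, c) grid samples -> (..., j, m, n) frequency bins via
    sum_{ac} X e^{-i(m alpha_a + n gamma_c)}."""
    nB = X.shape[-1]
    single = X.dtype in (np.float32, np.complex64)
    W = _dft_matrix(nB, L, -1, single)
    T = X @ W  # (..., a, j, n)
    T = np.moveaxis(T, -3, -1) @ W  # (..., j, n, m)
    return np.swapaxes(T, -2, -1)  # (..., j, m, n)


def so3_synthesize(blocks: np.ndarray, grid_B: int, real: bool = True) -> np.ndarray:
    """Synthesize SO(3) grid samples from Wigner blocks.

    f(alpha_a, beta_j, gamma_c) = sum_{lmn} G[l,m,n] e^{i m alpha} d^l_mn(beta)
    e^{i n gamma}, on the 2B x 2B x 2B ZYZ grid with alpha_a = gamma_a =
    pi a / B and beta_j the equiangular colatitudes.

    blocks: (..., L, 2L-1, 2L-1) with L <= grid_B.
    returns (..., 2B, 2B, 2B) with axes (alpha, beta, gamma).
    """
    blocks = np.asarray(blocks)
    L = blocks.shape[-3]
    if L > grid_B:
        raise ValueError(f"band limit {L} exceeds grid bandwidth {grid_B}")
    single = blocks.dtype == np.complex64
    tab = wigner_d_table(L, grid_B, single=single)  # (L, 2B, 2L-1, 2L-1)
    A = np.einsum("...lmn,ljmn->...jmn", blocks, tab, optimize=True)
    out = _freq_synth(A, 2 * grid_B)  # (..., j, alpha, gamma)
    out = np.moveaxis(out, -2, -3)  # -> (..., alpha, beta, gamma)
    return out.real if real else out


def so3_analyze(values: np.ndarray, L: int) -> np.ndarray:
    """Project SO(3) grid samples onto Wigner blocks of degree < L.

    Inverse of :func:`so3_synthesize` for signals band-limited below L
    (L <= grid bandwidth).  values: (..., 2B, 2B, 2B), axes (alpha, beta,
    gamma); returns blocks (..., L, 2L-1, 2L-1).
    """
    values = np.asarray(values)
    nB = values.shape[-3]
    if values.shape[-3:] != (nB, nB, nB) or nB % 2:
        raise ValueError(f"expected cubic 2B x 2B x 2B trailing shape, got {values.shape[-3:]}")
    grid_B = nB // 2
    if L > grid_B:
        raise ValueError(f"band limit {L} exceeds grid bandwidth {grid_B}")
    single = values.dtype in (np.float32, np.complex64)
    Fg = _freq_gather(values, L)  # (..., beta, m, n)
    tab = wigner_d_table(L, grid_B, single=single)
    ls = np.arange(L)
    scale = ((2 * ls + 1) / (8 * np.pi**2)).astype(tab.dtype)
    wj = so3_weights(grid_B).astype(tab.dtype)
    blocks = np.einsum("...jmn,j,ljmn->...lmn", Fg, wj, tab, optimize=True)
    blocks = blocks * scale[:, None, None]
    mask = block_degree_mask(L)
    return blocks * mask


@lru_cache(maxsize=16)
def _conj_perm(bandwidth: int) -> tuple[np.ndarray, np.ndarray]:
    ls, ms = _lm_arrays(bandwidth)
    perm = lm_index(ls, -ms)
    sign = np.where(ms % 2 == 0, 1.0, -1.0)
    return perm, sign


def real_symmetrize(coeffs: np.ndarray) -> np.ndarray:
    """Project packed SHT coefficients onto the real-signal subspace
    (c_{l,-m} = (-1)^m conj(c_{lm}))."""
    coeffs = np.asarray(coeffs, dtype=complex)
    B = int(round(np.sqrt(coeffs.shape[-1])))
    perm, sign = _conj_perm(B)
    return 0.5 * (coeffs + sign * np.conj(coeffs[..., perm]))


def so3_real_symmetrize(blocks: np.ndarray) -> np.ndarray:
    """Project Wigner blocks onto the real-signal subspace
    (G^l_{mn} = (-1)^{m-n} conj(G^l_{-m,-n}))."""
    blocks = np.asarray(blocks, dtype=complex)
    L = blocks.shape[-3]
    m = np.arange(-(L - 1), L)
    sgn = np.where((m[:, None] - m[None, :]) % 2 == 0, 1.0, -1.0)
    flipped = np.conj(blocks[..., ::-1, ::-1])
    return 0.5 * (blocks + sgn * flipped)


def so3_integral(values: np.ndarray) -> np.ndarray:
    """Quadrature integral over SO(3) of grid samples (last three axes)."""
    nB = values.shape[-2]
    w = so3_weights(nB // 2)
    return np.einsum("...ajc,j->...", values, w)
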