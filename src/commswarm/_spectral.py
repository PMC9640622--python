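"""Shared spectral helpers for periodic square grids.

Fields live on an M x M grid over a periodic box of side L, with
``field[i, j]`` the value at ``x = i * L/M``, ``y = j * L/M`` (x along axis
0, y along axis 1).  Real FFTs are used throughout (last axis halved).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rfft2_wavenumbers",
    "spectral_gradient",
    "spectral_curl",
    "dealias_mask",
    "bilinear_sample",
    "cic_deposit",
    "gaussian_filter_hat",
]


def rfft2_wavenumbers(M: int, L: float):
    """Angular wavenumbers (kx, ky) broadcastable to the rfft2 layout."""
    kx = 2.0 * np.pi * np.fft.fftfreq(M, d=L / M)
    ky = 2.0 * np.pi * np.fft.rfftfreq(M, d=L / M)
    return kx[:, None], ky[None, :]


def spectral_gradient(field: np.ndarray, L: float):
    """(d/dx, d/dy) of a real periodic field by spectral differentiation."""
    M = field.shape[0]
    kx, ky = rfft2_wavenumbers(M, L)
    fh = np.fft.rfft2(field)
    gx = np.fft.irfft2(1j * kx * fh, s=field.shape)
    gy = np.fft.irfft2(1j * ky * fh, s=field.shape)
    return gx, gy


def spectral_curl(px: np.ndarray, py: np.ndarray, L: float) -> np.ndarray:
    """Scalar curl  d(py)/dx - d(px)/dy  of a 2D vector field."""
    M = px.shape[0]
    kx, ky = rfft2_wavenumbers(M, L)
    return np.fft.irfft2(
        1j * kx * np.fft.rfft2(py) - 1j * ky * np.fft.rfft2(px), s=px.shape
    )


def dealias_mask(M: int) -> np.ndarray:
    """Boolean 2/3-rule mask in the rfft2 layout (True = keep)."""
    cut = M // 3
    ix = np.abs(np.fft.fftfreq(M) * M)
    iy = np.abs(np.fft.rfftfreq(M) * M)
    return (ix[:, None] <= cut) & (iy[None, :] <= cut)


def bilinear_sample(field: np.ndarray, positions: np.ndarray, L: float) -> np.ndarray:
    """Bilinear interpolation of a periodic grid field at off-grid points."""
    M = field.shape[0]
    g = np.asarray(positions, dtype=float) * (M / L)
    i0 = np.floor(g).astype(np.int64)
    frac = g - i0
    i0 %= M
    i1 = (i0 + 1) % M
    fx, fy = frac[:, 0], frac[:, 1]
    return (
        field[i0[:, 0], i0[:, 1]] * (1 - fx) * (1 - fy)
        + field[i1[:, 0], i0[:, 1]] * fx * (1 - fy)
        + field[i0[:, 0], i1[:, 1]] * (1 - fx) * fy
        + field[i1[:, 0], i1[:, 1]] * fx * fy
    )


def cic_deposit(positions: np.ndarray, weights, M: int, L: float) -> np.ndarray:
    """Cloud-in-cell (bilinear) deposition onto the grid, as a density.

    The returned field has domain integral exactly ``sum(weights)``
    (deposited weights are divided by the cell area).
    """
    dx = L / M
    g = np.asarray(positions, dtype=float) / dx
    i0 = np.floor(g).astype(np.int64)
    frac = g - i0
    i0 %= M
    i1 = (i0 + 1) % M
    fx, fy = frac[:, 0], frac[:, 1]
    w = np.broadcast_to(np.asarray(weights, dtype=float), (len(g),)) / dx**2
    out = np.zeros((M, M))
    np.add.at(out, (i0[:, 0], i0[:, 1]), w * (1 - fx) * (1 - fy))
    np.add.at(out, (i1[:, 0], i0[:, 1]), w * fx * (1 - fy))
    np.add.at(out, (i0[:, 0], i1[:, 1]), w * (1 - fx) * fy)
    np.add.at(out, (i1[:, 0], i1[:, 1]), w * fx * fy)
    return out


def gaussian_filter_hat(M: int, L: float, width: float) -> np.ndarray:
    """rfft2 transfer function of a normalized periodic Gaussian of width w.

    Convolving a density with this kernel preserves the domain integral
    (the k = 0 factor is exactly 1).
    """
    kx, ky = rfft2_wavenumbers(M, L)
    return np.exp(-0.5 * width**2 * (kx**2 + ky**2))
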