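"""Independent brute-force oracles used by the test suite.

These deliberately avoid the FFT code paths under test: the transforms are
literal double sums over pixels/frequencies, and the spectral-energy oracle
works directly on annulus sums of |F|^2 computed from the slow transform.
They are O(N^4), so keep grids small (<= 16 px) when calling them.
"""

from __future__ import annotations

import numpy as np


def slow_dft2(f: np.ndarray) -> np.ndarray:
    """Literal forward DFT: F(kx,ky) = sum f(nx,ny) exp(-2 pi i (kx nx + ky ny)/N)."""
    n = f.shape[0]
    out = np.zeros((n, n), dtype=complex)
    nx = np.arange(n)
    for kx in range(n):
        for ky in range(n):
            phase = np.exp(-2j * np.pi * (kx * nx[:, None] + ky * nx[None, :]) / n)
            out[kx, ky] = np.sum(f * phase)
    return out


def signed_freqs(n: int) -> np.ndarray:
    """Signed (centred) frequency index of each fft-layout bin."""
    return np.where(np.arange(n) <= (n - 1) // 2, np.arange(n), np.arange(n) - n).astype(float)


def slow_lowpass(f: np.ndarray, radius: float) -> np.ndarray:
    """Literal inverse transform over retained frequencies only:
    f~(nx,ny) = (1/N^2) sum_{|k| < r} F(kx,ky) exp(+2 pi i (kx nx + ky ny)/N)."""
    n = f.shape[0]
    coeffs = slow_dft2(f)
    k = signed_freqs(n)
    out = np.zeros((n, n), dtype=complex)
    nx = np.arange(n)
    for kx in range(n):
        for ky in range(n):
            if np.hypot(k[kx], k[ky]) >= radius:
                continue
            phase = np.exp(2j * np.pi * (kx * nx[:, None] + ky * nx[None, :]) / n)
            out += coeffs[kx, ky] * phase
    return (out / n**2).real


def annulus_energy_profile(f: np.ndarray, radii: tuple[float, ...]) -> np.ndarray:
    """Expected partial complexities from spectral energy alone (Parseval):
    C_k = (1/(2 N^4)) * sum of |F|^2 over the ring radii[k] <= d < radii[k-1]."""
    n = f.shape[0]
    coeffs = np.fft.fft2(f)  # spectrum only; the path under test is the filter+overlap chain
    k = signed_freqs(n)
    dist = np.hypot(k[:, None], k[None, :])
    bounds = (np.inf,) + tuple(radii)
    out = np.zeros(len(radii))
    for i in range(len(radii)):
        ring = (dist >= bounds[i + 1]) & (dist < bounds[i])
        out[i] = np.sum(np.abs(coeffs[ring]) ** 2) / (2 * n**4)
    return out
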