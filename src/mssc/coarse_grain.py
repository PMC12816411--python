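r"""Fourier coarse graining: the stack of progressively low-passed images.

The coarse-graining operator is an *ideal* (sharp-cutoff) low-pass filter:
the image is taken to frequency space with an unnormalised forward DFT,

    F(kx, ky) = sum_{nx,ny} f(nx, ny) * exp(-2*pi*i*(kx*nx + ky*ny)/N),

every coefficient whose centred frequency distance sqrt(kx'^2 + ky'^2)
reaches the cutoff radius is zeroed, and the image is rebuilt with the
inverse transform (which carries the 1/N^2 factor). Because the filter is an
orthogonal projection, filtering at radius r2 and then r1 <= r2 equals
filtering once at r1; the whole stack can therefore be built from the
original image's spectrum, and per-pixel energy is non-increasing along it.

Cutoff radii follow the geometric (log-even) schedule from N down to 1, so
the first step is a no-op (nothing lies beyond distance N) and the last keeps
only the DC term, i.e. the image's mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, SymmetryError
from .image_io import ImageGrid

__all__ = [
    "Spectrum",
    "RadiusSchedule",
    "CoarseStack",
    "forward_dft",
    "lowpass_reconstruct",
    "make_schedule",
    "build_stack",
    "export_stack_pngs",
]

#: relative bound on the imaginary residue tolerated after inverse transform
IMAG_RESIDUE_RTOL = 1e-8


@dataclass(frozen=True)
class Spectrum:
    """DFT coefficients of a square grid, in numpy layout (DC at [0, 0])."""

    coeffs: np.ndarray
    side_px: int

    def __post_init__(self) -> None:
        if self.coeffs.shape != (self.side_px, self.side_px):
            raise ConfigurationError("spectrum shape disagrees with side_px")


@dataclass(frozen=True)
class RadiusSchedule:
    """Strictly decreasing cutoff radii, in centred frequency-index units.

    ``radii[0] >= N/sqrt(2)`` passes every coefficient and acts as the
    identity step; a radius of 1 keeps only DC.
    """

    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=np.float64)
        if r.size < 2:
            raise ConfigurationError("a schedule needs at least 2 radii")
        if np.any(r <= 0) or not np.all(np.isfinite(r)):
            raise ConfigurationError("radii must be finite and positive")
        if np.any(np.diff(r) >= 0):
            raise ConfigurationError("radii must be strictly decreasing")
        object.__setattr__(self, "radii", tuple(float(x) for x in r))

    @property
    def steps(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class CoarseStack:
    """P_0 ... P_S: the original grid followed by its low-passed versions."""

    grids: tuple[ImageGrid, ...]
    schedule: RadiusSchedule

    def __post_init__(self) -> None:
        if len(self.grids) != self.schedule.steps + 1:
            raise ConfigurationError("stack length must be steps + 1")
        sides = {g.side_px for g in self.grids}
        if len(sides) > 1:
            raise ConfigurationError("stack members disagree on grid size")

    @property
    def steps(self) -> int:
        return self.schedule.steps


def forward_dft(g: ImageGrid) -> Spectrum:
    """Unnormalised forward DFT of a grid (the 1/N^2 lives in the inverse)."""
    return Spectrum(coeffs=np.fft.fft2(g.pixels), side_px=g.side_px)


def _centered_distance(n: int) -> np.ndarray:
    """Euclidean distance of each numpy-layout coefficient from DC,
    measured with signed (centred) frequency indices."""
    k = np.fft.fftfreq(n) * n  # signed integer frequencies, fft layout
    return np.hypot(*np.meshgrid(k, k, indexing="ij"))


def lowpass_reconstruct(s: Spectrum, radius: float) -> ImageGrid:
    """Zero every coefficient at centred distance >= ``radius`` and invert.

    Keeping strictly-inside coefficients fixes the tie-break for
    coefficients lying exactly on the cutoff circle. The mask is radially
    symmetric, so conjugate symmetry of a real image's spectrum is preserved
    and the reconstruction is real up to float noise; a larger imaginary
    residue signals a corrupted spectrum and raises :class:`SymmetryError`.
    """
    if radius <= 0:
        raise ConfigurationError(f"cutoff radius must be positive, got {radius}")
    mask = _centered_distance(s.side_px) < radius
    out = np.fft.ifft2(s.coeffs * mask)
    scale = max(float(np.max(np.abs(out.real))), 1e-12)
    residue = float(np.max(np.abs(out.imag)))
    if residue > IMAG_RESIDUE_RTOL * scale:
        raise SymmetryError(
            f"imaginary residue {residue:.3e} exceeds {IMAG_RESIDUE_RTOL:.0e} "
            "of the pixel range; spectrum is not conjugate-symmetric"
        )
    return ImageGrid(out.real)


def make_schedule(side_px: int, steps: int = 10) -> RadiusSchedule:
    """Geometrically spaced cutoff radii from ``side_px`` down to 1.

    "Evenly on a log scale" over the image side: r_k = N^(1 - k/(S-1)) for
    k = 0 .. S-1. The first radius N exceeds the largest possible centred
    distance N/sqrt(2), so step one removes nothing; the last radius 1
    leaves only the mean.
    """
    if steps < 2:
        raise ConfigurationError(f"need at least 2 steps, got {steps}")
    if side_px < 8:
        raise ConfigurationError(f"side_px must be >= 8, got {side_px}")
    return RadiusSchedule(radii=tuple(np.geomspace(side_px, 1.0, steps)))


def build_stack(g: ImageGrid, sched: RadiusSchedule) -> CoarseStack:
    """Compute P_0 = g and P_k = lowpass(g, radii[k-1]) for k = 1..S.

    Every member is cut from the *original* spectrum: for ideal filters this
    equals iterative re-filtering (projections compose by the smaller
    radius) and avoids accumulating round-off.
    """
    spec = forward_dft(g)
    grids = [g] + [lowpass_reconstruct(spec, r) for r in sched.radii]
    return CoarseStack(grids=tuple(grids), schedule=sched)


def export_stack_pngs(stack: CoarseStack, out_dir: str | Path, prefix: str = "P") -> list[Path]:
    """Write the stack as numbered 8-bit PNGs for visual inspection.

    Values are clipped to [0, 1] for display only — the in-memory stack is
    never altered.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, grid in enumerate(stack.grids):
        arr = np.clip(grid.pixels, 0.0, 1.0)
        img = Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L")
        p = out_dir / f"{prefix}_{i}.png"
        img.save(p)
        paths.append(p)
    return paths
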