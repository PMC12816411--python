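"""Seeded synthetic images with controlled spatial-frequency content.

Every fixture is fully determined by its spec (kind, size, parameters, seed),
so the whole test corpus regenerates bit-identically from integers — no
image downloads, no binary assets. The kinds cover the analytically useful
extremes: constants (zero complexity), white noise (energy spread over all
annuli in proportion to their area), band-limited noise (energy confined to
a known annulus), checkerboards and cosines (discrete spectral lines),
gradients (low-frequency energy), and composites.

``annulus_noise_mixture`` builds noise fields whose spectral energy per
coarse-graining annulus is set explicitly — the workhorse for benchmarks
that need per-scale complexity to vary independently across images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .coarse_grain import RadiusSchedule, _centered_distance
from .errors import ConfigurationError
from .image_io import ChannelSet, ImageGrid

__all__ = [
    "FixtureSpec",
    "generate",
    "write_image",
    "annulus_noise_mixture",
    "standard_corpus",
]

KINDS = ("constant", "white_noise", "band_limited", "checkerboard", "cosine", "gradient", "composite")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image; seed + params fully determine pixels."""

    kind: str
    side_px: int = 64
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown fixture kind {self.kind!r}; expected one of {KINDS}")
        if self.side_px < 8:
            raise ConfigurationError(f"side_px must be >= 8, got {self.side_px}")


def _grid(pixels: np.ndarray) -> ChannelSet:
    return ChannelSet(channels={"L": ImageGrid(pixels)}, weights={"L": 1.0})


def _gen_constant(spec: FixtureSpec) -> np.ndarray:
    value = spec.params.get("value", 0.5)
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"constant fixture: value {value} outside [0, 1]")
    return np.full((spec.side_px, spec.side_px), float(value))


def _gen_white_noise(spec: FixtureSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(0.0, 1.0, size=(spec.side_px, spec.side_px))


def _gen_band_limited(spec: FixtureSpec) -> np.ndarray:
    n = spec.side_px
    lo = spec.params.get("lo")
    hi = spec.params.get("hi")
    limit = n / np.sqrt(2.0)
    if lo is None or hi is None:
        raise ConfigurationError("band_limited fixture: params lo and hi are required")
    if not (0 < lo < hi <= limit):
        raise ConfigurationError(
            f"band_limited fixture: need 0 < lo < hi <= N/sqrt(2) ({limit:.2f}), got lo={lo}, hi={hi}"
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.uniform(0.0, 1.0, size=(n, n))
    dist = _centered_distance(n)
    spec_f = np.fft.fft2(noise)
    keep = (dist >= lo) & (dist < hi)
    band = np.fft.ifft2(spec_f * keep).real
    # affine rescale into [0,1]; the map only touches DC and a global gain,
    # so the band-limited support is preserved
    lo_v, hi_v = band.min(), band.max()
    if hi_v - lo_v < 1e-12:
        return np.full((n, n), 0.5)
    return (band - lo_v) / (hi_v - lo_v)


def _gen_checkerboard(spec: FixtureSpec) -> np.ndarray:
    n = spec.side_px
    period = spec.params.get("period")
    if period is None:
        raise ConfigurationError("checkerboard fixture: param period is required")
    if period < 1 or n % period != 0:
        raise ConfigurationError(
            f"checkerboard fixture: period {period} must be >= 1 and divide N={n}"
        )
    i, j = np.indices((n, n))
    return (((i // period) + (j // period)) % 2 == 0).astype(np.float64)


def _gen_cosine(spec: FixtureSpec) -> np.ndarray:
    n = spec.side_px
    freq = spec.params.get("frequency")
    amp = spec.params.get("amplitude", 1.0)
    if freq is None:
        raise ConfigurationError("cosine fixture: param frequency is required")
    if not 0 < freq < n / 2:
        raise ConfigurationError(f"cosine fixture: frequency {freq} outside (0, N/2)")
    if not 0 < amp <= 1.0:
        raise ConfigurationError(f"cosine fixture: amplitude {amp} outside (0, 1]")
    nx = np.arange(n)
    row = 0.5 + (amp / 2.0) * np.cos(2 * np.pi * freq * nx / n)
    return np.tile(row, (n, 1))


def _gen_gradient(spec: FixtureSpec) -> np.ndarray:
    n = spec.side_px
    ramp = np.linspace(0.0, 1.0, n)
    return np.tile(ramp, (n, 1))


def _gen_composite(spec: FixtureSpec) -> np.ndarray:
    comps = spec.params.get("components")
    if not comps:
        raise ConfigurationError("composite fixture: param components must be a non-empty list")
    planes = []
    for c in comps:
        if not isinstance(c, FixtureSpec):
            raise ConfigurationError("composite fixture: components must be FixtureSpec instances")
        if c.side_px != spec.side_px:
            raise ConfigurationError("composite fixture: components must share side_px")
        planes.append(generate(c).channels["L"].pixels)
    return np.mean(planes, axis=0)


_GENERATORS = {
    "constant": _gen_constant,
    "white_noise": _gen_white_noise,
    "band_limited": _gen_band_limited,
    "checkerboard": _gen_checkerboard,
    "cosine": _gen_cosine,
    "gradient": _gen_gradient,
    "composite": _gen_composite,
}


def generate(spec: FixtureSpec) -> ChannelSet:
    """Render a fixture spec to a single-channel ChannelSet in [0, 1]."""
    return _grid(_GENERATORS[spec.kind](spec))


def annulus_noise_mixture(
    side_px: int,
    schedule: RadiusSchedule,
    gains: np.ndarray,
    seed: int,
    contrast: float = 0.1,
) -> ChannelSet:
    """Noise whose spectral energy in each coarse-graining annulus is dialled.

    Annulus k (for step k) is the ring radii[k] <= d < radii[k-1]; its
    coefficients are rescaled to a fixed energy proportional to gains[k]^2,
    so the partial complexity of step k becomes gains[k]^2 * contrast^2 / (2 S)
    exactly, independent of the noise draw. Steps whose annulus is empty
    (gains[0] under the default schedule) contribute nothing. The field is
    centred at 0.5; ``contrast`` sets the overall pixel standard deviation,
    small enough that clipping into [0, 1] is negligible.
    """
    n = side_px
    s = schedule.steps
    gains = np.asarray(gains, dtype=np.float64)
    if gains.shape != (s,):
        raise ConfigurationError(f"gains must have length {s}, got {gains.shape}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    coeffs = np.fft.fft2(noise)
    dist = _centered_distance(n)
    out = np.zeros_like(coeffs)
    sigma0 = contrast / np.sqrt(s)
    bounds = (np.inf,) + schedule.radii
    for k in range(s):
        ring = (dist >= bounds[k + 1]) & (dist < bounds[k])
        if not ring.any():
            continue
        energy = float(np.sum(np.abs(coeffs[ring]) ** 2))
        if energy <= 0:
            continue
        target = gains[k] ** 2 * n**4 * sigma0**2
        out[ring] = coeffs[ring] * np.sqrt(target / energy)
    fieldv = np.fft.ifft2(out).real
    return _grid(np.clip(0.5 + fieldv, 0.0, 1.0))


def write_image(cs: ChannelSet, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a ChannelSet as a lossless PNG at 8 or 16 bits.

    Round-tripping through ``image_io.load_image`` recovers pixels within
    the quantisation bound 1/(2 * bit-depth maximum). 16-bit output is
    supported for single-channel images only.
    """
    if bit_depth not in (8, 16):
        raise ConfigurationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    names = list(cs.channels)
    planes = [cs.channels[n].pixels for n in names]
    for name, p in zip(names, planes):
        if p.min() < 0.0 or p.max() > 1.0:
            raise ConfigurationError(f"channel {name!r} has values outside [0, 1]; cannot quantise")
    path = Path(path)
    maxval = 255 if bit_depth == 8 else 65535
    if len(planes) == 1:
        arr = np.round(planes[0] * maxval)
        if bit_depth == 8:
            img = Image.fromarray(arr.astype(np.uint8), mode="L")
        else:
            img = Image.fromarray(arr.astype(np.uint16))
    elif set(names) == {"R", "G", "B"}:
        if bit_depth == 16:
            raise ConfigurationError("16-bit RGB PNG output is not supported; use 8-bit")
        stackp = np.stack([cs.channels[n].pixels for n in ("R", "G", "B")], axis=-1)
        img = Image.fromarray(np.round(stackp * 255).astype(np.uint8), mode="RGB")
    else:
        raise ConfigurationError(f"cannot write channel layout {names!r}; expected L or R,G,B")
    try:
        img.save(path, format="PNG")
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc
    return path


def standard_corpus(seed: int = 0, side_px: int = 64) -> list[tuple[str, FixtureSpec]]:
    """The package's reference fixture corpus: >= 20 deterministic images.

    Spans all kinds; noise-bearing fixtures derive their seeds from ``seed``
    so two corpora with the same seed are bit-identical.
    """
    n = side_px
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=16)]
    specs: list[tuple[str, FixtureSpec]] = [
        ("constant_mid", FixtureSpec("constant", n, {"value": 0.5})),
        ("constant_low", FixtureSpec("constant", n, {"value": 0.1})),
        ("constant_high", FixtureSpec("constant", n, {"value": 0.9})),
        ("gradient", FixtureSpec("gradient", n)),
        ("checker_2", FixtureSpec("checkerboard", n, {"period": 2})),
        ("checker_4", FixtureSpec("checkerboard", n, {"period": 4})),
        ("checker_8", FixtureSpec("checkerboard", n, {"period": 8})),
        ("checker_16", FixtureSpec("checkerboard", n, {"period": n // 4})),
        ("cosine_f2", FixtureSpec("cosine", n, {"frequency": 2, "amplitude": 0.8})),
        ("cosine_f8", FixtureSpec("cosine", n, {"frequency": 8, "amplitude": 0.8})),
        ("cosine_f24", FixtureSpec("cosine", n, {"frequency": 24, "amplitude": 0.6})),
    ]
    for i in range(4):
        specs.append((f"white_noise_{i}", FixtureSpec("white_noise", n, seed=sub[i])))
    bands = [(2.0, 6.0), (6.0, 18.0), (12.0, 30.0), (3.0, 40.0)]
    for i, (lo, hi) in enumerate(bands):
        specs.append(
            (f"band_{i}", FixtureSpec("band_limited", n, {"lo": lo, "hi": hi}, seed=sub[4 + i]))
        )
    for i in range(3):
        a = FixtureSpec("band_limited", n, {"lo": 2.0, "hi": 8.0}, seed=sub[8 + i])
        b = FixtureSpec("band_limited", n, {"lo": 12.0, "hi": 28.0}, seed=sub[11 + i])
        specs.append((f"composite_{i}", FixtureSpec("composite", n, {"components": [a, b]})))
    specs.append(
        (
            "composite_checker_noise",
            FixtureSpec(
                "composite",
                n,
                {
                    "components": [
                        FixtureSpec("checkerboard", n, {"period": 8}),
                        FixtureSpec("white_noise", n, seed=sub[14]),
                    ]
                },
            ),
        )
    )
    specs.append(
        (
            "composite_gradient_cosine",
            FixtureSpec(
                "composite",
                n,
                {
                    "components": [
                        FixtureSpec("gradient", n),
                        FixtureSpec("cosine", n, {"frequency": 12, "amplitude": 0.7}),
                    ]
                },
            ),
        )
    )
    return specs
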