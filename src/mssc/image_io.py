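"""Raster-image ingest: loading, normalisation, canonical resizing, channels.

Images are represented as square grids of float intensities. On ingest every
pixel is scaled into [0, 1] by dividing by the bit-depth maximum, so an 8-bit
and a 16-bit encoding of the same scene produce the same grid up to
quantisation. Colour images are split into per-channel grids, each carrying an
*intensity weight* (the channel's mean value) used later when per-channel
complexities are summed into a single score.

Pixel indices are 0-based, row-major, origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _skimage_resize

from .errors import ConfigurationError, DimensionError, FormatError

MIN_SIDE_PX = 8

__all__ = [
    "ImageGrid",
    "ChannelSet",
    "load_image",
    "resize_canonical",
    "channel_intensity",
]


@dataclass(frozen=True)
class ImageGrid:
    """A single-channel square image: an N x N array of float intensities.

    Freshly ingested grids hold values in [0, 1]; grids derived by Fourier
    filtering may overshoot that range slightly (Gibbs ringing) and are
    deliberately never clamped, since clamping would corrupt the spectral
    identities the complexity measure relies on.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise DimensionError(f"image grid must be square, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE_PX:
            raise ConfigurationError(
                f"grid side {px.shape[0]} px is below the minimum of {MIN_SIDE_PX}"
            )
        if not np.all(np.isfinite(px)):
            raise ConfigurationError("image grid contains non-finite values")
        object.__setattr__(self, "pixels", px)

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ChannelSet:
    """An ordered collection of same-sized channels with intensity weights.

    Grayscale images yield a single channel ``"L"`` with weight 1. For RGB
    the weight of each channel is its mean intensity, computed at load time.
    Weights are not renormalised to sum to one.
    """

    channels: dict[str, ImageGrid]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigurationError("a ChannelSet needs at least one channel")
        sides = {g.side_px for g in self.channels.values()}
        if len(sides) > 1:
            raise DimensionError(f"channels disagree on size: {sorted(sides)}")
        if not self.weights:
            self.weights = {name: 1.0 for name in self.channels}
        if set(self.weights) != set(self.channels):
            raise ConfigurationError("weights must cover exactly the channel names")
        for name, w in self.weights.items():
            if not np.isfinite(w) or w < 0:
                raise ConfigurationError(f"weight for channel {name!r} must be finite and >= 0")

    @property
    def side_px(self) -> int:
        return next(iter(self.channels.values())).side_px


def _bit_depth_max(mode: str) -> int:
    if mode in ("I;16", "I;16B", "I;16L", "I"):
        return 65535
    return 255


def load_image(path: str | Path) -> ChannelSet:
    """Load a PNG/JPEG/TIFF file into a :class:`ChannelSet`.

    8- and 16-bit, grayscale or RGB inputs are accepted; an alpha channel is
    dropped; palette images are expanded. Values are divided by the bit-depth
    maximum so the result lies in [0, 1]. RGB channel weights are the
    per-channel mean intensities; grayscale gets a single channel ``"L"``
    with weight 1.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "P":
                im = im.convert("RGB")
                mode = "RGB"
            if mode in ("RGBA", "LA"):
                # drop alpha, keep colour planes
                im = im.convert("RGB" if mode == "RGBA" else "L")
                mode = im.mode
            if mode not in ("L", "I", "I;16", "I;16B", "I;16L", "RGB"):
                raise FormatError(
                    f"unsupported channel layout {mode!r} in {path} "
                    "(expected 8/16-bit grayscale or RGB)"
                )
            arr = np.asarray(im, dtype=np.float64)
            maxval = _bit_depth_max(mode)
    except UnidentifiedImageError as exc:
        raise OSError(f"cannot decode image file {path}") from exc
    except FileNotFoundError as exc:
        raise OSError(f"no such image file {path}") from exc

    arr = arr / maxval
    if arr.ndim == 2:
        grid = ImageGrid(_squareable(arr))
        return ChannelSet(channels={"L": grid}, weights={"L": 1.0})
    channels: dict[str, ImageGrid] = {}
    weights: dict[str, float] = {}
    for i, name in enumerate(("R", "G", "B")):
        grid = ImageGrid(_squareable(arr[:, :, i]))
        channels[name] = grid
        weights[name] = channel_intensity(grid)
    return ChannelSet(channels=channels, weights=weights)


def _squareable(arr: np.ndarray) -> np.ndarray:
    """Make a plane square by anisotropic rescale if needed (no crop/pad)."""
    h, w = arr.shape
    if h == w:
        return arr
    side = max(h, w, MIN_SIDE_PX)
    return _resize_plane(arr, side)


def _resize_plane(arr: np.ndarray, side: int) -> np.ndarray:
    downscaling = side < max(arr.shape)
    out = _skimage_resize(
        arr,
        (side, side),
        order=1,
        mode="reflect",
        anti_aliasing=downscaling,
        preserve_range=True,
    )
    # bilinear + gaussian prefilter can overshoot [0,1] by float dust; this is
    # an ingest path so the contract range is restored
    return np.clip(out, 0.0, 1.0)


def resize_canonical(cs: ChannelSet, side_px: int = 512) -> ChannelSet:
    """Resample every channel to ``side_px`` x ``side_px``.

    Non-square sources are rescaled anisotropically to the square — no
    cropping, no padding. Uses bilinear interpolation with Gaussian
    anti-aliasing when downscaling, to avoid injecting spurious
    high-frequency energy. Weights are passed through unchanged.
    """
    if side_px < MIN_SIDE_PX:
        raise ConfigurationError(f"side_px must be >= {MIN_SIDE_PX}, got {side_px}")
    out: dict[str, ImageGrid] = {}
    for name, grid in cs.channels.items():
        if grid.side_px == side_px:
            out[name] = grid
        else:
            out[name] = ImageGrid(_resize_plane(grid.pixels, side_px))
    return ChannelSet(channels=out, weights=dict(cs.weights))


def channel_intensity(g: ImageGrid) -> float:
    """Mean pixel value of a channel — the weight used in channel aggregation."""
    return float(np.mean(g.pixels))
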