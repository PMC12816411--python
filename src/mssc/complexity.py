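r"""Multiscale structural complexity: per-scale dissimilarities and their sum.

The similarity kernel between two patterns is the normalised inner product

    O(a, b) = (1/N^2) * sum_{i,j} a(i,j) * b(i,j),

and the *partial complexity* of coarse-graining step k is the overlap-based
dissimilarity between consecutive stack members,

    C_k = | O(P_k, P_{k+1}) - (O(P_k, P_k) + O(P_{k+1}, P_{k+1})) / 2 |.

For an ideal low-pass stack, O(P_k, P_{k+1}) = O(P_{k+1}, P_{k+1}) (the
filter is an orthogonal projection), so C_k collapses to half the per-pixel
energy removed at step k+1 — the "information lost" at that scale. Two exact
identities follow and serve as the package's strongest self-checks:

* Parseval: C_k is half the mean squared magnitude of the spectral annulus
  removed at step k+1 (with the 1/N^2 inverse-transform normalisation).
* Telescoping: the full-window sum equals (O(P_0,P_0) - O(P_S,P_S)) / 2.

The total score windows the profile to a contiguous range of scales — the
smallest and largest scales track artefacts and whole-image layout rather
than perceived content, so by default the first two and last two of ten
steps are dropped — and sums across colour channels weighted by their mean
intensity.

MSSC is translation-invariant (cyclic shifts) and scales as the square of
image intensity: multiplying pixels by alpha multiplies every C_k, and hence
the total, by alpha^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coarse_grain import CoarseStack, RadiusSchedule, build_stack, make_schedule
from .errors import ConfigurationError, DimensionError
from .image_io import ChannelSet, ImageGrid

__all__ = [
    "PartialProfile",
    "ScaleWindow",
    "ChannelScore",
    "MsscResult",
    "overlap",
    "partial_complexities",
    "windowed_total",
    "aggregate_channels",
    "compute_mssc",
    "DEFAULT_WINDOW",
]


@dataclass(frozen=True)
class PartialProfile:
    """Partial complexities C_0 .. C_{S-1} for one channel (intensity^2 units)."""

    values: tuple[float, ...]
    radii: tuple[float, ...]
    channel_name: str = "L"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.radii):
            raise ConfigurationError("profile length must match the radius schedule")
        if any(v < 0 for v in self.values):
            raise ConfigurationError("partial complexities must be non-negative")

    @property
    def steps(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)


@dataclass(frozen=True)
class ScaleWindow:
    """Inclusive range [lo, hi] of coarse-graining steps entering the total."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ConfigurationError(f"invalid scale window ({self.lo}, {self.hi})")

    def validate_for(self, steps: int) -> None:
        if self.hi > steps - 1:
            raise ConfigurationError(
                f"window ({self.lo}, {self.hi}) exceeds profile of {steps} steps"
            )


#: middle scales of the default 10-step schedule: drop 2 finest, 2 coarsest
DEFAULT_WINDOW = ScaleWindow(2, 7)


@dataclass(frozen=True)
class ChannelScore:
    profile: PartialProfile
    windowed_sum: float
    weight: float


@dataclass(frozen=True)
class MsscResult:
    """Windowed, channel-aggregated complexity plus its full breakdown."""

    total: float
    per_channel: dict[str, ChannelScore]
    window: ScaleWindow
    side_px: int
    steps: int
    radii: tuple[float, ...]

    def aggregate_profile(self) -> np.ndarray:
        """Intensity-weighted sum of the per-channel profiles, step by step."""
        out = np.zeros(self.steps)
        for score in self.per_channel.values():
            out += score.weight * score.profile.as_array()
        return out


def overlap(a: ImageGrid, b: ImageGrid) -> float:
    """Normalised inner product O(a, b): mean of the pixel-wise product."""
    if a.side_px != b.side_px:
        raise DimensionError(f"overlap needs equal sizes, got {a.side_px} and {b.side_px}")
    return float(np.mean(a.pixels * b.pixels))


def partial_complexities(stack: CoarseStack, channel_name: str = "L") -> PartialProfile:
    """C_k for every step of a coarse stack.

    The absolute value guards the general (non-projection) case; for ideal
    low-pass stacks the inner expression is already >= 0.
    """
    values = []
    for k in range(stack.steps):
        a, b = stack.grids[k], stack.grids[k + 1]
        c = abs(overlap(a, b) - 0.5 * (overlap(a, a) + overlap(b, b)))
        values.append(c)
    return PartialProfile(
        values=tuple(values), radii=stack.schedule.radii, channel_name=channel_name
    )


def windowed_total(profile: PartialProfile, w: ScaleWindow) -> float:
    """Sum C_k over the inclusive window; the full window reproduces sum(C)."""
    w.validate_for(profile.steps)
    return float(sum(profile.values[w.lo : w.hi + 1]))


def aggregate_channels(results: dict[str, tuple[float, float]]) -> float:
    """Combine per-channel windowed sums: sum of weight * windowed_sum."""
    if not results:
        raise ConfigurationError("cannot aggregate an empty channel map")
    return float(sum(w * s for s, w in results.values()))


def compute_mssc(
    cs: ChannelSet,
    sched: RadiusSchedule | None = None,
    w: ScaleWindow | None = None,
) -> MsscResult:
    """Full pipeline for one image: stack, profile, window, channel sum.

    With no schedule given, a 10-step geometric schedule for the image's own
    side length is used; the default window keeps steps 2..7.
    """
    side = cs.side_px
    if sched is None:
        sched = make_schedule(side, 10)
    if w is None:
        w = DEFAULT_WINDOW
    w.validate_for(sched.steps)

    per_channel: dict[str, ChannelScore] = {}
    sums: dict[str, tuple[float, float]] = {}
    for name, grid in cs.channels.items():
        if grid.side_px != side:
            raise DimensionError("all channels must match the canonical size")
        stack = build_stack(grid, sched)
        profile = partial_complexities(stack, channel_name=name)
        ws = windowed_total(profile, w)
        weight = cs.weights[name]
        per_channel[name] = ChannelScore(profile=profile, windowed_sum=ws, weight=weight)
        sums[name] = (ws, weight)

    return MsscResult(
        total=aggregate_channels(sums),
        per_channel=per_channel,
        window=w,
        side_px=side,
        steps=sched.steps,
        radii=sched.radii,
    )
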