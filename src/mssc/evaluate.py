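"""Correlating complexity scores with subjective (human) complexity ratings.

The protocol mirrors how perceptual-complexity metrics are benchmarked:
images carry a continuous subjective complexity score (here read from a CSV,
one row per image with a category label), the metric is computed for every
image, and agreement is summarised as the Pearson correlation per category —
both for the final windowed total and for each coarse-graining step's
partial complexity, which reveals *which scales* carry the perceptually
relevant structure.

``window_sweep`` formalises the choice of the scale window: it scores every
contiguous window by the mean correlation across categories, under the
constraint that one common window serves all categories, and reports the
argmax. Zero-variance cells yield an explicit ``None`` marker rather than a
NaN, so category means stay interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .complexity import MsscResult, PartialProfile, ScaleWindow
from .errors import DataError, DimensionError

__all__ = [
    "pearson_r",
    "load_ratings",
    "validate_ratings",
    "CorrelationReport",
    "correlation_report",
    "WindowSweep",
    "window_sweep",
]

RATINGS_COLUMNS = ("image_id", "category", "score")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Product-moment correlation; ``None`` when either variance is zero.

    Zero-variance input is a legitimate outcome (e.g. constant images), so
    it is reported as an explicit undefined marker instead of raising or
    propagating NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DataError(f"need at least 3 pairs for a correlation, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def validate_ratings(df: pd.DataFrame, source: str = "<ratings>") -> pd.DataFrame:
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{source}: missing column(s) {missing}; expected {RATINGS_COLUMNS}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[~np.isfinite(scores)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise DataError(f"{source}: non-numeric score at line {int(bad[0]) + 2}")
    out = df.assign(score=scores.astype(float))
    dup = out.duplicated(subset=["category", "image_id"])
    if dup.any():
        raise DataError(
            f"{source}: duplicate image_id within a category at line {int(out.index[dup][0]) + 2}"
        )
    return out


def load_ratings(path: str | Path) -> pd.DataFrame:
    """Read an image_id,category,score CSV into a validated DataFrame."""
    try:
        df = pd.read_csv(path, dtype={"image_id": str, "category": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot read ratings CSV {path}: {exc}") from exc
    return validate_ratings(df, source=str(path))


@dataclass(frozen=True)
class CorrelationReport:
    """Per-category correlations for totals and for each step's C_k."""

    totals: dict[str, tuple[float | None, int]]
    steps: dict[tuple[str, int], tuple[float | None, int]]
    unmatched_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: category, step_or_total, r, n."""
        rows = [
            {"category": cat, "step_or_total": "total", "r": r, "n": n}
            for cat, (r, n) in self.totals.items()
        ]
        rows += [
            {"category": cat, "step_or_total": str(k), "r": r, "n": n}
            for (cat, k), (r, n) in self.steps.items()
        ]
        return pd.DataFrame(rows, columns=["category", "step_or_total", "r", "n"])


def correlation_report(
    scores: Mapping[str, MsscResult], ratings: pd.DataFrame
) -> CorrelationReport:
    """Join computed results with ratings on image_id and correlate.

    Step-level correlations use the channel-aggregated profile (intensity
    weights applied), matching how the total is assembled. Unmatched ids on
    either side are surfaced in the report, never silently dropped.
    """
    ratings = validate_ratings(ratings)
    matched = ratings[ratings["image_id"].isin(scores.keys())]
    unmatched = sorted(set(ratings["image_id"]) ^ set(scores.keys()))
    if matched.empty:
        raise DataError("no overlapping image_ids between results and ratings")

    totals: dict[str, tuple[float | None, int]] = {}
    steps: dict[tuple[str, int], tuple[float | None, int]] = {}
    for cat, grp in matched.groupby("category", sort=True):
        if len(grp) < 3:
            raise DataError(f"category {cat!r} has only {len(grp)} matched rows; need >= 3")
        grp = grp.sort_values("image_id")  # row order must not leak into float sums
        ids = grp["image_id"].tolist()
        y = grp["score"].to_numpy()
        tot = [scores[i].total for i in ids]
        totals[str(cat)] = (pearson_r(tot, y), len(ids))
        profiles = np.array([scores[i].aggregate_profile() for i in ids])
        for k in range(profiles.shape[1]):
            steps[(str(cat), k)] = (pearson_r(profiles[:, k], y), len(ids))
    return CorrelationReport(totals=totals, steps=steps, unmatched_ids=tuple(unmatched))


@dataclass(frozen=True)
class WindowSweep:
    """Mean-r scores for every contiguous scale window, plus the argmax."""

    table: pd.DataFrame  # columns lo, hi, mean_r, n_categories
    per_category: pd.DataFrame  # columns lo, hi, category, r, n
    best: ScaleWindow


def _as_profile_array(p) -> np.ndarray:
    if isinstance(p, PartialProfile):
        return p.as_array()
    return np.asarray(p, dtype=np.float64)


def window_sweep(
    profiles: Mapping[str, "PartialProfile | np.ndarray"],
    ratings: pd.DataFrame,
) -> WindowSweep:
    """Exhaustively score every contiguous window by cross-category mean r.

    One window must serve all categories, so the objective is the mean of
    the per-category correlations (undefined cells excluded). Ties are
    broken toward the widest window, then the smallest lo, so the result is
    deterministic.
    """
    ratings = validate_ratings(ratings)
    matched = ratings[ratings["image_id"].isin(profiles.keys())]
    if matched.empty:
        raise DataError("no overlapping image_ids between profiles and ratings")
    steps = {_as_profile_array(p).size for p in profiles.values()}
    if len(steps) != 1:
        raise DimensionError(f"profiles disagree on step count: {sorted(steps)}")
    s = steps.pop()

    groups = []
    for cat, grp in matched.groupby("category", sort=True):
        if len(grp) < 3:
            raise DataError(f"category {cat!r} has only {len(grp)} matched rows; need >= 3")
        grp = grp.sort_values("image_id")
        prof = np.array([_as_profile_array(profiles[i]) for i in grp["image_id"]])
        # cumulative sums let every window total come from one subtraction
        cum = np.concatenate([np.zeros((len(grp), 1)), np.cumsum(prof, axis=1)], axis=1)
        groups.append((str(cat), cum, grp["score"].to_numpy()))

    rows, cat_rows = [], []
    best_key, best_window = None, None
    for lo in range(s):
        for hi in range(lo, s):
            rs = []
            for cat, cum, y in groups:
                totals = cum[:, hi + 1] - cum[:, lo]
                r = pearson_r(totals, y)
                cat_rows.append({"lo": lo, "hi": hi, "category": cat, "r": r, "n": len(y)})
                if r is not None:
                    rs.append(r)
            mean_r = float(np.mean(rs)) if rs else None
            rows.append({"lo": lo, "hi": hi, "mean_r": mean_r, "n_categories": len(rs)})
            if mean_r is not None and not math.isnan(mean_r):
                key = (mean_r, hi - lo, -lo)
                if best_key is None or key > best_key:
                    best_key, best_window = key, ScaleWindow(lo, hi)
    if best_window is None:
        raise DataError("every window had undefined correlation (zero variance throughout)")
    return WindowSweep(
        table=pd.DataFrame(rows, columns=["lo", "hi", "mean_r", "n_categories"]),
        per_category=pd.DataFrame(cat_rows, columns=["lo", "hi", "category", "r", "n"]),
        best=best_window,
    )
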