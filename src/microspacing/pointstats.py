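"""Spatial regularity statistics for planar cell-soma point patterns.

The central quantity is the Hopkins–Skellam index (HSI),

    HSI = sum_i r1_i^2 / sum_i r2_i^2,

where ``r1`` are distances from random origins in the observation window to
their nearest cell, and ``r2`` are distances from randomly chosen cells to
their nearest other cell.  HSI < 1 indicates a regular (inhibited) pattern,
HSI = 1 complete spatial randomness, HSI > 1 aggregation.

No edge correction is applied: origins are drawn uniformly over the full
window and nearest-neighbour distances are plain Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["PointPattern", "HsiResult", "NndSummary", "hsi", "nnd"]


@dataclass(frozen=True)
class PointPattern:
    """Planar point pattern inside an axis-aligned rectangular window.

    Parameters
    ----------
    points:
        ``(n, 2)`` array of (x, y) coordinates in µm.
    window:
        ``(xmin, ymin, xmax, ymax)`` in µm; must have positive area and
        contain every point.
    """

    points: np.ndarray
    window: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        object.__setattr__(self, "points", pts)
        xmin, ymin, xmax, ymax = self.window
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("window must have positive area")
        if pts.size and (
            pts[:, 0].min() < xmin
            or pts[:, 0].max() > xmax
            or pts[:, 1].min() < ymin
            or pts[:, 1].max() > ymax
        ):
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)


@dataclass(frozen=True)
class HsiResult:
    hsi: float
    n_pattern: int
    n_sample: int
    seed: int


@dataclass(frozen=True)
class NndSummary:
    """Per-point nearest-neighbour distances with min/mean summaries."""

    nnd: np.ndarray
    min: float
    mean: float
    has_duplicates: bool = field(default=False)


def _nearest_other(points: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest *other* point (kd-tree)."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]


def hsi(
    pattern: PointPattern,
    n_sample: int | None = None,
    seed: int = 0,
    origins: np.ndarray | None = None,
) -> HsiResult:
    """Hopkins–Skellam index of a point pattern.

    Parameters
    ----------
    pattern:
        The pattern to score; needs at least two points.
    n_sample:
        Number N of random origins (r1) and of sampled cells (r2).  Default:
        the number of pattern points.  When ``n_sample`` equals the pattern
        size every cell is used once for r2; when smaller, cells are sampled
        without replacement; when larger, with replacement.
    seed:
        Integer seed; the result is bit-reproducible for a given seed.
    origins:
        Optional explicit ``(n_sample, 2)`` origin coordinates, overriding
        random origin placement (used for deterministic verification).
    """
    if pattern.n < 2:
        raise ValueError("degenerate pattern: need at least 2 points")
    if n_sample is None:
        n_sample = pattern.n
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")

    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = pattern.window
    if origins is None:
        origins = np.column_stack(
            [
                rng.uniform(xmin, xmax, size=n_sample),
                rng.uniform(ymin, ymax, size=n_sample),
            ]
        )
    else:
        origins = np.asarray(origins, dtype=float)
        if origins.shape != (n_sample, 2):
            raise ValueError("origins must have shape (n_sample, 2)")

    tree = cKDTree(pattern.points)
    r1, _ = tree.query(origins, k=1)

    if n_sample == pattern.n:
        idx = np.arange(pattern.n)
    elif n_sample < pattern.n:
        idx = rng.choice(pattern.n, size=n_sample, replace=False)
    else:
        idx = rng.choice(pattern.n, size=n_sample, replace=True)
    d2, _ = tree.query(pattern.points[idx], k=2)
    r2 = d2[:, 1]

    denom = float(np.sum(r2**2))
    if denom == 0.0:
        raise ValueError("degenerate pattern: zero nearest-neighbour distances")
    return HsiResult(
        hsi=float(np.sum(r1**2)) / denom,
        n_pattern=pattern.n,
        n_sample=int(n_sample),
        seed=int(seed),
    )


def nnd(pattern: PointPattern) -> NndSummary:
    """Nearest-neighbour distance of every point to its closest other point."""
    if pattern.n < 2:
        raise ValueError("need at least 2 points for nearest-neighbour distances")
    d = _nearest_other(pattern.points)
    dup = bool(np.any(d == 0.0))
    if dup:
        warnings.warn(
            "duplicate points present: zero nearest-neighbour distances reported",
            stacklevel=2,
        )
    return NndSummary(nnd=d, min=float(d.min()), mean=float(d.mean()), has_duplicates=dup)
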