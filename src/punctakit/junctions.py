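"""Spatial statistics for STIM1 / IP3R punctum geometry at ER-PM junctions.

Nearest-neighbour distances, proximity fractions, point densities and the
store-depletion translocation signal measured in per-punctum ROIs. Distances
are centroid-to-centroid Euclidean distances in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class PointPattern:
    """A planar point set with its observation window.

    Attributes
    ----------
    points : ndarray, shape (n, 2)
        (x, y) coordinates in µm.
    field_size_um : tuple
        (width, height) of the rectangular observation window in µm,
        with origin at (0, 0).
    """

    points: np.ndarray
    field_size_um: tuple

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = np.empty((0, 2))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area_um2(self) -> float:
        w, h = self.field_size_um
        return float(w) * float(h)

    @property
    def intensity(self) -> float:
        """Point density λ (points µm⁻²)."""
        return len(self.points) / self.area_um2


def nn_distances(
    from_pattern: PointPattern | np.ndarray,
    to_pattern: PointPattern | np.ndarray,
    exclude_self: bool | None = None,
) -> np.ndarray:
    """Nearest-neighbour distance from each source point to the target set.

    When both arguments are the same point set (and ``exclude_self`` is not
    explicitly False) each point is excluded from its own neighbour search.
    """
    a = _points(from_pattern)
    b = _points(to_pattern)
    if len(b) == 0:
        raise ValueError("target pattern is empty")
    if exclude_self is None:
        exclude_self = a.shape == b.shape and np.array_equal(a, b)
    if exclude_self and len(b) < 2:
        raise ValueError("self-excluded search needs >= 2 target points")
    tree = cKDTree(b)
    if exclude_self:
        d, _ = tree.query(a, k=2)
        return d[:, 1]
    d, _ = tree.query(a, k=1)
    return np.atleast_1d(d)


def nn_summary(distances: np.ndarray) -> dict:
    """Median, mean and SEM of a nearest-neighbour distance sample."""
    d = np.asarray(distances, dtype=float)
    return {
        "n": int(d.size),
        "median_um": float(np.median(d)),
        "mean_um": float(np.mean(d)),
        "sem_um": float(np.std(d, ddof=1) / np.sqrt(d.size)) if d.size > 1 else np.nan,
    }


def fraction_within(
    from_pattern: PointPattern | np.ndarray,
    to_pattern: PointPattern | np.ndarray,
    radius_um: float,
) -> tuple[float, np.ndarray]:
    """Fraction of source points with a target neighbour within ``radius_um``.

    Returns the fraction and the per-point boolean flags.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    d = nn_distances(from_pattern, to_pattern)
    flags = d <= radius_um
    return float(np.mean(flags)) if len(flags) else np.nan, flags


def edge_flags(pattern: PointPattern, radius_um: float) -> np.ndarray:
    """Flag points closer than ``radius_um`` to the window border.

    Proximity fractions for flagged points are censored by the window edge;
    summaries should be reported with and without them.
    """
    p = pattern.points
    w, h = pattern.field_size_um
    return (
        (p[:, 0] < radius_um)
        | (p[:, 1] < radius_um)
        | (p[:, 0] > w - radius_um)
        | (p[:, 1] > h - radius_um)
    )


def pattern_density(points: PointPattern | np.ndarray, region: tuple) -> float:
    """Point density λ (points µm⁻²) inside a rectangular region.

    ``region`` is (xmin, xmax, ymin, ymax) in µm.
    """
    xmin, xmax, ymin, ymax = region
    area = (xmax - xmin) * (ymax - ymin)
    if area <= 0:
        raise ValueError("region area must be > 0")
    p = _points(points)
    if len(p) == 0:
        return 0.0
    inside = (
        (p[:, 0] >= xmin) & (p[:, 0] <= xmax) & (p[:, 1] >= ymin) & (p[:, 1] <= ymax)
    )
    return float(np.sum(inside)) / area


@dataclass
class TranslocationResult:
    """Per-punctum translocation signal ΔF = (F_post − F_pre)/F_pre."""

    table: pd.DataFrame
    group_stats: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        ok = self.table[~self.table["excluded"]]
        rows = []
        for label, g in ok.groupby("label"):
            rows.append(
                {
                    "label": label,
                    "n": len(g),
                    "mean_delta_f": g["delta_f"].mean(),
                    "sem_delta_f": g["delta_f"].sem(),
                }
            )
        self.group_stats = pd.DataFrame(rows)


def stim_translocation_delta(
    pre_image: np.ndarray,
    post_image: np.ndarray,
    puncta: pd.DataFrame,
    pixel_size_um: float,
    roi_scale: float = 2.0,
) -> TranslocationResult:
    """Measure STIM1 channel intensity change in ROIs centred on IP3R puncta.

    For each punctum the mean intensity in a disc of radius
    ``roi_scale * radius_um`` is measured in both images and
    ΔF = (F_post − F_pre)/F_pre reported, grouped by the punctum's
    mobility label. Puncta with non-positive pre-intensity are flagged
    and excluded from group statistics.

    ``puncta`` needs columns x_um, y_um, radius_um, label.
    """
    pre = np.asarray(pre_image, dtype=float)
    post = np.asarray(post_image, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post images must share geometry")
    h, w = pre.shape
    yy, xx = np.mgrid[0:h, 0:w]
    xx_um = xx * pixel_size_um
    yy_um = yy * pixel_size_um
    rows = []
    for _, p in puncta.iterrows():
        r = roi_scale * p["radius_um"]
        mask = (xx_um - p["x_um"]) ** 2 + (yy_um - p["y_um"]) ** 2 <= r**2
        if not mask.any():
            rows.append(_trans_row(p, np.nan, True))
            continue
        f_pre = pre[mask].mean()
        f_post = post[mask].mean()
        if f_pre <= 0:
            rows.append(_trans_row(p, np.nan, True))
        else:
            rows.append(_trans_row(p, (f_post - f_pre) / f_pre, False))
    return TranslocationResult(table=pd.DataFrame(rows))


def _trans_row(p, delta_f, excluded):
    return {
        "x_um": p["x_um"],
        "y_um": p["y_um"],
        "radius_um": p["radius_um"],
        "label": p["label"],
        "delta_f": delta_f,
        "excluded": excluded,
    }


def _points(obj) -> np.ndarray:
    if isinstance(obj, PointPattern):
        return obj.points
    p = np.atleast_2d(np.asarray(obj, dtype=float))
    if p.size == 0:
        return np.empty((0, 2))
    return p
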