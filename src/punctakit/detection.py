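"""Punctum detection: background correction, DoG spot detection with
sub-pixel localization, and density-threshold Voronoi tessellation of
single-molecule localization tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi, QhullError
from shapely.geometry import Polygon, box

from .io import Movie


def subtract_background(movie: Movie, blank_region: tuple) -> Movie:
    """Subtract the per-frame mean of a cell-free region from every frame.

    ``blank_region`` is (row_min, row_max, col_min, col_max) in pixels
    (half-open). Output values are clipped at zero.
    """
    r0, r1, c0, c1 = blank_region
    data = np.asarray(movie.data, dtype=float)
    sub = data[:, r0:r1, c0:c1]
    if sub.size == 0:
        raise ValueError("blank_region overlaps no pixels")
    bg = sub.mean(axis=(1, 2), keepdims=True)
    corrected = np.clip(data - bg, 0.0, None)
    return Movie(
        data=corrected,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
        channel=movie.channel,
        meta={**movie.meta, "background_region": blank_region},
    )


def detect_spots(
    frame: np.ndarray,
    pixel_size_um: float,
    psf_sigma_um: float,
    threshold_sd: float = 5.0,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one frame.

    The frame is filtered with a difference of Gaussians at scales
    ``psf_sigma`` and 1.6·``psf_sigma`` (the standard blob-detection
    ratio). Local maxima of the DoG response exceeding
    ``threshold_sd`` robust SDs of the response are accepted, localized to
    sub-pixel precision by per-axis parabolic interpolation of the 3×3
    neighbourhood, and deduplicated so no two spots lie within one PSF
    sigma (the brighter wins). Spots within one PSF sigma of the border
    are discarded (parabolic interpolation is undefined there).

    Returns a spot table with columns
    frame, x_um, y_um, peak, integrated, quality.
    """
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be > 0")
    img = np.asarray(frame, dtype=float)
    sigma_px = psf_sigma_um / pixel_size_um
    g1 = ndimage.gaussian_filter(img, sigma_px)
    g2 = ndimage.gaussian_filter(img, 1.6 * sigma_px)
    dog = g1 - g2

    mad = np.median(np.abs(dog - np.median(dog)))
    noise = 1.4826 * mad
    thresh = threshold_sd * noise
    if thresh <= 0:
        thresh = np.finfo(float).tiny

    footprint = np.ones((3, 3), dtype=bool)
    local_max = (dog == ndimage.maximum_filter(dog, footprint=footprint)) & (
        dog > thresh
    )
    ys, xs = np.nonzero(local_max)

    h, w = img.shape
    border = max(1, int(np.ceil(sigma_px)))
    keep = (xs >= border) & (xs < w - border) & (ys >= border) & (ys < h - border)
    ys, xs = ys[keep], xs[keep]

    rows = []
    win = max(1, int(round(2 * sigma_px)))
    for y, x in zip(ys, xs):
        dx = _parabolic_offset(dog[y, x - 1], dog[y, x], dog[y, x + 1])
        dy = _parabolic_offset(dog[y - 1, x], dog[y, x], dog[y + 1, x])
        integ = float(
            img[
                max(0, y - win) : y + win + 1, max(0, x - win) : x + win + 1
            ].sum()
        )
        rows.append(
            {
                "frame": frame_index,
                "x_um": (x + dx) * pixel_size_um,
                "y_um": (y + dy) * pixel_size_um,
                "peak": float(img[y, x]),
                "integrated": integ,
                "quality": float(dog[y, x]),
            }
        )
    spots = pd.DataFrame(
        rows, columns=["frame", "x_um", "y_um", "peak", "integrated", "quality"]
    )
    return _suppress_close(spots, psf_sigma_um)


def detect_spots_movie(
    movie: Movie, psf_sigma_um: float, threshold_sd: float = 5.0
) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame of a movie."""
    tables = [
        detect_spots(
            movie.data[f],
            movie.pixel_size_um,
            psf_sigma_um,
            threshold_sd,
            frame_index=f,
        )
        for f in range(movie.n_frames)
    ]
    return pd.concat(tables, ignore_index=True)


def _parabolic_offset(fm, f0, fp) -> float:
    """Sub-pixel offset of a parabola through three equispaced samples."""
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a maximum; refuse to extrapolate
        return 0.0
    off = 0.5 * (fm - fp) / denom
    return float(np.clip(off, -0.5, 0.5))


def _suppress_close(spots: pd.DataFrame, min_sep_um: float) -> pd.DataFrame:
    if len(spots) < 2:
        return spots.reset_index(drop=True)
    order = spots.sort_values("quality", ascending=False).index
    kept: list[int] = []
    coords = spots[["x_um", "y_um"]].to_numpy()
    for idx in order:
        p = coords[spots.index.get_loc(idx)]
        if all(
            np.hypot(*(p - coords[spots.index.get_loc(j)])) > min_sep_um for j in kept
        ):
            kept.append(idx)
    out = spots.loc[sorted(kept)].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Voronoi tessellation of localization tables


@dataclass
class LocalizationCluster:
    """A density-thresholded cluster of localization events.

    ``level`` 1 marks first-round clusters (density ≥ 1.2× the ROI mean);
    ``level`` 2 marks sub-clusters thresholded at 1.2× the mean density of
    their parent cluster.
    """

    members: np.ndarray  # indices into the input point table
    area_um2: float
    level: int
    parent: int | None = None

    @property
    def density(self) -> float:
        """Localization density within the cluster (points µm⁻²)."""
        return len(self.members) / self.area_um2


def tessellate_localizations(
    points: np.ndarray,
    roi: tuple,
    density_factor: float = 1.2,
    min_cluster_size: int = 3,
) -> tuple[list[LocalizationCluster], pd.DataFrame]:
    """Two-round density-threshold segmentation of a localization table.

    Every localization is enclosed in its Voronoi cell (boundaries
    equidistant between neighbours, clipped to the rectangular ROI so
    border cells have finite area); the local density is the inverse cell
    area. First-round clusters are connected components of points whose
    density is at least ``density_factor`` times the mean density of the
    ROI (count / ROI area); second-round sub-clusters re-threshold each
    cluster at ``density_factor`` times its own mean density.

    Parameters
    ----------
    points : (n, 2) array of localization coordinates, µm.
    roi : (xmin, xmax, ymin, ymax) rectangle, µm.

    Returns the cluster list (levels 1 and 2) and a per-point table with
    columns x_um, y_um, cell_area_um2, density.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xmin, xmax, ymin, ymax = roi
    inside = (
        (pts[:, 0] >= xmin)
        & (pts[:, 0] <= xmax)
        & (pts[:, 1] >= ymin)
        & (pts[:, 1] <= ymax)
    )
    idx = np.flatnonzero(inside)
    if len(idx) < 4:
        raise ValueError("need at least 4 localizations inside the ROI")
    pts_in = pts[idx]
    try:
        vor = Voronoi(pts_in)
    except QhullError as e:
        raise ValueError(f"degenerate localization geometry: {e}") from e

    roi_poly = box(xmin, ymin, xmax, ymax)
    areas = _cell_areas(vor, pts_in, roi_poly)
    density = 1.0 / areas

    roi_area = (xmax - xmin) * (ymax - ymin)
    mean_density = len(pts_in) / roi_area
    neighbours = _neighbour_lists(vor, len(pts_in))

    clusters: list[LocalizationCluster] = []
    level1 = _connected_dense(
        density, density_factor * mean_density, neighbours, min_cluster_size
    )
    for comp in level1:
        area = float(areas[comp].sum())
        clusters.append(
            LocalizationCluster(members=idx[comp], area_um2=area, level=1)
        )
    for ci, comp in enumerate(level1):
        a1_mean = len(comp) / float(areas[comp].sum())
        sub = _connected_dense(
            density, density_factor * a1_mean, neighbours, min_cluster_size, comp
        )
        for s in sub:
            clusters.append(
                LocalizationCluster(
                    members=idx[s],
                    area_um2=float(areas[s].sum()),
                    level=2,
                    parent=ci,
                )
            )
    table = pd.DataFrame(
        {
            "x_um": pts_in[:, 0],
            "y_um": pts_in[:, 1],
            "cell_area_um2": areas,
            "density": density,
        },
        index=idx,
    )
    return clusters, table


def _cell_areas(vor: Voronoi, pts: np.ndarray, roi_poly: Polygon) -> np.ndarray:
    """Voronoi cell areas clipped to the ROI (finite even on the hull).

    Open cells are closed by intersecting a generously padded half-plane
    construction with the ROI: each unbounded cell is replaced by the set
    of points in the padded ROI nearer to its generator than to any
    neighbour, evaluated on the clipped polygon.
    """
    pad = 2 * max(
        roi_poly.bounds[2] - roi_poly.bounds[0],
        roi_poly.bounds[3] - roi_poly.bounds[1],
    )
    areas = np.empty(len(pts))
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 not in region and len(region) > 0:
            poly = Polygon(vor.vertices[region])
        else:
            poly = _halfplane_cell(vor, pts, i, pad)
        clipped = poly.intersection(roi_poly)
        areas[i] = max(clipped.area, np.finfo(float).tiny)
    return areas


def _halfplane_cell(vor: Voronoi, pts: np.ndarray, i: int, pad: float) -> Polygon:
    cx, cy = pts[i]
    cell = box(cx - pad, cy - pad, cx + pad, cy + pad)
    for j in set(
        int(b) for a, b in vor.ridge_points if a == i
    ) | set(int(a) for a, b in vor.ridge_points if b == i):
        mid = 0.5 * (pts[i] + pts[j])
        n = pts[j] - pts[i]
        norm = np.hypot(*n)
        if norm == 0:
            continue
        n = n / norm
        t = np.array([-n[1], n[0]])
        # half-plane on i's side of the perpendicular bisector
        a = mid + t * 4 * pad
        b = mid - t * 4 * pad
        c = a - n * 8 * pad
        d = b - n * 8 * pad
        half = Polygon([a, b, d, c])
        cell = cell.intersection(half)
        if cell.is_empty:
            break
    return cell if not cell.is_empty else Polygon()


def _neighbour_lists(vor: Voronoi, n: int) -> list[list[int]]:
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for a, b in vor.ridge_points:
        nbrs[a].append(int(b))
        nbrs[b].append(int(a))
    return nbrs


def _connected_dense(density, threshold, neighbours, min_size, subset=None):
    """Connected components (Voronoi adjacency) of above-threshold points."""
    if subset is None:
        candidates = set(np.flatnonzero(density >= threshold))
    else:
        candidates = {i for i in subset if density[i] >= threshold}
    comps = []
    seen: set[int] = set()
    for start in sorted(candidates):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for vtx in neighbours[u]:
                if vtx in candidates and vtx not in seen:
                    seen.add(vtx)
                    stack.append(vtx)
        if len(comp) >= min_size:
            comps.append(np.array(sorted(comp)))
    return comps
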