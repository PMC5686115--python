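"""Punctum mobility: MSD profiles, motion-state classification, immobile
punctum identification by frame overlay, and directed-motion speed.

Classification uses transparent thresholds on the time-averaged MSD
scaling exponent α and trajectory straightness S: puncta whose mean
frame-to-frame displacement does not exceed the 40 nm mobility floor are
immobile; mobile puncta are directed (α ≥ 0.9 and S ≥ 0.35),
sub-diffusive (α ≤ 0.6) or diffusive (otherwise). The directed
thresholds sit at the equal-error point between the diffusive and
directed populations of the synthetic-data generator at its default
noise: motor transport at cargo speeds carries a Brownian component that
keeps the fine-scale straightness of real directed tracks well below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detection import detect_spots

MOBILITY_LABELS = ("immobile", "subdiffusive", "diffusive", "directed")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the deterministic motion classifier (all logged)."""

    immobile_floor_um: float = 0.04  # mean frame-to-frame displacement
    alpha_directed: float = 0.9
    straightness_directed: float = 0.35
    alpha_subdiffusive: float = 0.6
    min_track_frames: int = 30


@dataclass
class MSDProfile:
    """Time-averaged MSD of one trajectory with derived motion parameters."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    alpha: float
    straightness: float
    D_um2_s: float
    v_um_s: float
    mean_step_um: float
    n_frames: int
    alpha_valid: bool = True


def compute_msd(
    positions: np.ndarray,
    frame_interval_s: float,
    min_track_frames: int = 30,
    fit_lags_D: int = 4,
    max_lag_fraction: float = 0.25,
    fit_v: bool = True,
) -> MSDProfile:
    """Time-averaged MSD profile of one trajectory.

    MSD(τ) is averaged over all lag pairs for lags up to
    ``max_lag_fraction`` of the track length. α is the least-squares slope
    of log MSD vs log τ; D comes from the through-origin fit
    MSD = 4Dτ over the first ``fit_lags_D`` lags; v (when requested) from
    the fit MSD = v²τ² + 4Dτ over the same lag range as α.

    Raises for tracks shorter than ``min_track_frames``.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < min_track_frames:
        raise ValueError(
            f"track has {n} frames; at least {min_track_frames} required"
        )
    max_lag = max(2, int(n * max_lag_fraction))
    lags = np.arange(1, max_lag + 1)
    msd = np.array(
        [np.mean(((pos[lag:] - pos[:-lag]) ** 2).sum(axis=1)) for lag in lags]
    )
    tau = lags * frame_interval_s

    steps = np.hypot(*np.diff(pos, axis=0).T)
    mean_step = float(steps.mean())
    path_len = float(steps.sum())
    net = float(np.hypot(*(pos[-1] - pos[0])))
    straightness = net / path_len if path_len > 0 else 0.0

    alpha_valid = bool(np.all(msd > 0))
    alpha = (
        float(np.polyfit(np.log(tau), np.log(msd), 1)[0]) if alpha_valid else np.nan
    )

    k = min(fit_lags_D, len(lags))
    t_d, m_d = tau[:k], msd[:k]
    D = float(np.sum(m_d * t_d) / (4.0 * np.sum(t_d**2)))

    v = 0.0
    if fit_v:
        A = np.column_stack([4.0 * tau, tau**2])
        coef, *_ = np.linalg.lstsq(A, msd, rcond=None)
        v = float(np.sqrt(coef[1])) if coef[1] > 0 else 0.0

    return MSDProfile(
        lags_s=tau,
        msd_um2=msd,
        alpha=alpha,
        straightness=float(np.clip(straightness, 0.0, 1.0)),
        D_um2_s=D,
        v_um_s=v,
        mean_step_um=mean_step,
        n_frames=n,
        alpha_valid=alpha_valid,
    )


def classify_trajectory(
    profile: MSDProfile, config: ClassifierConfig | None = None
) -> str:
    """Assign one of the four mobility labels to an MSD profile."""
    c = config or ClassifierConfig()
    if profile.mean_step_um <= c.immobile_floor_um or not profile.alpha_valid:
        return "immobile"
    if (
        profile.alpha >= c.alpha_directed
        and profile.straightness >= c.straightness_directed
    ):
        return "directed"
    if profile.alpha <= c.alpha_subdiffusive:
        return "subdiffusive"
    return "diffusive"


def classify_tracks(
    tracks: pd.DataFrame,
    frame_interval_s: float,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Classify every sufficiently long track in a track table.

    Expects columns track_id, frame, x_um, y_um. Returns one row per kept
    track: track_id, label, alpha, straightness, D, v, n_frames.
    """
    c = config or ClassifierConfig()
    rows = []
    for tid, g in tracks.sort_values("frame").groupby("track_id"):
        pos = g[["x_um", "y_um"]].to_numpy()
        if len(pos) < c.min_track_frames:
            continue
        prof = compute_msd(pos, frame_interval_s, min_track_frames=c.min_track_frames)
        rows.append(
            {
                "track_id": tid,
                "label": classify_trajectory(prof, c),
                "alpha": prof.alpha,
                "straightness": prof.straightness,
                "D_um2_s": prof.D_um2_s,
                "v_um_s": prof.v_um_s,
                "n_frames": prof.n_frames,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "label",
            "alpha",
            "straightness",
            "D_um2_s",
            "v_um_s",
            "n_frames",
        ],
    )


def directed_speed(
    positions: np.ndarray, frame_interval_s: float, min_track_frames: int = 30
) -> float:
    """Transport speed v (µm s⁻¹) from the MSD fit MSD = v²τ² + 4Dτ.

    Returns 0 (flagged by the zero value) when the fitted quadratic
    coefficient is negative.
    """
    prof = compute_msd(
        positions, frame_interval_s, min_track_frames=min_track_frames, fit_v=True
    )
    return prof.v_um_s


def overlay_immobile(
    frame_t0: np.ndarray,
    frame_t1: np.ndarray,
    pixel_size_um: float,
    psf_sigma_um: float,
    dt_s: float,
    match_radius_um: float = 0.32,
    threshold_sd: float = 5.0,
) -> tuple[pd.DataFrame, float]:
    """Identify immobile puncta from two frames separated by ``dt_s``.

    A punctum detected at t0 is immobile iff a punctum detected at t1 lies
    within ``match_radius_um`` of its position — the quantitative
    counterpart of the pseudocolour-overlay criterion (immobile puncta
    appear white when the two frames are overlaid in different colours).

    Returns the t0 spot table with an ``immobile`` flag plus the immobile
    fraction.
    """
    if np.shape(frame_t0) != np.shape(frame_t1):
        raise ValueError("frames must share geometry")
    s0 = detect_spots(frame_t0, pixel_size_um, psf_sigma_um, threshold_sd, 0)
    s1 = detect_spots(frame_t1, pixel_size_um, psf_sigma_um, threshold_sd, 1)
    s0 = s0.copy()
    s0["dt_s"] = dt_s
    if len(s0) == 0:
        s0["immobile"] = pd.Series(dtype=bool)
        return s0, np.nan
    if len(s1) == 0:
        s0["immobile"] = False
        return s0, 0.0
    tree = cKDTree(s1[["x_um", "y_um"]].to_numpy())
    d, _ = tree.query(s0[["x_um", "y_um"]].to_numpy())
    s0["immobile"] = d <= match_radius_um
    return s0, float(s0["immobile"].mean())


# ---------------------------------------------------------------------------
# sub-trajectory splitting and per-cell summaries


def split_by_motion_change(
    positions: np.ndarray,
    frame_interval_s: float,
    window: int = 15,
    persistence: int = 10,
    config: ClassifierConfig | None = None,
) -> list[tuple[int, int]]:
    """Segment a track where its motion state changes.

    A sliding ``window``-frame classification is computed at every start
    frame; the track is re-segmented where the window label changes and
    the new label persists for at least ``persistence`` consecutive
    windows. Returns the list of (start, end) frame-index segments (end
    exclusive); a single segment means the track was not split.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    c = config or ClassifierConfig()
    if n < 2 * window:
        return [(0, n)]
    labels = []
    for s in range(n - window + 1):
        prof = compute_msd(
            pos[s : s + window], frame_interval_s, min_track_frames=window
        )
        labels.append(classify_trajectory(prof, c))
    segments = []
    seg_start = 0
    cur = labels[0]
    i = 1
    while i < len(labels):
        if labels[i] != cur:
            run = 1
            while i + run < len(labels) and labels[i + run] == labels[i]:
                run += 1
            if run >= persistence:
                segments.append((seg_start, i + window // 2))
                seg_start = i + window // 2
                cur = labels[i]
            i += run
        else:
            i += 1
    segments.append((seg_start, n))
    return segments


def mobility_summary(
    labels_per_cell: list[list[str]],
    n_split: int | None = None,
    n_total: int | None = None,
) -> dict:
    """Per-cell and pooled mobility-state fractions.

    Parameters
    ----------
    labels_per_cell : one list of track labels per cell.
    n_split, n_total : optionally, the number of trajectories split into
        sub-trajectories and the total trajectory count, reported as a
        rounded percentage.

    Returns per-cell fractions, the pooled mean ± SEM per label, and the
    split percentage when provided.
    """
    if not labels_per_cell:
        raise ValueError("need at least one cell")
    per_cell = []
    for labels in labels_per_cell:
        n = len(labels)
        per_cell.append(
            {lab: (labels.count(lab) / n if n else np.nan) for lab in MOBILITY_LABELS}
        )
    table = pd.DataFrame(per_cell)
    pooled = {
        lab: {
            "mean": float(table[lab].mean()),
            "sem": float(table[lab].sem()) if len(table) > 1 else np.nan,
        }
        for lab in MOBILITY_LABELS
    }
    out = {"per_cell": table, "pooled": pooled}
    if n_split is not None and n_total:
        out["percent_split"] = round(100.0 * n_split / n_total)
    return out
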