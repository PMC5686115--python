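"""Single-particle tracking by linear-assignment-problem (LAP) linking.

Frame-to-frame correspondences are solved as a global optimal bipartite
assignment with birth/death alternatives, followed by gap closing (one
missing frame) and split/merge annotation. Distance gates default to the
values used for IP3R punctum tracking: 400 nm frame-to-frame, 600 nm for
gap closing, 300 nm for splits and merges, with a 30-frame minimum
trajectory for downstream classification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

_BIG = 1e12


@dataclass(frozen=True)
class LinkingConfig:
    max_link_um: float = 0.4
    max_gap_link_um: float = 0.6
    max_gap_frames: int = 1
    max_split_merge_um: float = 0.3
    min_track_frames: int = 30
    #: Cost charged for leaving a spot unlinked (birth or death), in units
    #: of squared distance; defaults to the squared linking gate.
    birth_death_cost: float | None = None

    def __post_init__(self) -> None:
        if min(self.max_link_um, self.max_gap_link_um, self.max_split_merge_um) <= 0:
            raise ValueError("all gate distances must be > 0")
        if self.min_track_frames < 2:
            raise ValueError("min_track_frames must be >= 2")

    @property
    def bd_cost(self) -> float:
        return (
            self.birth_death_cost
            if self.birth_death_cost is not None
            else self.max_link_um**2
        )


def link_frames(spots: pd.DataFrame, config: LinkingConfig | None = None) -> pd.DataFrame:
    """Link per-frame spots into track segments.

    For each consecutive frame pair the correspondence minimizing total
    squared displacement is found, subject to the ``max_link_um`` gate,
    with unmatched spots becoming track deaths/births at the birth/death
    cost. Deterministic: spots are canonically ordered by (frame, x, y)
    before assignment.

    Returns the spot table with an added ``track_id`` column (one id per
    unbroken segment) and a ``gap_flag`` column (all False here).
    """
    config = config or LinkingConfig()
    spots = spots.sort_values(["frame", "x_um", "y_um"], kind="mergesort").reset_index(
        drop=True
    )
    track_of = np.full(len(spots), -1, dtype=int)
    next_track = 0
    frames = sorted(spots["frame"].unique())
    idx_by_frame = {f: spots.index[spots["frame"] == f].to_numpy() for f in frames}

    prev_idx = np.empty(0, dtype=int)
    for f in frames:
        cur_idx = idx_by_frame[f]
        if len(prev_idx) and len(cur_idx):
            a = spots.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            b = spots.loc[cur_idx, ["x_um", "y_um"]].to_numpy()
            pairs = solve_gated_assignment(a, b, config.max_link_um, config.bd_cost)
            matched_b = set()
            for i, j in pairs:
                track_of[cur_idx[j]] = track_of[prev_idx[i]]
                matched_b.add(j)
            for j in range(len(cur_idx)):
                if j not in matched_b:
                    track_of[cur_idx[j]] = next_track
                    next_track += 1
        else:
            for j in cur_idx:
                track_of[j] = next_track
                next_track += 1
        prev_idx = cur_idx

    out = spots.copy()
    out["track_id"] = track_of
    out["gap_flag"] = False
    return out


def solve_gated_assignment(
    a: np.ndarray, b: np.ndarray, gate_um: float, bd_cost: float
) -> list[tuple[int, int]]:
    """Optimal gated bipartite assignment with birth/death alternatives.

    Builds the standard augmented square cost matrix: squared distances in
    the link block (infeasible beyond the gate), the birth/death cost on
    the auxiliary diagonals, and zeros in the lower-right transpose block.
    Minimized exactly with the Hungarian algorithm.
    """
    n, m = len(a), len(b)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    link = np.where(d2 <= gate_um**2, d2, _BIG)
    cost = np.full((n + m, n + m), _BIG)
    cost[:n, :m] = link
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), bd_cost, _BIG)  # deaths
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), bd_cost, _BIG)  # births
    cost[n:, m:] = np.where(link.T < _BIG, 0.0, _BIG)
    if n + m == 0:
        return []
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and link[r, c] < _BIG
    ]


def brute_force_assignment(
    a: np.ndarray, b: np.ndarray, gate_um: float, bd_cost: float
) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive minimum-cost gated assignment (oracle for small scenes).

    Enumerates every partial matching between the two point sets and
    returns the one minimizing total squared displacement plus the
    birth/death cost for each unmatched point. Exponential; use only for
    ≤ 5 points per frame.
    """
    n, m = len(a), len(b)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2) if n and m else np.empty((n, m))
    best_cost = np.inf
    best: list[tuple[int, int]] = []
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                if any(d2[r, c] > gate_um**2 for r, c in zip(rows, cols)):
                    continue
                cost = sum(d2[r, c] for r, c in zip(rows, cols))
                cost += bd_cost * (n - k) + bd_cost * (m - k)
                if cost < best_cost - 1e-15:
                    best_cost = cost
                    best = sorted(zip(rows, cols))
    return best, float(best_cost)


def assignment_cost(
    pairs: list[tuple[int, int]], a: np.ndarray, b: np.ndarray, bd_cost: float
) -> float:
    """Total cost of a gated assignment under the birth/death convention."""
    c = sum(((a[i] - b[j]) ** 2).sum() for i, j in pairs)
    return float(c + bd_cost * (len(a) - len(pairs)) + bd_cost * (len(b) - len(pairs)))


def close_gaps_and_merge(
    segments: pd.DataFrame, config: LinkingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join track segments across one-frame gaps and annotate splits/merges.

    Segment ends are joined to segment starts ``max_gap_frames + 1`` frames
    later (default: one missing frame) within the gap-closing gate, solved
    as a gated assignment. Split and merge candidates — a segment starting
    (ending) within the split/merge gate of another track's position in the
    adjacent frame — are annotated in the summary, not fused.

    Returns
    -------
    tracks : DataFrame
        track_id, frame, x_um, y_um, gap_flag. ``gap_flag`` marks the row
        that follows a closed gap.
    summary : DataFrame
        track_id, n_frames, duration_frames, start_frame, end_frame,
        parent_id (split source, -1 if none), merged_into (-1 if none),
        kept (long enough for classification).
    """
    config = config or LinkingConfig()
    df = segments.copy()

    for _pass in range(config.max_gap_frames):
        ends = df.loc[df.groupby("track_id")["frame"].idxmax()]
        starts = df.loc[df.groupby("track_id")["frame"].idxmin()]
        remap: dict[int, int] = {}
        gap_rows: list[int] = []
        for f in sorted(ends["frame"].unique()):
            e = ends[ends["frame"] == f]
            s = starts[starts["frame"] == f + 2]
            if e.empty or s.empty:
                continue
            a = e[["x_um", "y_um"]].to_numpy()
            b = s[["x_um", "y_um"]].to_numpy()
            pairs = solve_gated_assignment(
                a, b, config.max_gap_link_um, config.max_gap_link_um**2
            )
            for i, j in pairs:
                old = int(s.iloc[j]["track_id"])
                new = int(e.iloc[i]["track_id"])
                remap[old] = new
                gap_rows.append(s.index[j])
        if not remap:
            break
        # resolve chains a<-b<-c
        def resolve(tid: int) -> int:
            while tid in remap:
                tid = remap[tid]
            return tid

        df["track_id"] = df["track_id"].map(resolve)
        df.loc[gap_rows, "gap_flag"] = True

    summary = _summarize(df, config)
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True), summary


def _summarize(df: pd.DataFrame, config: LinkingConfig) -> pd.DataFrame:
    rows = []
    by_track = {tid: g.sort_values("frame") for tid, g in df.groupby("track_id")}
    starts = {tid: g.iloc[0] for tid, g in by_track.items()}
    ends = {tid: g.iloc[-1] for tid, g in by_track.items()}
    pos = {
        tid: dict(zip(g["frame"], zip(g["x_um"], g["y_um"])))
        for tid, g in by_track.items()
    }
    for tid, g in by_track.items():
        parent, merged = -1, -1
        s, e = starts[tid], ends[tid]
        for other, p in pos.items():
            if other == tid:
                continue
            q = p.get(s["frame"] - 1)
            if q is not None and np.hypot(
                s["x_um"] - q[0], s["y_um"] - q[1]
            ) <= config.max_split_merge_um:
                parent = other
                break
        for other, p in pos.items():
            if other == tid:
                continue
            q = p.get(e["frame"] + 1)
            if q is not None and np.hypot(
                e["x_um"] - q[0], e["y_um"] - q[1]
            ) <= config.max_split_merge_um:
                merged = other
                break
        rows.append(
            {
                "track_id": tid,
                "n_frames": len(g),
                "start_frame": int(s["frame"]),
                "end_frame": int(e["frame"]),
                "duration_frames": int(e["frame"] - s["frame"]) + 1,
                "parent_id": parent,
                "merged_into": merged,
                "kept": len(g) >= config.min_track_frames,
            }
        )
    return pd.DataFrame(rows).sort_values("track_id").reset_index(drop=True)


def track(
    spots: pd.DataFrame, config: LinkingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full tracking: frame linking then gap closing / split-merge handling."""
    config = config or LinkingConfig()
    return close_gaps_and_merge(link_frames(spots, config), config)
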