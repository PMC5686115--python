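"""Photobleaching stoichiometry: bleach-step detection, fluorophore
counting from the final-step amplitude, and the random-tetramer-assembly
probability model.

IP3R channels are tetramers assembled from up to three subunit subtypes.
When only one subtype carries a fluorescent tag, the number of tagged
channels and the fluorophores per channel follow binomial statistics in
the subtype fraction and the probability that a tag is fluorescent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AssemblyModel:
    """Random assembly of tagged subunits into tetrameric channels.

    Defaults describe HeLa cells: 61% of IP3R subunits are the tagged
    subtype (IP3R1) and about 80% of expressed EGFP tags are fluorescent.
    """

    p_subunit: float = 0.61
    p_fluor: float = 0.8
    subunits_per_channel: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.p_subunit <= 1 and 0 <= self.p_fluor <= 1):
            raise ValueError("probabilities must be in [0, 1]")

    @property
    def fluorescent_subunits_per_tetramer(self) -> float:
        """Expected fluorescent subunits per channel (default 1.952)."""
        return self.subunits_per_channel * self.p_subunit * self.p_fluor


def prob_tagged_tetramer(
    model: AssemblyModel | None = None, require_fluorescent: bool = False
) -> float:
    """Probability that a random tetramer contains ≥ 1 tagged subunit.

    With ``require_fluorescent`` the subunit must also carry a fluorescent
    tag: q = p_subunit·p_fluor instead of p_subunit. Returns 1 − (1−q)⁴.
    """
    m = model or AssemblyModel()
    q = m.p_subunit * (m.p_fluor if require_fluorescent else 1.0)
    return 1.0 - (1.0 - q) ** m.subunits_per_channel


def fluorophores_from_trace(f0: float, final_step_amplitude: float) -> int:
    """Fluorophore count n = round(F0 / final-step amplitude).

    F0 is the initial (pre-bleach) intensity and the final bleaching step
    provides the unitary single-fluorophore amplitude.
    """
    if f0 <= 0 or final_step_amplitude <= 0:
        raise ValueError("F0 and final_step_amplitude must be > 0")
    if final_step_amplitude > f0 * 1.5:
        raise ValueError("final step exceeds initial intensity")
    return max(1, int(round(f0 / final_step_amplitude)))


def tetramers_from_fluorophores(
    n_fluorophores: float, model: AssemblyModel | None = None
) -> float:
    """Expected tetramer count from a fluorophore count.

    Divides by the expected number of fluorescent subunits per tetramer
    under independent random assembly (default 4 × 0.61 × 0.8 = 1.952).
    """
    m = model or AssemblyModel()
    denom = m.fluorescent_subunits_per_tetramer
    if denom <= 0:
        raise ValueError("expected fluorescent subunits per tetramer is zero")
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    return n_fluorophores / denom


# ---------------------------------------------------------------------------
# change-point step detection


def detect_bleach_steps(
    intensity: np.ndarray,
    frame_interval_s: float = 1.0,
    min_step: float | None = None,
    window: int = 1,
) -> pd.DataFrame:
    """Detect downward bleaching steps by recursive binary segmentation.

    The trace is recursively split at the change point maximizing the
    residual-sum-of-squares reduction until no split is statistically
    worthwhile (relative to the robust noise SD estimated from successive
    differences). Downward level changes are accepted as steps when they
    exceed 3× the noise SD and ``min_step``; when ``min_step`` is None it
    defaults to half a robust (median-based) estimate of the unitary
    single-fluorophore amplitude taken from the detected steps (the
    median is insensitive to an occasional double step, including a
    doubled final step).

    Returns a table (frame, time_s, amplitude) ordered in time; the last
    row is the final bleaching step. Empty for stepless traces.
    """
    y = np.asarray(intensity, dtype=float)
    if len(y) < 2 * window:
        raise ValueError(f"trace must contain at least {2 * window} samples")
    noise_sd = _robust_noise_sd(y)
    boundaries = sorted(_segment(y, 0, len(y), noise_sd, window))
    steps = _steps_from_boundaries(y, boundaries)
    # keep downward steps above the noise floor
    steps = [s for s in steps if s[1] >= max(3.0 * noise_sd, 1e-12)]
    if steps and min_step is None:
        min_step = 0.5 * float(np.median([amp for _, amp in steps]))
    if min_step:
        steps = [s for s in steps if s[1] >= min_step]
    return pd.DataFrame(
        [
            {"frame": k, "time_s": k * frame_interval_s, "amplitude": amp}
            for k, amp in steps
        ],
        columns=["frame", "time_s", "amplitude"],
    )


def analyze_bleach_trace(
    intensity: np.ndarray,
    frame_interval_s: float = 1.0,
    model: AssemblyModel | None = None,
    min_step: float | None = None,
) -> dict:
    """Per-punctum stoichiometry report.

    F0 is the mean of the pre-first-step plateau; the unitary amplitude is
    the final bleaching step; n = round(F0/unitary) and the tetramer count
    follows the random-assembly conversion.
    """
    steps = detect_bleach_steps(intensity, frame_interval_s, min_step=min_step)
    if steps.empty:
        return {"n_steps_detected": 0, "F0": float(np.mean(intensity)), "n_fluorophores": 0, "n_tetramers": 0.0, "final_step": np.nan, "steps": steps}
    first = int(steps["frame"].iloc[0])
    f0 = float(np.mean(intensity[:first]))
    final = float(steps["amplitude"].iloc[-1])
    n = fluorophores_from_trace(f0, final)
    return {
        "n_steps_detected": int(len(steps)),
        "F0": f0,
        "final_step": final,
        "n_fluorophores": n,
        "n_tetramers": tetramers_from_fluorophores(n, model),
        "steps": steps,
    }


def _robust_noise_sd(y: np.ndarray) -> float:
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def _segment(y, lo, hi, noise_sd, window, depth=0) -> list[int]:
    """Recursive binary segmentation; returns interior change points."""
    n = hi - lo
    if n < 2 * window or depth > 64:
        return []
    seg = y[lo:hi]
    k, gain = _best_split(seg, window)
    if k is None:
        return []
    # penalty: a real split must beat what noise alone could explain
    penalty = max(9.0 * noise_sd**2 * np.log(max(n, 2)), 1e-24)
    if gain <= penalty:
        return []
    cp = lo + k
    return (
        _segment(y, lo, cp, noise_sd, window, depth + 1)
        + [cp]
        + _segment(y, cp, hi, noise_sd, window, depth + 1)
    )


def _best_split(seg: np.ndarray, window: int):
    """Split index maximizing the RSS reduction (O(n) via cumulants)."""
    n = len(seg)
    c1 = np.cumsum(seg)
    total_mean = c1[-1] / n
    rss0 = float(np.sum((seg - total_mean) ** 2))
    ks = np.arange(window, n - window + 1)
    if len(ks) == 0:
        return None, 0.0
    left_sum = c1[ks - 1]
    right_sum = c1[-1] - left_sum
    nl = ks.astype(float)
    nr = n - nl
    # RSS after split = Σy² − Σl²/nl − Σr²/nr ; gain = rss0 − that
    sq = float(np.sum(seg**2))
    rss_split = sq - left_sum**2 / nl - right_sum**2 / nr
    gains = rss0 - rss_split
    j = int(np.argmax(gains))
    return int(ks[j]), float(gains[j])


def _steps_from_boundaries(y: np.ndarray, boundaries: list[int]):
    """(frame, drop amplitude) for each downward level change."""
    edges = [0] + boundaries + [len(y)]
    levels = [float(np.mean(y[a:b])) for a, b in zip(edges[:-1], edges[1:])]
    steps = []
    for i, cp in enumerate(boundaries):
        drop = levels[i] - levels[i + 1]
        if drop > 0:
            steps.append((cp, drop))
    return steps
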