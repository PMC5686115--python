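"""FRAP analysis: double normalization, mobile fraction, half-time and
diffusion coefficient.

The double normalization divides the bleach-ROI intensity by the
whole-cell intensity at every time point (cancelling acquisition
photobleaching) and then by the pre-bleach mean, so the pre-bleach level
is 1 by construction. The mobile fraction is Mf = F300/F0 with F300 the
normalized fluorescence at the recovery plateau (300 s by default); the
half-time is read off the curve by interpolation, model-free; and
D = r²γ/(4·t½) with r the bleach-spot radius and γ ≈ 1 for a circular
beam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RecoveryCurve:
    """A double-normalized FRAP recovery curve.

    ``time_s`` is relative to the bleach (negative = pre-bleach);
    ``normalized`` has pre-bleach mean 1.
    """

    time_s: np.ndarray
    normalized: np.ndarray
    bleach_frame: int
    meta: dict = field(default_factory=dict)

    @property
    def f0(self) -> float:
        """Pre-bleach normalized level (1 by construction)."""
        return float(np.mean(self.normalized[: self.bleach_frame]))

    @property
    def post_bleach(self) -> float:
        """Normalized level immediately after the bleach."""
        return float(self.normalized[self.bleach_frame])


def normalize_frap(
    roi_series: np.ndarray,
    cell_series: np.ndarray,
    bleach_frame: int,
    time_s: np.ndarray | None = None,
    frame_interval_s: float | None = None,
) -> RecoveryCurve:
    """Double-normalize a FRAP ROI series against the whole-cell series."""
    roi = np.asarray(roi_series, dtype=float)
    cell = np.asarray(cell_series, dtype=float)
    if roi.shape != cell.shape:
        raise ValueError("roi and cell series must have the same length")
    if not 0 < bleach_frame < len(roi):
        raise ValueError("bleach_frame out of range")
    if np.any(cell == 0):
        raise ValueError("zero whole-cell intensity at some frame")
    ratio = roi / cell
    pre = ratio[:bleach_frame].mean()
    if pre == 0:
        raise ValueError("pre-bleach ratio is zero")
    if time_s is None:
        if frame_interval_s is None:
            raise ValueError("provide time_s or frame_interval_s")
        time_s = (np.arange(len(roi)) - bleach_frame) * frame_interval_s
    return RecoveryCurve(
        time_s=np.asarray(time_s, dtype=float),
        normalized=ratio / pre,
        bleach_frame=bleach_frame,
    )


def mobile_fraction(
    curve: RecoveryCurve, plateau_time_s: float = 300.0, window: int = 10
) -> float:
    """Mobile fraction Mf = F_plateau / F0.

    F_plateau is averaged over a ``window``-frame window centred at
    ``plateau_time_s`` after the bleach. Raises when the curve does not
    reach the plateau time.
    """
    t = curve.time_s
    if t[-1] < plateau_time_s:
        raise ValueError(
            f"curve ends at {t[-1]:.1f} s; needs to reach {plateau_time_s:.0f} s"
        )
    i = int(np.argmin(np.abs(t - plateau_time_s)))
    half = window // 2
    lo = max(curve.bleach_frame, i - half)
    hi = min(len(t), i + half + (window % 2))
    f_plateau = float(np.mean(curve.normalized[lo:hi]))
    return f_plateau / curve.f0


def half_time(curve: RecoveryCurve, plateau_time_s: float = 300.0) -> float:
    """Half-time of recovery, model-free, by interpolation.

    The time after the bleach at which the recovery reaches halfway
    between the post-bleach level and the plateau. Recovery is physically
    monotone, so the noisy curve is projected onto the nearest monotone
    curve (isotonic regression) before the crossing is located by linear
    interpolation between the bracketing samples; a noise-free monotone
    curve is left untouched. No kinetic model is fitted.
    """
    from sklearn.isotonic import IsotonicRegression

    post = curve.time_s >= 0
    t = curve.time_s[post]
    f = curve.normalized[post]
    f = IsotonicRegression(increasing=True).fit(t, f).predict(t)
    f_b = f[0]
    tail = f[t >= min(plateau_time_s, t[-1]) * 0.9]
    plateau = float(tail.mean()) if len(tail) else float(f[-1])
    if plateau <= f_b + 1e-12:
        raise ValueError("no recovery: plateau does not exceed post-bleach level")
    target = f_b + 0.5 * (plateau - f_b)
    above = np.flatnonzero(f >= target)
    if len(above) == 0:
        raise ValueError("curve never reaches half recovery")
    j = int(above[0])
    if j == 0:
        return float(t[0])
    t0, t1 = t[j - 1], t[j]
    f0_, f1_ = f[j - 1], f[j]
    if f1_ == f0_:
        return float(t1)
    return float(t0 + (target - f0_) * (t1 - t0) / (f1_ - f0_))


def diffusion_coefficient(r_um: float, t_half_s: float, gamma: float = 1.0) -> float:
    """D = r²γ/(4·t½), µm² s⁻¹.

    ``r_um`` is the bleach-spot radius and ``gamma`` the bleach-geometry
    correction (≈1 for a circular beam).
    """
    if r_um <= 0 or t_half_s <= 0 or gamma <= 0:
        raise ValueError("r_um, t_half_s and gamma must all be > 0")
    return r_um**2 * gamma / (4.0 * t_half_s)


def analyze_frap(
    roi_series,
    cell_series,
    bleach_frame: int,
    frame_interval_s: float,
    r_um: float = 1.84,
    gamma: float = 1.0,
    plateau_time_s: float = 300.0,
) -> dict:
    """Full FRAP report: Mf, t½ and D from raw series."""
    curve = normalize_frap(
        roi_series, cell_series, bleach_frame, frame_interval_s=frame_interval_s
    )
    mf = mobile_fraction(curve, plateau_time_s=plateau_time_s)
    th = half_time(curve, plateau_time_s=plateau_time_s)
    return {
        "Mf": mf,
        "t_half_s": th,
        "D_um2_per_s": diffusion_coefficient(r_um, th, gamma),
        "curve": curve,
    }
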