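"""Movie container and TIFF/CSV input-output.

All analysis runs in physical units (µm, s). Pixel coordinates are 0-based
indices at pixel centres; ``x_um = column_index * pixel_size_um`` and
``y_um = row_index * pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class Movie:
    """A time-lapse image stack with physical calibration.

    Attributes
    ----------
    data : ndarray, shape (n_frames, height, width)
        Fluorescence intensity in arbitrary units.
    pixel_size_um : float
        Physical size of one pixel (µm).
    frame_interval_s : float
        Time between consecutive frames (s).
    channel : str
        Free-text channel label (e.g. ``"EGFP"``, ``"Cal-590"``).
    meta : dict
        Extra metadata (seed, generator parameters, ...).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("movie data must be a (T, H, W) stack")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def field_size_um(self) -> tuple:
        """(width, height) of the field of view in µm."""
        t, h, w = self.data.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.data, dtype=np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "channel": movie.channel,
        **{k: v for k, v in movie.meta.items() if _json_safe(v)},
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_movie(path: str | Path) -> Movie:
    """Read a multi-page TIFF written by :func:`write_movie`."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    return Movie(
        data=data,
        pixel_size_um=float(meta.pop("pixel_size_um")),
        frame_interval_s=float(meta.pop("frame_interval_s")),
        channel=meta.pop("channel", ""),
        meta=meta,
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
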