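"""Shared domain containers for the proteostasis-flux pipeline.

Conventions used throughout the package:

* image coordinates are 0-based ``(row, col)`` with the origin at the top
  left; the time axis always comes first,
* the green channel carries the unconverted (GFP-filter) Dendra2 signal and
  the red channel the photoconverted (TRITC-filter) signal,
* timestamps are hours since photoconversion and start at 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageStack",
    "LaneRecord",
    "SurvivalRecord",
    "DegradationRecord",
    "CellROI",
    "CellTrack",
]


@dataclass
class ImageStack:
    """Two-channel (green/red) time-lapse volume with physical timestamps.

    Parameters
    ----------
    green, red : ndarray, shape (T, H, W)
        Per-channel intensity frames.  Green is the unconverted Dendra2
        pool used for segmentation; red is the photoconverted pool whose
        decay reports degradation.
    timestamps_h : ndarray, shape (T,)
        Hours since photoconversion; strictly increasing, first entry 0.
    pixel_size_um : float
        Physical pixel size in microns.
    """

    green: np.ndarray
    red: np.ndarray
    timestamps_h: np.ndarray
    pixel_size_um: float = 0.65

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        if self.green.ndim != 3 or self.red.ndim != 3:
            raise ValueError("channel arrays must be 3-D (time, row, col)")
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel shape mismatch: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.green.shape[0] != self.timestamps_h.size:
            raise ValueError("number of frames must match number of timestamps")
        if self.n_frames < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if self.timestamps_h[0] != 0:
            raise ValueError("timestamps must start at 0 (photoconversion)")
        if np.any(np.diff(self.timestamps_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.green < 0) or np.any(self.red < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (rows, cols) shape of a single frame."""
        return self.green.shape[1:]

    @property
    def channels(self) -> tuple[str, str]:
        return ("green", "red")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; expected green or red")
        return self.green if name == "green" else self.red


@dataclass(frozen=True)
class LaneRecord:
    """One western-blot lane: target densitometry plus loading control."""

    blot_id: str
    condition: str
    mg132: bool
    target_intensity: float
    loading_intensity: float

    def __post_init__(self) -> None:
        if self.loading_intensity <= 0:
            raise ValueError("loading_intensity must be > 0")
        if self.target_intensity < 0:
            raise ValueError("target_intensity must be >= 0")

    @property
    def normalized(self) -> float:
        return self.target_intensity / self.loading_intensity


@dataclass(frozen=True)
class SurvivalRecord:
    """Survival readout for one coverslip at one concentration.

    ``count_or_signal`` is either a motor-neuron count averaged over the
    fields of one coverslip or an XTT absorbance; ``concentration`` is in
    molar units with 0 denoting vehicle.
    """

    concentration: float
    replicate_id: str
    count_or_signal: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 (0 = vehicle)")
        if self.count_or_signal < 0:
            raise ValueError("count_or_signal must be >= 0")


@dataclass(frozen=True)
class DegradationRecord:
    """One band of an in vitro degradation time course."""

    condition: str
    replicate_id: str
    time_min: float
    target_intensity: float
    loading_intensity: float

    def __post_init__(self) -> None:
        if self.loading_intensity <= 0:
            raise ValueError("loading_intensity must be > 0")
        if self.target_intensity < 0:
            raise ValueError("target_intensity must be >= 0")
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")

    @property
    def normalized(self) -> float:
        return self.target_intensity / self.loading_intensity


@dataclass
class CellROI:
    """A segmented soma in one frame."""

    frame_index: int
    centroid: tuple[float, float]  # (row, col)
    mask: np.ndarray  # boolean, full-frame shape
    area_px: int
    mean_green: float
    mean_red: float
    eccentricity: float = 0.0


@dataclass
class CellTrack:
    """One cell followed through the time lapse.

    ``rois[t]`` is ``None`` where the cell was not found in frame ``t``;
    ``trace[t]`` is the background-subtracted mean red intensity and NaN at
    gaps.
    """

    cell_id: int
    rois: list[Optional[CellROI]]
    trace: np.ndarray
    timestamps_h: np.ndarray
    is_short: bool = False

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.trace)))

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.trace)
        return self.timestamps_h[ok], self.trace[ok]
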