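"""Core in-memory containers shared across the pipeline.

An :class:`ImageStack` is an (n_frames, rows, cols) float array with physical
calibration (pixel size in um/px, frame interval in s).  A :class:`TraceSet`
holds per-ROI intensity time series on a common frame clock.  Both are plain
dataclasses: generators return them, the io module persists them (TIFF + CSV),
and the analysis modules consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StackMeta:
    """Physical calibration of an image stack."""

    pixel_size: float = 0.16  # um / px
    frame_interval: float = 1.0  # s; meaningful for movies only
    channel_name: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")


@dataclass
class ImageStack:
    """N-frame grayscale raster with calibration metadata.

    ``data`` is float64 in acquisition units (a.u.); conversion to a 16-bit
    container happens only on disk (see :mod:`synaptoflux.io`).
    """

    data: np.ndarray  # (frames, rows, cols)
    meta: StackMeta = field(default_factory=StackMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 2-D or 3-D")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.data.shape[1:]

    @property
    def pixel_size(self) -> float:
        return self.meta.pixel_size

    @property
    def frame_times(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.meta.frame_interval


@dataclass
class TraceSet:
    """Per-ROI intensity time series sharing one frame clock.

    ``intensities`` has shape (n_rois, n_frames); ``frame_rate`` is in Hz.
    """

    intensities: np.ndarray
    frame_rate: float = 1.0
    roi_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=np.float64))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.roi_ids is None:
            self.roi_ids = np.arange(1, self.intensities.shape[0] + 1)
        else:
            self.roi_ids = np.asarray(self.roi_ids)
            if self.roi_ids.shape[0] != self.intensities.shape[0]:
                raise ValueError("roi_ids length must match number of traces")

    @property
    def n_rois(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    def trace(self, roi_id: int) -> np.ndarray:
        """Return the intensity series of one ROI by id."""
        idx = np.flatnonzero(self.roi_ids == roi_id)
        if idx.size == 0:
            raise KeyError(f"no trace for ROI id {roi_id}")
        return self.intensities[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: (roi, frame, time_s, intensity)."""
        n_r, n_f = self.intensities.shape
        return pd.DataFrame(
            {
                "roi": np.repeat(self.roi_ids, n_f),
                "frame": np.tile(np.arange(n_f), n_r),
                "time_s": np.tile(self.times, n_r),
                "intensity": self.intensities.ravel(),
            }
        )
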