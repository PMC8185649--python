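"""Calibrated multichannel time-lapse image container.

The package works on 4-D intensity arrays ordered T x C x Y x X, with the
physical calibration (pixel size in nanometres, frame interval in seconds)
carried alongside so that all geometry is computed in pixel/frame units and
converted only at reporting time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A T x C x Y x X fluorescence stack with physical calibration.

    Parameters
    ----------
    data:
        Nonnegative intensities, shape ``(T, C, Y, X)``.
    pixel_size:
        Physical size of one pixel, in nanometres.
    frame_interval:
        Time between consecutive frames, in seconds.
    channel_names:
        Ordered channel labels, e.g. ``("membrane", "probe")``.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be T x C x Y x X, got shape {self.data.shape}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("need at least one frame and one channel")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[1]))
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel axis")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (Y, X)."""
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the T x Y x X sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.data[:, idx]

    def frame(self, t: int, channel: str | int = 0) -> np.ndarray:
        """Return one Y x X frame."""
        if isinstance(channel, str):
            return self.channel(channel)[t]
        return self.data[t, channel]

    def to_tiff(self, path: str | Path) -> None:
        """Write as multi-page 16-bit TIFF with calibration in the description."""
        meta = {
            "axes": "TCYX",
            "pixel_size_nm": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "channel_names": list(self.channel_names),
        }
        out = np.clip(np.rint(self.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(str(path), out, description=json.dumps(meta))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        """Read a stack written by :meth:`to_tiff` (or any TCYX TIFF with
        a JSON description carrying the calibration keys)."""
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        if data.ndim == 3:  # T x Y x X, single channel
            data = data[:, None]
        elif data.ndim == 2:
            data = data[None, None]
        return cls(
            data=data.astype(float),
            pixel_size=float(meta.get("pixel_size_nm", 1.0)),
            frame_interval=float(meta.get("frame_interval_s", 1.0)),
            channel_names=tuple(meta.get("channel_names", ())),
        )
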