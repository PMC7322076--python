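"""Multi-channel, multi-frame image container with physical calibration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FrameSeries"]


@dataclass
class FrameSeries:
    """Image data shaped (channel, time, y, x) plus calibration.

    ``channel_names`` gives the semantic identity of each channel
    (e.g. ``eres``, ``golgi``, ``er``, ``copii``).
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_nm: float
    frame_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (channel, time, y, x)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names must match data.shape[0]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (time, y, x) stack for one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.data[idx]

    def frame(self, name: str, t: int) -> np.ndarray:
        return self.channel(name)[t]

    # -- persistence -------------------------------------------------------
    def write_tiff(self, path: str | Path) -> None:
        """Write as a CTYX TIFF with calibration in the image description."""
        desc = json.dumps(
            {
                "channel_names": list(self.channel_names),
                "pixel_size_nm": self.pixel_size_nm,
                "frame_interval_s": self.frame_interval_s,
                "axes": "CTYX",
            }
        )
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            metadata=None,
            description=desc,
        )

    @classmethod
    def read_tiff(cls, path: str | Path) -> "FrameSeries":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc)
        data = data.reshape(
            len(meta["channel_names"]), -1, data.shape[-2], data.shape[-1]
        )
        return cls(
            data=data,
            channel_names=tuple(meta["channel_names"]),
            pixel_size_nm=float(meta["pixel_size_nm"]),
            frame_interval_s=float(meta["frame_interval_s"]),
        )
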