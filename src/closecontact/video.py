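"""Image-stack container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageVideo:
    """A single-channel fluorescence time-lapse.

    ``data`` is ordered ``(time, y, x)``; ``pixel_size_um`` and
    ``frame_interval_s`` carry the physical calibration every downstream
    measurement needs.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("video data must be (time, y, x)")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def with_data(self, data: np.ndarray) -> "ImageVideo":
        return ImageVideo(data, self.pixel_size_um, self.frame_interval_s, self.channel)

    def write_tiff(self, path: str | Path) -> None:
        """Write as OME-TIFF with physical pixel size and frame interval."""
        tifffile.imwrite(
            str(path),
            np.asarray(self.data, np.float32),
            ome=True,
            metadata={
                "axes": "TYX",
                "PhysicalSizeX": self.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "TimeIncrement": self.frame_interval_s,
                "TimeIncrementUnit": "s",
            },
        )


def read_tiff(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel: str = "",
) -> ImageVideo:
    """Read a (T, Y, X) TIFF stack; metadata arguments override what (if
    anything) is stored in the file."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if pixel_size_um is None or frame_interval_s is None:
            meta = {}
            if tf.ome_metadata:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                for px in root.iter():
                    if px.tag.endswith("Pixels"):
                        meta = px.attrib
                        break
            if pixel_size_um is None:
                pixel_size_um = float(meta.get("PhysicalSizeX", 1.0))
            if frame_interval_s is None:
                frame_interval_s = float(meta.get("TimeIncrement", 1.0))
    return ImageVideo(data, pixel_size_um, frame_interval_s, channel)
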