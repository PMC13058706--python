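"""Named multi-channel image container and TIFF round-trip.

A :class:`ChannelStack` is the unit every pipeline stage consumes: a
``(C, H, W)`` float array with one name per channel plus the physical pixel
size.  The default seven-channel layout mirrors a 5-plex B-lineage panel
acquired alongside a nuclear counterstain and a dedicated autofluorescence
channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Default channel order: nuclear stain, autofluorescence, then markers.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "DAPI", "AF", "CD79a", "CD38", "Ki67", "CD19", "CD138",
)

#: Acquisition fluorophore conventionally carrying each channel.
CHANNEL_FLUOROPHORES: dict[str, str] = {
    "DAPI": "DAPI",
    "AF": "CFP",
    "CD79a": "FITC",
    "CD38": "Rhodamine 6G",
    "Ki67": "Red 610",
    "CD19": "Cy5",
    "CD138": "CY7",
}

#: Whole-slide scan resolution in micrometres per pixel (20x objective).
DEFAULT_PIXEL_SIZE_UM: float = 0.325


class ChannelError(KeyError):
    """Requested channel is not present in the stack."""


@dataclass
class ChannelStack:
    """Multi-channel 2D fluorescence image with named channels.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, rows, cols)``.
    channels
        One name per channel, same order as ``data``.
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    """

    data: np.ndarray
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError(f"expected (C, H, W) data, got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} planes"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape ``(rows, cols)``."""
        return self.data.shape[1], self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel plane by name.

        Raises
        ------
        ChannelError
            If ``name`` is absent; the message lists available channels.
        """
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise ChannelError(
                f"channel {name!r} not found; available: {list(self.channels)}"
            ) from None
        return self.data[idx]

    def write_tiff(self, path) -> None:
        """Write a multi-page TIFF, one page per channel.

        Each page's ImageDescription carries a small JSON record with the
        channel name and pixel size so the stack round-trips losslessly.
        """
        with tifffile.TiffWriter(path) as tif:
            for name, plane in zip(self.channels, self.data):
                desc = json.dumps(
                    {"channel": name, "pixel_size_um": self.pixel_size_um}
                )
                tif.write(plane, description=desc, contiguous=False)

    @classmethod
    def read_tiff(cls, path, channels: tuple[str, ...] | None = None,
                  pixel_size_um: float | None = None) -> "ChannelStack":
        """Read a multi-page TIFF written by :meth:`write_tiff`.

        ``channels``/``pixel_size_um`` override metadata when the file was
        produced by another tool and carries none.
        """
        names: list[str] = []
        planes: list[np.ndarray] = []
        px = pixel_size_um
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                planes.append(page.asarray())
                meta = {}
                if page.description:
                    try:
                        meta = json.loads(page.description)
                    except (json.JSONDecodeError, TypeError):
                        meta = {}
                names.append(meta.get("channel", f"ch{i}"))
                if px is None and "pixel_size_um" in meta:
                    px = float(meta["pixel_size_um"])
        data = np.stack(planes)
        if channels is not None:
            names = list(channels)
        return cls(data, tuple(names), px if px is not None else DEFAULT_PIXEL_SIZE_UM)
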