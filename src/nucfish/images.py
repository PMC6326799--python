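"""Multi-channel 3D image stacks with physical voxel size.

Axis order is ``(channel, z, y, x)``; voxel size is ``(z, y, x)`` in
micrometres. Physical positions are measured from the centre of voxel
``(0, 0, 0)``, i.e. ``position_um = index * voxel_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A channel x z x y x x intensity grid with physical voxel size (um)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4-D (C, Z, Y, X), got shape {self.voxels.shape}"
            )
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match number of channels")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None
        return self.voxels[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def index_to_um(self, idx_zyx) -> np.ndarray:
        return np.asarray(idx_zyx, dtype=float) * np.asarray(self.voxel_size)

    def um_to_index(self, pos_um) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical position."""
        return np.asarray(pos_um, dtype=float) / np.asarray(self.voxel_size)

    def contains_um(self, pos_um) -> bool:
        idx = self.um_to_index(pos_um)
        hi = np.array(self.shape_zyx) - 1
        return bool(np.all(idx >= 0) and np.all(idx <= hi))


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF in CZYX order.

    The voxel size and channel names are stored as a JSON document in the
    TIFF image description so that a stack round-trips losslessly.
    """
    meta = {
        "axes": "CZYX",
        "voxel_size_um": list(stack.voxel_size),
        "channel_names": list(stack.channel_names),
    }
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except (tifffile.TiffFileError, FileNotFoundError):
        raise
    except Exception as exc:  # truncated/corrupt files surface here
        raise ValueError(f"could not parse TIFF {path}: {exc}") from exc
    try:
        meta = json.loads(desc)
        voxel_size = tuple(meta["voxel_size_um"])
        channel_names = list(meta["channel_names"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(
            f"TIFF {path} lacks the expected JSON metadata in its description"
        ) from exc
    if data.ndim == 3:  # single-channel file
        data = data[None]
    return ImageStack(np.asarray(data, dtype=float), voxel_size, channel_names)
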