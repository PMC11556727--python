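"""Core in-memory containers for multichannel confocal z-stacks.

Axis convention, used everywhere in this package: ``(channel, z, y, x)``
for multichannel stacks, ``(z, y, x)`` for single volumes, 0-based indices.
Physical voxel sizes ride along as ``(dz, dy, dx)`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A multichannel 3D voxel grid with physical voxel sizes.

    Parameters
    ----------
    voxels : ndarray
        ``(C, Z, Y, X)`` or ``(Z, Y, X)`` intensity grid. Rendered images are
        unsigned 16-bit; noiseless scenes are float32 in arbitrary units.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in micrometres; all entries strictly positive.
    channel_names : list of str
        One name per channel (a single implicit channel for 3D input).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
            if not self.channel_names:
                self.channel_names = ["channel0"]
        if self.voxels.ndim != 4:
            raise ValueError(f"expected 3D or 4D voxel grid, got ndim={self.voxels.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")
        if not self.channel_names:
            self.channel_names = [f"channel{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.voxels.shape[0]} channels"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` volume for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None
        return self.voxels[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names
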