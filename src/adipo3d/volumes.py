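"""Core grid containers shared by every stage of the pipeline.

Conventions (fixed package-wide):

* grids are indexed ``(z, y, x)``;
* ``voxel_size`` is always reported in ``(dx, dy, dz)`` order, in µm;
* physical positions are measured at voxel centers, origin at the first
  voxel center, so voxel ``(k, j, i)`` sits at ``(i*dx, j*dy, k*dz)`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "AdipoError",
    "ParameterError",
    "voxel_volume",
]


class AdipoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AdipoError, ValueError):
    """Invalid user-supplied parameter."""


def voxel_volume(voxel_size: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in µm³ for spacing ``(dx, dy, dz)``."""
    dx, dy, dz = voxel_size
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ParameterError(f"voxel_size must be positive, got {voxel_size}")
    return float(dx * dy * dz)


@dataclass
class ImageVolume:
    """Multi-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    channels
        Mapping of channel tag (``"lipid"``, ``"ecm"``) to a 3D float
        array indexed ``(z, y, x)``.  All channels must share one shape.
    voxel_size
        ``(dx, dy, dz)`` spacing in µm.
    meta
        Free-form provenance metadata (seed, config hash, crop origin...).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ParameterError("ImageVolume needs at least one channel")
        shapes = {tag: ch.shape for tag, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ParameterError(f"channel shapes differ: {shapes}")
        first = next(iter(self.channels.values()))
        if first.ndim != 3:
            raise ParameterError(f"channels must be 3D (z, y, x), got ndim={first.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        voxel_volume(self.voxel_size)  # validates positivity

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        return voxel_volume(self.voxel_size)

    def channel(self, tag: str) -> np.ndarray:
        try:
            return self.channels[tag]
        except KeyError:
            raise KeyError(
                f"channel {tag!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass
class LabelVolume:
    """Integer-labeled 3D grid; 0 is background, labels are positive."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ParameterError(f"labels must be 3D (z, y, x), got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ParameterError(f"labels must be integer-typed, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ParameterError("labels must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        voxel_volume(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return voxel_volume(self.voxel_size)

    def ids(self) -> np.ndarray:
        """Sorted array of nonzero label ids present in the grid."""
        ids = np.unique(self.data)
        return ids[ids > 0]

    def matches(self, image: ImageVolume) -> bool:
        return self.shape == image.shape and tuple(self.voxel_size) == tuple(image.voxel_size)
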