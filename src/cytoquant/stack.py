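"""Core containers: acquisition geometry and multi-channel 3D image stacks.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x, channel)``;
* 2D images and masks are indexed ``(row, column) = (y, x)``, 0-based;
* physical pixel sizes are in micrometres (µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ChannelNotFoundError, DimensionError, ValidationError

#: default lateral pixel size, µm (confocal, 63x oil objective, zoomed)
DEFAULT_DX = 0.07
#: default axial step between optical sections, µm
DEFAULT_DZ = 0.19


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical sampling of a confocal z-stack.

    Parameters
    ----------
    dx, dy : float
        Lateral pixel size in µm.  The acquisition model assumes square
        pixels, so ``dx == dy`` is enforced.
    dz : float
        Axial distance between optical sections in µm.
    field_pixels : (int, int)
        Image field as ``(ny, nx)``.
    n_slices : int
        Number of optical sections.
    """

    dx: float = DEFAULT_DX
    dy: float = DEFAULT_DX
    dz: float = DEFAULT_DZ
    field_pixels: tuple[int, int] = (256, 256)
    n_slices: int = 31

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValidationError("pixel sizes dx, dy, dz must be positive")
        if self.dx != self.dy:
            raise ValidationError("square pixels required (dx == dy)")
        ny, nx = self.field_pixels
        if ny < 1 or nx < 1 or self.n_slices < 1:
            raise ValidationError("field_pixels and n_slices must be >= 1")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        ny, nx = self.field_pixels
        return (self.n_slices, ny, nx)

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical extent of the field (y, x) in µm."""
        ny, nx = self.field_pixels
        return ((ny - 1) * self.dy, (nx - 1) * self.dx)

    @property
    def depth_um(self) -> float:
        """Physical extent of the imaged slab in µm."""
        return (self.n_slices - 1) * self.dz


@dataclass
class ImageStack:
    """A multi-channel 3D confocal stack with physical geometry.

    ``voxels`` has shape ``(z, y, x, channel)`` and non-negative intensities
    in arbitrary units.  ``channel_names`` labels the last axis.
    """

    voxels: np.ndarray
    geometry: AcquisitionGeometry
    channel_names: tuple[str, ...] = ("dapi", "marker")
    stack_id: str = ""
    _index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise DimensionError(
                f"voxels must be 4D (z, y, x, channel); got shape {v.shape}"
            )
        if v.shape[:3] != self.geometry.shape_zyx:
            raise DimensionError(
                f"voxel grid {v.shape[:3]} does not match geometry "
                f"{self.geometry.shape_zyx}"
            )
        if v.shape[3] != len(self.channel_names):
            raise DimensionError(
                f"{v.shape[3]} channels but {len(self.channel_names)} names"
            )
        if v.size and float(v.min()) < 0:
            raise ValidationError("intensities must be non-negative")
        self.voxels = v
        self._index = {name: i for i, name in enumerate(self.channel_names)}

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` sub-array for one named channel."""
        try:
            idx = self._index[name]
        except KeyError:
            raise ChannelNotFoundError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.voxels[..., idx]
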