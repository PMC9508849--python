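"""Shared domain types for the ExEpi pipeline.

Axis convention
---------------
Image arrays are indexed ``(channel, z, y, x)``, 0-based.  Sub-pixel
coordinates are continuous in voxel units with voxel centers at integer
coordinates; physical position is ``index * spacing``.  Anisotropy
(``dz != dx``) is handled wherever distances are computed, never by
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "NucleusRegion",
    "Spot",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel sizes and gel expansion ratio.

    Parameters
    ----------
    dx_um, dy_um : float
        Lateral pixel size in micrometers per pixel.
    dz_um : float
        Axial step in micrometers per z-slice (confocal stacks here use
        0.2 um between slices).
    expansion_factor : float
        Linear gel expansion ratio (dimensionless, >= 1).  Pre-expansion
        data uses 1.0; expanded gels are typically ~3.5.  Distances measured
        in the gel are divided by this factor to recover biological scale.
    """

    dx_um: float
    dy_um: float
    dz_um: float
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dx_um > 0 and self.dy_um > 0 and self.dz_um > 0):
            raise ValueError("voxel spacings must be strictly positive")
        if self.expansion_factor < 1.0:
            raise ValueError("expansion_factor must be >= 1 (use 1.0 for pre-expansion data)")

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel spacing as (dz, dy, dx) in micrometers."""
        return (self.dz_um, self.dy_um, self.dx_um)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx_um * self.dy_um * self.dz_um


@dataclass
class ImageStack:
    """A multi-channel 3D intensity stack.

    ``data`` is indexed ``(channel, z, y, x)`` with non-negative
    intensities in arbitrary units; intensities are never compared across
    channels.  ``channel_names`` gives the ordered channel labels
    (e.g. ``["dapi", "reader", "marker"]``).
    """

    data: np.ndarray
    channel_names: list[str]
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (channel, z, y, x); got ndim={self.data.ndim}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} channels in data but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.shape[1] < 1:
            raise ValueError("z-dimension must be >= 1")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (z, y, x) view."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel not found: {name!r} (have {self.channel_names})"
            ) from None
        return self.data[idx]


@dataclass
class NucleusRegion:
    """One segmented nucleus: its 3D mask and rim-distance map.

    Attributes
    ----------
    cell_id : int
        Stable label (regions are sorted by centroid).
    mask : np.ndarray
        Boolean (z, y, x) array marking the nucleus interior.
    rim_distance_map : np.ndarray
        Physical distance (um, sample scale, i.e. before division by the
        expansion factor) from each interior voxel to the nearest exterior
        voxel, anisotropy-aware; exactly 0 outside the mask.
    centroid_px : tuple of float
        Mask centroid in (z, y, x) voxel coordinates.
    equivalent_radius_um : float
        Radius of the sphere with the same volume as the mask.
    touches_border : bool
        True if the mask touches a lateral stack border; such cells are
        excluded from spatial analysis by default (a stack border is not a
        nuclear rim).
    """

    cell_id: int
    mask: np.ndarray
    rim_distance_map: np.ndarray
    centroid_px: tuple[float, float, float]
    equivalent_radius_um: float
    touches_border: bool = False

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Spot:
    """One detected emitter with sub-pixel 3D position and fit parameters.

    ``position_px`` is (z, y, x) in voxel units.  ``sigma_px`` is the fitted
    lateral Gaussian width; the axial position comes from a parabolic
    refinement across slices rather than a full 3D fit (thin stacks
    under-sample the axial PSF).  ``fit_quality`` is the RMS fit residual
    divided by the fitted amplitude (smaller is better).
    """

    cell_id: int
    position_px: tuple[float, float, float]
    amplitude: float
    background: float
    sigma_px: float
    fit_quality: float
    z_slice_of_max: int
    spot_id: int = -1

    @property
    def z(self) -> float:
        return self.position_px[0]

    @property
    def y(self) -> float:
        return self.position_px[1]

    @property
    def x(self) -> float:
        return self.position_px[2]
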