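"""Reading and writing image stacks and tabular results.

Stacks are (OME-)TIFF; tables are plain CSV with a stable, documented
column order.  Geometry precedence: an explicit ``geometry`` argument
overrides file metadata (microscope metadata is frequently wrong); a
conflict is logged as a warning.  If neither the file nor the caller
provides voxel sizes, reading fails loudly — geometry is never silently
defaulted.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, VoxelGeometry

log = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "SPOT_COLUMNS",
    "COLOC_COLUMNS",
    "DISTANCE_COLUMNS",
    "RATIO_COLUMNS",
]

# Stable column orders for the tabular outputs (one row per spot or cell).
SPOT_COLUMNS = [
    "sample_id", "cell_id", "spot_id", "z_px", "y_px", "x_px",
    "amplitude", "background", "sigma_px", "fit_quality", "z_slice_of_max",
]
COLOC_COLUMNS = [
    "sample_id", "cell_id", "spot_id", "observed_intensity", "p_value", "is_coloc",
]
DISTANCE_COLUMNS = [
    "sample_id", "cell_id", "spot_id", "category", "distance_um", "p_value",
]
RATIO_COLUMNS = [
    "sample_id", "cell_id", "condition", "n_total", "n_coloc",
    "ratio", "percentage",
]


def _parse_ome_geometry(ome_xml: str) -> dict[str, float]:
    """Extract PhysicalSizeX/Y/Z (um) from OME-XML, if present."""
    out: dict[str, float] = {}
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return out
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            for key, name in (
                ("PhysicalSizeX", "dx_um"),
                ("PhysicalSizeY", "dy_um"),
                ("PhysicalSizeZ", "dz_um"),
            ):
                val = elem.get(key)
                if val is not None:
                    out[name] = float(val)
            break
    return out


def _normalize_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (C, Z, Y, X), squeezing size-1 extras."""
    axes = axes.upper()
    # squeeze singleton axes that are not C/Z/Y/X (e.g. T, S); a single
    # unknown page axis in a plain multi-page TIFF (often 'Q' or 'I') is
    # interpreted as Z
    kept_axes = []
    keep = []
    for i, ax in enumerate(axes):
        if ax in "CZYX":
            keep.append(i)
            kept_axes.append(ax)
        elif arr.shape[i] == 1:
            arr = np.squeeze(arr, axis=len(keep))
            continue
        elif ax in "QI" and "Z" not in axes:
            keep.append(i)
            kept_axes.append("Z")
        else:
            raise ValueError(f"unsupported non-singleton axis {ax!r} in TIFF (axes={axes})")
    axes = "".join(kept_axes)
    for ax in "CZYX":
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(arr, order)


def read_stack(
    path: str | Path,
    channel_map: dict[str, int],
    geometry: VoxelGeometry | None = None,
    expansion_factor: float | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF z-stack into an :class:`ImageStack`.

    Parameters
    ----------
    path : path
        TIFF or OME-TIFF file with one or more channels.
    channel_map : dict
        Mapping from channel name (e.g. ``"dapi"``) to the channel index in
        the file.  The resulting stack's channel order follows the mapping's
        insertion order, never the file-internal order.
    geometry : VoxelGeometry, optional
        Explicit voxel geometry.  Overrides file metadata (a conflict is
        logged).  If omitted, geometry must be recoverable from OME
        metadata, otherwise reading fails.
    expansion_factor : float, optional
        Expansion factor to attach when geometry comes from file metadata
        (metadata never stores it); defaults to 1.0.

    Raises
    ------
    KeyError
        If a mapped channel index does not exist in the file.
    ValueError
        If geometry is available neither from metadata nor the caller.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = _normalize_axes(series.asarray(), series.axes)
        meta_geom: dict[str, float] = {}
        if tif.ome_metadata:
            meta_geom = _parse_ome_geometry(tif.ome_metadata)

    n_channels = arr.shape[0]
    for name, idx in channel_map.items():
        if not (0 <= idx < n_channels):
            raise KeyError(
                f"channel not found: {name!r} maps to index {idx} "
                f"but file has {n_channels} channel(s)"
            )

    if geometry is not None:
        if meta_geom:
            for key, val in meta_geom.items():
                if not np.isclose(getattr(geometry, key), val):
                    log.warning(
                        "geometry conflict for %s: config=%g, file metadata=%g "
                        "(using config)", key, getattr(geometry, key), val,
                    )
        geom = geometry
    elif {"dx_um", "dy_um", "dz_um"} <= meta_geom.keys():
        geom = VoxelGeometry(
            dx_um=meta_geom["dx_um"],
            dy_um=meta_geom["dy_um"],
            dz_um=meta_geom["dz_um"],
            expansion_factor=expansion_factor if expansion_factor is not None else 1.0,
        )
    else:
        raise ValueError(
            f"voxel geometry for {path} is absent from file metadata and no "
            "explicit geometry was supplied; refusing to guess"
        )

    names = list(channel_map)
    data = np.stack([arr[channel_map[name]] for name in names])
    return ImageStack(data=data, channel_names=names, geometry=geom)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with physical voxel sizes."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.geometry.dx_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.geometry.dy_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.geometry.dz_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": stack.channel_names},
        },
    )


def write_table(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None,
                header_comment: str | None = None) -> None:
    """Write a results table as CSV in a stable column order.

    Floats are written at full precision so the table round-trips exactly.
    An optional ``header_comment`` (e.g. package version and config hash) is
    written as a leading ``#`` line.
    """
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"table is missing columns {missing}")
        df = df[columns]
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")
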