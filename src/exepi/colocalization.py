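"""Empirical-p-value co-localization of spots with a marker channel.

For each detected spot, the marker intensity at the spot's position is
compared with the distribution of marker intensities at random locations
inside the same nucleus.  The upper-tail empirical p-value uses the
add-one (permutation-test) correction

    p = (1 + #{reference >= observed}) / (1 + n_reference),

so p > 0 always and the statistic is valid (super-uniform under the null)
at finite sample size; ties count toward the tail (conservative — intensity
images are discrete).  A spot is called co-localizing when p < alpha
(default 0.05).  Per-cell summaries are the co-localization ratio

    R = 100 * n_coloc / (n_total - n_coloc)

and the percentage 100 * n_coloc / n_total.  The statistic depends on the
marker channel only through intensity ranks, so it is invariant under any
strictly monotone intensity transform.

The 180-degree rotation of the marker channel destroys true spatial
correspondence while preserving the marker's intensity statistics; the
ratio measured after rotation estimates the false-positive (background)
co-localization floor.  The reversed (marker-anchored) analysis is the same
machinery with the channel roles exchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import NucleusRegion, Spot

log = logging.getLogger(__name__)

__all__ = [
    "ColocParams",
    "ColocResult",
    "read_intensity",
    "readout_image",
    "valid_readout_support",
    "sample_random_intensities",
    "empirical_pvalue",
    "classify_spots",
    "coloc_ratio",
    "coloc_percentage",
    "rotate_channel_180",
]


@dataclass(frozen=True)
class ColocParams:
    """Parameters of the empirical-p-value test.

    ``readout_radius_px`` is the lateral radius of the intensity-readout
    disc on the spot's nearest z-slice (0 reads a single voxel); a natural
    choice is ``round(FWHM / 2)`` of the marker spots.  ``n_random`` random
    nuclear locations per cell give p-value granularity 1/(n_random + 1).
    ``anchor`` records which channel provided the spots ("reader" for the
    forward analysis, "marker" for the reversed one).
    """

    alpha: float = 0.05
    n_random: int = 10_000
    readout_radius_px: int = 2
    seed: int = 0
    anchor: str = "reader"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_random < 100:
            raise ValueError("n_random must be >= 100")
        if self.readout_radius_px < 0:
            raise ValueError("readout_radius_px must be >= 0")


def _disc_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    sel = dy ** 2 + dx ** 2 <= radius ** 2
    return np.stack([dy[sel], dx[sel]], axis=1)


def readout_image(marker: np.ndarray, readout_radius_px: int) -> np.ndarray:
    """Per-voxel disc-mean image: value at (z, y, x) equals the mean of the
    marker over the lateral disc of the readout radius on that slice."""
    marker = np.asarray(marker, dtype=float)
    if readout_radius_px == 0:
        return marker.copy()
    offs = _disc_offsets(readout_radius_px)
    kernel = np.zeros((1, 2 * readout_radius_px + 1, 2 * readout_radius_px + 1))
    kernel[0, offs[:, 0] + readout_radius_px, offs[:, 1] + readout_radius_px] = 1.0
    kernel /= kernel.sum()
    return ndimage.convolve(marker, kernel, mode="nearest")


def read_intensity(
    marker: np.ndarray,
    position_px: tuple[float, float, float],
    readout_radius_px: int = 0,
) -> float:
    """Marker intensity at a sub-pixel position: mean over the lateral disc
    of ``readout_radius_px`` centered on the nearest voxel of the nearest
    z-slice (radius 0 reads that single voxel)."""
    marker = np.asarray(marker, dtype=float)
    nz, ny, nx = marker.shape
    z, y, x = (int(round(c)) for c in position_px)
    if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
        raise ValueError(f"position {position_px} outside the stack")
    offs = _disc_offsets(readout_radius_px)
    ys = np.clip(y + offs[:, 0], 0, ny - 1)
    xs = np.clip(x + offs[:, 1], 0, nx - 1)
    return float(marker[z, ys, xs].mean())


def valid_readout_support(mask: np.ndarray, readout_radius_px: int) -> np.ndarray:
    """Interior voxels whose lateral readout disc lies entirely inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if readout_radius_px == 0:
        return mask.copy()
    r = np.arange(-readout_radius_px, readout_radius_px + 1)
    disc = (r[:, None] ** 2 + r[None, :] ** 2) <= readout_radius_px ** 2
    return np.stack([ndimage.binary_erosion(sl, structure=disc) for sl in mask])


def sample_random_intensities(
    marker: np.ndarray,
    region: NucleusRegion,
    params: ColocParams,
) -> np.ndarray:
    """Reference sample: marker readout at ``n_random`` locations drawn
    uniformly (with replacement) over mask voxels whose readout disc lies
    inside the mask.  Reproducible from ``params.seed``."""
    support = valid_readout_support(region.mask, params.readout_radius_px)
    idx = np.argwhere(support)
    if len(idx) == 0:
        raise ValueError(
            "nucleus mask too small to host any readout neighborhood of radius "
            f"{params.readout_radius_px} px"
        )
    rng = np.random.default_rng(params.seed)
    picks = idx[rng.integers(len(idx), size=params.n_random)]
    readout = readout_image(marker, params.readout_radius_px)
    return readout[picks[:, 0], picks[:, 1], picks[:, 2]]


def empirical_pvalue(observed: float, reference: np.ndarray) -> float:
    """Upper-tail add-one empirical p-value in (0, 1]."""
    if not np.isfinite(observed):
        raise ValueError("observed intensity must be finite")
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference sample is empty")
    return float((1 + np.count_nonzero(reference >= observed)) / (1 + reference.size))


def _pvalues(observed: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref_sorted = np.sort(reference)
    n = ref_sorted.size
    n_ge = n - np.searchsorted(ref_sorted, observed, side="left")
    return (1 + n_ge) / (1 + n)


@dataclass
class ColocResult:
    """Per-spot p-values and per-cell co-localization summary.

    ``records`` has one row per tested spot with columns
    ``spot_id, z_px, y_px, x_px, observed_intensity, p_value, is_coloc``.
    ``ratio`` is NaN (flagged via ``ratio_defined``) when every spot
    co-localizes or when there are no spots.
    """

    records: pd.DataFrame
    cell_id: int
    n_total: int
    n_coloc: int
    ratio: float
    percentage: float
    ratio_defined: bool
    alpha: float
    anchor: str = "reader"
    condition: str | None = None


def coloc_ratio(n_coloc: int, n_total: int) -> float:
    """Co-localization ratio R = 100 * n_coloc / (n_total - n_coloc).

    Raises ``ValueError`` when all spots co-localize (no denominator).
    """
    if not 0 <= n_coloc <= n_total or n_total <= 0:
        raise ValueError("need 0 <= n_coloc <= n_total with n_total > 0")
    if n_coloc == n_total:
        raise ValueError("ratio undefined (no non-co-localizing spots)")
    return 100.0 * n_coloc / (n_total - n_coloc)


def coloc_percentage(n_coloc: int, n_total: int) -> float:
    """Co-localization percentage 100 * n_coloc / n_total."""
    if not 0 <= n_coloc <= n_total or n_total <= 0:
        raise ValueError("need 0 <= n_coloc <= n_total with n_total > 0")
    return 100.0 * n_coloc / n_total


def classify_spots(
    spots: list[Spot],
    marker: np.ndarray,
    region: NucleusRegion,
    params: ColocParams,
) -> ColocResult:
    """Classify each spot as co-localizing (p < alpha) or not.

    One shared reference sample is drawn per (cell, marker channel) and used
    for all that cell's spots.  Zero spots yield an empty result with the
    ratio flagged undefined, not an error.
    """
    reference = sample_random_intensities(marker, region, params)
    readout = readout_image(marker, params.readout_radius_px)
    nz, ny, nx = marker.shape

    rows = []
    for spot in spots:
        z, y, x = (int(round(c)) for c in spot.position_px)
        z = min(max(z, 0), nz - 1)
        y = min(max(y, 0), ny - 1)
        x = min(max(x, 0), nx - 1)
        rows.append((spot.spot_id, *spot.position_px, readout[z, y, x]))
    if rows:
        records = pd.DataFrame(rows, columns=["spot_id", "z_px", "y_px", "x_px",
                                              "observed_intensity"])
        records["p_value"] = _pvalues(records["observed_intensity"].to_numpy(), reference)
        records["is_coloc"] = records["p_value"] < params.alpha
    else:
        records = pd.DataFrame(columns=["spot_id", "z_px", "y_px", "x_px",
                                        "observed_intensity", "p_value", "is_coloc"])

    n_total = len(records)
    n_coloc = int(records["is_coloc"].sum()) if n_total else 0
    if n_total == 0:
        log.info("cell %d: no spots to classify; ratio undefined", region.cell_id)
        ratio, percentage, defined = float("nan"), float("nan"), False
    elif n_coloc == n_total:
        log.info("cell %d: all %d spots co-localize; ratio undefined", region.cell_id, n_total)
        ratio, percentage, defined = float("nan"), 100.0, False
    else:
        ratio = coloc_ratio(n_coloc, n_total)
        percentage = coloc_percentage(n_coloc, n_total)
        defined = True
    return ColocResult(
        records=records,
        cell_id=region.cell_id,
        n_total=n_total,
        n_coloc=n_coloc,
        ratio=ratio,
        percentage=percentage,
        ratio_defined=defined,
        alpha=params.alpha,
        anchor=params.anchor,
    )


def rotate_channel_180(channel: np.ndarray) -> np.ndarray:
    """Rotate every z-slice 180 degrees in-plane (y and x both reversed,
    z order unchanged).  Applying it twice is the identity."""
    channel = np.asarray(channel)
    return channel[:, ::-1, ::-1].copy()
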