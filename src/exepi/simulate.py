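"""Ground-truthed synthetic z-stacks and dose-response tables.

The generator emulates the statistical structure the co-localization
analysis assumes, not optical realism: an ellipsoidal nucleus with a
textured nuclear stain, diffraction-limited reader spots rendered as 3D
Gaussians, and a marker channel built from a Gaussian random field with a
chosen correlation length — the "strong intensity fluctuations" regime of
nuclear histone-mark stains that defeats voxel-correlation measures.
Planted co-localization is a local marker boost (a Gaussian bump with the
imaging PSF width) centered on a deterministic subset of the reader
emitters, never a copied reader channel: the statistic under test is
intensity-at-location, not channel correlation.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, with fixed substream order
(per cell: emitter placement, dapi texture, marker texture, then one noise
stream per channel), so stacks are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageStack, VoxelGeometry

__all__ = [
    "NucleusSpec",
    "EmitterSpec",
    "MarkerSpec",
    "GroundTruth",
    "DEFAULT_GEOMETRY",
    "DEFAULT_SHAPE_ZYX",
    "generate_cell",
    "generate_field",
    "generate_dose_response",
    "four_param_logistic",
]

#: Default post-expansion acquisition geometry: 60 nm lateral sampling,
#: 200 nm z-step, gel expansion factor 3.5.
DEFAULT_GEOMETRY = VoxelGeometry(dx_um=0.06, dy_um=0.06, dz_um=0.2, expansion_factor=3.5)

#: Default test-scale stack: 96 x 96 px laterally, 11 z-slices (matching the
#: 9-11 slice stacks the analysis is designed for, while staying seconds-fast).
DEFAULT_SHAPE_ZYX = (11, 96, 96)


@dataclass(frozen=True)
class NucleusSpec:
    """Ellipsoidal nucleus with a textured nuclear-stain signal.

    ``semi_axes_um`` are the (z, y, x) ellipsoid semi-axes in um (sample
    scale).  The default nucleus is a miniaturized ellipsoid that fits the
    default test stack; real HeLaP4 nuclei (equivalent radius ~6 um before
    expansion) need correspondingly larger stacks.  ``dapi_texture`` is
    ``(correlation_length_um, contrast)`` of a smooth multiplicative random
    field on the nuclear stain.
    """

    semi_axes_um: tuple[float, float, float] = (0.9, 2.4, 2.4)
    center_px: tuple[float, float, float] | None = None  # None -> stack center
    interior_level: float = 120.0
    dapi_texture: tuple[float, float] = (0.3, 0.25)
    background_level: float = 8.0

    def resolved_center(self, shape_zyx: tuple[int, int, int]) -> tuple[float, float, float]:
        if self.center_px is not None:
            return self.center_px
        return tuple((n - 1) / 2.0 for n in shape_zyx)


@dataclass(frozen=True)
class EmitterSpec:
    """Punctate reader emitters rendered as 3D Gaussians.

    ``psf_sigma_px`` is (sigma_z, sigma_y, sigma_x) in voxel units.
    ``edge_margin_px`` keeps emitters away from the lateral mask boundary so
    that detection windows and intensity-readout neighborhoods stay inside
    the nucleus.  ``amplitude`` is the peak height above local background;
    with the default Gaussian read noise of 4 this gives peak SNR ~10.
    """

    n_spots: int = 200
    amplitude: float = 40.0
    psf_sigma_px: tuple[float, float, float] = (0.9, 1.4, 1.4)
    min_separation_px: float = 3.0
    edge_margin_px: float = 5.0
    reader_background: float = 12.0


@dataclass(frozen=True)
class MarkerSpec:
    """Heterogeneous nuclear marker field with optional planted co-localization.

    ``texture = (correlation_length_um, mean, variance)`` of the Gaussian
    random field inside the nucleus.  ``coloc_fraction`` is the fraction of
    reader emitters that receive a marker boost; the boost is a Gaussian
    bump of peak height ``enrichment * sqrt(variance)`` (i.e. ``enrichment``
    is in units of the texture standard deviation).  ``noise`` is
    ``(poisson_scale, gaussian_sd)`` applied to every channel:
    ``poisson_scale > 0`` applies scaled shot noise, Gaussian read noise is
    added after.
    """

    texture: tuple[float, float, float] = (0.25, 100.0, 1600.0)
    coloc_fraction: float = 0.0
    enrichment: float = 3.0
    noise: tuple[float, float] = (0.0, 4.0)
    marker_background: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.texture[2] < 0 or self.noise[1] < 0:
            raise ValueError("variance and gaussian_sd must be non-negative")


@dataclass
class GroundTruth:
    """Exact generative truth for one synthetic cell."""

    mask: np.ndarray                      # analytic ellipsoid interior (voxel-center test)
    emitter_zyx: np.ndarray               # (n, 3) sub-pixel emitter positions
    is_coloc_planted: np.ndarray          # (n,) bool, which emitters got a marker boost
    seed: int


def _ellipsoid_mask(shape_zyx, center, semi_axes_um, geometry) -> np.ndarray:
    spacing = np.asarray(geometry.spacing_zyx)
    semi = np.asarray(semi_axes_um, dtype=float)
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape_zyx), indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)
    rel = (coords - np.asarray(center)) * spacing / semi
    return (rel ** 2).sum(axis=-1) <= 1.0


def _gaussian_random_field(shape_zyx, corr_len_um, geometry, rng) -> np.ndarray:
    """Zero-mean unit-variance smooth field via Gaussian spectral filtering."""
    sigmas = [max(corr_len_um / s, 1e-6) for s in geometry.spacing_zyx]
    white = rng.standard_normal(shape_zyx)
    fieldv = ndimage.gaussian_filter(white, sigma=sigmas, mode="reflect")
    sd = fieldv.std()
    if sd < 1e-12:
        return np.zeros(shape_zyx)
    return (fieldv - fieldv.mean()) / sd


def _render_gaussians(shape_zyx, positions, amplitudes, sigma_zyx) -> np.ndarray:
    """Sum of 3D Gaussian bumps, each rendered in a +/-4 sigma local window."""
    img = np.zeros(shape_zyx)
    sz, sy, sx = sigma_zyx
    ext = (int(np.ceil(4 * sz)), int(np.ceil(4 * sy)), int(np.ceil(4 * sx)))
    for (z0, y0, x0), amp in zip(positions, amplitudes):
        lo = [max(0, int(np.floor(c)) - e) for c, e in zip((z0, y0, x0), ext)]
        hi = [min(n, int(np.ceil(c)) + e + 1) for c, e, n in zip((z0, y0, x0), ext, shape_zyx)]
        zg = np.arange(lo[0], hi[0])[:, None, None]
        yg = np.arange(lo[1], hi[1])[None, :, None]
        xg = np.arange(lo[2], hi[2])[None, None, :]
        bump = amp * np.exp(
            -((zg - z0) ** 2 / (2 * sz ** 2)
              + (yg - y0) ** 2 / (2 * sy ** 2)
              + (xg - x0) ** 2 / (2 * sx ** 2))
        )
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += bump
    return img


def _place_emitters(mask, spec: EmitterSpec, rng) -> np.ndarray:
    """Uniform emitter positions inside the margin-eroded mask with a
    minimum pairwise separation (voxel metric), by bounded rejection."""
    margin = int(round(spec.edge_margin_px))
    if margin > 0:
        r = np.arange(-margin, margin + 1)
        disc = (r[:, None] ** 2 + r[None, :] ** 2) <= margin ** 2
        valid = np.stack([
            ndimage.binary_erosion(sl, structure=disc) for sl in mask
        ])
    else:
        valid = mask.copy()
    # keep emitters off the first/last slice so the axial profile has support
    valid[0] = False
    valid[-1] = False
    idx = np.argwhere(valid)
    if len(idx) == 0:
        raise ValueError("no valid emitter support: mask too small for edge margin")

    positions: list[np.ndarray] = []
    max_attempts = 200 * spec.n_spots
    attempts = 0
    min_sep2 = spec.min_separation_px ** 2
    while len(positions) < spec.n_spots:
        if attempts >= max_attempts:
            raise ValueError(
                f"infeasible spot packing: placed {len(positions)} of "
                f"{spec.n_spots} emitters at min_separation="
                f"{spec.min_separation_px} px after {max_attempts} attempts"
            )
        attempts += 1
        base = idx[rng.integers(len(idx))]
        pos = base + rng.uniform(-0.5, 0.5, size=3)
        if positions:
            d2 = ((np.asarray(positions) - pos) ** 2).sum(axis=1)
            if d2.min() < min_sep2:
                continue
        positions.append(pos)
    return np.asarray(positions)


def _apply_noise(img, noise, rng) -> np.ndarray:
    poisson_scale, gaussian_sd = noise
    out = img.astype(float)
    if poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0) / poisson_scale) * poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def generate_cell(
    nucleus: NucleusSpec = NucleusSpec(),
    emitters: EmitterSpec = EmitterSpec(),
    marker: MarkerSpec = MarkerSpec(),
    geometry: VoxelGeometry = DEFAULT_GEOMETRY,
    seed: int = 0,
    shape_zyx: tuple[int, int, int] = DEFAULT_SHAPE_ZYX,
) -> tuple[ImageStack, GroundTruth]:
    """Generate one 3-channel cell (dapi, reader, marker) plus ground truth.

    Exactly ``round(coloc_fraction * n_spots)`` emitters receive the marker
    boost; which ones is a seeded permutation, so the planted count is
    deterministic.  Identical seeds give bit-identical stacks.
    """
    stack, truths = generate_field([(nucleus, emitters, marker)], geometry, seed, shape_zyx)
    return stack, truths[0]


def generate_field(
    cells: list[tuple[NucleusSpec, EmitterSpec, MarkerSpec]],
    geometry: VoxelGeometry = DEFAULT_GEOMETRY,
    seed: int = 0,
    shape_zyx: tuple[int, int, int] = DEFAULT_SHAPE_ZYX,
) -> tuple[ImageStack, list[GroundTruth]]:
    """Generate a stack containing one or more cells (shared background/noise)."""
    shape_zyx = tuple(int(n) for n in shape_zyx)
    ss = np.random.SeedSequence(seed)
    noise_ss, *cell_ss = ss.spawn(1 + len(cells))

    dapi = np.zeros(shape_zyx)
    reader = np.zeros(shape_zyx)
    marker_img = np.zeros(shape_zyx)
    truths: list[GroundTruth] = []

    bg_dapi = bg_reader = bg_marker = 0.0
    noise_spec = (0.0, 0.0)

    for (nuc, emi, mar), css in zip(cells, cell_ss):
        place_ss, dapi_ss, marker_ss = css.spawn(3)
        center = nuc.resolved_center(shape_zyx)
        spacing = np.asarray(geometry.spacing_zyx)
        semi_px = np.asarray(nuc.semi_axes_um) / spacing
        for c, s, n in zip(center, semi_px, shape_zyx):
            if c - s < -0.5 or c + s > n - 0.5:
                raise ValueError(
                    f"ellipsoid does not fit inside the stack bounds "
                    f"(center {center}, semi-axes {tuple(semi_px)} px, shape {shape_zyx})"
                )
        mask = _ellipsoid_mask(shape_zyx, center, nuc.semi_axes_um, geometry)

        tex = _gaussian_random_field(shape_zyx, nuc.dapi_texture[0], geometry,
                                     np.random.default_rng(dapi_ss))
        dapi += mask * np.clip(nuc.interior_level * (1.0 + nuc.dapi_texture[1] * tex), 0, None)

        rng_place = np.random.default_rng(place_ss)
        pos = _place_emitters(mask, emi, rng_place)
        reader += _render_gaussians(shape_zyx, pos, np.full(len(pos), emi.amplitude),
                                    emi.psf_sigma_px)

        corr_len, mean, variance = mar.texture
        mtex = _gaussian_random_field(shape_zyx, corr_len, geometry,
                                      np.random.default_rng(marker_ss))
        marker_field = np.clip(mean + np.sqrt(variance) * mtex, 0.0, None)

        n_coloc = int(round(mar.coloc_fraction * emi.n_spots))
        planted = np.zeros(emi.n_spots, dtype=bool)
        order = rng_place.permutation(emi.n_spots)
        planted[order[:n_coloc]] = True
        if n_coloc > 0:
            boost_amp = mar.enrichment * np.sqrt(variance)
            marker_field += _render_gaussians(
                shape_zyx, pos[planted], np.full(n_coloc, boost_amp), emi.psf_sigma_px
            )
        marker_img += mask * marker_field

        bg_dapi = max(bg_dapi, nuc.background_level)
        bg_reader = max(bg_reader, emi.reader_background)
        bg_marker = max(bg_marker, mar.marker_background)
        noise_spec = mar.noise
        truths.append(GroundTruth(mask=mask, emitter_zyx=pos,
                                  is_coloc_planted=planted, seed=seed))

    channels = []
    rng_noise = np.random.default_rng(noise_ss)
    for img, bg in ((dapi, bg_dapi), (reader, bg_reader), (marker_img, bg_marker)):
        channels.append(_apply_noise(img + bg, noise_spec, rng_noise))
    stack = ImageStack(
        data=np.stack(channels),
        channel_names=["dapi", "reader", "marker"],
        geometry=geometry,
    )
    return stack, truths


# ---------------------------------------------------------------------------
# Dose-response simulation

#: Default inhibitor titration design: six doses 0-500 nM, 50 cells per dose,
#: matching a BET-inhibitor (JQ1) titration read out as co-localization ratios.
DEFAULT_DOSES_NM = (0.0, 25.0, 50.0, 125.0, 250.0, 500.0)


def four_param_logistic(c, top, bottom, ic50, hill):
    """4PL inhibition curve R(c) = bottom + (top - bottom) / (1 + (c/ic50)^hill).

    At c = 0 the curve equals ``top`` (for hill > 0); at c = ic50 it equals
    (top + bottom) / 2 exactly.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def generate_dose_response(
    top: float = 15.88,
    bottom: float = 8.0,
    ic50: float = 137.0,
    hill: float = 1.0,
    concentrations=DEFAULT_DOSES_NM,
    n_cells_per_dose: int = 50,
    cell_sd: float = 1.5,
    seed: int = 0,
):
    """Per-cell co-localization ratios drawn around a 4PL inhibition curve.

    Returns a DataFrame with columns ``dose_nM, cell_id, ratio``.  With
    ``cell_sd = 0`` every cell sits exactly on the curve.
    """
    import pandas as pd

    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if hill == 0:
        raise ValueError("hill slope must be non-zero")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be non-negative")
    if cell_sd < 0:
        raise ValueError("cell_sd must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for dose in concentrations:
        mu = float(four_param_logistic(dose, top, bottom, ic50, hill))
        vals = mu + rng.normal(0.0, cell_sd, size=n_cells_per_dose) if cell_sd > 0 \
            else np.full(n_cells_per_dose, mu)
        for i, v in enumerate(vals):
            rows.append({"dose_nM": dose, "cell_id": i, "ratio": float(v)})
    return pd.DataFrame(rows, columns=["dose_nM", "cell_id", "ratio"])
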