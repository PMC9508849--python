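"""The empirical-p-value co-localization statistic and its summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exepi.colocalization import (ColocParams, classify_spots, coloc_percentage,
                                  coloc_ratio, empirical_pvalue, read_intensity,
                                  readout_image, rotate_channel_180,
                                  sample_random_intensities, valid_readout_support)
from exepi.fixtures import spots_from_truth
from exepi.simulate import _render_gaussians


# --- empirical p-value -----------------------------------------------------

def test_empirical_pvalue_add_one_formula():
    ref = np.arange(1.0, 1000.0)  # 999 values
    assert empirical_pvalue(5000.0, ref) == pytest.approx(1 / 1000)
    assert empirical_pvalue(1.0, ref) == 1.0  # equal to the minimum: ties count
    med = float(np.median(ref))
    assert abs(empirical_pvalue(med, ref) - 0.5) <= 1.5 / 1000


def test_empirical_pvalue_rejects_bad_input():
    with pytest.raises(ValueError):
        empirical_pvalue(np.nan, np.ones(10))
    with pytest.raises(ValueError):
        empirical_pvalue(1.0, np.array([]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200), st.floats(-1e6, 1e6))
def test_empirical_pvalue_in_unit_interval_and_monotone(ref, obs):
    ref = np.asarray(ref)
    p = empirical_pvalue(obs, ref)
    assert 0 < p <= 1
    assert empirical_pvalue(obs + 1.0, ref) <= p  # monotone in observed


# --- intensity readout -----------------------------------------------------

def test_read_intensity_radius_zero_and_constant():
    img = np.arange(4 * 5 * 6, dtype=float).reshape(4, 5, 6)
    assert read_intensity(img, (2, 3, 4), 0) == img[2, 3, 4]
    assert read_intensity(img, (1.6, 2.6, 3.4), 0) == img[2, 3, 3]  # nearest voxel
    const = np.full((3, 9, 9), 7.5)
    assert read_intensity(const, (1, 4, 4), 1) == 7.5


def test_read_intensity_disc_mean_matches_enumeration_oracle():
    img = 5.0 + _render_gaussians((5, 21, 21), [(2.0, 10.0, 10.0)], [40.0],
                                  (0.9, 1.8, 1.8))
    radius = 2
    vals = [img[2, 10 + dy, 10 + dx]
            for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dy * dy + dx * dx <= radius * radius]
    assert read_intensity(img, (2, 10, 10), radius) == pytest.approx(np.mean(vals))
    # the precomputed per-voxel readout image agrees at interior voxels
    rimg = readout_image(img, radius)
    assert rimg[2, 10, 10] == pytest.approx(np.mean(vals))


def test_random_reference_sample(dense_null):
    stack, truth, region = dense_null
    marker = stack.channel("marker")
    params = ColocParams(seed=5, n_random=10_000, readout_radius_px=2)
    a = sample_random_intensities(marker, region, params)
    b = sample_random_intensities(marker, region, params)
    assert np.array_equal(a, b)  # same seed, identical sample
    assert len(a) == 10_000
    # Monte-Carlo mean matches full enumeration over the valid support within 2%
    support = valid_readout_support(region.mask, 2)
    enum_mean = readout_image(marker, 2)[support].mean()
    assert abs(a.mean() - enum_mean) / enum_mean < 0.02

    const = np.full(marker.shape, 3.0)
    c = sample_random_intensities(const, region, params)
    assert np.allclose(c, 3.0)


def test_reference_sample_needs_viable_mask(dense_null, geometry):
    from exepi.core import NucleusRegion

    tiny = np.zeros((5, 9, 9), bool)
    tiny[2, 4, 4] = True
    region = NucleusRegion(0, tiny, np.zeros(tiny.shape), (2, 4, 4), 0.1)
    with pytest.raises(ValueError, match="too small"):
        sample_random_intensities(np.ones(tiny.shape), region,
                                  ColocParams(readout_radius_px=3))


# --- ratio and percentage --------------------------------------------------

def test_ratio_and_percentage_worked_values():
    assert coloc_ratio(12, 112) == pytest.approx(12.0)
    assert coloc_ratio(0, 287) == 0.0
    assert round(coloc_ratio(265, 287), 1) == 1204.5
    assert coloc_percentage(265, 287) == pytest.approx(92.33449, abs=1e-4)
    assert round(coloc_percentage(265, 287)) == 92
    assert coloc_percentage(0, 10) == 0.0
    assert coloc_percentage(10, 10) == 100.0
    with pytest.raises(ValueError, match="undefined"):
        coloc_ratio(10, 10)
    with pytest.raises(ValueError):
        coloc_percentage(1, 0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(1, 10_000), st.integers(0, 10_000))
def test_ratio_percentage_identity(n_total, n_coloc):
    n_coloc = min(n_coloc, n_total - 1)  # keep the ratio defined
    r = coloc_ratio(n_coloc, n_total)
    p = coloc_percentage(n_coloc, n_total)
    assert r == pytest.approx(100 * p / (100 - p))


# --- classification --------------------------------------------------------

def test_classify_reports_counts_and_flags(dense_null):
    stack, truth, region = dense_null
    spots = spots_from_truth(truth)
    res = classify_spots(spots, stack.channel("marker"), region, ColocParams(seed=1))
    assert res.n_total == len(spots)
    assert res.n_coloc == int((res.records["p_value"] < 0.05).sum())
    assert (res.records["is_coloc"] == (res.records["p_value"] < res.alpha)).all()
    if res.ratio_defined:
        assert res.ratio == pytest.approx(
            100 * res.n_coloc / (res.n_total - res.n_coloc))


def test_classify_zero_spots_flagged_not_error(dense_null):
    stack, _, region = dense_null
    res = classify_spots([], stack.channel("marker"), region, ColocParams(seed=1))
    assert res.n_total == 0 and not res.ratio_defined
    assert np.isnan(res.ratio)


def test_classify_invariant_under_monotone_marker_transform(dense_null):
    """The statistic is rank-based: strictly monotone intensity transforms
    leave every p-value unchanged (readout radius 0 keeps readouts pointwise)."""
    stack, truth, region = dense_null
    spots = spots_from_truth(truth)[:50]
    marker = stack.channel("marker")
    params = ColocParams(seed=2, readout_radius_px=0)
    base = classify_spots(spots, marker, region, params)
    transformed = classify_spots(spots, 3.0 * np.sqrt(marker) + 5.0, region, params)
    assert np.allclose(base.records["p_value"], transformed.records["p_value"])
    assert (base.records["is_coloc"] == transformed.records["is_coloc"]).all()


def test_flagged_fraction_monotone_in_planted_fraction():
    from exepi.fixtures import sparse_cell
    from exepi.segmentation import segment_nuclei

    fracs = [0.0, 0.5, 1.0]
    flagged = []
    for f in fracs:
        stack, truth = sparse_cell(seed=21, coloc_fraction=f, enrichment=10.0)
        region = segment_nuclei(stack.channel("dapi"), stack.geometry)[0]
        res = classify_spots(spots_from_truth(truth), stack.channel("marker"),
                             region, ColocParams(seed=21))
        flagged.append(res.n_coloc / res.n_total)
    assert flagged == sorted(flagged)
    assert flagged[-1] > 0.95


# --- rotation control ------------------------------------------------------

def test_rotation_is_involution_and_index_map():
    arr = np.random.default_rng(0).uniform(size=(3, 5, 7))
    rot = rotate_channel_180(arr)
    assert np.array_equal(rotate_channel_180(rot), arr)
    for z in range(3):
        assert rot[z, 0, 0] == arr[z, 4, 6]
        assert rot[z, 4, 6] == arr[z, 0, 0]


def test_rotated_marker_returns_to_chance_level(sparse_planted):
    stack, truth, region = sparse_planted
    spots = spots_from_truth(truth)
    params = ColocParams(seed=3)
    forward = classify_spots(spots, stack.channel("marker"), region, params)
    control = classify_spots(spots, rotate_channel_180(stack.channel("marker")),
                             region, params)
    assert forward.n_coloc / forward.n_total > 0.3  # planted signal detected
    assert control.n_coloc / control.n_total < 0.2  # collapses toward alpha
    assert control.n_coloc < forward.n_coloc
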