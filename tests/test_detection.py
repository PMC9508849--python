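"""Spot detection: candidate statistics, sub-pixel fits, preset behaviour."""

import numpy as np
import pytest

from exepi.detection import (POST_EXPANSION, PRE_EXPANSION, DetectionParams,
                             count_spots, detect_candidates, detect_spots,
                             fit_spots)
from exepi.fixtures import dense_cell
from exepi.segmentation import segment_nuclei
from exepi.simulate import EmitterSpec, _render_gaussians, generate_cell

SYNTH = DetectionParams(loc_roi_px=9, chi2_threshold=25.0, fwhm_px=3.3)


def _noiseless_emitter(pos, amp=50.0, sigma=1.4, offset=10.0, shape=(11, 64, 64)):
    img = offset + _render_gaussians(shape, [pos], [amp], (0.9, sigma, sigma))
    return img


def test_params_validation_and_presets():
    with pytest.raises(ValueError):
        DetectionParams(loc_roi_px=2)
    with pytest.raises(ValueError):
        DetectionParams(fwhm_px=0.0)
    assert DetectionParams(loc_roi_px=10).window_px == 11  # odd after rounding
    assert (PRE_EXPANSION.loc_roi_px, PRE_EXPANSION.chi2_threshold,
            PRE_EXPANSION.fwhm_px) == (10, 15.0, 2.0)
    assert (POST_EXPANSION.loc_roi_px, POST_EXPANSION.chi2_threshold,
            POST_EXPANSION.fwhm_px) == (20, 70.0, 10.0)


def test_noiseless_single_emitter_subpixel_fit():
    pos = (5.0, 40.3, 17.7)
    img = _noiseless_emitter(pos, amp=50.0, sigma=1.4, offset=10.0)
    cand = detect_candidates(img, None, SYNTH)
    assert len(cand) == 1
    spots = fit_spots(img, cand, SYNTH)
    assert len(spots) == 1
    s = spots[0]
    for got, want in zip(s.position_px, pos):
        assert abs(got - want) < 0.05
    # fit consistency: amplitude and width recover generative values within 1%
    assert s.amplitude == pytest.approx(50.0, rel=0.01)
    assert s.sigma_px == pytest.approx(1.4, rel=0.01)
    assert s.background == pytest.approx(10.0, rel=0.01)


def test_detection_invariant_to_offset_and_equivariant_to_translation():
    rng = np.random.default_rng(0)
    img = _noiseless_emitter((5.0, 30.0, 30.0)) + rng.normal(0, 2, (11, 64, 64))
    img = np.clip(img, 0, None)
    interior = np.zeros(img.shape, bool)
    interior[:, 8:-8, 8:-8] = True  # keep clear of roll wrap-around artifacts
    base = detect_candidates(img, interior, SYNTH)
    assert len(base) >= 1
    shifted_img = np.roll(img, (3, 5), axis=(1, 2))
    offset_img = img + 100.0
    assert np.array_equal(detect_candidates(offset_img, interior, SYNTH), base)
    shifted = detect_candidates(shifted_img, interior, SYNTH)
    assert np.array_equal(shifted, base + np.array([0, 3, 5]))


def test_close_pair_suppressed_to_one_candidate():
    sep = SYNTH.separation_px - 1
    img = (10.0
           + _render_gaussians((11, 64, 64), [(5.0, 30.0, 30.0)], [50.0], (0.9, 1.4, 1.4))
           + _render_gaussians((11, 64, 64), [(5.0, 30.0, 30.0 + sep)], [50.0],
                               (0.9, 1.4, 1.4)))
    cand = detect_candidates(img, None, SYNTH)
    assert len(cand) == 1


def test_planted_emitters_recall_precision_localization(geometry):
    matched_err2, n_true, n_det, n_matched = [], 0, 0, 0
    for seed in range(5):
        stack, truth = generate_cell(
            emitters=EmitterSpec(n_spots=25, min_separation_px=10.0), seed=seed)
        region = segment_nuclei(stack.channel("dapi"), geometry)[0]
        spots = detect_spots(stack.channel("reader"), region, SYNTH)
        det = np.array([s.position_px for s in spots])
        n_true += len(truth.emitter_zyx)
        n_det += len(det)
        used = set()
        for tz, ty, tx in truth.emitter_zyx:
            if len(det) == 0:
                continue
            d2 = (det[:, 1] - ty) ** 2 + (det[:, 2] - tx) ** 2
            j = int(np.argmin(d2))
            if d2[j] < 4.0 and j not in used:
                used.add(j)
                n_matched += 1
                matched_err2.append(d2[j])
    assert n_matched / n_true >= 0.95          # recall
    assert n_matched / n_det >= 0.98           # precision
    assert np.sqrt(np.mean(matched_err2)) < 0.5  # lateral RMS error (px)


def test_noise_only_nucleus_yields_no_candidates(geometry):
    clean = 0
    for seed in range(20):
        stack, truth = generate_cell(emitters=EmitterSpec(n_spots=0), seed=900 + seed)
        cand = detect_candidates(stack.channel("reader"), truth.mask, SYNTH)
        clean += len(cand) == 0
    assert clean >= 19  # >= 95% of seeds


def test_counts_monotone_in_chi2_threshold():
    stack, _ = dense_cell(seed=4, n_spots=80)
    counts = []
    for chi2 in (5.0, 25.0, 100.0, 400.0, 1600.0):
        p = DetectionParams(loc_roi_px=9, chi2_threshold=chi2, fwhm_px=3.3)
        counts.append(len(detect_candidates(stack.channel("reader"), None, p)))
    assert counts == sorted(counts, reverse=True)


def test_flat_background_candidate_rejected():
    rng = np.random.default_rng(1)
    img = np.clip(rng.normal(20, 2, (11, 32, 32)), 0, None)
    spots = fit_spots(img, np.array([[5, 16, 16]]), SYNTH)
    assert spots == []


def test_border_clipped_window_dropped():
    img = _noiseless_emitter((5.0, 2.0, 2.0))
    spots = fit_spots(img, np.array([[5, 2, 2]]), SYNTH)
    assert spots == []  # window extends past the border


def test_expansion_decrowds_spots():
    """More resolved spots post-expansion than on the same cell imaged at
    1/3.5 sampling with the pre-expansion preset (qualitative de-crowding)."""
    rng = np.random.default_rng(6)
    factor = 3.5
    shape_hi, shape_lo = (7, 140, 140), (7, 40, 40)
    pts = []
    while len(pts) < 30:
        cand = rng.uniform([2, 15, 15], [5, 125, 125])
        if all(np.hypot(cand[1] - p[1], cand[2] - p[2]) > 9 for p in pts):
            pts.append(cand)
    pts = np.asarray(pts)
    hi = 10 + _render_gaussians(shape_hi, pts, np.full(30, 60.0), (0.9, 4.25, 4.25))
    lo_pts = np.c_[pts[:, 0], pts[:, 1] / factor, pts[:, 2] / factor]
    lo = 10 + _render_gaussians(shape_lo, lo_pts, np.full(30, 60.0), (0.9, 1.2, 1.2))
    hi = np.clip(hi + rng.normal(0, 3, shape_hi), 0, None)
    lo = np.clip(lo + rng.normal(0, 3, shape_lo), 0, None)
    n_post = count_spots(fit_spots(hi, detect_candidates(hi, None, POST_EXPANSION),
                                   POST_EXPANSION))
    n_pre = count_spots(fit_spots(lo, detect_candidates(lo, None, PRE_EXPANSION),
                                  PRE_EXPANSION))
    assert n_post > n_pre
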