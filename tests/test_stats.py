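"""Group comparisons, PCC, intensity quantification, and 4PL IC50 fitting."""

import numpy as np
import pytest
from scipy import stats as sps

from exepi.fixtures import sparse_cell, spots_from_truth
from exepi.segmentation import segment_nuclei
from exepi.simulate import (EmitterSpec, MarkerSpec, NucleusSpec,
                            generate_dose_response, generate_field)
from exepi.stats import (fit_dose_response, nuclear_mean_intensity,
                         one_way_anova, pearson_cc, significance_tier)


# --- PCC -------------------------------------------------------------------

def test_pearson_identity_affine_and_symmetry():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 100, (5, 16, 16))
    b = rng.uniform(0, 100, (5, 16, 16))
    mask = np.ones(a.shape, bool)
    assert pearson_cc(a, a, mask) == pytest.approx(1.0)
    assert pearson_cc(a, 3.0 * a + 7.0, mask) == pytest.approx(1.0)
    assert pearson_cc(a, b, mask) == pytest.approx(pearson_cc(b, a, mask))


def test_pearson_zero_variance_flagged_nan():
    mask = np.ones((2, 4, 4), bool)
    a = np.random.default_rng(1).uniform(size=(2, 4, 4))
    assert np.isnan(pearson_cc(a, np.ones_like(a), mask))


def test_pcc_blind_to_spot_level_coloc_in_fluctuating_marker(sparse_planted):
    """Planted spot-level co-localization inside a strongly fluctuating
    marker texture: voxel correlation stays near zero while the
    empirical-p-value statistic flags the planted spots."""
    from exepi.colocalization import ColocParams, classify_spots

    stack, truth, region = sparse_planted
    r = pearson_cc(stack.channel("reader"), stack.channel("marker"), region.mask)
    res = classify_spots(spots_from_truth(truth), stack.channel("marker"),
                         region, ColocParams(seed=9))
    assert abs(r) < 0.2
    assert res.n_coloc / res.n_total > 0.35
    assert res.n_coloc / res.n_total > 3 * abs(r)


# --- nuclear mean intensity ------------------------------------------------

def test_nuclear_mean_intensity_constant_linearity_and_two_cells(geometry):
    nuc_a = NucleusSpec(semi_axes_um=(0.8, 2.0, 2.0), center_px=(5.0, 47.5, 45.0),
                        interior_level=100.0, dapi_texture=(0.3, 0.05))
    nuc_b = NucleusSpec(semi_axes_um=(0.8, 2.0, 2.0), center_px=(5.0, 47.5, 145.0),
                        interior_level=150.0, dapi_texture=(0.3, 0.05))
    emi = EmitterSpec(n_spots=5)
    stack, truths = generate_field(
        [(nuc_a, emi, MarkerSpec()), (nuc_b, emi, MarkerSpec())],
        seed=0, shape_zyx=(11, 96, 192),
    )
    regions = segment_nuclei(stack.channel("dapi"), geometry)
    assert len(regions) == 2
    means = [nuclear_mean_intensity(stack.channel("dapi"), r) for r in regions]
    assert means[0] == pytest.approx(100.0 + 8.0, rel=0.10)  # interior + background
    assert means[1] == pytest.approx(150.0 + 8.0, rel=0.10)
    # linearity in the channel
    scaled = nuclear_mean_intensity(0.3 * stack.channel("dapi"), regions[0])
    assert scaled == pytest.approx(0.3 * means[0])

    const = np.full(stack.shape_zyx, 4.2)
    assert nuclear_mean_intensity(const, regions[0]) == pytest.approx(4.2)


# --- one-way ANOVA ---------------------------------------------------------

def test_anova_degenerate_identical_groups():
    res = one_way_anova({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0], "c": [5.0] * 4})
    assert res.f_statistic == 0.0 and res.p_value == 1.0
    assert (res.pairwise["tier"] == "ns").all()


def test_anova_power_and_tiers():
    rng = np.random.default_rng(0)
    for _ in range(5):
        res = one_way_anova({
            "ctrl": rng.normal(0, 1, 50),
            "treated": rng.normal(2, 1, 50),
        })
        assert res.p_value < 0.001
        assert res.pairwise["tier"].iloc[0] == "***"
    assert significance_tier(0.03) == "*" and significance_tier(0.5) == "ns"


def test_anova_matches_scipy_and_null_type_I():
    rng = np.random.default_rng(1)
    groups = {k: rng.normal(0, 1, 30) for k in "abc"}
    res = one_way_anova(groups)
    f, p = sps.f_oneway(*groups.values())
    assert res.f_statistic == pytest.approx(f)
    assert res.p_value == pytest.approx(p)

    # type-I error calibration and p-uniformity under the null
    pvals = []
    for _ in range(400):
        pvals.append(one_way_anova({
            "a": rng.normal(0, 1, 12), "b": rng.normal(0, 1, 12),
            "c": rng.normal(0, 1, 12)}).p_value)
    pvals = np.asarray(pvals)
    rate = (pvals < 0.05).mean()
    assert abs(rate - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / 400) + 0.01
    assert sps.kstest(pvals, "uniform").statistic < 0.05 + 1.36 / np.sqrt(400)


def test_anova_input_validation():
    with pytest.raises(ValueError):
        one_way_anova({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        one_way_anova({"a": [1.0, 2.0], "b": [3.0]})


# --- dose-response fitting -------------------------------------------------

def test_4pl_noiseless_self_consistency():
    df = generate_dose_response(top=15.88, bottom=8.0, ic50=137.0, hill=1.0,
                                cell_sd=0.0, seed=0)
    for fix_hill in (None, 1.0):
        fit = fit_dose_response(df["dose_nM"], df["ratio"], fix_hill=fix_hill)
        assert abs(fit.ic50 - 137.0) / 137.0 < 1e-6
        assert fit.top == pytest.approx(15.88, abs=1e-6)
        assert fit.bottom == pytest.approx(8.0, abs=1e-5)
        assert fit.identifiable and fit.converged
        # 4PL midpoint identity of the fitted curve
        assert fit.predict(fit.ic50) == pytest.approx((fit.top + fit.bottom) / 2)


def test_4pl_scale_equivariance():
    df = generate_dose_response(cell_sd=0.0, seed=0)
    base = fit_dose_response(df["dose_nM"], df["ratio"])
    scaled = fit_dose_response(df["dose_nM"], 3.0 * df["ratio"])
    assert scaled.top == pytest.approx(3 * base.top, rel=1e-6)
    assert scaled.bottom == pytest.approx(3 * base.bottom, rel=1e-5)
    assert scaled.ic50 == pytest.approx(base.ic50, rel=1e-5)
    assert scaled.hill == pytest.approx(base.hill, rel=1e-4)


def test_4pl_flat_response_flagged_unidentifiable():
    df = generate_dose_response(top=10.0, bottom=10.0, cell_sd=0.2, seed=1)
    fit = fit_dose_response(df["dose_nM"], df["ratio"])
    assert not fit.identifiable


def test_4pl_requires_enough_doses():
    with pytest.raises(ValueError, match="4 distinct positive doses"):
        fit_dose_response([0, 10, 20, 10, 20, 0], [1, 2, 3, 4, 5, 6])


def test_4pl_cells_mode_agrees_with_means_mode():
    df = generate_dose_response(cell_sd=1.0, seed=4)
    means = fit_dose_response(df["dose_nM"], df["ratio"], mode="means")
    cells = fit_dose_response(df["dose_nM"], df["ratio"], mode="cells")
    # equal per-dose n makes the two estimators near-identical
    assert cells.ic50 == pytest.approx(means.ic50, rel=0.02)


def test_4pl_recovery_spread_at_high_cell_noise():
    """At per-cell sd 1.5 (n = 50/dose) the lower plateau is unreached by the
    dose range and the Cramer-Rao bound puts sigma_log(IC50) near 0.18; the
    estimator should be consistent with that spread, not much worse."""
    errs = []
    for seed in range(15):
        df = generate_dose_response(cell_sd=1.5, n_cells_per_dose=50, seed=seed)
        fit = fit_dose_response(df["dose_nM"], df["ratio"], fix_hill=1.0)
        errs.append(np.log(fit.ic50 / 137.0))
    assert abs(np.median(errs)) < 0.15          # near-unbiased
    assert np.std(errs) < 0.4                   # CRLB-consistent order
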