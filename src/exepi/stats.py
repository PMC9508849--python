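"""Condition-level statistics: group comparison, PCC, intensity
quantification, and dose-response (IC50) fitting.

The dose-response model is the four-parameter logistic

    R(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill),

fitted by least squares on per-dose means weighted by their standard
errors (or on per-cell values).  Zero-dose observations are used directly
— at c = 0 the model equals ``top`` — rather than being placed on a log
axis; they initialize and constrain the upper plateau.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares
from statsmodels.stats.multitest import multipletests

from .core import NucleusRegion
from .simulate import four_param_logistic

log = logging.getLogger(__name__)

__all__ = [
    "pearson_cc",
    "nuclear_mean_intensity",
    "one_way_anova",
    "GroupComparison",
    "fit_dose_response",
    "DoseResponseFit",
    "significance_tier",
]


def pearson_cc(ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two channels over mask voxels only.

    Returns NaN (logged) when either channel has zero variance inside the
    mask — the coefficient is undefined there.
    """
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(ch1, dtype=float)[mask]
    b = np.asarray(ch2, dtype=float)[mask]
    if a.size < 2:
        raise ValueError("mask must select at least 2 voxels")
    if a.std() == 0 or b.std() == 0:
        log.warning("pearson_cc undefined: zero variance inside mask")
        return float("nan")
    return float(sps.pearsonr(a, b).statistic)


def nuclear_mean_intensity(channel: np.ndarray, region: NucleusRegion) -> float:
    """Mean channel intensity over the nucleus mask."""
    mask = region.mask
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    return float(np.asarray(channel, dtype=float)[mask].mean())


def significance_tier(p: float) -> str:
    """Asterisk tier used in figure captions: ns / * / ** / ***."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """One-way ANOVA result with Holm-adjusted pairwise comparisons."""

    groups: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_raw, p_holm, tier


def one_way_anova(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Standard one-way ANOVA across condition groups of per-cell values.

    Pairwise two-sample t-tests are Holm-adjusted.  Degenerate input where
    every group is the same constant yields F = 0, p = 1 exactly.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")

    values = np.concatenate(list(arrays.values()))
    labels = list(arrays)
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b = len(arrays) - 1
    df_w = values.size - len(arrays)
    if ss_between == 0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))

    pairs = list(itertools.combinations(labels, 2))
    raw = []
    for a, b in pairs:
        if arrays[a].std() == 0 and arrays[b].std() == 0:
            raw.append(1.0 if arrays[a].mean() == arrays[b].mean() else 0.0)
        else:
            raw.append(float(sps.ttest_ind(arrays[a], arrays[b]).pvalue))
    if pairs:
        adj = multipletests(raw, method="holm")[1]
    else:
        adj = np.array([])
    pairwise = pd.DataFrame({
        "group_a": [a for a, _ in pairs],
        "group_b": [b for _, b in pairs],
        "p_raw": raw,
        "p_holm": adj,
    })
    pairwise["tier"] = [significance_tier(p_) for p_ in pairwise["p_holm"]]

    return GroupComparison(
        groups=labels,
        n={k: int(v.size) for k, v in arrays.items()},
        mean={k: float(v.mean()) for k, v in arrays.items()},
        sd={k: float(v.std(ddof=1)) for k, v in arrays.items()},
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise=pairwise,
    )


@dataclass
class DoseResponseFit:
    """Fitted 4PL inhibition curve.

    ``identifiable`` is False when the response is flat (top == bottom
    within noise) so the IC50 carries no information; ``converged`` is the
    optimizer's success flag.  Standard errors come from the Gauss-Newton
    covariance approximation and are NaN when not estimable.
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    se: dict[str, float]
    converged: bool
    identifiable: bool
    mode: str
    n_doses: int

    def predict(self, c) -> np.ndarray:
        return four_param_logistic(c, self.top, self.bottom, self.ic50, self.hill)


def fit_dose_response(
    concentrations,
    ratios,
    mode: str = "means",
    fix_hill: float | None = None,
) -> DoseResponseFit:
    """Fit the 4PL inhibition curve to per-cell co-localization ratios.

    Parameters
    ----------
    concentrations : sequence of float
        Dose (nM) per observation.
    ratios : sequence of float
        Per-cell ratio per observation (same length).
    mode : {"means", "cells"}
        "means": fit per-dose means weighted by their standard errors
        (unweighted if any dose has no estimable SE).  "cells": fit all
        per-cell values directly.
    fix_hill : float, optional
        Fix the Hill slope (e.g. 1.0) instead of fitting it.

    Requires >= 4 distinct positive doses (an optional 0-dose arm
    constrains the upper plateau).  Non-convergence and unidentifiable
    (flat) responses are returned flagged, never silently.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and ratios must have equal length")
    doses = np.unique(c)
    if (doses > 0).sum() < 4:
        raise ValueError("need at least 4 distinct positive doses")

    means = np.array([r[c == d].mean() for d in doses])
    sems = np.array([
        r[c == d].std(ddof=1) / np.sqrt((c == d).sum()) if (c == d).sum() > 1 else 0.0
        for d in doses
    ])

    if mode == "means":
        x_fit, y_fit = doses, means
        w = 1.0 / sems if np.all(sems > 0) else np.ones_like(means)
    elif mode == "cells":
        x_fit, y_fit = c, r
        w = np.ones_like(r)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    top0 = means[doses == 0][0] if (doses == 0).any() else means[np.argmin(doses)]
    bottom0 = means[np.argmax(doses)]
    pos = doses[doses > 0]
    ic50_0 = float(np.exp(np.mean(np.log(pos))))

    def unpack(theta):
        if fix_hill is None:
            top, bottom, log_ic50, hill = theta
        else:
            top, bottom, log_ic50 = theta
            hill = fix_hill
        return top, bottom, np.exp(log_ic50), hill

    def resid(theta):
        top, bottom, ic50, hill = unpack(theta)
        return w * (four_param_logistic(x_fit, top, bottom, ic50, hill) - y_fit)

    theta0 = [top0, bottom0, np.log(ic50_0)] + ([] if fix_hill is not None else [1.0])
    res = least_squares(resid, theta0, method="lm", max_nfev=5000)
    top, bottom, ic50, hill = unpack(res.x)

    # covariance from the Jacobian; guard rank deficiency
    se = {k: float("nan") for k in ("top", "bottom", "ic50", "hill")}
    dof = max(len(y_fit) - len(res.x), 1)
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * 2 * res.cost / dof
        diag = np.sqrt(np.clip(np.diag(cov), 0, None))
        names = ["top", "bottom", "log_ic50"] + ([] if fix_hill is not None else ["hill"])
        for name, s in zip(names, diag):
            if name == "log_ic50":
                se["ic50"] = float(s * ic50)  # delta method
            else:
                se[name] = float(s)
    except np.linalg.LinAlgError:
        pass

    span = abs(top - bottom)
    scale = max(abs(top), abs(bottom), 1e-12)
    identifiable = bool(span > 1e-6 * scale and np.isfinite(ic50))
    if mode == "means" and np.any(sems > 0):
        # flat relative to the measurement noise is also unidentifiable
        identifiable = identifiable and span > 2.0 * float(np.median(sems[sems > 0]))
    # an IC50 far outside the dose range, or with relative SE > 1, carries
    # no information
    identifiable = identifiable and ic50 <= 10.0 * float(pos.max())
    if np.isfinite(se["ic50"]) and se["ic50"] > ic50:
        identifiable = False
    if not identifiable:
        log.warning("dose-response fit unidentifiable: top~=bottom (flat response)")
    if not res.success:
        log.warning("dose-response fit did not converge: %s", res.message)

    return DoseResponseFit(
        top=float(top), bottom=float(bottom), ic50=float(ic50), hill=float(hill),
        se=se, converged=bool(res.success), identifiable=bool(identifiable),
        mode=mode, n_doses=len(doses),
    )
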