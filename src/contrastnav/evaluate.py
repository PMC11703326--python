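"""ROI-variability analysis: does the artifact level grow with motion?

With a radial readout, rigid motion manifests mostly as noise-like
artifacts, so the standard deviation of a quantitative parameter within an
anatomically homogeneous ROI is a usable artifact proxy.  Regressing that
SD against each subject's mean pair-wise motion score gives a slope per
(parameter, ROI); slopes are made comparable across parameters by
normalizing with the regression intercept (the zero-motion SD), and two
correction methods are compared with a paired t-test on the pooled
normalized slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["roi_std", "motion_regression", "paired_slope_test"]


def roi_std(param_map: np.ndarray, mask: np.ndarray, names: dict[int, str] | None = None) -> pd.DataFrame:
    """Sample standard deviation (ddof=1) of a parameter map per ROI label.

    ``mask`` is an integer label volume aligned with ``param_map``; label 0
    is background and skipped.
    """
    param_map = np.asarray(param_map)
    mask = np.asarray(mask, dtype=int)
    if param_map.shape != mask.shape:
        raise ValueError("parameter map and ROI mask must share the same grid")
    rows = []
    for lab in np.unique(mask):
        if lab == 0:
            continue
        vals = param_map[mask == lab]
        if vals.size == 0:
            raise ValueError(f"ROI {lab} is empty")
        rows.append(
            {
                "roi": names.get(int(lab), str(lab)) if names else str(lab),
                "n_voxels": int(vals.size),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def motion_regression(sd_table: pd.DataFrame, score_col: str = "score", sd_col: str = "sd") -> pd.DataFrame:
    """Per-(parameter, ROI) OLS of artifact SD on motion score.

    ``sd_table`` holds one row per subject per (parameter, ROI) with columns
    ``parameter``, ``roi``, ``sd`` and ``score``.  Returns slope, intercept,
    the two-sided p-value of the slope t-test, and the intercept-normalized
    slope, for each (parameter, ROI) pair.  Requires at least 3 subjects
    and non-degenerate scores.
    """
    results = []
    for (param, roi), grp in sd_table.groupby(["parameter", "roi"]):
        x = grp[score_col].to_numpy(dtype=float)
        y = grp[sd_col].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"need >= 3 subjects for regression, got {x.size} for {param}/{roi}")
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate design: all motion scores equal for {param}/{roi}")
        fit = scipy.stats.linregress(x, y)
        norm_slope = fit.slope / fit.intercept if fit.intercept != 0 else np.nan
        results.append(
            {
                "parameter": param,
                "roi": roi,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "p_value": fit.pvalue,
                "normalized_slope": norm_slope,
            }
        )
    return pd.DataFrame(results)


def paired_slope_test(slopes_a: np.ndarray, slopes_b: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t-test on pooled normalized slopes of two methods.

    Returns ``(t, p)``.  Degenerate input (identical pairs, zero variance of
    the differences) yields ``(0.0, nan)`` with a warning rather than a
    spurious significance.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            warnings.warn("identical samples: zero-variance differences, p undefined")
            return 0.0, float("nan")
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)
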