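"""Per-ROI intensity statistics and between-condition comparisons.

Covers background-subtracted mean intensity, the clustering index (the
population SD of pixel intensities within a punctum, a proxy for how tightly
vesicles cluster), before/after FM differences, percent differences, linear
channel-vs-channel regression, Cohen's d, two-sample Kolmogorov-Smirnov
comparison of pooled distributions, and geometric Sholl intersection counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, UndefinedValueError, ValidationError
from .segmentation import BackgroundModel, RoiSet
from .types import ImageStack

logger = logging.getLogger("synaptoflux")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of paired intensities plus their Pearson correlation."""

    slope: float
    intercept: float
    pearson_r: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValidationError("|pearson_r| must be <= 1")


def measure_rois(
    image: ImageStack | np.ndarray,
    rois: RoiSet,
    background: BackgroundModel,
) -> pd.DataFrame:
    """Background-subtracted mean intensity and clustering index per ROI.

    The mean over each ROI's pixels has the pooled background mean subtracted
    (negative values are kept -- clamping would bias group comparisons).  The
    clustering index is the population SD of the raw pixel values; background
    subtraction shifts the mean only, so the SD is subtraction-invariant.
    """
    img = image.data[0] if isinstance(image, ImageStack) else np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img[0]
    if rois.labels.shape != img.shape:
        raise ValidationError("RoiSet labels do not match image shape")
    rows = []
    for roi_id in rois.ids:
        pix = img[rois.labels == roi_id]
        if pix.size == 0:
            warnings.warn(f"ROI {roi_id} is empty; skipped", stacklevel=2)
            continue
        area = rois.table.loc[rois.table["id"] == roi_id, "area_um2"].iloc[0]
        rows.append(
            {
                "roi": int(roi_id),
                "mean_intensity": float(pix.mean() - background.mean),
                "clustering_index": float(pix.std()),  # population SD
                "area_um2": float(area),
                "n_pixels": int(pix.size),
            }
        )
    return pd.DataFrame(rows, columns=["roi", "mean_intensity", "clustering_index", "area_um2", "n_pixels"])


def delta_fm(before_mean: float, after_mean: float) -> float:
    """FM fluorescence lost to exhaustive stimulation: before - after."""
    if not (np.isfinite(before_mean) and np.isfinite(after_mean)):
        raise ValidationError("delta_fm requires finite inputs")
    return float(before_mean - after_mean)


def percent_difference(test: float, reference: float) -> float:
    """Percent change of ``test`` relative to ``reference``.

    100 * (test - reference) / reference; summaries round to the nearest
    integer percent (e.g. 29.2 vs 23.2 -> 25.9 -> "~26%").
    """
    if reference == 0:
        raise UndefinedValueError("percent_difference undefined for reference 0")
    return float(100.0 * (test - reference) / reference)


def fit_linear(pairs: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares on an (x, y) table, with Pearson r."""
    x = np.asarray(pairs["x"], dtype=np.float64)
    y = np.asarray(pairs["y"], dtype=np.float64)
    if x.size < 3:
        raise ValidationError("fit_linear needs at least 3 pairs")
    if np.ptp(x) == 0:
        raise FitError("x is constant; the fit is degenerate")
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue), x.size)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d: mean difference over the pooled (n-1 weighted) SD."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValidationError("cohens_d needs >= 2 values per sample")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0
        raise UndefinedValueError("zero pooled SD with unequal means")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def ks_compare(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("ks_compare needs non-empty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def sholl_counts(
    neurites: list[np.ndarray],
    soma_center: tuple[float, float],
    radius_step: float,
    max_radius: float,
) -> pd.DataFrame:
    """Neurite intersections with concentric circles around the soma.

    ``neurites`` are polylines as (N, 2) arrays in um.  For each radius the
    count is the number of polyline segments whose distance-to-center changes
    sign across the circle; a vertex lying exactly on a circle (tangency)
    counts once.  Returns a table (radius_um, intersections).
    """
    cx, cy = soma_center
    radii = np.arange(radius_step, max_radius + 1e-9, radius_step)
    counts = np.zeros(radii.size, dtype=int)
    for poly in neurites:
        pts = np.asarray(poly, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValidationError("each neurite must be an (N>=2, 2) polyline")
        d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        for j, r in enumerate(radii):
            s = d - r
            on_circle = np.isclose(s, 0.0, atol=1e-12)
            # strict sign changes between consecutive non-tangent vertices
            crossings = int(np.sum(s[:-1] * s[1:] < 0))
            # each tangent vertex counts exactly once
            crossings += int(np.sum(on_circle))
            counts[j] += crossings
    return pd.DataFrame({"radius_um": radii, "intersections": counts})


def summarize_conditions(
    measurements: pd.DataFrame,
    condition_col: str = "condition",
    value_col: str = "mean_intensity",
) -> pd.DataFrame:
    """Group mean, SD, S.E.M. and n per condition for a measurement table."""
    g = measurements.groupby(condition_col)[value_col]
    out = g.agg(["mean", "std", "count"]).rename(columns={"count": "n"})
    out["sem"] = out["std"] / np.sqrt(out["n"])
    return out.reset_index()
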