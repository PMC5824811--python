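"""Spectral correction and enzymatic-assay quantification.

Graphene in suspension attenuates fluorescence broadband; the Beer-Lambert
transmittance T = 10^(-epsilon * c * l) (epsilon = 2460 L/g/m at 660 nm,
c in g/L, l in m) drives both the correction of measured emission spectra,
F' = F + (1 - T) * F = F * (2 - T), and the synthetic attenuation in the
generator.  Spectra are smoothed with a nine-point Savitzky-Golay filter.
Cholesterol assays are quantified against an ordinary least-squares standard
curve fitted on a 0-20 uM serial dilution.

Note on the correction formula: the additive form F * (2 - T) is applied
verbatim as reported; it is a first-order approximation of the division-based
correction F / T (they agree to O((1-T)^2) for weakly absorbing samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .errors import FitError, UndefinedValueError, ValidationError

logger = logging.getLogger("synaptoflux")

#: Graphene absorption coefficient at 660 nm, L/g/m.
EPSILON_GRAPHENE = 2460.0

#: Default cuvette path length, m (standard 1 cm cuvette).
DEFAULT_PATH_M = 0.01


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: fluorescence = slope * conc + intercept."""

    slope: float  # a.u. / uM
    intercept: float  # a.u.
    r_squared: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards < 3:
            raise ValidationError("standard curve needs >= 3 standards")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError("r_squared must be in [0, 1]")


def transmittance(
    conc: float | np.ndarray,
    epsilon: float = EPSILON_GRAPHENE,
    path: float = DEFAULT_PATH_M,
) -> float | np.ndarray:
    """Beer-Lambert transmittance, base 10: T = 10^(-epsilon * c * l).

    ``conc`` is in mg/L (converted internally to g/L), ``path`` in m.
    T is in (0, 1]; strictly decreasing in concentration and path.
    """
    c = np.asarray(conc, dtype=np.float64)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    if path <= 0 or epsilon <= 0:
        raise ValidationError("path and epsilon must be > 0")
    t = 10.0 ** (-epsilon * (c / 1000.0) * path)
    return float(t) if np.isscalar(conc) else t


def absorbance_correct(
    spectrum: pd.DataFrame, t_per_wavelength: float | np.ndarray
) -> pd.DataFrame:
    """Correct a measured spectrum for broadband absorbance: F' = F * (2 - T)."""
    t = np.asarray(t_per_wavelength, dtype=np.float64)
    if np.any(t <= 0) or np.any(t > 1):
        raise ValidationError("transmittance must lie in (0, 1]")
    out = spectrum.copy()
    out["intensity"] = spectrum["intensity"].to_numpy() * (2.0 - t)
    return out


def savgol_smooth(spectrum: pd.DataFrame, window: int = 9, order: int = 2) -> pd.DataFrame:
    """Savitzky-Golay smoothing (default nine points, quadratic)."""
    y = spectrum["intensity"].to_numpy(dtype=np.float64)
    if y.size < window:
        raise ValidationError(f"spectrum length {y.size} < window {window}")
    if order >= window:
        raise ValidationError("polynomial order must be < window")
    out = spectrum.copy()
    out["intensity"] = savgol_filter(y, window, order)
    return out


def normalize_two_condition(
    reference: pd.DataFrame, attenuated: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Per-wavelength linear map: reference -> 1, attenuated -> 0.

    Both spectra must share a wavelength grid.  Wavelengths with zero dynamic
    range are flagged (returned boolean mask) and set to NaN.
    """
    w_ref = reference["wavelength_nm"].to_numpy()
    w_att = attenuated["wavelength_nm"].to_numpy()
    if w_ref.shape != w_att.shape or not np.allclose(w_ref, w_att):
        raise ValidationError("spectra must share a common wavelength grid")
    hi = reference["intensity"].to_numpy(dtype=np.float64)
    lo = attenuated["intensity"].to_numpy(dtype=np.float64)
    span = hi - lo
    flagged = span == 0
    if flagged.any():
        logger.warning("%d wavelengths have zero dynamic range; excluded", flagged.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ref_norm = np.where(flagged, np.nan, (hi - lo) / span)
        att_norm = np.where(flagged, np.nan, (lo - lo) / span)
    out_ref = reference.copy()
    out_ref["intensity"] = ref_norm
    out_att = attenuated.copy()
    out_att["intensity"] = att_norm
    return out_ref, out_att, flagged


def normalize_spectrum(spectrum: pd.DataFrame, reference: pd.DataFrame,
                       attenuated: pd.DataFrame) -> pd.DataFrame:
    """Map an arbitrary spectrum through the two-condition normalization."""
    hi = reference["intensity"].to_numpy(dtype=np.float64)
    lo = attenuated["intensity"].to_numpy(dtype=np.float64)
    span = hi - lo
    y = spectrum["intensity"].to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(span == 0, np.nan, (y - lo) / span)
    out = spectrum.copy()
    out["intensity"] = norm
    return out


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """OLS line through (conc_uM, fluorescence) standards."""
    conc = standards["conc_uM"].to_numpy(dtype=np.float64)
    fluo = standards["fluorescence"].to_numpy(dtype=np.float64)
    if np.unique(conc).size < 3:
        raise FitError("standard curve needs >= 3 distinct concentrations")
    if np.ptp(conc) == 0:
        raise FitError("constant concentration; degenerate standard curve")
    res = linregress(conc, fluo)
    # constant readings leave Pearson r undefined; report zero explained variance
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    curve = StandardCurve(
        float(res.slope), float(res.intercept), r2, int(np.unique(conc).size)
    )
    logger.info(
        "standard curve: slope=%.3f a.u./uM, intercept=%.2f, r2=%.4f",
        curve.slope, curve.intercept, curve.r_squared,
    )
    return curve


def conc_from_fluorescence(reading: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Invert the standard curve: conc = (reading - intercept) / slope."""
    if curve.slope == 0:
        raise UndefinedValueError("zero-slope standard curve cannot be inverted")
    out = (np.asarray(reading, dtype=np.float64) - curve.intercept) / curve.slope
    return float(out) if np.isscalar(reading) else out
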