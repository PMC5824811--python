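"""Generalized-polarization (GP) membrane-order imaging.

GP is the ratiometric statistic (I_blue - G*I_green)/(I_blue + G*I_green)
of an environment-sensitive membrane dye's two emission channels; higher GP
indicates a more ordered, cholesterol-rich membrane.  G is the instrument
sensitivity correction between channels, calibrated on a reference solvent
of known GP (dye in DMSO, GP_ref = 0.006):

    G = (I_blue * (1 - GP_ref)) / (I_green * (1 + GP_ref))

which makes the calibration an exact round trip: feeding the calibration
pair back through the GP formula with that G returns GP_ref.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ValidationError
from .puncta_stats import ks_compare
from .types import ImageStack

logger = logging.getLogger("synaptoflux")

#: GP of C-laurdan in DMSO, the conventional calibration reference.
GP_REFERENCE_DMSO = 0.006

#: Default histogram bin width for pooled GP distributions over [-1, 1].
GP_HIST_BIN_WIDTH = 0.02


@dataclass(frozen=True)
class GPCalibration:
    """Instrument calibration: reference GP and the derived G factor."""

    g_factor: float
    gp_reference: float = GP_REFERENCE_DMSO

    def __post_init__(self) -> None:
        if self.g_factor <= 0:
            raise ValidationError("g_factor must be > 0")
        if not -1.0 < self.gp_reference < 1.0:
            raise ValidationError("gp_reference must be in (-1, 1)")


@dataclass
class GPResult:
    """Per-pixel GP map with validity mask and the pooled distribution."""

    gp_map: np.ndarray  # NaN where invalid
    valid_mask: np.ndarray
    values: np.ndarray = field(repr=False)  # pooled valid pixels, 1-D

    @property
    def mean(self) -> float:
        """Mean of pooled valid pixels; NaN when the pool is empty."""
        return float(self.values.mean()) if self.values.size else float("nan")

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0

    def histogram(self, bin_width: float = GP_HIST_BIN_WIDTH) -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin_edges) over [-1, 1]."""
        edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
        counts, _ = np.histogram(self.values, bins=edges)
        return counts, edges


def g_factor(i_blue_ref: float, i_green_ref: float, gp_reference: float = GP_REFERENCE_DMSO) -> float:
    """Sensitivity correction factor from a reference-solvent channel pair."""
    if i_green_ref <= 0:
        raise CalibrationError("reference green-channel intensity must be > 0")
    if not -1.0 < gp_reference < 1.0:
        raise CalibrationError("gp_reference must be in (-1, 1)")
    return float(i_blue_ref * (1.0 - gp_reference) / (i_green_ref * (1.0 + gp_reference)))


def gp_value(i_blue: float, i_green: float, g: float) -> float:
    """GP of one channel pair; NaN when the denominator is non-positive."""
    denom = i_blue + g * i_green
    if denom <= 0:
        return float("nan")
    return float((i_blue - g * i_green) / denom)


def gp_map(
    blue: ImageStack | np.ndarray,
    green: ImageStack | np.ndarray,
    cal: GPCalibration,
    mask: np.ndarray | None = None,
) -> GPResult:
    """Per-pixel GP over masked pixels; invalid pixels become NaN, not errors.

    Channels must be co-registered (same shape).  The pooled distribution
    keeps every valid masked pixel, matching the convention of pooling all
    pixels per treatment condition for test statistics.
    """
    b = blue.data[0] if isinstance(blue, ImageStack) else np.asarray(blue, dtype=np.float64)
    g_img = green.data[0] if isinstance(green, ImageStack) else np.asarray(green, dtype=np.float64)
    if b.ndim == 3:
        b = b[0]
    if g_img.ndim == 3:
        g_img = g_img[0]
    if b.shape != g_img.shape:
        raise ValidationError(f"channel shapes differ: {b.shape} vs {g_img.shape}")
    if mask is None:
        mask = np.ones(b.shape, dtype=bool)
    elif mask.shape != b.shape:
        raise ValidationError("mask shape does not match channels")

    denom = b + cal.g_factor * g_img
    with np.errstate(divide="ignore", invalid="ignore"):
        gp = (b - cal.g_factor * g_img) / denom
    valid = mask & (denom > 0) & np.isfinite(gp)
    gp = np.where(valid, gp, np.nan)
    values = gp[valid]
    if values.size == 0:
        logger.warning("gp_map: no valid pixels; summary undefined")
    return GPResult(gp_map=gp, valid_mask=valid, values=values)


def gp_shift(result_a: GPResult, result_b: GPResult) -> tuple[float, float, float]:
    """Between-condition shift of pooled GP distributions.

    Returns (mean(a) - mean(b), KS D, KS p) on the pooled pixels.
    """
    if result_a.is_empty or result_b.is_empty:
        raise ValidationError("gp_shift requires non-empty GP distributions")
    shift = result_a.mean - result_b.mean
    d, p = ks_compare(result_a.values, result_b.values)
    return float(shift), d, p


def pool_results(results: list[GPResult]) -> GPResult:
    """Pool valid pixels of several FOVs into one distribution."""
    values = np.concatenate([r.values for r in results]) if results else np.empty(0)
    # map/mask of the pooled object are not spatial; keep a 1-D stand-in
    return GPResult(gp_map=values.copy(), valid_mask=np.ones(values.size, dtype=bool), values=values)
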