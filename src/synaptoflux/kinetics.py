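"""Time-course analytics for destaining and Ca2+ imaging.

FM-dye traces are normalized to the mean of their first 10 frames; the
destaining extent is 1 minus the mean normalized intensity over a five-frame
window at the end of stimulation; the destaining rate comes from a
single-exponential-with-plateau fit.  Paired Ca2+ responses (two consecutive
agonist applications) are summarized as the ratio of their dF/F peaks.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, UndefinedValueError, ValidationError

logger = logging.getLogger("synaptoflux")


def normalize_first_n(trace: np.ndarray, n: int = 10) -> np.ndarray:
    """Divide a trace by the mean of its first n frames."""
    x = np.asarray(trace, dtype=np.float64)
    if x.size <= n:
        raise ValidationError(f"trace length {x.size} must exceed n={n}")
    baseline = x[:n].mean()
    if baseline <= 0:
        raise ValidationError(f"non-positive baseline mean {baseline:.3g}; cannot normalize")
    return x / baseline


def destain_extent(normalized: np.ndarray, end_window: int = 5) -> float:
    """Fractional dye loss: 1 - mean of the last ``end_window`` frames."""
    x = np.asarray(normalized, dtype=np.float64)
    if x.size < end_window:
        raise ValidationError("trace shorter than the end window")
    return float(1.0 - x[-end_window:].mean())


def _decay_model(t: np.ndarray, rate: float, plateau: float) -> np.ndarray:
    return plateau + (1.0 - plateau) * np.exp(-rate * t)


def fit_decay(
    normalized: np.ndarray,
    stim_onset: int,
    frame_interval: float = 1.0,
) -> tuple[float, float]:
    """Rate (1/s) and plateau of a normalized destaining trace.

    Least-squares fit of ``plateau + (1 - plateau) * exp(-rate * (t - t_on))``
    on the post-onset segment; needs at least 10 post-onset frames.
    """
    x = np.asarray(normalized, dtype=np.float64)
    seg = x[stim_onset:]
    if seg.size < 10:
        raise ValidationError("fit_decay needs >= 10 post-onset frames")
    if np.ptp(seg) < 1e-12:
        # no decay at all: rate/plateau are jointly unidentifiable; report
        # the zero-rate solution
        return 0.0, float(seg.mean())
    t = np.arange(seg.size) * frame_interval
    try:
        popt, _ = curve_fit(
            _decay_model,
            t,
            seg,
            p0=(0.05, float(seg[-1])),
            bounds=([0.0, -np.inf], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"destain decay fit did not converge: {exc}") from exc
    rate, plateau = float(popt[0]), float(popt[1])
    logger.info("fit_decay: rate=%.4f /s, plateau=%.3f", rate, plateau)
    return rate, plateau


def paired_response_ratio(
    trace: np.ndarray,
    stim_frames: tuple[int, int],
    baseline_window: int = 10,
    peak_window: int = 30,
) -> float:
    """Ratio of the second to the first dF/F peak of paired responses.

    Each response's peak is the maximum within ``peak_window`` frames after
    its stimulus onset, measured as dF/F against the mean of
    ``baseline_window`` frames immediately before that onset.  A first peak
    <= 0 leaves the ratio undefined.
    """
    x = np.asarray(trace, dtype=np.float64)
    s1, s2 = stim_frames
    if not 0 <= s1 < s2 < x.size:
        raise ValidationError("stimulation onsets must be ordered and inside the trace")
    peaks = []
    for onset in (s1, s2):
        b0 = max(0, onset - baseline_window)
        baseline = x[b0:onset].mean()
        if baseline <= 0:
            raise UndefinedValueError("non-positive pre-stimulus baseline")
        seg = x[onset : min(onset + peak_window, x.size)]
        peaks.append((seg.max() - baseline) / baseline)
    if peaks[0] <= 0:
        raise UndefinedValueError("first response peak <= 0; paired ratio undefined")
    return float(peaks[1] / peaks[0])
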