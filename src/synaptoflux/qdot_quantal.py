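"""Quantal analysis of quantum-dot photoluminescence.

Qdots loaded singly into synaptic vesicles emit a unitary photoluminescence,
so a bouton's net intensity is (number of labeled vesicles) x (unit
intensity).  This module estimates the unit intensity q by maximum
likelihood on binned intensities (30 a.u. bins), sets the single-Qdot
cutoff from background statistics (mean + 2 SD), converts background-
subtracted totals into vesicle counts (total / q), smooths traces with a
five-frame moving window, and detects and classifies single-vesicle fusion
events: a small transient rise alone is fast-and-reversible fusion (FRF,
"kiss-and-run"); the same rise followed by a unitary loss of baseline is
full-collapse fusion (FCF).

Likelihood definition (deterministic, so an exhaustive grid search can serve
as an independent cross-check): intensities are histogrammed with the given
bin width; each occupied bin center c is hard-assigned to its nearest
multiple k*q (k = 1..K); sigma^2 is profiled as the count-weighted mean of
(c - k q)^2 / k (variance grows linearly with the number of quanta);
component weights are the assigned count fractions; the log-likelihood is
the multinomial log-probability of the observed counts under the resulting
Normal-mixture bin masses.  Candidate q values that leave the k = 1
component empty are rejected, which removes the exact q/m subharmonic
degeneracy of quantal likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, UndefinedValueError, ValidationError
from .segmentation import BackgroundModel
from .types import TraceSet

logger = logging.getLogger("synaptoflux")

#: Histogram bin width for quantal fits, a.u.
DEFAULT_BIN_WIDTH = 30.0

#: Search window for the unit intensity, a.u.
Q_SEARCH_RANGE = (100.0, 800.0)

#: Fixed weight of the uniform background component in the quantal mixture.
BACKGROUND_WEIGHT = 0.01


@dataclass(frozen=True)
class QuantalFit:
    """Unit-intensity estimate and its fit diagnostics."""

    unit_intensity: float  # q, a.u.
    unit_sd: float  # component spread at k = 1, a.u.
    bin_width: float
    max_quanta: int
    log_likelihood: float
    n_obs: int
    single_cutoff: float | None = None  # a.u., set via single_cutoff()

    def __post_init__(self) -> None:
        if self.unit_intensity <= 0:
            raise ValidationError("unit intensity must be > 0")
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.single_cutoff is not None and self.single_cutoff <= 0:
            raise ValidationError("single_cutoff must be > 0")


@dataclass(frozen=True)
class FusionEvent:
    """One detected fusion event on a single-Qdot trace."""

    roi: int
    onset_frame: int
    peak_amplitude: float  # a.u. above the pre-event baseline
    kind: str  # "frf" | "fcf" | "unclassified"
    baseline_drop: float  # pre-event baseline minus post-event baseline, a.u.


@dataclass(frozen=True)
class VesicleEstimate:
    """Vesicle count of one bouton: background-subtracted total over q."""

    roi: int
    total_intensity: float
    vesicle_count: float


def _bin_counts(intensities: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with edges aligned to multiples of the bin width."""
    lo = np.floor(intensities.min() / bin_width) * bin_width
    hi = np.ceil(intensities.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(intensities, bins=edges)
    return counts, edges


def quantal_loglik(
    counts: np.ndarray, edges: np.ndarray, q: float, k_max: int
) -> float:
    """Profile log-likelihood of the binned quantal mixture at unit size q.

    Returns -inf for invalid candidates (no bin assigned to k = 1, or a
    degenerate profiled sigma).  This function is the single canonical
    objective; tests cross-check it against an independently coded
    exhaustive grid search.
    """
    centers = (edges[:-1] + edges[1:]) / 2.0
    occ = counts > 0
    c = centers[occ]
    n = counts[occ].astype(np.float64)
    total = n.sum()
    k = np.clip(np.round(c / q), 1, k_max).astype(int)
    if not np.any(k == 1):
        return -np.inf
    sigma2 = float(np.sum(n * (c - k * q) ** 2 / k) / total)
    sigma = np.sqrt(sigma2)
    if sigma <= 0:
        # all mass exactly on multiples of q: perfect fit
        return 0.0
    # component weights from the hard assignment
    w = np.bincount(k, weights=n, minlength=k_max + 1)[1:] / total
    ks = np.arange(1, k_max + 1)
    # Normal-mixture mass in every bin; mass falling outside the observed
    # range is NOT renormalized away -- a candidate q that parks a component
    # where there is no data (the q/m subharmonics) pays for it
    lo_z = (edges[:-1, None] - ks[None, :] * q) / (np.sqrt(ks)[None, :] * sigma)
    hi_z = (edges[1:, None] - ks[None, :] * q) / (np.sqrt(ks)[None, :] * sigma)
    p_quantal = ((stats.norm.cdf(hi_z) - stats.norm.cdf(lo_z)) * w[None, :]).sum(axis=1)
    # small fixed-weight uniform background over the observed range guards
    # against stray outlier bins
    n_bins = edges.size - 1
    p_bin = (1.0 - BACKGROUND_WEIGHT) * p_quantal + BACKGROUND_WEIGHT / n_bins
    p_occ = p_bin[occ]
    if np.any(p_occ <= 0):
        return -np.inf
    return float(np.sum(n * np.log(p_occ)))


def quantal_fit(
    intensities: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    k_max: int = 10,
) -> QuantalFit:
    """Maximum-likelihood unit (single-Qdot) intensity from an ROI sample.

    Coarse grid over the q search window followed by bounded scalar
    refinement of the same objective.  Needs >= 30 intensities spanning at
    least 2 occupied bins.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size < 30:
        raise ValidationError(f"quantal_fit needs >= 30 intensities, got {x.size}")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    counts, edges = _bin_counts(x, bin_width)
    if np.count_nonzero(counts) < 2:
        # single occupied bin: all mass at one value -> q is that bin's mean
        q0 = float(x.mean())
        if not Q_SEARCH_RANGE[0] <= q0 <= Q_SEARCH_RANGE[1]:
            raise FitError(
                f"degenerate sample mean {q0:.1f} outside the q search window"
            )
        return QuantalFit(q0, float(x.std()), bin_width, k_max, 0.0, x.size)

    lo, hi = Q_SEARCH_RANGE
    grid = np.arange(lo, hi + 1e-9, 5.0)
    lls = np.array([quantal_loglik(counts, edges, q, k_max) for q in grid])
    if not np.any(np.isfinite(lls)):
        raise FitError("no valid unit-intensity candidate in the search window")
    q_best = float(grid[np.argmax(lls)])

    res = optimize.minimize_scalar(
        lambda q: -quantal_loglik(counts, edges, q, k_max),
        bounds=(max(lo, q_best - 5.0), min(hi, q_best + 5.0)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    q_hat = float(res.x)
    ll = -float(res.fun)
    if not np.isfinite(ll):
        raise FitError("quantal fit failed to converge; inspect the intensity histogram")
    centers = (edges[:-1] + edges[1:]) / 2.0
    occ = counts > 0
    k = np.clip(np.round(centers[occ] / q_hat), 1, k_max)
    sigma = float(
        np.sqrt(np.sum(counts[occ] * (centers[occ] - k * q_hat) ** 2 / k) / counts[occ].sum())
    )
    logger.info("quantal_fit: q=%.2f a.u., sigma=%.2f, LL=%.2f, n=%d", q_hat, sigma, ll, x.size)
    return QuantalFit(q_hat, sigma, bin_width, k_max, ll, x.size)


def single_cutoff(background: BackgroundModel) -> float:
    """Single-Qdot cutoff: background mean + 2 SD (near 3000 a.u. in practice)."""
    return background.threshold


def is_single_qdot(raw_intensity: float, cutoff: float, fit: QuantalFit) -> bool:
    """True when a raw ROI intensity lies between cutoff and cutoff + one unit."""
    return cutoff < raw_intensity <= cutoff + fit.unit_intensity


def vesicle_count(total_intensity: float, fit: QuantalFit, roi: int = 0) -> VesicleEstimate:
    """Vesicles per bouton: background-subtracted total over the unit q.

    Negative totals are clipped to a count of 0 with a logged warning.
    Summaries report the count to one decimal (e.g. 8787/378 -> 23.2).
    """
    if fit.unit_intensity <= 0:
        raise ValidationError("fit.unit_intensity must be > 0")
    if total_intensity < 0:
        logger.warning("negative total intensity %.1f for ROI %d; count set to 0",
                       total_intensity, roi)
        return VesicleEstimate(roi, float(total_intensity), 0.0)
    return VesicleEstimate(roi, float(total_intensity), float(total_intensity / fit.unit_intensity))


def smooth_trace(trace: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; edges use the truncated window."""
    x = np.asarray(trace, dtype=np.float64)
    if x.size < window:
        raise ValidationError(f"trace length {x.size} < window {window}")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_and_classify(
    trace: np.ndarray,
    fit: QuantalFit,
    noise_sd: float,
    roi: int = 0,
    window: int = 5,
    baseline_frames: int = 5,
    threshold_sigma: float = 3.0,
    unit_tolerance: float = 0.5,
) -> list[FusionEvent]:
    """Detect fusion events on a smoothed single-Qdot trace and classify them.

    A rise above the local pre-event baseline by ``threshold_sigma *
    noise_sd`` opens an event; once the trace returns below that threshold
    the post-event baseline (mean of ``baseline_frames`` frames after a
    ``window``-frame guard for smoothing smear) is compared with the
    pre-event baseline.  A drop within ``unit_tolerance * q`` of one unit is
    full-collapse (fcf); a drop within the same tolerance of zero is
    fast-and-reversible (frf); anything else is flagged unclassified and
    excluded from ratios.
    """
    x = np.asarray(trace, dtype=np.float64)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    thr = threshold_sigma * noise_sd
    q = fit.unit_intensity
    events: list[FusionEvent] = []
    i = baseline_frames
    n = x.size
    while i < n:
        pre = float(np.mean(x[max(0, i - baseline_frames) : i]))
        if x[i] > pre + thr:
            onset = i
            j = i
            while j < n and x[j] > pre + thr:
                j += 1
            peak = float(x[onset:j].max() - pre)
            post_lo = min(j + window, n)
            post_hi = min(post_lo + baseline_frames, n)
            if post_hi - post_lo < 1:
                break  # event runs off the end of the trace; drop it
            post = float(np.mean(x[post_lo:post_hi]))
            drop = pre - post
            if abs(drop) <= unit_tolerance * q:
                kind = "frf"
            elif abs(drop - q) <= unit_tolerance * q:
                kind = "fcf"
            else:
                kind = "unclassified"
                logger.info("ROI %d frame %d: ambiguous baseline drop %.1f (q=%.1f)",
                            roi, onset, drop, q)
            events.append(FusionEvent(roi, onset, peak, kind, float(drop)))
            i = post_hi
        else:
            i += 1
    return events


def detect_events_traceset(
    traces: TraceSet,
    fit: QuantalFit,
    noise_sd: float,
    window: int = 5,
    **kwargs,
) -> list[FusionEvent]:
    """Smooth every trace and collect classified events across ROIs."""
    events: list[FusionEvent] = []
    for idx, roi_id in enumerate(traces.roi_ids):
        sm = smooth_trace(traces.intensities[idx], window=window)
        events.extend(
            detect_and_classify(sm, fit, noise_sd, roi=int(roi_id), window=window, **kwargs)
        )
    return events


def frf_ratio_timecourse(
    events: list[FusionEvent],
    n_frames: int,
    window: int = 5,
) -> tuple[np.ndarray, float]:
    """Cumulative FRF fraction per frame plus the end-of-run value.

    The per-frame ratio is (cumulative FRF events) / (cumulative classified
    events); frames before the first classified event are NaN.  The
    end-of-run value is the mean over the last ``window`` frames.
    """
    classified = [e for e in events if e.kind in ("frf", "fcf")]
    if not classified:
        raise UndefinedValueError("no classified events; FRF ratio undefined")
    frf = np.zeros(n_frames)
    tot = np.zeros(n_frames)
    for e in classified:
        if e.onset_frame < n_frames:
            tot[e.onset_frame] += 1
            if e.kind == "frf":
                frf[e.onset_frame] += 1
    cum_tot = np.cumsum(tot)
    cum_frf = np.cumsum(frf)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cum_tot > 0, cum_frf / cum_tot, np.nan)
    end_value = float(np.nanmean(ratio[-window:]))
    return ratio, end_value


def events_to_frame(events: list[FusionEvent]) -> pd.DataFrame:
    """Event list as a table matching the 'events' CSV schema."""
    return pd.DataFrame(
        [
            {
                "roi": e.roi,
                "frame": e.onset_frame,
                "kind": e.kind,
                "amplitude": e.peak_amplitude,
                "baseline_drop": e.baseline_drop,
            }
            for e in events
        ],
        columns=["roi", "frame", "kind", "amplitude", "baseline_drop"],
    )
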