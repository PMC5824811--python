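"""Quantal analysis: unit-intensity fit against an independently coded
exhaustive grid-search oracle, cutoffs, vesicle counting, smoothing, and
fusion-event classification against truth labels."""

import math

import numpy as np
import pytest

from synaptoflux.errors import UndefinedValueError, ValidationError
from synaptoflux.qdot_quantal import (
    BACKGROUND_WEIGHT,
    FusionEvent,
    detect_and_classify,
    detect_events_traceset,
    frf_ratio_timecourse,
    is_single_qdot,
    quantal_fit,
    single_cutoff,
    smooth_trace,
    vesicle_count,
)
from synaptoflux.segmentation import BackgroundModel
from synaptoflux.synthgen import (
    QdotSimSpec,
    gen_qdot_traces,
    random_event_schedule,
)


def _oracle_grid_search(intensities, bin_width=30.0, k_max=10):
    """Independent exhaustive grid search for the unit intensity.

    Re-derives the binned quantal likelihood with plain Python loops and
    math.erf: histogram at ``bin_width``; hard-assign occupied bin centers to
    the nearest multiple k*q; profile sigma^2 = sum n*(c - k*q)^2/k / N;
    weights = assigned count fractions; bin mass from the Normal mixture CDF
    plus a 1% uniform background over the observed bins; reject q with no
    k=1 assignment.  Scans q = 100..800 in 1 a.u. steps.
    """
    x = sorted(float(v) for v in intensities)
    lo = math.floor(x[0] / bin_width) * bin_width
    hi = math.ceil(x[-1] / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    counts = [0] * n_bins
    for v in x:
        b = min(int((v - lo) / bin_width), n_bins - 1)
        counts[b] += 1
    centers = [lo + (b + 0.5) * bin_width for b in range(n_bins)]

    def phi(z):
        return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))

    best_q, best_ll = None, -math.inf
    for q in range(100, 801):
        ks = []
        for b in range(n_bins):
            if counts[b] > 0:
                k = max(1, min(k_max, round(centers[b] / q)))
                ks.append((b, k))
        if not any(k == 1 for _, k in ks):
            continue
        total = sum(counts[b] for b, _ in ks)
        s2 = sum(counts[b] * (centers[b] - k * q) ** 2 / k for b, k in ks) / total
        if s2 <= 0:
            ll = 0.0
        else:
            sigma = math.sqrt(s2)
            w = [0.0] * (k_max + 1)
            for b, k in ks:
                w[k] += counts[b] / total
            ll = 0.0
            ok = True
            for b, k_assigned in ks:
                e_lo = lo + b * bin_width
                e_hi = e_lo + bin_width
                mass = 0.0
                for k in range(1, k_max + 1):
                    if w[k] == 0.0:
                        continue
                    sd_k = math.sqrt(k) * sigma
                    mass += w[k] * (phi((e_hi - k * q) / sd_k) - phi((e_lo - k * q) / sd_k))
                p = (1.0 - BACKGROUND_WEIGHT) * mass + BACKGROUND_WEIGHT / n_bins
                if p <= 0:
                    ok = False
                    break
                ll += counts[b] * math.log(p)
            if not ok:
                continue
        if ll > best_ll:
            best_q, best_ll = float(q), ll
    return best_q


class TestQuantalFit:
    def test_degenerate_single_value_sample_returns_that_value(self):
        x = np.full(50, 378.0)
        fit = quantal_fit(x)
        assert fit.unit_intensity == pytest.approx(378.0)

    def test_mixed_sample_recovers_unit_within_3_se(self):
        rng = np.random.default_rng(0)
        quanta = tuple(int(k) for k in rng.choice([1, 1, 1, 2, 2, 3], size=1000))
        traces, _ = gen_qdot_traces(
            QdotSimSpec(n_rois=1000, quanta_per_roi=quanta, n_frames=1, seed=1)
        )
        fit = quantal_fit(traces.intensities[:, 0])
        se = 41.0 / np.sqrt(1000)
        assert abs(fit.unit_intensity - 378.0) < 3 * se

    @pytest.mark.parametrize("seed", [1, 7])
    def test_fit_matches_exhaustive_grid_oracle(self, seed):
        """Package optimum equals the independent 1 a.u. grid search within
        one grid step."""
        rng = np.random.default_rng(seed)
        quanta = tuple(int(k) for k in rng.choice([1, 1, 2], size=400))
        traces, _ = gen_qdot_traces(
            QdotSimSpec(n_rois=400, quanta_per_roi=quanta, n_frames=1, seed=seed + 50)
        )
        x = traces.intensities[:, 0]
        fit = quantal_fit(x)
        q_oracle = _oracle_grid_search(x)
        assert abs(fit.unit_intensity - q_oracle) <= 1.0

    def test_pure_singles_do_not_collapse_to_subharmonic(self):
        """A unimodal sample near 378 must fit q ~ 378, not q/2."""
        traces, _ = gen_qdot_traces(QdotSimSpec(n_rois=300, n_frames=1, seed=5))
        fit = quantal_fit(traces.intensities[:, 0])
        assert fit.unit_intensity == pytest.approx(378.0, rel=0.05)

    def test_too_few_intensities_rejected(self):
        with pytest.raises(ValidationError):
            quantal_fit(np.full(10, 378.0))


class TestCutoffAndCounting:
    def test_cutoff_is_mean_plus_two_sd(self):
        assert single_cutoff(BackgroundModel(2900.0, 50.0)) == 3000.0
        assert single_cutoff(BackgroundModel(2900.0, 0.0)) == 2900.0

    def test_single_classification_accuracy_on_synthetic_mix(self):
        """Singles vs doubles classified by the cutoff-plus-one-unit rule at
        >= 0.95 accuracy at default unit spread."""
        rng = np.random.default_rng(3)
        n = 400
        quanta = tuple(int(k) for k in rng.choice([1, 2], size=n))
        traces, _ = gen_qdot_traces(
            QdotSimSpec(
                n_rois=n, quanta_per_roi=quanta, n_frames=1,
                background_mean=2900.0, background_sd=50.0, seed=4,
            )
        )
        fit = quantal_fit(
            traces.intensities[:, 0][np.asarray(quanta) == 1] - 2900.0
        )
        cutoff = single_cutoff(BackgroundModel(2900.0, 50.0))
        pred = [
            is_single_qdot(v, cutoff, fit) for v in traces.intensities[:, 0]
        ]
        truth = [k == 1 for k in quanta]
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc >= 0.95

    def test_vesicle_count_paper_arithmetic(self):
        fit = quantal_fit(np.full(50, 378.0))
        assert round(vesicle_count(8787.0, fit).vesicle_count, 1) == 23.2
        assert round(vesicle_count(11050.0, fit).vesicle_count, 1) == 29.2
        assert vesicle_count(378.0, fit).vesicle_count == pytest.approx(1.0)

    def test_vesicle_count_negative_total_clips_to_zero(self):
        fit = quantal_fit(np.full(50, 378.0))
        assert vesicle_count(-10.0, fit).vesicle_count == 0.0

    def test_vesicle_count_scale_invariance(self):
        fit_a = quantal_fit(np.full(50, 378.0))
        fit_b = quantal_fit(np.full(50, 2 * 378.0))
        assert vesicle_count(8787.0, fit_a).vesicle_count == pytest.approx(
            vesicle_count(2 * 8787.0, fit_b).vesicle_count
        )


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        x = np.full(20, 5.0)
        np.testing.assert_allclose(smooth_trace(x), x)

    def test_interior_impulse_becomes_fifth(self):
        x = np.zeros(21)
        x[10] = 10.0
        sm = smooth_trace(x)
        assert sm[10] == pytest.approx(2.0)
        assert sm[7] == 0.0 and sm[13] == 0.0

    def test_linear_ramp_unchanged_in_interior(self):
        x = np.arange(30.0)
        sm = smooth_trace(x)
        np.testing.assert_allclose(sm[2:-2], x[2:-2], rtol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            smooth_trace(np.zeros(3), window=5)


class _FakeFit:
    unit_intensity = 378.0


class TestEventDetection:
    def test_flat_noise_free_trace_has_no_events(self):
        events = detect_and_classify(np.full(50, 400.0), _FakeFit(), noise_sd=20.0)
        assert events == []

    def test_constructed_frf_event_detected_as_frf(self):
        spec = QdotSimSpec(n_rois=1, n_frames=80, background_sd=0.0,
                           event_schedule=((0, 30, "frf"),), seed=0)
        traces, _ = gen_qdot_traces(spec)
        sm = smooth_trace(traces.intensities[0])
        events = detect_and_classify(sm, _FakeFit(), noise_sd=5.0)
        assert len(events) == 1
        assert events[0].kind == "frf"
        assert abs(events[0].onset_frame - 30) <= 3

    def test_constructed_fcf_event_detected_with_unit_drop(self):
        spec = QdotSimSpec(n_rois=1, n_frames=80, background_sd=0.0,
                           event_schedule=((0, 30, "fcf"),), seed=0)
        traces, truth = gen_qdot_traces(spec)
        sm = smooth_trace(traces.intensities[0])
        events = detect_and_classify(sm, _FakeFit(), noise_sd=5.0)
        assert len(events) == 1
        assert events[0].kind == "fcf"
        unit = truth.dropna(subset=["kind"])["unit_lost"].iloc[0]
        assert events[0].baseline_drop == pytest.approx(unit, rel=0.15)

    def test_classification_accuracy_on_truth_labeled_mix(self):
        """>= 0.9 of 500 scheduled 70/30 FRF/FCF events recover their truth
        kind at default noise."""
        n_rois, n_frames = 250, 300
        sched = random_event_schedule(
            n_rois, n_frames, frf_probability=0.7, events_per_roi=2, seed=8
        )
        assert len(sched) >= 400
        # load each bouton with enough Qdots for its scheduled full collapses
        n_fcf = np.zeros(n_rois, dtype=int)
        for r, _, k in sched:
            n_fcf[r] += k == "fcf"
        quanta = tuple(int(max(1, k)) for k in n_fcf)
        traces, _ = gen_qdot_traces(
            QdotSimSpec(n_rois=n_rois, n_frames=n_frames, quanta_per_roi=quanta,
                        event_schedule=sched, seed=9)
        )
        fit = quantal_fit(traces.intensities[:, :10].mean(axis=1))
        events = detect_events_traceset(traces, fit, noise_sd=20.0)
        truth = {(r, f): k for r, f, k in sched}
        by_roi: dict[int, list] = {}
        for e in events:
            by_roi.setdefault(e.roi, []).append(e)
        correct = 0
        for (r, f), kind in truth.items():
            match = next(
                (e for e in by_roi.get(r, []) if abs(e.onset_frame - f) <= 5), None
            )
            if match is not None and match.kind == kind:
                correct += 1
        assert correct / len(truth) >= 0.9


class TestFRFRatio:
    def _ev(self, roi, frame, kind):
        return FusionEvent(roi, frame, 200.0, kind, 0.0)

    def test_all_frf_ratio_one_after_first_event(self):
        events = [self._ev(i, 10 + i, "frf") for i in range(5)]
        ratio, end = frf_ratio_timecourse(events, 30)
        assert np.isnan(ratio[5])
        assert np.all(ratio[10:] == 1.0)
        assert end == 1.0

    def test_alternating_kinds_converge_to_half(self):
        events = [
            self._ev(i, 2 * i, "frf" if i % 2 == 0 else "fcf") for i in range(50)
        ]
        _, end = frf_ratio_timecourse(events, 110)
        assert end == pytest.approx(0.5, abs=0.02)

    def test_known_proportion_recovered_within_tolerance(self):
        sched = random_event_schedule(300, 300, frf_probability=0.7, seed=2)
        events = [self._ev(r, f, k) for r, f, k in sched]
        truth_ratio = sum(1 for *_, k in sched if k == "frf") / len(sched)
        _, end = frf_ratio_timecourse(events, 300)
        assert end == pytest.approx(truth_ratio, abs=0.05)

    def test_unclassified_events_excluded_and_empty_raises(self):
        with pytest.raises(UndefinedValueError):
            frf_ratio_timecourse(
                [FusionEvent(0, 5, 100.0, "unclassified", 0.0)], 20
            )
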