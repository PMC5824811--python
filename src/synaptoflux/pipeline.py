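"""End-to-end experiment runners: simulate -> segment -> measure -> compare.

Each ``*_experiment`` function composes the generator and analysis stages for
one acquisition mode and returns a plain-dict report (group means, S.E.M.,
percent differences, effect sizes, KS statistics, unit intensity, vesicle
counts, FRF ratios, GP shifts -- whatever applies).  :func:`run_pipeline`
dispatches on a :class:`RunConfig`, persists every stage's tables, and writes
the report as JSON; reruns with the same config and seed reproduce the
report bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import synthgen
from .errors import SynaptofluxError, ValidationError
from .gp_imaging import GPCalibration, g_factor, gp_map, gp_shift, pool_results
from .kinetics import destain_extent, normalize_first_n
from .puncta_stats import (
    cohens_d,
    fit_linear,
    ks_compare,
    measure_rois,
    percent_difference,
)
from .qdot_quantal import (
    detect_events_traceset,
    frf_ratio_timecourse,
    quantal_fit,
    vesicle_count,
)
from .segmentation import BackgroundModel, RoiSet, estimate_background, segment_scene
from .spectra_assay import conc_from_fluorescence, fit_standard_curve
from .synthgen import (
    AssaySpec,
    ConditionSpec,
    GPSimSpec,
    QdotSimSpec,
    RegressionSpec,
    SceneSpec,
    child_seeds,
)
from .types import ImageStack, TraceSet

logger = logging.getLogger("synaptoflux")

EXPERIMENT_KINDS = (
    "filipin", "fm_load", "fm_destain", "qdot_pool", "qdot_single",
    "gp", "calcium", "spectra", "assay",
)


@dataclass
class RunConfig:
    """One pipeline run: an experiment kind, its conditions, seed and outdir."""

    kind: str
    seed: int = 0
    outdir: str | Path | None = None
    conditions: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValidationError(f"unknown experiment kind {self.kind!r}; "
                                  f"choose from {EXPERIMENT_KINDS}")


def cellfree_rectangles(
    truth: pd.DataFrame,
    scene: SceneSpec,
    n_rects: int = 4,
    rect_size: int = 16,
) -> list[tuple[int, int, int, int]]:
    """Deterministically pick rectangles clear of every bouton footprint.

    Falls back to smaller rectangles in dense scenes before giving up.
    """
    h, w = scene.height_px, scene.width_px
    max_sigma = np.hypot(scene.bouton_diameter_range[1] / 2.3548, scene.psf_sigma)
    support_radius = 2.5 * max_sigma / scene.pixel_size
    centers = truth[["center_row", "center_col"]].to_numpy()
    for size in dict.fromkeys((rect_size, 12, 8)):
        # spot footprint cannot reach inside a rect whose corner clears it
        keep_out = support_radius + size * np.sqrt(2.0) / 2.0 + 1.0
        rects: list[tuple[int, int, int, int]] = []
        for r0 in range(0, h - size, size):
            for c0 in range(0, w - size, size):
                mid = np.array([r0 + size / 2, c0 + size / 2])
                if centers.size == 0 or np.all(
                    np.hypot(*(centers - mid).T) > keep_out
                ):
                    rects.append((r0, c0, size, size))
                    if len(rects) == n_rects:
                        return rects
    raise SynaptofluxError("could not find enough cell-free rectangles; scene too dense")


def _measure_condition_scenes(
    cond: ConditionSpec,
    scene: SceneSpec,
    n_fovs: int,
    seeds: list[int],
) -> tuple[pd.DataFrame, BackgroundModel, list[pd.DataFrame]]:
    """Generate FOVs for one condition and return pooled ROI measurements."""
    stacks: list[ImageStack] = []
    truths: list[pd.DataFrame] = []
    rect_lists = []
    for f in range(n_fovs):
        sc = dataclasses.replace(scene, seed=seeds[f])
        stack, truth = synthgen.gen_bouton_scene(sc, cond)
        stacks.append(stack)
        truths.append(truth)
        rect_lists.append(cellfree_rectangles(truth, sc))
    background = estimate_background(stacks, rect_lists)
    frames = []
    for f, stack in enumerate(stacks):
        rois = segment_scene(stack, background)
        m = measure_rois(stack, rois, background)
        m.insert(0, "fov", f)
        m.insert(0, "condition", cond.name)
        frames.append(m)
    return pd.concat(frames, ignore_index=True), background, truths


def fm_load_experiment(
    cond_a: ConditionSpec,
    cond_b: ConditionSpec,
    scene: SceneSpec | None = None,
    n_fovs: int = 6,
    seed: int = 0,
) -> dict[str, Any]:
    """Two-condition puncta-intensity comparison through the full pipeline.

    Returns per-condition mean background-subtracted intensity, the percent
    difference (b vs a), Cohen's d and a KS comparison of the pooled per-ROI
    intensities.  Also used for Syp/filipin-style static puncta channels.
    """
    scene = scene or SceneSpec()
    seeds = child_seeds(seed, 2 * n_fovs)
    meas_a, bg_a, _ = _measure_condition_scenes(cond_a, scene, n_fovs, seeds[:n_fovs])
    meas_b, bg_b, _ = _measure_condition_scenes(cond_b, scene, n_fovs, seeds[n_fovs:])
    xa = meas_a["mean_intensity"].to_numpy()
    xb = meas_b["mean_intensity"].to_numpy()
    d_stat, p = ks_compare(xb, xa)
    report = {
        "kind": "fm_load",
        "conditions": [cond_a.name, cond_b.name],
        "n_rois": {cond_a.name: int(xa.size), cond_b.name: int(xb.size)},
        "mean_intensity": {cond_a.name: float(xa.mean()), cond_b.name: float(xb.mean())},
        "sem": {
            cond_a.name: float(xa.std(ddof=1) / np.sqrt(xa.size)),
            cond_b.name: float(xb.std(ddof=1) / np.sqrt(xb.size)),
        },
        "percent_difference": percent_difference(float(xb.mean()), float(xa.mean())),
        "cohens_d": cohens_d(xb, xa),
        "ks": {"D": d_stat, "p": p},
        "background_threshold": {cond_a.name: bg_a.threshold, cond_b.name: bg_b.threshold},
    }
    report["_tables"] = {"measurements": pd.concat([meas_a, meas_b], ignore_index=True)}
    return report


def extract_traces(
    stack: ImageStack, rois: RoiSet, background: BackgroundModel
) -> TraceSet:
    """Per-ROI, per-frame mean intensity minus the background mean."""
    n_f = stack.n_frames
    ids = rois.ids
    out = np.empty((ids.size, n_f))
    for k, roi_id in enumerate(ids):
        rr, cc = rois.pixels(int(roi_id))
        out[k] = stack.data[:, rr, cc].mean(axis=1) - background.mean
    return TraceSet(out, frame_rate=1.0 / stack.meta.frame_interval, roi_ids=ids)


def fm_destain_experiment(
    cond_a: ConditionSpec,
    cond_b: ConditionSpec,
    scene: SceneSpec | None = None,
    n_fovs: int = 5,
    n_baseline_frames: int = 10,
    n_stim_frames: int = 120,
    seed: int = 0,
) -> dict[str, Any]:
    """Two-condition destaining comparison: normalized traces, end-window loss.

    ROIs are segmented on the average of the baseline frames; traces are the
    per-frame ROI means (background-subtracted), normalized to the first 10
    frames; the destain extent uses a five-frame end window.
    """
    scene = scene or SceneSpec()
    seeds = child_seeds(seed, 2 * n_fovs)
    extents: dict[str, list[float]] = {}
    for cond, cond_seeds in ((cond_a, seeds[:n_fovs]), (cond_b, seeds[n_fovs:])):
        vals: list[float] = []
        stacks, rect_lists = [], []
        for f in range(n_fovs):
            sc = dataclasses.replace(scene, seed=cond_seeds[f])
            stack, truth = synthgen.gen_destain_stack(sc, cond, n_baseline_frames, n_stim_frames)
            stacks.append(stack)
            rect_lists.append(cellfree_rectangles(truth, sc))
        background = estimate_background(stacks, rect_lists)
        for stack in stacks:
            baseline_img = ImageStack(stack.data[:n_baseline_frames].mean(axis=0)[None], stack.meta)
            rois = segment_scene(baseline_img, background)
            traces = extract_traces(stack, rois, background)
            for row in traces.intensities:
                vals.append(destain_extent(normalize_first_n(row, n_baseline_frames)))
        extents[cond.name] = vals
    xa = np.asarray(extents[cond_a.name])
    xb = np.asarray(extents[cond_b.name])
    return {
        "kind": "fm_destain",
        "conditions": [cond_a.name, cond_b.name],
        "n_rois": {cond_a.name: int(xa.size), cond_b.name: int(xb.size)},
        "destain_extent": {cond_a.name: float(xa.mean()), cond_b.name: float(xb.mean())},
        "percent_difference": percent_difference(float(xb.mean()), float(xa.mean())),
        "_tables": {
            "extents": pd.DataFrame(
                {
                    "condition": [cond_a.name] * xa.size + [cond_b.name] * xb.size,
                    "extent": np.concatenate([xa, xb]),
                }
            )
        },
    }


def qdot_pool_experiment(
    cond_a: ConditionSpec,
    cond_b: ConditionSpec,
    n_rois: int = 190,
    seed: int = 0,
    unit_mean: float = 378.0,
    unit_sd: float = 41.0,
) -> dict[str, Any]:
    """Total-recycling-pool comparison via quantal vesicle counting.

    Single-Qdot intensities (pooled across conditions) give the unit q by
    quantal fit; each bouton's vesicle count is its net total over q.
    """
    s_single, s_a, s_b = child_seeds(seed, 3)
    rng_a, rng_b = np.random.default_rng(s_a), np.random.default_rng(s_b)
    singles_spec = QdotSimSpec(n_rois=1000, n_frames=1, seed=s_single)
    singles, _ = synthgen.gen_qdot_traces(singles_spec)
    fit = quantal_fit(singles.intensities[:, 0])
    counts = {}
    totals_by_cond = {}
    for cond, rng in ((cond_a, rng_a), (cond_b, rng_b)):
        k = rng.poisson(cond.vesicles_per_bouton_mean, size=n_rois)
        k = np.clip(k, 1, None)
        totals = np.array(
            [rng.normal(unit_mean, unit_sd, size=int(ki)).sum() for ki in k]
        )
        est = [vesicle_count(t, fit, roi=i).vesicle_count for i, t in enumerate(totals)]
        counts[cond.name] = np.asarray(est)
        totals_by_cond[cond.name] = totals
    xa, xb = counts[cond_a.name], counts[cond_b.name]
    d_stat, p = ks_compare(totals_by_cond[cond_b.name], totals_by_cond[cond_a.name])
    return {
        "kind": "qdot_pool",
        "conditions": [cond_a.name, cond_b.name],
        "unit_intensity": fit.unit_intensity,
        "mean_vesicle_count": {
            cond_a.name: round(float(xa.mean()), 1),
            cond_b.name: round(float(xb.mean()), 1),
        },
        "mean_total_intensity": {
            cond_a.name: float(totals_by_cond[cond_a.name].mean()),
            cond_b.name: float(totals_by_cond[cond_b.name].mean()),
        },
        "percent_difference": percent_difference(float(xb.mean()), float(xa.mean())),
        "ks": {"D": d_stat, "p": p},
    }


def qdot_single_experiment(
    cond_a: ConditionSpec,
    cond_b: ConditionSpec,
    n_rois: int = 150,
    n_frames: int = 300,
    seed: int = 0,
) -> dict[str, Any]:
    """Single-vesicle fusion-mode comparison: FRF ratio per condition."""
    seeds = child_seeds(seed, 4)
    report: dict[str, Any] = {"kind": "qdot_single", "conditions": [cond_a.name, cond_b.name],
                              "frf_ratio_end": {}, "n_events": {}}
    for i, cond in enumerate((cond_a, cond_b)):
        schedule = synthgen.random_event_schedule(
            n_rois, n_frames, cond.frf_probability, seed=seeds[2 * i]
        )
        spec = QdotSimSpec(
            n_rois=n_rois, n_frames=n_frames, event_schedule=schedule, seed=seeds[2 * i + 1]
        )
        traces, _ = synthgen.gen_qdot_traces(spec)
        fit = quantal_fit(traces.intensities[:, :10].mean(axis=1))
        events = detect_events_traceset(traces, fit, noise_sd=spec.background_sd)
        _, end_ratio = frf_ratio_timecourse(events, n_frames)
        report["frf_ratio_end"][cond.name] = end_ratio
        report["n_events"][cond.name] = len(events)
    return report


def gp_experiment(
    gp_mean_a: float,
    gp_mean_b: float,
    gp_sd: float = 0.15,
    n_fovs: int = 6,
    scene: SceneSpec | None = None,
    g_true: float = 1.05,
    seed: int = 0,
) -> dict[str, Any]:
    """Two-condition GP comparison with in-run G-factor calibration.

    A noise-free reference pair at the DMSO GP (0.006) calibrates G; each
    condition contributes ``n_fovs`` image pairs whose valid pixels are
    pooled before computing the mean shift and KS statistic.
    """
    scene = scene or SceneSpec(width_px=128, height_px=128)
    seeds = child_seeds(seed, 2 * n_fovs + 1)
    # calibration: uniform reference solvent imaged with the same setup
    ref_spec = GPSimSpec(gp_mean=0.006, gp_sd=0.0, g_true=g_true, noise_sd=0.0, seed=seeds[-1])
    blue_ref, green_ref, _ = synthgen.gen_gp_pair(ref_spec, scene)
    g = g_factor(float(blue_ref.data.mean()), float(green_ref.data.mean()), 0.006)
    cal = GPCalibration(g_factor=g)

    pooled = {}
    for name, gp_mean, cond_seeds in (
        ("a", gp_mean_a, seeds[:n_fovs]),
        ("b", gp_mean_b, seeds[n_fovs : 2 * n_fovs]),
    ):
        results = []
        for f in range(n_fovs):
            spec = GPSimSpec(gp_mean=gp_mean, gp_sd=gp_sd, g_true=g_true, seed=cond_seeds[f])
            blue, green, _ = synthgen.gen_gp_pair(spec, scene)
            results.append(gp_map(blue, green, cal))
        pooled[name] = pool_results(results)
    shift, d_stat, p = gp_shift(pooled["b"], pooled["a"])
    return {
        "kind": "gp",
        "g_factor": g,
        "gp_mean": {"a": pooled["a"].mean, "b": pooled["b"].mean},
        "gp_shift": shift,
        "ks": {"D": d_stat, "p": p},
    }


def regression_experiment(spec: RegressionSpec | None = None, seed: int = 0) -> dict[str, Any]:
    """Paired-intensity OLS recovery (TFC-vs-FM-style channel regression)."""
    spec = spec or RegressionSpec()
    spec = dataclasses.replace(spec, seed=child_seeds(seed, 1)[0])
    pairs = synthgen.gen_paired_intensities(spec)
    fit = fit_linear(pairs)
    se = spec.noise_sd / (spec.x_sd * np.sqrt(spec.n_points)) if spec.noise_sd > 0 else 0.0
    return {
        "kind": "regression",
        "slope": fit.slope,
        "intercept": fit.intercept,
        "pearson_r": fit.pearson_r,
        "n": fit.n,
        "slope_se_expected": float(se),
        "true_slope": spec.slope,
        "_tables": {"pairs": pairs},
    }


def assay_experiment(spec: AssaySpec | None = None, seed: int = 0) -> dict[str, Any]:
    """Standard-curve fit and unknown-sample quantification."""
    spec = spec or AssaySpec(replicate_noise_sd=20.0)
    spec = dataclasses.replace(spec, seed=child_seeds(seed, 1)[0])
    standards, samples = synthgen.gen_assay(spec)
    curve = fit_standard_curve(standards)
    samples = samples.copy()
    samples["conc_est_uM"] = conc_from_fluorescence(
        samples["fluorescence"].to_numpy(), curve
    )
    by_sample = samples.groupby("sample")["conc_est_uM"].mean()
    return {
        "kind": "assay",
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "sample_conc_uM": {int(k): float(v) for k, v in by_sample.items()},
        "_tables": {"samples": samples},
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Dispatch a configured experiment, persist artifacts, return the report.

    Stage failures abort the run with the failing stage named; partial
    outputs already written are retained.
    """
    conds = [ConditionSpec(**c) for c in config.conditions]
    p = dict(config.params)
    try:
        if config.kind in ("fm_load", "filipin"):
            scene = SceneSpec(**p.pop("scene", {}))
            report = fm_load_experiment(conds[0], conds[1], scene=scene, seed=config.seed, **p)
            report["kind"] = config.kind
        elif config.kind == "fm_destain":
            scene = SceneSpec(**p.pop("scene", {}))
            report = fm_destain_experiment(conds[0], conds[1], scene=scene, seed=config.seed, **p)
        elif config.kind == "qdot_pool":
            report = qdot_pool_experiment(conds[0], conds[1], seed=config.seed, **p)
        elif config.kind == "qdot_single":
            report = qdot_single_experiment(conds[0], conds[1], seed=config.seed, **p)
        elif config.kind == "gp":
            report = gp_experiment(seed=config.seed, **p)
        elif config.kind == "calcium":
            raise SynaptofluxError(
                "stage 'calcium': configure via kinetics.paired_response_ratio on trace CSVs"
            )
        elif config.kind == "spectra":
            from .synthgen import SpectrumSpec, gen_spectrum
            spec = SpectrumSpec(**p)
            meas, truth = gen_spectrum(spec)
            report = {
                "kind": "spectra",
                "transmittance": meas.attrs["transmittance"],
                "_tables": {"measured": meas, "truth": truth},
            }
        elif config.kind == "assay":
            spec = AssaySpec(**p) if p else None
            report = assay_experiment(spec, seed=config.seed)
        else:  # pragma: no cover - RunConfig validates kinds
            raise ValidationError(f"unhandled kind {config.kind}")
    except SynaptofluxError as exc:
        raise SynaptofluxError(f"stage {config.kind!r} failed: {exc}") from exc

    tables = report.pop("_tables", {})
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        logger.info("pipeline %s: report written to %s", config.kind, outdir)
    return report
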