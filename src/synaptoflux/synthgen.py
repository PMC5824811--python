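"""Synthetic imaging experiments with ground truth.

Every generator emulates one acquisition mode of a live-neuron fluorescence
study on graphene vs. glass substrates -- diffraction-limited synaptic-bouton
fields, FM-dye destaining movies, quantum-dot photoluminescence traces,
two-channel generalized-polarization (GP) image pairs, dye emission spectra
attenuated by graphene absorbance, and enzymatic-assay plates -- and returns
both the measurable data and a ground-truth table sufficient to score every
downstream estimator.

Determinism contract: identical spec (including its ``seed``) produces
bitwise-identical output.  A single master seed can be expanded into
per-generator child seeds with :func:`child_seeds`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .types import ImageStack, StackMeta, TraceSet

# FWHM of a Gaussian = _FWHM_K * sigma
_FWHM_K = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Boutons are rendered as Gaussian profiles with compact support truncated at
# this many sigma.  A finite footprint means a common intensity threshold
# selects the same pixel set for bright and dim conditions, so programmed
# between-condition intensity ratios survive segmentation unbiased.
_SUPPORT_SIGMA = 2.5


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Expand one master seed into ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionSpec:
    """Biological condition: the between-group effect sizes live here.

    ``bouton_intensity_scale`` multiplies mean puncta intensity (e.g. 1.27 for
    a 27% uptake increase), ``destain_rate``/``destain_plateau`` set the
    exponential dye-loss kinetics, ``frf_probability`` the fraction of fusion
    events that are fast-and-reversible, ``gp_offset`` a condition-wide GP
    shift.
    """

    name: str
    bouton_intensity_scale: float = 1.0
    vesicles_per_bouton_mean: float = 25.0
    destain_rate: float = 0.05  # 1/s
    destain_plateau: float = 0.35  # fraction of baseline remaining at t->inf
    frf_probability: float = 0.5
    gp_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frf_probability <= 1.0:
            raise ValidationError("frf_probability must be in [0, 1]")
        if self.vesicles_per_bouton_mean <= 0:
            raise ValidationError("vesicles_per_bouton_mean must be > 0")
        if self.bouton_intensity_scale <= 0:
            raise ValidationError("bouton_intensity_scale must be > 0")
        if self.destain_rate < 0:
            raise ValidationError("destain_rate must be >= 0")
        if not 0.0 <= self.destain_plateau <= 1.0:
            raise ValidationError("destain_plateau must be in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Field-of-view geometry, optics and noise for puncta scenes."""

    width_px: int = 320
    height_px: int = 320
    pixel_size: float = 0.1  # um / px
    background_mean: float = 100.0  # a.u.
    background_sd: float = 10.0  # a.u.
    n_boutons: int = 40
    bouton_diameter_range: tuple[float, float] = (0.8, 1.2)  # um, FWHM
    psf_sigma: float = 0.15  # um
    noise_model: str = "gaussian"  # or "poisson-gaussian"
    base_amplitude: float = 2000.0  # a.u. peak above background, before scaling
    frame_interval: float = 1.0  # s, for movies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValidationError("background_sd must be >= 0")
        lo, hi = self.bouton_diameter_range
        fov_um = min(self.width_px, self.height_px) * self.pixel_size
        if not (0 < lo <= hi < fov_um):
            raise ValidationError(
                "bouton_diameter_range must lie within (0, min image dimension in um)"
            )
        if self.noise_model not in ("gaussian", "poisson-gaussian"):
            raise ValidationError("noise_model must be 'gaussian' or 'poisson-gaussian'")
        if self.pixel_size <= 0 or self.base_amplitude <= 0:
            raise ValidationError("pixel_size and base_amplitude must be > 0")


@dataclass(frozen=True)
class QdotSimSpec:
    """Single-vesicle quantum-dot photoluminescence traces.

    Unit (single-Qdot) intensity defaults to 378 +/- 41 a.u. after background
    subtraction; acquisition at 5 Hz.  ``event_schedule`` lists
    (roi_index, onset_frame, kind) with kind in {"frf", "fcf"}.
    """

    n_rois: int = 100
    quanta_per_roi: tuple[int, ...] | None = None  # default: all single Qdots
    unit_intensity_mean: float = 378.0  # a.u.
    unit_intensity_sd: float = 41.0  # a.u.
    background_mean: float = 0.0  # a.u. (net traces by default)
    background_sd: float = 20.0  # a.u. per-frame noise
    n_frames: int = 300
    frame_rate: float = 5.0  # Hz
    transient_amplitude: float = 200.0  # a.u.
    transient_duration: int = 5  # frames
    event_schedule: tuple[tuple[int, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit_intensity_mean <= 0:
            raise ValidationError("unit_intensity_mean must be > 0")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        for roi, frame, kind in self.event_schedule:
            if not 0 <= frame < self.n_frames:
                raise ValidationError(f"event frame {frame} outside 0..{self.n_frames - 1}")
            if not 0 <= roi < self.n_rois:
                raise ValidationError(f"event roi {roi} outside 0..{self.n_rois - 1}")
            if kind not in ("frf", "fcf"):
                raise ValidationError(f"unknown event kind {kind!r}")
        if self.quanta_per_roi is not None and len(self.quanta_per_roi) != self.n_rois:
            raise ValidationError("quanta_per_roi length must equal n_rois")


@dataclass(frozen=True)
class GPSimSpec:
    """Two-channel C-laurdan-style image pair realizing a target GP field."""

    gp_mean: float = 0.3
    gp_sd: float = 0.1
    total_intensity_mean: float = 2000.0  # a.u., I_blue + g_true * I_green
    g_true: float = 1.0  # instrument sensitivity factor
    noise_sd: float = 10.0  # a.u. per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.gp_mean < 1.0:
            raise ValidationError("gp_mean must be in (-1, 1)")
        if self.g_true <= 0:
            raise ValidationError("g_true must be > 0")
        if self.gp_sd < 0 or self.noise_sd < 0:
            raise ValidationError("gp_sd and noise_sd must be >= 0")


@dataclass(frozen=True)
class SpectrumSpec:
    """Dye emission spectrum attenuated by graphene broadband absorbance."""

    wavelengths: tuple[float, ...] = tuple(float(w) for w in range(500, 651))
    peak_center: float = 520.0  # nm
    peak_width: float = 25.0  # nm (Gaussian sigma)
    peak_amplitude: float = 1000.0  # a.u.
    graphene_conc: float = 0.0  # mg/L
    path_length: float = 0.01  # m (1 cm cuvette)
    epsilon: float = 2460.0  # L/g/m, absorption coefficient at 660 nm
    noise_sd: float = 0.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.graphene_conc < 0:
            raise ValidationError("graphene_conc must be >= 0")
        w = np.asarray(self.wavelengths)
        if w.size < 2 or np.any(np.diff(w) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class AssaySpec:
    """Fluorometric cholesterol assay plate with a linear standard curve."""

    standard_concs: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0)  # uM
    slope_true: float = 120.0  # a.u. / uM
    intercept_true: float = 50.0  # a.u.
    sample_concs: tuple[float, ...] = (12.3,)  # uM; fresh-media emulation default
    replicate_noise_sd: float = 0.0  # a.u.
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.standard_concs)
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise ValidationError("standard_concs must be non-negative and strictly increasing")
        if self.slope_true <= 0:
            raise ValidationError("slope_true must be > 0")


@dataclass(frozen=True)
class RegressionSpec:
    """Paired bouton intensities with a linear relation between two channels.

    Defaults reproduce the graphene-group TFC-on-FM4-64 relation
    ``y = 1.2083 x - 253.29`` a.u.; the residual SD is derived once from the
    accompanying Pearson r = 0.6629 via sigma_eps = slope * x_sd * sqrt(1/r^2 - 1).
    """

    slope: float = 1.2083
    intercept: float = -253.29  # a.u.
    x_mean: float = 2000.0  # a.u.
    x_sd: float = 600.0  # a.u.
    noise_sd: float = 818.9  # a.u.; realizes Pearson r ~ 0.6629 at defaults
    n_points: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("n_points must be >= 3")
        if self.x_sd <= 0:
            raise ValidationError("x_sd must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _apply_noise(clean: np.ndarray, scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """EMCCD-like noise: optional Poisson shot noise, then Gaussian read noise."""
    img = clean
    if scene.noise_model == "poisson-gaussian":
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if scene.background_sd > 0:
        img = img + rng.normal(0.0, scene.background_sd, size=img.shape)
    return np.clip(img, 0.0, 65535.0)


def _place_spots(scene: SceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample non-overlapping spot centers, diameters and amplitude factors."""
    h, w = scene.height_px, scene.width_px
    lo_d, hi_d = scene.bouton_diameter_range
    # support radius of the largest possible spot, in px
    max_sigma_um = np.hypot(hi_d / _FWHM_K, scene.psf_sigma)
    margin = _SUPPORT_SIGMA * max_sigma_um / scene.pixel_size + 1.0
    min_sep = 2.0 * margin  # keep footprints disjoint
    centers: list[tuple[float, float]] = []
    max_tries = 1000 * max(scene.n_boutons, 1)
    tries = 0
    while len(centers) < scene.n_boutons:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {scene.n_boutons} non-overlapping boutons "
                f"after {max_tries} tries; reduce density"
            )
        tries += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    diam = rng.uniform(lo_d, hi_d, size=scene.n_boutons)
    # per-bouton brightness heterogeneity; bounded so the dimmest footprint
    # edge still clears a mean+2SD background threshold at default settings
    amp_factor = rng.uniform(0.8, 1.2, size=scene.n_boutons)
    return pd.DataFrame(
        {
            "bouton": np.arange(1, scene.n_boutons + 1),
            "center_row": [rc[0] for rc in centers],
            "center_col": [rc[1] for rc in centers],
            "diameter_um": diam,
            "amp_factor": amp_factor,
        }
    )


def _render_spots(
    scene: SceneSpec, spots: pd.DataFrame, amplitudes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Render clean spots (no background) and return (image, per-spot mean).

    The per-spot mean is the mean clean intensity over the spot's compact
    support footprint -- the ground-truth analogue of a per-ROI mean.
    """
    h, w = scene.height_px, scene.width_px
    img = np.zeros((h, w), dtype=np.float64)
    means = np.empty(len(spots), dtype=np.float64)
    for i, row in enumerate(spots.itertuples(index=False)):
        sigma_um = float(np.hypot(row.diameter_um / _FWHM_K, scene.psf_sigma))
        sigma_px = sigma_um / scene.pixel_size
        rad = _SUPPORT_SIGMA * sigma_px
        r0, c0 = row.center_row, row.center_col
        rmin, rmax = int(np.floor(r0 - rad)), int(np.ceil(r0 + rad)) + 1
        cmin, cmax = int(np.floor(c0 - rad)), int(np.ceil(c0 + rad)) + 1
        rr, cc = np.mgrid[max(rmin, 0) : min(rmax, h), max(cmin, 0) : min(cmax, w)]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        inside = d2 <= rad**2
        patch = np.where(inside, amplitudes[i] * np.exp(-d2 / (2.0 * sigma_px**2)), 0.0)
        img[rr, cc] += patch
        means[i] = patch[inside].mean() if inside.any() else 0.0
    return img, means


def _spot_field(
    scene: SceneSpec, cond: ConditionSpec, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Clean (noise-free, background-free) spot image plus ground truth."""
    spots = _place_spots(scene, rng)
    amplitudes = scene.base_amplitude * cond.bouton_intensity_scale * spots["amp_factor"].to_numpy()
    clean, means = _render_spots(scene, spots, amplitudes)
    truth = spots.drop(columns=["amp_factor"]).copy()
    truth.insert(0, "condition", cond.name)
    truth["amplitude"] = amplitudes
    truth["mean_intensity"] = means
    return clean, truth


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_bouton_scene(
    scene: SceneSpec, cond: ConditionSpec
) -> tuple[ImageStack, pd.DataFrame]:
    """Single-frame field of Gaussian boutons on noisy background.

    Returns the image stack and a ground-truth table with one row per bouton
    (center, FWHM diameter, peak amplitude, mean clean intensity over the
    spot footprint).  Identical spec + seed => identical output.
    """
    rng = np.random.default_rng(scene.seed)
    clean, truth = _spot_field(scene, cond, rng)
    img = _apply_noise(clean + scene.background_mean, scene, rng)
    stack = ImageStack(
        img[None],
        StackMeta(pixel_size=scene.pixel_size, frame_interval=scene.frame_interval,
                  channel_name=cond.name),
    )
    return stack, truth


def gen_destain_stack(
    scene: SceneSpec,
    cond: ConditionSpec,
    n_baseline_frames: int = 10,
    n_stim_frames: int = 120,
) -> tuple[ImageStack, pd.DataFrame]:
    """FM-dye destaining movie: constant baseline, then exponential decay.

    During stimulation bouton intensity follows
    ``A * (plateau + (1 - plateau) * exp(-rate * t))`` with t measured from
    stimulation onset; the ground-truth table carries each bouton's rate,
    plateau and noise-free fractional loss at the end of the movie.
    """
    if n_baseline_frames < 1 or n_stim_frames < 1:
        raise ValidationError("frame counts must be >= 1")
    rng = np.random.default_rng(scene.seed)
    clean, truth = _spot_field(scene, cond, rng)
    dt = scene.frame_interval
    t_stim = np.arange(n_stim_frames) * dt
    decay = cond.destain_plateau + (1.0 - cond.destain_plateau) * np.exp(
        -cond.destain_rate * t_stim
    )
    factors = np.concatenate([np.ones(n_baseline_frames), decay])
    frames = np.empty((factors.size, scene.height_px, scene.width_px))
    for i, f in enumerate(factors):
        frames[i] = _apply_noise(clean * f + scene.background_mean, scene, rng)
    truth["destain_rate"] = cond.destain_rate
    truth["plateau"] = cond.destain_plateau
    truth["final_fraction"] = factors[-1]
    truth["total_loss"] = 1.0 - factors[-1]
    stack = ImageStack(
        frames,
        StackMeta(pixel_size=scene.pixel_size, frame_interval=dt, channel_name=cond.name),
    )
    return stack, truth


def random_event_schedule(
    n_rois: int,
    n_frames: int,
    frf_probability: float,
    events_per_roi: int = 1,
    min_gap: int = 25,
    start: int = 20,
    seed: int = 0,
) -> tuple[tuple[int, int, str], ...]:
    """Sample an event schedule with enough spacing for clean classification."""
    rng = np.random.default_rng(seed)
    schedule: list[tuple[int, int, str]] = []
    for roi in range(n_rois):
        last_end = n_frames - min_gap
        if last_end <= start:
            raise ValidationError("n_frames too short for the requested schedule")
        onsets = np.sort(rng.choice(np.arange(start, last_end), size=events_per_roi, replace=False))
        prev = -min_gap
        for onset in onsets:
            if onset - prev < min_gap:
                continue
            kind = "frf" if rng.random() < frf_probability else "fcf"
            schedule.append((roi, int(onset), kind))
            prev = onset
    return tuple(schedule)


def gen_qdot_traces(spec: QdotSimSpec) -> tuple[TraceSet, pd.DataFrame]:
    """Quantum-dot photoluminescence traces with FRF / full-collapse events.

    A loaded pool of k Qdots starts at ``background + sum of k sampled unit
    intensities``.  An FRF event adds a transient of ``transient_amplitude``
    for ``transient_duration`` frames and returns to the prior baseline; a
    full-collapse (fcf) event adds the same transient and then steps the
    baseline down by one sampled unit.  Negative intensities are clipped at
    zero and flagged in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    quanta = (
        np.asarray(spec.quanta_per_roi, dtype=int)
        if spec.quanta_per_roi is not None
        else np.ones(spec.n_rois, dtype=int)
    )
    # sample every unit intensity up front, per ROI
    units = [rng.normal(spec.unit_intensity_mean, spec.unit_intensity_sd, size=k) for k in quanta]
    clean = np.empty((spec.n_rois, spec.n_frames))
    for i, u in enumerate(units):
        clean[i] = spec.background_mean + u.sum()

    events: list[dict] = []
    lost_count = np.zeros(spec.n_rois, dtype=int)
    for roi, onset, kind in sorted(spec.event_schedule, key=lambda e: (e[0], e[1])):
        end = min(onset + spec.transient_duration, spec.n_frames)
        clean[roi, onset:end] += spec.transient_amplitude
        unit_lost = 0.0
        if kind == "fcf":
            k = lost_count[roi]
            if k >= quanta[roi]:
                raise ValidationError(f"ROI {roi}: more full-collapse events than loaded Qdots")
            unit_lost = float(units[roi][k])
            clean[roi, end:] -= unit_lost
            lost_count[roi] += 1
        events.append(
            {
                "roi": roi,
                "frame": onset,
                "kind": kind,
                "amplitude": spec.transient_amplitude,
                "unit_lost": unit_lost,
            }
        )

    noisy = clean + rng.normal(0.0, spec.background_sd, size=clean.shape)
    clipped = noisy < 0
    noisy = np.clip(noisy, 0.0, None)

    truth = pd.DataFrame(events, columns=["roi", "frame", "kind", "amplitude", "unit_lost"])
    truth_rois = pd.DataFrame(
        {
            "roi": np.arange(spec.n_rois),
            "quanta": quanta,
            "baseline_intensity": [spec.background_mean + u.sum() for u in units],
            "clipped_frames": clipped.sum(axis=1),
        }
    )
    truth = truth.merge(truth_rois, on="roi", how="outer").sort_values(
        ["roi", "frame"], na_position="last"
    )
    truth.attrs["unit_intensities"] = units
    traces = TraceSet(noisy, frame_rate=spec.frame_rate, roi_ids=np.arange(spec.n_rois))
    return traces, truth


def gen_gp_pair(
    spec: GPSimSpec, scene: SceneSpec
) -> tuple[ImageStack, ImageStack, np.ndarray]:
    """Two-channel image pair realizing a target per-pixel GP field.

    For each pixel a true GP value g is drawn from Normal(gp_mean, gp_sd)
    truncated to (-1, 1) by reject-and-redraw; channel intensities satisfy
    ``(I_blue - g_true*I_green) / (I_blue + g_true*I_green) = g`` at total
    (weighted) intensity ``total_intensity_mean``, then per-channel Gaussian
    noise is added.  Returns (blue, green, truth GP map).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (scene.height_px, scene.width_px)
    g = rng.normal(spec.gp_mean, spec.gp_sd, size=shape)
    bad = (g <= -1.0) | (g >= 1.0)
    while bad.any():
        g[bad] = rng.normal(spec.gp_mean, spec.gp_sd, size=int(bad.sum()))
        bad = (g <= -1.0) | (g >= 1.0)
    s = spec.total_intensity_mean
    i_blue = s * (1.0 + g) / 2.0
    i_green = s * (1.0 - g) / (2.0 * spec.g_true)
    if spec.noise_sd > 0:
        i_blue = i_blue + rng.normal(0.0, spec.noise_sd, size=shape)
        i_green = i_green + rng.normal(0.0, spec.noise_sd, size=shape)
    i_blue = np.clip(i_blue, 0.0, 65535.0)
    i_green = np.clip(i_green, 0.0, 65535.0)
    meta_b = StackMeta(pixel_size=scene.pixel_size, channel_name="blue")
    meta_g = StackMeta(pixel_size=scene.pixel_size, channel_name="green")
    return ImageStack(i_blue[None], meta_b), ImageStack(i_green[None], meta_g), g


def gen_spectrum(spec: SpectrumSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emission spectrum attenuated by graphene transmittance, plus truth.

    The measured spectrum is ``truth(lambda) * T + noise`` with T from the
    Beer-Lambert relationship (flat absorption coefficient across the
    emission band); the unattenuated emission is returned as truth.  Both are
    tables with columns (wavelength_nm, intensity).
    """
    from .spectra_assay import transmittance

    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.wavelengths, dtype=np.float64)
    emission = spec.peak_amplitude * np.exp(-((w - spec.peak_center) ** 2) / (2 * spec.peak_width**2))
    t = transmittance(spec.graphene_conc, epsilon=spec.epsilon, path=spec.path_length)
    measured = emission * t
    if spec.noise_sd > 0:
        measured = measured + rng.normal(0.0, spec.noise_sd, size=w.size)
    meas = pd.DataFrame({"wavelength_nm": w, "intensity": measured})
    truth = pd.DataFrame({"wavelength_nm": w, "intensity": emission})
    meas.attrs["graphene_conc_mg_per_L"] = spec.graphene_conc
    meas.attrs["transmittance"] = t
    return meas, truth


def gen_assay(spec: AssaySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assay plate: standard curve readings plus unknown-sample readings.

    Fluorescence = slope_true * conc + intercept_true + Normal(0, noise) per
    replicate.  Returns (standards table, samples table); the samples table
    carries the true concentrations for scoring.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for conc in spec.standard_concs:
        for rep in range(spec.n_replicates):
            f = spec.slope_true * conc + spec.intercept_true
            if spec.replicate_noise_sd > 0:
                f += rng.normal(0.0, spec.replicate_noise_sd)
            rows.append({"conc_uM": conc, "replicate": rep, "fluorescence": f})
    standards = pd.DataFrame(rows)
    rows = []
    for i, conc in enumerate(spec.sample_concs):
        for rep in range(spec.n_replicates):
            f = spec.slope_true * conc + spec.intercept_true
            if spec.replicate_noise_sd > 0:
                f += rng.normal(0.0, spec.replicate_noise_sd)
            rows.append(
                {"sample": i, "conc_true_uM": conc, "replicate": rep, "fluorescence": f}
            )
    samples = pd.DataFrame(rows, columns=["sample", "conc_true_uM", "replicate", "fluorescence"])
    return standards, samples


def gen_paired_intensities(spec: RegressionSpec) -> pd.DataFrame:
    """Paired bouton intensities: x ~ Normal, y = slope*x + intercept + noise."""
    rng = np.random.default_rng(spec.seed)
    x = rng.normal(spec.x_mean, spec.x_sd, size=spec.n_points)
    y = spec.slope * x + spec.intercept
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    return pd.DataFrame({"x": x, "y": y})


def with_seed(spec, seed: int):
    """Return a copy of any frozen spec with its seed replaced."""
    return replace(spec, seed=seed)
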