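"""Generator contracts: noise-free forced values, ground-truth sufficiency,
programmed effect sizes, and bitwise determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from synaptoflux.errors import GenerationError, ValidationError
from synaptoflux.synthgen import (
    AssaySpec,
    ConditionSpec,
    GPSimSpec,
    QdotSimSpec,
    RegressionSpec,
    SceneSpec,
    SpectrumSpec,
    child_seeds,
    gen_assay,
    gen_bouton_scene,
    gen_destain_stack,
    gen_gp_pair,
    gen_paired_intensities,
    gen_qdot_traces,
    gen_spectrum,
    random_event_schedule,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frf_probability": 1.2},
            {"vesicles_per_bouton_mean": 0.0},
            {"bouton_intensity_scale": -1.0},
            {"destain_plateau": 1.5},
        ],
    )
    def test_condition_invariants(self, kwargs):
        with pytest.raises(ValidationError):
            ConditionSpec(name="bad", **kwargs)

    def test_scene_diameter_must_fit_fov(self):
        with pytest.raises(ValidationError):
            SceneSpec(width_px=32, height_px=32, pixel_size=0.1,
                      bouton_diameter_range=(1.0, 10.0))

    def test_qdot_event_frame_bounds(self):
        with pytest.raises(ValidationError):
            QdotSimSpec(n_frames=10, event_schedule=((0, 10, "frf"),))

    def test_gp_mean_bounds(self):
        with pytest.raises(ValidationError):
            GPSimSpec(gp_mean=1.0)

    def test_assay_concs_strictly_increasing(self):
        with pytest.raises(ValidationError):
            AssaySpec(standard_concs=(0.0, 5.0, 5.0))


class TestBoutonScene:
    def test_noise_free_center_value_is_background_plus_amplitude(self):
        scene = SceneSpec(width_px=96, height_px=96, n_boutons=1,
                          background_sd=0.0, seed=3)
        stack, truth = gen_bouton_scene(scene, ConditionSpec(name="c"))
        r = int(round(truth["center_row"].iloc[0]))
        c = int(round(truth["center_col"].iloc[0]))
        # center pixel sits within half a pixel of the true center
        expected = scene.background_mean + truth["amplitude"].iloc[0]
        assert stack.data[0, r, c] == pytest.approx(expected, rel=0.02)

    def test_zero_boutons_gives_pure_background(self):
        scene = SceneSpec(width_px=64, height_px=64, n_boutons=0,
                          background_sd=0.0, seed=0)
        stack, truth = gen_bouton_scene(scene, ConditionSpec(name="c"))
        assert truth.empty
        assert np.all(stack.data == scene.background_mean)

    def test_programmed_intensity_ratio_is_exact_in_truth(self, small_scene):
        """Conditions sharing a scene seed differ in truth means by exactly
        the programmed uptake ratio (e.g. a 27% FM1-43 increase)."""
        _, t_a = gen_bouton_scene(small_scene, ConditionSpec(name="a"))
        _, t_b = gen_bouton_scene(
            small_scene, ConditionSpec(name="b", bouton_intensity_scale=1.27)
        )
        ratio = t_b["mean_intensity"].to_numpy() / t_a["mean_intensity"].to_numpy()
        np.testing.assert_allclose(ratio, 1.27, rtol=1e-12)

    def test_overcrowded_scene_raises_generation_error(self):
        with pytest.raises(GenerationError):
            gen_bouton_scene(
                SceneSpec(width_px=64, height_px=64, n_boutons=80, seed=0),
                ConditionSpec(name="c"),
            )

    def test_determinism_bitwise(self, small_scene, glass):
        s1, t1 = gen_bouton_scene(small_scene, glass)
        s2, t2 = gen_bouton_scene(small_scene, glass)
        np.testing.assert_array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(t1, t2)

    def test_poisson_gaussian_noise_model_runs(self, glass):
        scene = SceneSpec(width_px=64, height_px=64, n_boutons=2,
                          noise_model="poisson-gaussian", seed=5)
        stack, _ = gen_bouton_scene(scene, glass)
        assert np.all(stack.data >= 0) and np.all(stack.data <= 65535)


class TestDestainStack:
    def test_zero_rate_keeps_all_frames_identical(self, glass):
        scene = SceneSpec(width_px=96, height_px=96, n_boutons=3,
                          background_sd=0.0, seed=2)
        cond = dataclasses.replace(glass, destain_rate=0.0)
        stack, _ = gen_destain_stack(scene, cond, 3, 5)
        for k in range(1, stack.n_frames):
            np.testing.assert_array_equal(stack.data[k], stack.data[0])

    def test_noise_free_decay_follows_closed_form(self):
        scene = SceneSpec(width_px=96, height_px=96, n_boutons=1,
                          background_sd=0.0, seed=4)
        cond = ConditionSpec(name="c", destain_rate=0.1, destain_plateau=0.0)
        stack, truth = gen_destain_stack(scene, cond, n_baseline_frames=2, n_stim_frames=20)
        r = int(round(truth["center_row"].iloc[0]))
        c = int(round(truth["center_col"].iloc[0]))
        net = stack.data[:, r, c] - scene.background_mean
        baseline = net[0]
        t = np.arange(20) * scene.frame_interval
        np.testing.assert_allclose(net[2:], baseline * np.exp(-0.1 * t), rtol=1e-12)

    def test_programmed_loss_difference_is_exact_in_truth(self, small_scene):
        """Plateaus chosen for a 30% dye-loss difference yield truth losses
        in exactly that ratio (the decay factor cancels)."""
        c_a = ConditionSpec(name="a", destain_plateau=0.5)
        c_b = ConditionSpec(name="b", destain_plateau=0.35)
        _, t_a = gen_destain_stack(small_scene, c_a, 2, 30)
        _, t_b = gen_destain_stack(small_scene, c_b, 2, 30)
        ratio = t_b["total_loss"].iloc[0] / t_a["total_loss"].iloc[0]
        assert ratio == pytest.approx(1.3, rel=1e-9)


class TestQdotTraces:
    def test_empty_schedule_no_noise_is_constant_at_k_units(self):
        spec = QdotSimSpec(n_rois=3, quanta_per_roi=(1, 2, 3), n_frames=8,
                           background_sd=0.0, unit_intensity_sd=0.0, seed=0)
        traces, truth = gen_qdot_traces(spec)
        for i, k in enumerate((1, 2, 3)):
            np.testing.assert_allclose(traces.intensities[i], k * 378.0)
        assert truth["clipped_frames"].fillna(0).eq(0).all()

    def test_fcf_steps_baseline_down_by_sampled_unit(self):
        spec = QdotSimSpec(n_rois=1, n_frames=40, background_sd=0.0,
                           event_schedule=((0, 10, "fcf"),), seed=1)
        traces, truth = gen_qdot_traces(spec)
        x = traces.intensities[0]
        unit = truth.dropna(subset=["kind"])["unit_lost"].iloc[0]
        assert unit > 0
        assert x[0] - x[-1] == pytest.approx(unit, abs=1e-9)
        # transient present during the event window
        assert x[10] == pytest.approx(x[0] + spec.transient_amplitude, abs=1e-9)

    def test_frf_restores_prior_baseline(self):
        spec = QdotSimSpec(n_rois=1, n_frames=40, background_sd=0.0,
                           event_schedule=((0, 10, "frf"),), seed=1)
        traces, _ = gen_qdot_traces(spec)
        x = traces.intensities[0]
        assert x[-1] == pytest.approx(x[0], abs=1e-9)

    def test_unit_intensity_sample_mean_near_378(self):
        spec = QdotSimSpec(n_rois=1000, n_frames=1, background_sd=0.0, seed=11)
        traces, _ = gen_qdot_traces(spec)
        sample = traces.intensities[:, 0]
        se = 41.0 / np.sqrt(1000)
        assert abs(sample.mean() - 378.0) < 3 * se

    def test_negative_clipping_is_flagged(self):
        spec = QdotSimSpec(n_rois=1, quanta_per_roi=(1,), n_frames=30,
                           background_sd=0.0, unit_intensity_sd=200.0,
                           event_schedule=((0, 5, "fcf"), (0, 35 - 20, "fcf")),
                           seed=2)
        # second fcf would need a second Qdot; use a legal schedule instead
        spec = QdotSimSpec(n_rois=1, quanta_per_roi=(1,), n_frames=30,
                           background_mean=-100.0, background_sd=0.0, seed=2)
        traces, truth = gen_qdot_traces(spec)
        assert np.all(traces.intensities >= 0)


class TestGPPair:
    def test_zero_gp_forces_channel_balance(self):
        scene = SceneSpec(width_px=16, height_px=16)
        spec = GPSimSpec(gp_mean=0.0, gp_sd=0.0, g_true=1.3, noise_sd=0.0, seed=0)
        blue, green, truth = gen_gp_pair(spec, scene)
        np.testing.assert_allclose(blue.data, 1.3 * green.data, rtol=1e-12)
        np.testing.assert_allclose(truth, 0.0)

    def test_truth_recovered_through_gp_formula(self):
        from synaptoflux.gp_imaging import GPCalibration, gp_map

        scene = SceneSpec(width_px=32, height_px=32)
        spec = GPSimSpec(gp_mean=0.006, gp_sd=0.0, g_true=0.97, noise_sd=0.0, seed=0)
        blue, green, _ = gen_gp_pair(spec, scene)
        res = gp_map(blue, green, GPCalibration(g_factor=0.97))
        np.testing.assert_allclose(res.values, 0.006, atol=1e-12)

    def test_programmed_offset_appears_in_truth_maps(self):
        scene = SceneSpec(width_px=64, height_px=64)
        a = GPSimSpec(gp_mean=0.30, gp_sd=0.0, seed=5)
        b = GPSimSpec(gp_mean=0.45, gp_sd=0.0, seed=5)
        *_, t_a = gen_gp_pair(a, scene)
        *_, t_b = gen_gp_pair(b, scene)
        assert t_b.mean() - t_a.mean() == pytest.approx(0.15, abs=1e-12)

    def test_truth_values_respect_gp_bounds(self):
        scene = SceneSpec(width_px=64, height_px=64)
        spec = GPSimSpec(gp_mean=0.9, gp_sd=0.5, seed=3)
        *_, truth = gen_gp_pair(spec, scene)
        assert np.all(truth > -1.0) and np.all(truth < 1.0)


class TestSpectrumAndAssay:
    def test_zero_graphene_leaves_emission_unattenuated(self):
        meas, truth = gen_spectrum(SpectrumSpec(graphene_conc=0.0, noise_sd=0.0))
        pd.testing.assert_frame_equal(meas, truth, check_like=True)

    def test_attenuation_matches_beer_lambert_oracle(self):
        # independent evaluation: T = 10^(-2460 * 0.026 g/L * 0.01 m)
        t_expected = 10.0 ** (-2460.0 * 0.026 * 0.01)
        meas, truth = gen_spectrum(
            SpectrumSpec(graphene_conc=26.0, path_length=0.01, noise_sd=0.0)
        )
        assert meas.attrs["transmittance"] == pytest.approx(t_expected, rel=1e-12)
        np.testing.assert_allclose(
            meas["intensity"], truth["intensity"] * t_expected, rtol=1e-12
        )

    def test_assay_noise_free_reading_is_exact(self):
        spec = AssaySpec(slope_true=100.0, intercept_true=7.0,
                         sample_concs=(10.0,), replicate_noise_sd=0.0)
        standards, samples = gen_assay(spec)
        assert (samples["fluorescence"] == 100.0 * 10.0 + 7.0).all()
        ten = standards[standards["conc_uM"] == 10.0]["fluorescence"]
        assert (ten == 1007.0).all()


class TestPairedIntensities:
    def test_noise_free_pairs_are_perfectly_correlated(self):
        pairs = gen_paired_intensities(RegressionSpec(noise_sd=0.0, seed=0))
        r = np.corrcoef(pairs["x"], pairs["y"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_yields_near_zero_fit(self):
        spec = RegressionSpec(slope=0.0, intercept=5.0, noise_sd=1.0,
                              n_points=5000, seed=1)
        pairs = gen_paired_intensities(spec)
        slope = np.polyfit(pairs["x"], pairs["y"], 1)[0]
        se = 1.0 / (spec.x_sd * np.sqrt(5000))
        assert abs(slope) < 3 * se


class TestScheduleAndSeeds:
    def test_child_seeds_are_deterministic_and_bounded(self):
        a = child_seeds(42, 5)
        b = child_seeds(42, 5)
        assert a == b
        assert all(0 <= s < 2**31 for s in a)
        assert len(set(a)) == 5

    def test_random_schedule_respects_spacing_and_bounds(self):
        sched = random_event_schedule(20, 200, frf_probability=0.5,
                                      events_per_roi=2, min_gap=30, seed=0)
        by_roi: dict[int, list[int]] = {}
        for roi, frame, kind in sched:
            assert kind in ("frf", "fcf")
            assert 0 <= frame < 200
            by_roi.setdefault(roi, []).append(frame)
        for frames in by_roi.values():
            diffs = np.diff(sorted(frames))
            assert np.all(diffs >= 30)
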