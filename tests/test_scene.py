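"""Ground-truth scene generation, staining/treatment models, rendering."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from orgstack import (InvalidParameterError, OpticalModel, Scene, SceneObject,
                      StainingModel, TreatmentEffect, apply_staining,
                      apply_treatment, generate_scene, plan_zstack,
                      render_stack)


class TestGenerateScene:
    def test_empty_scene(self):
        scene = generate_scene(0, 20.0, seed=0)
        assert scene.objects == []

    def test_objects_fill_gel_and_reruns_are_identical(self):
        scene = generate_scene(100, 20.0, gel_depth=1100.0, seed=42)
        assert scene.n_objects == 100
        zs = np.array([o.center[2] for o in scene.objects])
        assert zs.min() >= 0 and zs.max() <= 1100.0
        again = generate_scene(100, 20.0, gel_depth=1100.0, seed=42)
        assert all(a.center == b.center for a, b in zip(scene.objects, again.objects))

    def test_density_matches_count_over_volume(self):
        # 10 uL gel volume: 1100 um deep, xy sized to make up the rest
        side = np.sqrt(1e10 / 1100.0)
        scene = generate_scene(200, 20.0, gel_depth=1100.0,
                               xy_extent=(side, side), seed=0)
        assert scene.density == pytest.approx(20.0, abs=1e-9)

    @pytest.mark.parametrize("kwargs", [
        {"n_objects": -1, "diameter_spec": 20.0},
        {"n_objects": 5, "diameter_spec": 20.0, "gel_depth": 0.0},
        {"n_objects": 5, "diameter_spec": -3.0},
        {"n_objects": 5, "diameter_spec": 20.0, "xy_extent": (0.0, 100.0)},
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(InvalidParameterError):
            generate_scene(**kwargs)

    def test_uniform_diameter_range(self):
        scene = generate_scene(500, (10.0, 100.0), seed=1)
        d = np.array([o.diameter for o in scene.objects])
        assert d.min() >= 10.0 and d.max() <= 100.0
        assert d.std() > 10.0  # actually spread, not constant


class TestSceneObjectInvariants:
    def test_unlabeled_objects_cannot_carry_green(self):
        with pytest.raises(InvalidParameterError):
            SceneObject(id=0, center=(0, 0, 0), diameter=20.0,
                        labeled=False, green_intensity=1.0)

    def test_live_fraction_bounds(self):
        with pytest.raises(InvalidParameterError):
            SceneObject(id=0, center=(0, 0, 0), diameter=20.0, live_fraction=1.5)

    def test_object_outside_volume_rejected(self):
        obj = SceneObject(id=0, center=(600.0, 10.0, 10.0), diameter=20.0)
        with pytest.raises(InvalidParameterError):
            Scene(objects=[obj], gel_depth=1100.0, xy_extent=(512.0, 512.0))


class TestStaining:
    def test_zero_dose_labels_nothing(self):
        scene = generate_scene(200, 20.0, seed=0)
        stained = apply_staining(scene, StainingModel(concentration=0.0), seed=0)
        assert not any(o.labeled for o in stained.objects)

    def test_working_point_labels_every_live_object(self):
        # 2 uM x 60 min saturates the default kinetics (K = 120 uM min)
        scene = generate_scene(300, 20.0, seed=1)
        stained = apply_staining(
            scene, StainingModel(concentration=2.0, time=60.0), seed=1)
        assert all(o.labeled and o.green_intensity > 0 for o in stained.objects)

    def test_half_saturation_matches_binomial_oracle(self):
        # c*t/K = 0.5 -> Binomial(1000, 0.5); 3 SE band
        scene = generate_scene(1000, 20.0, seed=2)
        stained = apply_staining(
            scene, StainingModel(concentration=1.0, time=60.0), seed=2)
        labeled = sum(o.labeled for o in stained.objects)
        assert abs(labeled - 500) <= 3 * np.sqrt(1000 * 0.25)

    def test_dead_objects_never_labeled(self):
        objs = [SceneObject(id=i, center=(50.0 + i, 50.0, 50.0), diameter=20.0,
                            live_fraction=0.0) for i in range(50)]
        scene = Scene(objects=objs, gel_depth=1100.0, xy_extent=(512.0, 512.0))
        stained = apply_staining(scene, StainingModel(), seed=0)
        assert not any(o.labeled for o in stained.objects)

    def test_labeled_fraction_monotone_in_dose_and_time(self):
        scene = generate_scene(800, 20.0, seed=3)

        def frac(c, t):
            st = apply_staining(scene, StainingModel(concentration=c, time=t),
                                seed=3)
            return sum(o.labeled for o in st.objects)

        # shared seed stream -> monotone even at finite n
        assert frac(0.5, 30) <= frac(1.0, 30) <= frac(2.0, 30)
        assert frac(1.0, 15) <= frac(1.0, 30) <= frac(1.0, 60)


class TestTreatment:
    def test_identity_effect_leaves_scene_unchanged(self):
        scene = generate_scene(50, 30.0, seed=0)
        out = apply_treatment(scene, TreatmentEffect(
            kill_fraction=0.0, shrink_factor=1.0, dead_shell_width=0.0), seed=0)
        assert all(a == b for a, b in zip(scene.objects, out.objects))

    def test_total_kill_leaves_nothing_stainable(self):
        scene = generate_scene(80, 30.0, seed=1)
        dead = apply_treatment(scene, TreatmentEffect(kill_fraction=1.0), seed=1)
        assert all(o.live_fraction == 0 and o.red_intensity > 0
                   for o in dead.objects)
        stained = apply_staining(dead, StainingModel(), seed=1)
        assert all(o.green_intensity == 0 for o in stained.objects)

    def test_kill_count_matches_binomial_oracle(self):
        scene = generate_scene(500, 30.0, seed=2)
        out = apply_treatment(scene, TreatmentEffect(kill_fraction=0.6), seed=2)
        dead = sum(1 for o in out.objects if o.live_fraction == 0)
        assert abs(dead - 300) <= 3 * np.sqrt(500 * 0.6 * 0.4)

    def test_survivors_shrink_and_gain_shell(self):
        scene = generate_scene(100, 40.0, seed=3)
        out = apply_treatment(scene, TreatmentEffect(
            kill_fraction=0.3, shrink_factor=0.7, dead_shell_width=12.0), seed=3)
        survivors = [o for o in out.objects if o.live_fraction > 0]
        assert survivors
        assert all(o.diameter == pytest.approx(28.0) for o in survivors)
        assert all(o.shell_width == 12.0 and o.red_intensity > 0
                   for o in survivors)


class TestRenderStack:
    def test_in_focus_object_is_an_unblurred_disk(self):
        # one object exactly at a focal plane, no noise: the rendered layer
        # equals the analytic anti-aliased disk
        obj = SceneObject(id=0, center=(64.0, 64.0, 500.0), diameter=40.0)
        scene = Scene(objects=[obj], gel_depth=1000.0, xy_extent=(128.0, 128.0))
        plan = plan_zstack(1000.0, 3, round_to=0)  # planes at 0, 500, 1000
        optics = OpticalModel(noise_sd=0.0)
        stack = render_stack(scene, plan, optics, channels=("brightfield",))
        img = stack.pixels[1, 0]
        yy, xx = np.mgrid[:128, :128]
        dist = np.hypot(yy + 0.5 - 64.0, xx + 0.5 - 64.0)
        disk = np.clip(20.0 + 0.5 - dist, 0.0, 1.0)
        assert np.allclose(img, disk, atol=1e-6)

    def test_rendering_is_bit_reproducible(self, plan7, optics):
        scene = generate_scene(20, (20.0, 60.0), seed=5)
        a = render_stack(scene, plan7, optics, seed=9)
        b = render_stack(scene, plan7, optics, seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_quench_reduces_green_background_monotonically(self, plan7, optics):
        scene = generate_scene(0, 20.0, seed=0)
        means = []
        for cu in (0.0, 0.05, 0.1, 0.2):
            staining = StainingModel(time=60.0, cu_concentration=cu)
            stack = render_stack(scene, plan7, optics,
                                 channels=("green",), staining=staining, seed=1)
            means.append(stack.pixels.mean())
        assert all(a >= b for a, b in zip(means, means[1:]))
        assert means[0] > means[2]  # 0.1 mM Cu2+ strictly below unquenched

    def test_object_beyond_detectability_depth_leaves_no_footprint(self):
        obj = SceneObject(id=0, center=(64.0, 64.0, 500.0), diameter=20.0)
        scene = Scene(objects=[obj], gel_depth=1000.0, xy_extent=(128.0, 128.0))
        plan = plan_zstack(1000.0, 2)  # planes at 0 and 1000: 490 um away
        optics = OpticalModel(noise_sd=0.0)
        stack = render_stack(scene, plan, optics, channels=("brightfield",))
        assert stack.pixels.max() == 0.0

    def test_footprints_per_layer_never_exceed_object_count(self, optics):
        scene = generate_scene(15, 40.0, gel_depth=1100.0,
                               xy_extent=(256.0, 256.0), seed=7, xy_margin=25.0)
        plan = plan_zstack(1100.0, 7)
        stack = render_stack(scene, plan, OpticalModel(noise_sd=0.0),
                             channels=("brightfield",))
        for layer in stack.pixels[:, 0]:
            _, n = ndi.label(layer > 0.3)
            assert n <= scene.n_objects

    def test_empty_channel_set_rejected(self, plan7, optics):
        scene = generate_scene(1, 20.0, seed=0)
        with pytest.raises(InvalidParameterError):
            render_stack(scene, plan7, optics, channels=())
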