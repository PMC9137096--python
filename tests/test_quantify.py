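"""Detection, measurement and per-well readouts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgstack import (CompositeImage, EmptyWellError, InvalidParameterError,
                      NoBackgroundError, ObjectRecord, OpticalModel, Scene,
                      SceneObject, background_intensity, labeling_rate,
                      overlap_rate, plan_zstack, records_from_scene,
                      render_stack, segment_objects, size_distribution,
                      fuse_stack, generate_scene, summarize_well)


def _composite_from_image(img, channels=("brightfield",), pixel_size=1.0):
    pixels = np.stack([np.asarray(img, dtype=np.float32)] * len(channels))
    return CompositeImage(pixels=pixels, index_map=np.zeros(img.shape, dtype=int),
                          pixel_size=pixel_size, channel_names=list(channels))


def _disk(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return np.clip(r + 0.5 - np.hypot(yy + 0.5 - cy, xx + 0.5 - cx), 0.0, 1.0)


class TestSegmentObjects:
    def test_blank_image_yields_no_objects(self):
        comp = _composite_from_image(np.zeros((128, 128)))
        label_map, records = segment_objects(comp, "brightfield")
        assert records == [] and label_map.max() == 0

    def test_noise_only_image_yields_no_objects(self):
        noise = np.abs(np.random.default_rng(0).normal(0.05, 0.01, (256, 256)))
        _, records = segment_objects(_composite_from_image(noise), "brightfield")
        assert records == []

    def test_single_disk_area_and_short_diameter(self):
        img = _disk((128, 128), 64, 64, 25.0)
        _, records = segment_objects(_composite_from_image(img), "brightfield")
        assert len(records) == 1
        rec = records[0]
        assert rec.area == pytest.approx(np.pi * 25.0**2, rel=0.03)
        assert rec.short_diameter == pytest.approx(50.0, rel=0.04)
        assert rec.centroid[0] == pytest.approx(64.0, abs=1.0)

    def test_touching_disks_are_split_by_watershed(self):
        # centers 0.8 x the sum of radii apart -> overlapping footprints
        img = _disk((160, 160), 80, 60, 20.0) + _disk((160, 160), 80, 92, 20.0)
        _, records = segment_objects(_composite_from_image(np.clip(img, 0, 1)),
                                     "brightfield")
        assert len(records) == 2

    def test_min_area_filters_debris(self):
        img = _disk((128, 128), 40, 40, 25.0) + _disk((128, 128), 100, 100, 6.0)
        _, records = segment_objects(_composite_from_image(img), "brightfield",
                                     min_area=314.0)
        assert len(records) == 1

    def test_area_conservation_against_label_map(self):
        img = _disk((160, 160), 50, 50, 20.0) + _disk((160, 160), 110, 110, 15.0)
        label_map, records = segment_objects(_composite_from_image(img),
                                             "brightfield")
        assert sum(r.area for r in records) == pytest.approx(
            np.count_nonzero(label_map), abs=1e-6)

    def test_recall_on_separated_in_focus_objects(self):
        # a grid of well-separated organoids, all at one focal plane
        objs = [SceneObject(id=i * 4 + j, center=(64.0 + 128 * i, 64.0 + 128 * j,
                                                  500.0), diameter=50.0)
                for i in range(4) for j in range(4)]
        scene = Scene(objects=objs, gel_depth=1000.0, xy_extent=(512.0, 512.0))
        plan = plan_zstack(1000.0, 3, round_to=0)
        stack = render_stack(scene, plan, OpticalModel(), channels=("brightfield",),
                             seed=0)
        comp = fuse_stack(stack)
        _, records = segment_objects(comp, "brightfield")
        assert len(records) == 16  # >= 99% recall requirement at full separation


class TestLabelingRate:
    def test_all_dark_records_rate_zero(self):
        records = [ObjectRecord(id=i, centroid=(0, 0), area=400.0,
                                short_diameter=20.0, mean_green=0.0)
                   for i in range(5)]
        assert labeling_rate(records) == 0.0

    def test_empty_well_is_an_error_not_zero(self):
        with pytest.raises(EmptyWellError):
            labeling_rate([])

    def test_rate_counts_only_records_above_threshold(self):
        records = [ObjectRecord(id=i, centroid=(0, 0), area=400.0,
                                short_diameter=20.0, mean_green=g)
                   for i, g in enumerate([0.0, 0.5, 1.0, 0.02])]
        assert labeling_rate(records, green_threshold=0.08) == 50.0


class TestOverlapRate:
    def test_single_object_never_overlaps(self):
        scene = generate_scene(1, 100.0, seed=0)
        assert overlap_rate(scene) == 0.0

    def test_forced_intersection_flags_both(self):
        objs = [SceneObject(id=0, center=(100.0, 100.0, 50.0), diameter=100.0),
                SceneObject(id=1, center=(160.0, 100.0, 900.0), diameter=100.0)]
        scene = Scene(objects=objs, gel_depth=1100.0, xy_extent=(512.0, 512.0))
        assert overlap_rate(scene) == 100.0

    def test_expected_overlap_increases_with_density(self):
        rates = []
        volume_um3 = 2000.0 * 2000.0 * 1100.0  # 4.4 uL field
        for density in (2, 8, 20):
            n = int(density * volume_um3 / 1e9)
            vals = [overlap_rate(generate_scene(
                n, 100.0, gel_depth=1100.0, xy_extent=(2000.0, 2000.0), seed=s))
                for s in range(8)]
            rates.append(np.mean(vals))
        assert rates[0] < rates[1] < rates[2]

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(2, 60))
    def test_matches_quadratic_brute_force_exactly(self, seed, n):
        scene = generate_scene(n, (20.0, 100.0), seed=seed)
        objs = scene.objects
        flagged = set()
        for i in range(n):
            for j in range(i + 1, n):
                dx = objs[i].center[0] - objs[j].center[0]
                dy = objs[i].center[1] - objs[j].center[1]
                if np.hypot(dx, dy) < objs[i].radius + objs[j].radius:
                    flagged.update((i, j))
        assert overlap_rate(scene) == pytest.approx(100.0 * len(flagged) / n)

    def test_detected_mode_requires_ground_truth_count(self):
        with pytest.raises(InvalidParameterError):
            overlap_rate([], mode="detected")

    def test_detected_mode_reports_count_deficit(self):
        records = [ObjectRecord(id=i, centroid=(0, 0), area=400.0,
                                short_diameter=20.0) for i in range(8)]
        assert overlap_rate(records, mode="detected", n_true=10) == pytest.approx(20.0)


class TestBackgroundIntensity:
    def test_zero_image_gives_zero(self):
        assert background_intensity(np.zeros((128, 128)), seed=0) == 0.0

    def test_constant_background_recovered(self):
        img = np.full((128, 128), 0.23)
        assert background_intensity(img, seed=0) == pytest.approx(0.23)

    def test_noisy_background_within_sampling_error(self):
        rng = np.random.default_rng(0)
        img = 0.2 + rng.normal(0.0, 0.01, (256, 256))
        est = background_intensity(img, seed=1)
        assert abs(est - 0.2) <= 5 * 0.01 / np.sqrt(9 * 25)

    def test_fully_masked_image_is_an_error(self):
        with pytest.raises(NoBackgroundError):
            background_intensity(np.zeros((64, 64)), np.ones((64, 64)), seed=0)


class TestSizeDistribution:
    def test_empty_records_give_zero_histogram(self):
        counts = size_distribution([], [0, 20, 50, 100])
        assert counts.tolist() == [0, 0, 0]

    def test_identical_objects_occupy_one_bin(self):
        records = [ObjectRecord(id=i, centroid=(0, 0), area=1963.0,
                                short_diameter=50.0) for i in range(7)]
        counts = size_distribution(records, [0, 20, 40, 60, 100])
        assert counts.tolist() == [0, 0, 7, 0]
        assert counts.sum() == len(records)

    def test_unsorted_bins_rejected(self):
        with pytest.raises(InvalidParameterError):
            size_distribution([], [10, 5, 20])


class TestSummaries:
    def test_summary_aggregates_area_and_counts(self):
        scene = generate_scene(10, 50.0, seed=0)
        summary = summarize_well(records_from_scene(scene))
        assert summary.n_objects == 10
        assert summary.total_area == pytest.approx(10 * np.pi * 25.0**2)
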