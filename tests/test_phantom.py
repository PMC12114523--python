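"""The phantom generator: caliber profiles, rendering physics, scenes."""

import math

import numpy as np
import pytest

from caliberkit.phantom import (
    CaliberProfileSpec,
    DividingCellSceneSpec,
    DynamicsEventSpec,
    PhantomSpec,
    eval_caliber_profile,
    render_axon_image,
    render_dividing_scene,
    render_timelapse,
    straight_axon_spec,
    timelapse_caliber_fn,
)


class TestCaliberProfile:
    def test_baseline_only(self):
        spec = CaliberProfileSpec(0.3)
        for s in (0.0, 2.5, 17.0):
            assert eval_caliber_profile(spec, s) == pytest.approx(0.3)

    def test_pearl_peak_value(self):
        spec = CaliberProfileSpec(0.3, pearls=((5.0, 0.4, 0.5),))
        assert eval_caliber_profile(spec, 5.0) == pytest.approx(0.7)

    def test_gaussian_tail_three_widths_out(self):
        # at s = center + 3·width the pearl contributes amp·exp(-4.5)
        spec = CaliberProfileSpec(0.3, pearls=((5.0, 0.4, 0.5),))
        expected = 0.3 + 0.4 * math.exp(-4.5)
        got = eval_caliber_profile(spec, 5.0 + 3 * 0.5)
        assert got == pytest.approx(expected, abs=1e-12)
        assert abs(got - 0.3) / 0.3 < 0.015  # within 1.5% of baseline

    def test_floor_clamps_constrictions(self):
        spec = CaliberProfileSpec(0.3, pearls=((5.0, -0.28, 0.5),), floor_um=0.06)
        assert eval_caliber_profile(spec, 5.0) == pytest.approx(0.06)

    def test_invariants(self):
        with pytest.raises(ValueError):
            CaliberProfileSpec(0.0)
        with pytest.raises(ValueError):
            CaliberProfileSpec(0.3, pearls=((1.0, -0.4, 0.5),))
        with pytest.raises(ValueError):
            CaliberProfileSpec(0.3, pearls=((1.0, 0.4, 0.0),))


class TestRenderAxonImage:
    def test_same_seed_identical(self):
        s1, _ = render_axon_image(straight_axon_spec(8.0, 0.5, rng_seed=9))
        s2, _ = render_axon_image(straight_axon_spec(8.0, 0.5, rng_seed=9))
        assert np.array_equal(s1.pixels, s2.pixels)

    def test_distinct_seeds_differ_only_in_noise(self):
        a, _ = render_axon_image(straight_axon_spec(8.0, 0.5, rng_seed=1))
        b, _ = render_axon_image(straight_axon_spec(8.0, 0.5, rng_seed=2))
        assert not np.array_equal(a.pixels, b.pixels)
        a0, _ = render_axon_image(straight_axon_spec(8.0, 0.5, rng_seed=1, noise=False))
        b0, _ = render_axon_image(straight_axon_spec(8.0, 0.5, rng_seed=2, noise=False))
        assert np.array_equal(a0.pixels, b0.pixels)

    def test_signal_linear_in_label_density(self):
        lo, _ = render_axon_image(
            straight_axon_spec(8.0, 0.5, noise=False, photons_per_um_membrane=1000, background_level=0.0)
        )
        hi, _ = render_axon_image(
            straight_axon_spec(8.0, 0.5, noise=False, photons_per_um_membrane=2000, background_level=0.0)
        )
        assert np.allclose(hi.pixels, 2 * lo.pixels, rtol=1e-9, atol=1e-9)

    def test_transverse_profile_bimodal_at_true_separation(self):
        # two PSF-blurred membrane lines at ±c/2: mode separation equals c
        # within half a pixel once c >= ~2.4 sigma
        spec = straight_axon_spec(8.0, 0.6, noise=False)
        stack, truth = render_axon_image(spec)
        img = stack.channel("axon")[0]
        col = img.shape[1] // 2
        profile = img[:, col]
        peaks = [
            i
            for i in range(1, len(profile) - 1)
            if profile[i] > profile[i - 1] and profile[i] >= profile[i + 1]
            and profile[i] > profile.max() * 0.5
        ]
        assert len(peaks) == 2
        sep = (peaks[1] - peaks[0]) * stack.pixel_size_um
        assert abs(sep - 0.6) <= stack.pixel_size_um / 2 + 1e-9
        assert truth["c_um"].unique() == pytest.approx([0.6])

    def test_field_margin_enforced(self):
        spec = straight_axon_spec(8.0, 0.5, margin_um=0.2)
        with pytest.raises(ValueError, match="margin"):
            render_axon_image(spec)

    def test_ground_truth_sampling(self):
        _, truth = render_axon_image(straight_axon_spec(10.0, 0.4, noise=False))
        assert truth["s_um"].iloc[0] == 0.0
        assert np.allclose(np.diff(truth["s_um"])[:5], 0.1)


class TestTimelapse:
    def test_zero_events_static(self):
        spec = straight_axon_spec(8.0, 0.4, noise=False)
        stack, truth = render_timelapse(spec, [], n_frames=4)
        for t in range(1, 4):
            assert np.array_equal(stack.pixels[t], stack.pixels[0])
        assert stack.frame_interval_min == 5.0

    def test_traveling_pearl_ground_truth_advances(self):
        spec = straight_axon_spec(16.0, 0.25, noise=False)
        ev = DynamicsEventSpec(
            "traveling_pearl",
            dict(center_s_um=3.0, amplitude_um=0.4, width_s_um=0.6, speed_um_per_frame=1.0),
        )
        _, truth = render_timelapse(spec, [ev], n_frames=6)
        for t in range(6):
            g = truth[truth.frame == t]
            s_max = g.loc[g["c_um"].idxmax(), "s_um"]
            assert s_max == pytest.approx(3.0 + t, abs=0.1)

    def test_widening_scales_span_mean(self):
        spec = straight_axon_spec(14.0, 0.3, noise=False)
        ev = DynamicsEventSpec(
            "segment_widening_narrowing",
            dict(span_um=(4.0, 10.0), scale_factor=1.5, start_frame=1, rise_frames=1,
                 hold_frames=10, fall_frames=1),
        )
        _, truth = render_timelapse(spec, [ev], n_frames=5)
        g0 = truth[(truth.frame == 0) & truth.s_um.between(4, 10)]["c_um"].mean()
        g3 = truth[(truth.frame == 3) & truth.s_um.between(4, 10)]["c_um"].mean()
        assert g3 / g0 == pytest.approx(1.5, rel=1e-6)

    def test_constriction_toggles(self):
        spec = straight_axon_spec(10.0, 0.45, noise=False)
        ev = DynamicsEventSpec(
            "constriction_point",
            dict(center_s_um=5.0, depth_um=0.2, width_s_um=0.5, on_frames=(2,)),
        )
        fn = timelapse_caliber_fn(spec, [ev], 4, 10.0)
        assert fn(5.0, 2) == pytest.approx(0.25)
        for t in (0, 1, 3):
            assert fn(5.0, t) == pytest.approx(0.45)

    def test_event_outside_segment_rejected(self):
        spec = straight_axon_spec(10.0, 0.3)
        ev = DynamicsEventSpec(
            "traveling_pearl",
            dict(center_s_um=8.0, amplitude_um=0.3, width_s_um=0.5, speed_um_per_frame=2.0),
        )
        with pytest.raises(ValueError, match="leaves the segment"):
            render_timelapse(spec, [ev], n_frames=5)

    def test_unknown_event_class_rejected(self):
        with pytest.raises(ValueError, match="event_class"):
            DynamicsEventSpec("wiggle", {})


def small_scene(**kw):
    defaults = dict(
        flat_length_um=10.0,
        flat_height_um=1.0,
        round_length_um=7.0,
        round_height_um=3.5,
        border_schedule_um=(8.0, 7.4, 9.8, 10.0),
        neighbor_length_um=5.0,
    )
    defaults.update(kw)
    return DividingCellSceneSpec(**defaults)


def scene_axon(seed=0, width=26.0, caliber=0.3):
    spec = straight_axon_spec(width, caliber, rng_seed=seed)
    h = 9.0
    spec.field_size_um = (width + 4.0, h)
    spec.centerline_points_um = np.array([[1.0, h / 2], [width + 3.0, h / 2]])
    return spec


class TestDividingScene:
    def test_round_flat_frames_from_schedule(self):
        r = render_dividing_scene(small_scene(), scene_axon())
        assert (r.round_frame, r.flat_frame) == (1, 2)  # largest jump 7.4 -> 9.8
        assert np.allclose(r.border_lengths_um, (8.0, 7.4, 9.8, 10.0))

    def test_monotone_schedule_monotone_lengths(self):
        r = render_dividing_scene(
            small_scene(border_schedule_um=(7.0, 8.0, 9.0, 10.0)), scene_axon()
        )
        assert np.all(np.diff(r.border_lengths_um) > 0)

    def test_caliber_offset_in_ground_truth(self):
        r = render_dividing_scene(
            small_scene(dividing_caliber_offset_um=0.06), scene_axon(caliber=0.25)
        )
        t0 = r.truth[r.truth.frame == 0]
        on = t0[t0.region == "dividing"]["c_um"]
        off = t0[t0.region == "neighbor1"]["c_um"]
        assert on.max() == pytest.approx(0.31, abs=0.005)
        assert off.min() == pytest.approx(0.25, abs=0.005)

    def test_two_channels_with_roles(self):
        r = render_dividing_scene(small_scene(), scene_axon())
        assert r.stack.pixels.shape[-1] == 2
        assert set(r.stack.channel_roles) == {"axon", "cell"}

    def test_geometry_invariants_enforced(self):
        with pytest.raises(ValueError, match="round length"):
            small_scene(round_length_um=11.0)
        with pytest.raises(ValueError, match="round height"):
            small_scene(round_height_um=0.5)

    def test_axon_must_cross_all_regions(self):
        spec = scene_axon()
        spec.centerline_points_um = np.array([[1.0, 4.5], [6.0, 4.5]])
        with pytest.raises(ValueError, match="cross"):
            render_dividing_scene(small_scene(), spec)
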