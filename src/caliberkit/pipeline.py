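"""End-to-end study pipelines over synthetic scenes with known ground truth.

Each function here simulates one of the study designs at its default
conditions, runs the full measurement path on the rendered images, and
returns both the measured quantities and the generator's ground truth so
recovery can be quantified.  The analysis drivers under ``analysis/`` and
the acceptance machinery all call these entry points; nothing below reaches
into simulator internals for its "measured" numbers.

Default study conditions
------------------------
- branch scene: (P, S1, S2) = (0.43, 0.32, 0.20) µm, the cohort means of
  the segment calibers at the most proximal branch point
- lengthwise profile: 0.25 µm baseline with Gaussian pearls of ~0.35 µm
  amplitude (distinctly pearled morphology)
- time lapse: 5-min frame interval, 12 frames, mean caliber 0.45 µm
- dividing-cell scene: 0.25 µm axon crossing a mitotic basal cell with a
  +0.06 µm caliber offset over the dividing territory
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .branching import SegmentUnmeasurable, assign_triplet, cohort_summaries, segment_mean_caliber
from .config import RunConfig
from .dynamics import (
    border_to_border,
    dynamicity,
    group_by_region,
    pair_days,
    pearling_index,
    round_flat_pairing,
    select_round_flat,
)
from .geometry import build_centerline
from .io import stage, write_results
from .measure import measure_at, measure_lengthwise, measure_timeseries
from .phantom import (
    BranchSceneRender,
    CaliberProfileSpec,
    DividingCellSceneSpec,
    DividingSceneRender,
    DynamicsEventSpec,
    PhantomSpec,
    render_branch_scene,
    render_dividing_scene,
    render_timelapse,
    straight_axon_spec,
)
from .stats import PairedSample, mann_whitney_u, paired_mean_difference_ci, paired_permutation_test

logger = logging.getLogger("caliberkit")

__all__ = [
    "measure_branch_scene",
    "simulate_branch_cohort",
    "simulate_lengthwise_profile",
    "two_level_sequence",
    "simulate_rsd_recovery",
    "simulate_event_signatures",
    "measure_dividing_scene",
    "simulate_dividing_study",
    "simulate_day_pairing",
    "run_demo_pipeline",
]


# --------------------------------------------------------------------------
# branch-point study
# --------------------------------------------------------------------------


def measure_branch_scene(scene: BranchSceneRender, config: RunConfig) -> dict:
    """Segment calibers (3/4/5 µm averages) and the derived triplet."""
    stack = scene.stack
    means = {}
    for label in ("P", "Sa", "Sb"):
        pl = scene.annotations.centerline(label, 0)
        cl = build_centerline(pl.vertices, config.centerline_step_um, config.tangent_smooth_um)
        cl.set_anchor(scene.annotations.branch_points[0].xy_um)
        ms = [
            measure_at(stack, cl, 0, cl.anchor_s + off, config)
            for off in config.branch_offsets_um
        ]
        means[label] = segment_mean_caliber(ms)
    triplet = assign_triplet(means["P"], means["Sa"], means["Sb"])
    return {"segment_means": means, "triplet": triplet}


def simulate_branch_cohort(
    seed: int,
    config: RunConfig | None = None,
    n_axons: int = 8,
    mean_calibers: tuple[float, float, float] = (0.43, 0.32, 0.20),
    spread: float = 0.05,
) -> dict:
    """Render and measure a small cohort of branch scenes.

    Per-axon true calibers jitter around the cohort means with SD
    ``spread`` (clipped to stay well above the resolution limit), the
    between-axon variability of segment calibers.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    measured, truth = [], []
    n_excluded = 0
    for i in range(n_axons):
        p, s1, s2 = np.clip(
            rng.normal(mean_calibers, spread), 0.18, 1.4
        )
        s1, s2 = max(s1, s2), min(s1, s2)
        scene = render_branch_scene(p, s1, s2, rng_seed=int(rng.integers(2**31)))
        try:
            res = measure_branch_scene(scene, config)
        except SegmentUnmeasurable:
            # a segment entirely below the resolution limit excludes the
            # branch point, the same rule applied to real acquisitions
            n_excluded += 1
            logger.info("branch cohort: axon %d excluded (segment unresolvable)", i)
            continue
        measured.append(res["triplet"])
        truth.append(assign_triplet(p, s1, s2))
    if len(measured) < 2:
        raise RuntimeError("fewer than 2 measurable branch scenes in the cohort")
    return {
        "measured": measured,
        "truth": truth,
        "n_excluded": n_excluded,
        "measured_summary": cohort_summaries(measured),
        "truth_summary": cohort_summaries(truth),
    }


# --------------------------------------------------------------------------
# lengthwise (pearling) study
# --------------------------------------------------------------------------


def simulate_lengthwise_profile(
    seed: int,
    config: RunConfig | None = None,
    length_um: float = 20.0,
    baseline_um: float = 0.25,
    pearls: tuple = ((5.0, 0.35, 0.8), (11.0, 0.3, 1.0), (16.0, 0.35, 0.7)),
) -> dict:
    """Pearled straight axon: lengthwise series vs ground-truth profile."""
    config = config or RunConfig()
    profile = CaliberProfileSpec(baseline_um, pearls)
    spec = straight_axon_spec(length_um, profile, rng_seed=seed)
    from .phantom import render_axon_image

    stack, truth = render_axon_image(spec)
    pl = spec.centerline_points_um
    cl = build_centerline(pl, config.centerline_step_um, config.tangent_smooth_um)
    series = measure_lengthwise(stack, cl, 0, config, anchors_s=[])
    used_s = np.array([m.s_um for m in series.measurements if not m.below_limit])
    true_at_stations = profile(used_s)
    return {
        "series": series,
        "truth_profile": truth,
        "pearling_measured": pearling_index(series),
        "pearling_truth": float(np.std(true_at_stations, ddof=1)),
        "stations_s_um": used_s,
        "true_at_stations": true_at_stations,
    }


# --------------------------------------------------------------------------
# dynamicity (%RSD) study
# --------------------------------------------------------------------------


def two_level_sequence(
    mean_um: float, rsd_percent: float, n_frames: int = 12, n_high: int = 4
) -> np.ndarray:
    """A caliber schedule with an exact sample %RSD.

    ``n_high`` frames sit above the mean and the rest below, scaled so the
    sample SD over frames divided by the mean equals ``rsd_percent``/100 —
    a skewed fluctuation pattern that keeps every value resolvable even at
    high relative dynamicity.
    """
    if not 0 < n_high < n_frames:
        raise ValueError("n_high must be strictly between 0 and n_frames")
    pattern = -np.ones(n_frames)
    high_at = np.unique(np.linspace(1, n_frames - 1, n_high).round().astype(int))
    pattern[high_at] = (n_frames - len(high_at)) / len(high_at)  # zero mean
    sd_p = float(np.std(pattern, ddof=1))
    amp = (rsd_percent / 100.0) * mean_um / sd_p
    return mean_um + amp * pattern


def simulate_rsd_recovery(
    seed: int,
    config: RunConfig | None = None,
    targets_percent: tuple[float, ...] = (10.0, 30.0, 60.0),
    mean_um: float = 0.45,
    n_frames: int = 12,
) -> dict:
    """Render 5-min time lapses with prescribed %RSD and re-measure them."""
    config = config or RunConfig()
    out = {}
    for k, target in enumerate(targets_percent):
        c_t = two_level_sequence(mean_um, target, n_frames)
        spec = straight_axon_spec(8.0, mean_um, rng_seed=seed + 7 * k + 1)
        stack, truth = render_timelapse(
            spec, [], n_frames, caliber_fn=lambda s, t: np.full_like(np.asarray(s, float), c_t[t])
        )
        cl = build_centerline(spec.centerline_points_um, config.centerline_step_um)
        cl.anchor_s = 0.0
        series = measure_timeseries(stack, cl, 4.0, config)
        summ = dynamicity(series, config)
        used = [m.frame for m in series.measurements if not m.below_limit]
        truth_rsd = 100.0 * np.std(c_t[used], ddof=1) / np.mean(c_t[used])
        out[target] = {
            "measured_rsd": summ.rsd_percent,
            "truth_rsd": float(truth_rsd),
            "truth_rsd_nominal": float(target),
            "series": series,
            "summary": summ,
        }
    return out


def simulate_event_signatures(seed: int, config: RunConfig | None = None) -> dict:
    """Render one time lapse per dynamics class and extract its signature.

    Signatures (all from *measured* series): a traveling pearl advances the
    lengthwise caliber maximum at its speed; focal inflation/deflation is a
    transient rise at the event center; segment widening scales the mean
    caliber over the span; a constriction point is a transient dip.
    """
    config = config or RunConfig()
    n_frames = 8
    out = {}

    # traveling pearl, 1 µm/frame
    spec = straight_axon_spec(16.0, 0.25, rng_seed=seed + 11)
    ev = DynamicsEventSpec(
        "traveling_pearl",
        dict(center_s_um=4.0, amplitude_um=0.4, width_s_um=0.7, speed_um_per_frame=1.0),
    )
    stack, _ = render_timelapse(spec, [ev], n_frames)
    cl = build_centerline(spec.centerline_points_um, config.centerline_step_um)
    argmax_s = []
    for t in range(n_frames):
        series = measure_lengthwise(stack, cl, t, config, anchors_s=[])
        vals = [(m.s_um, m.caliber_um) for m in series.measurements if not m.below_limit]
        argmax_s.append(max(vals, key=lambda v: v[1])[0])
    speed = float(np.polyfit(np.arange(n_frames), argmax_s, 1)[0])
    out["traveling_pearl"] = {"argmax_s_um": argmax_s, "speed_um_per_frame": speed}

    # focal inflation/deflation at a fixed station
    spec = straight_axon_spec(10.0, 0.25, rng_seed=seed + 23)
    ev = DynamicsEventSpec(
        "focal_inflation_deflation",
        dict(center_s_um=5.0, amplitude_um=0.35, width_s_um=0.8, start_frame=0,
             rise_frames=3, fall_frames=3),
    )
    stack, _ = render_timelapse(spec, [ev], n_frames)
    cl = build_centerline(spec.centerline_points_um, config.centerline_step_um)
    cl.anchor_s = 0.0
    series = measure_timeseries(stack, cl, 5.0, config)
    vals = np.array([m.caliber_um for m in series.measurements])
    out["focal_inflation_deflation"] = {
        "series_um": vals,
        "peak_frame": int(np.nanargmax(vals)),
        "rise_um": float(np.nanmax(vals) - vals[0]),
        "returns_um": float(abs(vals[-1] - vals[0])),
    }

    # segment widening ×1.5
    spec = straight_axon_spec(14.0, 0.3, rng_seed=seed + 37)
    ev = DynamicsEventSpec(
        "segment_widening_narrowing",
        dict(span_um=(4.0, 10.0), scale_factor=1.5, start_frame=1, rise_frames=1,
             hold_frames=n_frames, fall_frames=1),
    )
    stack, _ = render_timelapse(spec, [ev], n_frames)
    cl = build_centerline(spec.centerline_points_um, config.centerline_step_um)

    def span_mean(t):
        series = measure_lengthwise(stack, cl, t, config, anchors_s=[])
        vals = [
            m.caliber_um
            for m in series.measurements
            if not m.below_limit and 4.0 <= m.s_um <= 10.0
        ]
        return float(np.mean(vals))

    before, during = span_mean(0), span_mean(4)
    out["segment_widening_narrowing"] = {
        "span_mean_before_um": before,
        "span_mean_during_um": during,
        "scale_measured": during / before,
    }

    # transient constriction
    spec = straight_axon_spec(10.0, 0.45, rng_seed=seed + 53)
    ev = DynamicsEventSpec(
        "constriction_point",
        dict(center_s_um=5.0, depth_um=0.22, width_s_um=0.6, on_frames=(3, 4)),
    )
    stack, _ = render_timelapse(spec, [ev], n_frames)
    cl = build_centerline(spec.centerline_points_um, config.centerline_step_um)
    cl.anchor_s = 0.0
    series = measure_timeseries(stack, cl, 5.0, config)
    vals = np.array([m.caliber_um for m in series.measurements])
    out["constriction_point"] = {
        "series_um": vals,
        "dip_frame": int(np.nanargmin(vals)),
        "dip_um": float(vals[0] - np.nanmin(vals)),
    }
    return out


# --------------------------------------------------------------------------
# dividing-cell study
# --------------------------------------------------------------------------


def default_dividing_scene(
    dividing_offset_um: float = 0.06,
    flat_deflation_um: float = 0.03,
    baseline_um: float = 0.25,
    seed: int = 0,
) -> tuple[DividingCellSceneSpec, PhantomSpec]:
    """The default mitotic-rounding scene: shrink-then-jump border schedule."""
    scene = DividingCellSceneSpec(
        flat_length_um=12.0,
        flat_height_um=1.0,
        round_length_um=8.2,
        round_height_um=4.0,
        border_schedule_um=(9.5, 9.0, 8.6, 8.2, 11.6, 12.0),
        neighbor_length_um=7.0,
        dividing_caliber_offset_um=dividing_offset_um,
        flat_deflation_um=flat_deflation_um,
    )
    width = 32.0
    axon = straight_axon_spec(width - 2.0, baseline_um, margin_um=2.0, rng_seed=seed)
    axon.field_size_um = (width + 2.0, 6.0 + 4.0)
    # re-center the axon across the full field height
    h = axon.field_size_um[1]
    axon.centerline_points_um = np.array([[1.0, h / 2.0], [width + 1.0, h / 2.0]])
    return scene, axon


def measure_dividing_scene(render: DividingSceneRender, config: RunConfig) -> dict:
    """Measure every frame of a dividing-cell scene.

    Returns per-frame lengthwise series, per-station region labels (polygon
    containment, dividing-cell priority at exact borders), and the measured
    border-to-border lengths.
    """
    stack = render.stack
    pl = render.annotations.centerline("axon", 0)
    cl = build_centerline(pl.vertices, config.centerline_step_um, config.tangent_smooth_um)
    from shapely.geometry import Point, Polygon

    series_by_frame, regions_by_frame, b2b = [], [], []
    for t in range(stack.n_frames):
        series = measure_lengthwise(stack, cl, t, config, anchors_s=[])
        borders = render.annotations.borders_for_frame(t)
        polys = {lab: Polygon(p.vertices) for lab, p in borders.items()}
        regions = []
        for m in series.measurements:
            pt = Point(cl.frame_at(m.s_um)[0])
            if polys["dividing"].covers(pt):  # border ties go to the dividing cell
                regions.append("dividing")
            elif polys["neighbor1"].covers(pt):
                regions.append("neighbor1")
            elif polys["neighbor2"].covers(pt):
                regions.append("neighbor2")
            else:
                regions.append("outside")
        series_by_frame.append(series)
        regions_by_frame.append(regions)
        b2b.append(border_to_border(pl.vertices, borders["dividing"].vertices))
    return {
        "series_by_frame": series_by_frame,
        "regions_by_frame": regions_by_frame,
        "border_lengths_um": np.asarray(b2b),
        "centerline": cl,
    }


def simulate_dividing_study(
    seed: int,
    config: RunConfig | None = None,
    dividing_offset_um: float = 0.06,
    flat_deflation_um: float = 0.03,
) -> dict:
    """Full dividing-cell analysis on one rendered scene.

    Groups round-frame calibers by territory and runs the Mann–Whitney
    comparisons; selects the round/flat frames from the *measured*
    border-to-border lengths; pairs stations across the transition for the
    permutation test and the pearling-change pair.
    """
    config = config or RunConfig()
    scene_spec, axon_spec = default_dividing_scene(
        dividing_offset_um, flat_deflation_um, seed=seed
    )
    render = render_dividing_scene(scene_spec, axon_spec)
    meas = measure_dividing_scene(render, config)

    sel = select_round_flat(meas["border_lengths_um"])
    groups = group_by_region(
        meas["series_by_frame"][sel.round_frame], meas["regions_by_frame"][sel.round_frame]
    )
    comparisons = {
        "dividing_vs_neighbor1": mann_whitney_u(groups["dividing"], groups["neighbor1"]),
        "dividing_vs_neighbor2": mann_whitney_u(groups["dividing"], groups["neighbor2"]),
        "neighbor1_vs_neighbor2": mann_whitney_u(groups["neighbor1"], groups["neighbor2"]),
    }
    pairing = round_flat_pairing(
        meas["series_by_frame"][sel.round_frame],
        meas["series_by_frame"][sel.flat_frame],
        meas["regions_by_frame"][sel.round_frame],
        meas["regions_by_frame"][sel.flat_frame],
    )
    perm = (
        paired_permutation_test(PairedSample(pairing["differences"]), seed=seed)
        if pairing["differences"].size >= 2
        else None
    )
    return {
        "render": render,
        "measurement": meas,
        "selection": sel,
        "groups": groups,
        "comparisons": comparisons,
        "pairing": pairing,
        "round_flat_permutation": perm,
        "truth": {
            "round_frame": render.round_frame,
            "flat_frame": render.flat_frame,
            "border_lengths_um": render.border_lengths_um,
            "dividing_offset_um": dividing_offset_um,
            "flat_deflation_um": flat_deflation_um,
        },
    }


# --------------------------------------------------------------------------
# developmental (day-1 vs day-2) dynamicity pairing
# --------------------------------------------------------------------------


def simulate_day_pairing(
    seed: int,
    config: RunConfig | None = None,
    n_locations: int = 6,
    rsd_day1_percent: float = 28.0,
    rsd_day2_percent: float = 20.0,
    n_frames: int = 10,
) -> dict:
    """Two imaging sessions a day apart at matched locations.

    Day-2 relative dynamicity is lower at all but one location, emulating
    the developmental decline; each location is an independently rendered
    station time series.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    decline = rsd_day1_percent - rsd_day2_percent
    day1, day2 = {}, {}
    for i in range(n_locations):
        loc = f"loc{i}"
        r1 = rsd_day1_percent + rng.normal(0, 3)
        # paired decline per location; one location bucks the trend
        r2 = r1 + 3.0 if i == n_locations - 1 else r1 - decline + rng.normal(0, 1.5)
        for day, r, store in ((1, r1, day1), (2, r2, day2)):
            c_t = two_level_sequence(0.45, max(r, 4.0), n_frames)
            spec = straight_axon_spec(8.0, 0.45, rng_seed=int(rng.integers(2**31)))
            stack, _ = render_timelapse(
                spec, [], n_frames,
                caliber_fn=lambda s, t, c_t=c_t: np.full_like(np.asarray(s, float), c_t[t]),
            )
            cl = build_centerline(spec.centerline_points_um, config.centerline_step_um)
            cl.anchor_s = 0.0
            series = measure_timeseries(stack, cl, 4.0, config)
            store[loc] = dynamicity(series, config)
    paired = pair_days(day1, day2)
    perm = paired_permutation_test(PairedSample(paired["delta"].to_numpy()), seed=seed)
    est = paired_mean_difference_ci(
        PairedSample(paired["delta"].to_numpy()), reps=config.bootstrap_reps, seed=seed
    )
    return {
        "paired": paired,
        "n_decreased": int((paired["delta"] < 0).sum()),
        "permutation": perm,
        "estimation": est,
    }


# --------------------------------------------------------------------------
# one-command demo pipeline
# --------------------------------------------------------------------------


def run_demo_pipeline(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """simulate → measure → branch/dynamics/divide → stats, on seeded scenes.

    Writes the measurement and statistics tables under ``outdir`` when
    given, and returns a summary dict comparing every measured quantity to
    the generator's ground truth.
    """
    config = RunConfig(rng_seed=seed)
    out: dict = {"seed": seed}

    with stage("branch cohort"):
        branch = simulate_branch_cohort(seed, config, n_axons=6)
    mt, tt = branch["measured_summary"], branch["truth_summary"]
    out["branch"] = {
        "measured_taper_area_ratio": mt["mean_taper_area_ratio"],
        "truth_taper_area_ratio": tt["mean_taper_area_ratio"],
        "measured_symmetry": mt["mean_symmetry"],
        "truth_symmetry": tt["mean_symmetry"],
        "measured_pooled_s_over_p": mt["mean_pooled_s_over_p"],
        "truth_pooled_s_over_p": tt["mean_pooled_s_over_p"],
    }

    with stage("lengthwise pearling"):
        lengthwise = simulate_lengthwise_profile(seed + 1, config)
    out["pearling"] = {
        "measured_sd_um": lengthwise["pearling_measured"],
        "truth_sd_um": lengthwise["pearling_truth"],
    }

    with stage("dynamicity"):
        rsd = simulate_rsd_recovery(seed + 2, config)
    out["rsd"] = {
        t: {"measured": r["measured_rsd"], "truth": r["truth_rsd"]} for t, r in rsd.items()
    }

    with stage("day pairing"):
        days = simulate_day_pairing(seed + 3, config)
    out["days"] = {
        "n_decreased": days["n_decreased"],
        "n_locations": len(days["paired"]),
        "permutation_p": days["permutation"].p_value,
        "mean_delta_rsd": days["estimation"].effect_size,
        "ci": (days["estimation"].ci_low, days["estimation"].ci_high),
    }

    with stage("dividing cell"):
        div = simulate_dividing_study(seed + 4, config)
    groups = div["groups"]
    out["dividing"] = {
        "mean_dividing_um": float(np.mean(groups["dividing"])),
        "mean_neighbor1_um": float(np.mean(groups["neighbor1"])),
        "mean_neighbor2_um": float(np.mean(groups["neighbor2"])),
        "p_dividing_vs_neighbor1": div["comparisons"]["dividing_vs_neighbor1"].p_value,
        "p_dividing_vs_neighbor2": div["comparisons"]["dividing_vs_neighbor2"].p_value,
        "p_neighbor1_vs_neighbor2": div["comparisons"]["neighbor1_vs_neighbor2"].p_value,
        "round_frame": div["selection"].round_frame,
        "truth_round_frame": div["truth"]["round_frame"],
        "mean_round_flat_difference_um": float(np.mean(div["pairing"]["differences"])),
        "truth_flat_deflation_um": div["truth"]["flat_deflation_um"],
        "border_length_max_error_um": float(
            np.max(np.abs(div["measurement"]["border_lengths_um"] - div["truth"]["border_lengths_um"]))
        ),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_results(mt["table"], outdir / "branch_triplets.csv")
        write_results(
            pd.DataFrame(lengthwise["series"].to_records(axon_id="lengthwise")),
            outdir / "lengthwise_measurements.csv",
        )
        write_results(days["paired"], outdir / "day_pairing.csv")
        stats_rows = [
            days["permutation"].to_record("rsd_day2_vs_day1"),
            days["estimation"].to_record("rsd_day2_vs_day1"),
        ]
        for name, tr in div["comparisons"].items():
            stats_rows.append(tr.to_record(name))
        if div["round_flat_permutation"] is not None:
            stats_rows.append(div["round_flat_permutation"].to_record("round_vs_flat"))
        write_results(pd.DataFrame(stats_rows), outdir / "stats_table.csv")
    return out
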