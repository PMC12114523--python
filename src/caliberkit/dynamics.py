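"""Time-domain and dividing-cell analyses.

Dynamicity of a caliber time series is summarized two ways: absolute
(sample SD of the per-frame calibers at a fixed location) and relative
(%RSD = 100·SD/mean), computed over non-flagged frames.  Pearling of a
lengthwise profile is the sample SD of calibers at the 1 µm stations.

For the dividing-cell experiment, axon stations are grouped by the cell
territory beneath them ({dividing, neighbor1, neighbor2}); the
border-to-border length is the straight-line distance between the two
points where the axon crosses the dividing territory's border; and the
round → flat transition is the consecutive frame pair with the largest
increase in border-to-border length.  A circular-arc model turns the
rounded cell's planar extent (chord ℓ) and height (sagitta h) into the
theoretical axon path length across the rounded surface, compared with the
flat path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .config import RunConfig
from .measure import CaliberSeries, apply_series_exclusion

logger = logging.getLogger("caliberkit")

__all__ = [
    "DynamicitySummary",
    "ArcModel",
    "RoundFlatSelection",
    "SeriesUnmeasurable",
    "dynamicity",
    "pair_days",
    "pearling_index",
    "group_by_region",
    "border_to_border",
    "select_round_flat",
    "round_flat_pairing",
    "arc_path_ratio",
]


class SeriesUnmeasurable(ValueError):
    """Too few usable (non-flagged) measurements to summarize."""


@dataclass
class DynamicitySummary:
    """Mean caliber, absolute (SD) and relative (%RSD) dynamicity."""

    mean_caliber_um: float
    sd_um: float
    rsd_percent: float
    n_frames_used: int
    excluded: bool = False


def dynamicity(series: CaliberSeries, config: RunConfig | None = None) -> DynamicitySummary:
    """Summarize a caliber time series at one location.

    Requires ≥ 3 non-flagged frames.  When a config is given, the series
    exclusion rule (> 20% flagged by default) sets the ``excluded`` flag;
    excluded summaries must not enter cross-condition comparisons.
    """
    vals = series.values()
    if vals.size < 3:
        raise SeriesUnmeasurable(
            f"only {vals.size} usable frames (need >= 3) at {series.label or 'location'}"
        )
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    excluded = apply_series_exclusion(series, config) if config is not None else False
    return DynamicitySummary(mean, sd, 100.0 * sd / mean, int(vals.size), excluded)


def pair_days(
    day1: dict[str, DynamicitySummary], day2: dict[str, DynamicitySummary]
) -> pd.DataFrame:
    """Pair per-location dynamicity between the first and second day.

    Locations missing on either day or excluded by the below-resolution
    rule are dropped (counts logged).  Returns rows
    (location, rsd_day1, rsd_day2, delta) feeding the paired permutation
    test; ``delta`` = day2 − day1.
    """
    rows = []
    dropped = 0
    for loc in sorted(set(day1) | set(day2)):
        a, b = day1.get(loc), day2.get(loc)
        if a is None or b is None or a.excluded or b.excluded:
            dropped += 1
            continue
        rows.append(
            {
                "location": loc,
                "rsd_day1": a.rsd_percent,
                "rsd_day2": b.rsd_percent,
                "delta": b.rsd_percent - a.rsd_percent,
            }
        )
    if not rows:
        raise ValueError("no matched locations between days")
    if dropped:
        logger.info("pair_days: dropped %d unmatched/excluded locations", dropped)
    return pd.DataFrame(rows)


def pearling_index(lengthwise: CaliberSeries) -> float:
    """Pearling: sample SD of calibers along the length (non-flagged)."""
    vals = lengthwise.values()
    if vals.size < 3:
        raise SeriesUnmeasurable(f"only {vals.size} usable stations (need >= 3)")
    return float(np.std(vals, ddof=1))


# --------------------------------------------------------------------------
# dividing-cell analyses
# --------------------------------------------------------------------------


def group_by_region(
    series: CaliberSeries, regions: list[str]
) -> dict[str, np.ndarray]:
    """Split station calibers into {dividing, neighbor1, neighbor2} samples.

    ``regions`` is aligned with ``series.measurements`` (one label per
    station, ties at a border already resolved to the dividing cell by the
    labeling convention).  Flagged stations are dropped; empty region
    samples are logged and reported as empty arrays so the caller can skip
    that comparison.
    """
    if len(regions) != len(series.measurements):
        raise ValueError("one region label per measurement required")
    out: dict[str, list[float]] = {}
    for m, r in zip(series.measurements, regions):
        if m.below_limit:
            continue
        out.setdefault(r, []).append(m.caliber_um)
    result = {r: np.asarray(v, float) for r, v in out.items()}
    for r in ("dividing", "neighbor1", "neighbor2"):
        if len(result.get(r, ())) == 0:
            logger.info("group_by_region: region %r has no usable stations", r)
            result.setdefault(r, np.empty(0))
    return result


def border_to_border(axon_path_um, border_polygon_um) -> float:
    """Straight-line distance between the axon's two border crossings.

    ``axon_path_um`` is the axon polyline; ``border_polygon_um`` the
    dividing cell's (or daughters') territory polygon, both in µm.  With
    more than two crossings the two extreme crossings along the path are
    used; fewer than two is an error.
    """
    line = LineString(np.asarray(axon_path_um, float))
    poly = Polygon(np.asarray(border_polygon_um, float))
    crossings = line.intersection(poly.exterior)
    if crossings.is_empty:
        raise ValueError("axon path does not cross the cell border")
    if isinstance(crossings, Point):
        pts = [crossings]
    else:
        pts = [g for g in getattr(crossings, "geoms", [crossings]) if isinstance(g, Point)]
    if len(pts) < 2:
        raise ValueError(f"axon path crosses the border {len(pts)} time(s); need 2")
    pts.sort(key=lambda p: line.project(p))
    return float(pts[0].distance(pts[-1]))


@dataclass
class RoundFlatSelection:
    round_frame: int
    flat_frame: int
    max_increase_um: float
    tie_flag: bool = False

    def __post_init__(self) -> None:
        assert self.flat_frame == self.round_frame + 1


def select_round_flat(lengths_um) -> RoundFlatSelection:
    """The consecutive frame pair with the largest border-length increase.

    Ties pick the earliest pair (flagged); an all-decreasing schedule still
    returns the least-negative step, with a warning, since the transition
    definition degenerates there.
    """
    lengths = np.asarray(lengths_um, float)
    if lengths.size < 2:
        raise ValueError("need at least 2 frames")
    inc = np.diff(lengths)
    k = int(np.argmax(inc))
    tie = bool(np.sum(np.isclose(inc, inc[k])) > 1)
    if inc[k] <= 0:
        logger.warning(
            "select_round_flat: border length never increases (max step %.3g µm)", inc[k]
        )
    return RoundFlatSelection(k, k + 1, float(inc[k]), tie)


def round_flat_pairing(
    series_round: CaliberSeries,
    series_flat: CaliberSeries,
    regions_round: list[str],
    regions_flat: list[str],
    on_regions: tuple[str, ...] = ("dividing",),
) -> dict:
    """Pair station calibers between the round and flat frames.

    Only stations that lie on the dividing cell (or its daughters) in *both*
    frames and are unflagged in both enter the pairs; stations that left the
    territory are dropped and logged.  Returns the paired arrays for the
    permutation test plus the per-frame pearling indices (SD across the
    retained stations).
    """
    r_by_s = {m.s_um: (m, r) for m, r in zip(series_round.measurements, regions_round)}
    f_by_s = {m.s_um: (m, r) for m, r in zip(series_flat.measurements, regions_flat)}
    s_vals, rv, fv = [], [], []
    dropped = 0
    for s in sorted(set(r_by_s) & set(f_by_s)):
        (mr, rr), (mf, rf) = r_by_s[s], f_by_s[s]
        if rr not in on_regions or rf not in on_regions:
            dropped += 1
            continue
        if mr.below_limit or mf.below_limit:
            dropped += 1
            continue
        s_vals.append(s)
        rv.append(mr.caliber_um)
        fv.append(mf.caliber_um)
    if dropped:
        logger.info("round_flat_pairing: dropped %d stations", dropped)
    rv = np.asarray(rv)
    fv = np.asarray(fv)
    pearl = (
        (float(np.std(rv, ddof=1)), float(np.std(fv, ddof=1)))
        if rv.size >= 3
        else (math.nan, math.nan)
    )
    return {
        "s_um": np.asarray(s_vals),
        "round": rv,
        "flat": fv,
        "differences": fv - rv,
        "pearling_round": pearl[0],
        "pearling_flat": pearl[1],
        "n_dropped": dropped,
    }


# --------------------------------------------------------------------------
# circular-arc path model
# --------------------------------------------------------------------------


@dataclass
class ArcModel:
    """Axon path across a rounded cell, modeled as a circular arc.

    The rounded cell presents a chord ℓ (its planar extent) and a sagitta h
    (its height above the flat reference).  The axon, fixed at the cell
    borders and running straight across the surface, follows the arc; the
    flat reference path is the flat cell's planar length.
    """

    chord_um: float
    sagitta_um: float
    arc_length_um: float
    flat_length_um: float
    path_ratio: float


def arc_path_ratio(chord_um: float, sagitta_um: float, flat_length_um: float) -> ArcModel:
    """Arc length over a circular segment and its ratio to the flat path.

    R = (chord²/4 + sagitta²) / (2·sagitta); arc = 2R·arcsin(chord/(2R)).
    A zero sagitta degenerates to the chord.  For sagitta > chord/2 the arc
    passes the semicircle and the reflex arc is used (arc = 2R(π − arcsin)).
    """
    if chord_um <= 0:
        raise ValueError("chord must be positive")
    if sagitta_um < 0:
        raise ValueError("sagitta must be >= 0")
    if flat_length_um < chord_um:
        raise ValueError("flat path cannot be shorter than the chord")
    if sagitta_um == 0:
        arc = chord_um
    else:
        r = (chord_um**2 / 4.0 + sagitta_um**2) / (2.0 * sagitta_um)
        half_angle = math.asin(min(chord_um / (2.0 * r), 1.0))
        if sagitta_um > chord_um / 2.0:  # bulge beyond a semicircle
            half_angle = math.pi - half_angle
        arc = 2.0 * r * half_angle
    return ArcModel(chord_um, sagitta_um, arc, flat_length_um, arc / flat_length_um)
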