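"""Ground-truth phantoms of membrane-labeled axons in larval zebrafish skin.

No imaging data ships with this package, so every measurement routine is
validated against synthetic scenes with known caliber.  The membrane model
is an infinitely thin label sheet: in a 2-D image the axon projects to two
bright boundary lines offset ±c(s)/2 along the centerline normal, which is
what produces the characteristic double-peak line-scan profile of a
membrane-targeted fluorophore (e.g. EGFP-CAAX).  Rendering is 2-D only —
calibers are measured as in-plane peak separations, so a 3-D optical model
adds nothing the measurements would see.

Rendering pipeline per frame: rasterize the two boundary curves with
line-integrated label density (photons per µm of membrane), convolve with
an isotropic Gaussian PSF, add a constant background, then Poisson shot
noise on signal+background plus Gaussian read noise.  Everything is seeded
and reproducible; a noise-free render is available for oracle tests.

Four time-lapse event classes emulate the caliber dynamics observed in
5-minute-interval movies of Rohon–Beard axons: a traveling pearl, focal
inflation/deflation, segment widening/narrowing, and a transient
constriction point.  A separate scene builder emulates an axon crossing a
rounding/flattening (dividing) basal epithelial cell flanked by two
non-dividing neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import Centerline, build_centerline
from .io import AnnotationSet, BranchPoint, CalibratedStack, Polyline

__all__ = [
    "CaliberProfileSpec",
    "PhantomSpec",
    "DynamicsEventSpec",
    "DividingCellSceneSpec",
    "eval_caliber_profile",
    "render_axon_image",
    "render_timelapse",
    "render_dividing_scene",
    "straight_axon_spec",
    "render_branch_scene",
    "BranchSceneRender",
    "DividingSceneRender",
]

EVENT_CLASSES = (
    "traveling_pearl",
    "focal_inflation_deflation",
    "segment_widening_narrowing",
    "constriction_point",
)


# --------------------------------------------------------------------------
# caliber profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CaliberProfileSpec:
    """Caliber along arc length: a baseline plus Gaussian pearls.

    c(s) = max(floor, baseline + Σ amp · exp(−(s − center)² / (2 · width²)))

    Negative amplitudes model constrictions; the floor keeps the tube open.
    """

    baseline_um: float
    pearls: tuple[tuple[float, float, float], ...] = ()  # (center_s, amp, width)
    floor_um: float = 0.04

    def __post_init__(self) -> None:
        if self.baseline_um <= 0:
            raise ValueError("baseline_um must be positive")
        if self.floor_um <= 0:
            raise ValueError("floor_um must be positive")
        object.__setattr__(
            self, "pearls", tuple((float(c), float(a), float(w)) for c, a, w in self.pearls)
        )
        for c, a, w in self.pearls:
            if w <= 0:
                raise ValueError("pearl width must be positive")
            if a < -self.baseline_um:
                raise ValueError("pearl amplitude below -baseline")

    def raw(self, s) -> np.ndarray:
        """Baseline + pearls without the floor clamp (for composition)."""
        s = np.asarray(s, dtype=float)
        c = np.full_like(s, self.baseline_um)
        for center, amp, width in self.pearls:
            c = c + amp * np.exp(-((s - center) ** 2) / (2.0 * width**2))
        return c

    def __call__(self, s) -> np.ndarray:
        return np.maximum(self.raw(s), self.floor_um)


def eval_caliber_profile(spec: CaliberProfileSpec, s) -> np.ndarray | float:
    """Caliber c(s) in µm for scalar or array arc length ``s``."""
    out = spec(s)
    return float(out) if np.ndim(s) == 0 else out


# --------------------------------------------------------------------------
# phantom specification
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """One synthetic axon: geometry, caliber profile, optics and noise.

    Noise defaults approximate a bright membrane label against a dim
    cytoplasmic/autofluorescent background at Airyscan-class resolution;
    ``noise=False`` renders the deterministic expected image.
    """

    centerline_points_um: np.ndarray
    caliber: CaliberProfileSpec
    pixel_size_um: float = 0.04
    psf_sigma_um: float = 0.07
    photons_per_um_membrane: float = 20000.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    field_size_um: tuple[float, float] | None = None  # (width_x, height_y)
    noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.centerline_points_um = np.asarray(self.centerline_points_um, dtype=float)
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.photons_per_um_membrane < 0 or self.background_level < 0:
            raise ValueError("label density and background must be nonnegative")

    def centerline(self, step_um: float | None = None) -> Centerline:
        step = step_um if step_um is not None else self.pixel_size_um / 4.0
        return build_centerline(self.centerline_points_um, step_um=step)


def straight_axon_spec(
    length_um: float = 20.0,
    caliber: CaliberProfileSpec | float = 0.3,
    pixel_size_um: float = 0.04,
    margin_um: float = 2.0,
    **kwargs,
) -> PhantomSpec:
    """A horizontal straight axon centered in an auto-sized field.

    ``margin_um`` is the clearance on every side; it must exceed the scan
    half-length of any planned measurement so that perpendicular line scans
    stay inside the field.
    """
    if not isinstance(caliber, CaliberProfileSpec):
        caliber = CaliberProfileSpec(baseline_um=float(caliber))
    h = 2.0 * margin_um
    pts = np.array([[margin_um, h / 2.0], [margin_um + length_um, h / 2.0]])
    return PhantomSpec(
        pts,
        caliber,
        pixel_size_um=pixel_size_um,
        field_size_um=(length_um + 2 * margin_um, h),
        **kwargs,
    )


# --------------------------------------------------------------------------
# rasterization internals
# --------------------------------------------------------------------------


def _deposit(img: np.ndarray, pts_um: np.ndarray, weights: np.ndarray, px: float) -> None:
    """Bilinear scatter-add of point weights (photons) into an image."""
    col = pts_um[:, 0] / px
    row = pts_um[:, 1] / px
    c0 = np.floor(col).astype(int)
    r0 = np.floor(row).astype(int)
    fc = col - c0
    fr = row - r0
    h, w = img.shape
    if c0.min() < 0 or r0.min() < 0 or c0.max() >= w - 1 or r0.max() >= h - 1:
        raise ValueError("membrane geometry leaves the image field")
    np.add.at(img, (r0, c0), weights * (1 - fr) * (1 - fc))
    np.add.at(img, (r0, c0 + 1), weights * (1 - fr) * fc)
    np.add.at(img, (r0 + 1, c0), weights * fr * (1 - fc))
    np.add.at(img, (r0 + 1, c0 + 1), weights * fr * fc)


def _field_shape(spec: PhantomSpec) -> tuple[int, int]:
    if spec.field_size_um is None:
        pts = spec.centerline_points_um
        chord = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        cmax = float(np.max(spec.caliber(np.linspace(0.0, chord, 64))))
        margin = cmax / 2.0 + 4.0 * spec.psf_sigma_um + 0.5
        w_um = pts[:, 0].max() + margin
        h_um = pts[:, 1].max() + margin
    else:
        w_um, h_um = spec.field_size_um
    return int(round(h_um / spec.pixel_size_um)), int(round(w_um / spec.pixel_size_um))


def _render_signal(
    shape_px: tuple[int, int],
    segments: list[tuple[Centerline, np.ndarray]],
    spec: PhantomSpec,
) -> np.ndarray:
    """Noise-free membrane signal (no background) for labeled tube segments.

    ``segments`` pairs a finely resampled centerline with the caliber value
    at each of its vertices.
    """
    img = np.zeros(shape_px, dtype=float)
    margin = 3.0 * spec.psf_sigma_um
    h_um = shape_px[0] * spec.pixel_size_um
    w_um = shape_px[1] * spec.pixel_size_um
    for cl, c_vals in segments:
        ds = np.gradient(cl.s)
        weights = spec.photons_per_um_membrane * ds
        for side in (+1.0, -1.0):
            pts = cl.vertices + side * 0.5 * c_vals[:, None] * cl.normals
            if (
                pts[:, 0].min() < margin
                or pts[:, 1].min() < margin
                or pts[:, 0].max() > w_um - margin
                or pts[:, 1].max() > h_um - margin
            ):
                raise ValueError(
                    "caliber plus PSF margin exceeds the image field; enlarge "
                    "field_size_um or reposition the centerline"
                )
            _deposit(img, pts, weights, spec.pixel_size_um)
    sigma_px = spec.psf_sigma_um / spec.pixel_size_um
    return gaussian_filter(img, sigma=sigma_px, mode="constant")


def _apply_noise(signal: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    expected = signal + spec.background_level
    if not spec.noise:
        return expected
    noisy = rng.poisson(expected).astype(float)
    noisy += rng.normal(0.0, spec.read_noise_sd, size=expected.shape)
    return np.clip(noisy, 0.0, None)


def _truth_table(cl: Centerline, c_fn, frame: int = 0, step: float = 0.1) -> pd.DataFrame:
    s = np.arange(0.0, cl.length_um + 1e-9, step)
    return pd.DataFrame({"frame": frame, "s_um": s, "c_um": np.asarray(c_fn(s), float)})


# --------------------------------------------------------------------------
# single-frame and time-lapse rendering
# --------------------------------------------------------------------------


def render_axon_image(spec: PhantomSpec) -> tuple[CalibratedStack, pd.DataFrame]:
    """Render one frame; return the stack and ground-truth c(s) at 0.1 µm."""
    shape = _field_shape(spec)
    cl = spec.centerline()
    c_vals = spec.caliber(cl.s)
    signal = _render_signal(shape, [(cl, c_vals)], spec)
    rng = np.random.default_rng(spec.rng_seed)
    pixels = _apply_noise(signal, spec, rng)[None, ...]
    stack = CalibratedStack(pixels, spec.pixel_size_um, 0.0, {"axon": 0})
    return stack, _truth_table(cl, spec.caliber)


# --------------------------------------------------------------------------
# dynamics events
# --------------------------------------------------------------------------


@dataclass
class DynamicsEventSpec:
    """One caliber-dynamics event of the four observed classes.

    Parameters by class (all lengths µm, times in frames):

    - ``traveling_pearl``: center_s_um, amplitude_um, width_s_um,
      speed_um_per_frame, start_frame (default 0)
    - ``focal_inflation_deflation``: center_s_um, amplitude_um, width_s_um,
      start_frame, rise_frames, fall_frames
    - ``segment_widening_narrowing``: span_um=(s0, s1), scale_factor,
      start_frame, rise_frames, hold_frames, fall_frames
    - ``constriction_point``: center_s_um, depth_um, width_s_um, on_frames
      (iterable of frame indices when the constriction is present)
    """

    event_class: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(
                f"event_class {self.event_class!r} not one of {EVENT_CLASSES}"
            )


def _ramp(t: float, start: float, rise: float, hold: float, fall: float) -> float:
    """0→1→0 trapezoid in time; rise/fall of zero frames switch instantly."""
    if t < start:
        return 0.0
    if t < start + rise:
        return (t - start) / rise
    if t <= start + rise + hold:
        return 1.0
    if fall > 0 and t < start + rise + hold + fall:
        return 1.0 - (t - start - rise - hold) / fall
    return 0.0


def _compile_event(ev: DynamicsEventSpec, n_frames: int, length_um: float):
    """Return (extra_pearls(t), scale(s, t)) for one event."""
    p = dict(ev.params)
    kind = ev.event_class

    def no_scale(s, t):
        return 1.0

    if kind == "traveling_pearl":
        c0, amp, w = p["center_s_um"], p["amplitude_um"], p["width_s_um"]
        v = p["speed_um_per_frame"]
        start = p.get("start_frame", 0)
        if amp <= 0 or w <= 0:
            raise ValueError("traveling pearl needs positive amplitude and width")
        for t in range(start, n_frames):
            c_t = c0 + v * (t - start)
            if not 0.0 <= c_t <= length_um:
                raise ValueError(
                    f"traveling pearl leaves the segment at frame {t} (center {c_t:.2f} µm)"
                )

        def pearls(t):
            if t < start:
                return []
            return [(c0 + v * (t - start), amp, w)]

        return pearls, no_scale

    if kind == "focal_inflation_deflation":
        c0, amp, w = p["center_s_um"], p["amplitude_um"], p["width_s_um"]
        start = p.get("start_frame", 0)
        rise = p.get("rise_frames", 2)
        fall = p.get("fall_frames", 2)
        if not 0.0 <= c0 <= length_um:
            raise ValueError("event center outside segment")

        def pearls(t):
            a = amp * _ramp(t, start, rise, 0.0, fall)
            return [(c0, a, w)] if a != 0.0 else []

        return pearls, no_scale

    if kind == "segment_widening_narrowing":
        s0, s1 = p["span_um"]
        factor = p["scale_factor"]
        start = p.get("start_frame", 0)
        rise = p.get("rise_frames", 1)
        hold = p.get("hold_frames", n_frames)
        fall = p.get("fall_frames", 1)
        edge = p.get("edge_um", 0.3)
        if not (0.0 <= s0 < s1 <= length_um):
            raise ValueError("widening span outside segment")

        def scale(s, t):
            f_t = 1.0 + (factor - 1.0) * _ramp(t, start, rise, hold, fall)
            s = np.asarray(s, float)
            # full factor inside [s0, s1]; relaxes to 1 over `edge` µm outside
            inside = np.clip(
                np.minimum((s - (s0 - edge)) / edge, ((s1 + edge) - s) / edge), 0.0, 1.0
            )
            return 1.0 + (f_t - 1.0) * inside

        return (lambda t: []), scale

    # constriction_point
    c0, depth, w = p["center_s_um"], p["depth_um"], p["width_s_um"]
    on = set(int(t) for t in p["on_frames"])
    if depth <= 0:
        raise ValueError("constriction depth must be positive")
    if not 0.0 <= c0 <= length_um:
        raise ValueError("event center outside segment")

    def pearls(t):
        return [(c0, -depth, w)] if t in on else []

    return pearls, no_scale


def timelapse_caliber_fn(
    spec: PhantomSpec, events: list[DynamicsEventSpec], n_frames: int, length_um: float
):
    """c(s, t): the base profile scaled and decorated by the events."""
    compiled = [_compile_event(ev, n_frames, length_um) for ev in events]

    def c_fn(s, t):
        s = np.asarray(s, dtype=float)
        base = spec.caliber.raw(s)
        scale = np.ones_like(s)
        for _pearls, sc in compiled:
            scale = scale * sc(s, t)
        val = base * scale
        for pearls, _sc in compiled:
            for center, amp, width in pearls(t):
                val = val + amp * np.exp(-((s - center) ** 2) / (2.0 * width**2))
        return np.maximum(val, spec.caliber.floor_um)

    return c_fn


def render_timelapse(
    spec: PhantomSpec,
    events: list[DynamicsEventSpec],
    n_frames: int,
    frame_interval_min: float = 5.0,
    caliber_fn=None,
) -> tuple[CalibratedStack, pd.DataFrame]:
    """Render a seeded time lapse; returns the stack and ground-truth c(s, t).

    ``caliber_fn(s, t)`` overrides the event machinery when a test needs a
    directly prescribed caliber schedule (e.g. a target %RSD sequence).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    shape = _field_shape(spec)
    cl = spec.centerline()
    if caliber_fn is None:
        caliber_fn = timelapse_caliber_fn(spec, events, n_frames, cl.length_um)
    rng = np.random.default_rng(spec.rng_seed)
    frames = []
    truths = []
    for t in range(n_frames):
        c_vals = np.asarray(caliber_fn(cl.s, t), dtype=float)
        signal = _render_signal(shape, [(cl, c_vals)], spec)
        frames.append(_apply_noise(signal, spec, rng))
        truths.append(_truth_table(cl, lambda s: caliber_fn(s, t), frame=t))
    stack = CalibratedStack(
        np.stack(frames), spec.pixel_size_um, frame_interval_min, {"axon": 0}
    )
    return stack, pd.concat(truths, ignore_index=True)


# --------------------------------------------------------------------------
# branch scene (primary + two secondaries meeting at a junction)
# --------------------------------------------------------------------------


@dataclass
class BranchSceneRender:
    stack: CalibratedStack
    annotations: AnnotationSet
    truth: dict[str, float]  # segment label -> true caliber (µm)
    junction_um: np.ndarray


def render_branch_scene(
    p_um: float,
    sec_a_um: float,
    sec_b_um: float,
    segment_length_um: float = 7.0,
    margin_um: float = 2.5,
    pixel_size_um: float = 0.04,
    **spec_kwargs,
) -> BranchSceneRender:
    """A Y-shaped scene: primary axon entering a branch point, two sisters.

    Segments leave the junction 120° apart, so line scans 3–5 µm out do not
    graze the sister branch.  Annotation polylines are ordered away from the
    junction, and the branch point itself is exported as an annotation.
    """
    for name, v in (("p", p_um), ("sec_a", sec_a_um), ("sec_b", sec_b_um)):
        if v <= 0:
            raise ValueError(f"{name} caliber must be positive")
    L = segment_length_um
    half = L + margin_um
    junction = np.array([half, half])
    dirs = {
        "P": np.array([-1.0, 0.0]),
        "Sa": np.array([math.cos(math.pi / 3), math.sin(math.pi / 3)]),
        "Sb": np.array([math.cos(-math.pi / 3), math.sin(-math.pi / 3)]),
    }
    calibers = {"P": p_um, "Sa": sec_a_um, "Sb": sec_b_um}
    base = PhantomSpec(
        np.array([junction, junction + dirs["P"] * L]),
        CaliberProfileSpec(p_um),
        pixel_size_um=pixel_size_um,
        field_size_um=(2 * half, 2 * half),
        **spec_kwargs,
    )
    shape = _field_shape(base)
    segments = []
    polylines = []
    for label, d in dirs.items():
        pts = np.array([junction, junction + d * L])
        cl = build_centerline(pts, step_um=pixel_size_um / 4.0)
        segments.append((cl, np.full(len(cl.s), calibers[label])))
        polylines.append(Polyline(label, 0, pts))
    signal = _render_signal(shape, segments, base)
    rng = np.random.default_rng(base.rng_seed)
    pixels = _apply_noise(signal, base, rng)[None, ...]
    stack = CalibratedStack(pixels, pixel_size_um, 0.0, {"axon": 0})
    ann = AnnotationSet(polylines, [BranchPoint(0, junction)], [])
    return BranchSceneRender(stack, ann, calibers, junction)


# --------------------------------------------------------------------------
# dividing-cell scene
# --------------------------------------------------------------------------


@dataclass
class DividingCellSceneSpec:
    """An axon crossing a dividing basal cell flanked by two flat neighbors.

    ``flat_*`` and ``round_*`` give the cell's planar length and (orthogonal)
    height in its flattened and mitotic-rounded states; they feed the
    circular-arc path model.  ``border_schedule_um`` is the border-to-border
    extent of the dividing cell/daughters per frame — it shrinks while the
    cell is round and jumps as the daughters flatten.
    """

    flat_length_um: float
    flat_height_um: float
    round_length_um: float
    round_height_um: float
    border_schedule_um: tuple[float, ...]
    neighbor_length_um: float = 8.0
    cell_band_height_um: float = 6.0
    dividing_caliber_offset_um: float = 0.0
    flat_deflation_um: float = 0.0
    cell_photons_per_um: float = 2000.0

    def __post_init__(self) -> None:
        if not self.round_length_um < self.flat_length_um:
            raise ValueError("round length must be shorter than flat length")
        if not self.round_height_um > self.flat_height_um >= 0:
            raise ValueError("round height must exceed flat height >= 0")
        self.border_schedule_um = tuple(float(v) for v in self.border_schedule_um)
        if len(self.border_schedule_um) < 2:
            raise ValueError("border schedule needs >= 2 frames")
        if min(self.border_schedule_um) <= 0:
            raise ValueError("border lengths must be positive")


@dataclass
class DividingSceneRender:
    stack: CalibratedStack  # 2 channels: axon, cell
    annotations: AnnotationSet  # axon centerline + per-frame border polygons
    truth: pd.DataFrame  # (frame, s_um, c_um, region)
    border_lengths_um: np.ndarray  # ground-truth border-to-border per frame
    round_frame: int
    flat_frame: int
    axon_centerline: Centerline


def _region_for(x: float, b1: float, b2: float, x_left: float, x_right: float) -> str:
    # boundary ties go to the dividing cell
    if b1 <= x <= b2:
        return "dividing"
    if x_left <= x < b1:
        return "neighbor1"
    if b2 < x <= x_right:
        return "neighbor2"
    return "outside"


def render_dividing_scene(
    scene: DividingCellSceneSpec, axon: PhantomSpec, frame_interval_min: float = 5.0
) -> DividingSceneRender:
    """Render the two-channel dividing-cell scene with full ground truth.

    The axon runs straight through all three cell territories; the cell
    channel draws each territory's border polygon per frame.  The axon's
    caliber gains ``dividing_caliber_offset_um`` on the dividing territory
    (smoothed over ~0.3 µm at the borders) and loses ``flat_deflation_um``
    uniformly from the flattening frame onward.
    """
    n_frames = len(scene.border_schedule_um)
    sched = np.asarray(scene.border_schedule_um)
    increments = np.diff(sched)
    round_frame = int(np.argmax(increments))
    flat_frame = round_frame + 1

    shape = _field_shape(axon)
    h_um = shape[0] * axon.pixel_size_um
    w_um = shape[1] * axon.pixel_size_um
    cl = axon.centerline()

    # cell band geometry (µm): dividing cell centered mid-field
    x_c = w_um / 2.0
    y0 = max(h_um / 2.0 - scene.cell_band_height_um / 2.0, 3 * axon.psf_sigma_um)
    y1 = min(h_um / 2.0 + scene.cell_band_height_um / 2.0, h_um - 3 * axon.psf_sigma_um)
    margin_x = 3 * axon.psf_sigma_um + 0.1
    x_left_lim = margin_x
    x_right_lim = w_um - margin_x

    def borders(t: int) -> tuple[float, float]:
        b1 = x_c - sched[t] / 2.0
        b2 = x_c + sched[t] / 2.0
        if b1 - scene.neighbor_length_um < x_left_lim or b2 + scene.neighbor_length_um > x_right_lim:
            raise ValueError("scene geometry exceeds the image field")
        return b1, b2

    # ground-truth caliber: offset on the dividing territory, by arc length
    def c_fn_for(t: int):
        b1, b2 = borders(t)
        edge = 0.3

        def c_fn(s):
            s = np.asarray(s, float)
            base = axon.caliber.raw(s)
            x = np.interp(s, cl.s, cl.vertices[:, 0])
            inside = np.clip(
                np.minimum((x - (b1 - edge)) / edge, ((b2 + edge) - x) / edge), 0.0, 1.0
            )
            val = base + scene.dividing_caliber_offset_um * inside
            if t >= flat_frame:
                val = val - scene.flat_deflation_um
            return np.maximum(val, axon.caliber.floor_um)

        return c_fn

    rng = np.random.default_rng(axon.rng_seed)
    cell_spec = replace(axon, photons_per_um_membrane=scene.cell_photons_per_um)
    frames = []
    truth_rows = []
    border_polys = []
    # verify the axon crosses all three territories at every frame
    x_min, x_max = cl.vertices[:, 0].min(), cl.vertices[:, 0].max()
    for t in range(n_frames):
        b1, b2 = borders(t)
        if not (x_min < b1 and x_max > b2):
            raise ValueError("axon path does not cross all three cell territories")

        c_fn = c_fn_for(t)
        axon_sig = _render_signal(shape, [(cl, np.asarray(c_fn(cl.s)))], axon)
        axon_img = _apply_noise(axon_sig, axon, rng)

        # cell channel: rectangle outlines for the three territories
        cell_img = np.zeros(shape, dtype=float)
        rects = {
            "neighbor1": (b1 - scene.neighbor_length_um, b1),
            "dividing": (b1, b2),
            "neighbor2": (b2, b2 + scene.neighbor_length_um),
        }
        for label, (xa, xb) in rects.items():
            poly = np.array([[xa, y0], [xb, y0], [xb, y1], [xa, y1], [xa, y0]])
            pcl = build_centerline(poly, step_um=axon.pixel_size_um / 4.0)
            ds = np.gradient(pcl.s)
            _deposit(cell_img, pcl.vertices, scene.cell_photons_per_um * ds, axon.pixel_size_um)
            border_polys.append(Polyline(label, t, poly[:-1], closed=True))
        cell_img = gaussian_filter(cell_img, sigma=axon.psf_sigma_um / axon.pixel_size_um, mode="constant")
        cell_img = _apply_noise(cell_img, cell_spec, rng)

        frames.append(np.stack([axon_img, cell_img], axis=-1))

        s_grid = np.arange(0.0, cl.length_um + 1e-9, 0.1)
        x_grid = np.interp(s_grid, cl.s, cl.vertices[:, 0])
        regions = [
            _region_for(x, b1, b2, b1 - scene.neighbor_length_um, b2 + scene.neighbor_length_um)
            for x in x_grid
        ]
        truth_rows.append(
            pd.DataFrame(
                {"frame": t, "s_um": s_grid, "c_um": np.asarray(c_fn(s_grid)), "region": regions}
            )
        )

    stack = CalibratedStack(
        np.stack(frames), axon.pixel_size_um, frame_interval_min, {"axon": 0, "cell": 1}
    )
    ann = AnnotationSet(
        [Polyline("axon", 0, axon.centerline_points_um)], [], border_polys
    )
    return DividingSceneRender(
        stack,
        ann,
        pd.concat(truth_rows, ignore_index=True),
        sched.copy(),
        round_frame,
        flat_frame,
        cl,
    )
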