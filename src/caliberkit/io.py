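"""On-disk artifacts: calibrated image stacks, annotations, result tables.

Images travel as (multi-page) TIFF with an explicit JSON calibration sidecar
(`<file>.tif.json`); physical calibration is never guessed from TIFF
metadata alone — a missing calibration is a hard error, and a sidecar that
contradicts a caller-supplied calibration is also an error, because silent
unit mistakes are the dominant failure mode in morphometry.

Coordinate convention, used everywhere in the package: (x, y) in µm with the
origin at the *center* of pixel (row 0, col 0); x = col·pixel_size,
y = row·pixel_size.  All module boundaries speak µm and minutes; pixel
units never leave this module.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("caliberkit")

__all__ = [
    "CalibratedStack",
    "Polyline",
    "BranchPoint",
    "AnnotationSet",
    "read_stack",
    "write_stack",
    "read_annotations",
    "write_annotations",
    "read_results",
    "write_results",
    "stage",
]


@contextmanager
def stage(name: str):
    """Log wall-clock timing of a pipeline stage to the package logger."""
    t0 = time.perf_counter()
    logger.info("%s: start", name)
    try:
        yield
    finally:
        logger.info("%s: done in %.2f s", name, time.perf_counter() - t0)


# --------------------------------------------------------------------------
# calibrated image stacks
# --------------------------------------------------------------------------


@dataclass
class CalibratedStack:
    """Pixel data plus physical calibration.

    ``pixels`` is (frames, rows, cols) or (frames, rows, cols, channels),
    arbitrary-unit nonnegative intensities.  ``channel_roles`` maps a role
    name ("axon", "cell") to a channel index and must contain "axon".
    ``frame_interval_min`` is 0 for a single-frame acquisition.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_min: float = 0.0
    channel_roles: dict[str, int] = field(default_factory=lambda: {"axon": 0})

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None, ...]
        if self.pixels.ndim not in (3, 4):
            raise ValueError("pixels must be (T,H,W) or (T,H,W,C)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_min < 0:
            raise ValueError("frame_interval_min must be >= 0")
        if self.pixels.shape[0] < 1:
            raise ValueError("stack must have at least one frame")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.min(self.pixels) < 0:
            raise ValueError("intensities must be nonnegative")
        if "axon" not in self.channel_roles:
            raise ValueError('channel_roles must contain "axon"')
        n_ch = self.pixels.shape[3] if self.pixels.ndim == 4 else 1
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_ch:
                raise ValueError(f"channel index {idx} for role {role!r} out of range")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width_x, height_y) of the field in µm."""
        h, w = self.shape_px
        return w * self.pixel_size_um, h * self.pixel_size_um

    def channel(self, role: str = "axon") -> np.ndarray:
        """The (T, H, W) intensity array for a channel role."""
        idx = self.channel_roles[role]
        return self.pixels if self.pixels.ndim == 3 else self.pixels[..., idx]


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: CalibratedStack, path) -> Path:
    """Write a TIFF plus its calibration sidecar; returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_min": stack.frame_interval_min,
        "channel_roles": stack.channel_roles,
        "shape": list(stack.pixels.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(
    path,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
    channel_roles: dict[str, int] | None = None,
) -> CalibratedStack:
    """Read a TIFF stack with calibration from a sidecar and/or arguments.

    Calibration must come from somewhere: either the ``<file>.json`` sidecar
    or explicit arguments.  When both exist they must agree; a mismatch is
    an error rather than a silent preference.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pixels = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc

    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())

    def pick(name, given, caster):
        stored = meta.get(name)
        if given is None and stored is None:
            raise ValueError(
                f"calibration field {name!r} missing: supply it or provide a sidecar"
            )
        if given is not None and stored is not None and caster(given) != caster(stored):
            raise ValueError(
                f"calibration mismatch for {name!r}: argument {given!r} vs sidecar {stored!r}"
            )
        return caster(given if given is not None else stored)

    ps = pick("pixel_size_um", pixel_size_um, float)
    fi = pick(
        "frame_interval_min",
        frame_interval_min,
        float,
    ) if (frame_interval_min is not None or "frame_interval_min" in meta) else 0.0
    roles = channel_roles or meta.get("channel_roles") or {"axon": 0}
    roles = {k: int(v) for k, v in roles.items()}
    if "shape" in meta:
        pixels = pixels.reshape(meta["shape"])
    return CalibratedStack(pixels, ps, fi, roles)


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------


@dataclass
class Polyline:
    """A labeled polyline (µm) on one frame: a centerline or cell border."""

    label: str
    frame: int
    vertices: np.ndarray  # (M, 2) µm
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError(f"polyline {self.label!r}: vertices must be (M, 2)")
        if len(self.vertices) < 2:
            raise ValueError(f"polyline {self.label!r}: needs >= 2 vertices")


@dataclass
class BranchPoint:
    frame: int
    xy_um: np.ndarray

    def __post_init__(self) -> None:
        self.xy_um = np.asarray(self.xy_um, dtype=float).reshape(2)


@dataclass
class AnnotationSet:
    """Centerlines, branch points and optional cell-border polygons (µm)."""

    centerlines: list[Polyline] = field(default_factory=list)
    branch_points: list[BranchPoint] = field(default_factory=list)
    cell_borders: list[Polyline] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for pl in self.centerlines:
            key = (pl.label, pl.frame)
            if key in seen:
                raise ValueError(
                    f"duplicate centerline label {pl.label!r} in frame {pl.frame}"
                )
            seen.add(key)

    def centerline(self, label: str, frame: int = 0) -> Polyline:
        for pl in self.centerlines:
            if pl.label == label and pl.frame == frame:
                return pl
        raise KeyError(f"no centerline {label!r} in frame {frame}")

    def borders_for_frame(self, frame: int) -> dict[str, Polyline]:
        return {pl.label: pl for pl in self.cell_borders if pl.frame == frame}

    def validate_bounds(self, field_size_um: tuple[float, float]) -> None:
        """Check every vertex lies inside [0, W] x [0, H] µm."""
        w, h = field_size_um
        for group in (self.centerlines, self.cell_borders):
            for pl in group:
                for i, (x, y) in enumerate(pl.vertices):
                    if not (0 <= x <= w and 0 <= y <= h):
                        raise ValueError(
                            f"vertex {i} of {pl.label!r} (frame {pl.frame}) at "
                            f"({x:.3f}, {y:.3f}) µm outside field {w:.3f} x {h:.3f} µm"
                        )


def write_annotations(ann: AnnotationSet, path) -> Path:
    """Write annotations as JSON (preferred) or flat CSV by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for pl in ann.centerlines:
            for i, (x, y) in enumerate(pl.vertices):
                rows.append(("centerline", pl.label, pl.frame, i, x, y))
        for bp in ann.branch_points:
            rows.append(("branch_point", "", bp.frame, 0, bp.xy_um[0], bp.xy_um[1]))
        for pl in ann.cell_borders:
            for i, (x, y) in enumerate(pl.vertices):
                rows.append(("cell_border", pl.label, pl.frame, i, x, y))
        df = pd.DataFrame(
            rows, columns=["kind", "label", "frame", "vertex_order", "x_um", "y_um"]
        )
        df.to_csv(path, index=False, float_format="%.12g")
        return path
    doc = {
        "units": "um",
        "centerlines": [
            {
                "label": pl.label,
                "frame": pl.frame,
                "closed": pl.closed,
                "vertices": pl.vertices.tolist(),
            }
            for pl in ann.centerlines
        ],
        "branch_points": [
            {"frame": bp.frame, "x_um": bp.xy_um[0], "y_um": bp.xy_um[1]}
            for bp in ann.branch_points
        ],
        "cell_borders": [
            {
                "label": pl.label,
                "frame": pl.frame,
                "closed": pl.closed,
                "vertices": pl.vertices.tolist(),
            }
            for pl in ann.cell_borders
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_annotations(path, pixel_size_um: float | None = None) -> AnnotationSet:
    """Read a JSON or CSV annotation file.

    Coordinates are µm unless the file declares ``"units": "px"``, in which
    case ``pixel_size_um`` is required for conversion.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, keep_default_na=False)
        scale = 1.0
        cls, bps, cbs = [], [], []
        for (kind, label, frame), g in df.groupby(["kind", "label", "frame"], sort=False):
            g = g.sort_values("vertex_order")
            verts = g[["x_um", "y_um"]].to_numpy(float) * scale
            if kind == "centerline":
                cls.append(Polyline(str(label), int(frame), verts))
            elif kind == "branch_point":
                for v in verts:
                    bps.append(BranchPoint(int(frame), v))
            elif kind == "cell_border":
                cbs.append(Polyline(str(label), int(frame), verts, closed=True))
            else:
                raise ValueError(f"unknown annotation kind {kind!r}")
        return AnnotationSet(cls, bps, cbs)

    doc = json.loads(path.read_text())
    units = doc.get("units", "um")
    if units == "px":
        if pixel_size_um is None:
            raise ValueError("annotations are in pixels; pixel_size_um required")
        scale = float(pixel_size_um)
    elif units == "um":
        scale = 1.0
    else:
        raise ValueError(f"unknown units {units!r}")
    cls = [
        Polyline(
            d["label"], int(d["frame"]), np.asarray(d["vertices"], float) * scale,
            closed=bool(d.get("closed", False)),
        )
        for d in doc.get("centerlines", [])
    ]
    bps = [
        BranchPoint(int(d["frame"]), np.array([d["x_um"], d["y_um"]]) * scale)
        for d in doc.get("branch_points", [])
    ]
    cbs = [
        Polyline(
            d["label"], int(d["frame"]), np.asarray(d["vertices"], float) * scale,
            closed=bool(d.get("closed", True)),
        )
        for d in doc.get("cell_borders", [])
    ]
    return AnnotationSet(cls, bps, cbs)


# --------------------------------------------------------------------------
# result tables
# --------------------------------------------------------------------------

# canonical leading columns; any extra metric columns follow alphabetically
_LEAD = ["axon_id", "label", "frame", "s_um", "caliber_um", "below_limit"]


def write_results(records, path) -> Path:
    """Write measurements as CSV: header always present, stable column order,
    "." decimal, UTF-8, deterministic float formatting."""
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.shape[1] == 0:  # empty record list still yields a header-only CSV
        df = pd.DataFrame(columns=_LEAD)
    lead = [c for c in _LEAD if c in df.columns]
    rest = sorted(c for c in df.columns if c not in lead)
    df = df.loc[:, lead + rest] if len(df.columns) else df
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
    return path


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
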