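"""Run configuration: every tunable of the measurement pipeline in one place.

All lengths are µm, all times minutes.  The defaults encode the measurement
conventions used throughout: segment calibers averaged over line scans 3, 4
and 5 µm from the branch point; lengthwise sampling at 1 µm intervals
excluding regions < 3 µm from a branch point; a time series is discarded
when more than 20% of its measurements fall below the optical resolution
limit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline parameters.

    Attributes
    ----------
    resolution_limit_um : float
        Smallest trusted peak-to-peak caliber.  Measurements below it (or
        with unresolvable membrane peaks) are flagged and excluded from
        summaries.  Default 0.14 µm, an Airyscan-class lateral limit.
    scan_half_length_um : float
        Half-length of the perpendicular line scan; 1.5 µm spans the largest
        calibers with margin.
    scan_spacing_um : float or None
        Sample spacing along the scan; None means half the pixel size.
    branch_offsets_um : tuple of float
        Geodesic distances from the branch point at which each segment is
        measured and averaged.
    lengthwise_interval_um : float
        Station spacing for lengthwise profiles.
    branch_exclusion_um : float
        Stations closer than this to a branch point are omitted (strict <).
    below_limit_series_fraction : float
        A series with flagged fraction strictly above this is excluded.
    min_prominence_frac : float
        Peak prominence threshold as a fraction of the profile's dynamic
        range.
    profile_smooth_sigma_samples : float
        Light Gaussian presmoothing (in samples) of the profile used for
        sub-sample peak refinement; 0 disables.
    detect_smooth_sigma_samples : float
        Heavier presmoothing used only to *select* the membrane peak pair,
        suppressing shot-noise maxima inside wide lumens; 0 disables.
    offset_mode : str
        "geodesic" (along-path, default) or "euclidean" branch offsets.
    """

    resolution_limit_um: float = 0.14
    scan_half_length_um: float = 1.5
    scan_spacing_um: float | None = None
    branch_offsets_um: tuple[float, ...] = (3.0, 4.0, 5.0)
    lengthwise_interval_um: float = 1.0
    branch_exclusion_um: float = 3.0
    below_limit_series_fraction: float = 0.20
    min_prominence_frac: float = 0.10
    profile_smooth_sigma_samples: float = 0.75
    detect_smooth_sigma_samples: float = 1.2
    centerline_step_um: float = 0.05
    tangent_smooth_um: float = 0.5
    offset_mode: str = "geodesic"
    timeseries_reanchor: bool = True
    rng_seed: int = 0
    bootstrap_reps: int = 5000
    permutation_reps: int = 10000
    permutation_exact_max_n: int = 20

    def __post_init__(self) -> None:
        for name in (
            "resolution_limit_um",
            "scan_half_length_um",
            "lengthwise_interval_um",
            "branch_exclusion_um",
            "centerline_step_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.branch_offsets_um = tuple(float(o) for o in self.branch_offsets_um)
        if any(o <= 0 for o in self.branch_offsets_um):
            raise ValueError("branch_offsets_um must be strictly positive")
        if not 0.0 <= self.below_limit_series_fraction <= 1.0:
            raise ValueError("below_limit_series_fraction must be in [0, 1]")
        if self.scan_spacing_um is not None and self.scan_spacing_um <= 0:
            raise ValueError("scan_spacing_um must be positive or None")
        if self.offset_mode not in ("geodesic", "euclidean"):
            raise ValueError("offset_mode must be 'geodesic' or 'euclidean'")

    def spacing_for(self, pixel_size_um: float) -> float:
        """Scan sample spacing: explicit value or half the pixel size."""
        return self.scan_spacing_um if self.scan_spacing_um is not None else pixel_size_um / 2.0

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["branch_offsets_um"] = list(self.branch_offsets_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
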