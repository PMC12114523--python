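"""Branch-point morphometrics: P/S1/S2 assignment, symmetry, tapering.

At the most proximal branch point the segment entering from the spinal cord
is the primary (P); the two daughter segments are labeled S1 (thicker) and
S2 (thinner).  Segment caliber is the mean of line scans taken 3, 4 and
5 µm from the branch point.  Derived quantities:

- normalized calibers  norm_s1 = S1/P,  norm_s2 = S2/P
- symmetry            S2/S1  (≡ norm_s2 / norm_s1; 1 = perfectly symmetric)
- cross-sectional areas  area = π (c/2)²  treating segments as cylinders
- area tapering ratio  (area_S1 + area_S2) / area_P  (≡ (s1² + s2²)/p²)
- radius scaling ratios  S1/P, S2/P and the two secondaries pooled

A triplet is excluded when its primary caliber is below the resolution
limit; a segment mean uses only non-flagged offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measure import CaliberMeasurement

__all__ = [
    "BranchTriplet",
    "segment_mean_caliber",
    "assign_triplet",
    "cohort_summaries",
    "SegmentUnmeasurable",
]


class SegmentUnmeasurable(ValueError):
    """All offset measurements of a segment were below the resolution limit."""


def segment_mean_caliber(measurements: list[CaliberMeasurement]) -> float:
    """Mean caliber over the configured branch offsets, non-flagged only."""
    vals = [m.caliber_um for m in measurements if not m.below_limit]
    if not vals:
        raise SegmentUnmeasurable(
            "all offset measurements flagged below the resolution limit"
        )
    return float(np.mean(vals))


@dataclass(frozen=True)
class BranchTriplet:
    """Calibers and derived metrics at one branch point."""

    p_um: float
    s1_um: float
    s2_um: float
    tie_flag: bool = False  # equal secondaries; S1 taken in annotation order

    def __post_init__(self) -> None:
        if min(self.p_um, self.s1_um, self.s2_um) <= 0:
            raise ValueError("calibers must be positive")
        if self.s1_um < self.s2_um:
            raise ValueError("S1 must be the thicker secondary (use assign_triplet)")

    @property
    def norm_s1(self) -> float:
        return self.s1_um / self.p_um

    @property
    def norm_s2(self) -> float:
        return self.s2_um / self.p_um

    @property
    def symmetry(self) -> float:
        """S2/S1: thinner over thicker sister caliber, in (0, 1]."""
        return self.s2_um / self.s1_um

    @property
    def area_p(self) -> float:
        return math.pi * (self.p_um / 2.0) ** 2

    @property
    def area_s1(self) -> float:
        return math.pi * (self.s1_um / 2.0) ** 2

    @property
    def area_s2(self) -> float:
        return math.pi * (self.s2_um / 2.0) ** 2

    @property
    def taper_area_ratio(self) -> float:
        """(area_S1 + area_S2)/area_P; < 1 means the arbor tapers in area."""
        return (self.area_s1 + self.area_s2) / self.area_p

    @property
    def r_ratio_s1(self) -> float:
        return self.s1_um / self.p_um

    @property
    def r_ratio_s2(self) -> float:
        return self.s2_um / self.p_um

    def to_record(self, axon_id: str = "") -> dict:
        return {
            "axon_id": axon_id,
            "p_um": self.p_um,
            "s1_um": self.s1_um,
            "s2_um": self.s2_um,
            "norm_s1": self.norm_s1,
            "norm_s2": self.norm_s2,
            "symmetry": self.symmetry,
            "taper_area_ratio": self.taper_area_ratio,
            "r_ratio_s1": self.r_ratio_s1,
            "r_ratio_s2": self.r_ratio_s2,
            "tie_flag": self.tie_flag,
        }


def assign_triplet(
    primary_um: float, secondary_a_um: float, secondary_b_um: float
) -> BranchTriplet:
    """Order the two secondaries into S1 (thicker) / S2 (thinner).

    An exact tie keeps the first secondary (annotation order) as S1 and sets
    ``tie_flag``.  The caller is responsible for excluding triplets whose
    primary was below the resolution limit.
    """
    if min(primary_um, secondary_a_um, secondary_b_um) <= 0:
        raise ValueError("calibers must be positive")
    tie = secondary_a_um == secondary_b_um
    s1, s2 = (
        (secondary_a_um, secondary_b_um)
        if secondary_a_um >= secondary_b_um
        else (secondary_b_um, secondary_a_um)
    )
    return BranchTriplet(primary_um, s1, s2, tie_flag=tie)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) >= 2 else float("nan")


def cohort_summaries(triplets: list[BranchTriplet]) -> dict:
    """Cohort means ± SEM and the regression inputs for a set of branch points.

    The pooled S/P sample puts both secondaries of every triplet into one
    sample, the convention for comparing against theoretical radius-scaling
    regimes.  Regression inputs (s1 vs s2, symmetry vs normalized calibers)
    are returned for the statistics layer.
    """
    if len(triplets) < 2:
        raise ValueError("need at least 2 triplets")
    arr = pd.DataFrame([t.to_record() for t in triplets])
    pooled = np.concatenate([arr["r_ratio_s1"].to_numpy(), arr["r_ratio_s2"].to_numpy()])
    out = {
        "n": len(triplets),
        "mean_p_um": float(arr["p_um"].mean()),
        "mean_s1_um": float(arr["s1_um"].mean()),
        "mean_s2_um": float(arr["s2_um"].mean()),
        "mean_symmetry": float(arr["symmetry"].mean()),
        "sem_symmetry": _sem(arr["symmetry"].to_numpy()),
        "mean_taper_area_ratio": float(arr["taper_area_ratio"].mean()),
        "sem_taper_area_ratio": _sem(arr["taper_area_ratio"].to_numpy()),
        "mean_r_ratio_s1": float(arr["r_ratio_s1"].mean()),
        "sem_r_ratio_s1": _sem(arr["r_ratio_s1"].to_numpy()),
        "mean_r_ratio_s2": float(arr["r_ratio_s2"].mean()),
        "sem_r_ratio_s2": _sem(arr["r_ratio_s2"].to_numpy()),
        "mean_pooled_s_over_p": float(pooled.mean()),
        "sem_pooled_s_over_p": _sem(pooled),
        "regressions": {
            "s1_vs_s2": (arr["s1_um"].to_numpy(), arr["s2_um"].to_numpy()),
            "symmetry_vs_norm_s1": (arr["norm_s1"].to_numpy(), arr["symmetry"].to_numpy()),
            "symmetry_vs_norm_s2": (arr["norm_s2"].to_numpy(), arr["symmetry"].to_numpy()),
        },
        "table": arr,
    }
    return out
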