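"""Simulated localized RNFL defects.

The simulation engine carves sector defects into the normal average
peripapillary profile: the circle is divided into 12 evenly spaced 30deg
sectors (clock hours) and, within a sector, the profile is replaced by the
pointwise 10th, 5th or 1st percentile of the glaucoma population — never
rising above the healthy base.  Edges are abrupt by default (an optional
cosine taper exists for exploration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vf_geometry import N_RNFL, rnfl_angles

DEPTHS = (10, 5, 1)


@dataclass(frozen=True)
class DefectSpec:
    """A sector defect: half-open angular span [start, end) at percentile depth."""

    sector_start_deg: float
    sector_end_deg: float
    depth_percentile: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.sector_start_deg <= self.sector_end_deg <= 360.0):
            raise ValueError("need 0 <= start <= end <= 360")
        if self.depth_percentile not in DEPTHS:
            raise ValueError(f"depth percentile must be one of {DEPTHS}")

    def mask(self) -> np.ndarray:
        """(768,) boolean membership of the half-open sector."""
        ang = rnfl_angles()
        return (ang >= self.sector_start_deg) & (ang < self.sector_end_deg)


def healthy_mean_profile(profiles) -> np.ndarray:
    """Pointwise mean of healthy 768-point profiles (the simulation base)."""
    arr = np.atleast_2d(np.asarray(profiles, dtype=float))
    if arr.size == 0:
        raise ValueError("need at least one healthy profile")
    if arr.shape[1] != N_RNFL:
        raise ValueError(f"profiles must have {N_RNFL} points")
    return arr.mean(axis=0)


def simulate_defect(
    base: np.ndarray,
    spec: DefectSpec,
    percentile_profiles: dict[int, np.ndarray],
    taper_deg: float = 0.0,
) -> np.ndarray:
    """Carve one sector defect into ``base``.

    Inside [start, end) the thickness becomes ``min(base, P_q)`` — the min
    guard keeps a percentile that exceeds the healthy mean (possible in
    suspect-heavy cohorts) from thickening the profile.  Outside, the base
    is untouched; edges are a step unless ``taper_deg > 0`` requests a
    cosine ramp of that angular width just inside the sector.
    """
    base = np.asarray(base, dtype=float)
    if spec.depth_percentile not in percentile_profiles:
        raise ValueError(f"no percentile profile for q={spec.depth_percentile}")
    target = np.minimum(base, np.asarray(percentile_profiles[spec.depth_percentile]))
    m = spec.mask()
    if taper_deg <= 0:
        return np.where(m, target, base)
    ang = rnfl_angles()
    d_edge = np.minimum(ang - spec.sector_start_deg, spec.sector_end_deg - ang)
    ramp = np.clip(d_edge / taper_deg, 0.0, 1.0)
    w = np.where(m, ramp, 0.0)
    return base * (1 - w) + target * w


def enumerate_simulations(
    base: np.ndarray,
    percentile_profiles: dict[int, np.ndarray],
    sector_width_deg: float = 30.0,
    depths: tuple[int, ...] = DEPTHS,
) -> list[tuple[DefectSpec, np.ndarray]]:
    """One simulated profile per (sector, depth): 12 x 3 = 36 by default.

    Sectors start at 0deg (temporal) and advance through superior, nasal,
    inferior; within a sector, depths follow the given order.
    """
    if sector_width_deg <= 0 or 360.0 % sector_width_deg != 0:
        raise ValueError("sector width must evenly divide 360")
    out = []
    n_sec = int(360.0 / sector_width_deg)
    for s in range(n_sec):
        start = s * sector_width_deg
        for q in depths:
            spec = DefectSpec(start, start + sector_width_deg, q)
            out.append((spec, simulate_defect(base, spec, percentile_profiles)))
    return out


def match_real_to_simulated(
    real: np.ndarray,
    simulations: list[tuple[DefectSpec, np.ndarray]],
    metric: str = "rmse",
) -> tuple[DefectSpec, float]:
    """Nearest simulated profile to a real one (ties -> first enumerated)."""
    if not simulations:
        raise ValueError("empty simulation list")
    real = np.asarray(real, dtype=float)
    best: tuple[DefectSpec, float] | None = None
    for spec, prof in simulations:
        if metric == "rmse":
            d = float(np.sqrt(np.mean((real - prof) ** 2)))
        elif metric == "mae":
            d = float(np.mean(np.abs(real - prof)))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        if best is None or d < best[1]:
            best = (spec, d)
    return best
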