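"""Structure-function map assembly.

Feeding every simulated sector defect (12 sectors x 3 percentile depths)
through a trained predictor and deriving a SAP-style report for each yields
the structure-function map: which field locations lose sensitivity when a
given clock-hour of the RNFL is damaged, and how loss deepens with defect
depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .defect_sim import DEPTHS, DefectSpec, enumerate_simulations
from .synthetic_cohort import (
    GeneratorConfig,
    NormativeTables,
    forward_sf_model,
)
from .vf_geometry import SectorAssignment, VfGrid, build_grid_24_2
from .vf_report import VfReport, derive_report

ABNORMAL_CATEGORIES = ("<5%", "<2%", "<1%", "<0.5%")


@dataclass
class SfMapEntry:
    spec: DefectSpec
    profile: np.ndarray
    predicted: np.ndarray
    report: VfReport

    def abnormal_points(self, which: str = "pd") -> np.ndarray:
        cats = self.report.pd_prob if which == "pd" else self.report.td_prob
        return np.array([c in ABNORMAL_CATEGORIES for c in cats])


@dataclass
class SfMap:
    entries: list[SfMapEntry]
    base_profile: np.ndarray
    age_years: float

    def entry(self, sector_start: float, depth: int) -> SfMapEntry:
        for e in self.entries:
            if e.spec.sector_start_deg == sector_start and e.spec.depth_percentile == depth:
                return e
        raise KeyError((sector_start, depth))

    def to_json_dict(self) -> dict:
        return {
            "age_years": self.age_years,
            "base_profile": self.base_profile.tolist(),
            "entries": [
                {
                    "sector_start_deg": e.spec.sector_start_deg,
                    "sector_end_deg": e.spec.sector_end_deg,
                    "depth_percentile": e.spec.depth_percentile,
                    "profile": e.profile.tolist(),
                    "predicted": e.predicted.tolist(),
                    "report": e.report.to_json_dict(),
                }
                for e in self.entries
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)


class OracleForwardPredictor:
    """The synthetic generator's own forward model wrapped as a predictor.

    Useful as a ground-truth reference: feeding it the simulated defects
    shows the map a perfect model would produce.
    """

    def __init__(self, cfg: GeneratorConfig, sectors: SectorAssignment,
                 age: float = 60.0, grid: VfGrid | None = None):
        self.cfg = cfg
        self.sectors = sectors
        self.age = age
        self.grid = grid or build_grid_24_2()

    def predict(self, profiles) -> np.ndarray:
        return forward_sf_model(
            profiles, self.age, self.cfg, self.sectors, self.grid
        )


def build_sf_map(
    predictor,
    base_profile: np.ndarray,
    normative: NormativeTables,
    age: float = 60.0,
    depths: tuple[int, ...] = DEPTHS,
    sector_width_deg: float = 30.0,
) -> SfMap:
    """Enumerate sector defects, predict each field, derive each report.

    ``predictor`` is anything with ``predict(profiles) -> (n, 52)`` — the
    trained network, the OLS baseline or the generator-oracle.  Deterministic
    given its weights and the tables.
    """
    sims = enumerate_simulations(
        base_profile,
        normative.glaucoma_percentile_profiles,
        sector_width_deg=sector_width_deg,
        depths=depths,
    )
    profiles = np.array([p for _, p in sims])
    preds = np.asarray(predictor.predict(profiles), dtype=float)
    if preds.shape != (len(sims), 52):
        raise ValueError(
            f"predictor returned shape {preds.shape}, expected ({len(sims)}, 52)"
        )
    entries = [
        SfMapEntry(
            spec=spec,
            profile=prof,
            predicted=preds[i],
            report=derive_report(preds[i], age, normative),
        )
        for i, (spec, prof) in enumerate(sims)
    ]
    return SfMap(entries=entries, base_profile=np.asarray(base_profile, float),
                 age_years=age)


def compare_maps(map_a: SfMap, map_b: SfMap, which: str = "pd"):
    """Per-entry abnormal-point set relations between two maps.

    Both maps must enumerate the same defect specs.  For each entry, counts
    of abnormal points (probability category worse than ns) in A and B and
    of the A-only / B-only / shared sets.
    """
    import pandas as pd

    specs_a = [e.spec for e in map_a.entries]
    specs_b = [e.spec for e in map_b.entries]
    if specs_a != specs_b:
        raise ValueError("maps enumerate different defect specs")
    rows = []
    for ea, eb in zip(map_a.entries, map_b.entries):
        a = ea.abnormal_points(which)
        b = eb.abnormal_points(which)
        rows.append(
            {
                "sector_start_deg": ea.spec.sector_start_deg,
                "depth_percentile": ea.spec.depth_percentile,
                "n_abnormal_a": int(a.sum()),
                "n_abnormal_b": int(b.sum()),
                "a_only": int((a & ~b).sum()),
                "b_only": int((b & ~a).sum()),
                "both": int((a & b).sum()),
            }
        )
    return pd.DataFrame(rows)


def hemifield_pd_means(entry: SfMapEntry, grid: VfGrid) -> tuple[float, float]:
    """(superior, inferior) hemifield means of pattern deviation."""
    y = grid.xy()[:, 1]
    pdv = entry.report.pattern_deviation
    return float(pdv[y > 0].mean()), float(pdv[y < 0].mean())


def render_sf_map_figure(sf_map: SfMap, grid: VfGrid, path=None):
    """Composite figure: rows = sectors, columns = profile + one field panel
    per depth (pattern-deviation grayscale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .vf_geometry import rnfl_angles

    starts = sorted({e.spec.sector_start_deg for e in sf_map.entries})
    depths = sorted({e.spec.depth_percentile for e in sf_map.entries}, reverse=True)
    fig, axes = plt.subplots(
        len(starts), 1 + len(depths), figsize=(3 * (1 + len(depths)), 2.2 * len(starts))
    )
    axes = np.atleast_2d(axes)
    ang = rnfl_angles()
    xy = grid.xy()
    for row, s0 in enumerate(starts):
        axp = axes[row, 0]
        axp.plot(ang, sf_map.base_profile, lw=0.8, color="0.6")
        deep = sf_map.entry(s0, min(depths))
        axp.plot(ang, deep.profile, lw=0.8, color="k")
        for edge in (s0, deep.spec.sector_end_deg):
            axp.axvline(edge, ls="--", lw=0.6, color="r")
        axp.set_xlim(0, 360)
        axp.set_ylabel(f"{s0:.0f}-{deep.spec.sector_end_deg:.0f}deg", fontsize=7)
        axp.tick_params(labelsize=6)
        for col, q in enumerate(depths, start=1):
            e = sf_map.entry(s0, q)
            ax = axes[row, col]
            level = [
                ("ns", "<5%", "<2%", "<1%", "<0.5%").index(c) for c in e.report.pd_prob
            ]
            ax.scatter(xy[:, 0], xy[:, 1], c=level, cmap="Greys", vmin=0, vmax=4,
                       s=28, marker="s")
            ax.set_aspect("equal")
            ax.set_xticks([])
            ax.set_yticks([])
            if row == 0:
                ax.set_title(f"p{q}", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return None
    return fig
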