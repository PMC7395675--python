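"""SAP-style visual-field report: total deviation, pattern deviation,
probability maps, global indices, and a printable rendering.

Definitions (matching commercial perimetry printouts where the underlying
formulas are public):

* total deviation: ``TD_i = threshold_i - age-corrected normal_i``;
* general height: the 7th-best (7th-largest, ties counted) TD value;
* pattern deviation: ``PD_i = TD_i - GH``, removing diffuse loss;
* probability categories: the most extreme of the empirical normative
  percentiles {5, 2, 1, 0.5}% that the deviation falls at or below;
* MD is the unweighted mean of TD and PSD the sample SD of TD about MD
  (the proprietary eccentricity weights of commercial devices are not
  public; this divergence is deliberate and documented).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import NormativeTables
from .vf_geometry import N_VF, VfGrid

PROB_CATEGORIES = ("ns", "<5%", "<2%", "<1%", "<0.5%")
_CUT_ORDER = (0.5, 1.0, 2.0, 5.0)  # most extreme first
_SYMBOL = {"ns": ".", "<5%": "+", "<2%": "o", "<1%": "*", "<0.5%": "#"}


def total_deviation(thresholds, age: float, normative: NormativeTables) -> np.ndarray:
    """TD per point: threshold minus the age-corrected normal threshold."""
    import warnings

    th = np.asarray(thresholds, dtype=float)
    if th.shape[-1] != N_VF:
        raise ValueError(f"expected {N_VF} thresholds")
    if not 18.0 <= age <= 100.0:
        warnings.warn(f"age {age} outside the normative range; extrapolating",
                      stacklevel=2)
    return th - normative.normal_thresholds(age)


def general_height(td) -> float:
    """The 7th-largest TD value (1-based, duplicates counted)."""
    td = np.asarray(td, dtype=float)
    if td.size < 7:
        raise ValueError("need at least 7 TD values")
    return float(np.sort(td)[-7])


def pattern_deviation(td) -> np.ndarray:
    """PD per point: TD minus the general height.  Shift invariant."""
    td = np.asarray(td, dtype=float)
    return td - general_height(td)


def probability_categories(deviations, percentile_table: dict) -> list[str]:
    """Per-point category: the most extreme cut whose normative percentile
    the deviation falls at or below (boundary inclusive toward abnormal),
    else ``"ns"``."""
    dev = np.asarray(deviations, dtype=float)
    for q in _CUT_ORDER:
        if float(q) not in {float(k) for k in percentile_table}:
            raise ValueError(f"percentile table lacks the {q}% column")
    tab = {float(k): np.asarray(v, dtype=float) for k, v in percentile_table.items()}
    if any(v.shape[-1] != dev.shape[-1] for v in tab.values()):
        raise ValueError("percentile table does not cover every point")
    out = []
    for i, d in enumerate(dev):
        cat = "ns"
        for q in _CUT_ORDER:
            if d <= tab[q][i]:
                cat = f"<{q:g}%"
                break
        out.append(cat)
    return out


def global_indices(td) -> tuple[float, float]:
    """(MD, PSD): unweighted mean of TD and sample SD of TD about MD."""
    td = np.asarray(td, dtype=float)
    if td.size < 2:
        raise ValueError("need at least 2 TD values")
    md = float(td.mean())
    psd = float(td.std(ddof=1))
    return md, psd


@dataclass
class VfReport:
    thresholds: np.ndarray
    total_deviation: np.ndarray
    pattern_deviation: np.ndarray
    td_prob: list[str]
    pd_prob: list[str]
    md: float
    psd: float
    age_years: float

    def to_json_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "total_deviation": self.total_deviation.tolist(),
            "pattern_deviation": self.pattern_deviation.tolist(),
            "td_prob": self.td_prob,
            "pd_prob": self.pd_prob,
            "md": self.md,
            "psd": self.psd,
            "age_years": self.age_years,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)


def derive_report(thresholds, age: float, normative: NormativeTables) -> VfReport:
    """Full report from a (predicted or measured) 52-point field."""
    th = np.asarray(thresholds, dtype=float)
    td = total_deviation(th, age, normative)
    pdv = pattern_deviation(td)
    md, psd = global_indices(td)
    return VfReport(
        thresholds=th,
        total_deviation=td,
        pattern_deviation=pdv,
        td_prob=probability_categories(td, normative.td_percentiles),
        pd_prob=probability_categories(pdv, normative.pd_percentiles),
        md=md,
        psd=psd,
        age_years=age,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _value_grid(grid: VfGrid, values, fmt: str, width: int = 7) -> str:
    """Fixed-layout text block of per-point values on the 24-2 pattern."""
    xs = sorted({p[0] for p in grid.points} | {p[0] for p in grid.blind_spot_points})
    ys = sorted({p[1] for p in grid.points}, reverse=True)
    lookup = {p: i for i, p in enumerate(grid.points)}
    lines = []
    for y in ys:
        cells = []
        for x in xs:
            p = (x, y)
            if p in lookup:
                cells.append(format(values[lookup[p]], fmt).rjust(width))
            elif p in grid.blind_spot_points:
                cells.append(" " * width)      # blind spot left blank
            else:
                cells.append(" " * width)
        lines.append("".join(cells).rstrip())
    return "\n".join(lines)


def _symbol_grid(grid: VfGrid, cats: list[str]) -> str:
    sym = [_SYMBOL[c] for c in cats]
    return _value_grid(grid, sym, "s", width=3)


def render_report_text(report: VfReport, grid: VfGrid) -> str:
    """Deterministic fixed-layout text report (thresholds clamped to
    [0, 50] dB for display only)."""
    shown = np.clip(report.thresholds, 0.0, 50.0)
    buf = io.StringIO()
    buf.write("== Sensitivity thresholds (dB) ==\n")
    buf.write(_value_grid(grid, shown, ".1f") + "\n")
    buf.write("== Total deviation (dB) ==\n")
    buf.write(_value_grid(grid, report.total_deviation, ".1f") + "\n")
    buf.write("== Pattern deviation (dB) ==\n")
    buf.write(_value_grid(grid, report.pattern_deviation, ".1f") + "\n")
    buf.write("== TD probability ==\n")
    buf.write(_symbol_grid(grid, report.td_prob) + "\n")
    buf.write("== PD probability ==\n")
    buf.write(_symbol_grid(grid, report.pd_prob) + "\n")
    buf.write(f"MD {report.md:+.2f} dB   PSD {report.psd:.2f} dB   "
              f"age {report.age_years:.1f} y\n")
    buf.write("symbols: . ns   + <5%   o <2%   * <1%   # <0.5%\n")
    return buf.getvalue()


def parse_rendered_thresholds(text: str, grid: VfGrid) -> np.ndarray:
    """Recover the displayed thresholds from a rendered report (round-trip
    inverse of the first block, at the printed 0.1 dB precision)."""
    lines = text.splitlines()
    start = lines.index("== Sensitivity thresholds (dB) ==") + 1
    ys = sorted({p[1] for p in grid.points}, reverse=True)
    xs = sorted({p[0] for p in grid.points} | {p[0] for p in grid.blind_spot_points})
    vals = np.full(N_VF, np.nan)
    lookup = {p: i for i, p in enumerate(grid.points)}
    for row, y in enumerate(ys):
        line = lines[start + row].ljust(7 * len(xs))
        for col, x in enumerate(xs):
            cell = line[col * 7 : (col + 1) * 7].strip()
            if cell and (x, y) in lookup:
                vals[lookup[(x, y)]] = float(cell)
    return vals


def render_report_figure(report: VfReport, grid: VfGrid, path=None):
    """Four-panel report figure (grayscale thresholds, TD, PD, PD probability)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = grid.xy()
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    panels = [
        ("Thresholds (dB)", np.clip(report.thresholds, 0, 50), "gray"),
        ("Total deviation (dB)", report.total_deviation, "RdBu_r"),
        ("Pattern deviation (dB)", report.pattern_deviation, "RdBu_r"),
    ]
    for ax, (title, vals, cmap) in zip(axes.ravel(), panels):
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=vals, cmap=cmap, s=140, marker="s")
        ax.set_title(title)
        ax.set_aspect("equal")
        fig.colorbar(sc, ax=ax, shrink=0.8)
    ax = axes.ravel()[3]
    level = [PROB_CATEGORIES.index(c) for c in report.pd_prob]
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=level, cmap="Greys", vmin=0, vmax=4,
                    s=140, marker="s")
    ax.set_title("PD probability (darker = more abnormal)")
    ax.set_aspect("equal")
    fig.suptitle(f"MD {report.md:+.2f} dB   PSD {report.psd:.2f} dB")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
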