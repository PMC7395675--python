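"""24-2 visual-field geometry: test grid, blind-spot exclusion, laterality,
and Garway-Heath sectorization.

Conventions used throughout the package
---------------------------------------
* Field coordinates are degrees in **right-eye convention**: positive x is
  the temporal field, positive y the superior field.  The blind spot sits at
  (15, +3) and (15, -3); those two locations are excluded, leaving 52 points.
* Peripapillary RNFL profiles are 768 samples on the 3.45-mm circle in TSNIT
  order: index k corresponds to angle ``theta_k = k * 360 / 768`` degrees,
  with 0deg temporal, 90deg superior, 180deg nasal, 270deg inferior.
* Left-eye data are mirrored into right-eye convention on ingest, so a single
  structure-function map serves both eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

N_RNFL = 768
N_VF = 52

RIGHT = "right"
LEFT = "left"

#: Table 2 sector names (visual-field regions of the Garway-Heath map).
GH_SECTORS = (
    "central",
    "temporal",
    "inferior",
    "inferior-nasal",
    "superior",
    "superior-nasal",
)

# Optic-disc sector boundaries of the Garway-Heath map, TSNIT degrees.
# Each disc sector serves the *opposite* vertical field region because the
# retinal image is inverted: superotemporal disc fibers come from superior
# retina and therefore subserve the inferior field.
_DISC_SECTOR_LABELS = (
    (311.0, 360.0, "central"),          # temporal disc (311-40)
    (0.0, 41.0, "central"),
    (41.0, 81.0, "inferior"),           # superotemporal disc
    (81.0, 121.0, "inferior-nasal"),    # superonasal disc
    (121.0, 231.0, "temporal"),         # nasal disc
    (231.0, 271.0, "superior-nasal"),   # inferonasal disc
    (271.0, 311.0, "superior"),         # inferotemporal disc
)


def rnfl_angles() -> np.ndarray:
    """Angles (deg) of the 768 TSNIT samples: k * 360/768."""
    return np.arange(N_RNFL) * (360.0 / N_RNFL)


@dataclass(frozen=True)
class VfGrid:
    """The 24-2 test-point grid after blind-spot exclusion.

    ``points`` is the fixed (row-major, superior to inferior; within a row
    nasal to temporal, i.e. ascending x in right-eye convention) ordering of
    the 52 retained locations.  The same ordering indexes every 52-vector in
    the package.
    """

    eye: str
    points: tuple[tuple[float, float], ...]
    blind_spot_points: tuple[tuple[float, float], ...]

    @property
    def n_points(self) -> int:
        return len(self.points)

    def xy(self) -> np.ndarray:
        """(52, 2) array of field coordinates."""
        return np.asarray(self.points, dtype=float)

    def index_of(self, x: float, y: float) -> int:
        return self.points.index((float(x), float(y)))

    def to_json_dict(self) -> dict:
        return {
            "eye": self.eye,
            "points": [list(p) for p in self.points],
            "blind_spot_points": [list(p) for p in self.blind_spot_points],
        }


_ROW_EXTENT = {
    21.0: (-9.0, 9.0),
    15.0: (-15.0, 15.0),
    9.0: (-21.0, 21.0),
    3.0: (-27.0, 21.0),  # nasal step extension: 9 points, to 27deg nasally
}


def build_grid_24_2(eye: str = RIGHT) -> VfGrid:
    """Construct the 24-2 grid for one eye and drop the blind-spot points.

    The candidate pattern has 54 locations on a 6deg lattice offset 3deg from
    the meridians (rows y in {+-21, +-15, +-9, +-3} with 4/6/8/9 points per
    half-row), extended one point nasally at y = +-3.  The two locations that
    fall on the optic-nerve head, (15, +-3) in right-eye convention, are
    removed, leaving 52.  A left-eye grid is the mirror image (x negated).
    """
    if eye not in (RIGHT, LEFT):
        raise ValueError(f"unknown laterality {eye!r}: expected 'right' or 'left'")
    sign = 1.0 if eye == RIGHT else -1.0
    blind = tuple(sorted(((sign * 15.0, 3.0), (sign * 15.0, -3.0)), key=lambda p: -p[1]))
    pts: list[tuple[float, float]] = []
    for y in sorted({*_ROW_EXTENT, *(-y for y in _ROW_EXTENT)}, reverse=True):
        lo, hi = _ROW_EXTENT[abs(y)]
        xs = np.arange(lo, hi + 1e-9, 6.0)
        for x in sorted(sign * xs):
            p = (float(x), float(y))
            if p not in blind:
                pts.append(p)
    assert len(pts) == N_VF
    return VfGrid(eye=eye, points=tuple(pts), blind_spot_points=blind)


def candidate_points_24_2(eye: str = RIGHT) -> list[tuple[float, float]]:
    """All 54 candidate locations, before blind-spot exclusion."""
    g = build_grid_24_2(eye)
    return sorted(
        list(g.points) + list(g.blind_spot_points), key=lambda p: (-p[1], p[0])
    )


# ---------------------------------------------------------------------------
# Garway-Heath sectorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectorAssignment:
    """Per-point Garway-Heath field-sector labels and disc entry angles."""

    labels: tuple[str, ...]                 # one of GH_SECTORS per grid point
    disc_angle_deg: np.ndarray = field(compare=False)  # (52,) TSNIT degrees

    def indices(self, sector: str) -> np.ndarray:
        if sector not in GH_SECTORS:
            raise ValueError(f"unknown sector {sector!r}")
        return np.flatnonzero(np.asarray(self.labels) == sector)

    def sector_sizes(self) -> dict[str, int]:
        return {s: int(self.indices(s).size) for s in GH_SECTORS}

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "disc_angle_deg": [float(a) for a in self.disc_angle_deg],
        }


def disc_entry_angle(x: float, y: float) -> float:
    """Disc entry angle (TSNIT deg, right-eye) for a field location.

    A compact retinotopic fiber-bundle model.  The field point projects onto
    the inverted retina (temporal field -> nasal retina, superior field ->
    inferior retina); the optic disc lies 15deg nasal on the retina.  Fibers
    from the retina nasal to the disc run straight in; fibers on the temporal
    side arc around the macula without crossing the horizontal raphe, so
    their entry angle sweeps toward the vertical poles as the bundle origin
    approaches the raphe.  This reproduces the familiar topology: macular
    points enter temporally, arcuate regions at the superior/inferior poles,
    and the nasal-step region infero/supero-nasally.
    """
    # retina coords relative to the disc: u temporal+, v superior+
    u = 15.0 - x
    v = -y
    if u < 0:  # retina nasal to the disc: direct radial entry, pulled nasal
        raw = np.degrees(np.arctan2(v, u)) % 360.0
        dev = ((raw - 180.0 + 180.0) % 360.0) - 180.0
        return (180.0 + 0.7 * dev) % 360.0
    # temporal side: position angle about the macula (at u=15, v=0)
    beta = np.degrees(np.arctan2(v, u - 15.0))  # 0 = raphe direction, +-180 = papillomacular
    if v == 0.0 and u == 15.0:
        return 0.0
    sweep = 115.0 * (1.0 - abs(beta) / 180.0) ** 0.8
    return (np.sign(beta) * sweep) % 360.0


def _label_from_disc_angle(theta: float) -> str:
    theta = theta % 360.0
    for lo, hi, lab in _DISC_SECTOR_LABELS:
        if lo <= theta < hi:
            return lab
    raise AssertionError("disc sector boundaries do not cover the circle")


def default_sector_table(grid: VfGrid | None = None) -> dict:
    """Build the default point -> (sector, disc angle) table from the
    retinotopic model.  Mirrors the shipped YAML config."""
    grid = grid or build_grid_24_2(RIGHT)
    entries = []
    for i, (x, y) in enumerate(grid.points):
        ang = float(disc_entry_angle(x, y))
        entries.append(
            {
                "point": i,
                "x_deg": x,
                "y_deg": y,
                "sector": _label_from_disc_angle(ang),
                "disc_angle_deg": round(ang, 2),
            }
        )
    return {"convention": "right-eye, TSNIT disc angles", "points": entries}


def load_sector_table(path=None) -> dict:
    """Load a sector config from YAML; default is the packaged table."""
    if path is None:
        ref = resources.files("oct2vf.data").joinpath("garway_heath_24_2.yaml")
        with ref.open("r") as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def assign_gh_sectors(grid: VfGrid, table: dict | None = None) -> SectorAssignment:
    """Attach a Garway-Heath sector label and disc angle to every grid point.

    ``table`` must cover every grid point exactly once (checked); by default
    the packaged YAML encoding of the published map is used.
    """
    table = table if table is not None else load_sector_table()
    by_xy: dict[tuple[float, float], dict] = {}
    for e in table["points"]:
        key = (float(e["x_deg"]), float(e["y_deg"]))
        if key in by_xy:
            raise ValueError(f"sector table covers point {key} twice")
        by_xy[key] = e
    labels = []
    angles = []
    for p in grid.points:
        if p not in by_xy:
            raise ValueError(f"sector table does not cover grid point {p}")
        e = by_xy[p]
        if e["sector"] not in GH_SECTORS:
            raise ValueError(f"unknown sector label {e['sector']!r} at {p}")
        labels.append(e["sector"])
        angles.append(float(e["disc_angle_deg"]))
    extra = set(by_xy) - set(grid.points)
    if extra:
        raise ValueError(f"sector table lists points not on the grid: {sorted(extra)}")
    return SectorAssignment(labels=tuple(labels), disc_angle_deg=np.asarray(angles))


# ---------------------------------------------------------------------------
# Laterality
# ---------------------------------------------------------------------------

def mirror_field(values: Sequence[float], eye: str) -> np.ndarray:
    """Re-express a 52-vector of field values in right-eye convention.

    Right-eye input is returned unchanged.  For a left eye the grid is the
    mirror image, so values are re-indexed onto the right-eye point order by
    negating x.  Mirroring twice is the identity.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape[-1] != N_VF:
        raise ValueError(f"expected {N_VF} field values, got {vals.shape[-1]}")
    if eye == RIGHT:
        return vals.copy()
    if eye != LEFT:
        raise ValueError(f"unknown laterality {eye!r}")
    left = build_grid_24_2(LEFT)
    right = build_grid_24_2(RIGHT)
    order = [left.index_of(-x, y) for (x, y) in right.points]
    return vals[..., order]


def mirror_profile(rnfl: Sequence[float], eye: str) -> np.ndarray:
    """Re-express a 768-point TSNIT profile in right-eye convention.

    The left-eye circle is the reflection about the 0deg/180deg (temporal-
    nasal) axis: sample at angle theta maps to 360 - theta, i.e. index k to
    (768 - k) mod 768.  An involution.
    """
    prof = np.asarray(rnfl, dtype=float)
    if prof.shape[-1] != N_RNFL:
        raise ValueError(f"expected {N_RNFL} samples, got {prof.shape[-1]}")
    if eye == RIGHT:
        return prof.copy()
    if eye != LEFT:
        raise ValueError(f"unknown laterality {eye!r}")
    idx = (N_RNFL - np.arange(N_RNFL)) % N_RNFL
    return prof[..., idx]
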