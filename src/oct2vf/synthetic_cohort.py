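"""Synthetic paired-exam cohort with known ground truth.

Real structure-function registries pair a peripapillary SDOCT RNFL scan
(768 thickness samples, um) with a 24-2 SAP visual field (52 thresholds,
dB) for each clinic visit.  This module emulates such a cohort:

* a double-hump TSNIT normative profile (temporal base with superior- and
  inferior-temporal peaks);
* glaucomatous eyes with localized wedge defects plus optional diffuse loss,
  applied above a non-axonal tissue floor;
* a nonlinear structure-function forward model: each field location pools
  RNFL thickness around its optic-disc entry angle with circular-Gaussian
  weights, and sensitivity falls with the log of floored local thickness;
* threshold noise whose SD grows as sensitivity falls (perimetric
  variability becomes very large below ~15 dB);
* age decline of normal sensitivity, hierarchical patient/eye/test
  structure, and reliability/quality metadata including a configured
  fraction of exams that fail the curation filters.

Everything is reproducible from the config seed.  The forward model's
disc-angle map is the same editable sector config used for Garway-Heath
sectorization, so the ground-truth map the network must recover is known.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .vf_geometry import (
    LEFT,
    N_RNFL,
    N_VF,
    RIGHT,
    SectorAssignment,
    VfGrid,
    assign_gh_sectors,
    build_grid_24_2,
    mirror_field,
    mirror_profile,
    rnfl_angles,
)

DEG_PER_SAMPLE = 360.0 / N_RNFL
_EPOCH = date(2015, 1, 1)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (units in docstrings).

    The structure-function forward model is
    ``S_i = clamp(N_i(age) + 10*gamma*log10((t_i - b)/(tbar_i - b)), 0, ceiling)``
    where ``t_i`` is the circular-Gaussian-weighted RNFL thickness around
    point i's disc entry angle, ``tbar_i`` the same functional of the healthy
    mean profile, and ``b`` the residual (non-axonal) thickness floor.
    Noise SD is ``sigma0 + sigma1 * max(0, knee - S)``, capped.
    """

    n_patients: int = 200
    fraction_glaucoma: float = 0.7
    both_eyes_prob: float = 0.7
    extra_tests_poisson_mean: float = 0.75   # tests per eye = 1 + Poisson(.)

    # healthy double-hump profile (um / deg)
    temporal_base_um: float = 50.0
    peak_amplitude_um: tuple[float, float] = (45.0, 45.0)
    peak_center_deg: tuple[float, float] = (80.0, 280.0)
    peak_width_deg: tuple[float, float] = (35.0, 35.0)
    subject_scale_sd: float = 0.07           # lognormal SD of global scaling
    oct_noise_um: float = 2.5                # per-test smooth measurement noise

    # localized / diffuse loss
    extra_defects_poisson_mean: float = 0.7  # defects = 1 + Poisson(.)
    defect_width_deg: tuple[float, float] = (20.0, 60.0)
    defect_depth_frac: tuple[float, float] = (0.3, 0.9)
    polar_defect_prob: float = 0.8           # defect centered near vertical poles
    diffuse_prob: float = 0.5
    diffuse_frac: tuple[float, float] = (0.05, 0.30)

    # structure-function forward model
    sigma_map_deg: float = 15.0              # circular-Gaussian spread
    residual_base_um: float = 30.0           # b: floor thickness
    gamma_db_per_log: float = 1.0            # dB per 10*log10 thickness ratio
    noise_sigma0_db: float = 1.5
    noise_sigma1_db_per_db: float = 0.4
    noise_knee_db: float = 25.0
    noise_cap_db: float = 8.0
    ceiling_db: float = 40.0

    # normal sensitivity and age model
    base_sensitivity_db: float = 34.0        # at fixation, age 50
    eccentricity_slope_db_per_deg: float = 0.1
    age_slope_db_per_yr: float = -0.07
    age_mean_yr: float = 65.0
    age_sd_yr: float = 10.0

    # metadata model
    filter_fail_frac: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_glaucoma", "both_eyes_prob", "polar_defect_prob",
                     "diffuse_prob", "filter_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("subject_scale_sd", "oct_noise_um", "noise_sigma0_db",
                     "noise_sigma1_db_per_db", "noise_cap_db", "age_sd_yr",
                     "sigma_map_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.residual_base_um >= self.temporal_base_um:
            raise ValueError("residual_base_um must be below temporal_base_um")

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PairedExam:
    """One SAP test paired with one OCT scan, plus metadata.

    ``true_vf`` and ``is_glaucoma`` are ground truth only a synthetic cohort
    can carry (the noiseless field and the generating disease state).
    """

    patient_id: str
    eye_id: str
    laterality: str
    test_date_sap: date
    test_date_oct: date
    age_years: float
    rnfl: np.ndarray                 # (768,) um, stored eye's own convention
    vf: np.ndarray                   # (52,) dB
    fixation_loss_frac: float
    false_positive_frac: float
    oct_quality_score: float
    true_vf: np.ndarray | None = None
    is_glaucoma: bool | None = None

    def __post_init__(self) -> None:
        self.rnfl = np.asarray(self.rnfl, dtype=float)
        self.vf = np.asarray(self.vf, dtype=float)
        if self.rnfl.shape != (N_RNFL,):
            raise ValueError(f"rnfl must have {N_RNFL} samples")
        if self.vf.shape != (N_VF,):
            raise ValueError(f"vf must have {N_VF} thresholds")
        if not self.eye_id.startswith(self.patient_id):
            raise ValueError("eye_id must be nested in patient_id")


@dataclass
class NormativeTables:
    """Age-corrected normals, deviation percentiles and percentile profiles."""

    normal_intercept_db: np.ndarray      # (52,) at age 0 (regression intercept)
    normal_slope_db_per_yr: np.ndarray   # (52,)
    td_percentiles: dict[float, np.ndarray]   # {5,2,1,0.5} -> (52,)
    pd_percentiles: dict[float, np.ndarray]
    healthy_mean_rnfl: np.ndarray        # (768,) um
    glaucoma_percentile_profiles: dict[int, np.ndarray]  # {10,5,1} -> (768,)

    def __post_init__(self) -> None:
        q = sorted(self.glaucoma_percentile_profiles)
        if q != [1, 5, 10]:
            raise ValueError("glaucoma percentile profiles must be {1, 5, 10}")

    def normal_thresholds(self, age: float) -> np.ndarray:
        return self.normal_intercept_db + self.normal_slope_db_per_yr * age

    def to_json_dict(self) -> dict:
        return {
            "normal_intercept_db": self.normal_intercept_db.tolist(),
            "normal_slope_db_per_yr": self.normal_slope_db_per_yr.tolist(),
            "td_percentiles": {str(k): v.tolist() for k, v in self.td_percentiles.items()},
            "pd_percentiles": {str(k): v.tolist() for k, v in self.pd_percentiles.items()},
            "healthy_mean_rnfl": self.healthy_mean_rnfl.tolist(),
            "glaucoma_percentile_profiles": {
                str(k): v.tolist() for k, v in self.glaucoma_percentile_profiles.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "NormativeTables":
        return cls(
            normal_intercept_db=np.asarray(d["normal_intercept_db"]),
            normal_slope_db_per_yr=np.asarray(d["normal_slope_db_per_yr"]),
            td_percentiles={float(k): np.asarray(v) for k, v in d["td_percentiles"].items()},
            pd_percentiles={float(k): np.asarray(v) for k, v in d["pd_percentiles"].items()},
            healthy_mean_rnfl=np.asarray(d["healthy_mean_rnfl"]),
            glaucoma_percentile_profiles={
                int(k): np.asarray(v)
                for k, v in d["glaucoma_percentile_profiles"].items()
            },
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def load(cls, path) -> "NormativeTables":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Healthy profile and forward model
# ---------------------------------------------------------------------------

def normative_rnfl_mean(angle_deg, cfg: GeneratorConfig | None = None) -> np.ndarray:
    """Healthy mean RNFL thickness (um) at TSNIT angle(s) in [0, 360).

    Smooth 360-periodic double-hump curve: a temporal base plus circular-
    Gaussian bumps at the superior- and inferior-temporal peaks.
    """
    cfg = cfg or GeneratorConfig()
    ang = np.asarray(angle_deg, dtype=float)
    if np.any(ang < 0) or np.any(ang >= 360.0):
        raise ValueError("angle must be in [0, 360)")
    out = np.full_like(ang, cfg.temporal_base_um, dtype=float)
    for amp, c, w in zip(cfg.peak_amplitude_um, cfg.peak_center_deg, cfg.peak_width_deg):
        d = (ang - c + 180.0) % 360.0 - 180.0
        out = out + amp * np.exp(-0.5 * (d / w) ** 2)
    return out


def sampled_healthy_profile(cfg: GeneratorConfig | None = None) -> np.ndarray:
    """The healthy mean curve sampled at the 768 TSNIT angles."""
    return normative_rnfl_mean(rnfl_angles(), cfg)


def sf_weight_matrix(sectors: SectorAssignment, sigma_map_deg: float) -> np.ndarray:
    """(52, 768) row-normalized circular-Gaussian weights around each
    point's optic-disc entry angle."""
    d = (rnfl_angles()[None, :] - sectors.disc_angle_deg[:, None] + 180.0) % 360.0 - 180.0
    w = np.exp(-0.5 * (d / sigma_map_deg) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def normal_sensitivity(age: float, grid: VfGrid, cfg: GeneratorConfig) -> np.ndarray:
    """Age-corrected normal thresholds N_i(age), dB, per grid point."""
    ecc = np.hypot(*grid.xy().T)
    return (
        cfg.base_sensitivity_db
        - cfg.eccentricity_slope_db_per_deg * ecc
        + cfg.age_slope_db_per_yr * (age - 50.0)
    )


def noise_sd(sensitivity_db, cfg: GeneratorConfig) -> np.ndarray:
    """Threshold-noise SD as a function of noiseless sensitivity."""
    s = np.asarray(sensitivity_db, dtype=float)
    sd = cfg.noise_sigma0_db + cfg.noise_sigma1_db_per_db * np.maximum(
        0.0, cfg.noise_knee_db - s
    )
    return np.minimum(sd, cfg.noise_cap_db)


def forward_sf_model(
    rnfl,
    age: float,
    cfg: GeneratorConfig,
    sectors: SectorAssignment,
    grid: VfGrid | None = None,
    noisy: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Ground-truth mapping from a (…, 768) RNFL profile to 52 thresholds (dB).

    Local thickness ``t_i`` pools the profile with circular-Gaussian weights
    around point i's disc angle; sensitivity is the age-corrected normal plus
    ``10*gamma*log10`` of the floored thickness ratio, clamped to
    ``[0, ceiling]``.  With ``noisy=True``, heteroscedastic Gaussian noise
    (larger at low sensitivity) is added and the result re-clamped.
    """
    grid = grid or build_grid_24_2(RIGHT)
    prof = np.atleast_2d(np.asarray(rnfl, dtype=float))
    if prof.shape[-1] != N_RNFL:
        raise ValueError(f"profile must have {N_RNFL} samples")
    w = sf_weight_matrix(sectors, cfg.sigma_map_deg)
    t = prof @ w.T                                   # (n, 52)
    tbar = w @ sampled_healthy_profile(cfg)          # (52,)
    b = cfg.residual_base_um
    if np.any(tbar <= b):
        raise ValueError("healthy local mean at or below the residual base: degenerate floor")
    eps = 1e-6
    n_age = normal_sensitivity(age, grid, cfg)
    s = n_age + 10.0 * cfg.gamma_db_per_log * np.log10(
        np.maximum(t - b, eps) / (tbar - b)
    )
    s = np.clip(s, 0.0, cfg.ceiling_db)
    if noisy:
        if rng is None:
            raise ValueError("noisy=True requires an rng")
        s = s + rng.normal(0.0, noise_sd(s, cfg))
        s = np.clip(s, 0.0, cfg.ceiling_db)
    return s[0] if np.asarray(rnfl).ndim == 1 else s


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _smooth_circular_noise(rng: np.random.Generator, sd_um: float, n_harm: int = 8) -> np.ndarray:
    """Smooth zero-mean periodic noise, used as OCT segmentation jitter."""
    if sd_um == 0:
        return np.zeros(N_RNFL)
    theta = np.deg2rad(rnfl_angles())
    out = np.zeros(N_RNFL)
    for h in range(1, n_harm + 1):
        a, b = rng.normal(0.0, 1.0, size=2)
        out += a * np.cos(h * theta) + b * np.sin(h * theta)
    return out * (sd_um / np.sqrt(n_harm))


def _apply_wedge(profile: np.ndarray, center: float, width: float, depth: float,
                 floor: float) -> np.ndarray:
    """Multiplicative wedge loss above the tissue floor, cosine-tapered edges."""
    d = np.abs((rnfl_angles() - center + 180.0) % 360.0 - 180.0)
    half = width / 2.0
    shape = np.where(d <= half, 0.5 * (1.0 + np.cos(np.pi * d / half)), 0.0)
    return floor + (profile - floor) * (1.0 - depth * shape)


def _true_eye_profile(rng: np.random.Generator, cfg: GeneratorConfig,
                      glaucoma: bool) -> np.ndarray:
    base = sampled_healthy_profile(cfg)
    b = cfg.residual_base_um
    scale = np.exp(rng.normal(0.0, cfg.subject_scale_sd))
    prof = b + (base - b) * scale
    if glaucoma:
        n_def = 1 + rng.poisson(cfg.extra_defects_poisson_mean)
        for _ in range(n_def):
            if rng.random() < cfg.polar_defect_prob:
                pole = rng.choice([90.0, 270.0])
                center = (pole + rng.normal(0.0, 30.0)) % 360.0
            else:
                center = rng.uniform(0.0, 360.0)
            width = rng.uniform(*cfg.defect_width_deg)
            depth = rng.uniform(*cfg.defect_depth_frac)
            prof = _apply_wedge(prof, center, width, depth, b)
        if rng.random() < cfg.diffuse_prob:
            frac = rng.uniform(*cfg.diffuse_frac)
            prof = b + (prof - b) * (1.0 - frac)
    return np.maximum(prof, 0.0)


def _sample_metadata(rng: np.random.Generator, cfg: GeneratorConfig):
    fl = rng.beta(1.2, 12.0)
    fp = rng.beta(1.2, 25.0)
    q = float(np.clip(rng.normal(27.0, 5.0), 5.0, 40.0))
    fl, fp = min(fl, 0.33), min(fp, 0.15)
    q = max(q, 15.0)
    if rng.random() < cfg.filter_fail_frac:
        which = rng.integers(3)
        if which == 0:
            fl = rng.uniform(0.34, 0.6)
        elif which == 1:
            fp = rng.uniform(0.16, 0.4)
        else:
            q = rng.uniform(5.0, 14.9)
    return float(fl), float(fp), q


def simulate_cohort(cfg: GeneratorConfig,
                    sectors: SectorAssignment | None = None) -> list[PairedExam]:
    """Sample a hierarchical cohort: patients -> eyes -> paired tests.

    Each eye owns a true RNFL profile (healthy jittered double-hump, with
    wedge defects and diffuse loss if the patient is glaucomatous); every
    test of that eye re-measures it with smooth OCT noise and generates the
    field with the noisy forward model.  Left-eye profiles/fields are stored
    in their own convention (mirror of right).  Deterministic given the seed.
    """
    if cfg.n_patients <= 0:
        raise ValueError("n_patients must be positive")
    grid = build_grid_24_2(RIGHT)
    sectors = sectors or assign_gh_sectors(grid)
    rng = np.random.default_rng(cfg.seed)
    exams: list[PairedExam] = []
    for p in range(cfg.n_patients):
        pid = f"P{p:05d}"
        glaucoma = bool(rng.random() < cfg.fraction_glaucoma)
        age0 = float(np.clip(rng.normal(cfg.age_mean_yr, cfg.age_sd_yr), 40.0, 90.0))
        sides = [RIGHT, LEFT] if rng.random() < cfg.both_eyes_prob else [
            RIGHT if rng.random() < 0.5 else LEFT
        ]
        base_day = int(rng.integers(0, 1000))
        for side in sides:
            eye_id = f"{pid}-{'OD' if side == RIGHT else 'OS'}"
            true_prof = _true_eye_profile(rng, cfg, glaucoma)  # right-eye convention
            n_tests = 1 + int(rng.poisson(cfg.extra_tests_poisson_mean))
            for t in range(n_tests):
                day = base_day + t * int(rng.integers(120, 260))
                sap_date = _EPOCH + timedelta(days=day)
                oct_date = sap_date + timedelta(days=int(rng.integers(-60, 61)))
                age = age0 + day / 365.25
                measured = true_prof + _smooth_circular_noise(rng, cfg.oct_noise_um)
                measured = np.maximum(measured, 0.0)
                true_vf = forward_sf_model(true_prof, age, cfg, sectors, grid)
                vf = forward_sf_model(measured, age, cfg, sectors, grid,
                                      noisy=True, rng=rng)
                fl, fp, q = _sample_metadata(rng, cfg)
                if side == LEFT:
                    # store device (own-eye) convention; the mirror maps are
                    # involutions so the same function recovers right-eye order
                    measured = mirror_profile(measured, LEFT)
                    vf = mirror_field(vf, LEFT)
                    true_vf = mirror_field(true_vf, LEFT)
                exams.append(
                    PairedExam(
                        patient_id=pid,
                        eye_id=eye_id,
                        laterality=side,
                        test_date_sap=sap_date,
                        test_date_oct=oct_date,
                        age_years=age,
                        rnfl=measured,
                        vf=vf,
                        fixation_loss_frac=fl,
                        false_positive_frac=fp,
                        oct_quality_score=q,
                        true_vf=true_vf,
                        is_glaucoma=glaucoma,
                    )
                )
    return exams


def exam_arrays_right_eye(exam: PairedExam) -> tuple[np.ndarray, np.ndarray]:
    """(rnfl, vf) of one exam normalized to right-eye convention."""
    return (
        mirror_profile(exam.rnfl, exam.laterality),
        mirror_field(exam.vf, exam.laterality),
    )


# ---------------------------------------------------------------------------
# Normative tables
# ---------------------------------------------------------------------------

TD_PD_CUTS = (5.0, 2.0, 1.0, 0.5)


def empirical_percentile(values: np.ndarray, q: float, axis: int = 0) -> np.ndarray:
    """Linear-interpolation empirical percentile (the package-wide choice)."""
    return np.percentile(values, q, axis=axis, method="linear")


def derive_normative_tables(
    healthy: list[PairedExam],
    glaucoma: list[PairedExam],
    cfg: GeneratorConfig | None = None,
) -> NormativeTables:
    """Build normative tables from cohort subgroups.

    Healthy exams give (i) a per-point linear age regression of threshold,
    (ii) empirical 5/2/1/0.5 percentiles of total and pattern deviation and
    (iii) the mean RNFL profile.  Glaucoma exams give the pointwise 10/5/1
    percentile profiles used as simulated-defect depths.  RNFL profiles are
    normalized to right-eye convention first.
    """
    import warnings

    if not healthy or not glaucoma:
        raise ValueError("need at least one healthy and one glaucoma exam")
    if len(healthy) < 50 or len(glaucoma) < 100:
        warnings.warn(
            "small normative samples (recommended >=50 healthy, >=100 glaucoma)",
            stacklevel=2,
        )
    ages = np.array([e.age_years for e in healthy])
    vf = np.array([mirror_field(e.vf, e.laterality) for e in healthy])  # (n, 52)
    X = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(X, vf, rcond=None)                # (2, 52)
    intercept, slope = coef
    if len(healthy) < 2:
        slope = np.zeros(N_VF)
        intercept = vf[0]
    td = vf - (intercept + np.outer(ages, slope))
    gh = np.sort(td, axis=1)[:, -7]                              # 7th largest
    pdev = td - gh[:, None]
    td_pct = {q: empirical_percentile(td, q) for q in TD_PD_CUTS}
    pd_pct = {q: empirical_percentile(pdev, q) for q in TD_PD_CUTS}
    h_rnfl = np.array([mirror_profile(e.rnfl, e.laterality) for e in healthy])
    g_rnfl = np.array([mirror_profile(e.rnfl, e.laterality) for e in glaucoma])
    pct_prof = {q: empirical_percentile(g_rnfl, q) for q in (10, 5, 1)}
    return NormativeTables(
        normal_intercept_db=intercept,
        normal_slope_db_per_yr=slope,
        td_percentiles=td_pct,
        pd_percentiles=pd_pct,
        healthy_mean_rnfl=h_rnfl.mean(axis=0),
        glaucoma_percentile_profiles=pct_prof,
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def cohort_to_frames(exams: list[PairedExam]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(metadata, wide-format measurements) DataFrames, one row per exam."""
    meta = pd.DataFrame(
        {
            "exam_id": range(len(exams)),
            "patient_id": [e.patient_id for e in exams],
            "eye_id": [e.eye_id for e in exams],
            "laterality": [e.laterality for e in exams],
            "test_date_sap": [e.test_date_sap.isoformat() for e in exams],
            "test_date_oct": [e.test_date_oct.isoformat() for e in exams],
            "age_years": [e.age_years for e in exams],
            "fixation_loss_frac": [e.fixation_loss_frac for e in exams],
            "false_positive_frac": [e.false_positive_frac for e in exams],
            "oct_quality_score": [e.oct_quality_score for e in exams],
            "is_glaucoma": [e.is_glaucoma for e in exams],
        }
    )
    rnfl = pd.DataFrame(
        np.array([e.rnfl for e in exams]),
        columns=[f"rnfl_{k:03d}" for k in range(N_RNFL)],
    )
    vfd = pd.DataFrame(
        np.array([e.vf for e in exams]),
        columns=[f"vf_{i:02d}" for i in range(N_VF)],
    )
    wide = pd.concat([pd.Series(range(len(exams)), name="exam_id"), rnfl, vfd], axis=1)
    return meta, wide


def frames_to_cohort(meta: pd.DataFrame, wide: pd.DataFrame) -> list[PairedExam]:
    wide = wide.set_index("exam_id").loc[meta["exam_id"]]
    rn = wide[[f"rnfl_{k:03d}" for k in range(N_RNFL)]].to_numpy()
    vf = wide[[f"vf_{i:02d}" for i in range(N_VF)]].to_numpy()
    out = []
    for j, row in enumerate(meta.itertuples(index=False)):
        out.append(
            PairedExam(
                patient_id=row.patient_id,
                eye_id=row.eye_id,
                laterality=row.laterality,
                test_date_sap=date.fromisoformat(row.test_date_sap),
                test_date_oct=date.fromisoformat(row.test_date_oct),
                age_years=float(row.age_years),
                rnfl=rn[j],
                vf=vf[j],
                fixation_loss_frac=float(row.fixation_loss_frac),
                false_positive_frac=float(row.false_positive_frac),
                oct_quality_score=float(row.oct_quality_score),
                is_glaucoma=None if pd.isna(row.is_glaucoma) else bool(row.is_glaucoma),
            )
        )
    return out


def write_cohort(exams: list[PairedExam], out_dir, cfg: GeneratorConfig | None = None) -> None:
    """Write exams.csv / measurements.csv (+ manifest.json with the config)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta, wide = cohort_to_frames(exams)
    meta.to_csv(out / "exams.csv", index=False)
    wide.to_csv(out / "measurements.csv", index=False)
    if cfg is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump({"generator_config": cfg.to_json_dict()}, fh, indent=2)


def read_cohort(in_dir) -> list[PairedExam]:
    from pathlib import Path

    p = Path(in_dir)
    meta = pd.read_csv(p / "exams.csv")
    wide = pd.read_csv(p / "measurements.csv")
    return frames_to_cohort(meta, wide)
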