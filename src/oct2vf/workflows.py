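"""End-to-end study workflow: generate a cohort, curate it, train the CNN
and the OLS baseline, evaluate on the held-out patients, and assemble the
structure-function map.

This is the programmatic equivalent of running the CLI subcommands in
sequence, returning all intermediate objects.  The default problem size
(1,500 patients, ~5,000 paired exams, 30 epochs) is chosen so the whole
study runs in minutes on a single CPU while leaving enough signal for the
nonlinear model to separate from the linear baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation
from .cohort_prep import SplitResult, apply_reliability_filters, split_by_patient
from .defect_sim import DEPTHS
from .sf_model import (
    LinearBaseline,
    TrainedModel,
    TrainingConfig,
    build_cnn,
    exams_to_xy,
    fit_linear_baseline,
    train_cnn,
)
from .sfmap import SfMap, build_sf_map
from .synthetic_cohort import (
    GeneratorConfig,
    NormativeTables,
    PairedExam,
    derive_normative_tables,
    noise_sd,
    simulate_cohort,
)
from .vf_geometry import SectorAssignment, VfGrid, assign_gh_sectors, build_grid_24_2


@dataclass
class StudyResult:
    cfg: GeneratorConfig
    grid: VfGrid
    sectors: SectorAssignment
    exams: list[PairedExam]
    kept: list[PairedExam]
    split: SplitResult
    normative: NormativeTables
    cnn: TrainedModel
    ols: LinearBaseline
    pred_cnn: np.ndarray
    pred_ols: np.ndarray
    y_test: np.ndarray
    metrics_cnn: evaluation.PointwiseMetrics
    metrics_ols: evaluation.PointwiseMetrics
    avg_noise_sd: float
    sf_map: SfMap = None


def run_structure_function_study(
    seed: int = 0,
    n_patients: int = 1500,
    epochs: int = 30,
    batch_size: int = 128,
    fraction_glaucoma: float = 0.7,
    build_map: bool = True,
    verbose: bool = False,
) -> StudyResult:
    """Run the full synthetic study once, deterministically per seed.

    Steps: simulate cohort -> reliability/quality filters -> patient-level
    split -> train CNN (best-val-MSE checkpoint) + OLS baseline -> test-set
    pointwise metrics -> normative tables -> structure-function map from
    the trained CNN.

    ``avg_noise_sd`` is the generator's mean threshold-noise SD over all
    test-set points (computed from the ground-truth noiseless fields) — the
    irreducible-error scale predictions can be judged against.
    """
    cfg = GeneratorConfig(
        n_patients=n_patients, fraction_glaucoma=fraction_glaucoma, seed=seed
    )
    grid = build_grid_24_2()
    sectors = assign_gh_sectors(grid)
    exams = simulate_cohort(cfg, sectors)
    kept, _ = apply_reliability_filters(exams)
    split = split_by_patient(kept, test_frac=0.15, val_frac=0.15, seed=seed)

    net = build_cnn(seed=seed)
    tcfg = TrainingConfig(epochs=epochs, batch_size=batch_size, seed=seed)
    cnn = train_cnn(net, split.train, split.validation, tcfg, verbose=verbose)
    ols = fit_linear_baseline(split.train)

    x_test, y_test = exams_to_xy(split.test)
    pred_cnn = cnn.predict(x_test)
    pred_ols = ols.predict(x_test)
    metrics_cnn = evaluation.pointwise_metrics(pred_cnn, y_test)
    metrics_ols = evaluation.pointwise_metrics(pred_ols, y_test)

    true_vf = np.array([e.true_vf for e in split.test])
    avg_noise = float(np.mean(noise_sd(true_vf, cfg)))

    healthy = [e for e in exams if not e.is_glaucoma]
    glauc = [e for e in exams if e.is_glaucoma]
    normative = derive_normative_tables(healthy, glauc, cfg)

    sf_map = None
    if build_map:
        sf_map = build_sf_map(
            cnn, normative.healthy_mean_rnfl, normative, age=60.0, depths=DEPTHS
        )
    return StudyResult(
        cfg=cfg,
        grid=grid,
        sectors=sectors,
        exams=exams,
        kept=kept,
        split=split,
        normative=normative,
        cnn=cnn,
        ols=ols,
        pred_cnn=pred_cnn,
        pred_ols=pred_ols,
        y_test=y_test,
        metrics_cnn=metrics_cnn,
        metrics_ols=metrics_ols,
        avg_noise_sd=avg_noise,
        sf_map=sf_map,
    )
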