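"""Test-set statistics for structure-function models.

Pointwise and Garway-Heath-sector MAE and Pearson correlations, cluster
(patient) bootstrap confidence intervals, model-comparison tests (bootstrap
difference of correlations with a Fisher-z reference, and a random-intercept
mixed model on absolute errors), error-by-measured-threshold bins, and
exam-level error correlates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vf_geometry import GH_SECTORS, N_VF, SectorAssignment


# ---------------------------------------------------------------------------
# Pointwise metrics
# ---------------------------------------------------------------------------

@dataclass
class PointwiseMetrics:
    mae: np.ndarray          # (52,) dB
    r: np.ndarray            # (52,) Pearson r; NaN where undefined
    mae_avg: float
    r_avg: float             # mean of defined per-point r's
    mae_ci: tuple[float, float] | None = None
    r_ci: tuple[float, float] | None = None


def pointwise_metrics(pred: np.ndarray, meas: np.ndarray,
                      pooled_r: bool = False) -> PointwiseMetrics:
    """Per-location MAE and Pearson r between predicted and measured fields.

    ``pred``/``meas`` are (n_exams, 52).  The average r is the mean of the 52
    per-point correlations (points with zero variance in either series are
    reported NaN with a warning and excluded from it); ``pooled_r=True``
    computes one correlation over all point-exam pairs instead.
    """
    import warnings

    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("prediction and measurement shapes differ")
    if pred.ndim != 2 or pred.shape[1] != N_VF:
        raise ValueError(f"expected (n, {N_VF}) arrays")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 exams")
    mae = np.mean(np.abs(pred - meas), axis=0)
    r = np.empty(N_VF)
    for i in range(N_VF):
        if np.std(pred[:, i]) == 0 or np.std(meas[:, i]) == 0:
            r[i] = np.nan
        else:
            r[i] = np.corrcoef(pred[:, i], meas[:, i])[0, 1]
    if np.isnan(r).any():
        warnings.warn(
            f"{int(np.isnan(r).sum())} points with zero variance: r undefined, "
            "excluded from the average",
            stacklevel=2,
        )
    if pooled_r:
        r_avg = float(np.corrcoef(pred.ravel(), meas.ravel())[0, 1])
    else:
        r_avg = float(np.nanmean(r))
    return PointwiseMetrics(mae=mae, r=r, mae_avg=float(mae.mean()), r_avg=r_avg)


def pearson_p_two_sided(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t approximation."""
    if n < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else np.nan
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# Cluster bootstrap
# ---------------------------------------------------------------------------

def bootstrap_cis(
    statistic,
    cluster_ids,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Cluster (patient) bootstrap percentile CIs.

    ``statistic(exam_indices)`` maps an index array (rows of the resampled
    exams, with repetition) to a scalar or vector; clusters are resampled
    with replacement and all their exams included.  Returns (lo, hi) arrays
    at the 2.5/97.5 percentiles (for alpha=0.05) plus the bootstrap draws.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    ids = np.asarray(cluster_ids)
    uniq = np.unique(ids)
    if uniq.size < 2:
        raise ValueError("need at least two clusters to bootstrap")
    members = [np.flatnonzero(ids == c) for c in uniq]
    sizes = {m.size for m in members}
    uniform = np.array(members) if len(sizes) == 1 else None
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        chosen = rng.integers(0, uniq.size, size=uniq.size)
        if uniform is not None:
            idx = uniform[chosen].ravel()
        else:
            idx = np.concatenate([members[c] for c in chosen])
        draws.append(np.atleast_1d(np.asarray(statistic(idx), dtype=float)))
    draws = np.vstack(draws)
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return lo, hi, draws


# ---------------------------------------------------------------------------
# Sector metrics
# ---------------------------------------------------------------------------

def sector_averages(fields: np.ndarray, sectors: SectorAssignment) -> pd.DataFrame:
    """(n_exams, 6) per-exam mean threshold by Garway-Heath sector."""
    fields = np.atleast_2d(np.asarray(fields, dtype=float))
    cols = {}
    for s in GH_SECTORS:
        idx = sectors.indices(s)
        if idx.size == 0:
            raise ValueError(f"sector {s!r} is empty")
        cols[s] = fields[:, idx].mean(axis=1)
    return pd.DataFrame(cols)


def sector_metrics(pred: np.ndarray, meas: np.ndarray,
                   sectors: SectorAssignment) -> pd.DataFrame:
    """MAE and Pearson r computed on sector-averaged values (Table-2 shape)."""
    pa = sector_averages(pred, sectors)
    ma = sector_averages(meas, sectors)
    rows = []
    for s in GH_SECTORS:
        err = np.abs(pa[s] - ma[s])
        r = (
            np.nan
            if pa[s].std() == 0 or ma[s].std() == 0
            else float(np.corrcoef(pa[s], ma[s])[0, 1])
        )
        rows.append({"sector": s, "mae": float(err.mean()), "r": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model comparisons
# ---------------------------------------------------------------------------

def _avg_r(pred, meas, idx):
    """Mean of per-point Pearson r, columnwise vectorized."""
    sub_p, sub_m = pred[idx], meas[idx]
    cp = sub_p - sub_p.mean(axis=0)
    cm = sub_m - sub_m.mean(axis=0)
    denom = np.sqrt((cp**2).sum(axis=0) * (cm**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cp * cm).sum(axis=0) / denom
    return float(np.nanmean(np.where(denom > 0, r, np.nan)))


def compare_models_correlation(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    meas: np.ndarray,
    cluster_ids,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Test the difference in average pointwise r between two models.

    Primary: cluster bootstrap of ``r_A - r_B`` (percentile CI; two-sided p
    by percentile inversion of the sign).  A Fisher-z statistic on the
    average correlations is reported alongside for reference (it ignores
    both the within-patient clustering and the A/B pairing).
    """
    pred_a, pred_b, meas = (np.asarray(v, dtype=float) for v in (pred_a, pred_b, meas))
    if not (pred_a.shape == pred_b.shape == meas.shape):
        raise ValueError("both models must predict the same exam set")
    delta_obs = _avg_r(pred_a, meas, slice(None)) - _avg_r(pred_b, meas, slice(None))
    lo, hi, draws = bootstrap_cis(
        lambda idx: _avg_r(pred_a, meas, idx) - _avg_r(pred_b, meas, idx),
        cluster_ids,
        n_boot=n_boot,
        seed=seed,
    )
    d = draws[:, 0]
    p_boot = 2 * min(np.mean(d <= 0), np.mean(d >= 0))
    p_boot = min(1.0, max(p_boot, 1.0 / len(d)))
    if np.allclose(pred_a, pred_b):
        p_boot = 1.0
    ra, rb = _avg_r(pred_a, meas, slice(None)), _avg_r(pred_b, meas, slice(None))
    n = meas.shape[0]
    za, zb = np.arctanh(np.clip([ra, rb], -0.999999, 0.999999))
    z = (za - zb) / np.sqrt(2.0 / max(n - 3, 1))
    return {
        "delta_r": float(delta_obs),
        "ci": (float(lo[0]), float(hi[0])),
        "p_bootstrap": float(p_boot),
        "fisher_z": float(z),
        "p_fisher": float(2 * stats.norm.sf(abs(z))),
        "r_a": ra,
        "r_b": rb,
    }


def compare_models_abs_error(
    abs_err_a: np.ndarray,
    abs_err_b: np.ndarray,
    participant_ids,
) -> dict:
    """Random-intercept comparison of exam-level absolute errors.

    Fits ``|err| ~ model_indicator + (1 | participant)`` on the long-format
    stack of both models' per-exam absolute errors, accounting for multiple
    tests per participant.  Returns the model coefficient (B minus A), its
    SE and p-value.
    """
    import statsmodels.formula.api as smf

    a = np.asarray(abs_err_a, dtype=float)
    b = np.asarray(abs_err_b, dtype=float)
    ids = np.asarray(participant_ids)
    if a.shape != b.shape or a.shape[0] != ids.shape[0]:
        raise ValueError("error vectors and participant ids must align")
    if np.unique(ids).size < 2:
        raise ValueError("need at least two participants")
    df = pd.DataFrame(
        {
            "abs_error": np.concatenate([a, b]),
            "model": np.repeat([0.0, 1.0], a.size),
            "participant": np.concatenate([ids, ids]),
        }
    )
    if np.allclose(a, b):
        # degenerate: no contrast; the MLE coefficient is exactly 0
        return {"coef": 0.0, "se": 0.0, "p": 1.0, "converged": True}
    md = smf.mixedlm("abs_error ~ model", df, groups=df["participant"])
    with np.errstate(all="ignore"):
        fit = md.fit(reml=True, method="lbfgs")
    return {
        "coef": float(fit.params["model"]),
        "se": float(fit.bse["model"]),
        "p": float(fit.pvalues["model"]),
        "converged": bool(fit.converged),
    }


# ---------------------------------------------------------------------------
# Error structure
# ---------------------------------------------------------------------------

def mae_by_threshold_bins(pred: np.ndarray, meas: np.ndarray,
                          bin_width: float = 2.0,
                          lo: float = 0.0, hi: float = 40.0) -> pd.DataFrame:
    """MAE grouped by bins of the measured threshold, plus bin counts.

    Bins are ``[lo, lo+w), ...`` covering [0, 40] dB; the last bin is closed.
    Empty bins report NaN MAE.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    meas = np.asarray(meas, dtype=float).ravel()
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    which = np.digitize(meas, edges[1:-1], right=False)
    rows = []
    for b in range(len(edges) - 1):
        m = which == b
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "count": int(m.sum()),
                "mae": float(np.mean(np.abs(pred[m] - meas[m]))) if m.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def error_correlates(mean_abs_error: np.ndarray, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with two-sided p) of exam-level mean |error| against each
    exam-level covariate (e.g. MD, PSD, global RNFL thickness)."""
    err = np.asarray(mean_abs_error, dtype=float)
    if err.size < 3:
        raise ValueError("need at least 3 exams")
    rows = []
    for col in covariates.columns:
        v = covariates[col].to_numpy(dtype=float)
        r = float(np.corrcoef(err, v)[0, 1])
        rows.append({"covariate": col, "r": r, "p": pearson_p_two_sided(r, err.size)})
    return pd.DataFrame(rows)
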