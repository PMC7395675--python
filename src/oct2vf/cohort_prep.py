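"""Cohort curation: SAP-OCT pairing, reliability/quality filters, and
patient-level train/validation/test splitting.

The curation rules follow standard registry practice: a SAP test is usable
only with an OCT scan of the same eye acquired within 180 days; unreliable
fields (>33% fixation losses or >15% false positives) and poor scans
(quality score below 15) are excluded; and the split into training,
validation and test sets is randomized at the *patient* level so no
patient contributes to more than one set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .synthetic_cohort import PairedExam

MAX_PAIRING_DAYS = 180
MAX_FIXATION_LOSS = 0.33
MAX_FALSE_POSITIVE = 0.15
MIN_QUALITY_SCORE = 15.0


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_exams(
    sap: pd.DataFrame,
    oct_scans: pd.DataFrame,
    max_days: int = MAX_PAIRING_DAYS,
) -> tuple[pd.DataFrame, dict]:
    """Pair each SAP test with the nearest-in-time OCT of the same eye.

    ``sap`` and ``oct_scans`` need ``eye_id`` and ``date`` columns (dates or
    ISO strings).  Within each eye every SAP row is matched to the OCT row
    minimizing |Delta days|, kept only if |Delta| <= max_days (boundary
    inclusive); ties go to the earlier OCT.  One OCT may serve several SAPs.
    Returns the merged pair table and a log of dropped SAP counts.
    """
    sap = sap.copy()
    oct_scans = oct_scans.copy()
    sap["date"] = pd.to_datetime(sap["date"])
    oct_scans["date"] = pd.to_datetime(oct_scans["date"])
    pairs = []
    dropped = 0
    oct_by_eye = dict(tuple(oct_scans.groupby("eye_id")))
    for _, srow in sap.iterrows():
        cands = oct_by_eye.get(srow["eye_id"])
        if cands is None:
            dropped += 1
            continue
        delta = (cands["date"] - srow["date"]).dt.days.abs()
        best = delta.min()
        if best > max_days:
            dropped += 1
            continue
        tied = cands[delta == best]
        orow = tied.sort_values("date").iloc[0]   # earlier OCT wins ties
        rec = {f"sap_{k}": v for k, v in srow.items()}
        rec.update({f"oct_{k}": v for k, v in orow.items()})
        rec["delta_days"] = int(best)
        pairs.append(rec)
    log = {"n_sap": len(sap), "n_paired": len(pairs), "n_dropped": dropped}
    return pd.DataFrame(pairs), log


# ---------------------------------------------------------------------------
# Reliability / quality filters
# ---------------------------------------------------------------------------

def apply_reliability_filters(
    pairs: list[PairedExam],
) -> tuple[list[PairedExam], pd.DataFrame]:
    """Drop unreliable/poor-quality exams; keep iff

    fixation_loss <= 0.33 and false_positive <= 0.15 and quality >= 15.

    The boundaries follow the stated wording literally: "more than 33%" and
    "more than 15%" exclude strictly above; "lower than 15" excludes
    strictly below.  Missing metadata excludes with reason
    ``missing_metadata``.  Returns (kept, exclusion log).  Idempotent.
    """
    kept: list[PairedExam] = []
    reasons: list[tuple[int, str]] = []
    for i, e in enumerate(pairs):
        meta = (e.fixation_loss_frac, e.false_positive_frac, e.oct_quality_score)
        if any(m is None or (isinstance(m, float) and np.isnan(m)) for m in meta):
            reasons.append((i, "missing_metadata"))
            continue
        if e.fixation_loss_frac > MAX_FIXATION_LOSS:
            reasons.append((i, "fixation_loss"))
            continue
        if e.false_positive_frac > MAX_FALSE_POSITIVE:
            reasons.append((i, "false_positive"))
            continue
        if e.oct_quality_score < MIN_QUALITY_SCORE:
            reasons.append((i, "low_quality"))
            continue
        kept.append(e)
    log = pd.DataFrame(reasons, columns=["exam_index", "reason"])
    return kept, log


# ---------------------------------------------------------------------------
# Patient-level split
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    train: list[PairedExam]
    validation: list[PairedExam]
    test: list[PairedExam]
    patient_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [set(self.patient_ids.get(k, [])) for k in ("train", "validation", "test")]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("patient appears in more than one set")


def split_by_patient(
    pairs: list[PairedExam],
    test_frac: float = 0.15,
    val_frac: float = 0.15,
    seed: int = 0,
) -> SplitResult:
    """Partition exams into train/validation/test at the patient level.

    Patients are shuffled with a seeded RNG; the first ``test_frac`` of
    patients form the test set, the next ``val_frac`` *of the remainder*
    the validation set, and the rest train.  Every exam follows its patient,
    so no patient is present in more than one set.  Deterministic per seed.
    """
    if not (0.0 < test_frac < 1.0 and 0.0 < val_frac < 1.0):
        raise ValueError("fractions must be in (0, 1)")
    patients = sorted({e.patient_id for e in pairs})
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to form 3 sets")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n_test = max(1, round(test_frac * len(order)))
    n_val = max(1, round(val_frac * (len(order) - n_test)))
    test_ids = set(order[:n_test])
    val_ids = set(order[n_test : n_test + n_val])
    train_ids = set(order[n_test + n_val :])
    if not train_ids:
        raise ValueError("no patients left for the training set")
    by_set = {"train": [], "validation": [], "test": []}
    for e in pairs:
        if e.patient_id in test_ids:
            by_set["test"].append(e)
        elif e.patient_id in val_ids:
            by_set["validation"].append(e)
        else:
            by_set["train"].append(e)
    return SplitResult(
        train=by_set["train"],
        validation=by_set["validation"],
        test=by_set["test"],
        patient_ids={
            "train": sorted(train_ids),
            "validation": sorted(val_ids),
            "test": sorted(test_ids),
        },
    )
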