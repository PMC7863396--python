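"""Micronutrient status classification from biomarker values.

Cut-offs follow clinical practice for young children: retinol-binding
protein (RBP) below 0.83 umol/l marks vitamin A deficiency and below
1.17 umol/l insufficiency; total 25-hydroxyvitamin D below 50 nmol/l marks
vitamin D insufficiency. Boundary values belong to the better category —
pathology is "below the cut-off". Vitamin A status can also be estimated
from a published regression of retinol on RBP, transthyretin, and CRP
(inflammation-corrected); its coefficients live in the cited external
validation study and must be supplied through configuration, never guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InputError, UnitError

RBP_DEFICIENCY_CUTOFF = 0.83  # umol/l
RBP_INSUFFICIENCY_CUTOFF = 1.17  # umol/l
VITAMIN_D_CUTOFF = 50.0  # nmol/l total 25(OH)D
RETINOL_DEFICIENCY_THRESHOLD = 0.70  # umol/l, conventional

#: erythrocyte folate reference interval, nmol/l
FOLATE_REFERENCE_RANGE = (208.0, 972.0)

#: upper linear detection limit of transcobalamin-bound B12, pmol/l
B12_DETECTION_LIMIT = 128.0


@dataclass(frozen=True)
class StatusCall:
    participant: str
    analyte: str
    value: float
    unit: str
    status: str  # sufficient | insufficient | deficient | censored | not_evaluable
    rule: str


@dataclass(frozen=True)
class VitaminAModel:
    """Linear estimator of serum retinol from RBP, transthyretin, and CRP."""

    intercept: float
    coef_rbp: float
    coef_transthyretin: float
    coef_crp: float
    crp_transform: str = "log1p"
    threshold: float = RETINOL_DEFICIENCY_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("intercept", "coef_rbp", "coef_transthyretin", "coef_crp"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"vitamin A model: {name} not finite")
        if self.threshold <= 0:
            raise ConfigurationError("vitamin A model: threshold must be > 0")


def _check_unit(unit: str, expected: str, analyte: str) -> None:
    norm = unit.strip().lower().replace("µ", "u").replace("μ", "u")
    if norm != expected.lower():
        raise UnitError(f"{analyte} expects {expected}, got {unit!r}")


def classify_rbp(
    rbp: float, participant: str = "", unit: str = "umol/l"
) -> StatusCall:
    """Vitamin A status from RBP: < 0.83 deficient, < 1.17 insufficient."""
    _check_unit(unit, "umol/l", "RBP")
    if rbp < 0:
        raise InputError(f"negative RBP value {rbp}")
    if rbp < RBP_DEFICIENCY_CUTOFF:
        status, rule = "deficient", f"rbp<{RBP_DEFICIENCY_CUTOFF}"
    elif rbp < RBP_INSUFFICIENCY_CUTOFF:
        status, rule = "insufficient", f"rbp<{RBP_INSUFFICIENCY_CUTOFF}"
    else:
        status, rule = "sufficient", f"rbp>={RBP_INSUFFICIENCY_CUTOFF}"
    return StatusCall(participant, "rbp", float(rbp), "umol/l", status, rule)


def classify_vitamin_d(
    total_25ohd: float, participant: str = "", unit: str = "nmol/l"
) -> StatusCall:
    """Vitamin D status from total 25(OH)D: < 50 nmol/l insufficient."""
    _check_unit(unit, "nmol/l", "25(OH)D")
    if total_25ohd < 0:
        raise InputError(f"negative 25(OH)D value {total_25ohd}")
    if total_25ohd < VITAMIN_D_CUTOFF:
        status, rule = "insufficient", f"25ohd<{VITAMIN_D_CUTOFF}"
    else:
        status, rule = "sufficient", f"25ohd>={VITAMIN_D_CUTOFF}"
    return StatusCall(participant, "vitd_25oh", float(total_25ohd), "nmol/l", status, rule)


def vitamin_a_model_estimate(
    rbp: float,
    transthyretin: float,
    crp: float,
    model: VitaminAModel | None,
    participant: str = "",
) -> tuple[float, StatusCall]:
    """Inflammation-adjusted retinol estimate and its deficiency call."""
    if model is None:
        raise ConfigurationError(
            "vitamin A regression model unconfigured: supply the published "
            "coefficients (intercept, RBP, transthyretin, CRP) via the rules "
            "file; they are not hard-coded here"
        )
    if min(rbp, transthyretin, crp) < 0:
        raise InputError("vitamin A model inputs must be >= 0")
    if model.crp_transform == "log1p":
        crp_term = math.log1p(crp)
    elif model.crp_transform == "identity":
        crp_term = crp
    else:
        raise ConfigurationError(f"unknown CRP transform {model.crp_transform!r}")
    estimate = (
        model.intercept
        + model.coef_rbp * rbp
        + model.coef_transthyretin * transthyretin
        + model.coef_crp * crp_term
    )
    status = "deficient" if estimate < model.threshold else "sufficient"
    call = StatusCall(
        participant, "retinol_estimate", float(estimate), "umol/l",
        status, f"talsma_model<{model.threshold}",
    )
    return float(estimate), call


def flag_reference_range(value: float, lo: float, hi: float) -> str:
    """Three-way call against a reference interval; boundaries are within."""
    if lo >= hi:
        raise InputError(f"reference range requires lo < hi, got ({lo}, {hi})")
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "within"


def censored_fraction(values, censored, limit: float) -> float:
    """Fraction of records censored at the assay's upper detection limit."""
    values = np.asarray(values, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if values.size == 0:
        raise InputError("censored_fraction requires >= 1 record")
    bad = censored & (values != limit)
    if bad.any():
        raise DataError(
            f"{int(bad.sum())} censored record(s) not stored at the limit {limit}"
        )
    return float(censored.mean())


def conjugation_ratio(bile_acid_table: pd.DataFrame) -> pd.DataFrame:
    """Taurine:glycine bile-acid conjugation ratio per participant.

    Expects columns id, conjugation ({taurine, glycine, none}), value. The
    ratio is the summed taurine-conjugated concentration over the summed
    glycine-conjugated concentration; a zero glycine denominator yields a
    not_evaluable row, not an exception.
    """
    required = {"id", "conjugation", "value"}
    if not required <= set(bile_acid_table.columns):
        raise InputError(f"bile acid table needs columns {sorted(required)}")
    rows = []
    for pid, sub in bile_acid_table.groupby("id", sort=True):
        tau = sub.loc[sub["conjugation"] == "taurine", "value"].sum()
        gly = sub.loc[sub["conjugation"] == "glycine", "value"].sum()
        if gly > 0:
            rows.append({"id": pid, "ratio": tau / gly, "status": "ok"})
        else:
            rows.append({"id": pid, "ratio": float("nan"), "status": "not_evaluable"})
    return pd.DataFrame(rows)


def classify_cohort(cohort, vitamin_a_model: VitaminAModel | None = None) -> pd.DataFrame:
    """Status calls for every classifiable biomarker record in a cohort.

    Censored records become status "censored" (the assay saw >= the limit;
    no cut-off applies). Analytes without a classification rule are skipped.
    """
    calls: list[StatusCall] = []
    bio = cohort.biomarkers
    for row in bio.itertuples():
        if row.censored:
            calls.append(
                StatusCall(row.id, row.analyte, float(row.value), row.unit,
                           "censored", f"censored@{row.value}")
            )
            continue
        if row.analyte == "rbp":
            calls.append(classify_rbp(row.value, row.id, row.unit))
        elif row.analyte == "vitd_25oh":
            calls.append(classify_vitamin_d(row.value, row.id, row.unit))
        elif row.analyte == "folate_rbc":
            flag = flag_reference_range(row.value, *FOLATE_REFERENCE_RANGE)
            status = {"below": "deficient", "within": "sufficient",
                      "above": "above_reference"}[flag]
            calls.append(
                StatusCall(row.id, row.analyte, float(row.value), row.unit,
                           status, f"ref_range{FOLATE_REFERENCE_RANGE}")
            )
    if vitamin_a_model is not None:
        wide = bio.pivot_table(index="id", columns="analyte", values="value")
        if {"rbp", "transthyretin", "crp"} <= set(wide.columns):
            for pid, r in wide.iterrows():
                _, call = vitamin_a_model_estimate(
                    r["rbp"], r["transthyretin"], r["crp"], vitamin_a_model, pid
                )
                calls.append(call)
    return pd.DataFrame([c.__dict__ for c in calls])
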