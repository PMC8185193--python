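"""Log-gonadotropin regression quantifying gonadal damage after radiotherapy.

FSH and LH rise when gonadal (ovarian/testicular) feedback fails, so
log-transformed hormone levels are a continuous readout of gonadal damage.
The model fitted here is a linear regression of ln(FSH) and ln(LH) on

    intercept + age(z) + sex + age×sex + chemo(ABVD vs 2+2) + RT field (IDRT vs SDRT)

where age is z-scored over the cohort, sex is coded symmetrically (±½ by
default, female positive; 0/1 dummy coding available), and the two treatment
factors are 0/1 indicators on the same column scale so their coefficients are
directly comparable effect sizes.  Fitting is (weighted) least squares with
t-based two-sided p-values; FSH and LH are fitted separately on the same
design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .errors import ValidationError

logger = logging.getLogger(__name__)

SEX_LEVELS = ("female", "male")
CHEMO_LEVELS = ("ABVD", "2+2")
FIELD_LEVELS = ("IDRT", "SDRT")

#: Maximum age at diagnosis per the cohort definition (years).
MAX_AGE = {"female": 40.0, "male": 50.0}

TERMS = ("intercept", "age_z", "sex", "age_sex", "chemo_abvd", "rt_idrt")

OUTCOMES = ("log_fsh", "log_lh")

#: Age split (years) for the stratified group summary.
AGE_GROUP_SPLIT = 30.0


@dataclass(frozen=True)
class HormoneRecord:
    """One patient's hormone measurement with treatment covariates."""

    patient_id: str
    sex: str
    age: float
    chemo: str
    rt_field: str
    fsh: float
    lh: float
    months_since_rt: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise ValidationError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.chemo not in CHEMO_LEVELS:
            raise ValidationError(f"{self.patient_id}: unknown chemo {self.chemo!r}")
        if self.rt_field not in FIELD_LEVELS:
            raise ValidationError(f"{self.patient_id}: unknown rt_field {self.rt_field!r}")
        if self.fsh <= 0 or self.lh <= 0:
            raise ValidationError(
                f"{self.patient_id}: hormone levels must be positive "
                f"(FSH={self.fsh}, LH={self.lh})"
            )
        if not (0 < self.age < MAX_AGE[self.sex]):
            raise ValidationError(
                f"{self.patient_id}: age {self.age} outside cohort definition "
                f"(< {MAX_AGE[self.sex]} years for {self.sex})"
            )
        if self.weight <= 0:
            raise ValidationError(f"{self.patient_id}: non-positive weight")


def log_transform(record: HormoneRecord) -> tuple[float, float]:
    """Natural log of (FSH, LH); positivity is enforced by the record type."""
    return math.log(record.fsh), math.log(record.lh)


def cohort_frame(cohort: Iterable[HormoneRecord]) -> pd.DataFrame:
    """Tidy per-record table with log-transformed outcomes."""
    rows = []
    for r in cohort:
        log_fsh, log_lh = log_transform(r)
        rows.append(
            {
                "patient_id": r.patient_id,
                "sex": r.sex,
                "age": r.age,
                "chemo": r.chemo,
                "rt_field": r.rt_field,
                "fsh": r.fsh,
                "lh": r.lh,
                "log_fsh": log_fsh,
                "log_lh": log_lh,
                "weight": r.weight,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DesignMatrix:
    """Design matrix plus the coding metadata needed to reproduce predictions."""

    X: np.ndarray
    terms: tuple[str, ...]
    coding_note: str
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    sex_coding: str
    weights: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _sex_codes(sex_coding: str) -> dict[str, float]:
    if sex_coding == "halves":
        return {"female": 0.5, "male": -0.5}
    if sex_coding == "dummy":
        return {"female": 1.0, "male": 0.0}
    raise ValueError(f"unknown sex coding {sex_coding!r}; use 'halves' or 'dummy'")


def build_design(
    cohort: Sequence[HormoneRecord], sex_coding: str = "halves"
) -> DesignMatrix:
    """Build the regression design matrix for a hormone cohort.

    Columns, in order: intercept; age z-scored over this cohort; sex
    (±½ symmetric by default, female positive; 0/1 with ``sex_coding="dummy"``);
    age×sex product; chemotherapy indicator (ABVD = 1, 2+2 = 0); RT-field
    indicator (IDRT = 1, SDRT = 0).
    """
    if not cohort:
        raise ValueError("empty hormone cohort")
    codes = _sex_codes(sex_coding)
    age = np.array([r.age for r in cohort], dtype=float)
    age_mean = float(age.mean())
    age_sd = float(age.std(ddof=1)) if age.size > 1 else 0.0
    if age_sd <= 0:
        raise ValidationError("cannot z-score age: zero variance in the cohort")
    age_z = (age - age_mean) / age_sd
    sex = np.array([codes[r.sex] for r in cohort])
    chemo = np.array([1.0 if r.chemo == "ABVD" else 0.0 for r in cohort])
    rt = np.array([1.0 if r.rt_field == "IDRT" else 0.0 for r in cohort])
    for name, col, levels in (
        ("sex", sex, set(codes.values())),
        ("chemo_abvd", chemo, {0.0, 1.0}),
        ("rt_idrt", rt, {0.0, 1.0}),
    ):
        if len(set(col.tolist())) < 2:
            logger.warning("factor %r has a single level in this cohort", name)
    X = np.column_stack([np.ones_like(age_z), age_z, sex, age_z * sex, chemo, rt])
    note = (
        f"age z-scored (mean={age_mean:.4f} y, sd={age_sd:.4f} y); "
        f"sex {sex_coding} coding {codes}; age_sex = age_z * sex; "
        "chemo_abvd: ABVD=1 vs 2+2=0; rt_idrt: IDRT=1 vs SDRT=0"
    )
    weights = np.array([r.weight for r in cohort], dtype=float)
    return DesignMatrix(
        X=X,
        terms=TERMS,
        coding_note=note,
        age_mean=age_mean,
        age_sd=age_sd,
        age_range=(float(age.min()), float(age.max())),
        sex_coding=sex_coding,
        weights=weights,
    )


@dataclass(frozen=True)
class RegressionFit:
    """Fitted linear model for one log-hormone outcome."""

    outcome: str
    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    n_used: int
    coding_note: str
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    sex_coding: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": self.coefficients,
                "standard_error": self.standard_errors,
                "p_value": self.p_values,
            }
        )


def fit_linear(
    design: DesignMatrix,
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    outcome: str = "log_fsh",
) -> RegressionFit:
    """Fit the log-hormone linear model by (weighted) least squares.

    Default weights are all 1 (ordinary least squares).  Standard errors use
    the unbiased residual variance; p-values are two-sided from the t
    distribution on ``n − p`` degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome length does not match design")
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more records ({X.shape[0]}) than terms ({X.shape[1]})"
        )
    w = np.asarray(weights if weights is not None else design.weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, pivoting=True)
        collinear = [design.terms[i] for i in sorted(piv[rank:])]
        raise ValidationError(
            f"design matrix is rank deficient; collinear terms: {collinear}"
        )
    res = sm.WLS(y, X, weights=w).fit()
    return RegressionFit(
        outcome=outcome,
        terms=design.terms,
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        n_used=int(X.shape[0]),
        coding_note=design.coding_note,
        age_mean=design.age_mean,
        age_sd=design.age_sd,
        age_range=design.age_range,
        sex_coding=design.sex_coding,
    )


def fit_cohort(
    cohort: Sequence[HormoneRecord],
    sex_coding: str = "halves",
    weights: Sequence[float] | None = None,
) -> dict[str, RegressionFit]:
    """Fit both outcomes (ln FSH, ln LH) on the shared design."""
    design = build_design(cohort, sex_coding=sex_coding)
    df = cohort_frame(cohort)
    return {
        outcome: fit_linear(design, df[outcome].to_numpy(), weights, outcome=outcome)
        for outcome in OUTCOMES
    }


def group_summary(cohort: Sequence[HormoneRecord]) -> pd.DataFrame:
    """Stratified hormone summaries, original and log scale.

    Strata: sex × age group (split at 30 years) and sex × RT field, for each
    hormone.  Empty strata are emitted with ``n = 0`` and blank statistics;
    single-record strata report SD 0 with ``sd_defined = False``.
    """
    if not cohort:
        raise ValueError("empty hormone cohort")
    df = cohort_frame(cohort)
    df["age_group"] = np.where(
        df["age"] < AGE_GROUP_SPLIT, f"<{AGE_GROUP_SPLIT:g}", f">={AGE_GROUP_SPLIT:g}"
    )
    out_rows = []
    strata = {
        "age_group": (f"<{AGE_GROUP_SPLIT:g}", f">={AGE_GROUP_SPLIT:g}"),
        "rt_field": FIELD_LEVELS,
    }
    for stratifier, levels in strata.items():
        for hormone in ("fsh", "lh"):
            for sex in SEX_LEVELS:
                for level in levels:
                    sub = df[(df["sex"] == sex) & (df[stratifier] == level)]
                    row = {
                        "stratifier": stratifier,
                        "stratum": level,
                        "hormone": hormone,
                        "sex": sex,
                        "n": int(len(sub)),
                    }
                    if len(sub) == 0:
                        row.update(
                            mean=np.nan, sd=np.nan, log_mean=np.nan, log_sd=np.nan,
                            sd_defined=False,
                        )
                    else:
                        vals = sub[hormone].to_numpy()
                        logs = sub[f"log_{hormone}"].to_numpy()
                        defined = len(sub) > 1
                        row.update(
                            mean=float(vals.mean()),
                            sd=float(vals.std(ddof=1)) if defined else 0.0,
                            log_mean=float(logs.mean()),
                            log_sd=float(logs.std(ddof=1)) if defined else 0.0,
                            sd_defined=defined,
                        )
                    out_rows.append(row)
    return pd.DataFrame(out_rows)


HORMONE_CSV_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "chemo",
    "rt_field",
    "fsh_u_per_l",
    "lh_u_per_l",
)


def read_hormone_table(path) -> list[HormoneRecord]:
    """Read a hormone cohort CSV.

    Required columns: ``patient_id, sex, age_years, chemo, rt_field,
    fsh_u_per_l, lh_u_per_l``; optional ``months_since_rt`` and ``weight``.
    """
    from .errors import SchemaError

    df = pd.read_csv(path)
    for col in HORMONE_CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"hormone table is missing required column: {col!r}")
    records = []
    for _, row in df.iterrows():
        months = row.get("months_since_rt")
        records.append(
            HormoneRecord(
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                age=float(row["age_years"]),
                chemo=str(row["chemo"]),
                rt_field=str(row["rt_field"]),
                fsh=float(row["fsh_u_per_l"]),
                lh=float(row["lh_u_per_l"]),
                months_since_rt=float(months) if pd.notna(months) else None,
                weight=float(row["weight"]) if "weight" in df.columns else 1.0,
            )
        )
    return records


def write_hormone_table(cohort: Iterable[HormoneRecord], path) -> None:
    """Write a hormone cohort to the package CSV schema."""
    pd.DataFrame(
        {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age_years": r.age,
            "chemo": r.chemo,
            "rt_field": r.rt_field,
            "fsh_u_per_l": r.fsh,
            "lh_u_per_l": r.lh,
            "months_since_rt": r.months_since_rt,
            "weight": r.weight,
        }
        for r in cohort
    ).to_csv(path, index=False)


def predict_grid(
    fit: RegressionFit, ages: Sequence[float] | None = None
) -> pd.DataFrame:
    """Predicted hormone surface over sex × chemo × RT-field × age.

    Predictions are on the log scale (``predicted_log``) with the
    back-transformed level in U/L (``predicted``).  Ages outside the fitted
    range trigger a warning, not an error.
    """
    if ages is None:
        lo, hi = fit.age_range
        ages = np.linspace(lo, hi, 6)
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < fit.age_range[0]) or np.any(ages > fit.age_range[1]):
        logger.warning(
            "prediction ages extend outside the fitted range %s", fit.age_range
        )
    codes = _sex_codes(fit.sex_coding)
    rows = []
    for sex in SEX_LEVELS:
        for chemo in CHEMO_LEVELS:
            for rt in FIELD_LEVELS:
                for age in ages:
                    age_z = (age - fit.age_mean) / fit.age_sd
                    x = np.array(
                        [
                            1.0,
                            age_z,
                            codes[sex],
                            age_z * codes[sex],
                            1.0 if chemo == "ABVD" else 0.0,
                            1.0 if rt == "IDRT" else 0.0,
                        ]
                    )
                    eta = float(x @ fit.coefficients)
                    rows.append(
                        {
                            "outcome": fit.outcome,
                            "sex": sex,
                            "chemo": chemo,
                            "rt_field": rt,
                            "age": float(age),
                            "predicted_log": eta,
                            "predicted": math.exp(eta),
                        }
                    )
    return pd.DataFrame(rows)
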