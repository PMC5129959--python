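"""Cox proportional-hazards fitting and training-to-validation risk transfer.

The external-validation procedure: freeze the training cohort's Cox
coefficients, compute each validation patient's prognostic index (linear
predictor) from them, then refit a univariate Cox model of validation
survival on that single index. A calibration slope whose 95% CI covers 1
indicates the transferred model's risk ordering and scaling hold up in the
new cohort. A second check compares the validation hazard ratio of a
covariate against the training CI of the same covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.duration.hazard_regression import PHReg

#: standard covariate columns of a survival table
COVARIATES = ("age_decades", "figo", "residual", "grade", "predictor")

#: training-cohort multiple Cox coefficients (165 patients, 78 events):
#: age in decades, ordinal FIGO stage (II/III/IV -> 0/1/2), residual tumor
#: (yes vs no), grade (3 vs 2), median-dichotomized spread predictor
TRAINING_COEFFICIENTS = {
    "age_decades": 0.38,
    "figo": 1.02,
    "residual": 0.70,
    "grade": 0.54,
    "predictor": 0.56,
}


@dataclass
class CoxModel:
    """Fitted Cox model: coefficients, covariance, Wald CIs, cohort size."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    n: int
    n_events: int

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients).rename("hazard_ratio")

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance)), index=self.coefficients.index
        )

    def ci95_coef(self) -> pd.DataFrame:
        half = 1.959963984540054 * self.se
        return pd.DataFrame(
            {"lower": self.coefficients - half, "upper": self.coefficients + half}
        )

    def ci95_hr(self) -> pd.DataFrame:
        return np.exp(self.ci95_coef())

    def to_json(self, path) -> None:
        payload = {
            "covariates": list(self.coefficients.index),
            "coef": self.coefficients.tolist(),
            "covariance": self.covariance.values.tolist(),
            "n": self.n,
            "n_events": self.n_events,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CoxModel":
        with open(path) as fh:
            d = json.load(fh)
        names = d["covariates"]
        return cls(
            coefficients=pd.Series(d["coef"], index=names),
            covariance=pd.DataFrame(d["covariance"], index=names, columns=names),
            n=d["n"],
            n_events=d["n_events"],
        )


@dataclass
class TransferValidationResult:
    """Calibration slope of a transferred prognostic index on validation data."""

    slope: float
    ci_lower: float
    ci_upper: float
    n: int
    n_events: int

    @property
    def passed(self) -> bool:
        return self.ci_lower <= 1.0 <= self.ci_upper


def _validate_records(records: pd.DataFrame) -> None:
    if "time_months" not in records or "event" not in records:
        raise ValueError("survival table needs time_months and event columns")
    if (records["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    if records["event"].sum() < 1:
        raise ValueError("no events in survival table")


def fit_cox(records: pd.DataFrame, covariates: Sequence[str]) -> CoxModel:
    """Fit a (multiple) Cox proportional-hazards model, Breslow tie handling.

    ``records`` carries time_months, event and the covariate columns.
    Coefficient covariance is the inverse observed information; CIs are Wald.
    """
    _validate_records(records)
    covariates = list(covariates)
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    x = records[covariates].to_numpy(dtype=float)
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < len(covariates):
        raise ValueError("covariates are collinear")
    model = PHReg(
        records["time_months"].to_numpy(dtype=float),
        x,
        status=records["event"].to_numpy(dtype=int),
        ties="breslow",
    )
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        fit = model.fit()
    converged = not any("failed to converge" in str(w.message) for w in caught)
    coef = pd.Series(fit.params, index=covariates)
    se = np.sqrt(np.diag(fit.cov_params()))
    if (
        not converged
        or not np.all(np.isfinite(coef))
        or np.abs(coef).max() > 15
        or np.max(se) > 100
    ):
        raise ValueError(
            "monotone partial likelihood (a covariate separates events perfectly)"
        )
    cov = pd.DataFrame(fit.cov_params(), index=covariates, columns=covariates)
    return CoxModel(
        coefficients=coef,
        covariance=cov,
        n=len(records),
        n_events=int(records["event"].sum()),
    )


def linear_predictor(model: CoxModel, new_records: pd.DataFrame) -> pd.Series:
    """Prognostic index sum(coef_j * covariate_j) per subject (no baseline needed)."""
    missing = [c for c in model.coefficients.index if c not in new_records.columns]
    if missing:
        raise ValueError(f"validation table missing model covariates: {missing}")
    x = new_records[list(model.coefficients.index)].to_numpy(dtype=float)
    return pd.Series(
        x @ model.coefficients.to_numpy(), index=new_records.index, name="risk"
    )


def validate_transfer(
    training: CoxModel, validation: pd.DataFrame
) -> TransferValidationResult:
    """Transfer the training model's risk to a validation cohort and refit.

    The training linear predictor is computed for every validation subject
    and entered as the single covariate of a new Cox model on the validation
    survival data. Validation succeeds when the 95% CI of its coefficient
    (the calibration slope) covers 1.
    """
    _validate_records(validation)
    risk = linear_predictor(training, validation)
    frame = pd.DataFrame(
        {
            "time_months": validation["time_months"],
            "event": validation["event"],
            "risk": risk,
        }
    )
    refit = fit_cox(frame, ["risk"])
    ci = refit.ci95_coef()
    return TransferValidationResult(
        slope=float(refit.coefficients["risk"]),
        ci_lower=float(ci.loc["risk", "lower"]),
        ci_upper=float(ci.loc["risk", "upper"]),
        n=refit.n,
        n_events=refit.n_events,
    )


def hr_within_ci(
    validation_model: CoxModel, training_model: CoxModel, covariate: str
) -> bool:
    """Does the validation hazard ratio fall inside the training HR's 95% CI?"""
    for model in (validation_model, training_model):
        if covariate not in model.coefficients.index:
            raise ValueError(f"covariate {covariate!r} absent from model")
    hr_val = float(validation_model.hazard_ratios[covariate])
    ci = training_model.ci95_hr().loc[covariate]
    return bool(ci["lower"] <= hr_val <= ci["upper"])
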