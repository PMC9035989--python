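"""Exposure-toxicity modelling and therapeutic-window construction.

The probability of myelosuppression during therapy is modelled as a
logistic function of the steady-state trough concentration,

    P(toxicity) = 1 / (1 + exp(b0_mag - b1 * Cmin)),

so the logit-scale intercept is ``-b0_mag`` and ``b1 > 0`` makes toxicity
risk increase with exposure.  The trough giving 50% toxicity probability is
the upper bound of the therapeutic window; the lower bound comes from
inverting the (empirically near-deterministic) linear Cmin-AUC relation at
the efficacy requirement AUC0-24/MIC >= 80.  Time to myelosuppression is
summarised by the Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from lifelines import KaplanMeierFitter

from .dataio import Cohort, Outcome, classify_myelosuppression

__all__ = [
    "LogisticTD",
    "ExposureRegression",
    "EfficacyTargetConfig",
    "TherapeuticWindow",
    "KMCurve",
    "SeparationError",
    "fit_logistic",
    "prob_myelosuppression",
    "toxicity_threshold",
    "fit_cmin_auc",
    "auc_at_cmin",
    "therapeutic_window",
    "km_estimator",
    "toxicity_report",
]


class SeparationError(RuntimeError):
    """Raised when the logistic fit is degenerate (one outcome class or
    complete separation)."""


@dataclass(frozen=True)
class LogisticTD:
    """Logistic exposure-toxicity model on the logit scale:
    ``logit p = beta0 + beta1 * cmin`` with ``beta0 = -beta0_mag``."""

    beta0_mag: float = 3.767  # magnitude of the (negative) logit intercept
    beta1: float = 0.481      # per mg/L

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ValueError(
                "beta1 must be positive for a finite toxicity threshold")

    @property
    def beta0(self) -> float:
        return -self.beta0_mag


@dataclass(frozen=True)
class ExposureRegression:
    """OLS line AUC0-24 = slope * Cmin + intercept."""

    slope: float = 26.354       # mg*h/L per mg/L
    intercept: float = 91.607   # mg*h/L
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")


@dataclass(frozen=True)
class EfficacyTargetConfig:
    """AUC/MIC efficacy requirement; the derived AUC target is their
    product (default 80 x 2 mg/L = 160 mg*h/L)."""

    auc_mic_target: float = 80.0
    mic: float = 2.0

    @property
    def auc_target(self) -> float:
        return self.auc_mic_target * self.mic


@dataclass(frozen=True)
class TherapeuticWindow:
    lower: float  # mg/L
    upper: float  # mg/L

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(
                f"inconsistent window: lower {self.lower} >= upper {self.upper}")

    def contains(self, cmin) -> np.ndarray:
        cmin = np.asarray(cmin, float)
        return (cmin >= self.lower) & (cmin <= self.upper)


@dataclass
class KMCurve:
    times: np.ndarray          # event/censoring times (days), sorted
    survival: np.ndarray       # S(t) at those times
    n_at_risk: np.ndarray
    median: float | None       # first time with S(t) <= 0.5, None if never


def fit_logistic(cmin, outcome) -> LogisticTD:
    """Maximum-likelihood logistic regression of toxicity on trough.

    Raises :class:`SeparationError` when only one outcome class is present
    or the likelihood is unbounded (complete separation).
    """
    cmin = np.asarray(cmin, float)
    y = np.asarray(outcome, float)
    if cmin.shape != y.shape or cmin.ndim != 1:
        raise ValueError("cmin and outcome must be matching 1-d sequences")
    if len(np.unique(y)) < 2:
        raise SeparationError("both outcome classes must be present")
    X = sm.add_constant(cmin)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    b0, b1 = res.params
    if not np.all(np.isfinite(res.bse)) or abs(b1) > 50:
        raise SeparationError("complete or quasi-complete separation detected")
    if b1 <= 0:
        raise ValueError("fitted slope is non-positive; no toxicity threshold")
    return LogisticTD(beta0_mag=-b0, beta1=b1)


def prob_myelosuppression(model: LogisticTD, cmin) -> float | np.ndarray:
    """Probability of myelosuppression at trough ``cmin`` (mg/L)."""
    cmin = np.asarray(cmin, float)
    if np.any(cmin < 0):
        raise ValueError("cmin must be non-negative")
    out = 1.0 / (1.0 + np.exp(model.beta0_mag - model.beta1 * cmin))
    return float(out) if out.ndim == 0 else out


def toxicity_threshold(model: LogisticTD, p: float = 0.5,
                       decimals: int | None = 1) -> float:
    """Trough at which toxicity probability reaches ``p``:
    ``(logit(p) + beta0_mag) / beta1``, reported to one decimal by default."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    thr = (math.log(p / (1 - p)) + model.beta0_mag) / model.beta1
    return round(thr, decimals) if decimals is not None else thr


def fit_cmin_auc(pairs) -> ExposureRegression:
    """OLS of AUC0-24 on Cmin over (cmin, auc) pairs."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (cmin, auc) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all cmin values identical; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    r2 = 1.0 if arr.shape[0] == 2 else float(res.rsquared)
    return ExposureRegression(slope=float(slope), intercept=float(intercept),
                              r2=r2)


def auc_at_cmin(reg: ExposureRegression, cmin: float,
                decimals: int | None = 1) -> float:
    """AUC0-24 implied by the regression at a given trough."""
    auc = reg.slope * cmin + reg.intercept
    return round(auc, decimals) if decimals is not None else auc


def therapeutic_window(
    reg: ExposureRegression,
    eff: EfficacyTargetConfig | None = None,
    td: LogisticTD | None = None,
    decimals: int = 1,
) -> TherapeuticWindow:
    """Trough window bounded below by efficacy and above by toxicity.

    lower = (AUC target - intercept) / slope; upper = trough at 50%
    toxicity probability.  Both reported to one decimal (full precision is
    available via ``decimals=None`` on the component functions).
    """
    eff = eff or EfficacyTargetConfig()
    td = td or LogisticTD()
    lower = (eff.auc_target - reg.intercept) / reg.slope
    upper = toxicity_threshold(td, 0.5, decimals=None)
    lower_r, upper_r = round(lower, decimals), round(upper, decimals)
    if lower_r >= upper_r:
        raise ValueError(
            f"inconsistent window: efficacy bound {lower_r} >= toxicity bound {upper_r}")
    return TherapeuticWindow(lower=lower_r, upper=upper_r)


def km_estimator(event_time, censored) -> KMCurve:
    """Kaplan-Meier product-limit estimate of time to myelosuppression.

    ``censored`` flags subjects whose follow-up ended without the event.
    The median is the first time at which S(t) <= 0.5 (None if the curve
    never reaches 0.5).
    """
    t = np.asarray(event_time, float)
    c = np.asarray(censored, bool)
    if t.size == 0:
        raise ValueError("no event times supplied")
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=~c)
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(float)[1:]          # drop t=0 row
    surv = sf.to_numpy(float)[1:]
    below = surv <= 0.5 + 1e-12
    median = float(times[below][0]) if np.any(below) else None
    n_at_risk = np.array(
        [int(np.sum(t >= ti)) for ti in times], dtype=int)
    return KMCurve(times=times, survival=surv, n_at_risk=n_at_risk,
                   median=median)


def toxicity_report(cohort: Cohort, decimals: int = 2) -> dict:
    """Classify every patient's hematology and summarise incidence.

    Percentages are computed from the classified counts over all patients
    with hematology data.
    """
    outcomes = []
    for p in cohort:
        if p.hematology is None:
            continue
        outcomes.append(classify_myelosuppression(p.hematology))
    n = len(outcomes)
    if n == 0:
        raise ValueError("no patients with hematology data")
    n_myelo = sum(1 for o in outcomes if o.is_myelosuppression)
    n_thrombo = sum(1 for o in outcomes
                    if o in (Outcome.THROMBOCYTOPENIA, Outcome.BOTH))
    n_anemia = sum(1 for o in outcomes if o in (Outcome.ANEMIA, Outcome.BOTH))
    return {
        "n": n,
        "n_myelosuppression": n_myelo,
        "n_thrombocytopenia": n_thrombo,
        "n_anemia": n_anemia,
        "pct_myelosuppression": round(100.0 * n_myelo / n, decimals),
        "pct_thrombocytopenia": round(100.0 * n_thrombo / n, decimals),
        "pct_anemia": round(100.0 * n_anemia / n, decimals),
    }
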