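"""Closed-form one-compartment IV-infusion pharmacokinetics.

The structural model is a one-compartment disposition with linear
elimination and zero-order (constant-rate) infusion input.  Clearance is
modelled as an affine function of creatinine clearance,

    CL (L/h) = theta_cl_intercept + theta_cl_slope * (CrCL / crcl_ref),

with log-normal between-subject variability on CL (``CL_i = TVCL_i *
exp(eta_i)``) and a fixed volume of distribution.  All exposure metrics
(steady-state trough, AUC over 24 h) follow from the closed-form solution
of the infusion model; no ODE solver is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationModel",
    "IndividualParams",
    "Regimen",
    "ExposureSummary",
    "typical_cl",
    "individual_params",
    "concentration",
    "steady_state_cmin",
    "steady_state_auc24",
    "steady_state_grid",
    "auc_linlog",
    "omega_to_cv",
    "cv_to_omega",
]

# Default evaluation grid spacing (h) for steady-state exposure profiles:
# 10-minute resolution over a 24-h interval.
GRID_STEP_H = 1.0 / 6.0

# Steady state is operationalised as at least this many doses and at least
# this many elimination half-lives of prior dosing, whichever is longer.
SS_MIN_DOSES = 10
SS_MIN_HALF_LIVES = 7.0


@dataclass(frozen=True)
class PopulationModel:
    """Population PK parameters for the CrCL-on-clearance model.

    ``omega_cl`` is the SD of the log-normal between-subject variability on
    CL; ``sigma_prop`` is the SD of the proportional residual error.
    """

    theta_cl_intercept: float = 3.66   # L/h
    theta_cl_slope: float = 2.18       # L/h per (CrCL / crcl_ref)
    crcl_ref: float = 65.0             # mL/min
    volume: float = 54.0               # L
    omega_cl: float = 0.3519
    sigma_prop: float = 0.1905

    def __post_init__(self) -> None:
        for name in ("theta_cl_intercept", "theta_cl_slope", "crcl_ref", "volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.omega_cl < 0 or self.sigma_prop < 0:
            raise ValueError("variability parameters must be non-negative")

    def with_(self, **kw) -> "PopulationModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class IndividualParams:
    """One subject's realised PK parameters."""

    cl: float        # L/h
    volume: float    # L
    eta_cl: float = 0.0

    def __post_init__(self) -> None:
        if self.cl <= 0:
            raise ValueError("cl must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    @property
    def k(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl / self.volume

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.k


@dataclass(frozen=True)
class Regimen:
    """A repeated intravenous infusion schedule."""

    dose: float                    # mg
    interval: float                # h
    infusion_duration: float = 1.0  # h
    duration_days: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if not 0 < self.infusion_duration < self.interval:
            raise ValueError("infusion_duration must lie in (0, interval)")

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.interval


@dataclass(frozen=True)
class ExposureSummary:
    """Steady-state exposure metrics used by the toxicodynamic analyses."""

    cmin_ss: float   # mg/L
    auc24_ss: float  # mg*h/L

    def __post_init__(self) -> None:
        if self.cmin_ss < 0 or self.auc24_ss < 0:
            raise ValueError("exposure metrics must be non-negative")


def typical_cl(model: PopulationModel, crcl: float | np.ndarray) -> float | np.ndarray:
    """Typical (population) clearance at a given creatinine clearance."""
    crcl = np.asarray(crcl, dtype=float)
    if np.any(crcl < 0):
        raise ValueError("crcl must be non-negative")
    out = model.theta_cl_intercept + model.theta_cl_slope * (crcl / model.crcl_ref)
    return float(out) if out.ndim == 0 else out


def individual_params(
    model: PopulationModel, crcl: float, eta_cl: float = 0.0
) -> IndividualParams:
    """Realise individual parameters: ``CL = TVCL * exp(eta)``, V fixed."""
    cl = typical_cl(model, crcl) * math.exp(eta_cl)
    return IndividualParams(cl=cl, volume=model.volume, eta_cl=eta_cl)


def _infusion_conc(
    t_rel: np.ndarray,
    rate: np.ndarray,
    duration: np.ndarray,
    cl: np.ndarray | float,
    k: np.ndarray | float,
) -> np.ndarray:
    """Concentration contribution of one infusion at time ``t_rel`` after its
    start.  Zero before the start; rising exponential during the infusion;
    mono-exponential decay afterwards."""
    t_rel = np.asarray(t_rel, dtype=float)
    during = (rate / cl) * -np.expm1(-k * np.minimum(t_rel, duration))
    after = np.exp(-k * np.maximum(t_rel - duration, 0.0))
    return np.where(t_rel > 0.0, during * after, 0.0)


def concentration(t, doses: Sequence, p: IndividualParams):
    """Plasma concentration at time(s) ``t`` by superposition of infusions.

    ``doses`` is a sequence of objects with ``time``, ``amount`` and
    ``duration`` attributes (h, mg, h).  Exact closed form.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    for d in doses:
        rate = d.amount / d.duration
        out += _infusion_conc(t - d.time, rate, d.duration, p.cl, p.k)
    return float(out[0]) if scalar else out


def steady_state_cmin(reg: Regimen, p: IndividualParams) -> float:
    """Steady-state trough (pre-dose) concentration for repeated infusions.

    Closed form: the superposition geometric series of the single-dose
    solution evaluated at the end of the dosing interval.
    """
    if reg.dose == 0:
        return 0.0
    k, tau, tinf = p.k, reg.interval, reg.infusion_duration
    if k <= 0:
        raise ValueError("elimination rate constant must be positive")
    rate = reg.dose / tinf
    peak_ss_rise = -math.expm1(-k * tinf)
    accum = 1.0 / -math.expm1(-k * tau)
    return (rate / p.cl) * peak_ss_rise * math.exp(-k * (tau - tinf)) * accum


def steady_state_auc24(reg: Regimen, p: IndividualParams) -> float:
    """AUC over 24 h at steady state via the clearance identity
    (daily dose / CL)."""
    if p.cl <= 0:
        raise ValueError("cl must be positive")
    return reg.daily_dose / p.cl


def _n_doses_to_steady_state(reg: Regimen, p: IndividualParams) -> int:
    n_half = math.ceil(SS_MIN_HALF_LIVES * p.half_life / reg.interval)
    return max(SS_MIN_DOSES, n_half)


def steady_state_grid(
    reg: Regimen, p: IndividualParams, window: float = 24.0, step: float = GRID_STEP_H
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration-time profile over a steady-state window.

    Doses are stacked by superposition until steady state (>=10 doses and
    >=7 half-lives), then times and concentrations over the next ``window``
    hours are returned with the time origin at the start of a dosing
    interval.
    """
    n_pre = _n_doses_to_steady_state(reg, p)
    n_in_window = math.ceil(window / reg.interval) + 1
    t0 = n_pre * reg.interval
    times = t0 + np.arange(0.0, window + step / 2, step)
    dose_times = np.arange(n_pre + n_in_window) * reg.interval
    rate = reg.dose / reg.infusion_duration if reg.dose > 0 else 0.0
    conc = np.zeros_like(times)
    if reg.dose > 0:
        for td in dose_times:
            conc += _infusion_conc(
                times - td, rate, reg.infusion_duration, p.cl, p.k
            )
    return times - t0, conc


def auc_linlog(times: Sequence[float], concs: Sequence[float]) -> float:
    """Linear-up / log-down trapezoidal AUC.

    Ascending (or flat) segments use the linear trapezoid; descending
    segments with both endpoints positive use the log-trapezoid
    ``(C1 - C2) * dt / ln(C1 / C2)``.  Segments touching zero fall back to
    the linear rule.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or t.size < 2:
        raise ValueError("times and concs must be matching 1-d arrays, n >= 2")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = 0.5 * (c1 + c2) * dt
    descending = (c2 < c1) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) * dt / np.log(c1 / c2)
    return float(np.sum(np.where(descending, log_seg, lin)))


def omega_to_cv(omega: float) -> float:
    """%CV of a log-normal random effect with log-scale SD ``omega``."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    return 100.0 * math.sqrt(math.expm1(omega**2))


def cv_to_omega(cv_percent: float) -> float:
    """Inverse of :func:`omega_to_cv`."""
    if cv_percent < 0:
        raise ValueError("cv_percent must be non-negative")
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))
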