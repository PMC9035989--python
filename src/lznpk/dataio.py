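"""Longitudinal PK dataset I/O, renal-function covariate, screening filters
and hematological toxicity classification.

Datasets follow NONMEM column conventions: one row per dose or observation
event with columns ID, TIME, AMT, RATE, DV, EVID, MDV plus per-subject
covariate columns (AGE, SEX, WT, HT, SCR, CRCL).  Dose rows have EVID=1;
observation rows have EVID=0 and MDV=0 when the measurement is usable.
Missing values are written as ".".

Hematology baselines/nadirs, toxicity outcomes and event times travel in a
sidecar outcomes table keyed by ID.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Outcome",
    "DoseEvent",
    "Observation",
    "Hematology",
    "PatientRecord",
    "Cohort",
    "read_dataset",
    "write_dataset",
    "cockcroft_gault",
    "screen_eligibility",
    "classify_myelosuppression",
]

LLOQ_MG_L = 0.1  # assay lower limit of quantification

# Conversion of serum creatinine from umol/L to mg/dL.
_SCR_UMOL_PER_MGDL = 88.4

PK_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV"]
COVARIATE_COLUMNS = ["AGE", "SEX", "WT", "HT", "SCR", "CRCL"]
OUTCOME_COLUMNS = [
    "ID", "OUTCOME", "EVENT_DAY", "CENSORED",
    "BASE_PLT", "NADIR_PLT", "BASE_HB", "NADIR_HB", "BASE_ANC", "BASE_TBIL_XULN",
]
MISSING = "."


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def from_code(cls, code: int) -> "Sex":
        # File encoding: 0 = male, 1 = female.
        return cls.FEMALE if int(code) == 1 else cls.MALE

    @property
    def code(self) -> int:
        return 1 if self is Sex.FEMALE else 0


class Outcome(str, Enum):
    NONE = "none"
    THROMBOCYTOPENIA = "thrombocytopenia"
    ANEMIA = "anemia"
    BOTH = "both"

    @property
    def is_myelosuppression(self) -> bool:
        return self is not Outcome.NONE


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous infusion: start time (h), amount (mg), duration (h)."""

    time: float
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")


@dataclass(frozen=True)
class Observation:
    """One concentration measurement."""

    time: float
    concentration: float
    kind: str = "other"  # {trough, peak, other}
    bql: bool = False    # below the assay LLOQ
    mdv: bool = False    # carried but ignored in fitting

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class Hematology:
    """Baseline and nadir hematology.  PLT in 1e9 cells/L, Hb in g/L,
    ANC in cells/uL, TBIL as a multiple of the upper limit of normal."""

    baseline_plt: float
    nadir_plt: float
    baseline_hb: float
    nadir_hb: float
    baseline_anc: float = 4000.0
    baseline_tbil_xuln: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.baseline_plt, self.nadir_plt, self.baseline_hb,
                self.nadir_hb, self.baseline_anc, self.baseline_tbil_xuln)
        if any(v < 0 for v in vals):
            raise ValueError("hematology values must be non-negative")


@dataclass
class PatientRecord:
    id: int
    sex: Sex = Sex.MALE
    age: float = 60.0
    weight: float = 64.0
    height: float = 165.0
    scr: float = 81.0       # umol/L
    crcl: float = 65.0      # mL/min
    doses: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    hematology: Hematology | None = None
    outcome: Outcome = Outcome.NONE
    event_time: float | None = None   # days to myelosuppression (or censoring)
    censored: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.crcl <= 0:
            raise ValueError("crcl must be positive")
        if self.doses and self.observations:
            first_dose = min(d.time for d in self.doses)
            first_obs = min(o.time for o in self.observations)
            if first_obs < first_dose:
                raise ValueError(
                    f"subject {self.id}: observation precedes first dose"
                )

    def fit_observations(self) -> list:
        """Observations usable for model fitting (not missing, not BQL)."""
        return [o for o in self.observations if not o.mdv and not o.bql]

    def covariate(self, name: str) -> float:
        key = name.upper()
        builtin = {
            "CRCL": self.crcl, "AGE": self.age, "WT": self.weight,
            "HT": self.height, "SCR": self.scr, "SEX": float(self.sex.code),
        }
        if key in builtin:
            return builtin[key]
        if name in self.extras:
            return float(self.extras[name])
        raise KeyError(f"unknown covariate {name!r} for subject {self.id}")

    def to_json(self) -> str:
        d = asdict(self)
        d["sex"] = self.sex.value
        d["outcome"] = self.outcome.value
        return json.dumps(d, indent=1)


@dataclass
class Cohort:
    patients: list

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def n_observations(self) -> int:
        return sum(len(p.fit_observations()) for p in self.patients)

    def fit_subset(self) -> "Cohort":
        """Patients with at least one usable (non-missing, above-LLOQ)
        observation; the subset estimation operates on."""
        return Cohort([p for p in self.patients if p.fit_observations()])


# ---------------------------------------------------------------------------
# CSV I/O (NONMEM column conventions)
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[MISSING], keep_default_na=False)


def read_dataset(path, outcomes_path=None) -> Cohort:
    """Read a NONMEM-convention CSV (plus optional outcomes sidecar).

    EVID=1 rows become dose events with ``duration = AMT / RATE`` (1 h when
    RATE is missing); EVID=0 rows become observations, ignored in fitting
    when MDV=1.  Covariates must be constant within a subject.
    """
    df = _read_table(path)
    missing = [c for c in PK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    outcomes = None
    if outcomes_path is not None:
        outcomes = _read_table(outcomes_path).set_index("ID")

    patients = []
    for pid, grp in df.groupby("ID", sort=True):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValueError(f"subject {pid}: TIME not non-decreasing")
        doses, obs = [], []
        for _, row in grp.iterrows():
            evid = int(row["EVID"])
            if evid == 1:
                amt = float(row["AMT"])
                rate = row["RATE"]
                dur = 1.0 if pd.isna(rate) or float(rate) == 0 else amt / float(rate)
                doses.append(DoseEvent(time=float(row["TIME"]), amount=amt,
                                       duration=dur))
            elif evid == 0:
                mdv = int(row["MDV"])
                dv = row["DV"]
                if pd.isna(dv):
                    if mdv == 0:
                        raise ValueError(
                            f"subject {pid}: observation with missing DV and MDV=0"
                        )
                    dv = 0.0
                dv = float(dv)
                kind = str(row["KIND"]) if "KIND" in grp.columns and not pd.isna(row.get("KIND")) else "other"
                obs.append(Observation(
                    time=float(row["TIME"]), concentration=dv, kind=kind,
                    bql=bool(dv < LLOQ_MG_L), mdv=bool(mdv),
                ))
        first = grp.iloc[0]

        def cov(col, default):
            if col in grp.columns and not pd.isna(first[col]):
                vals = grp[col].dropna().unique()
                if len(vals) > 1:
                    raise ValueError(f"subject {pid}: covariate {col} not constant")
                return float(first[col])
            return default

        age = cov("AGE", 60.0)
        sex = Sex.from_code(int(cov("SEX", 0)))
        wt = cov("WT", 64.0)
        ht = cov("HT", 165.0)
        scr = cov("SCR", 81.0)
        crcl = cov("CRCL", float("nan"))
        if np.isnan(crcl):
            crcl = cockcroft_gault(age, wt, scr, sex)

        rec = PatientRecord(
            id=int(pid), sex=sex, age=age, weight=wt, height=ht, scr=scr,
            crcl=crcl, doses=doses, observations=obs,
        )
        if outcomes is not None and int(pid) in outcomes.index:
            orow = outcomes.loc[int(pid)]
            rec.outcome = Outcome(str(orow["OUTCOME"]))
            rec.event_time = (None if pd.isna(orow["EVENT_DAY"])
                              else float(orow["EVENT_DAY"]))
            rec.censored = bool(int(orow["CENSORED"]))
            if not pd.isna(orow.get("BASE_PLT")):
                rec.hematology = Hematology(
                    baseline_plt=float(orow["BASE_PLT"]),
                    nadir_plt=float(orow["NADIR_PLT"]),
                    baseline_hb=float(orow["BASE_HB"]),
                    nadir_hb=float(orow["NADIR_HB"]),
                    baseline_anc=float(orow["BASE_ANC"]),
                    baseline_tbil_xuln=float(orow["BASE_TBIL_XULN"]),
                )
        patients.append(rec)
    return Cohort(patients=patients)


def write_dataset(cohort: Cohort, path, outcomes_path=None) -> None:
    """Write a cohort in the same CSV dialect accepted by read_dataset."""
    rows = []
    for p in cohort:
        events = [("dose", d.time, d) for d in p.doses]
        events += [("obs", o.time, o) for o in p.observations]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        base = dict(ID=p.id, AGE=p.age, SEX=p.sex.code, WT=p.weight,
                    HT=p.height, SCR=p.scr, CRCL=p.crcl)
        for kind, t, ev in events:
            row = dict(base)
            if kind == "dose":
                row.update(TIME=t, AMT=ev.amount, RATE=ev.amount / ev.duration,
                           DV=np.nan, EVID=1, MDV=1, KIND=np.nan)
            else:
                row.update(TIME=t, AMT=np.nan, RATE=np.nan,
                           DV=ev.concentration, EVID=0, MDV=int(ev.mdv),
                           KIND=ev.kind)
            rows.append(row)
    cols = PK_COLUMNS + ["KIND"] + COVARIATE_COLUMNS
    df = pd.DataFrame(rows)[cols]
    df.to_csv(path, index=False, na_rep=MISSING, float_format="%.6g")

    if outcomes_path is not None:
        orows = []
        for p in cohort:
            h = p.hematology
            orows.append(dict(
                ID=p.id, OUTCOME=p.outcome.value,
                EVENT_DAY=np.nan if p.event_time is None else p.event_time,
                CENSORED=int(p.censored),
                BASE_PLT=h.baseline_plt if h else np.nan,
                NADIR_PLT=h.nadir_plt if h else np.nan,
                BASE_HB=h.baseline_hb if h else np.nan,
                NADIR_HB=h.nadir_hb if h else np.nan,
                BASE_ANC=h.baseline_anc if h else np.nan,
                BASE_TBIL_XULN=h.baseline_tbil_xuln if h else np.nan,
            ))
        pd.DataFrame(orows)[OUTCOME_COLUMNS].to_csv(
            outcomes_path, index=False, na_rep=MISSING, float_format="%.6g")


# ---------------------------------------------------------------------------
# Covariate and screening rules
# ---------------------------------------------------------------------------

def cockcroft_gault(age: float, weight: float, scr_umol_l: float, sex) -> float:
    """Creatinine clearance (mL/min) by Cockcroft-Gault.

    ``scr_umol_l`` is serum creatinine in umol/L (converted internally to
    mg/dL); the result is multiplied by 0.85 for females.
    """
    if not 0 <= age < 140 + 1e-12:
        raise ValueError("age must be in [0, 140]")
    if weight <= 0:
        raise ValueError("weight must be positive")
    if scr_umol_l <= 0:
        raise ValueError("serum creatinine must be positive")
    sex = Sex(sex) if not isinstance(sex, Sex) else sex
    scr_mgdl = scr_umol_l / _SCR_UMOL_PER_MGDL
    crcl = (140.0 - age) * weight / (72.0 * scr_mgdl)
    if sex is Sex.FEMALE:
        crcl *= 0.85
    return crcl


def screen_eligibility(record: PatientRecord) -> tuple[bool, list[str]]:
    """Apply the study's hematological / hepatic / duration exclusion rules.

    Exclusions: baseline PLT < 75e9/L; baseline Hb < 6.8 g/dL (male) or
    < 6 g/dL (female); baseline ANC < 500 cells/uL; baseline TBIL > 5x ULN;
    treatment shorter than 3 days.  Missing baselines make the record
    unassessable rather than silently eligible.
    """
    h = record.hematology
    if h is None:
        return False, ["unassessable: missing hematology baselines"]
    reasons = []
    if h.baseline_plt < 75.0:
        reasons.append("PLT")
    hb_floor_g_l = 68.0 if record.sex is Sex.MALE else 60.0  # 6.8 / 6.0 g/dL
    if h.baseline_hb < hb_floor_g_l:
        reasons.append("Hb")
    if h.baseline_anc < 500.0:
        reasons.append("ANC")
    if h.baseline_tbil_xuln > 5.0:
        reasons.append("TBIL")
    if record.doses:
        span_days = (max(d.time for d in record.doses) - min(d.time for d in record.doses)) / 24.0
        if span_days < 3.0 - 1e-9:
            reasons.append("duration")
    return (len(reasons) == 0), reasons


def classify_myelosuppression(h: Hematology) -> Outcome:
    """Classify myelosuppression from baseline/nadir hematology.

    Thrombocytopenia: nadir PLT < 125e9/L AND a >= 25% drop from baseline.
    Anemia: >= 25% drop in hemoglobin.  The two calls are independent.
    """
    if h.baseline_plt <= 0 or h.baseline_hb <= 0:
        raise ValueError("baselines must be positive")
    plt_drop = (h.baseline_plt - h.nadir_plt) / h.baseline_plt
    thrombo = (h.nadir_plt < 125.0) and (plt_drop >= 0.25)
    hb_drop = (h.baseline_hb - h.nadir_hb) / h.baseline_hb
    anemia = hb_drop >= 0.25
    if thrombo and anemia:
        return Outcome.BOTH
    if thrombo:
        return Outcome.THROMBOCYTOPENIA
    if anemia:
        return Outcome.ANEMIA
    return Outcome.NONE
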