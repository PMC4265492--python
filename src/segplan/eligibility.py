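"""Computable inclusion/exclusion screening on structured patient records.

Each criterion is evaluated with the printed comparison direction and
inclusive boundary semantics (FEV1 = 20 %pred passes "between 20% and 45%",
DLCO = 20 passes, BMI = 32 passes).  History and imaging items that cannot
be derived from numbers are boolean attestations.  The overall decision is a
pure conjunction: eligible iff every criterion passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, Field, ValidationError

__all__ = ["PatientRecord", "CriterionResult", "EligibilityDecision", "evaluate_eligibility"]


class PatientRecord(BaseModel, extra="forbid"):
    """Screening measurements and attested history for one candidate.

    Percent-predicted quantities are in percent; pressures in mm Hg;
    ``lower_lobe_tar`` is the lower of the two sides, in percent.
    ``mmrc_rule`` selects the dyspnea threshold convention: the abstract's
    ">= 2" (default) or the tabulated "> 2".
    """

    age: float = Field(ge=0, le=120)
    fev1_pct_pred: float = Field(gt=0)
    tlc_pct_pred: float = Field(gt=0)
    rv_pct_pred: float = Field(gt=0)
    six_mwd_m: float = Field(ge=0)
    mmrc: int = Field(ge=0, le=4)
    paco2_mmhg: float = Field(gt=0)
    pao2_mmhg: float = Field(gt=0)
    bmi: float = Field(gt=0)
    dlco_pct_pred: float = Field(gt=0)
    lower_lobe_tar: float = Field(gt=0)
    pap_systolic_cath_mmhg: Optional[float] = None
    pap_mean_cath_mmhg: Optional[float] = None
    pap_systolic_echo_mmhg: Optional[float] = None
    pap_mean_echo_mmhg: Optional[float] = None
    no_pulmonary_hypertension_attested: bool = False
    prednisolone_daily_mg: float = Field(default=0.0, ge=0)
    largest_bulla_fraction_of_lobe: float = Field(default=0.0, ge=0, le=1)
    copd_hospitalizations_12m: int = Field(default=0, ge=0)
    # Attestations (True = criterion satisfied / exclusion absent)
    non_smoking_6m: bool = True
    optimized_medical_management: bool = True
    rehabilitation_completed: bool = True
    heterogeneous_ulpe_imaging: bool = True
    consent_and_cooperation: bool = True
    no_interfering_condition: bool = True
    no_bronchiectasis: bool = True
    no_pneumothorax_effusion_6m: bool = True
    no_excluded_cardiac_surgical_history: bool = True
    no_recent_exacerbation_6w: bool = True
    no_coagulopathy_anticoagulants: bool = True
    mmrc_rule: Literal["ge2", "gt2"] = "ge2"


@dataclass(frozen=True)
class CriterionResult:
    criterion_id: str
    description: str
    observed: object
    threshold: str
    passed: bool


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    results: tuple[CriterionResult, ...]
    failed: tuple[str, ...]
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "eligible": self.eligible,
            "failed_criteria": list(self.failed),
            "criteria": [
                {
                    "id": r.criterion_id,
                    "description": r.description,
                    "observed": r.observed,
                    "threshold": r.threshold,
                    "passed": r.passed,
                }
                for r in self.results
            ],
            "metadata": self.metadata,
        }


def _pap_values(r: PatientRecord) -> tuple[Optional[float], Optional[float], str]:
    """Resolve pulmonary-artery pressures; catheter is definitive over echo."""
    if r.pap_systolic_cath_mmhg is not None or r.pap_mean_cath_mmhg is not None:
        return r.pap_systolic_cath_mmhg, r.pap_mean_cath_mmhg, "catheter"
    if r.pap_systolic_echo_mmhg is not None or r.pap_mean_echo_mmhg is not None:
        return r.pap_systolic_echo_mmhg, r.pap_mean_echo_mmhg, "echo"
    return None, None, "none"


def evaluate_eligibility(record: PatientRecord | dict) -> EligibilityDecision:
    """Apply every computable criterion to a validated record."""
    if isinstance(record, dict):
        record = PatientRecord(**record)
    r = record
    results: list[CriterionResult] = []

    def add(cid: str, desc: str, observed, threshold: str, passed: bool) -> None:
        results.append(CriterionResult(cid, desc, observed, threshold, bool(passed)))

    # Inclusion criteria
    add("inc_age", "age 40-75 years", r.age, "40 <= age <= 75", 40 <= r.age <= 75)
    add(
        "inc_fev1",
        "FEV1 20-45 %predicted",
        r.fev1_pct_pred,
        "20 <= FEV1 <= 45",
        20 <= r.fev1_pct_pred <= 45,
    )
    add("inc_tlc", "TLC >= 100 %predicted", r.tlc_pct_pred, ">= 100", r.tlc_pct_pred >= 100)
    add("inc_rv", "RV > 150 %predicted", r.rv_pct_pred, "> 150", r.rv_pct_pred > 150)
    add(
        "inc_6mwd",
        "post-rehabilitation 6-minute walk distance > 140 m",
        r.six_mwd_m,
        "> 140",
        r.six_mwd_m > 140,
    )
    if r.mmrc_rule == "ge2":
        add("inc_mmrc", "mMRC dyspnea score", r.mmrc, ">= 2", r.mmrc >= 2)
    else:
        add("inc_mmrc", "mMRC dyspnea score", r.mmrc, "> 2", r.mmrc > 2)
    add("inc_paco2", "PaCO2 <= 50 mm Hg", r.paco2_mmhg, "<= 50", r.paco2_mmhg <= 50)
    add("inc_pao2", "PaO2 > 50 mm Hg on room air", r.pao2_mmhg, "> 50", r.pao2_mmhg > 50)
    add("inc_nonsmoking", "non-smoking >= 6 months", r.non_smoking_6m, "attested", r.non_smoking_6m)
    add(
        "inc_medical_mgmt",
        "optimized medical management",
        r.optimized_medical_management,
        "attested",
        r.optimized_medical_management,
    )
    add(
        "inc_rehab",
        "pulmonary rehabilitation completed",
        r.rehabilitation_completed,
        "attested",
        r.rehabilitation_completed,
    )
    add(
        "inc_heterogeneous",
        "heterogeneous upper-lobe-predominant emphysema on imaging",
        r.heterogeneous_ulpe_imaging,
        "attested",
        r.heterogeneous_ulpe_imaging,
    )
    add(
        "inc_consent",
        "able to cooperate and consent",
        r.consent_and_cooperation,
        "attested",
        r.consent_and_cooperation,
    )

    # Exclusion criteria (pass = exclusion absent)
    add(
        "exc_interfering",
        "no condition interfering with follow-up or outcome",
        r.no_interfering_condition,
        "attested",
        r.no_interfering_condition,
    )
    add(
        "exc_dlco",
        "DLCO not < 20 %predicted",
        r.dlco_pct_pred,
        "DLCO >= 20",
        r.dlco_pct_pred >= 20,
    )
    add("exc_bmi", "BMI within 18-32 kg/m2", r.bmi, "18 <= BMI <= 32", 18 <= r.bmi <= 32)
    pap_sys, pap_mean, pap_src = _pap_values(r)
    if pap_sys is None and pap_mean is None:
        pap_ok = r.no_pulmonary_hypertension_attested
        add(
            "exc_pap",
            "no pulmonary hypertension (no measurement; attestation required)",
            None,
            "systolic <= 45 and mean <= 35",
            pap_ok,
        )
    else:
        pap_ok = (pap_sys is None or pap_sys <= 45) and (pap_mean is None or pap_mean <= 35)
        add(
            "exc_pap",
            f"no pulmonary hypertension ({pap_src})",
            {"systolic": pap_sys, "mean": pap_mean},
            "systolic <= 45 and mean <= 35",
            pap_ok,
        )
    add(
        "exc_lower_lobe_tar",
        "lower-lobe tissue-to-air ratio not < 11%",
        r.lower_lobe_tar,
        "TAR >= 11",
        r.lower_lobe_tar >= 11,
    )
    add(
        "exc_bronchiectasis",
        "no clinically significant bronchiectasis",
        r.no_bronchiectasis,
        "attested",
        r.no_bronchiectasis,
    )
    add(
        "exc_pneumothorax",
        "no pneumothorax or pleural effusion in previous 6 months",
        r.no_pneumothorax_effusion_6m,
        "attested",
        r.no_pneumothorax_effusion_6m,
    )
    add(
        "exc_cardiac_surgical",
        "no excluded cardiac/surgical history",
        r.no_excluded_cardiac_surgical_history,
        "attested",
        r.no_excluded_cardiac_surgical_history,
    )
    add(
        "exc_exacerbation",
        "no COPD exacerbation in preceding 6 weeks",
        r.no_recent_exacerbation_6w,
        "attested",
        r.no_recent_exacerbation_6w,
    )
    add(
        "exc_hospitalizations",
        "not > 3 COPD hospitalizations requiring antibiotics in 12 months",
        r.copd_hospitalizations_12m,
        "<= 3",
        r.copd_hospitalizations_12m <= 3,
    )
    add(
        "exc_steroids",
        "daily systemic steroids not > 5 mg prednisolone",
        r.prednisolone_daily_mg,
        "<= 5",
        r.prednisolone_daily_mg <= 5,
    )
    add(
        "exc_bulla",
        "no single bulla > 1/3 of upper-lobe volume",
        r.largest_bulla_fraction_of_lobe,
        "<= 1/3",
        r.largest_bulla_fraction_of_lobe <= 1 / 3,
    )
    add(
        "exc_coagulopathy",
        "no coagulopathy or anticoagulant use",
        r.no_coagulopathy_anticoagulants,
        "attested",
        r.no_coagulopathy_anticoagulants,
    )

    failed = tuple(res.criterion_id for res in results if not res.passed)
    return EligibilityDecision(
        eligible=not failed,
        results=tuple(results),
        failed=failed,
        metadata={
            "mmrc_rule": r.mmrc_rule,
            "mmrc_rule_note": (
                "the design's summary states mMRC >= 2 while the tabulated "
                "criterion prints > 2; the configured rule was applied"
            ),
            "pap_source": pap_src,
        },
    )
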