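"""Cohort definition rules for the diabetic-CABG ICU delirium analysis.

Three deterministic pieces:

* ICD-code phenotyping — diabetes mellitus (ICD-9 prefix 250; ICD-10
  prefixes E10-E14) and coronary artery bypass grafting (ICD-9 procedure
  prefixes 3611-3619 and 362; ICD-10-PCS prefixes 0210-0213);
* the exclusion-criteria filter (age, ICU length of stay, early
  coma/delirium, psychiatric/neurological diagnoses, substance abuse,
  repeat admissions), with a one-row-per-exclusion log;
* delirium adjudication from a RASS score and the four CAM-ICU features
  (coma when RASS < -3; otherwise delirium iff features 1 and 2 plus
  3 or 4 are positive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

DM_ICD9_PREFIXES = ("250",)
DM_ICD10_PREFIXES = ("E10", "E11", "E12", "E13", "E14")
CABG_ICD9_PREFIXES = tuple(str(c) for c in range(3611, 3620)) + ("362",)
CABG_ICD10_PREFIXES = ("0210", "0211", "0212", "0213")

#: Exclusion rules in adjudication (and logging) order.
EXCLUSION_RULES = (
    "age<18",
    "icu_los<24h",
    "coma_or_delirium_24h",
    "psychiatric_or_neurological",
    "alcohol_drug_abuse",
    "not_first_admission",
)

PSYCH_NEURO_FLAGS = (
    "dementia",
    "psychoses",
    "tbi",
    "reading_disorder",
    "intellectual_disability",
    "neurological_disease",
)


def _normalize(code: str) -> str:
    return code.replace(".", "").strip().upper()


def _matches_any(codes, prefixes_by_version) -> bool:
    for code, version in codes:
        if version not in prefixes_by_version:
            raise ValueError(f"unknown ICD version {version!r} for code {code!r}")
        if _normalize(str(code)).startswith(prefixes_by_version[version]):
            return True
    return False


def parse_code_list(value: str) -> list[tuple[str, int]]:
    """Parse a semicolon-delimited ``code:version`` string.

    ``"25000:9;E11.65:10"`` -> ``[("25000", 9), ("E11.65", 10)]``; empty or
    missing values give an empty list.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return []
    out = []
    for item in str(value).split(";"):
        item = item.strip()
        if not item:
            continue
        code, _, version = item.rpartition(":")
        if not code or not version.isdigit():
            raise ValueError(f"malformed code entry {item!r}; expected code:version")
        out.append((code, int(version)))
    return out


def is_dm(diagnosis_codes) -> bool:
    """True iff any diagnosis code marks diabetes mellitus.

    ICD-9: prefix 250. ICD-10: prefixes E10-E14. Matching is
    case-insensitive and ignores embedded dots.
    """
    return _matches_any(diagnosis_codes, {9: DM_ICD9_PREFIXES, 10: DM_ICD10_PREFIXES})


def is_cabg(procedure_codes) -> bool:
    """True iff any procedure code marks coronary artery bypass grafting.

    ICD-9: prefixes 3611-3619 or 362 (362 is treated as a prefix, covering
    3621, 3622, ...). ICD-10-PCS: prefixes 0210-0213.
    """
    return _matches_any(
        procedure_codes, {9: CABG_ICD9_PREFIXES, 10: CABG_ICD10_PREFIXES}
    )


def _first_failing_rule(row) -> str | None:
    if row["age"] < 18:
        return "age<18"
    if row["icu_los_hours"] < 24:
        return "icu_los<24h"
    if row.get("coma_or_delirium_24h", False):
        return "coma_or_delirium_24h"
    if any(bool(row.get(f, False)) for f in PSYCH_NEURO_FLAGS):
        return "psychiatric_or_neurological"
    if row.get("alcohol_drug_abuse", False):
        return "alcohol_drug_abuse"
    if int(row.get("admission_index", 1)) != 1:
        return "not_first_admission"
    return None


def apply_exclusions(records: pd.DataFrame):
    """Apply the study exclusion criteria to an admissions table.

    Returns ``(kept, log)``: the kept cohort and an exclusion log with one
    row per excluded record, attributing each to the FIRST rule that fired
    in the fixed order age < 18; ICU stay < 24 h; coma/delirium within
    24 h; psychiatric or neurological diagnosis; alcohol/drug abuse;
    non-first admission. Idempotent: re-running on the kept set drops
    nothing.
    """
    for col in ("patient_id", "age", "icu_los_hours"):
        if col not in records.columns:
            raise ValueError(f"records missing required column {col!r}")
    if records[["age", "icu_los_hours"]].isna().any().any():
        bad = records.loc[records[["age", "icu_los_hours"]].isna().any(axis=1),
                          "patient_id"].iloc[0]
        raise ValueError(f"missing age/icu_los_hours for patient {bad!r}")
    keep_mask = []
    log_rows = []
    for _, row in records.iterrows():
        rule = _first_failing_rule(row)
        keep_mask.append(rule is None)
        if rule is not None:
            log_rows.append({"patient_id": row["patient_id"],
                             "admission_index": int(row.get("admission_index", 1)),
                             "rule": rule})
    kept = records.loc[keep_mask].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["patient_id", "admission_index", "rule"])
    return kept, log


class DeliriumStatus(enum.Enum):
    DELIRIUM = "delirium"
    NO_DELIRIUM = "no_delirium"
    COMA_INELIGIBLE = "coma_ineligible"


@dataclass(frozen=True)
class DeliriumAssessment:
    """One RASS + CAM-ICU assessment.

    rass: Richmond Agitation-Sedation Scale, -5..+4. The four CAM-ICU
    features: 1 altered level of consciousness, 2 mental-status change,
    3 inattention, 4 disorganized thinking.
    """

    rass: int
    feature1_altered_loc: bool
    feature2_ms_change: bool
    feature3_inattention: bool
    feature4_disorganized_thinking: bool

    def __post_init__(self):
        if not -5 <= self.rass <= 4:
            raise ValueError(f"RASS {self.rass} outside [-5, 4]")


def adjudicate_delirium(assessment: DeliriumAssessment) -> DeliriumStatus:
    """Coma when RASS < -3 (RASS = -3 exactly remains eligible); otherwise
    delirium iff features 1 AND 2 AND (3 OR 4) are positive."""
    if assessment.rass < -3:
        return DeliriumStatus.COMA_INELIGIBLE
    positive = (
        assessment.feature1_altered_loc
        and assessment.feature2_ms_change
        and (assessment.feature3_inattention
             or assessment.feature4_disorganized_thinking)
    )
    return DeliriumStatus.DELIRIUM if positive else DeliriumStatus.NO_DELIRIUM


def adjudicate_assessments(assessments: pd.DataFrame) -> pd.DataFrame:
    """Adjudicate a long table of assessments (one row per assessment).

    Expects columns patient_id, rass, feature1..feature4. Returns one row
    per patient with pod = 1 if ANY eligible assessment adjudicates to
    delirium, 0 otherwise, plus an ``ever_coma`` flag (any RASS < -3).
    """
    out = []
    for pid, grp in assessments.groupby("patient_id", sort=True):
        statuses = [
            adjudicate_delirium(DeliriumAssessment(
                int(r.rass), bool(r.feature1), bool(r.feature2),
                bool(r.feature3), bool(r.feature4)))
            for r in grp.itertuples()
        ]
        out.append({
            "patient_id": pid,
            "pod": int(any(s is DeliriumStatus.DELIRIUM for s in statuses)),
            "ever_coma": any(s is DeliriumStatus.COMA_INELIGIBLE for s in statuses),
        })
    return pd.DataFrame(out)
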