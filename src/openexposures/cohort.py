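"""Asthma-cohort selection from raw clinical extracts.

A patient enters the cohort through the union of four inclusion rules:

1. an asthma diagnosis AND a medication typically used to treat asthma;
2. a non-asthma respiratory diagnosis AND an asthma medication;
3. a non-asthma pulmonary diagnosis AND a test/procedure typically used to
   manage asthma (laboratory-measure criteria are folded into this code set);
4. a non-asthma respiratory diagnosis AND "frequent" ED visits in the study
   year during which a nebulizer medication was administered (threshold
   configurable, default 2 per study year).

Code sets are configuration (YAML); the shipped default is a synthetic
vocabulary matched to the bundled data generator, since real terminologies
are licensed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import FrozenSet

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

__all__ = ["CohortCriteria", "CohortSelection", "select_cohort",
           "load_criteria", "default_criteria", "count_outcomes"]

ENCOUNTER_CLASSES = ("ED", "inpatient", "outpatient")
CODE_TYPES = ("dx", "med", "proc")


@dataclass(frozen=True)
class CohortCriteria:
    asthma_dx_codes: FrozenSet[str]
    respiratory_dx_codes: FrozenSet[str]
    pulmonary_dx_codes: FrozenSet[str]
    asthma_med_codes: FrozenSet[str]
    asthma_proc_codes: FrozenSet[str]
    nebulizer_med_codes: FrozenSet[str]
    frequent_ed_threshold: int = 2
    # outcome counting (not part of inclusion): respiratory-issue dx codes
    # and prednisone medication codes
    respiratory_visit_dx_codes: FrozenSet[str] = frozenset()
    prednisone_med_codes: FrozenSet[str] = frozenset()

    def __post_init__(self):
        for name in ("asthma_dx_codes", "respiratory_dx_codes", "pulmonary_dx_codes",
                     "asthma_med_codes", "asthma_proc_codes", "nebulizer_med_codes"):
            value = getattr(self, name)
            object.__setattr__(self, name, frozenset(value))
            if not getattr(self, name):
                raise ConfigurationError(f"criteria code set {name} is empty")
        object.__setattr__(self, "respiratory_visit_dx_codes",
                           frozenset(self.respiratory_visit_dx_codes))
        object.__setattr__(self, "prednisone_med_codes",
                           frozenset(self.prednisone_med_codes))
        if self.frequent_ed_threshold < 1:
            raise ConfigurationError("frequent_ed_threshold must be >= 1")


@dataclass(frozen=True)
class CohortSelection:
    """The selected cohort plus each rule's member set (rules may overlap)."""

    cohort: FrozenSet[str]
    rule1: FrozenSet[str]
    rule2: FrozenSet[str]
    rule3: FrozenSet[str]
    rule4: FrozenSet[str]


def _validate_encounters(encounters: pd.DataFrame) -> pd.DataFrame:
    if len(encounters) == 0:
        return encounters
    bad_class = ~encounters["encounter_class"].isin(ENCOUNTER_CLASSES)
    if bad_class.any():
        v = encounters.loc[bad_class, "encounter_class"].iloc[0]
        raise ValidationError(f"unknown encounter_class {v!r}")
    bad_type = ~encounters["code_type"].isin(CODE_TYPES)
    if bad_type.any():
        v = encounters.loc[bad_type, "code_type"].iloc[0]
        raise ValidationError(f"unknown code_type {v!r}")
    return encounters


def select_cohort(records: pd.DataFrame, encounters: pd.DataFrame,
                  criteria: CohortCriteria, study_year: int) -> CohortSelection:
    """Evaluate the four inclusion rules and return their union.

    `records` needs a ``patient_id`` column; `encounters` needs
    ``patient_id, date, encounter_class, code_type, code`` with one row per
    coded event (an encounter is a (patient, date) pair).
    """
    known = set(records["patient_id"]) if len(records) else set()
    if not known or len(encounters) == 0:
        empty = frozenset()
        return CohortSelection(empty, empty, empty, empty, empty)
    enc = _validate_encounters(encounters)
    enc = enc[enc["patient_id"].isin(known)]

    def patients_with(code_type: str, codes) -> set:
        m = enc[(enc["code_type"] == code_type) & (enc["code"].isin(codes))]
        return set(m["patient_id"])

    has_asthma_dx = patients_with("dx", criteria.asthma_dx_codes)
    has_resp_dx = patients_with("dx", criteria.respiratory_dx_codes)
    has_pulm_dx = patients_with("dx", criteria.pulmonary_dx_codes)
    has_asthma_med = patients_with("med", criteria.asthma_med_codes)
    has_asthma_proc = patients_with("proc", criteria.asthma_proc_codes)

    rule1 = has_asthma_dx & has_asthma_med
    rule2 = has_resp_dx & has_asthma_med
    rule3 = has_pulm_dx & has_asthma_proc

    # rule 4: >= threshold ED encounters in the study year with a nebulizer
    # medication administered (encounter = distinct (patient, date))
    dates = pd.to_datetime(enc["date"])
    neb = enc[(enc["encounter_class"] == "ED")
              & (enc["code_type"] == "med")
              & (enc["code"].isin(criteria.nebulizer_med_codes))
              & (dates.dt.year == study_year)]
    per_patient = neb.drop_duplicates(["patient_id", "date"]).groupby("patient_id").size()
    frequent_ed = set(per_patient[per_patient >= criteria.frequent_ed_threshold].index)
    rule4 = has_resp_dx & frequent_ed

    return CohortSelection(
        cohort=frozenset(rule1 | rule2 | rule3 | rule4),
        rule1=frozenset(rule1), rule2=frozenset(rule2),
        rule3=frozenset(rule3), rule4=frozenset(rule4))


def count_outcomes(encounters: pd.DataFrame, criteria: CohortCriteria,
                   study_year: int) -> pd.DataFrame:
    """Annual outcome counts per patient for the study year.

    ``TotalEDInpatientVisits``: distinct (patient, date) ED or inpatient
    encounters carrying a respiratory-issue diagnosis code.
    ``TotalPrednisoneRx``: prednisone medication events.
    Patients absent from `encounters` simply have no rows; callers fill 0.
    """
    cols = ["patient_id", "TotalEDInpatientVisits", "TotalPrednisoneRx"]
    if len(encounters) == 0:
        return pd.DataFrame(columns=cols)
    enc = encounters.assign(_year=pd.to_datetime(encounters["date"]).dt.year)
    enc = enc[enc["_year"] == study_year]
    ed = enc[enc["encounter_class"].isin(("ED", "inpatient"))
             & (enc["code_type"] == "dx")
             & enc["code"].isin(criteria.respiratory_visit_dx_codes)]
    ed_counts = ed.drop_duplicates(["patient_id", "date"]).groupby("patient_id").size()
    rx = enc[(enc["code_type"] == "med")
             & enc["code"].isin(criteria.prednisone_med_codes)]
    rx_counts = rx.groupby("patient_id").size()
    out = pd.DataFrame({"TotalEDInpatientVisits": ed_counts,
                        "TotalPrednisoneRx": rx_counts}).fillna(0).astype(int)
    return out.rename_axis("patient_id").reset_index()


def _criteria_from_doc(doc) -> CohortCriteria:
    sets = doc.get("code_sets", {})
    try:
        return CohortCriteria(
            asthma_dx_codes=sets["asthma_dx"],
            respiratory_dx_codes=sets["respiratory_dx"],
            pulmonary_dx_codes=sets["pulmonary_dx"],
            asthma_med_codes=sets["asthma_med"],
            asthma_proc_codes=sets["asthma_proc"],
            nebulizer_med_codes=sets["nebulizer_med"],
            frequent_ed_threshold=int(doc.get("frequent_ed_threshold", 2)),
            respiratory_visit_dx_codes=sets.get("respiratory_visit_dx", ()),
            prednisone_med_codes=sets.get("prednisone_med", ()),
        )
    except KeyError as exc:
        raise ConfigurationError(f"criteria file missing code set {exc}") from exc


def load_criteria(path) -> CohortCriteria:
    with open(path) as fh:
        return _criteria_from_doc(yaml.safe_load(fh))


def default_criteria() -> CohortCriteria:
    """The shipped criteria with the synthetic default vocabulary."""
    ref = resources.files("openexposures.data").joinpath("default_criteria.yaml")
    return _criteria_from_doc(yaml.safe_load(ref.read_text()))
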