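"""End-to-end assembly: raw extracts -> cohort -> exposures -> feature table.

This is the glue the CLI and service use: select the cohort, integrate
exposures, count annual outcomes, and de-identify into a
:class:`~openexposures.table.FeatureTable` for one study year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .binning import BinningScheme, Deidentifier, default_identifiers, default_schemes
from .cohort import CohortCriteria, CohortSelection, count_outcomes, default_criteria, \
    select_cohort
from .exposures import integrate
from .stats import AssociationResult, OutcomeFeature, associations_to_all_features
from .synth import SyntheticBundle
from .table import FeatureTable

__all__ = ["build_feature_table", "run_pipeline", "PipelineResult"]

#: Prefix of generator-produced outcome-independent categorical columns;
#: they are carried through as categorical features named ExtraCatNN.
EXTRA_CAT_PREFIX = "extra_cat_"


def _extra_cat_schemes(patients: pd.DataFrame) -> list:
    out = []
    for col in patients.columns:
        if col.startswith(EXTRA_CAT_PREFIX):
            name = "ExtraCat" + col[len(EXTRA_CAT_PREFIX):]
            out.append(BinningScheme(feature=name, strategy="categorical_passthrough",
                                     source=col))
    return out


def build_feature_table(patients: pd.DataFrame, encounters: pd.DataFrame,
                        estimates: pd.DataFrame, study_year: int,
                        schemes: Optional[Sequence[BinningScheme]] = None,
                        criteria: Optional[CohortCriteria] = None,
                        cohort_ids=None) -> FeatureTable:
    """De-identified feature table for the given study year.

    `estimates` is the output of :func:`openexposures.exposures.integrate`.
    If `cohort_ids` is None the cohort is selected with `criteria`
    (shipped defaults if also None).
    """
    criteria = criteria or default_criteria()
    if cohort_ids is None:
        cohort_ids = select_cohort(patients, encounters, criteria, study_year).cohort
    cohort_patients = patients[patients["patient_id"].isin(cohort_ids)]
    raw = cohort_patients.merge(estimates, on="patient_id", how="left")
    counts = count_outcomes(encounters, criteria, study_year)
    raw = raw.merge(counts, on="patient_id", how="left")
    for col in ("TotalEDInpatientVisits", "TotalPrednisoneRx"):
        raw[col] = raw[col].fillna(0).astype(int)
    schemes = list(schemes) if schemes is not None else list(default_schemes())
    schemes = schemes + _extra_cat_schemes(cohort_patients)
    deid = Deidentifier(schemes=schemes, identifiers=default_identifiers(),
                        study_year=study_year)
    return deid.fit().transform(raw)


@dataclass
class PipelineResult:
    cohort: CohortSelection
    estimates: pd.DataFrame
    feature_table: FeatureTable
    results: list
    m: int
    alpha_adjusted: float
    skipped: dict


def run_pipeline(bundle: SyntheticBundle, study_year: Optional[int] = None,
                 outcome: OutcomeFeature = OutcomeFeature("TotalEDInpatientVisits", "=", 0),
                 criteria: Optional[CohortCriteria] = None,
                 schemes: Optional[Sequence[BinningScheme]] = None,
                 maximum_p_value: float = 1.0, alpha: float = 0.05,
                 correction: str = "bonferroni") -> PipelineResult:
    """Full chain on an in-memory bundle: cohort -> integrate -> bin -> associate."""
    study_year = study_year or int(bundle.truth.get("study_year", 2016))
    criteria = criteria or default_criteria()
    cohort = select_cohort(bundle.patients, bundle.encounters, criteria, study_year)
    estimates = integrate(bundle.patients, bundle.surfaces, bundle.roadways,
                          bundle.blockgroups, study_year)
    table = build_feature_table(bundle.patients, bundle.encounters, estimates,
                                study_year, schemes=schemes, criteria=criteria,
                                cohort_ids=cohort.cohort)
    results, m, alpha_adjusted, skipped = associations_to_all_features(
        table, None, outcome, maximum_p_value, alpha, correction)
    return PipelineResult(cohort=cohort, estimates=estimates, feature_table=table,
                          results=results, m=m, alpha_adjusted=alpha_adjusted,
                          skipped=skipped)
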