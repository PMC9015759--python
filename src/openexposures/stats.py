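"""Contingency-table construction and the 1xN chi-square association battery.

The exploration model: a cohort (rows of a feature table satisfying a
conjunction of constraints) and a dichotomized primary outcome (a count
feature split by a constraint, e.g. ``TotalEDInpatientVisits = 0`` versus the
complement) are crossed with every other available feature.  Each cross is a
contingency table tested with Pearson's chi-square — no continuity
correction, rows with missing data excluded — and the battery applies a
Bonferroni correction across the features actually tested (alpha=.05 over 50
features gives the adjusted threshold .001).  Contiguous ordinal bins may be
collapsed before testing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator

from .errors import DegenerateTableError, ValidationError
from .table import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDefinition", "OutcomeFeature", "ContingencyTable", "AssociationResult",
    "define_cohort", "build_contingency", "chi_square",
    "associations_to_all_features", "collapse_bins", "AssociationBattery",
    "bonferroni_alpha",
]

OPERATORS = ("=", "<", "<=", ">", ">=")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha/m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class OutcomeFeature:
    """Dichotomization of a count feature: constraint-true group versus
    complement (e.g. name='TotalEDInpatientVisits', operator='=', value=0)."""

    name: str
    operator: str = "="
    value: float = 0

    def __post_init__(self):
        if self.operator not in OPERATORS:
            raise ValidationError(f"unknown operator {self.operator!r}")

    def split(self, col: pd.Series) -> pd.Series:
        """Boolean series: True where the constraint holds (NaN stays NaN)."""
        return _compare(col, self.operator, self.value)

    @property
    def label_true(self) -> str:
        return f"{self.name} {self.operator} {_fmt_value(self.value)}"

    @property
    def label_false(self) -> str:
        return f"not ({self.name} {self.operator} {_fmt_value(self.value)})"


def _fmt_value(v):
    return int(v) if isinstance(v, float) and v == int(v) else v


def _compare(col: pd.Series, op: str, value):
    if op == "=":
        return col == value if pd.api.types.is_numeric_dtype(col) \
            else col.astype("object") == value
    num = pd.to_numeric(col, errors="coerce")
    if op == "<":
        return num < value
    if op == "<=":
        return num <= value
    if op == ">":
        return num > value
    return num >= value


@dataclass(frozen=True)
class CohortDefinition:
    """A conjunction of (feature, operator, value) constraints with a stable
    opaque identifier of the form ``COHORT:<hash>``."""

    cohort_id: str
    constraints: Tuple[tuple, ...]


def _cohort_id(constraints) -> str:
    canon = json.dumps(sorted([list(map(str, c)) for c in constraints]))
    return "COHORT:" + hashlib.sha1(canon.encode()).hexdigest()[:10]


def _constraint_mask(table: FeatureTable, constraints) -> pd.Series:
    mask = pd.Series(True, index=table.df.index)
    for feature, op, value in constraints:
        feat = table.feature(feature)  # KeyError -> caller validates
        if op not in OPERATORS:
            raise ValidationError(f"unknown operator {op!r}")
        col = table.df[feature]
        if feat.kind == "count":
            mask &= _compare(col, op, value).fillna(False)
        else:
            if op != "=":
                raise ValidationError(
                    f"operator {op!r} not supported on {feat.kind} feature {feature!r}")
            if str(value) not in feat.labels:
                raise ValidationError(f"label {value!r} not in {feature!r}")
            mask &= (col == str(value)).fillna(False)
    return mask


def define_cohort(table: FeatureTable, constraints) -> Tuple[CohortDefinition, int]:
    """Validate constraints, compute a deterministic cohort id and size."""
    constraints = tuple((str(f), str(op), v) for f, op, v in constraints)
    for feature, _, _ in constraints:
        try:
            table.feature(feature)
        except KeyError:
            raise ValidationError(f"unknown feature {feature!r}") from None
    mask = _constraint_mask(table, constraints)
    size = int(mask.sum())
    if size == 0:
        logger.warning("cohort %s is empty", constraints)
    return CohortDefinition(_cohort_id(constraints), constraints), size


@dataclass
class ContingencyTable:
    """Observed counts: outcome groups (rows) by feature bins (columns)."""

    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    counts: np.ndarray
    n_excluded_missing: int = 0
    feature: str = ""
    outcome: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match labels")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column_percentages(self) -> np.ndarray:
        """Each cell as a percentage of its column total (the k/n-per-bin
        presentation used for reporting per-bin outcome rates)."""
        colsum = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(colsum > 0, 100.0 * self.counts / colsum, np.nan)


def build_contingency(table: FeatureTable, cohort, outcome: OutcomeFeature,
                      feature: str) -> ContingencyTable:
    """Cross the outcome dichotomy with a feature's bins over the cohort rows.

    Rows with a missing outcome or missing feature value are excluded and
    tallied in ``n_excluded_missing``.
    """
    if feature == outcome.name:
        raise ValidationError("feature under test equals the outcome source feature")
    feat = table.feature(feature)
    if feat.kind == "count":
        raise DegenerateTableError(
            f"count feature {feature!r} is an outcome source, not a test feature")
    mask = _cohort_mask(table, cohort)
    sub = table.df.loc[mask, [outcome.name, feature]]
    ok = sub[outcome.name].notna() & sub[feature].notna()
    n_excluded = int((~ok).sum())
    sub = sub.loc[ok]
    in_group = outcome.split(sub[outcome.name])
    counts = np.zeros((2, len(feat.labels)), dtype=np.int64)
    vc_true = sub.loc[in_group, feature].value_counts()
    vc_false = sub.loc[~in_group, feature].value_counts()
    for j, label in enumerate(feat.labels):
        counts[0, j] = int(vc_true.get(label, 0))
        counts[1, j] = int(vc_false.get(label, 0))
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        raise DegenerateTableError(
            f"outcome dichotomy {outcome.label_true!r} is empty on one side")
    return ContingencyTable(
        row_labels=(outcome.label_true, outcome.label_false),
        col_labels=tuple(feat.labels), counts=counts,
        n_excluded_missing=n_excluded, feature=feature, outcome=outcome.name)


def _cohort_mask(table: FeatureTable, cohort) -> pd.Series:
    if cohort is None:
        return pd.Series(True, index=table.df.index)
    if isinstance(cohort, CohortDefinition):
        return _constraint_mask(table, cohort.constraints)
    return pd.Series(np.asarray(cohort, dtype=bool), index=table.df.index)


def chi_square(ct: ContingencyTable) -> Tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    All-zero rows/columns are pruned first (logged); at least a 2x2 table
    must remain. Returns ``(statistic, df, p_value)`` with
    ``df = (r-1)(c-1)`` after pruning.
    """
    obs = ct.counts
    rows = obs.sum(axis=1) > 0
    cols = obs.sum(axis=0) > 0
    if (~rows).any() or (~cols).any():
        logger.info("pruned %d all-zero row(s), %d all-zero column(s) for %s",
                    int((~rows).sum()), int((~cols).sum()), ct.feature or "table")
    obs = obs[np.ix_(rows, cols)]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError(
            f"fewer than 2 non-zero rows/columns for {ct.feature or 'table'}")
    stat, p, df, _ = chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def collapse_bins(ct: ContingencyTable, groups: Sequence[Sequence[int]]) -> ContingencyTable:
    """Sum columns within contiguous index groups; the groups must form an
    ordered partition of the columns into runs of adjacent indices."""
    flat = [i for g in groups for i in g]
    if sorted(flat) != list(range(len(ct.col_labels))):
        raise ValidationError("groups must partition all column indices")
    for g in groups:
        g = list(g)
        if g != list(range(g[0], g[0] + len(g))):
            raise ValidationError(f"group {g} is not contiguous")
    order = sorted(range(len(groups)), key=lambda k: groups[k][0])
    new_counts = np.column_stack(
        [ct.counts[:, list(groups[k])].sum(axis=1) for k in order])
    labels = []
    for k in order:
        g = list(groups[k])
        labs = [ct.col_labels[i] for i in g]
        labels.append(labs[0] if len(labs) == 1 else f"{labs[0]}..{labs[-1]}")
    return ContingencyTable(row_labels=ct.row_labels, col_labels=tuple(labels),
                            counts=new_counts,
                            n_excluded_missing=ct.n_excluded_missing,
                            feature=ct.feature, outcome=ct.outcome)


@dataclass
class AssociationResult:
    feature: str
    chi_square: float
    df: int
    p_value: float
    alpha_adjusted: float
    significant: bool
    table: ContingencyTable
    percentages: np.ndarray = field(repr=False, default=None)

    def to_record(self) -> dict:
        ct = self.table
        return {
            "feature": self.feature,
            "bins": ";".join(ct.col_labels),
            "counts": ";".join(",".join(str(c) for c in col) for col in ct.counts.T),
            "percentages": ";".join(
                ",".join(f"{p:.2f}" for p in col) for col in self.percentages.T),
            "chi_square": round(self.chi_square, 4),
            "df": self.df,
            "p_value": self.p_value,
            "alpha_adjusted": self.alpha_adjusted,
            "significant": self.significant,
        }


def associations_to_all_features(table: FeatureTable, cohort,
                                 outcome: OutcomeFeature,
                                 maximum_p_value: float = 1.0,
                                 alpha: float = 0.05,
                                 correction: str = "bonferroni",
                                 features: Optional[Sequence[str]] = None):
    """Chi-square of the outcome against every eligible feature.

    Eligible features are the binned/categorical features other than the
    outcome's source (count features are outcome sources, not test features).
    The Bonferroni denominator ``m`` is the number of features that actually
    produced a valid test; degenerate features are skipped with a logged
    reason. Results with ``p <= maximum_p_value`` are returned sorted by
    ascending p (ties broken by feature name).

    Returns ``(results, m, alpha_adjusted, skipped)``.
    """
    if not 0 <= maximum_p_value <= 1:
        raise ValidationError("maximum_p_value must be in [0, 1]")
    if correction not in ("bonferroni", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    if features is None:
        features = [f.name for f in table.schema
                    if f.kind != "count" and f.name != outcome.name]
    tested, skipped = [], {}
    for name in features:
        try:
            ct = build_contingency(table, cohort, outcome, name)
            stat, df, p = chi_square(ct)
        except DegenerateTableError as exc:
            logger.info("skipping %s: %s", name, exc)
            skipped[name] = str(exc)
            continue
        tested.append((name, ct, stat, df, p))
    m = len(tested)
    alpha_adjusted = bonferroni_alpha(alpha, m) if (correction == "bonferroni" and m) \
        else alpha
    results = [
        AssociationResult(feature=name, chi_square=stat, df=df, p_value=p,
                          alpha_adjusted=alpha_adjusted,
                          significant=p < alpha_adjusted, table=ct,
                          percentages=ct.column_percentages())
        for name, ct, stat, df, p in tested if p <= maximum_p_value
    ]
    results.sort(key=lambda r: (r.p_value, r.feature))
    return results, m, alpha_adjusted, skipped


def results_to_frame(results) -> pd.DataFrame:
    """Tabular projection: one row per tested feature."""
    cols = ["feature", "bins", "counts", "percentages", "chi_square", "df",
            "p_value", "alpha_adjusted", "significant"]
    return pd.DataFrame([r.to_record() for r in results], columns=cols)


class AssociationBattery(BaseEstimator):
    """scikit-learn shaped estimator for the 1xN association battery.

    Parameters mirror :func:`associations_to_all_features`; ``fit`` runs the
    battery on a :class:`FeatureTable` and exposes ``results_``, ``m_``,
    ``alpha_adjusted_`` and ``skipped_``.
    """

    def __init__(self, outcome=("TotalEDInpatientVisits", "=", 0),
                 alpha: float = 0.05, correction: str = "bonferroni",
                 maximum_p_value: float = 1.0, cohort=None, features=None):
        self.outcome = outcome
        self.alpha = alpha
        self.correction = correction
        self.maximum_p_value = maximum_p_value
        self.cohort = cohort
        self.features = features

    def fit(self, X: FeatureTable, y=None):
        outcome = self.outcome if isinstance(self.outcome, OutcomeFeature) \
            else OutcomeFeature(*self.outcome)
        self.results_, self.m_, self.alpha_adjusted_, self.skipped_ = \
            associations_to_all_features(
                X, self.cohort, outcome, self.maximum_p_value,
                self.alpha, self.correction, self.features)
        return self

    def to_frame(self) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "results_")
        return results_to_frame(self.results_)
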