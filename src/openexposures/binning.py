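"""De-identification by binning.

Continuous and potentially identifying patient-level values (age, exposure
estimates, census attributes) are converted to coarse ordinal bins before a
table is exposed, following the HIPAA Safe Harbor approach: ages above 89 are
excluded, identifiers are stripped, and exposure estimates — "secondary"
protected information because they derive from geocodes and dates — appear
only as bin labels.

Two fitted strategies are provided as scikit-learn style transformers:

* :class:`FrequencyBinner` — edges at empirical quantiles (near-equal counts);
* :class:`EqualWidthBinner` — k equal-width intervals spanning [min, max];

plus :class:`ExplicitBinner` for externally supplied edges (the shipped
default schemes carry the published edges for income, insurance, PM2.5,
ozone, and roadway proximity) and :class:`Deidentifier`, which applies a full
set of schemes to a raw per-patient data frame and returns a
:class:`~openexposures.table.FeatureTable`.

Closure convention: the first interval is closed on both ends and subsequent
intervals are left-open/right-closed, i.e. ``[a0, a1], (a1, a2], ...``.
Integer distance bins use the alternative left-closed convention
``[a, b), ..., [a_last, inf)``.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .table import FeatureDef, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "BinningScheme", "BinnedValue", "AgeExcluded",
    "bin_age", "age_on_jan1", "apply_explicit",
    "fit_frequency_quantiles", "fit_value_cut",
    "FrequencyBinner", "EqualWidthBinner", "ExplicitBinner", "Deidentifier",
    "deidentify", "load_schemes", "default_schemes",
]

STRATEGIES = (
    "explicit_edges", "frequency_quantiles", "value_cut",
    "categorical_passthrough", "age", "count_passthrough",
)

#: Age bins on day 1 of the study period; 89 is the oldest permissible age.
AGE_BOUNDS = ((0, 4), (5, 17), (18, 44), (45, 64), (65, 89))
AGE_LABELS = ("<5", "5-17", "18-44", "45-64", "65-89")
AGE_MAX = 89


def _fmt(x: float) -> str:
    if math.isfinite(x) and float(x) == int(x):
        return str(int(x))
    return format(x, "g")


@dataclass(frozen=True)
class BinnedValue:
    """A single de-identified cell: the bin label and its ordinal position."""

    feature: str
    label: str
    index: int


class AgeExcluded:
    """Marker returned for ages above the HIPAA cap (89 completed years)."""

    def __repr__(self):
        return "AgeExcluded()"

    def __eq__(self, other):
        return isinstance(other, AgeExcluded)


@dataclass(frozen=True)
class BinningScheme:
    """A per-feature de-identification rule.

    ``closure='right'`` means the first interval is closed on both ends and
    later intervals are ``(a, b]``; ``closure='left'`` means ``[a, b)`` with a
    final ``[a, inf)`` interval when the last edge is infinite.
    """

    feature: str
    strategy: str
    source: Optional[str] = None
    edges: Optional[tuple] = None
    labels: Optional[tuple] = None
    closure: str = "right"
    categories: Optional[tuple] = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown binning strategy {self.strategy!r}")
        if self.closure not in ("right", "left"):
            raise ConfigurationError(f"unknown closure {self.closure!r}")
        if self.strategy in ("explicit_edges",):
            if self.edges is None or len(self.edges) < 2:
                raise ConfigurationError(f"{self.feature}: explicit_edges needs >=2 edges")
            edges = tuple(float(e) for e in self.edges)
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ConfigurationError(f"{self.feature}: edges must be strictly increasing")
            object.__setattr__(self, "edges", edges)
            labels = self.labels or self._auto_labels(edges, self.closure)
            if len(labels) != len(edges) - 1:
                raise ConfigurationError(
                    f"{self.feature}: {len(labels)} labels for {len(edges)-1} intervals")
            object.__setattr__(self, "labels", tuple(str(x) for x in labels))
        if self.strategy == "categorical_passthrough" and self.categories is not None:
            object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        if self.strategy == "age":
            object.__setattr__(self, "labels", AGE_LABELS)

    @staticmethod
    def _auto_labels(edges, closure) -> tuple:
        out = []
        for i, (a, b) in enumerate(zip(edges, edges[1:])):
            if closure == "right":
                left = "[" if i == 0 else "("
                out.append(f"{left}{_fmt(a)}, {_fmt(b)}]")
            else:
                out.append(f">={_fmt(a)}" if math.isinf(b) else f"[{_fmt(a)}, {_fmt(b)})")
        return tuple(out)

    @property
    def n_bins(self) -> int:
        if self.strategy == "categorical_passthrough":
            return len(self.categories) if self.categories else 0
        return len(self.labels)

    # -- vectorized assignment ---------------------------------------------

    def assign(self, values) -> pd.Series:
        """Map numeric values to bin labels; out-of-range and NaN map to missing."""
        if self.edges is None:
            raise ConfigurationError(f"{self.feature}: no edges to assign against")
        v = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(dtype=float)
        edges = np.asarray(self.edges)
        if self.closure == "right":
            idx = np.searchsorted(edges, v, side="left") - 1
            idx[v == edges[0]] = 0
        else:
            idx = np.searchsorted(edges, v, side="right") - 1
        out_of_range = np.isfinite(v) & ((idx < 0) | (idx > len(self.labels) - 1))
        if out_of_range.any():
            warnings.warn(
                f"{self.feature}: {int(out_of_range.sum())} value(s) outside "
                f"[{_fmt(edges[0])}, {_fmt(edges[-1])}] treated as missing",
                stacklevel=2,
            )
        valid = np.isfinite(v) & ~out_of_range
        labels = np.full(len(v), None, dtype=object)
        labels[valid] = np.asarray(self.labels, dtype=object)[idx[valid]]
        return pd.Series(labels, index=pd.Series(values).index
                         if isinstance(values, pd.Series) else None)


# -- age ---------------------------------------------------------------------

def age_on_jan1(birth_date, study_year: int) -> int:
    """Completed years of age on January 1 of the study year."""
    bd = pd.Timestamp(birth_date)
    ref = _dt.date(study_year, 1, 1)
    if bd.date() > ref:
        raise ValidationError(f"birth date {bd.date()} is after reference date {ref}")
    return ref.year - bd.year - ((ref.month, ref.day) < (bd.month, bd.day))


def bin_age(birth_date, study_year: int):
    """Bin age on day 1 of the study period into <5 / 5-17 / 18-44 / 45-64 / 65-89.

    Returns ``None`` for a missing birth date and :class:`AgeExcluded` for
    ages above 89 (the oldest permissible age under Safe Harbor).
    """
    if birth_date is None or (isinstance(birth_date, float) and math.isnan(birth_date)) \
            or pd.isna(birth_date):
        return None
    age = age_on_jan1(birth_date, study_year)
    if age > AGE_MAX:
        logger.info("age %d exceeds HIPAA cap of %d; row excluded", age, AGE_MAX)
        return AgeExcluded()
    for i, (lo, hi) in enumerate(AGE_BOUNDS):
        if lo <= age <= hi:
            return BinnedValue("AgeStudyStart", AGE_LABELS[i], i)
    raise AssertionError("unreachable")


# -- scalar / functional surface --------------------------------------------

def apply_explicit(value, scheme: BinningScheme):
    """Assign a single value under an explicit-edge scheme; missing-propagating."""
    if scheme.strategy != "explicit_edges":
        raise ConfigurationError("apply_explicit requires an explicit_edges scheme")
    label = scheme.assign([value]).iloc[0]
    if label is None:
        return None
    return BinnedValue(scheme.feature, label, scheme.labels.index(label))


def fit_frequency_quantiles(values, k: int, feature: str = "feature") -> BinningScheme:
    """Edges at the 0, 1/k, ..., 1 empirical quantiles (linear interpolation).

    Duplicate edges (heavily tied data) are merged with a warning, reducing
    the bin count; fewer than `k` distinct finite values is a degenerate input.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    v = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(dtype=float)
    v = v[np.isfinite(v)]
    if len(np.unique(v)) < k:
        raise DegenerateInputError(
            f"{feature}: need >= {k} distinct finite values, got {len(np.unique(v))}")
    edges = np.quantile(v, np.linspace(0, 1, k + 1), method="linear")
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        warnings.warn(
            f"{feature}: duplicate quantile edges merged; bin count reduced "
            f"from {k} to {len(uniq) - 1}", stacklevel=2)
    return BinningScheme(feature=feature, strategy="explicit_edges", edges=tuple(uniq))


def fit_value_cut(values, k: int, feature: str = "feature") -> BinningScheme:
    """k equal-width intervals spanning [min, max] of the observed values."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    v = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0 or v.min() == v.max():
        raise DegenerateInputError(f"{feature}: all values identical or empty")
    edges = np.linspace(v.min(), v.max(), k + 1)
    return BinningScheme(feature=feature, strategy="explicit_edges", edges=tuple(edges))


# -- scikit-learn shaped transformers ---------------------------------------

class _BaseBinner(TransformerMixin, BaseEstimator):
    """Shared transform: 1-D numeric input to bin labels via ``scheme_``."""

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scheme_")
        return self.scheme_.assign(np.asarray(X).ravel())

    @staticmethod
    def _ravel(X):
        arr = pd.to_numeric(pd.Series(np.asarray(X).ravel()), errors="coerce")
        return arr.to_numpy(dtype=float)


class FrequencyBinner(_BaseBinner):
    """Quantile (frequency) binning: near-equal bin occupancy.

    Attributes
    ----------
    scheme_ : BinningScheme
    edges_ : ndarray of fitted quantile edges
    """

    def __init__(self, n_bins: int = 4, feature: str = "feature"):
        self.n_bins = n_bins
        self.feature = feature

    def fit(self, X, y=None):
        self.scheme_ = fit_frequency_quantiles(self._ravel(X), self.n_bins, self.feature)
        self.edges_ = np.asarray(self.scheme_.edges)
        return self


class EqualWidthBinner(_BaseBinner):
    """Equal-width (value) binning over the observed range."""

    def __init__(self, n_bins: int = 3, feature: str = "feature"):
        self.n_bins = n_bins
        self.feature = feature

    def fit(self, X, y=None):
        self.scheme_ = fit_value_cut(self._ravel(X), self.n_bins, self.feature)
        self.edges_ = np.asarray(self.scheme_.edges)
        return self


class ExplicitBinner(_BaseBinner):
    """Binning with externally supplied edges (no fitting from data)."""

    def __init__(self, edges=None, labels=None, closure: str = "right",
                 feature: str = "feature"):
        self.edges = edges
        self.labels = labels
        self.closure = closure
        self.feature = feature

    def fit(self, X=None, y=None):
        self.scheme_ = BinningScheme(
            feature=self.feature, strategy="explicit_edges",
            edges=tuple(self.edges),
            labels=tuple(self.labels) if self.labels else None,
            closure=self.closure)
        self.edges_ = np.asarray(self.scheme_.edges)
        return self


# -- de-identification of whole tables --------------------------------------

#: Columns stripped by default: direct identifiers plus primary PHI
#: (geocodes, dates) from which exposure estimates derive.
DEFAULT_IDENTIFIERS = (
    "patient_id", "birth_date", "x_m", "y_m", "geocode", "blockgroup_id", "date",
)


class Deidentifier(TransformerMixin, BaseEstimator):
    """Apply a scheme set to a raw per-patient frame, strip identifiers.

    ``transform`` returns a :class:`FeatureTable` containing only binned /
    recoded / count columns plus the study year (in the sidecar metadata).
    Rows whose age exceeds 89 are excluded (``age_policy='exclude'``, the
    default) or capped into the top bin (``'cap'``).
    """

    def __init__(self, schemes=None, identifiers=DEFAULT_IDENTIFIERS,
                 study_year: int = 2016, age_policy: str = "exclude"):
        self.schemes = schemes
        self.identifiers = identifiers
        self.study_year = study_year
        self.age_policy = age_policy

    def fit(self, X=None, y=None):
        self.schemes_ = tuple(self.schemes) if self.schemes is not None \
            else tuple(default_schemes())
        if not self.schemes_:
            raise ConfigurationError("no binning schemes configured")
        if self.age_policy not in ("exclude", "cap"):
            raise ConfigurationError(f"unknown age_policy {self.age_policy!r}")
        return self

    def transform(self, X: pd.DataFrame) -> FeatureTable:
        self.fit()
        df = pd.DataFrame(X)
        for sch in self.schemes_:
            src = sch.source or sch.feature
            if src not in df.columns:
                raise ConfigurationError(
                    f"scheme {sch.feature!r} references absent column {src!r}")

        cols, schema, n_excluded_age = {}, [], 0
        keep = np.ones(len(df), dtype=bool)
        for sch in self.schemes_:
            src = sch.source or sch.feature
            col = df[src]
            if sch.strategy == "age":
                binned = [bin_age(b, self.study_year) for b in col]
                excluded = np.array([isinstance(b, AgeExcluded) for b in binned])
                if excluded.any():
                    if self.age_policy == "exclude":
                        n_excluded_age += int(excluded.sum())
                        keep &= ~excluded
                    else:  # cap into the top bin
                        binned = [BinnedValue(sch.feature, AGE_LABELS[-1],
                                              len(AGE_LABELS) - 1)
                                  if isinstance(b, AgeExcluded) else b for b in binned]
                cols[sch.feature] = [None if b is None or isinstance(b, AgeExcluded)
                                     else b.label for b in binned]
                schema.append(FeatureDef(sch.feature, "binned_ordinal", AGE_LABELS))
            elif sch.strategy == "explicit_edges":
                cols[sch.feature] = sch.assign(col).to_numpy()
                schema.append(FeatureDef(sch.feature, "binned_ordinal", sch.labels))
            elif sch.strategy in ("frequency_quantiles", "value_cut"):
                fitted = (fit_frequency_quantiles if sch.strategy == "frequency_quantiles"
                          else fit_value_cut)(col, len(sch.labels) if sch.labels else 4,
                                              feature=sch.feature)
                cols[sch.feature] = fitted.assign(col).to_numpy()
                schema.append(FeatureDef(sch.feature, "binned_ordinal", fitted.labels))
            elif sch.strategy == "categorical_passthrough":
                values = col.astype("object").where(col.notna(), None)
                cats = sch.categories or tuple(sorted({str(v) for v in values.dropna()}))
                values = values.map(lambda v: str(v) if v is not None else None)
                values = values.where(values.isin(cats), None)
                cols[sch.feature] = values.to_numpy()
                schema.append(FeatureDef(sch.feature, "categorical", cats))
            elif sch.strategy == "count_passthrough":
                cols[sch.feature] = pd.to_numeric(col, errors="coerce").to_numpy()
                schema.append(FeatureDef(sch.feature, "count"))

        out = pd.DataFrame(cols).loc[keep].reset_index(drop=True)
        leaked = set(out.columns) & set(self.identifiers or ())
        assert not leaked, f"identifier columns leaked: {leaked}"
        meta = {
            "n_excluded_age": n_excluded_age,
            "identifiers_stripped": sorted(set(self.identifiers or ()) & set(df.columns)),
            "schemes": [sch.feature for sch in self.schemes_],
        }
        return FeatureTable(df=out, schema=schema, study_year=self.study_year, meta=meta)


def deidentify(raw: pd.DataFrame, schemes=None, identifiers=DEFAULT_IDENTIFIERS,
               study_year: int = 2016, age_policy: str = "exclude") -> FeatureTable:
    """Functional wrapper over :class:`Deidentifier`."""
    return Deidentifier(schemes=schemes, identifiers=identifiers,
                        study_year=study_year, age_policy=age_policy).fit().transform(raw)


# -- shipped default schemes -------------------------------------------------

def load_schemes(path) -> list:
    """Load a scheme set from a YAML file (see ``data/default_schemes.yaml``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _schemes_from_doc(doc)


def _schemes_from_doc(doc) -> list:
    out = []
    for entry in doc["schemes"]:
        edges = entry.get("edges")
        if edges is not None:
            edges = tuple(math.inf if e in (".inf", "inf") else float(e) for e in edges)
        out.append(BinningScheme(
            feature=entry["feature"],
            strategy=entry["strategy"],
            source=entry.get("source"),
            edges=edges,
            labels=tuple(entry["labels"]) if entry.get("labels") else None,
            closure=entry.get("closure", "right"),
            categories=tuple(entry["categories"]) if entry.get("categories") else None,
        ))
    return out


def default_schemes() -> list:
    """The shipped scheme set carrying the published bin edges."""
    ref = resources.files("openexposures.data").joinpath("default_schemes.yaml")
    return _schemes_from_doc(yaml.safe_load(ref.read_text()))


def default_identifiers() -> tuple:
    ref = resources.files("openexposures.data").joinpath("default_schemes.yaml")
    doc = yaml.safe_load(ref.read_text())
    return tuple(doc.get("identifiers", DEFAULT_IDENTIFIERS))
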