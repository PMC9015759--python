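"""Integrated feature tables: the openly exposable, de-identified unit of data.

A :class:`FeatureTable` holds one row per patient for a single 1-year study
period (a calendar year).  Cells contain only bin labels, recoded categories,
or small event counts; identifiers, geocodes, dates, and raw exposure
estimates are never present.  Tables round-trip through a CSV file plus a JSON
sidecar carrying the study year and the feature schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["FeatureDef", "FeatureTable", "round_pct"]

#: Cell value used for missing data in the CSV serialization.
MISSING_SENTINEL = ""

FEATURE_KINDS = ("binned_ordinal", "categorical", "count")


def round_pct(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage ``100*count/total`` rounded half-up to `ndigits` decimals."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FeatureDef:
    """One column of a feature table.

    Parameters
    ----------
    name : str
        Column header, e.g. ``"AvgDailyPM25Exposure"``.
    kind : str
        ``"binned_ordinal"`` (ordered bin labels), ``"categorical"``
        (unordered recoded categories), or ``"count"`` (small non-negative
        integers such as annual visit counts).
    labels : tuple of str, optional
        The closed label set, in ordinal order for binned features.  ``None``
        for counts.
    """

    name: str
    kind: str
    labels: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "count" and self.labels is not None:
            raise FormatError(f"count feature {self.name!r} must not declare labels")
        if self.kind != "count" and not self.labels:
            raise FormatError(f"feature {self.name!r} of kind {self.kind!r} needs labels")
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(str(v) for v in self.labels))


@dataclass
class FeatureTable:
    """A de-identified per-patient feature table for one study year."""

    df: pd.DataFrame
    schema: Sequence[FeatureDef]
    study_year: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.schema = tuple(self.schema)
        names = [f.name for f in self.schema]
        if len(set(names)) != len(names):
            raise FormatError("duplicate feature names in schema")
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise FormatError(f"schema features absent from data: {missing}")
        self.df = self.df.loc[:, names].reset_index(drop=True)
        self._validate_cells()

    # -- validation ---------------------------------------------------------

    def _validate_cells(self) -> None:
        for feat in self.schema:
            col = self.df[feat.name]
            if feat.kind == "count":
                vals = pd.to_numeric(col, errors="coerce")
                bad = vals.notna() & ((vals < 0) | (vals % 1 != 0))
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise FormatError(
                        f"row {row}: {feat.name}={col.iloc[row]!r} is not a "
                        "non-negative integer count"
                    )
                self.df[feat.name] = vals
            else:
                ok = col.isna() | col.astype("string").isin(feat.labels)
                if not ok.all():
                    row = int(np.flatnonzero(~ok.to_numpy())[0])
                    raise FormatError(
                        f"row {row}: value {col.iloc[row]!r} not in label set of "
                        f"{feat.name!r}"
                    )

    # -- basic introspection ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list:
        return [f.name for f in self.schema]

    def feature(self, name: str) -> FeatureDef:
        for f in self.schema:
            if f.name == name:
                return f
        raise KeyError(f"unknown feature {name!r}")

    def __eq__(self, other) -> bool:  # round-trip equality
        if not isinstance(other, FeatureTable):
            return NotImplemented
        if self.study_year != other.study_year or self.schema != tuple(other.schema):
            return False
        a, b = self.df, other.df
        if a.shape != b.shape or list(a.columns) != list(b.columns):
            return False
        for c in a.columns:
            x, y = a[c], b[c]
            if not ((x.isna() == y.isna()).all() and (x.dropna() == y.dropna()).all()):
                return False
        return True

    # -- summaries ----------------------------------------------------------

    def tabulate(self, feature: str) -> pd.DataFrame:
        """Counts and percentages per label, missing included in the denominator.

        Count features are dichotomized for display as ``0`` versus ``>=1``,
        the convention used for annual outcome measures.
        """
        feat = self.feature(feature)
        col = self.df[feature]
        total = self.n
        rows = []
        if feat.kind == "count":
            nonmiss = col.dropna()
            rows.append(("0", int((nonmiss == 0).sum())))
            rows.append((">=1", int((nonmiss >= 1).sum())))
        else:
            vc = col.value_counts()
            for label in feat.labels:
                rows.append((label, int(vc.get(label, 0))))
        rows.append(("Missing", int(col.isna().sum())))
        out = pd.DataFrame(rows, columns=["value", "count"])
        out["pct"] = [round_pct(c, total) for c in out["count"]]
        return out

    # -- persistence --------------------------------------------------------

    @staticmethod
    def _sidecar_path(path) -> Path:
        path = Path(path)
        return path.with_name(path.stem + ".meta.json")

    def write(self, path) -> None:
        """Write the table as CSV plus a JSON sidecar (schema, study year, meta)."""
        path = Path(path)
        df = self.df.copy()
        for f in self.schema:
            if f.kind == "count":
                df[f.name] = df[f.name].astype("Int64").astype("string")
        df = df.fillna(MISSING_SENTINEL)
        df.to_csv(path, index=False, lineterminator="\n")
        sidecar = {
            "study_year": self.study_year,
            "schema": [
                {"name": f.name, "kind": f.kind,
                 "labels": list(f.labels) if f.labels is not None else None}
                for f in self.schema
            ],
            "meta": self.meta,
        }
        self._sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def read(cls, path) -> "FeatureTable":
        path = Path(path)
        sidecar_path = cls._sidecar_path(path)
        if not sidecar_path.exists():
            raise FormatError(f"missing sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        schema = [
            FeatureDef(d["name"], d["kind"],
                       tuple(d["labels"]) if d["labels"] is not None else None)
            for d in sidecar["schema"]
        ]
        df = pd.read_csv(path, dtype="string", keep_default_na=False)
        df = df.replace({MISSING_SENTINEL: None})
        for f in schema:
            if f.kind == "count":
                df[f.name] = pd.to_numeric(df[f.name])
        return cls(df=df, schema=schema, study_year=int(sidecar["study_year"]),
                   meta=sidecar.get("meta", {}))
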