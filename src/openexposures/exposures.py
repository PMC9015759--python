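"""Per-patient environmental and socioeconomic exposure estimates.

Links each patient's residential geocode (planar x/y in meters on a synthetic
region) and the study year to:

* annual mean of daily-average PM2.5 (ug/m3) from a gridded daily surface;
* annual mean of daily-maximum ozone (ppb) from a gridded daily surface;
* Euclidean distance to the nearest major roadway segment (m);
* census block-group attributes: residential-density class, estimated
  probability of no health insurance, estimated median household income.

All estimates are missing-propagating: a patient with no geocode gets no
geography-derived estimate (this is the dominant source of missingness in
real extracts), and a geocode outside surface coverage yields missing rather
than an error.

Geometry is planar by default; ``distance_metric='haversine'`` is available
as a hook for geodetic coordinates (x=longitude, y=latitude in degrees).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiLineString, Point
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureSurface", "RoadwaySegment", "BlockGroup", "ExposureEstimate",
    "annual_pm25", "annual_max_ozone", "roadway_distance", "density_class",
    "integrate", "ExposureIntegrator",
]

EARTH_RADIUS_M = 6_371_000.0

#: Residential-density classification thresholds (persons per block group).
RURAL_MAX = 2500          # < 2500 -> rural
URBAN_CLUSTER_MAX = 50000  # 2500..50000 -> urban cluster; > 50000 -> urbanized


# -- domain types ------------------------------------------------------------

@dataclass
class ExposureSurface:
    """Daily pollutant values on rectangular grid cells.

    ``cells`` has columns ``cell_id, xmin, ymin, xmax, ymax``; ``daily`` has
    ``cell_id, date, value`` with one value per (cell, date).  For PM2.5 the
    value is the daily average concentration; for ozone it is the daily
    maximum.
    """

    pollutant: str
    cells: pd.DataFrame
    daily: pd.DataFrame

    def __post_init__(self):
        if self.pollutant not in ("pm25", "ozone"):
            raise ValidationError(f"unknown pollutant {self.pollutant!r}")
        if (pd.to_numeric(self.daily["value"]) < 0).any():
            raise ValidationError(f"{self.pollutant}: negative daily values")
        if self.daily.duplicated(["cell_id", "date"]).any():
            raise ValidationError(f"{self.pollutant}: duplicate (cell, date) values")
        self.daily = self.daily.assign(date=pd.to_datetime(self.daily["date"]))

    def locate(self, x, y):
        """Cell id containing (x, y); ties on shared edges resolve to the
        lowest cell id. Vectorized; returns an object array with None outside
        coverage."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, None, dtype=object)
        # iterate cells in descending id so the lowest id wins on overlap
        cells = self.cells.sort_values("cell_id", ascending=False)
        for row in cells.itertuples(index=False):
            inside = (x >= row.xmin) & (x <= row.xmax) & (y >= row.ymin) & (y <= row.ymax)
            out[inside] = row.cell_id
        return out

    def annual_mean(self, study_year: int) -> pd.Series:
        """Per-cell arithmetic mean of daily values over the calendar year;
        days absent from the surface are skipped."""
        d = self.daily[self.daily["date"].dt.year == study_year]
        return d.groupby("cell_id")["value"].mean()


@dataclass(frozen=True)
class RoadwaySegment:
    segment_id: str
    x1: float
    y1: float
    x2: float
    y2: float
    road_class: str = "primary"

    def __post_init__(self):
        if (self.x1, self.y1) == (self.x2, self.y2):
            raise ValidationError(f"segment {self.segment_id}: endpoints coincide")


@dataclass(frozen=True)
class BlockGroup:
    blockgroup_id: str
    population: Optional[float]
    prob_no_insurance: Optional[float]
    median_income: Optional[float]
    xmin: float = math.nan
    ymin: float = math.nan
    xmax: float = math.nan
    ymax: float = math.nan

    def __post_init__(self):
        if self.population is not None and not math.isnan(self.population) \
                and self.population < 0:
            raise ValidationError(f"{self.blockgroup_id}: negative population")
        p = self.prob_no_insurance
        if p is not None and not math.isnan(p) and not 0 <= p <= 1:
            raise ValidationError(f"{self.blockgroup_id}: prob_no_insurance outside [0,1]")


@dataclass(frozen=True)
class ExposureEstimate:
    """Per-patient, per-study-year exposure summary (raw, pre-binning)."""

    patient_id: str
    study_year: int
    avg_daily_pm25: Optional[float] = None
    avg_max_daily_ozone: Optional[float] = None
    roadway_distance: Optional[float] = None
    density_class: Optional[str] = None
    prob_no_insurance: Optional[float] = None
    median_income: Optional[float] = None


# -- pollutant summaries -----------------------------------------------------

def _annual_surface_value(geocode, surface: ExposureSurface, study_year: int):
    if geocode is None:
        return None
    x, y = geocode
    if x is None or y is None or (isinstance(x, float) and math.isnan(x)) \
            or (isinstance(y, float) and math.isnan(y)):
        return None
    cell = surface.locate(np.array([x]), np.array([y]))[0]
    if cell is None:
        logger.info("geocode (%s, %s) outside %s surface coverage", x, y,
                    surface.pollutant)
        return None
    means = surface.annual_mean(study_year)
    if cell not in means.index:
        return None
    return float(means.loc[cell])


def annual_pm25(geocode, surface: ExposureSurface, study_year: int):
    """Annual mean of daily-average PM2.5 for the cell containing `geocode`."""
    if surface.pollutant != "pm25":
        raise ValidationError("annual_pm25 requires a pm25 surface")
    return _annual_surface_value(geocode, surface, study_year)


def annual_max_ozone(geocode, surface: ExposureSurface, study_year: int):
    """Annual mean of daily-maximum ozone for the cell containing `geocode`."""
    if surface.pollutant != "ozone":
        raise ValidationError("annual_max_ozone requires an ozone surface")
    return _annual_surface_value(geocode, surface, study_year)


# -- roadway proximity -------------------------------------------------------

def _roadway_geometry(roadways: Sequence) -> Optional[MultiLineString]:
    lines = []
    for seg in roadways:
        if isinstance(seg, RoadwaySegment):
            lines.append(LineString([(seg.x1, seg.y1), (seg.x2, seg.y2)]))
        else:  # (x1, y1, x2, y2) tuple
            x1, y1, x2, y2 = seg
            lines.append(LineString([(x1, y1), (x2, y2)]))
    return MultiLineString(lines) if lines else None


def _haversine_point_to_segments(x, y, roadways, n_samples: int = 512):
    """Great-circle distance to densely sampled segment points (degrees in,
    meters out). Adequate for the short segments this hook is meant for."""
    best = math.inf
    lam1, phi1 = math.radians(x), math.radians(y)
    for seg in roadways:
        sx1, sy1, sx2, sy2 = (seg.x1, seg.y1, seg.x2, seg.y2) \
            if isinstance(seg, RoadwaySegment) else seg
        for t in np.linspace(0.0, 1.0, n_samples):
            lam2 = math.radians(sx1 + t * (sx2 - sx1))
            phi2 = math.radians(sy1 + t * (sy2 - sy1))
            h = (math.sin((phi2 - phi1) / 2) ** 2
                 + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2)
            best = min(best, 2 * EARTH_RADIUS_M * math.asin(math.sqrt(h)))
    return best


def roadway_distance(geocode, roadways: Sequence, distance_metric: str = "euclidean"):
    """Minimum point-to-segment distance in meters; missing on empty input."""
    if geocode is None or not roadways:
        return None
    x, y = geocode
    if x is None or y is None or (isinstance(x, float) and math.isnan(x)) \
            or (isinstance(y, float) and math.isnan(y)):
        return None
    if distance_metric == "haversine":
        return _haversine_point_to_segments(x, y, roadways)
    geom = _roadway_geometry(roadways)
    return float(Point(x, y).distance(geom))


def _roadway_distances_vec(xs, ys, roadways) -> np.ndarray:
    geom = _roadway_geometry(roadways)
    out = np.full(len(xs), np.nan)
    ok = np.isfinite(xs) & np.isfinite(ys)
    if geom is not None and ok.any():
        pts = shapely.points(xs[ok], ys[ok])
        out[ok] = shapely.distance(pts, geom)
    return out


# -- residential density -----------------------------------------------------

def density_class(population) -> str:
    """US-census style classification from persons per block group:
    <2500 rural; 2500-50,000 urban cluster; >50,000 urbanized."""
    population = float(population)
    if math.isnan(population):
        raise ValidationError("population is NaN; propagate missing upstream")
    if population < 0:
        raise ValidationError(f"negative population {population}")
    if population < RURAL_MAX:
        return "rural"
    if population <= URBAN_CLUSTER_MAX:
        return "urban cluster"
    return "urbanized"


# -- whole-cohort integration ------------------------------------------------

def _blockgroups_frame(blockgroups) -> pd.DataFrame:
    if isinstance(blockgroups, pd.DataFrame):
        return blockgroups.copy()
    return pd.DataFrame([vars(b) for b in blockgroups])


def integrate(patients: pd.DataFrame, surfaces: Sequence[ExposureSurface],
              roadways: Sequence, blockgroups, study_year: int,
              distance_metric: str = "euclidean") -> pd.DataFrame:
    """One :class:`ExposureEstimate` row per patient.

    `patients` needs columns ``patient_id, x_m, y_m`` and optionally
    ``blockgroup_id``; the block-group join uses the id when present, else
    point-in-extent. Missing geocode leaves every geography-derived field
    missing.
    """
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id {dup!r}")
    n = len(patients)
    out = pd.DataFrame({"patient_id": patients["patient_id"].to_numpy(),
                        "study_year": study_year})
    if n == 0:
        for c in ("avg_daily_pm25", "avg_max_daily_ozone", "roadway_distance",
                  "density_class", "prob_no_insurance", "median_income"):
            out[c] = pd.Series(dtype=float)
        return out

    xs = pd.to_numeric(patients.get("x_m"), errors="coerce").to_numpy(dtype=float)
    ys = pd.to_numeric(patients.get("y_m"), errors="coerce").to_numpy(dtype=float)
    has_geo = np.isfinite(xs) & np.isfinite(ys)

    # pollutant surfaces
    by_pollutant = {s.pollutant: s for s in surfaces}
    for pollutant, col in (("pm25", "avg_daily_pm25"), ("ozone", "avg_max_daily_ozone")):
        vals = np.full(n, np.nan)
        surf = by_pollutant.get(pollutant)
        if surf is not None and has_geo.any():
            cells = surf.locate(xs[has_geo], ys[has_geo])
            means = surf.annual_mean(study_year)
            vals[has_geo] = [float(means.loc[c]) if c is not None and c in means.index
                             else np.nan for c in cells]
        out[col] = vals

    # roadway proximity
    if distance_metric == "haversine":
        rd = np.array([_haversine_point_to_segments(x, y, roadways)
                       if ok and roadways else np.nan
                       for x, y, ok in zip(xs, ys, has_geo)])
    else:
        rd = _roadway_distances_vec(xs, ys, roadways) if roadways else np.full(n, np.nan)
    out["roadway_distance"] = rd

    # census block-group attributes
    bg = _blockgroups_frame(blockgroups)
    bg_id = patients.get("blockgroup_id")
    bg_id = bg_id.astype("object").where(bg_id.notna(), None) if bg_id is not None \
        else pd.Series([None] * n)
    resolved = np.array(bg_id.tolist(), dtype=object)
    need = np.array([b is None for b in resolved]) & has_geo
    if need.any() and {"xmin", "ymin", "xmax", "ymax"} <= set(bg.columns):
        for row in bg.sort_values("blockgroup_id", ascending=False).itertuples(index=False):
            inside = need & (xs >= row.xmin) & (xs <= row.xmax) \
                & (ys >= row.ymin) & (ys <= row.ymax)
            resolved[inside] = row.blockgroup_id
    lookup = bg.set_index("blockgroup_id")
    pop = np.full(n, np.nan)
    ins = np.full(n, np.nan)
    inc = np.full(n, np.nan)
    known = pd.Series(resolved).isin(lookup.index).to_numpy()
    idx = pd.Index(resolved[known])
    pop[known] = pd.to_numeric(lookup.loc[idx, "population"], errors="coerce")
    ins[known] = pd.to_numeric(lookup.loc[idx, "prob_no_insurance"], errors="coerce")
    inc[known] = pd.to_numeric(lookup.loc[idx, "median_income"], errors="coerce")
    out["density_class"] = [density_class(p) if np.isfinite(p) else None for p in pop]
    out["prob_no_insurance"] = ins
    out["median_income"] = inc
    return out


class ExposureIntegrator(TransformerMixin, BaseEstimator):
    """scikit-learn shaped wrapper: ``transform(patients)`` -> estimate frame."""

    def __init__(self, surfaces=(), roadways=(), blockgroups=(), study_year: int = 2016,
                 distance_metric: str = "euclidean"):
        self.surfaces = surfaces
        self.roadways = roadways
        self.blockgroups = blockgroups
        self.study_year = study_year
        self.distance_metric = distance_metric

    def fit(self, X=None, y=None):
        self.n_surfaces_ = len(self.surfaces)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        return integrate(X, self.surfaces, self.roadways, self.blockgroups,
                         self.study_year, self.distance_metric)
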