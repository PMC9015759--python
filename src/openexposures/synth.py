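"""Seeded synthetic cohort generator.

Emulates the structure of a large asthma cohort (~157,000 patients) linked to
environmental and census data so the full pipeline is testable without any
protected health information:

* a planar 100 km x 100 km region; census block groups are a rectangular
  tiling carrying population (rural / urban-cluster mix), estimated
  probability of no health insurance, and estimated median household income;
* gridded daily pollutant surfaces (PM2.5 daily averages, ozone daily
  maxima) generated as a seasonal sinusoid plus Gaussian noise, with
  per-cell annual means spanning the published bin ranges;
* random major-roadway segments, with patients preferentially placed near
  roads so the published proximity distribution is approximated;
* clinical extracts (patients + coded encounters) in which every
  non-"decoy" patient satisfies one of the four cohort-inclusion rules.

Outcome indicators are drawn from a logistic model on the patient's *binned*
features: logit(p) = logit(baseline prevalence) + centered per-bin log-odds
offsets.  Because the offsets act on the same bins the downstream pipeline
reconstructs, planted effects are exactly recoverable by the chi-square
battery.  The default effect specification is derived from the published
per-bin outcome rates, so the default simulation emulates the published
associations; a zero effect specification yields pure-noise features.

Everything is driven by a single integer seed: identical configurations
produce byte-identical written bundles.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .binning import default_schemes
from .errors import ConfigurationError
from .exposures import ExposureSurface, RoadwaySegment, _roadway_distances_vec
from .table import round_pct

__all__ = ["SimulationConfig", "SyntheticBundle", "generate", "write_bundle",
           "read_bundle", "default_effect_spec", "published_counts"]

AGE_BIN_BOUNDS = {"<5": (0, 4), "5-17": (5, 17), "18-44": (18, 44),
                  "45-64": (45, 64), "65-89": (65, 89)}


def published_counts() -> dict:
    """The shipped published summary counts for the asthma use case."""
    ref = resources.files("openexposures.data").joinpath("asthma_use_case_counts.yaml")
    return yaml.safe_load(ref.read_text())


def _normalized(counts: dict, drop=("missing",)) -> dict:
    kept = {k: v for k, v in counts.items() if k not in drop}
    total = sum(kept.values())
    return {k: v / total for k, v in kept.items()}


def default_effect_spec() -> dict:
    """Per-bin log-odds offsets derived from the published per-bin outcome
    rates, relative to each outcome's overall prevalence.

    The prednisone outcome shares the non-age feature effects with the
    ED/inpatient outcome (the published results were consistent across
    outcomes apart from the age pattern)."""
    doc = published_counts()
    prev = {k: v["prevalence"] for k, v in doc["outcomes"].items()}
    spec: Dict[str, dict] = {"ed": {}, "prednisone": {}}
    for assoc in doc["associations"]:
        base = logit(prev[assoc["outcome"]])
        offs = {b: float(logit(k / n) - base)
                for b, k, n in zip(assoc["bins"], assoc["positive"], assoc["totals"])}
        spec[assoc["outcome"]][assoc["feature"]] = offs
    for feat, offs in spec["ed"].items():
        spec["prednisone"].setdefault(feat, dict(offs))
    return spec


def _default_marginal(feature, drop=("missing",)):
    return _normalized(published_counts()["marginals"][feature], drop)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Marginal distributions default to the published cohort marginals
    (normalized over non-missing values); the effect specification defaults
    to the published per-bin associations.  ``missing_rates`` drives
    missing-completely-at-random missingness at its natural source: patient
    geocodes (which propagate to every geography-derived estimate) and
    block-group-level census attribute suppression.
    """

    seed: int = 0
    n_patients: int = 157410
    study_year: int = 2016
    outcome_prevalence_ed: float = 0.1673
    outcome_prevalence_prednisone: float = 0.1084
    age_dist: dict = field(default_factory=lambda: _default_marginal("AgeStudyStart"))
    sex_dist: dict = field(default_factory=lambda: {
        "female": 89531 / 157410, "male": 67875 / 157410, "other": 4 / 157410})
    race_dist: dict = field(default_factory=lambda: _default_marginal("Race", drop=()))
    ethnicity_dist: dict = field(
        default_factory=lambda: _default_marginal("Ethnicity", drop=()))
    insurance_bin_dist: dict = field(
        default_factory=lambda: _default_marginal("EstProbabilityNoHealthIns"))
    income_bin_dist: dict = field(
        default_factory=lambda: _default_marginal("EstHouseholdIncome"))
    rural_blockgroup_fraction: float = 0.696  # of non-missing: 95632/137430
    effect_spec: dict = field(default_factory=default_effect_spec)
    missing_rates: dict = field(default_factory=lambda: {
        # geocode missingness matches the published pollutant-bin missing
        # fraction; block-group attribute suppression adds the published
        # extra missingness for density / insurance / income
        "geocode": 0.1042,
        "bg_population": 0.0253,
        "bg_insurance": 0.0259,
        "bg_income": 0.0439,
    })
    decoy_fraction: float = 0.02      # patients failing all inclusion rules
    rule_probs: tuple = (0.70, 0.15, 0.10, 0.05)
    extra_null_features: int = 0      # additional outcome-independent categoricals
    # geography
    region_size_m: float = 100_000.0
    bg_grid: int = 20                 # block groups per side (20x20 tiling)
    cell_grid: int = 10               # pollutant grid cells per side
    n_roadways: int = 60
    near_road_fraction: float = 0.45
    near_road_max_offset: float = 250.0
    mid_road_fraction: float = 0.10
    mid_road_max_offset: float = 1500.0
    # pollutant surface parameters (per-cell annual-mean target ~ clipped
    # normal; daily value = target + seasonal sinusoid + Gaussian noise)
    pm25_mean: float = 7.1
    pm25_cell_sd: float = 0.55
    pm25_clip: tuple = (3.5, 10.6)    # inside the published [3.27, 10.83]
    pm25_amplitude: float = 1.5
    pm25_daily_sd: float = 1.2
    ozone_mean: float = 40.55
    ozone_cell_sd: float = 1.1
    ozone_clip: tuple = (28.2, 46.0)  # inside the published [27.80, 46.45]
    ozone_amplitude: float = 4.0
    ozone_daily_sd: float = 2.5
    # clinical event intensities
    extra_visits_poisson: float = 0.7
    inpatient_fraction: float = 0.15

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        for name in ("outcome_prevalence_ed", "outcome_prevalence_prednisone",
                     "decoy_fraction", "near_road_fraction", "mid_road_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("age_dist", "sex_dist", "race_dist", "ethnicity_dist",
                     "insurance_bin_dist", "income_bin_dist"):
            dist = getattr(self, name)
            if not dist:
                raise ConfigurationError(f"{name} is empty")
            if any(not 0 <= p <= 1 for p in dist.values()):
                raise ConfigurationError(f"{name} has probabilities outside [0, 1]")
            if abs(sum(dist.values()) - 1) > 1e-6:
                raise ConfigurationError(f"{name} proportions must sum to 1")
        for rate in self.missing_rates.values():
            if not 0 <= rate <= 1:
                raise ConfigurationError("missing rates must be in [0, 1]")
        if set(self.effect_spec) - {"ed", "prednisone"}:
            raise ConfigurationError("effect_spec keys must be 'ed'/'prednisone'")

    # convenience constructors ------------------------------------------------

    @classmethod
    def null(cls, seed: int, n_patients: int, **kw) -> "SimulationConfig":
        """All effect offsets zero: outcomes independent of every feature."""
        return cls(seed=seed, n_patients=n_patients,
                   effect_spec={"ed": {}, "prednisone": {}}, **kw)

    @classmethod
    def planted(cls, seed: int, n_patients: int, feature: str = "Sex",
                offsets: Optional[dict] = None, outcome: str = "ed",
                extra_null_features: int = 20, **kw) -> "SimulationConfig":
        """A single planted association among otherwise-null features."""
        if offsets is None:
            offsets = {"female": 0.3, "male": 0.0}
        spec = {"ed": {}, "prednisone": {}}
        spec[outcome] = {feature: dict(offsets)}
        return cls(seed=seed, n_patients=n_patients, effect_spec=spec,
                   extra_null_features=extra_null_features, **kw)


@dataclass
class SyntheticBundle:
    """Everything one simulation produced, plus the planted truth."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    surfaces: List[ExposureSurface]
    roadways: List[RoadwaySegment]
    blockgroups: pd.DataFrame
    truth: dict


# -- generation ---------------------------------------------------------------

def _grid_frame(n_side: int, size: float, prefix: str) -> pd.DataFrame:
    w = size / n_side
    rows = []
    for r in range(n_side):
        for c in range(n_side):
            rows.append({"cell_id" if prefix == "C" else "blockgroup_id":
                         f"{prefix}{r:02d}{c:02d}",
                         "xmin": c * w, "ymin": r * w,
                         "xmax": (c + 1) * w, "ymax": (r + 1) * w})
    return pd.DataFrame(rows)


def _grid_index(x, y, n_side: int, size: float, prefix: str) -> np.ndarray:
    w = size / n_side
    out = np.full(len(x), None, dtype=object)
    ok = np.isfinite(x) & np.isfinite(y)
    cx = np.clip((x[ok] // w).astype(int), 0, n_side - 1)
    cy = np.clip((y[ok] // w).astype(int), 0, n_side - 1)
    out[ok] = [f"{prefix}{r:02d}{c:02d}" for r, c in zip(cy, cx)]
    return out


def _make_blockgroups(cfg: SimulationConfig, rng) -> pd.DataFrame:
    bg = _grid_frame(cfg.bg_grid, cfg.region_size_m, "BG")
    n = len(bg)
    rural = rng.random(n) < cfg.rural_blockgroup_fraction
    pop = np.where(rural, rng.integers(200, 2500, n), rng.integers(2500, 50001, n))
    bg["population"] = pop.astype(float)

    def draw_within_bins(dist: dict, edges: list) -> np.ndarray:
        labels = list(dist)
        idx = rng.choice(len(labels), size=n, p=list(dist.values()))
        lo = np.array([edges[i] for i in idx], dtype=float)
        hi = np.array([edges[i + 1] for i in idx], dtype=float)
        u = rng.uniform(0.001, 0.999, n)  # keep strictly inside the interval
        return lo + u * (hi - lo)

    bg["prob_no_insurance"] = draw_within_bins(
        cfg.insurance_bin_dist, [0.0, 0.0637, 0.1121, 0.1644, 0.5548])
    bg["median_income"] = draw_within_bins(
        cfg.income_bin_dist, [7470, 36635, 46750, 59566, 78355, 250001])
    for col, key in (("population", "bg_population"),
                     ("prob_no_insurance", "bg_insurance"),
                     ("median_income", "bg_income")):
        mask = rng.random(n) < cfg.missing_rates.get(key, 0.0)
        bg.loc[mask, col] = np.nan
    return bg


def _make_roadways(cfg: SimulationConfig, rng) -> List[RoadwaySegment]:
    L = cfg.region_size_m
    out = []
    for i in range(cfg.n_roadways):
        x1, y1 = rng.uniform(0, L, 2)
        theta = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(0.2 * L, 0.8 * L)
        x2 = float(np.clip(x1 + length * math.cos(theta), 0, L))
        y2 = float(np.clip(y1 + length * math.sin(theta), 0, L))
        if (x1, y1) == (x2, y2):
            x2 = min(L, x1 + 1000.0)
        road_class = "highway" if rng.random() < 0.5 else "primary"
        out.append(RoadwaySegment(f"R{i:03d}", float(x1), float(y1), x2, y2, road_class))
    return out


def _make_surface(cfg: SimulationConfig, rng, pollutant: str) -> ExposureSurface:
    cells = _grid_frame(cfg.cell_grid, cfg.region_size_m, "C")
    mean, sd, clip, amp, noise = {
        "pm25": (cfg.pm25_mean, cfg.pm25_cell_sd, cfg.pm25_clip,
                 cfg.pm25_amplitude, cfg.pm25_daily_sd),
        "ozone": (cfg.ozone_mean, cfg.ozone_cell_sd, cfg.ozone_clip,
                  cfg.ozone_amplitude, cfg.ozone_daily_sd),
    }[pollutant]
    n_cells = len(cells)
    targets = np.clip(rng.normal(mean, sd, n_cells), *clip)
    phase = rng.uniform(0, 2 * math.pi, n_cells)
    dates = pd.date_range(f"{cfg.study_year}-01-01", f"{cfg.study_year}-12-31")
    doy = np.arange(len(dates))
    seasonal = np.sin(2 * math.pi * doy / len(dates) + phase[:, None])  # (cells, days)
    values = targets[:, None] + amp * seasonal + rng.normal(0, noise, (n_cells, len(dates)))
    values = np.maximum(values, 0.05)
    daily = pd.DataFrame({
        "cell_id": np.repeat(cells["cell_id"].to_numpy(), len(dates)),
        "date": np.tile(dates.strftime("%Y-%m-%d"), n_cells),
        "value": values.ravel().round(4),
    })
    return ExposureSurface(pollutant=pollutant, cells=cells, daily=daily)


def _place_patients(cfg: SimulationConfig, rng, roadways) -> np.ndarray:
    """Mixture placement: a share of patients near roadway segments (uniform
    perpendicular offset), the rest uniform over the region."""
    n = cfg.n_patients
    L = cfg.region_size_m
    pos = rng.uniform(0, L, (n, 2))
    u = rng.random(n)
    near = u < cfg.near_road_fraction
    mid = (~near) & (u < cfg.near_road_fraction + cfg.mid_road_fraction)
    for mask, lo, hi in ((near, 0.0, cfg.near_road_max_offset),
                         (mid, cfg.near_road_max_offset, cfg.mid_road_max_offset)):
        k = int(mask.sum())
        if k == 0 or not roadways:
            continue
        seg_idx = rng.integers(0, len(roadways), k)
        t = rng.random(k)
        offset = rng.uniform(lo, hi, k) * np.where(rng.random(k) < 0.5, 1.0, -1.0)
        p1 = np.array([(roadways[i].x1, roadways[i].y1) for i in seg_idx])
        p2 = np.array([(roadways[i].x2, roadways[i].y2) for i in seg_idx])
        d = p2 - p1
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        unit = d / np.where(norm == 0, 1.0, norm)
        perp = np.column_stack([-unit[:, 1], unit[:, 0]])
        pos[mask] = np.clip(p1 + t[:, None] * d + offset[:, None] * perp, 0, L)
    return pos


def _birth_dates(cfg: SimulationConfig, rng, age_labels: np.ndarray) -> np.ndarray:
    ages = np.empty(len(age_labels), dtype=int)
    for label, (lo, hi) in AGE_BIN_BOUNDS.items():
        mask = age_labels == label
        ages[mask] = rng.integers(lo, hi + 1, int(mask.sum()))
    offsets = rng.integers(0, 365, len(ages))
    base = pd.to_datetime({"year": cfg.study_year - ages, "month": 1, "day": 1})
    return (base - pd.to_timedelta(offsets, "D")).dt.strftime("%Y-%m-%d").to_numpy()


def _choice(rng, dist: dict, n: int) -> np.ndarray:
    labels = np.array(list(dist), dtype=object)
    return labels[rng.choice(len(labels), size=n, p=list(dist.values()))]


def _random_dates(cfg, rng, n) -> np.ndarray:
    days = (_dt.date(cfg.study_year + 1, 1, 1) - _dt.date(cfg.study_year, 1, 1)).days
    start = np.datetime64(f"{cfg.study_year}-01-01")
    return (start + rng.integers(0, days, n)).astype("datetime64[D]").astype(str)


def _make_encounters(cfg: SimulationConfig, rng, pids, ed_counts, rx_counts,
                     criteria_vocab: dict) -> pd.DataFrame:
    n = len(pids)
    cols = {"patient_id": [], "date": [], "encounter_class": [],
            "code_type": [], "code": []}

    def add(pid, date, klass, ctype, code):
        cols["patient_id"].append(np.asarray(pid, dtype=object))
        cols["date"].append(np.asarray(date, dtype=object))
        cols["encounter_class"].append(np.asarray(klass, dtype=object))
        cols["code_type"].append(np.asarray(ctype, dtype=object))
        cols["code"].append(np.asarray(code, dtype=object))

    decoy = rng.random(n) < cfg.decoy_fraction
    rule = np.zeros(n, dtype=int)  # 0 = decoy
    rule[~decoy] = rng.choice([1, 2, 3, 4], size=int((~decoy).sum()),
                              p=list(cfg.rule_probs))

    resp = criteria_vocab["respiratory_dx"]
    pulm = criteria_vocab["pulmonary_dx"]
    meds = criteria_vocab["asthma_med"]
    procs = criteria_vocab["asthma_proc"]
    neb = criteria_vocab["nebulizer_med"][0]
    threshold = int(criteria_vocab.get("frequent_ed_threshold", 2))

    # qualifying diagnosis for every patient (decoys get a respiratory dx only)
    dx_code = np.empty(n, dtype=object)
    dx_code[rule == 1] = "DX:ASTHMA"
    for r, vocab in ((2, resp), (4, resp), (3, pulm), (0, resp)):
        mask = rule == r
        dx_code[mask] = np.array(vocab, dtype=object)[
            rng.integers(0, len(vocab), int(mask.sum()))]
    add(pids, _random_dates(cfg, rng, n), np.full(n, "outpatient"),
        np.full(n, "dx"), dx_code)

    # companion medication / procedure establishing rules 1-3
    m12 = (rule == 1) | (rule == 2)
    k = int(m12.sum())
    add(pids[m12], _random_dates(cfg, rng, k), np.full(k, "outpatient"),
        np.full(k, "med"), np.array(meds, dtype=object)[rng.integers(0, len(meds), k)])
    m3 = rule == 3
    k = int(m3.sum())
    add(pids[m3], _random_dates(cfg, rng, k), np.full(k, "outpatient"),
        np.full(k, "proc"), np.array(procs, dtype=object)[rng.integers(0, len(procs), k)])

    # rule 4: `threshold` ED visits on distinct dates with nebulizer treatment
    m4 = rule == 4
    k = int(m4.sum())
    if k:
        days = (_dt.date(cfg.study_year + 1, 1, 1) - _dt.date(cfg.study_year, 1, 1)).days
        base = rng.integers(0, days - threshold, k)
        offs = base[:, None] + np.arange(threshold)[None, :]
        dates = (np.datetime64(f"{cfg.study_year}-01-01")
                 + offs.ravel()).astype("datetime64[D]").astype(str)
        rep = np.repeat(pids[m4], threshold)
        add(rep, dates, np.full(k * threshold, "ED"), np.full(k * threshold, "med"),
            np.full(k * threshold, neb))

    # outcome events: ED/inpatient visits with a respiratory dx; prednisone rx
    resp_all = criteria_vocab["respiratory_visit_dx"]
    rep = np.repeat(pids, ed_counts)
    k = len(rep)
    klass = np.where(rng.random(k) < cfg.inpatient_fraction, "inpatient", "ED")
    add(rep, _random_dates(cfg, rng, k), klass, np.full(k, "dx"),
        np.array(resp_all, dtype=object)[rng.integers(0, len(resp_all), k)])
    rep = np.repeat(pids, rx_counts)
    k = len(rep)
    add(rep, _random_dates(cfg, rng, k), np.full(k, "outpatient"),
        np.full(k, "med"), np.full(k, "MED:PREDNISONE"))

    enc = pd.DataFrame({c: np.concatenate(v) if v else np.array([], dtype=object)
                        for c, v in cols.items()})
    return enc.sort_values(list(enc.columns), kind="stable").reset_index(drop=True)


def generate(config: SimulationConfig) -> SyntheticBundle:
    """Run one simulation; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    blockgroups = _make_blockgroups(config, rng)
    roadways = _make_roadways(config, rng)
    pm25 = _make_surface(config, rng, "pm25")
    ozone = _make_surface(config, rng, "ozone")

    pos = _place_patients(config, rng, roadways)
    xs, ys = pos[:, 0].copy(), pos[:, 1].copy()
    geo_missing = rng.random(n) < config.missing_rates.get("geocode", 0.0)
    xs[geo_missing] = np.nan
    ys[geo_missing] = np.nan
    bg_id = _grid_index(xs, ys, config.bg_grid, config.region_size_m, "BG")

    pids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    age_label = _choice(rng, config.age_dist, n)
    birth = _birth_dates(config, rng, age_label)
    sex = _choice(rng, config.sex_dist, n)
    race = _choice(rng, config.race_dist, n)
    ethnicity = _choice(rng, config.ethnicity_dist, n)

    patients = pd.DataFrame({
        "patient_id": pids, "birth_date": birth, "sex": sex, "race": race,
        "ethnicity": ethnicity,
        "x_m": np.round(xs, 2), "y_m": np.round(ys, 2), "blockgroup_id": bg_id,
    })
    for j in range(config.extra_null_features):
        patients[f"extra_cat_{j + 1:02d}"] = _choice(
            rng, {f"L{i}": 0.25 for i in range(1, 5)}, n)

    # ground-truth binned features for the outcome model ---------------------
    schemes = {s.feature: s for s in default_schemes()}
    bg_lookup = blockgroups.set_index("blockgroup_id")
    known = pd.Series(bg_id).notna().to_numpy()
    pop = np.full(n, np.nan)
    ins = np.full(n, np.nan)
    inc = np.full(n, np.nan)
    if known.any():
        idx = pd.Index(bg_id[known])
        pop[known] = bg_lookup.loc[idx, "population"].to_numpy()
        ins[known] = bg_lookup.loc[idx, "prob_no_insurance"].to_numpy()
        inc[known] = bg_lookup.loc[idx, "median_income"].to_numpy()

    cell_id = _grid_index(xs, ys, config.cell_grid, config.region_size_m, "C")
    feat_bins = {}
    for pollutant, surf, column in (("pm25", pm25, "AvgDailyPM25Exposure"),
                                    ("ozone", ozone, "MaxDailyOzoneExposure")):
        means = surf.annual_mean(config.study_year)
        vals = np.full(n, np.nan)
        ok = pd.Series(cell_id).notna().to_numpy()
        if ok.any():
            vals[ok] = means.loc[pd.Index(cell_id[ok])].to_numpy()
        feat_bins[column] = schemes[column].assign(vals).to_numpy()

    rd = _roadway_distances_vec(xs, ys, roadways)
    feat_bins["MajorRoadwayHighwayExposure"] = \
        schemes["MajorRoadwayHighwayExposure"].assign(rd).to_numpy()
    feat_bins["EstProbabilityNoHealthIns"] = \
        schemes["EstProbabilityNoHealthIns"].assign(ins).to_numpy()
    feat_bins["EstHouseholdIncome"] = schemes["EstHouseholdIncome"].assign(inc).to_numpy()
    feat_bins["EstResidentialDensity"] = np.array(
        ["rural" if p < 2500 else ("urban cluster" if p <= 50000 else "urbanized")
         if np.isfinite(p) else None for p in pop], dtype=object)
    feat_bins["AgeStudyStart"] = age_label
    feat_bins["Sex"] = np.where(np.isin(sex, ("female", "male")), sex, None)
    feat_bins["Race"] = race
    feat_bins["Ethnicity"] = ethnicity
    for j in range(config.extra_null_features):
        feat_bins[f"ExtraCat{j + 1:02d}"] = patients[f"extra_cat_{j + 1:02d}"].to_numpy()

    # outcomes: logistic on binned features with centered planted offsets ----
    outcomes = {}
    truth_offsets = {}
    for key, prevalence in (("ed", config.outcome_prevalence_ed),
                            ("prednisone", config.outcome_prevalence_prednisone)):
        shifts = np.zeros(n)
        applied = {}
        for feature, offsets in config.effect_spec.get(key, {}).items():
            labels = feat_bins.get(feature)
            if labels is None:
                raise ConfigurationError(f"effect_spec references unknown "
                                         f"feature {feature!r}")
            off = np.array([offsets.get(lbl, 0.0) if lbl is not None else 0.0
                            for lbl in labels])
            if n:
                off = off - off.mean()
            shifts = shifts + off
            applied[feature] = dict(offsets)
        # calibrate the intercept so the expected prevalence equals the
        # configured one exactly (mean-zero log-odds shifts alone leave a
        # Jensen bias on the probability scale)
        intercept = logit(prevalence)
        if n and shifts.any():
            intercept = brentq(
                lambda c: expit(c + shifts).mean() - prevalence,
                logit(prevalence) - 5.0, logit(prevalence) + 5.0, xtol=1e-12)
        draw = rng.random(n) < expit(intercept + shifts)
        counts = np.where(draw, 1 + rng.poisson(config.extra_visits_poisson, n), 0)
        outcomes[key] = counts
        truth_offsets[key] = applied

    vocab = {
        "respiratory_dx": ["DX:RESP-BRONCHITIS", "DX:RESP-WHEEZE", "DX:RESP-URI"],
        "pulmonary_dx": ["DX:PULM-COPD", "DX:PULM-FIBROSIS"],
        "asthma_med": ["MED:ALBUTEROL-INH", "MED:FLUTICASONE", "MED:MONTELUKAST"],
        "asthma_proc": ["PROC:SPIROMETRY", "PROC:FENO"],
        "nebulizer_med": ["MED:ALBUTEROL-NEB"],
        "respiratory_visit_dx": ["DX:ASTHMA", "DX:RESP-BRONCHITIS", "DX:RESP-WHEEZE",
                                 "DX:RESP-URI", "DX:PULM-COPD", "DX:PULM-FIBROSIS"],
        "frequent_ed_threshold": 2,
    }
    encounters = _make_encounters(config, rng, pids, outcomes["ed"],
                                  outcomes["prednisone"], vocab)

    truth = {
        "effect_spec": truth_offsets,
        "outcome_prevalence": {"ed": config.outcome_prevalence_ed,
                               "prednisone": config.outcome_prevalence_prednisone},
        "realized_prevalence": {
            k: float((v > 0).mean()) if n else float("nan")
            for k, v in outcomes.items()},
        "study_year": config.study_year,
        "seed": config.seed,
    }
    return SyntheticBundle(patients=patients, encounters=encounters,
                           surfaces=[pm25, ozone], roadways=roadways,
                           blockgroups=blockgroups, truth=truth)


# -- persistence --------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, directory) -> dict:
    """Write the bundle as the CSV extract files consumed downstream.

    Returns a manifest mapping file name to row count (also written as
    ``manifest.json``). Identical bundles produce byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def put(name: str, df: pd.DataFrame, float_format="%.4f"):
        df.to_csv(directory / name, index=False, float_format=float_format,
                  lineterminator="\n")
        manifest[name] = int(len(df))

    put("patients.csv", bundle.patients, float_format="%.2f")
    put("encounters.csv", bundle.encounters)
    by_pollutant = {s.pollutant: s for s in bundle.surfaces}
    for pollutant in ("pm25", "ozone"):
        surf = by_pollutant.get(pollutant)
        if surf is not None:
            daily = surf.daily.assign(
                date=pd.to_datetime(surf.daily["date"]).dt.strftime("%Y-%m-%d"))
            put(f"{pollutant}_daily.csv", daily)
    cells = next(iter(by_pollutant.values())).cells if by_pollutant else \
        pd.DataFrame(columns=["cell_id", "xmin", "ymin", "xmax", "ymax"])
    put("cells.csv", cells, float_format="%.1f")
    put("roadways.csv", pd.DataFrame(
        [vars(r) for r in bundle.roadways],
        columns=["segment_id", "x1", "y1", "x2", "y2", "road_class"]),
        float_format="%.2f")
    put("blockgroups.csv", bundle.blockgroups, float_format="%.6f")
    (directory / "truth.json").write_text(json.dumps(bundle.truth, indent=1,
                                                     sort_keys=True))
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                        sort_keys=True))
    return manifest


def read_bundle(directory) -> SyntheticBundle:
    """Re-read a written bundle (inverse of :func:`write_bundle`)."""
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv",
                           dtype={"patient_id": str, "blockgroup_id": str})
    encounters = pd.read_csv(directory / "encounters.csv", dtype=str)
    cells = pd.read_csv(directory / "cells.csv")
    surfaces = []
    for pollutant in ("pm25", "ozone"):
        path = directory / f"{pollutant}_daily.csv"
        if path.exists():
            daily = pd.read_csv(path, dtype={"cell_id": str})
            surfaces.append(ExposureSurface(pollutant=pollutant, cells=cells,
                                            daily=daily))
    road_df = pd.read_csv(directory / "roadways.csv")
    roadways = [RoadwaySegment(str(r.segment_id), r.x1, r.y1, r.x2, r.y2,
                               str(r.road_class))
                for r in road_df.itertuples(index=False)]
    blockgroups = pd.read_csv(directory / "blockgroups.csv",
                              dtype={"blockgroup_id": str})
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticBundle(patients=patients, encounters=encounters,
                           surfaces=surfaces, roadways=roadways,
                           blockgroups=blockgroups, truth=truth)
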