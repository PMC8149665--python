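"""Synthetic segregated cities with known disparity and inequality structure.

Each generated urbanized area is a disk on a square grid: an urban core
surrounded by a nonurban ring (the rural reference), with optional water
patches and missing LST cells.  Land surface temperature is a rural base
plus a Gaussian urban-density kernel scaled by ``suhi_amplitude``, plus
i.i.d. Gaussian noise.  Census tracts partition the disk into contiguous
equal-cell chunks.  Tract demographics follow a multinomial-logit link: the
share of group g in tract t has logit alpha_g + beta_g * SUHI_t, so beta is
the recoverable "disparity" parameter (beta > 0 concentrates the group in
hotter tracts).  Person counts are drawn multinomially from those shares —
partition schemes therefore sum exactly to the tract population while still
carrying the sampling noise that makes null calibration of the disparity
tests meaningful.  Non-partition bands (age) are independent binomials.

Every city stores a truth record — tract-level SUHI, counts, per-group
weighted means and Kolm-Pollak indices of the generating distribution —
recomputable from stored quantities by code independent of the analysis
modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from .grids import NONURBAN, URBAN, WATER, Georeference, LandCoverGrid, TemperatureGrid, ZoneMap

logger = logging.getLogger(__name__)

CLIMATE_ZONES = ("arid", "snow", "temperate", "equatorial")


@dataclass(frozen=True)
class GroupSpec:
    """One demographic group's link parameters: share ~ logit(alpha + beta*SUHI)."""

    name: str
    alpha: float  # baseline log-odds (multinomial-logit scale for partitions)
    beta: float   # disparity slope per degC of SUHI


@dataclass(frozen=True)
class SchemeGen:
    """Generator for one grouping scheme.

    ``partition=True`` draws counts multinomially over the groups (softmax
    shares; sums to the tract population exactly); otherwise each group is
    an independent binomial band.
    """

    name: str
    groups: tuple[GroupSpec, ...]
    partition: bool = True


def _default_schemes() -> tuple[SchemeGen, ...]:
    # Baseline shares loosely matching national urban composition; slopes
    # chosen to produce a people-of-color vs white gap of roughly a degree.
    race = SchemeGen("race", (
        GroupSpec("hispanic", float(np.log(0.18)), 0.16),
        GroupSpec("nh_white", float(np.log(0.60)), -0.24),
        GroupSpec("nh_black", float(np.log(0.12)), 0.16),
        GroupSpec("nh_other", float(np.log(0.10)), 0.05),
    ))
    income = SchemeGen("income", (
        GroupSpec("below_poverty", float(np.log(0.13)), 0.14),
        GroupSpec("pov_1to2", float(np.log(0.17)), 0.06),
        GroupSpec("above_2x_poverty", float(np.log(0.70)), -0.12),
    ))
    age = SchemeGen("age", (
        GroupSpec("under_5", float(np.log(0.06 / 0.94)), 0.02),
        GroupSpec("over_65", float(np.log(0.16 / 0.84)), -0.05),
    ), partition=False)
    return (race, income, age)


#: Derived groups: name -> (total column, subtracted column).
DEFAULT_DERIVED: dict[str, tuple[str, str]] = {"people_of_color": ("total_pop", "nh_white")}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic panel.

    Defaults give desk-scale cities (40x40 grid, 50 tracts) whose SUHI
    distribution (population mean ~2 degC, SD ~2 degC) and group disparities
    (people-of-color vs white gap on the order of a degree) echo the
    multi-city analysis setting.
    """

    n_cities: int = 40
    grid_size: int = 40
    n_tracts_per_city: int = 50
    suhi_amplitude: float = 12.0    # degC peak of the urban kernel
    noise_sd: float = 1.5           # degC cell-level LST noise
    rural_lst: float = 30.0         # degC summer rural base
    water_frac: float = 0.02
    missing_frac: float = 0.02
    mean_tract_population: float = 4000.0
    pop_sigma: float = 0.5          # lognormal spread of tract populations
    schemes: tuple[SchemeGen, ...] = field(default_factory=_default_schemes)
    derived: tuple[tuple[str, tuple[str, str]], ...] = tuple(DEFAULT_DERIVED.items())
    climate_zones: tuple[str, ...] = CLIMATE_ZONES

    def __post_init__(self) -> None:
        if self.n_tracts_per_city < 1 or self.grid_size < 8:
            raise ValueError("invalid synthetic configuration")
        geo = _city_geometry(self.grid_size, self.n_tracts_per_city)
        if self.n_tracts_per_city > geo.n_ua_cells:
            raise ValueError(
                f"infeasible partition: {self.n_tracts_per_city} tracts for "
                f"{geo.n_ua_cells} urbanized-area cells"
            )

    def null(self) -> "SyntheticConfig":
        """Same config with every disparity slope set to zero."""
        schemes = tuple(
            SchemeGen(s.name, tuple(GroupSpec(g.name, g.alpha, 0.0) for g in s.groups),
                      s.partition)
            for s in self.schemes
        )
        return replace(self, schemes=schemes)


@dataclass(frozen=True, eq=False)
class _CityGeometry:
    """Static per-config geometry, shared by all cities of a panel."""

    shape: tuple[int, int]
    ua_mask: np.ndarray
    urban_mask: np.ndarray
    kernel: np.ndarray
    tract_code: np.ndarray  # 0 outside UA, 1..T inside
    n_ua_cells: int


@lru_cache(maxsize=8)
def _city_geometry(grid_size: int, n_tracts: int) -> _CityGeometry:
    n = grid_size
    idx = np.arange(n) - (n - 1) / 2
    r = np.hypot(idx[:, None], idx[None, :])
    r_ua, r_urban = 0.48 * n, 0.30 * n
    ua_mask = r <= r_ua
    urban_mask = r <= r_urban
    kernel = np.exp(-0.5 * (r / (0.6 * r_urban)) ** 2)
    # Contiguous tracts: chunk UA cells in row-major scan order.
    tract_code = np.zeros((n, n), dtype=np.int64)
    flat = np.flatnonzero(ua_mask.ravel())
    chunks = np.array_split(flat, n_tracts)
    codes = np.zeros(n * n, dtype=np.int64)
    for t, chunk in enumerate(chunks, start=1):
        codes[chunk] = t
    tract_code = codes.reshape(n, n)
    return _CityGeometry((n, n), ua_mask, urban_mask, kernel, tract_code, len(flat))


@dataclass
class SyntheticCity:
    ua_id: str
    climate_zone: str | None
    landcover: LandCoverGrid
    lst: TemperatureGrid
    zones: ZoneMap
    demographics: pd.DataFrame  # raw counts, one row per tract
    tract_truth: pd.DataFrame   # tract-level SUHI + counts incl. derived groups
    truth: dict                 # per-group weighted mean and KP index


def city_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based child seed: reproducible regardless of iteration order."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def _tract_fields(config: SyntheticConfig, rng: np.random.Generator):
    """Draw one city's cell fields and reduce to tract-level SUHI.

    Returns (labels, lst_values, geometry, tract frame with suhi/lst_t/lst_r/n_cells).
    """
    geo = _city_geometry(config.grid_size, config.n_tracts_per_city)
    n = config.grid_size
    labels = np.where(geo.urban_mask, URBAN, NONURBAN).astype(np.int64)
    water = geo.ua_mask & (rng.random(geo.shape) < config.water_frac)
    labels[water] = WATER
    lst = (config.rural_lst + config.suhi_amplitude * geo.kernel
           + rng.normal(0.0, config.noise_sd, geo.shape))
    missing = rng.random(geo.shape) < config.missing_frac
    lst_values = np.where(missing, np.nan, lst)

    valid = ~np.isnan(lst_values)
    ref_mask = geo.ua_mask & (labels == NONURBAN) & valid
    if not ref_mask.any():
        raise RuntimeError("degenerate draw: no rural reference cell")
    lst_r = float(lst_values[ref_mask].mean())

    tract_mask = (geo.tract_code > 0) & (labels != WATER) & valid
    codes = geo.tract_code[tract_mask]
    sums = np.bincount(codes, weights=lst_values[tract_mask],
                       minlength=config.n_tracts_per_city + 1)
    cnts = np.bincount(codes, minlength=config.n_tracts_per_city + 1)
    keep = np.flatnonzero(cnts[1:] > 0) + 1
    lst_t = sums[keep] / cnts[keep]
    tracts = pd.DataFrame({
        "tract_index": keep,
        "lst_t": lst_t,
        "lst_r": lst_r,
        "suhi": lst_t - lst_r,
        "n_cells": cnts[keep].astype(int),
    })
    return labels, lst_values, geo, tracts


def _draw_counts(
    config: SyntheticConfig,
    rng: np.random.Generator,
    suhi: np.ndarray,
    pop: np.ndarray,
    expected: bool = False,
) -> dict[str, np.ndarray]:
    """Group counts per tract from the logit link (sampled or expected)."""
    out: dict[str, np.ndarray] = {"total_pop": pop.astype(float)}
    for scheme in config.schemes:
        if scheme.partition:
            logits = np.stack([g.alpha + g.beta * suhi for g in scheme.groups], axis=1)
            shares = softmax(logits, axis=1)
            if expected:
                counts = shares * pop[:, None]
            else:
                counts = rng.multinomial(pop.astype(np.int64), shares).astype(float)
            for j, g in enumerate(scheme.groups):
                out[g.name] = counts[:, j]
        else:
            for g in scheme.groups:
                share = expit(g.alpha + g.beta * suhi)
                if expected:
                    out[g.name] = share * pop
                else:
                    out[g.name] = rng.binomial(pop.astype(np.int64), share).astype(float)
    for name, (total_col, minus_col) in dict(config.derived).items():
        out[name] = out[total_col] - out[minus_col]
    return out


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float((w * x).sum() / w.sum()) if w.sum() > 0 else float("nan")


def _kp_of(x: np.ndarray, w: np.ndarray, kappa: float = -0.5) -> float:
    # Independent arithmetic (plain shifted-exp evaluation) for truth records.
    m = _weighted_mean(x, w)
    z = kappa * (m - x)
    zmax = z.max()
    s = float((w / w.sum() * np.exp(z - zmax)).sum())
    return -(zmax + np.log(s)) / kappa


def generate_city(
    config: SyntheticConfig,
    seed,
    ua_id: str = "UA000",
    climate_zone: str | None = None,
) -> SyntheticCity:
    """Generate one synthetic urbanized area with recoverable truth."""
    rng = np.random.default_rng(seed)
    labels, lst_values, geo, tracts = _tract_fields(config, rng)

    mu = np.log(config.mean_tract_population) - config.pop_sigma ** 2 / 2
    pop = np.maximum(1, np.round(rng.lognormal(mu, config.pop_sigma, len(tracts)))).astype(int)
    counts = _draw_counts(config, rng, tracts["suhi"].to_numpy(), pop)

    tract_ids = [f"{ua_id}-{t:04d}" for t in tracts["tract_index"]]
    demo = pd.DataFrame({"tract_id": tract_ids})
    raw_cols = ["total_pop"] + [g.name for s in config.schemes for g in s.groups]
    for col in raw_cols:
        demo[col] = counts[col]

    truth_frame = tracts.copy()
    truth_frame.insert(0, "tract_id", tract_ids)
    truth_frame.insert(1, "urbanized_area_id", ua_id)
    for col, vals in counts.items():
        truth_frame[col] = vals

    suhi = tracts["suhi"].to_numpy()
    truth = {
        name: {"weighted_mean": _weighted_mean(suhi, w), "kp_index": _kp_of(suhi, w)}
        for name, w in counts.items()
    }

    ua = np.where(geo.ua_mask, 1, 0).astype(np.int64)
    tract_code = geo.tract_code.copy()
    # Drop codes for tracts that ended up with no qualifying cell (rare).
    dropped = set(range(1, config.n_tracts_per_city + 1)) - set(tracts["tract_index"])
    for code in dropped:
        tract_code[tract_code == code] = 0
    tract_names = {int(t): tid for t, tid in zip(tracts["tract_index"], tract_ids)}
    zones = ZoneMap(ua, tract_code, {1: ua_id}, tract_names)

    georef = Georeference(0.0, float(config.grid_size), 1.0)
    return SyntheticCity(
        ua_id, climate_zone,
        LandCoverGrid(labels, georef),
        TemperatureGrid(lst_values, georef),
        zones, demo, truth_frame, truth,
    )


def truth_disparity(city: SyntheticCity, group_a: str, group_b: str) -> float:
    """Realized weighted-mean exposure gap (a - b) from the stored truth table.

    Same estimand as the exposure statistics, independent code path.
    """
    t = city.tract_truth
    x = t["suhi"].to_numpy(dtype=float)
    wa = t[group_a].to_numpy(dtype=float)
    wb = t[group_b].to_numpy(dtype=float)
    return _weighted_mean(x, wa) - _weighted_mean(x, wb)


@dataclass
class SyntheticPanel:
    cities: list[SyntheticCity]
    zone_labels: dict[str, str]
    config: SyntheticConfig
    master_seed: int

    def suhi_frame(self) -> pd.DataFrame:
        cols = ["tract_id", "urbanized_area_id", "lst_t", "lst_r", "suhi", "n_cells"]
        return pd.concat([c.tract_truth[cols] for c in self.cities], ignore_index=True)

    def demographics_frame(self) -> pd.DataFrame:
        return pd.concat([c.demographics for c in self.cities], ignore_index=True)


def generate_panel(config: SyntheticConfig, seed: int) -> SyntheticPanel:
    """Generate ``config.n_cities`` cities with counter-derived child seeds.

    Climate zones are assigned round-robin (labels, not mechanisms).
    """
    cities = []
    zone_labels = {}
    for i in range(config.n_cities):
        ua_id = f"UA{i:03d}"
        zone = config.climate_zones[i % len(config.climate_zones)]
        cities.append(generate_city(config, city_seed(seed, i), ua_id, zone))
        zone_labels[ua_id] = zone
    return SyntheticPanel(cities, zone_labels, config, seed)


def expected_disparity(
    config: SyntheticConfig,
    group_a: str,
    group_b: str,
    n_cities: int = 20000,
    seed: int = 987654321,
) -> float:
    """Superpopulation weighted-mean gap implied by the generating process.

    Evaluated as the large-panel limit of the national estimator using
    expected (non-sampled) group counts, so only LST noise, water/missing
    masks and tract populations are integrated over.  Serves as the fixed
    truth for parameter-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    num = {group_a: 0.0, group_b: 0.0}
    den = {group_a: 0.0, group_b: 0.0}
    mu = np.log(config.mean_tract_population) - config.pop_sigma ** 2 / 2
    for _ in range(n_cities):
        _, _, _, tracts = _tract_fields(config, rng)
        pop = np.maximum(1, np.round(rng.lognormal(mu, config.pop_sigma, len(tracts))))
        suhi = tracts["suhi"].to_numpy()
        counts = _draw_counts(config, rng, suhi, pop, expected=True)
        for g in (group_a, group_b):
            num[g] += float((counts[g] * suhi).sum())
            den[g] += float(counts[g].sum())
    return num[group_a] / den[group_a] - num[group_b] / den[group_b]


def write_panel(panel: SyntheticPanel, outdir) -> Path:
    """Write a panel as the self-contained bundle the pipeline consumes.

    Layout: cities/<ua>/{lst,landcover,zones_ua,zones_tract}.tif + zone_ids.csv,
    demographics.csv, climate_zones.csv, scheme.yaml, truth_tracts.csv.
    """
    from . import raster_io
    from .demographics import write_default_schemes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in panel.cities:
        cdir = outdir / "cities" / c.ua_id
        cdir.mkdir(parents=True, exist_ok=True)
        raster_io.write_temperature(cdir / "lst.tif", c.lst)
        raster_io.write_landcover(cdir / "landcover.tif", c.landcover)
        raster_io.write_zonemap(cdir, c.zones, c.lst.georef)
    panel.demographics_frame().to_csv(outdir / "demographics.csv", index=False)
    pd.DataFrame(
        [{"urbanized_area_id": ua, "zone": z} for ua, z in panel.zone_labels.items()]
    ).to_csv(outdir / "climate_zones.csv", index=False)
    write_default_schemes(outdir / "scheme.yaml")
    pd.concat([c.tract_truth for c in panel.cities], ignore_index=True).to_csv(
        outdir / "truth_tracts.csv", index=False
    )
    return outdir
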