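"""End-to-end orchestration: grids -> SUHI -> groups -> tables and densities.

A run consumes a *bundle* directory (the layout written by
:func:`heat_equity.synthetic.write_panel`, or assembled by hand from real
rasters and tables) and emits delimited-text tables mirroring the study's
summary products: population-weighted means, clustered difference-in-means,
per-city tests and tallies, Kolm-Pollak indices, and kernel densities of
city means.  CSV numbers are formatted at 6 significant digits so reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, exposure, inequality, raster_io, suhi
from .demographics import (
    DemographicTable,
    build_groups,
    load_schemes,
    match_tracts,
    read_demographics_csv,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

DEFAULT_COMPARISONS: dict[str, list[tuple[str, str]]] = {
    "race": [("people_of_color", "nh_white"), ("hispanic", "nh_white"),
             ("nh_black", "nh_white")],
    "income": [("below_poverty", "above_2x_poverty")],
    "age": [("under_5", "over_65")],
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    bundle: Path
    out: Path
    kappa_list: tuple[float, ...] = (inequality.DEFAULT_KAPPA,)
    threshold: float = 2.0
    include_water: bool = False
    comparisons: dict = field(default_factory=lambda: dict(DEFAULT_COMPARISONS))
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        comparisons = {
            scheme: [tuple(pair) for pair in pairs]
            for scheme, pairs in raw.get("comparisons", DEFAULT_COMPARISONS).items()
        }
        return cls(
            bundle=Path(raw["bundle"]),
            out=Path(raw["out"]),
            kappa_list=tuple(raw.get("kappa_list", [inequality.DEFAULT_KAPPA])),
            threshold=float(raw.get("threshold", 2.0)),
            include_water=bool(raw.get("include_water", False)),
            comparisons=comparisons,
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def echo(self) -> dict:
        return {
            "bundle": str(self.bundle), "out": str(self.out),
            "kappa_list": list(self.kappa_list), "threshold": self.threshold,
            "include_water": self.include_water,
            "comparisons": {k: [list(p) for p in v] for k, v in self.comparisons.items()},
            "seed": self.seed, "log_level": self.log_level,
        }


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


def _city_dirs(bundle: Path) -> list[Path]:
    cities = sorted((bundle / "cities").iterdir()) if (bundle / "cities").is_dir() else []
    return [d for d in cities if d.is_dir()]


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Check grid alignment, tract-join coverage and partition invariants."""
    report = ValidationReport()
    bundle = Path(config.bundle)
    for name in ("demographics.csv", "climate_zones.csv", "scheme.yaml"):
        if not (bundle / name).exists():
            report.problems.append(f"missing bundle file: {name}")
    city_dirs = _city_dirs(bundle)
    if not city_dirs:
        report.problems.append("bundle has no cities/ directory with city rasters")
    if not report.ok:
        return report

    zone_tracts: set[str] = set()
    for cdir in city_dirs:
        try:
            lst = raster_io.read_temperature(cdir / "lst.tif")
            lc = raster_io.read_landcover(cdir / "landcover.tif")
            zones = raster_io.read_zonemap(cdir)
        except Exception as exc:  # unreadable raster is a hard violation
            report.problems.append(f"{cdir.name}: unreadable rasters ({exc})")
            continue
        if not (lst.shape == lc.shape == zones.shape):
            report.problems.append(
                f"{cdir.name}: grid shapes differ "
                f"(lst {lst.shape}, landcover {lc.shape}, zones {zones.shape})"
            )
        zone_tracts.update(zones.tract_names.values())

    demo_raw = read_demographics_csv(bundle / "demographics.csv")
    if demo_raw["tract_id"].duplicated().any():
        dupes = demo_raw.loc[demo_raw["tract_id"].duplicated(), "tract_id"]
        report.problems.append(f"duplicate tract_ids in demographics: {sorted(dupes)[:5]}")
    demo_tracts = set(demo_raw["tract_id"].astype(str))
    missing = sorted(zone_tracts - demo_tracts)
    if missing:
        report.problems.append(
            f"demographics missing {len(missing)} tract(s): {missing}"
        )
    extra = sorted(demo_tracts - zone_tracts)
    if extra:
        report.warnings.append(f"demographics has {len(extra)} tract(s) absent from zones")

    try:
        schemes = load_schemes(bundle / "scheme.yaml")
        if not demo_raw["tract_id"].duplicated().any():
            for scheme in schemes.values():
                build_groups(demo_raw, scheme)
    except Exception as exc:
        report.problems.append(f"grouping schemes fail on demographics: {exc}")
    return report


def _read_zone_labels(bundle: Path) -> dict[str, str]:
    zl = pd.read_csv(bundle / "climate_zones.csv", dtype=str)
    return dict(zip(zl["urbanized_area_id"], zl["zone"]))


def _means_table(suhi_df, tables: dict[str, DemographicTable], schemes,
                 zone_labels) -> pd.DataFrame:
    zones = sorted(set(zone_labels.values()))
    rows = []
    for scheme_name in schemes:
        demo = tables[scheme_name]
        for group in demo.counts.columns:
            for scope, value in [("national", None)] + [("zone", z) for z in zones]:
                try:
                    s = exposure.weighted_group_mean(
                        suhi_df, demo, group, scope, value, zone_labels)
                except exposure.EmptyGroupError:
                    continue
                rows.append({"scheme": scheme_name, "group": group, "scope": scope,
                             "scope_value": value or "", "weighted_mean": s.weighted_mean,
                             "weighted_sd": s.weighted_sd, "total_weight": s.total_weight,
                             "n_tracts": s.n_tracts})
    return pd.DataFrame(rows)


def _diffs_table(suhi_df, tables, comparisons, schemes, zone_labels) -> pd.DataFrame:
    zones = sorted(set(zone_labels.values()))
    rows = []
    for scheme_name in schemes:
        for a, b in comparisons.get(scheme_name, []):
            demo = tables[scheme_name]
            for scope, value in [("national", None)] + [("zone", z) for z in zones]:
                try:
                    d = exposure.group_mean_difference(
                        suhi_df, demo, a, b, scope, value, zone_labels)
                except exposure.EmptyGroupError:
                    continue
                rows.append({"scheme": scheme_name, "group_a": a, "group_b": b,
                             "scope": scope, "scope_value": value or "",
                             "diff": d.diff, "se": d.se, "p_value": d.p_value,
                             "stars": d.stars, "n_clusters": d.n_clusters})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns a name -> path map of outputs.

    Any stage failure aborts with a stage-named diagnostic and removes the
    partial outputs written so far.
    """
    bundle, outdir = Path(config.bundle), Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, Path] = {}

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("heat_equity")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    written.append(log_path)

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        outputs[name] = path
        written.append(path)

    stage = "validate"
    try:
        logger.info("heat-equity %s on python %s", __version__, platform.python_version())
        logger.info("config: %s", config.echo())
        report = validate_inputs(config)
        for w in report.warnings:
            logger.warning("validation: %s", w)
        if not report.ok:
            raise ValidationError("; ".join(report.problems))

        stage = "suhi"
        records = []
        for cdir in _city_dirs(bundle):
            lst = raster_io.read_temperature(cdir / "lst.tif")
            lc = raster_io.read_landcover(cdir / "landcover.tif")
            zones = raster_io.read_zonemap(cdir)
            for ua in sorted(set(zones.ua_names.values())):
                records.extend(suhi.compute_city_suhi(
                    lc, lst, zones, ua, include_water=config.include_water))
        suhi_df = suhi.records_to_frame(records)
        logger.info("computed SUHI for %d tracts (include_water=%s)",
                    len(suhi_df), config.include_water)
        emit("suhi.csv", suhi_df)

        stage = "groups"
        schemes = load_schemes(bundle / "scheme.yaml")
        demo_raw = read_demographics_csv(bundle / "demographics.csv")
        tables = {name: build_groups(demo_raw, s) for name, s in schemes.items()}
        zone_labels = _read_zone_labels(bundle)
        _, only_suhi, only_demo = match_tracts(suhi_df, next(iter(tables.values())))
        if only_suhi or only_demo:
            logger.warning("unmatched tracts: %d suhi-only, %d demo-only",
                           len(only_suhi), len(only_demo))

        stage = "tables"
        main_schemes = [s for s in schemes if s != "age"]
        age_schemes = [s for s in schemes if s == "age"]
        emit("table1_means.csv", _means_table(suhi_df, tables, main_schemes, zone_labels))
        emit("table1_diffs.csv", _diffs_table(suhi_df, tables, config.comparisons,
                                              main_schemes, zone_labels))
        if age_schemes:
            age_means = _means_table(suhi_df, tables, age_schemes, zone_labels)
            age_diffs = _diffs_table(suhi_df, tables, config.comparisons,
                                     age_schemes, zone_labels)
            age_diffs = age_diffs.reindex(columns=age_means.columns.union(
                age_diffs.columns, sort=False))
            emit("table3_age.csv", pd.concat([age_means, age_diffs], ignore_index=True))

        stage = "city_tests"
        cities = sorted(suhi_df["urbanized_area_id"].unique())
        test_rows, tally_frames = [], []
        density_rows = []
        for scheme_name, pairs in config.comparisons.items():
            if scheme_name not in tables:
                continue
            demo = tables[scheme_name]
            for a, b in pairs:
                tests = [exposure.city_level_test(suhi_df, demo, a, b, c) for c in cities]
                for t in tests:
                    test_rows.append({"scheme": scheme_name, "group_a": a, "group_b": b,
                                      "urbanized_area_id": t.scope_value, "diff": t.diff,
                                      "se": t.se, "p_value": t.p_value,
                                      "significant": t.significant,
                                      "comparable": t.comparable})
                tally = exposure.tally_city_comparisons(tests, zone_labels)
                tally.insert(0, "group_b", b)
                tally.insert(0, "group_a", a)
                tally.insert(0, "scheme", scheme_name)
                tally_frames.append(tally)
                for group in (a, b):
                    means = [exposure.weighted_group_mean(suhi_df, demo, group,
                                                          "city", c).weighted_mean
                             for c in cities if _has_group(suhi_df, demo, group, c)]
                    curve = exposure.exposure_density(means)
                    above = exposure.cities_above_threshold(means, config.threshold)
                    logger.info("%s/%s: %d of %d cities above %.3g degC",
                                scheme_name, group, above, len(means), config.threshold)
                    for gx, d, s in zip(curve.grid, curve.density, curve.scaled):
                        density_rows.append({"scheme": scheme_name, "group": group,
                                             "grid": gx, "density": d, "scaled": s,
                                             "bandwidth": curve.bandwidth,
                                             "n_cities": curve.n_cities})
        emit("city_tests.csv", pd.DataFrame(test_rows))
        emit("city_tallies.csv", pd.concat(tally_frames, ignore_index=True))
        emit("densities.csv", pd.DataFrame(density_rows).drop_duplicates(
            subset=["scheme", "group", "grid"]))

        stage = "kp"
        kp_rows = []
        for scheme_name, pairs in config.comparisons.items():
            if scheme_name not in tables:
                continue
            demo = tables[scheme_name]
            groups = sorted({g for pair in pairs for g in pair})
            for kappa in config.kappa_list:
                per_group = {}
                for group in groups:
                    idx = inequality.group_city_indices(suhi_df, demo, group, kappa)
                    per_group[group] = idx
                    for scope, value in ([("national", None)] +
                                         [("zone", z) for z in
                                          sorted(set(zone_labels.values()))]):
                        try:
                            m, sd, w = inequality.mean_city_index(
                                idx, zone_labels, scope, value)
                        except ValueError:
                            continue
                        kp_rows.append({"scheme": scheme_name, "group": group,
                                        "kappa": kappa, "scope": scope,
                                        "scope_value": value or "", "kind": "mean",
                                        "value": m, "sd_or_se": sd, "total_weight": w,
                                        "stars": ""})
                for a, b in pairs:
                    d = inequality.index_difference(per_group[a], per_group[b], a, b)
                    kp_rows.append({"scheme": scheme_name, "group": f"{a}-{b}",
                                    "kappa": kappa, "scope": "national",
                                    "scope_value": "", "kind": "diff", "value": d.diff,
                                    "sd_or_se": d.se, "total_weight": np.nan,
                                    "stars": d.stars})
        emit("table2_kp.csv", pd.DataFrame(kp_rows))
        logger.info("pipeline complete: %d outputs", len(outputs))
    except Exception as exc:
        for path in written:
            if path != log_path and path.exists():
                path.unlink()
        logger.error("aborted in stage %r: %s", stage, exc)
        if isinstance(exc, ValidationError):
            raise
        raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    outputs["run.log"] = log_path
    return outputs


def _has_group(suhi_df, demo, group, city) -> bool:
    joined, _, _ = match_tracts(suhi_df, demo)
    sub = joined[joined["urbanized_area_id"] == city]
    return bool(len(sub) and sub[group].sum() > 0)
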