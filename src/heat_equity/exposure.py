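"""Population-weighted exposure statistics and disparity inference.

The estimand throughout is the exposure of the average *person* in a group:
tract-level SUHI intensities weighted by the number of group members living
in each tract.  Group differences are estimated by weighted least squares of
SUHI on a group indicator over stacked (tract x group) observations, which
reproduces the difference of weighted means exactly; standard errors are
cluster-robust by urbanized area (t reference with G-1 degrees of freedom),
falling back to heteroskedasticity-robust errors when only one cluster is
available.  Per-city tests use heteroskedasticity-robust errors, since
tracts are the units within a single city and there is nothing to cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .demographics import DemographicTable, match_tracts

logger = logging.getLogger(__name__)


class EmptyGroupError(ValueError):
    def __init__(self, group: str, scope: str):
        super().__init__(f"group {group!r} has zero total weight at scope {scope}")
        self.group, self.scope = group, scope


def significance_stars(p: float) -> str:
    """Three-level scheme: * p<0.10, ** p<0.05, *** p<0.01."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.10 else ""


@dataclass(frozen=True)
class GroupExposureSummary:
    group: str
    scope: str               # "city" | "zone" | "national"
    scope_value: str | None
    weighted_mean: float     # degrees C
    weighted_sd: float       # degrees C
    total_weight: float      # persons
    n_tracts: int


@dataclass(frozen=True)
class MeanDifference:
    group_a: str
    group_b: str
    scope: str
    scope_value: str | None
    diff: float              # degrees C, mean(a) - mean(b)
    se: float                # degrees C
    p_value: float
    stars: str
    df: float
    n_clusters: int
    comparable: bool = True

    @property
    def significant(self) -> bool:
        return bool(self.comparable and self.p_value < 0.05)


def _scope_frame(
    joined: pd.DataFrame,
    scope: str,
    scope_value: str | None,
    zone_labels: dict[str, str] | None,
) -> pd.DataFrame:
    if scope == "national":
        return joined
    if scope == "city":
        return joined[joined["urbanized_area_id"] == scope_value]
    if scope == "zone":
        if zone_labels is None:
            raise ValueError("zone scope requires climate-zone labels")
        uas = {ua for ua, z in zone_labels.items() if z == scope_value}
        return joined[joined["urbanized_area_id"].isin(uas)]
    raise ValueError(f"unknown scope {scope!r}")


def weighted_group_mean(
    suhi: pd.DataFrame,
    demo: DemographicTable,
    group: str,
    scope: str = "national",
    scope_value: str | None = None,
    zone_labels: dict[str, str] | None = None,
    value_column: str = "suhi",
) -> GroupExposureSummary:
    """Population-weighted mean and SD of exposure for one group at a scope.

    Tracts with zero group count contribute zero weight (not dropped); the
    SD is the population form, sqrt of the weighted mean squared deviation.
    """
    joined, only_suhi, only_demo = match_tracts(suhi, demo)
    if only_suhi or only_demo:
        logger.warning("unmatched tract_ids excluded: %d suhi-only, %d demo-only",
                       len(only_suhi), len(only_demo))
    sub = _scope_frame(joined, scope, scope_value, zone_labels)
    w = sub[group].to_numpy(dtype=float)
    x = sub[value_column].to_numpy(dtype=float)
    total = w.sum()
    if sub.empty or total <= 0:
        raise EmptyGroupError(group, f"{scope}:{scope_value}")
    mean = float(np.dot(w, x) / total)
    var = float(np.dot(w, (x - mean) ** 2) / total)
    return GroupExposureSummary(group, scope, scope_value, mean,
                                float(np.sqrt(max(var, 0.0))), float(total), len(sub))


def _stack_observations(
    sub: pd.DataFrame, group_a: str, group_b: str, value_column: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack (tract x group) rows: y, indicator for group_a, weights, clusters."""
    ya = sub[value_column].to_numpy(dtype=float)
    wa = sub[group_a].to_numpy(dtype=float)
    wb = sub[group_b].to_numpy(dtype=float)
    cl = sub["urbanized_area_id"].to_numpy()
    y = np.concatenate([ya, ya])
    g = np.concatenate([np.ones_like(ya), np.zeros_like(ya)])
    w = np.concatenate([wa, wb])
    clusters = np.concatenate([cl, cl])
    keep = w > 0
    return y[keep], g[keep], w[keep], clusters[keep]


def _wls_difference(
    y: np.ndarray, g: np.ndarray, w: np.ndarray, clusters: np.ndarray | None
) -> tuple[float, float, float, float, int]:
    """Fit SUHI ~ group indicator by WLS; return (diff, se, p, df, n_clusters).

    With clusters: CR1 sandwich, t reference on G-1 df.  Without (or with a
    single cluster): HC1 robust errors on the residual df.
    """
    n_clusters = int(len(np.unique(clusters))) if clusters is not None else 0
    scale = max(1.0, float(np.abs(y).max()))
    if len(y) <= 2:
        # Saturated fit (one observation per group): exact difference, no
        # residual degrees of freedom for inference.
        mean_a = np.average(y[g == 1], weights=w[g == 1])
        mean_b = np.average(y[g == 0], weights=w[g == 0])
        diff = float(mean_a - mean_b)
        p = 1.0 if abs(diff) < 1e-12 * scale else 0.0
        return diff, 0.0, p, 0.0, n_clusters
    X = sm.add_constant(g)
    model = sm.WLS(y, X, weights=w)
    if clusters is not None and n_clusters >= 2:
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": pd.factorize(clusters)[0]},
                        use_t=True)
        df = float(n_clusters - 1)
    else:
        if clusters is not None:
            warnings.warn("single cluster: falling back to heteroskedasticity-"
                          "robust standard errors", stacklevel=3)
        res = model.fit(cov_type="HC1", use_t=True)
        df = float(res.df_resid)
    diff = float(res.params[1])
    se = float(res.bse[1])
    if se < 1e-12 * scale or not np.isfinite(se):
        # Degenerate exact fit (or float dust on both estimates): zero
        # residual variance carries no evidence against a zero difference.
        p = 1.0 if abs(diff) < 1e-9 * scale else 0.0
    else:
        p = float(2 * sps.t.sf(abs(diff) / se, df))
    return diff, se, p, df, n_clusters


def group_mean_difference(
    suhi: pd.DataFrame,
    demo: DemographicTable,
    group_a: str,
    group_b: str,
    scope: str = "national",
    scope_value: str | None = None,
    zone_labels: dict[str, str] | None = None,
    value_column: str = "suhi",
) -> MeanDifference:
    """Difference of population-weighted group means with cluster-robust SE.

    The point estimate equals ``weighted_group_mean(a) - weighted_group_mean(b)``
    exactly; inference clusters by urbanized area.
    """
    joined, _, _ = match_tracts(suhi, demo)
    sub = _scope_frame(joined, scope, scope_value, zone_labels)
    for grp in (group_a, group_b):
        if sub.empty or sub[grp].sum() <= 0:
            raise EmptyGroupError(grp, f"{scope}:{scope_value}")
    y, g, w, clusters = _stack_observations(sub, group_a, group_b, value_column)
    diff, se, p, df, n_clusters = _wls_difference(y, g, w, clusters)
    return MeanDifference(group_a, group_b, scope, scope_value, diff, se, p,
                          significance_stars(p), df, n_clusters)


def city_level_test(
    suhi: pd.DataFrame,
    demo: DemographicTable,
    group_a: str,
    group_b: str,
    city: str,
    value_column: str = "suhi",
) -> MeanDifference:
    """Within-city weighted difference with heteroskedasticity-robust SE.

    A city where either group is absent gets a non-comparable marker rather
    than an exception, so panel-wide tallies can track their denominators.
    """
    joined, _, _ = match_tracts(suhi, demo)
    sub = joined[joined["urbanized_area_id"] == city]
    if sub.empty or sub[group_a].sum() <= 0 or sub[group_b].sum() <= 0:
        return MeanDifference(group_a, group_b, "city", city, np.nan, np.nan,
                              np.nan, "", np.nan, 0, comparable=False)
    y, g, w, _ = _stack_observations(sub, group_a, group_b, value_column)
    diff, se, p, df, _ = _wls_difference(y, g, w, clusters=None)
    return MeanDifference(group_a, group_b, "city", city, diff, se, p,
                          significance_stars(p), df, 0)


def tally_city_comparisons(
    city_tests: list[MeanDifference],
    zone_labels: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Counts/proportions of cities where each group fares worse, by zone.

    Non-comparable cities are excluded from the denominator.  "Worse" for
    group a means diff > 0 (a's weighted mean exposure is higher);
    significance is judged at ``alpha``.
    """
    comparable = [t for t in city_tests if t.comparable]
    if not comparable:
        raise ValueError("no comparable cities to tally")

    def _row(label: str, tests: list[MeanDifference]) -> dict:
        n = len(tests)
        a_worse = sum(t.diff > 0 for t in tests)
        b_worse = sum(t.diff < 0 for t in tests)
        a_sig = sum(t.diff > 0 and t.p_value < alpha for t in tests)
        b_sig = sum(t.diff < 0 and t.p_value < alpha for t in tests)
        return {
            "scope": label, "n_cities": n,
            "n_a_worse": a_worse, "prop_a_worse": a_worse / n if n else np.nan,
            "n_a_worse_sig": a_sig, "prop_a_worse_sig": a_sig / n if n else np.nan,
            "n_b_worse": b_worse, "prop_b_worse": b_worse / n if n else np.nan,
            "n_b_worse_sig": b_sig, "prop_b_worse_sig": b_sig / n if n else np.nan,
        }

    rows = [_row("national", comparable)]
    if zone_labels:
        for zone in sorted(set(zone_labels.values())):
            in_zone = [t for t in comparable if zone_labels.get(t.scope_value) == zone]
            if in_zone:
                rows.append(_row(zone, in_zone))
    return pd.DataFrame(rows)


def cities_above_threshold(city_means, threshold: float) -> int:
    """Number of cities with group mean exposure strictly above threshold."""
    means = np.asarray(list(city_means), dtype=float)
    return int((means > threshold).sum())


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian-kernel density of city-level means on a fixed grid.

    ``density`` integrates to ~1 on the grid; ``scaled`` is rescaled so the
    area equals ``n_cities`` (the convention used for cross-group overlays).
    """

    grid: np.ndarray
    density: np.ndarray
    scaled: np.ndarray
    bandwidth: float
    n_cities: int


def exposure_density(
    city_means,
    n_cities: int | None = None,
    n_grid: int = 512,
    grid: np.ndarray | None = None,
) -> DensityCurve:
    """Silverman-bandwidth Gaussian KDE over city means.

    The default evaluation grid spans the data range plus 3 bandwidths on
    each side; pass ``grid`` to evaluate elsewhere.  Identical means
    degenerate to a spike (warning emitted).
    """
    x = np.asarray(list(city_means), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two city means for a density")
    n_cities = int(n_cities if n_cities is not None else x.size)
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("all city means identical: density degenerates to a spike")
        bw = max(abs(x[0]), 1.0) * 1e-6
    else:
        kde = sps.gaussian_kde(x, bw_method="silverman")
        bw = float(kde.factor * sd)
    if grid is None:
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    # Evaluate the Gaussian mixture directly so the spike fallback shares a path.
    z = (grid[:, None] - x[None, :]) / bw
    density = np.exp(-0.5 * z ** 2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))
    return DensityCurve(grid, density, density * n_cities, bw, n_cities)
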