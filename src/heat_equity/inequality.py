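"""Kolm-Pollak inequality index and equally-distributed-equivalent exposure.

For an exposure distribution x with weights w (persons per tract; everyone
in a tract shares its exposure), the weighted Kolm-Pollak index at aversion
parameter kappa < 0 (units 1/degC, so kappa*(xbar - x_n) is dimensionless) is

    I(x) = -(1/kappa) * ln( sum_n (w_n/W) * exp(kappa * (xbar - x_n)) )

with xbar the weighted mean and W the total weight; the nominal-count form
is the special case w_n = 1/N.  The equally distributed equivalent is
EDE = xbar + I(x): the uniform exposure an impartial agent would accept in
place of the actual unequal distribution.  For a "bad" like heat exposure
(kappa < 0), I >= 0 with equality iff the distribution is perfectly equal,
I is translation invariant, and EDE >= xbar.  More negative kappa penalizes
above-mean exposures more strongly.  The sum is evaluated through a
max-shifted log-sum-exp so extreme exposures cannot overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .demographics import DemographicTable, match_tracts
from .exposure import MeanDifference, _wls_difference, significance_stars

logger = logging.getLogger(__name__)

#: Default aversion parameter, labeled "moderate"; configurable everywhere
#: and always echoed in outputs.
DEFAULT_KAPPA = -0.5


@dataclass
class ExposureDistribution:
    """Weighted exposure distribution (exposures in degC, weights in persons)."""

    x: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if self.x.shape != self.w.shape:
            raise ValueError("exposures and weights differ in length")
        if not np.isfinite(self.x).all():
            raise ValueError("exposures must be finite")
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")
        if self.total_weight <= 0:
            raise ValueError("empty distribution: total weight is zero")

    @property
    def total_weight(self) -> float:
        return float(self.w.sum())

    @property
    def mean(self) -> float:
        return float(np.dot(self.w, self.x) / self.total_weight)

    @property
    def variance(self) -> float:
        m = self.mean
        return float(np.dot(self.w, (self.x - m) ** 2) / self.total_weight)


@dataclass(frozen=True)
class KPResult:
    kappa: float   # 1/degC, < 0
    index: float   # degC, >= 0
    ede: float     # degC, mean + index
    mean: float    # degC
    total_weight: float


def kp_index(dist: ExposureDistribution, kappa: float = DEFAULT_KAPPA) -> KPResult:
    """Weighted Kolm-Pollak index and EDE at one aversion parameter."""
    if not (np.isfinite(kappa) and kappa < 0):
        raise ValueError(f"kappa must be finite and < 0, got {kappa}")
    mean = dist.mean
    pos = dist.w > 0
    logw = np.log(dist.w[pos] / dist.total_weight)
    index = float(-logsumexp(kappa * (mean - dist.x[pos]) + logw) / kappa)
    # Jensen guarantees index >= 0, = 0 iff perfectly equal; clear float dust
    # (|index| below 1e-12 degC is summation noise, not inequality).
    if abs(index) < 1e-12 * max(1.0, abs(mean)):
        index = 0.0
    return KPResult(float(kappa), index, mean + index, mean, dist.total_weight)


def kp_sweep(dist: ExposureDistribution, kappas) -> list[KPResult]:
    """Index/EDE over a list of aversion parameters (each < 0)."""
    return [kp_index(dist, k) for k in kappas]


def group_city_indices(
    suhi: pd.DataFrame,
    demo: DemographicTable,
    group: str,
    kappa: float = DEFAULT_KAPPA,
    value_column: str = "suhi",
) -> pd.DataFrame:
    """Per-city KP index of one group's tract-level exposure distribution.

    Weights are the group's person counts per tract.  Cities where the group
    is absent are excluded with a logged note.  Columns: urbanized_area_id,
    kappa, index, ede, mean, total_weight, n_tracts.
    """
    joined, _, _ = match_tracts(suhi, demo)
    rows = []
    for city, sub in joined.groupby("urbanized_area_id", sort=True):
        w = sub[group].to_numpy(dtype=float)
        if w.sum() <= 0:
            logger.info("group %s absent from city %s: excluded from KP table", group, city)
            continue
        res = kp_index(ExposureDistribution(sub[value_column].to_numpy(dtype=float), w), kappa)
        rows.append({"urbanized_area_id": city, "kappa": res.kappa, "index": res.index,
                     "ede": res.ede, "mean": res.mean, "total_weight": res.total_weight,
                     "n_tracts": len(sub)})
    return pd.DataFrame(rows)


def mean_city_index(
    city_indices: pd.DataFrame,
    zone_labels: dict[str, str] | None = None,
    scope: str = "national",
    scope_value: str | None = None,
) -> tuple[float, float, float]:
    """Population-weighted mean (and SD, total weight) of per-city indices.

    Cities are weighted by the group's population in each city.
    """
    sub = city_indices
    if scope == "zone":
        if zone_labels is None:
            raise ValueError("zone scope requires climate-zone labels")
        uas = {ua for ua, z in zone_labels.items() if z == scope_value}
        sub = sub[sub["urbanized_area_id"].isin(uas)]
    if sub.empty:
        raise ValueError(f"no cities at scope {scope}:{scope_value}")
    w = sub["total_weight"].to_numpy()
    v = sub["index"].to_numpy()
    mean = float(np.dot(w, v) / w.sum())
    sd = float(np.sqrt(max(np.dot(w, (v - mean) ** 2) / w.sum(), 0.0)))
    return mean, sd, float(w.sum())


def index_difference(
    indices_a: pd.DataFrame,
    indices_b: pd.DataFrame,
    group_a: str = "a",
    group_b: str = "b",
    weighted: bool = True,
) -> MeanDifference:
    """Difference in population-weighted mean city indices, robust SE.

    Cities (not tracts) are the units; stacked city x group observations are
    regressed on a group indicator by WLS with city group populations as
    weights (or equal weights), with heteroskedasticity-robust errors.
    """
    merged = indices_a.merge(indices_b, on="urbanized_area_id", suffixes=("_a", "_b"))
    if len(merged) < 2:
        raise ValueError("need >= 2 cities with both groups for index inference")
    y = np.concatenate([merged["index_a"], merged["index_b"]])
    g = np.concatenate([np.ones(len(merged)), np.zeros(len(merged))])
    if weighted:
        w = np.concatenate([merged["total_weight_a"], merged["total_weight_b"]])
    else:
        w = np.ones_like(y)
    diff, se, p, df, _ = _wls_difference(y, g, w, clusters=None)
    return MeanDifference(group_a, group_b, "national", None, diff, se, p,
                          significance_stars(p), df, 0)
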