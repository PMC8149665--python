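"""Demographic group construction from tract-level count tables.

Raw inputs are delimited-text tables with one row per census tract (tract
identifiers kept as strings so leading zeros in 11-digit FIPS codes
survive).  A *grouping scheme* declares how analysis groups derive from raw
source columns by addition/subtraction — e.g. people of color as the total
population minus non-Hispanic whites — and which groups partition the
scheme's total.  Schemes are declared in YAML (see :data:`DEFAULT_SCHEMES`
for the shape) so the arithmetic is data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Grouping schemes mirroring the ACS-derived categories used in the study:
#: race/ethnicity (with the people-of-color complement), poverty-ratio
#: income bands, and the under-5 / over-65 age bands.  The age-by-race quirk
#: (Black including Hispanic Black) appears as an optional derived group.
DEFAULT_SCHEMES: dict = {
    "race": {
        "total": "total_pop",
        "groups": {
            "hispanic": {"add": ["hispanic"]},
            "nh_white": {"add": ["nh_white"]},
            "nh_black": {"add": ["nh_black"]},
            "nh_other": {"add": ["nh_other"]},
            "people_of_color": {"add": ["total_pop"], "subtract": ["nh_white"]},
        },
        "partitions": [["hispanic", "nh_white", "nh_black", "nh_other"]],
    },
    "income": {
        "total": "total_pop",
        "groups": {
            "below_poverty": {"add": ["below_poverty"]},
            "pov_1to2": {"add": ["pov_1to2"]},
            "above_2x_poverty": {"add": ["above_2x_poverty"]},
        },
        "partitions": [["below_poverty", "pov_1to2", "above_2x_poverty"]],
    },
    "age": {
        "total": "total_pop",
        "groups": {
            "under_5": {"add": ["under_5"]},
            "over_65": {"add": ["over_65"]},
        },
        "partitions": [],
    },
}


@dataclass(frozen=True)
class GroupDef:
    name: str
    add: tuple[str, ...]
    subtract: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupingScheme:
    """Named scheme: derived groups plus partition constraints on the total."""

    name: str
    total: str
    groups: tuple[GroupDef, ...]
    partitions: tuple[tuple[str, ...], ...] = ()

    @classmethod
    def from_dict(cls, name: str, spec: dict) -> "GroupingScheme":
        groups = tuple(
            GroupDef(g, tuple(d.get("add", ())), tuple(d.get("subtract", ())))
            for g, d in spec["groups"].items()
        )
        partitions = tuple(tuple(p) for p in spec.get("partitions", ()))
        return cls(name, spec["total"], groups, partitions)

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]


def load_schemes(path) -> dict[str, GroupingScheme]:
    spec = yaml.safe_load(Path(path).read_text())
    return {name: GroupingScheme.from_dict(name, s) for name, s in spec["schemes"].items()}


def write_default_schemes(path) -> None:
    Path(path).write_text(yaml.safe_dump({"schemes": DEFAULT_SCHEMES}, sort_keys=False))


def default_schemes() -> dict[str, GroupingScheme]:
    return {name: GroupingScheme.from_dict(name, s) for name, s in DEFAULT_SCHEMES.items()}


@dataclass
class DemographicTable:
    """Per-tract person counts for the groups of one scheme.

    ``counts`` is indexed by tract_id (string) and has one column per group
    plus the scheme's total column.
    """

    counts: pd.DataFrame
    scheme: str
    total_column: str = "total_pop"
    provenance: dict = field(default_factory=dict)

    def weights(self, group: str) -> pd.Series:
        if group not in self.counts.columns:
            raise KeyError(f"group {group!r} not in scheme {self.scheme!r}")
        return self.counts[group]


def build_groups(
    raw_counts: pd.DataFrame,
    scheme: GroupingScheme,
    tract_id_column: str = "tract_id",
    partition_tol: float = 1.0,
) -> DemographicTable:
    """Derive a scheme's groups from a raw tract count table.

    Counts must be nonnegative; a derived group that comes out negative for
    any tract is a hard error naming that tract.  Partition constraints are
    checked to within ``partition_tol`` persons per tract (source rounding).
    """
    raw = raw_counts.copy()
    raw[tract_id_column] = raw[tract_id_column].astype(str)
    if raw[tract_id_column].duplicated().any():
        dupes = raw.loc[raw[tract_id_column].duplicated(), tract_id_column].tolist()
        raise ValueError(f"duplicate tract_ids in demographic table: {dupes[:5]}")
    raw = raw.set_index(tract_id_column)

    needed = {scheme.total} | {c for g in scheme.groups for c in (*g.add, *g.subtract)}
    missing = sorted(needed - set(raw.columns))
    if missing:
        raise KeyError(f"scheme {scheme.name!r} needs missing source columns: {missing}")
    for col in sorted(needed):
        if (raw[col] < 0).any():
            bad = raw.index[raw[col] < 0][0]
            raise ValueError(f"negative count in column {col!r} at tract {bad}")

    out = pd.DataFrame(index=raw.index)
    out[scheme.total] = raw[scheme.total].astype(float)
    for g in scheme.groups:
        vals = sum(raw[c].astype(float) for c in g.add)
        for c in g.subtract:
            vals = vals - raw[c].astype(float)
        if (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise ValueError(f"derived group {g.name!r} negative at tract {bad}")
        out[g.name] = vals

    for part in scheme.partitions:
        gap = (out[list(part)].sum(axis=1) - out[scheme.total]).abs()
        if (gap > partition_tol).any():
            bad = gap.index[gap > partition_tol][0]
            raise ValueError(
                f"partition {part} does not sum to {scheme.total!r} at tract {bad} "
                f"(off by {gap.loc[bad]:.3g})"
            )

    provenance = {
        "scheme": scheme.name,
        "groups": {g.name: {"add": list(g.add), "subtract": list(g.subtract)}
                   for g in scheme.groups},
    }
    return DemographicTable(out, scheme.name, scheme.total, provenance)


def read_demographics_csv(path) -> pd.DataFrame:
    """Read a raw demographic CSV, preserving tract_id as text."""
    return pd.read_csv(path, dtype={"tract_id": str})


def match_tracts(
    suhi: pd.DataFrame, demo: DemographicTable
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Inner-join SUHI records with demographics on tract_id.

    Returns (joined frame, suhi-only ids, demo-only ids); unmatched ids are
    excluded from both sides and reported for logging.
    """
    suhi_ids = set(suhi["tract_id"])
    demo_ids = set(demo.counts.index)
    only_suhi = sorted(suhi_ids - demo_ids)
    only_demo = sorted(demo_ids - suhi_ids)
    joined = suhi.merge(demo.counts, left_on="tract_id", right_index=True, how="inner")
    return joined, only_suhi, only_demo
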