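"""Tract-level surface urban heat island (SUHI) intensity.

The simplified urban extent method defines the SUHI intensity of an urban
census tract t as

    SUHI_t = LST_t - LST_r

where LST_t is the tract's mean land surface temperature over pixels inside
its urbanized area, and LST_r is the mean LST of the rural reference: the
nonurban, nonwater land cover pixels within the tract's urbanized area.

By default the tract-side mean also excludes water pixels (mirroring the
rural-side nonwater rule); pass ``include_water=True`` to average every
non-missing pixel in the tract's urbanized-area portion instead.  Missing
LST cells are excluded from both sides; a tract or reference with no valid
cells is an explicit skip/error, never a silent NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import (
    NONURBAN,
    WATER,
    LandCoverGrid,
    TemperatureGrid,
    ZoneMap,
    check_aligned,
)

logger = logging.getLogger(__name__)

SUHI_COLUMNS = ["tract_id", "urbanized_area_id", "lst_t", "lst_r", "suhi", "n_cells"]


class NoRuralReferenceError(ValueError):
    """No nonurban, nonwater pixel with valid LST exists in the urbanized area."""

    def __init__(self, ua_id: str):
        super().__init__(f"no rural reference: urbanized area {ua_id!r} has no "
                         f"nonurban, nonwater cell with non-missing LST")
        self.ua_id = ua_id


class EmptyTractError(ValueError):
    """A tract has no qualifying pixel with valid LST inside its urbanized area."""

    def __init__(self, tract_id: str):
        super().__init__(f"tract {tract_id!r} has no qualifying cell with non-missing LST")
        self.tract_id = tract_id


@dataclass(frozen=True)
class RuralReference:
    urbanized_area_id: str
    lst_r: float  # degrees C
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1 or not np.isfinite(self.lst_r):
            raise ValueError("invalid rural reference")


@dataclass(frozen=True)
class TractSuhiRecord:
    tract_id: str
    urbanized_area_id: str
    lst_t: float  # degrees C
    lst_r: float  # degrees C
    suhi: float   # degrees C
    n_cells: int


def compute_rural_reference(
    lc: LandCoverGrid,
    lst: TemperatureGrid,
    zones: ZoneMap,
    ua: str,
) -> RuralReference:
    """Mean LST over nonurban (nonwater) cells of an urbanized area."""
    check_aligned(lc, lst, zones)
    code = zones.ua_code(ua)
    mask = (zones.ua == code) & (lc.labels == NONURBAN) & ~np.isnan(lst.values)
    n = int(mask.sum())
    if n == 0:
        raise NoRuralReferenceError(ua)
    return RuralReference(ua, float(lst.values[mask].mean()), n)


def compute_tract_suhi(
    lc: LandCoverGrid,
    lst: TemperatureGrid,
    zones: ZoneMap,
    ref: RuralReference,
    tract: str,
    include_water: bool = False,
) -> TractSuhiRecord:
    """SUHI intensity of one tract relative to its urbanized area's reference.

    Raises :class:`EmptyTractError` when the tract has no qualifying cell;
    callers batching over tracts should catch, log and skip.
    """
    check_aligned(lc, lst, zones)
    if zones.ua_of_tract(tract) != ref.urbanized_area_id:
        raise ValueError(
            f"tract {tract!r} does not belong to urbanized area {ref.urbanized_area_id!r}"
        )
    tcode = zones.tract_code(tract)
    ucode = zones.ua_code(ref.urbanized_area_id)
    mask = (zones.tract == tcode) & (zones.ua == ucode) & ~np.isnan(lst.values)
    if not include_water:
        mask &= lc.labels != WATER
    n = int(mask.sum())
    if n == 0:
        raise EmptyTractError(tract)
    lst_t = float(lst.values[mask].mean())
    return TractSuhiRecord(tract, ref.urbanized_area_id, lst_t, ref.lst_r,
                           lst_t - ref.lst_r, n)


def compute_city_suhi(
    lc: LandCoverGrid,
    lst: TemperatureGrid,
    zones: ZoneMap,
    ua: str,
    include_water: bool = False,
) -> list[TractSuhiRecord]:
    """SUHI records for every tract of one urbanized area.

    The rural reference is computed once and shared.  Tracts with no
    qualifying cell are skipped with a logged warning.
    """
    ref = compute_rural_reference(lc, lst, zones, ua)
    records: list[TractSuhiRecord] = []
    for tract in zones.tracts_of(ua):
        try:
            records.append(compute_tract_suhi(lc, lst, zones, ref, tract,
                                              include_water=include_water))
        except EmptyTractError:
            logger.warning("skipping tract %s in %s: no qualifying LST cell", tract, ua)
    return records


def records_to_frame(records: list[TractSuhiRecord]) -> pd.DataFrame:
    """Tabulate SUHI records with tract_id/urbanized_area_id as strings."""
    frame = pd.DataFrame([r.__dict__ for r in records], columns=SUHI_COLUMNS)
    return frame.astype({"tract_id": str, "urbanized_area_id": str})


def write_suhi_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_suhi_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tract_id": str, "urbanized_area_id": str})
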