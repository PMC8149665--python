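"""Gridded inputs for SUHI analysis: land cover, land surface temperature, zones.

All grids are row-major 2-D arrays with the origin at the top-left corner
and a square cell size.  A cell belongs to a zone iff its *center* falls
inside the zone polygon (half-open convention); rasterized zone maps carry
integer codes with ``0`` meaning "not assigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Land-cover label codes (match the GeoTIFF band encoding).
URBAN = 1
NONURBAN = 2
WATER = 3

_VALID_LABELS = frozenset({URBAN, NONURBAN, WATER})


class GridAlignmentError(ValueError):
    """Raised when paired grids do not share shape/georeference."""


@dataclass(frozen=True)
class Georeference:
    """Affine placement of a north-up grid: top-left corner and cell size."""

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates, each shaped like the grid."""
        nrow, ncol = shape
        xs = self.origin_x + (np.arange(ncol) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(nrow) + 0.5) * self.cell_size
        return np.broadcast_to(xs, (nrow, ncol)), np.broadcast_to(ys[:, None], (nrow, ncol))


@dataclass
class LandCoverGrid:
    """Categorical land cover: URBAN (1), NONURBAN (2), WATER (3)."""

    labels: np.ndarray
    georef: Georeference = field(default_factory=Georeference)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("land cover grid must be 2-D")
        bad = ~np.isin(self.labels, list(_VALID_LABELS))
        if bad.any():
            raise ValueError(
                f"land cover contains {int(bad.sum())} cells outside "
                f"{{URBAN=1, NONURBAN=2, WATER=3}}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class TemperatureGrid:
    """Land surface temperature in degrees Celsius; NaN marks missing cells."""

    values: np.ndarray
    georef: Georeference = field(default_factory=Georeference)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("temperature grid must be 2-D")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("temperature grid contains non-finite, non-NaN values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ZoneMap:
    """Per-cell assignment to an urbanized area and (optionally) a census tract.

    ``ua`` and ``tract`` are integer code grids (0 = unassigned); the code
    dictionaries map codes to external string identifiers.  Every cell with a
    tract code must carry a UA code, and each tract belongs to exactly one UA.
    """

    ua: np.ndarray
    tract: np.ndarray
    ua_names: dict[int, str]
    tract_names: dict[int, str]

    def __post_init__(self) -> None:
        self.ua = np.asarray(self.ua, dtype=np.int64)
        self.tract = np.asarray(self.tract, dtype=np.int64)
        if self.ua.shape != self.tract.shape:
            raise GridAlignmentError("UA and tract zone grids differ in shape")
        if ((self.tract > 0) & (self.ua == 0)).any():
            raise ValueError("found cells with a tract but no urbanized area")
        mask = self.tract > 0
        pairs = np.unique(
            np.stack([self.tract[mask].ravel(), self.ua[mask].ravel()]), axis=1
        )
        tract_codes, counts = np.unique(pairs[0], return_counts=True)
        if (counts > 1).any():
            bad = int(tract_codes[counts > 1][0])
            raise ValueError(f"tract code {bad} spans multiple urbanized areas")
        self._tract_to_ua: dict[int, int] = {
            int(t): int(u) for t, u in zip(pairs[0], pairs[1])
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.ua.shape

    def ua_code(self, ua_id: str) -> int:
        for code, name in self.ua_names.items():
            if name == ua_id:
                return code
        raise KeyError(f"urbanized area {ua_id!r} not present in zone map")

    def tract_code(self, tract_id: str) -> int:
        for code, name in self.tract_names.items():
            if name == tract_id:
                return code
        raise KeyError(f"tract {tract_id!r} not present in zone map")

    def tracts_of(self, ua_id: str) -> list[str]:
        """Tract identifiers belonging to a UA, in code order."""
        ua_code = self.ua_code(ua_id)
        codes = sorted(t for t, u in self._tract_to_ua.items() if u == ua_code)
        return [self.tract_names[c] for c in codes]

    def ua_of_tract(self, tract_id: str) -> str:
        return self.ua_names[self._tract_to_ua[self.tract_code(tract_id)]]


def check_aligned(*grids) -> None:
    """Require that all grids share one shape (and georeference when present)."""
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise GridAlignmentError(f"grids are not aligned: shapes {sorted(shapes)}")
    refs = {g.georef for g in grids if getattr(g, "georef", None) is not None}
    if len(refs) > 1:
        raise GridAlignmentError("grids are not aligned: differing georeferences")
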