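"""Data model for dated categorical land-cover map time-series.

A :class:`LandCoverMap` is one dated grid of category codes; a
:class:`ClassifiedStack` is an ordered, co-registered sequence of such maps
sharing a common permanent water mask. Time differences are expressed in
decimal years, ``days / 365.25``, because acquisition dates are day-resolved
and all rates are per-year.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .codes import GRID_DTYPE, MF, NODATA, WATER, validate_codes

DAYS_PER_YEAR = 365.25


def parse_date(value: int | str | _dt.date) -> _dt.date:
    """Parse a ``yyyymmdd`` integer/string (or pass through a date)."""
    if isinstance(value, _dt.date):
        return value
    s = str(value)
    if len(s) != 8 or not s.isdigit():
        raise ValueError(f"date {value!r} is not in yyyymmdd format")
    return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))


def format_date(date: _dt.date) -> str:
    return f"{date.year:04d}{date.month:02d}{date.day:02d}"


def decimal_years(d1: _dt.date, d2: _dt.date) -> float:
    """Signed gap ``d1 -> d2`` in decimal years (day count / 365.25)."""
    return (d2 - d1).days / DAYS_PER_YEAR


def decimal_year(date: _dt.date) -> float:
    """Calendar date as a decimal year (for trend regressions)."""
    start = _dt.date(date.year, 1, 1)
    return date.year + (date - start).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class LandCoverMap:
    """One dated categorical grid with a per-pixel area in hectares."""

    grid: np.ndarray
    date: _dt.date
    pixel_area_ha: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=GRID_DTYPE)
        if grid.ndim != 2 or min(grid.shape) < 1:
            raise ValueError(f"grid must be 2-D with positive dimensions, got shape {grid.shape}")
        validate_codes(grid)
        if not self.pixel_area_ha > 0:
            raise ValueError("pixel_area_ha must be positive")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "date", parse_date(self.date))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def class_area_ha(self, code: int) -> float:
        return float(np.count_nonzero(self.grid == code)) * self.pixel_area_ha


class StackError(ValueError):
    """Raised when maps cannot be assembled into a valid stack."""


@dataclass(frozen=True)
class ClassifiedStack:
    """Ordered co-registered map time-series with a common water mask.

    Use :func:`build_stack` to construct one; the constructor assumes the
    invariants (sorted unique dates, shared shape/pixel area, identical
    WATER cells on every date) already hold.
    """

    maps: tuple[LandCoverMap, ...]
    water_mask: np.ndarray = field(repr=False)

    @property
    def dates(self) -> tuple[_dt.date, ...]:
        return tuple(m.date for m in self.maps)

    @property
    def times(self) -> np.ndarray:
        """Decimal years elapsed since the first date, one per map."""
        d0 = self.maps[0].date
        return np.array([decimal_years(d0, m.date) for m in self.maps])

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[0].shape

    @property
    def pixel_area_ha(self) -> float:
        return self.maps[0].pixel_area_ha

    @property
    def n_dates(self) -> int:
        return len(self.maps)

    def grids(self) -> np.ndarray:
        """All grids stacked to shape ``(n_dates, rows, cols)``."""
        return np.stack([m.grid for m in self.maps])

    def with_grids(self, grids: np.ndarray) -> "ClassifiedStack":
        """Same dates/areas/mask with replaced label grids."""
        maps = tuple(
            replace(m, grid=np.asarray(g, dtype=GRID_DTYPE))
            for m, g in zip(self.maps, grids)
        )
        return ClassifiedStack(maps=maps, water_mask=self.water_mask)


def build_stack(maps: list[LandCoverMap] | tuple[LandCoverMap, ...]) -> ClassifiedStack:
    """Validate and assemble maps into a :class:`ClassifiedStack`.

    Maps are sorted by date; the common water mask is the union of WATER
    cells over all dates and is imposed on every date, so open water is
    identical throughout the series.

    Raises
    ------
    StackError
        On empty input, fewer than two dates, duplicate dates, shape
        mismatch, or differing pixel areas.
    """
    if not maps:
        raise StackError("no maps supplied")
    if len(maps) < 2:
        raise StackError("a stack needs at least two dates")
    shape = maps[0].shape
    area = maps[0].pixel_area_ha
    for m in maps:
        if m.shape != shape:
            raise StackError(f"shape mismatch: {m.shape} vs {shape} (date {m.date})")
        if m.pixel_area_ha != area:
            raise StackError("pixel_area_ha differs between maps")
    ordered = sorted(maps, key=lambda m: m.date)
    dates = [m.date for m in ordered]
    if len(set(dates)) != len(dates):
        dupes = sorted({d for d in dates if dates.count(d) > 1})
        raise StackError(f"duplicate dates in manifest: {[format_date(d) for d in dupes]}")
    water = np.zeros(shape, dtype=bool)
    for m in ordered:
        water |= m.grid == WATER
    fixed = []
    for m in ordered:
        g = m.grid.copy()
        g[water] = WATER
        fixed.append(replace(m, grid=g))
    return ClassifiedStack(maps=tuple(fixed), water_mask=water)


def fill_cloud_gaps(stack: ClassifiedStack, mf_mask: np.ndarray) -> ClassifiedStack:
    """Fill cloud gaps over persistent mature forest.

    ``mf_mask`` is a boolean grid of cells known to be MF throughout the
    series (derived from the most recent cloud-free imagery). Every NODATA
    cell inside the mask becomes MF on that date; all other cells are left
    untouched.
    """
    mf_mask = np.asarray(mf_mask, dtype=bool)
    if mf_mask.shape != stack.shape:
        raise StackError(f"mf_mask shape {mf_mask.shape} does not match stack {stack.shape}")
    grids = stack.grids()
    fill = (grids == NODATA) & mf_mask[None, :, :]
    grids[fill] = MF
    return stack.with_grids(grids)
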