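"""Readers and writers: headered text grids, manifests, points, truth tables.

Map files are plain-text single-band categorical grids with a small header,
chosen for bit-exact round-trips of the fixed integer code table::

    # lulctraj grid v1
    date 19840617
    pixel_area_ha 0.09
    nrows 3
    ncols 4
    codes 0=WATER 1=MF 2=NF 3=SF 255=NODATA
    1 1 2 3
    ...

A stack manifest is a CSV with columns ``date,path`` (dates yyyymmdd).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import CODE_TO_LABEL, GRID_DTYPE, validate_codes
from .core import ClassifiedStack, LandCoverMap, build_stack, format_date, parse_date

GRID_MAGIC = "# lulctraj grid v1"


def write_map(path: str | os.PathLike, lc_map: LandCoverMap) -> None:
    path = Path(path)
    codes = " ".join(f"{k}={v}" for k, v in sorted(CODE_TO_LABEL.items()))
    header = (
        f"{GRID_MAGIC}\n"
        f"date {format_date(lc_map.date)}\n"
        f"pixel_area_ha {lc_map.pixel_area_ha!r}\n"
        f"nrows {lc_map.shape[0]}\n"
        f"ncols {lc_map.shape[1]}\n"
        f"codes {codes}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, lc_map.grid, fmt="%d")


def read_map(path: str | os.PathLike) -> LandCoverMap:
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != GRID_MAGIC:
            raise ValueError(f"{path}: not a lulctraj grid file (header {magic!r})")
        meta = {}
        for _ in range(5):
            key, _, value = fh.readline().strip().partition(" ")
            meta[key] = value
        grid = np.loadtxt(fh, dtype=np.int64)
    grid = np.atleast_2d(grid)
    if grid.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match header")
    validate_codes(grid)
    return LandCoverMap(
        grid=grid.astype(GRID_DTYPE),
        date=parse_date(meta["date"]),
        pixel_area_ha=float(meta["pixel_area_ha"]),
    )


def write_manifest(path: str | os.PathLike, rows: list[tuple[str, str]]) -> None:
    """Write a stack manifest CSV; rows are (yyyymmdd, map path)."""
    pd.DataFrame(rows, columns=["date", "path"]).to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"date": str, "path": str})
    if list(manifest.columns) != ["date", "path"]:
        raise ValueError(f"{path}: manifest must have columns date,path")
    parsed = [parse_date(d) for d in manifest["date"]]
    if len(set(parsed)) != len(parsed):
        raise ValueError(f"{path}: duplicate dates in manifest")
    manifest = manifest.assign(parsed_date=parsed).sort_values("parsed_date")
    return manifest.reset_index(drop=True)


def read_stack(manifest_path: str | os.PathLike) -> ClassifiedStack:
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    maps = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        lc = read_map(p)
        if format_date(lc.date) != row["date"]:
            raise ValueError(f"{p}: file date {format_date(lc.date)} != manifest {row['date']}")
        maps.append(lc)
    return build_stack(maps)


def write_stack(directory: str | os.PathLike, stack: ClassifiedStack, prefix: str = "map") -> Path:
    """Write all maps plus a manifest.csv into ``directory``; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in stack.maps:
        name = f"{prefix}_{format_date(m.date)}.txt"
        write_map(directory / name, m)
        rows.append((format_date(m.date), name))
    manifest = directory / "manifest.csv"
    write_manifest(manifest, rows)
    return manifest


def write_points(path: str | os.PathLike, points: pd.DataFrame) -> None:
    points.to_csv(path, index=False)


def read_points(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
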