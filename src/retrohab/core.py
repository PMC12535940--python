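"""Shared raster/legend/trajectory data model and file I/O.

All grids in one analysis share a single north-up, square-pixel lattice
(30 m Landsat-style cells by default, 0.09 ha each).  Pixel (0, 0) is the
top-left cell and indexing is 0-based row-major throughout.  Class maps are
unsigned integers with 0 reserved for nodata/background; thematic codes
start at 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import tifffile

__all__ = [
    "Affine",
    "Grid",
    "Legend",
    "ClassMapSeries",
    "ValidationError",
    "read_grid",
    "write_grid",
    "extract_trajectories",
    "series_from_trajectories",
    "default_legend",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


class Affine(NamedTuple):
    """Affine georeference: world = (a*col + b*row + c, d*col + e*row + f).

    North-up square pixels have b = d = 0, a = pixel size, e = -pixel size.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def north_up(cls, x0: float = 0.0, y0: float = 0.0, pixel: float = 30.0) -> "Affine":
        return cls(pixel, 0.0, x0, 0.0, -pixel, y0)

    @property
    def pixel_size(self) -> float:
        return abs(self.a)


# GeoTIFF / GDAL tag codes used for round-tripping georeference + nodata.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class Grid:
    """A single-band raster sharing the run's common lattice.

    ``values`` may hold reflectance (0-1), index values, elevation (m) or
    integer class codes.  ``nodata`` never participates in statistics.
    """

    values: np.ndarray
    nodata: float | int | None = None
    transform: Affine = field(default_factory=Affine.north_up)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError(f"Grid values must be 2D, got ndim={self.values.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_ha(self) -> float:
        return self.transform.pixel_size ** 2 / 10_000.0

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        v = self.values
        mask = np.ones(v.shape, dtype=bool)
        if self.nodata is not None:
            mask &= v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= np.isfinite(v)
        return mask

    def like(self, values: np.ndarray, nodata: float | int | None = "inherit") -> "Grid":
        """New grid on the same lattice."""
        nd = self.nodata if nodata == "inherit" else nodata
        return Grid(values=values, nodata=nd, transform=self.transform)


def write_grid(path: str | Path, grid: Grid | Sequence[Grid]) -> None:
    """Write one or more co-registered bands to a GeoTIFF.

    Georeference and nodata are stored in the standard GeoTIFF/GDAL tags
    (ModelPixelScale, ModelTiepoint, GDAL_NODATA) so files interoperate with
    common GIS readers.
    """
    grids = [grid] if isinstance(grid, Grid) else list(grid)
    if not grids:
        raise ValidationError("no grids to write")
    t = grids[0].transform
    shape = grids[0].shape
    for g in grids[1:]:
        if g.shape != shape or g.transform != t:
            raise ValidationError("all bands of one file must share shape and transform")
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0), True),
    ]
    with tifffile.TiffWriter(str(path)) as tif:
        for g in grids:
            tags = list(extratags)
            if g.nodata is not None:
                nd = format(float(g.nodata), "g")
                tags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd, True))
            tif.write(g.values, extratags=tags, photometric="minisblack")


def read_grid(path: str | Path) -> Grid | list[Grid]:
    """Read a single- or multi-band GeoTIFF written by :func:`write_grid`.

    Returns one :class:`Grid` for a single band, a list for multi-band files.
    Raises :class:`ValidationError` when the georeference tags are missing,
    and ``OSError`` for unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    grids: list[Grid] = []
    with tifffile.TiffFile(str(path)) as tif:
        for page in tif.pages:
            scale = page.tags.get(_TAG_PIXEL_SCALE)
            tiepoint = page.tags.get(_TAG_TIEPOINT)
            if scale is None or tiepoint is None:
                raise ValidationError(f"{path}: missing GeoTIFF georeference tags")
            sx, sy = float(scale.value[0]), float(scale.value[1])
            x0, y0 = float(tiepoint.value[3]), float(tiepoint.value[4])
            transform = Affine(sx, 0.0, x0, 0.0, -sy, y0)
            nodata = None
            nd_tag = page.tags.get(_TAG_GDAL_NODATA)
            if nd_tag is not None:
                values_dtype = page.asarray().dtype
                raw = nd_tag.value
                nodata = (
                    int(float(raw)) if np.issubdtype(values_dtype, np.integer) else float(raw)
                )
            grids.append(Grid(values=page.asarray(), nodata=nodata, transform=transform))
    return grids[0] if len(grids) == 1 else grids


@dataclass(frozen=True)
class Legend:
    """Two-level thematic legend.

    Level 1 (L1) holds land-cover classes coded 1-8; level 2 (L2) holds
    habitat types nested inside the vegetated L1 classes.  Non-vegetated L1
    classes (rocks, snow/glaciers, water, wetland) carry no L2 children.
    """

    l1_entries: tuple[tuple[int, str], ...]
    l2_entries: tuple[tuple[int, str, int, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        l1 = {c for c, _ in self.l1_entries}
        for code, _, parent, _ in self.l2_entries:
            if parent not in l1:
                raise ValidationError(f"L2 code {code}: parent {parent} not in L1 legend")

    @property
    def l1_codes(self) -> list[int]:
        return sorted(c for c, _ in self.l1_entries)

    @property
    def l2_codes(self) -> list[int]:
        return sorted(c for c, _, _, _ in self.l2_entries)

    @property
    def vegetation_l1(self) -> list[int]:
        """L1 codes that have L2 children."""
        return sorted({parent for _, _, parent, _ in self.l2_entries})

    def parent_of(self, l2_code: int) -> int:
        for code, _, parent, _ in self.l2_entries:
            if code == l2_code:
                return parent
        raise KeyError(l2_code)

    def children_of(self, l1_code: int) -> list[int]:
        return sorted(c for c, _, p, _ in self.l2_entries if p == l1_code)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "l1": [{"code": c, "name": n} for c, n in self.l1_entries],
            "l2": [
                {"code": c, "name": n, "parent": p, "natura2000": list(nat)}
                for c, n, p, nat in self.l2_entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Legend":
        payload = json.loads(Path(path).read_text())
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "Legend":
        l1 = tuple((int(e["code"]), e["name"]) for e in payload["l1"])
        l2 = tuple(
            (int(e["code"]), e["name"], int(e["parent"]), tuple(e.get("natura2000", [])))
            for e in payload["l2"]
        )
        return cls(l1_entries=l1, l2_entries=l2)


def default_legend() -> Legend:
    """The packaged alpine land-cover/habitat legend (8 L1 classes, 21 L2)."""
    payload = json.loads(
        resources.files("retrohab").joinpath("data/legend_alpine.json").read_text()
    )
    return Legend._from_payload(payload)


@dataclass
class ClassMapSeries:
    """Annual (or windowed) integer class grids sharing one legend and lattice."""

    years: list[int]
    maps: list[Grid]
    level: str = "L1"
    legend: Legend | None = None

    def __post_init__(self) -> None:
        if len(self.years) != len(self.maps):
            raise ValidationError("years and maps must align")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValidationError("years must be strictly increasing")
        if self.maps:
            shape = self.maps[0].shape
            transform = self.maps[0].transform
            for g in self.maps[1:]:
                if g.shape != shape or g.transform != transform:
                    raise ValidationError("all maps in a series must share geometry")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[0].shape


def extract_trajectories(series: ClassMapSeries) -> np.ndarray:
    """Stack a series into per-pixel label trajectories.

    Returns an integer array of shape ``(n_years, height, width)`` where 0
    marks a missing label; ``out[:, r, c]`` is the trajectory of pixel
    (r, c) ordered as ``series.years``.
    """
    if not series.maps:
        raise ValidationError("empty series")
    stack = np.stack([np.asarray(g.values, dtype=np.int64) for g in series.maps])
    for idx, g in enumerate(series.maps):
        if g.nodata not in (None, 0):
            # normalise any non-zero nodata sentinel to the 0 convention
            stack[idx][g.values == g.nodata] = 0
    return stack


def series_from_trajectories(
    traj: np.ndarray, years: Sequence[int], template: Grid, level: str = "L1",
    legend: Legend | None = None,
) -> ClassMapSeries:
    """Inverse of :func:`extract_trajectories`."""
    if traj.shape[0] != len(years):
        raise ValidationError("trajectory length must equal number of years")
    maps = [template.like(traj[i].astype(np.uint16), nodata=0) for i in range(traj.shape[0])]
    return ClassMapSeries(years=list(years), maps=maps, level=level, legend=legend)
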