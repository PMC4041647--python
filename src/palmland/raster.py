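"""Raster grid container and plain-text (ESRI ASCII grid) I/O.

A :class:`RasterGrid` is the common currency of every spatial stage: a
rectangular 2-D array with a fixed square cell size, a top-left origin and a
nodata sentinel.  The default cell size is 100 m, so one cell is one hectare
— the resolution at which all the biophysical predictor layers are built.

Coordinate convention (used everywhere in the package): row-major arrays,
origin at the top-left corner, rows increase southward; distances are
measured between cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

#: Default nodata sentinel for integer-coded categorical layers.
NODATA_INT = -9999


@dataclass
class RasterGrid:
    """A rectangular raster layer with square cells.

    Parameters
    ----------
    values
        2-D array, continuous (float) or categorical (integer codes).
    cell_size
        Cell edge length in meters (> 0).  100 m cells are 1 ha.
    origin
        (x, y) map coordinates of the top-left corner of the grid.
    nodata
        Sentinel marking cells with no data.
    categories
        For categorical layers, the declared set of valid codes; ``None``
        for continuous layers.
    """

    values: np.ndarray
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA_INT
    categories: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.categories is not None:
            self._check_categories()

    def _check_categories(self) -> None:
        data = self.values[self.values != self.nodata]
        bad = set(np.unique(data)) - set(self.categories)
        if bad:
            raise ValueError(
                f"categorical raster contains undeclared codes {sorted(bad)}; "
                f"declared categories are {sorted(self.categories)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (1 ha = 10,000 m2)."""
        return self.cell_size**2 / 10_000.0

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return self.values != self.nodata

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def copy_with(self, values: np.ndarray, **kw) -> "RasterGrid":
        """New grid with the same georeferencing but different values."""
        opts = dict(cell_size=self.cell_size, origin=self.origin, nodata=self.nodata)
        opts.update(kw)
        return RasterGrid(values, **opts)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write a grid as an ESRI ASCII raster (.asc), a plain-text format.

    Integer-valued layers are written as integers so categorical codes
    round-trip exactly; continuous layers use repr-precision floats.
    """
    rows, cols = grid.shape
    x0, y0 = grid.origin
    # ESRI convention anchors the lower-left corner; our origin is top-left.
    yll = y0 - rows * grid.cell_size
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {int(grid.nodata) if is_int else grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in grid.values:
            if is_int:
                fh.write(" ".join("%d" % v for v in row))
            else:
                # repr round-trips doubles exactly
                fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path, categories: tuple[int, ...] | None = None) -> RasterGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = parts[1]
            else:
                data_lines.append(line)
    ncols = int(meta["ncols"])
    nrows = int(meta["nrows"])
    cell = float(meta["cellsize"])
    nodata_s = meta.get("nodata_value", str(NODATA_INT))
    flat = " ".join(data_lines).split()
    if len(flat) != nrows * ncols:
        raise ValueError(f"expected {nrows * ncols} cells, found {len(flat)}")
    is_int = all("." not in t and "e" not in t.lower() for t in flat)
    values = np.array(flat, dtype=np.int64 if is_int else np.float64).reshape(nrows, ncols)
    nodata = int(nodata_s) if is_int else float(nodata_s)
    y0 = float(meta["yllcorner"]) + nrows * cell
    return RasterGrid(
        values,
        cell_size=cell,
        origin=(float(meta["xllcorner"]), y0),
        nodata=nodata,
        categories=categories,
    )
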