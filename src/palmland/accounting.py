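"""Area cross-tabulation and headline-percentage accounting.

Hectare bookkeeping over categorical layers: cross-tabulate two aligned
rasters into an :class:`AreaCrossTab`, compute percentage shares with
half-up integer rounding (the rounding that reproduces every checkable
printed percentage), and load the packaged transcriptions of the study
region's summary tables (forest systems, land titles, title x forest-system
and title x suitability overlays, oil-palm productivity classes, and the
NPV calibration anchors).

Fixture files are checksummed; a mismatch raises, so silent edits to the
transcribed values cannot pass unnoticed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "AreaCrossTab",
    "crosstab_area",
    "percent_share",
    "combined_redundancy",
    "table_fixture",
    "round_half_up",
    "FixtureError",
]


class FixtureError(RuntimeError):
    """Unknown fixture name or checksum mismatch."""


@dataclass
class AreaCrossTab:
    """Hectares cross-tabulated over row and column categories.

    ``cells`` is a DataFrame of non-negative hectare values; margins and the
    grand total are derived from it.  ``annotations`` carries printed totals
    or notes that accompany a transcribed table without entering the sums.
    """

    cells: pd.DataFrame
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.cells.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("cross-tab cells must be non-negative")

    @property
    def row_totals(self) -> pd.Series:
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.cells.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.cells.to_numpy(dtype=float).sum())

    def transpose(self) -> "AreaCrossTab":
        return AreaCrossTab(self.cells.T.copy(), dict(self.annotations))

    def select(self, rows=None, cols=None) -> float:
        """Sum of the cells in the given row/column subset (None = all)."""
        sub = self.cells
        if rows is not None:
            if not isinstance(rows, (list, tuple)):
                rows = [rows]
            sub = sub.loc[list(rows)]
        if cols is not None:
            if not isinstance(cols, (list, tuple)):
                cols = [cols]
            sub = sub[list(cols)]
        return float(sub.to_numpy(dtype=float).sum())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# units: ha\n")
            for k, v in sorted(self.annotations.items()):
                fh.write(f"# {k}: {v}\n")
            self.cells.to_csv(fh)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero toward +inf at the half (decimal half-up)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def crosstab_area(layer_a: RasterGrid, layer_b: RasterGrid) -> AreaCrossTab:
    """Hectares per (class_a, class_b) over two aligned categorical layers.

    Cells that are nodata in either layer are excluded; the grand total then
    equals (jointly valid cell count) x cell area.

    Raises
    ------
    ValueError
        If the layers are not mutually aligned.
    """
    if not layer_a.aligned_with(layer_b):
        raise ValueError("layers are not aligned (shape, cell size and origin must match)")
    valid = layer_a.mask() & layer_b.mask()
    a = layer_a.values[valid].ravel()
    b = layer_b.values[valid].ravel()
    table = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    cells = table.astype(float) * layer_a.cell_area_ha
    return AreaCrossTab(cells)


def percent_share(tab: AreaCrossTab, numerator: dict,
                  denominator: dict | float | str = "all",
                  decimals: int = 0) -> float:
    """100 x selected-sum / denominator-sum, rounded half-up.

    ``numerator`` (and a dict ``denominator``) are selections
    ``{"rows": [...], "cols": [...]}``; ``denominator`` may also be the
    string ``"all"`` (the whole table) or an explicit hectare value, e.g. a
    printed total.

    Raises
    ------
    ValueError
        On a non-positive denominator.
    """
    num = tab.select(**numerator)
    if denominator == "all":
        den = tab.grand_total
    elif isinstance(denominator, dict):
        den = tab.select(**denominator)
    else:
        den = float(denominator)
    if den <= 0:
        raise ValueError(f"denominator must be positive, got {den}")
    return round_half_up(100.0 * num / den, decimals)


def combined_redundancy(existing_redundant_ha: float,
                        predicted_unsuitable_forest_ha: float) -> float:
    """Total potential commercially redundant area: already-mapped grossly
    underproductive oil palm plus inundation-prone forest that would join it
    if converted.

    Raises
    ------
    ValueError
        On negative inputs.
    """
    if existing_redundant_ha < 0 or predicted_unsuitable_forest_ha < 0:
        raise ValueError("areas must be non-negative")
    return existing_redundant_ha + predicted_unsuitable_forest_ha


# ---------------------------------------------------------------------------
# packaged table fixtures (transcriptions of the study's printed tables)

_FIXTURE_SHA256 = {
    "table1.csv": "23f4c20a2acec52dadf711c7ebd279b5200b13ea6e5b589c711d31897a077736",
    "table3.csv": "6a23a4009352009789755fe4f54e31986c518830cce282f9a22d629c0e6bed0a",
    "table4.csv": "1cb7a9ceaa9de3466a3f9435a26bf6f5c72e02bda706b4b7007ab2eed14aec5d",
    "table5.csv": "d994679ea62a70b588e2c79b0150829a586e3db193caac44225e718c04f26d78",
    "table6_anchors.csv": "086cd7a43d5e8306df51a4f72220e1cfc93986f02a06b37722882eda40ff597a",
    "codes.csv": "ef667c6fc87d37e999038069a0699abe796cbb2289eb765b8628e0c552de935e",
}

FIXTURE_NAMES = ("table1", "table3", "table4", "table5", "table6_anchors")


def _read_fixture(filename: str) -> pd.DataFrame:
    ref = resources.files("palmland.data") / filename
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _FIXTURE_SHA256.get(filename)
    if expected is None:
        raise FixtureError(f"unknown fixture file: {filename}")
    if digest != expected:
        raise FixtureError(
            f"fixture checksum mismatch for {filename}: {digest} != {expected}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), comment="#")


def table_fixture(name: str):
    """Load a packaged table transcription.

    ``table1``, ``table3``, ``table4``, ``table5`` return
    :class:`AreaCrossTab`; ``table6_anchors`` returns a DataFrame of
    (productivity class, capacity, discount rate, annualized NPV) anchor
    rows.  Printed grand totals that differ from recomputed cell sums by a
    few hectares (a known feature of the transcribed tables) are kept in
    ``annotations``.

    Raises
    ------
    FixtureError
        For an unknown name or a checksum mismatch.
    """
    if name == "table1":
        df = _read_fixture("table1.csv")
        cells = df.set_index(["forest_system", "forest_type"])[
            ["total_ha", "protected_ha", "unprotected_ha"]
        ]
        cells.index = [f"{s}/{t}" for s, t in cells.index]
        return AreaCrossTab(
            cells,
            annotations={
                "printed_sum_row": "251400 / 436295 / 30173 (column-misaligned in source)",
                "printed_unprotected_total_ha": 30173,
            },
        )
    if name == "table3":
        df = _read_fixture("table3.csv")
        cells = df.set_index("title_type")[["area_ha"]]
        n_titles = dict(zip(df["title_type"], df["n_titles"]))
        return AreaCrossTab(
            cells,
            annotations={
                "printed_total_ha": 30173,
                "printed_total_titles": 1338,
                "n_titles": n_titles,
            },
        )
    if name == "table4":
        df = _read_fixture("table4.csv")
        cells = df.set_index(["section", "category"])[
            ["NT", "CL", "state_demarcated", "state_undemarcated"]
        ]
        cells.index = [f"{s}/{c}" for s, c in cells.index]
        return AreaCrossTab(
            cells,
            annotations={
                "printed_col_totals": [9497, 9732, 3936, 7009],
                "printed_unprotected_total_ha": 30173,
                "note": "two sections share the same column margins",
            },
        )
    if name == "table5":
        df = _read_fixture("table5.csv")
        cells = df.set_index("palm_class")[["nt_ha", "cl_ha", "state_ha"]]
        printed_total = dict(zip(df["palm_class"], df["total_ha"]))
        return AreaCrossTab(
            cells,
            annotations={
                "printed_total_area_ha": 250617,
                "printed_col_totals": [70945, 174698, 4974],
                "printed_row_totals": printed_total,
            },
        )
    if name == "table6_anchors":
        return _read_fixture("table6_anchors.csv")
    raise FixtureError(f"unknown fixture name: {name!r}; expected one of {FIXTURE_NAMES}")


def load_code_table() -> pd.DataFrame:
    """The packaged (layer, code, label) table for categorical rasters."""
    return _read_fixture("codes.csv")
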