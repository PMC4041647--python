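"""Seeded synthetic floodplain landscapes.

Generates the raster stack the downstream analyses consume: a sinuous river
channel, Euclidean distance to it, elevation rising (in expectation) with
distance from the channel, patchy ordinal soil-suitability classes, a forest
system layer, a land-title layer derived from a random parcel tessellation,
and a palm-productivity layer labelled by the suitability rules (optionally
corrupted with label noise).  One integer seed drives a single
:class:`numpy.random.Generator`, so identical ``(shape, params, seed)``
produce bit-identical stacks.

The generator emulates the structure of a tropical floodplain study region:
low-lying flood-prone cells near the river, smallholder (Native Title)
parcels under 40 ha beside large commercial leases, and 1-ha cells
(100 m cell size) matching the resolution of the predictor layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box, mapping

from .raster import RasterGrid, read_ascii_grid, write_ascii_grid, NODATA_INT
from .suitability import (
    FULL_STAND,
    REDUNDANT,
    SUITABILITY_CODES,
    RuleSet,
    reference_ruleset,
)

__all__ = [
    "FOREST_SYSTEM_CODES",
    "TITLE_CODES",
    "SOIL_CLASSES",
    "LandscapeParams",
    "ParcelParams",
    "Parcel",
    "ParcelMap",
    "LandscapeStack",
    "distance_to_river",
    "generate_river_mask",
    "generate_landscape",
    "generate_parcels",
    "sample_suitability_points",
    "write_stack",
    "read_stack",
]

#: Integer codes for the forest-system layer.
FOREST_SYSTEM_CODES = {
    "mangrove": 1,
    "seasonally_flooded": 2,
    "lowland_dry": 3,
    "mixed_degraded": 4,
    "non_forest": 5,
}

#: Integer codes for the land-title layer.  NT = Native Title smallholdings
#: (<40 ha, perpetuity); CL = Country Land 99-year commercial leases.
TITLE_CODES = {
    "NT": 1,
    "CL": 2,
    "state_demarcated": 3,
    "state_undemarcated": 4,
}

#: Ordinal soil agricultural-suitability classes.
SOIL_CLASSES = (1, 2, 3, 4)  # unsuitable, marginal, suitable, very suitable


@dataclass(frozen=True)
class ParcelParams:
    """Target parcel counts and size ranges (ha) per title type.

    Native Title smallholdings are legally restricted to under 40 ha, so the
    NT upper size bound must stay below 40.
    """

    n_nt: int = 40
    nt_size_ha: tuple[float, float] = (2.0, 39.0)
    n_cl: int = 8
    cl_size_ha: tuple[float, float] = (50.0, 400.0)
    n_state_demarcated: int = 6
    state_size_ha: tuple[float, float] = (20.0, 150.0)

    def __post_init__(self) -> None:
        if self.nt_size_ha[1] >= 40.0:
            raise ValueError(
                f"Native Title parcels must be < 40 ha; got upper bound "
                f"{self.nt_size_ha[1]}"
            )
        for lo, hi in (self.nt_size_ha, self.cl_size_ha, self.state_size_ha):
            if not (0 < lo <= hi):
                raise ValueError("parcel size ranges must satisfy 0 < low <= high")


@dataclass(frozen=True)
class LandscapeParams:
    """Tunable structure of the synthetic floodplain.

    Parameters
    ----------
    cell_size
        Cell edge in meters; 100 m makes every cell 1 ha.
    river_amplitude
        Meander amplitude of the channel, in cells.
    river_sinuosity
        Number of meander periods across the grid width.
    elevation_base
        Elevation of the channel itself, m ASL.
    elev_gradient
        Mean elevation rise per meter of distance from the river (m/m).
    flood_extent
        Dimensionless flood-extent control >= 0.1: the distance ramp is
        divided by it, so larger values flatten the floodplain and enlarge
        the low-lying flood-prone fringe.
    noise_scale
        Standard deviation (m) of the smoothed elevation noise.
    noise_sigma
        Gaussian smoothing radius (cells) of the elevation noise.
    soil_patch_sigma
        Smoothing radius (cells) of the latent soil field; sets soil patch
        size (unconstrained by any field observation — a free choice).
    label_noise
        Probability in [0, 1) that a productivity cell's rule label is
        flipped, emulating mapping error.
    """

    cell_size: float = 100.0
    river_amplitude: float = 8.0
    river_sinuosity: float = 1.5
    elevation_base: float = 1.0
    elev_gradient: float = 0.004
    flood_extent: float = 1.0
    noise_scale: float = 2.0
    noise_sigma: float = 3.0
    soil_patch_sigma: float = 5.0
    label_noise: float = 0.0
    parcels: ParcelParams = field(default_factory=ParcelParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError(f"label_noise must be in [0, 1), got {self.label_noise}")
        if self.flood_extent < 0.1:
            raise ValueError("flood_extent must be >= 0.1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")


@dataclass
class Parcel:
    id: int
    title_type: str
    row0: int
    col0: int
    rows: int
    cols: int
    area_ha: float

    def cell_slice(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.rows),
                slice(self.col0, self.col0 + self.cols))


@dataclass
class ParcelMap:
    parcels: list[Parcel]
    shape: tuple[int, int]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def rasterize(self, nodata: int = NODATA_INT) -> RasterGrid:
        """Title-type raster; cells outside any parcel are undemarcated State land."""
        codes = np.full(self.shape, TITLE_CODES["state_undemarcated"], dtype=np.int64)
        for p in self.parcels:
            codes[p.cell_slice()] = TITLE_CODES[p.title_type]
        return RasterGrid(
            codes, cell_size=self.cell_size, origin=self.origin, nodata=nodata,
            categories=tuple(TITLE_CODES.values()),
        )

    def to_geojson(self) -> dict:
        feats = []
        x0, y0 = self.origin
        cs = self.cell_size
        for p in self.parcels:
            xmin = x0 + p.col0 * cs
            xmax = xmin + p.cols * cs
            ymax = y0 - p.row0 * cs
            ymin = ymax - p.rows * cs
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(box(xmin, ymin, xmax, ymax)),
                    "properties": {
                        "id": p.id,
                        "title_type": p.title_type,
                        "area_ha": p.area_ha,
                        "row0": p.row0,
                        "col0": p.col0,
                        "rows": p.rows,
                        "cols": p.cols,
                    },
                }
            )
        return {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {
                "shape": list(self.shape),
                "cell_size": self.cell_size,
                "origin": list(self.origin),
            },
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "ParcelMap":
        meta = obj["properties"]
        parcels = [
            Parcel(
                id=f["properties"]["id"],
                title_type=f["properties"]["title_type"],
                row0=f["properties"]["row0"],
                col0=f["properties"]["col0"],
                rows=f["properties"]["rows"],
                cols=f["properties"]["cols"],
                area_ha=f["properties"]["area_ha"],
            )
            for f in obj["features"]
        ]
        return cls(
            parcels=parcels,
            shape=tuple(meta["shape"]),
            cell_size=meta["cell_size"],
            origin=tuple(meta["origin"]),
        )


@dataclass
class LandscapeStack:
    """Mutually aligned raster layers of one synthetic floodplain."""

    elevation: RasterGrid
    dist_river: RasterGrid
    soil: RasterGrid
    forest_system: RasterGrid
    productivity: RasterGrid
    titles: RasterGrid
    aspect: RasterGrid | None = None
    slope: RasterGrid | None = None
    river: RasterGrid | None = None
    parcels: ParcelMap | None = None

    LAYERS = (
        "elevation", "dist_river", "soil", "forest_system",
        "productivity", "titles", "aspect", "slope", "river",
    )

    def __post_init__(self) -> None:
        ref = self.elevation
        for name in self.LAYERS:
            layer = getattr(self, name)
            if layer is not None and not ref.aligned_with(layer):
                raise ValueError(f"layer {name} is not aligned with elevation")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape


def distance_to_river(river_mask, cell_size: float = 100.0) -> RasterGrid:
    """Exact Euclidean distance (m) from each cell center to the nearest
    river cell center.

    Implemented with the exact Euclidean distance transform
    (:func:`scipy.ndimage.distance_transform_edt`), which equals the
    brute-force minimum over all river cells.

    Raises
    ------
    ValueError
        If the mask contains no river cell.
    """
    if isinstance(river_mask, RasterGrid):
        mask = river_mask.values.astype(bool)
        cell_size = river_mask.cell_size
        origin = river_mask.origin
    else:
        mask = np.asarray(river_mask, dtype=bool)
        origin = (0.0, 0.0)
    if not mask.any():
        raise ValueError("river mask contains no river cell")
    dist = ndimage.distance_transform_edt(~mask, sampling=cell_size)
    return RasterGrid(dist.astype(float), cell_size=cell_size, origin=origin,
                      nodata=float(NODATA_INT))


def generate_river_mask(shape: tuple[int, int], params: LandscapeParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Sinuous west-east channel: sinusoidal meanders plus a smoothed random walk."""
    rows, cols = shape
    j = np.arange(cols)
    meander = params.river_amplitude * np.sin(
        2 * np.pi * params.river_sinuosity * j / cols
    )
    walk = np.cumsum(rng.normal(0.0, 0.6, size=cols))
    walk = ndimage.gaussian_filter1d(walk, sigma=5.0, mode="nearest")
    center = rows / 2.0 + meander + (walk - walk.mean())
    center = np.clip(center, 1, rows - 2)
    mask = np.zeros(shape, dtype=bool)
    r = np.round(center).astype(int)
    mask[r, j] = True
    mask[np.clip(r + 1, 0, rows - 1), j] = True  # 2-cell-wide channel
    return mask


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Unit-variance smoothed Gaussian noise field."""
    raw = rng.normal(size=shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _soil_layer(shape, params, rng) -> np.ndarray:
    latent = _smooth_field(shape, params.soil_patch_sigma, rng)
    # quantile cut into four equally common ordinal classes
    qs = np.quantile(latent, [0.25, 0.5, 0.75])
    return (np.digitize(latent, qs) + 1).astype(np.int64)


def _forest_system_layer(elev, dist, params, rng) -> np.ndarray:
    """Heuristic forest systems: tidal mangrove lowest and river-proximal,
    seasonally flooded on the low floodplain, lowland dry above, with
    degraded patches sprinkled in."""
    codes = np.full(elev.shape, FOREST_SYSTEM_CODES["lowland_dry"], dtype=np.int64)
    codes[elev <= 10.0] = FOREST_SYSTEM_CODES["seasonally_flooded"]
    codes[(elev <= 3.0) & (dist <= 1500.0)] = FOREST_SYSTEM_CODES["mangrove"]
    degraded = _smooth_field(elev.shape, 4.0, rng) > 1.4
    codes[degraded] = FOREST_SYSTEM_CODES["mixed_degraded"]
    nonforest = _smooth_field(elev.shape, 6.0, rng) > 1.8
    codes[nonforest] = FOREST_SYSTEM_CODES["non_forest"]
    return codes


def generate_parcels(shape: tuple[int, int], params: ParcelParams, seed: int,
                     cell_size: float = 100.0,
                     origin: tuple[float, float] = (0.0, 0.0)) -> ParcelMap:
    """Random non-overlapping rectangular parcel tessellation.

    Placement is greedy: random rectangles are drawn per title type and kept
    when they do not overlap previously placed parcels; Native Title parcels
    never reach 40 ha.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    cell_ha = cell_size**2 / 10_000.0
    occupied = np.zeros(shape, dtype=bool)
    parcels: list[Parcel] = []
    pid = 1
    specs = [
        ("CL", params.n_cl, params.cl_size_ha),
        ("state_demarcated", params.n_state_demarcated, params.state_size_ha),
        ("NT", params.n_nt, params.nt_size_ha),
    ]
    for title, count, (lo_ha, hi_ha) in specs:
        placed = 0
        attempts = 0
        while placed < count and attempts < count * 200:
            attempts += 1
            target_ha = rng.uniform(lo_ha, hi_ha)
            n_cells = max(1, int(target_ha / cell_ha))
            if title == "NT":
                n_cells = min(n_cells, int(np.ceil(40.0 / cell_ha)) - 1)
            h = int(np.clip(round(np.sqrt(n_cells) * rng.uniform(0.7, 1.4)), 1, rows))
            w = max(1, n_cells // h)
            if title == "NT" and h * w * cell_ha >= 40.0:
                w = max(1, int((40.0 / cell_ha - 1) // h))
            if h > rows or w > cols or h * w == 0:
                continue
            r0 = int(rng.integers(0, rows - h + 1))
            c0 = int(rng.integers(0, cols - w + 1))
            window = occupied[r0:r0 + h, c0:c0 + w]
            if window.any():
                continue
            occupied[r0:r0 + h, c0:c0 + w] = True
            parcels.append(
                Parcel(id=pid, title_type=title, row0=r0, col0=c0,
                       rows=h, cols=w, area_ha=h * w * cell_ha)
            )
            pid += 1
            placed += 1
    return ParcelMap(parcels=parcels, shape=shape, cell_size=cell_size, origin=origin)


def generate_landscape(shape: tuple[int, int],
                       params: LandscapeParams | None = None,
                       seed: int = 0,
                       rules: RuleSet | None = None) -> LandscapeStack:
    """Generate a complete, mutually aligned synthetic floodplain stack.

    The productivity layer is the suitability rule set applied cell-wise to
    (dist_river, elevation, soil); with ``params.label_noise = e`` each
    cell's label is independently flipped with probability e.  Aspect and
    slope are derived from the noisy elevation surface and carry no
    suitability signal.

    Raises
    ------
    ValueError
        For grids smaller than 20 x 20 or invalid parameters.
    """
    if params is None:
        params = LandscapeParams()
    rows, cols = shape
    if rows < 20 or cols < 20:
        raise ValueError(f"shape must be at least 20x20, got {shape}")
    if rules is None:
        rules = reference_ruleset()
    rng = np.random.default_rng(seed)
    cs = params.cell_size
    origin = (0.0, float(rows) * cs)

    river = generate_river_mask(shape, params, rng)
    dist = distance_to_river(river, cell_size=cs)
    dist = dist.copy_with(dist.values, origin=origin)

    ramp = params.elevation_base + params.elev_gradient * dist.values / params.flood_extent
    noise = _smooth_field(shape, params.noise_sigma, rng) * params.noise_scale
    elev_vals = np.maximum(0.0, ramp + noise)
    elev_vals[river] = params.elevation_base
    elevation = RasterGrid(elev_vals, cell_size=cs, origin=origin,
                           nodata=float(NODATA_INT))

    soil = RasterGrid(_soil_layer(shape, params, rng), cell_size=cs, origin=origin,
                      nodata=NODATA_INT, categories=SOIL_CLASSES)

    # aspect/slope from the elevation surface; no rule reads them
    gy, gx = np.gradient(elev_vals, cs)
    slope_vals = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect_vals = np.degrees(np.arctan2(-gx, gy)) % 360.0
    slope = RasterGrid(slope_vals, cell_size=cs, origin=origin, nodata=float(NODATA_INT))
    aspect = RasterGrid(aspect_vals, cell_size=cs, origin=origin, nodata=float(NODATA_INT))

    labels = rules.classify(
        dist_river=dist.values, elevation=elev_vals, soil=soil.values
    )
    codes = np.where(labels == REDUNDANT, 1, 0).astype(np.int64)
    if params.label_noise > 0:
        flip = rng.random(shape) < params.label_noise
        codes = np.where(flip, 1 - codes, codes)
    productivity = RasterGrid(codes, cell_size=cs, origin=origin,
                              nodata=NODATA_INT, categories=(0, 1))

    forest = RasterGrid(
        _forest_system_layer(elev_vals, dist.values, params, rng),
        cell_size=cs, origin=origin, nodata=NODATA_INT,
        categories=tuple(FOREST_SYSTEM_CODES.values()),
    )

    parcel_seed = int(rng.integers(0, 2**31 - 1))
    parcel_map = generate_parcels(shape, params.parcels, parcel_seed,
                                  cell_size=cs, origin=origin)
    titles = parcel_map.rasterize()

    river_grid = RasterGrid(river.astype(np.int64), cell_size=cs, origin=origin,
                            nodata=NODATA_INT, categories=(0, 1))
    return LandscapeStack(
        elevation=elevation, dist_river=dist, soil=soil, forest_system=forest,
        productivity=productivity, titles=titles, aspect=aspect, slope=slope,
        river=river_grid, parcels=parcel_map,
    )


def flood_prone_fraction(stack: LandscapeStack, elev_threshold: float = 5.0,
                         dist_threshold: float = 1504.0) -> float:
    """Fraction of cells that are low-lying and river-proximal.

    For a fixed seed the elevation surface decreases pointwise as
    ``flood_extent`` grows (the ramp is divided by it while the noise field
    is unchanged), so this fraction is non-decreasing in the flood-extent
    control.
    """
    low = stack.elevation.values <= elev_threshold
    near = stack.dist_river.values <= dist_threshold
    return float((low & near).mean())


# ---------------------------------------------------------------------------
# training-point sampling for the suitability classifier


def sample_suitability_points(
    n: int,
    seed: int = 0,
    noise_rate: float = 0.0,
    rules: RuleSet | None = None,
    stratify: bool = True,
    dist_range: tuple[float, float] = (0.0, 5000.0),
    elev_range: tuple[float, float] = (0.0, 40.0),
    dist_step: float = 8.0,
    elev_step: float = 0.2,
) -> pd.DataFrame:
    """Sample labelled suitability training points on a regular value grid.

    Distances are drawn on a ``dist_step`` grid (default 8 m) and elevations
    on an ``elev_step`` grid (default 0.2 m), so decision-boundary recovery
    lands within one grid spacing of the generating thresholds.

    With ``stratify=True`` the draw covers the rule regions and their
    immediate full-stand counterparts: the three redundant rule regions
    (with extra weight just beyond each distance threshold, where training
    blocks cluster around the suitability transition), a uniform draw over
    the full-stand remainder, and the full-stand shadows adjoining each rule
    boundary (above 22.4 m near the river; 16-22.4 m and non-marginal soils
    beyond 1,504 m; the very-suitable-soil depression band short of 1,947 m
    and its elevation complement beyond it).  This mirrors training data
    extracted from mapped productive and grossly underproductive blocks,
    which interleave across flood boundaries, and gives every decision
    boundary data on both sides.  The class mix comes out near 56:44
    full-stand:redundant.

    Labels are the rule labels, independently flipped with probability
    ``noise_rate``.  Uninformative aspect and slope columns are included.
    """
    if not (0.0 <= noise_rate < 1.0):
        raise ValueError(f"noise_rate must be in [0, 1), got {noise_rate}")
    if rules is None:
        rules = reference_ruleset()
    rng = np.random.default_rng(seed)
    d_lo, d_hi = dist_range
    e_lo, e_hi = elev_range
    n_d = int(round((d_hi - d_lo) / dist_step))
    n_e = int(round((e_hi - e_lo) / elev_step))

    def grid_idx(value, step):
        return int(round(value / step))

    def draw_dist(size, lo=None, hi=None, strict_lo=False):
        lo_i = 0 if lo is None else grid_idx(lo, dist_step) + (1 if strict_lo else 0)
        hi_i = n_d if hi is None else grid_idx(hi, dist_step)
        return d_lo + rng.integers(lo_i, hi_i + 1, size=size) * dist_step

    def draw_elev(size, lo=None, hi=None, strict_lo=False):
        lo_i = 0 if lo is None else grid_idx(lo, elev_step) + (1 if strict_lo else 0)
        hi_i = n_e if hi is None else grid_idx(hi, elev_step)
        return e_lo + rng.integers(lo_i, hi_i + 1, size=size) * elev_step

    def near_far_dist(size, threshold, near_span=450.0):
        """Half the draws just beyond the threshold, half over the full tail."""
        k = size // 2
        near = threshold + dist_step + np.floor(
            rng.random(k) * (near_span / dist_step)
        ) * dist_step
        far = draw_dist(size - k, lo=threshold, strict_lo=True)
        return np.concatenate([near, far])

    if stratify:
        weights = {
            "r1": 0.20, "r2": 0.12, "r3": 0.12,
            "f0": 0.16, "f1": 0.08, "f2": 0.08,
            "f3": 0.08, "f4": 0.08, "f5": 0.08,
        }
        quota = {k: int(round(w * n)) for k, w in weights.items()}
        quota["f0"] += n - sum(quota.values())
        parts = []
        # R1: dist <= 1504, elev <= 22.4, any soil -> redundant
        m = quota["r1"]
        parts.append((draw_dist(m, hi=1504.0), draw_elev(m, hi=22.4),
                      rng.integers(1, 5, size=m)))
        # R2: dist > 1504, elev <= 16, marginal soil -> redundant
        m = quota["r2"]
        parts.append((near_far_dist(m, 1504.0), draw_elev(m, hi=16.0),
                      np.full(m, 2)))
        # R3: dist > 1947, very suitable soil, 9.9 <= elev <= 14 -> redundant
        m = quota["r3"]
        parts.append((near_far_dist(m, 1944.0), draw_elev(m, lo=10.0, hi=14.0),
                      np.full(m, 4)))
        # F1: near-river terrace above 22.4 m -> full stand
        m = quota["f1"]
        parts.append((draw_dist(m, hi=1504.0), draw_elev(m, lo=22.4, hi=40.0,
                                                         strict_lo=True),
                      rng.integers(1, 5, size=m)))
        # F2: beyond 1504 m, 16 < elev <= 22.4 -> full stand
        m = quota["f2"]
        parts.append((draw_dist(m, lo=1504.0, strict_lo=True),
                      draw_elev(m, lo=16.0, hi=22.4, strict_lo=True),
                      rng.integers(1, 5, size=m)))
        # F3: very-suitable depression band short of 1947 m -> full stand
        m = quota["f3"]
        parts.append((draw_dist(m, lo=1504.0, hi=1944.0, strict_lo=True),
                      draw_elev(m, lo=10.0, hi=14.0), np.full(m, 4)))
        # F4: beyond 1504 m, elev <= 16, non-marginal low soils -> full stand
        m = quota["f4"]
        parts.append((draw_dist(m, lo=1504.0, strict_lo=True),
                      draw_elev(m, hi=16.0),
                      rng.choice([1, 3], size=m)))
        # F5: beyond 1947 m, soil 4, outside the 9.9-14 m band -> full stand
        m = quota["f5"]
        lo_band = draw_elev(m, hi=9.8)
        hi_band = draw_elev(m, lo=14.0, hi=22.4, strict_lo=True)
        pick_hi = rng.random(m) < 0.5
        parts.append((draw_dist(m, lo=1944.0, strict_lo=True),
                      np.where(pick_hi, hi_band, lo_band), np.full(m, 4)))
        # F0: uniform full-stand remainder, by rejection from the whole box
        m = quota["f0"]
        ds, es, ss = [], [], []
        got = 0
        while got < m:
            k = max(4 * (m - got), 64)
            d = draw_dist(k)
            e = draw_elev(k)
            s = rng.integers(1, 5, size=k)
            keep = rules.classify(dist_river=d, elevation=e, soil=s) == FULL_STAND
            ds.append(d[keep]); es.append(e[keep]); ss.append(s[keep])
            got += int(keep.sum())
        parts.append((np.concatenate(ds)[:m], np.concatenate(es)[:m],
                      np.concatenate(ss)[:m]))
        dist = np.concatenate([p[0] for p in parts])
        elev = np.concatenate([p[1] for p in parts])
        soil = np.concatenate([p[2] for p in parts])
    else:
        dist = draw_dist(n)
        elev = draw_elev(n)
        soil = rng.integers(1, 5, size=n)

    labels = rules.classify(dist_river=dist, elevation=elev, soil=soil)
    if noise_rate > 0:
        flip = rng.random(len(labels)) < noise_rate
        flipped = np.where(labels == REDUNDANT, FULL_STAND, REDUNDANT)
        labels = np.where(flip, flipped, labels)
    df = pd.DataFrame(
        {
            "dist_river": dist.astype(float),
            "elevation": elev.astype(float),
            "soil": soil.astype(float),
            "aspect": rng.uniform(0, 360, size=len(dist)),
            "slope": rng.uniform(0, 5, size=len(dist)),
            "label": labels,
        }
    )
    # deterministic shuffle so stratified blocks are interleaved
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


# ---------------------------------------------------------------------------
# stack I/O


_CATEGORIES = {
    "soil": SOIL_CLASSES,
    "forest_system": tuple(FOREST_SYSTEM_CODES.values()),
    "productivity": (0, 1),
    "titles": tuple(TITLE_CODES.values()),
    "river": (0, 1),
}


def write_stack(stack: LandscapeStack, directory) -> list[Path]:
    """Write one ESRI ASCII raster per layer plus a GeoJSON parcel file.

    Round-trips losslessly through :func:`read_stack` (integer codes exact;
    floats at repr precision).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in LandscapeStack.LAYERS:
        layer = getattr(stack, name)
        if layer is None:
            continue
        path = directory / f"{name}.asc"
        write_ascii_grid(layer, path)
        written.append(path)
    if stack.parcels is not None:
        path = directory / "parcels.geojson"
        with open(path, "w") as fh:
            json.dump(stack.parcels.to_geojson(), fh, indent=1, sort_keys=True)
        written.append(path)
    return written


def read_stack(directory) -> LandscapeStack:
    """Read a stack written by :func:`write_stack`."""
    directory = Path(directory)
    layers = {}
    for name in LandscapeStack.LAYERS:
        path = directory / f"{name}.asc"
        if path.exists():
            layers[name] = read_ascii_grid(path, categories=_CATEGORIES.get(name))
        else:
            layers[name] = None
    parcels = None
    pj = directory / "parcels.geojson"
    if pj.exists():
        with open(pj) as fh:
            parcels = ParcelMap.from_geojson(json.load(fh))
    return LandscapeStack(parcels=parcels, **layers)
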