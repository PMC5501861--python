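"""Gridded landscape: covariates, forest types, neighbours and river barriers.

The study region is discretised into 1 x 1 km cells on a rectangular grid
(row-major, 0-based internally; exported tables use 1-based ``cell_id``).
Each cell carries static covariates (altitude ``ALT`` in m, dry- and
wet-season mean monthly rainfall ``DRY``/``WET`` in mm, proportion Muslim
per district ``MS``) and per-period covariates (distance to protected area
``DPA`` in km, natural forest extent ``FR`` as a fraction, distance to
forest recently converted to industrial agriculture ``CFA`` in km), plus a
majority forest-class label used to derive the nest-decay indicators.

Dispersal between cells is limited to the first-order Moore neighbourhood
and can be blocked by large rivers: the straight segment joining two cell
centres is intersected with the river layer, and a crossing that enters the
strict interior of the destination cell severs the link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
import shapely
from shapely.geometry import LineString, box

LANDUSE_CLASSES = ("PA", "LOGG", "ITP", "OPP", "OTHER")

#: majority forest-class labels accepted by :func:`forest_type_indicators`
FOREST_CLASSES = ("mangrove", "peat", "other", "lowland", "montane", "none")

#: altitude split (m) between lowland and montane forest
MONTANE_ALTITUDE_M = 500.0

#: forest fraction below which a cell counts as highly fragmented (25 ha/km2)
FRAGMENT_THRESHOLD = 0.25


class LandscapeError(ValueError):
    """Structural problem with a landscape, grid or covariate table."""


@dataclass
class GridLandscape:
    """Cell-level covariates for a rectangular 1-km grid.

    Arrays are indexed by flat cell index ``i = row * ncol + col``. Static
    covariates have shape ``(ncell,)``; time-varying ones ``(ncell, nperiod)``.
    """

    nrow: int
    ncol: int
    region: np.ndarray          # (C,) str
    landuse: np.ndarray         # (C, T) str in LANDUSE_CLASSES
    ALT: np.ndarray             # (C,) m
    DRY: np.ndarray             # (C,) mm/month, May-Sep
    WET: np.ndarray             # (C,) mm/month, Nov-Mar
    MS: np.ndarray              # (C,) fraction in [0, 1]
    DPA: np.ndarray             # (C, T) km
    FR: np.ndarray              # (C, T) fraction in [0, 1]
    CFA: np.ndarray             # (C, T) km
    forest_class: np.ndarray    # (C, T) str in FOREST_CLASSES
    village_flag: np.ndarray    # (C,) bool

    def __post_init__(self) -> None:
        C = self.nrow * self.ncol
        for name in ("region", "ALT", "DRY", "WET", "MS", "village_flag"):
            if len(getattr(self, name)) != C:
                raise LandscapeError(f"{name} must have length nrow*ncol={C}")
        T = self.nperiod
        for name in ("landuse", "DPA", "FR", "CFA", "forest_class"):
            arr = getattr(self, name)
            if arr.shape != (C, T):
                raise LandscapeError(f"{name} must have shape ({C}, {T})")
        self.validate()

    @property
    def ncell(self) -> int:
        return self.nrow * self.ncol

    @property
    def nperiod(self) -> int:
        return self.DPA.shape[1]

    @property
    def rows(self) -> np.ndarray:
        return np.arange(self.ncell) // self.ncol

    @property
    def cols(self) -> np.ndarray:
        return np.arange(self.ncell) % self.ncol

    def validate(self) -> None:
        if np.any(self.ALT < 0):
            raise LandscapeError("ALT must be non-negative")
        if np.any(self.DRY < 0) or np.any(self.WET < 0):
            raise LandscapeError("rainfall must be non-negative")
        if np.any((self.MS < 0) | (self.MS > 1)):
            raise LandscapeError("MS must lie in [0, 1]")
        if np.any((self.FR < 0) | (self.FR > 1)):
            raise LandscapeError("FR must lie in [0, 1]")
        if np.any(self.DPA < 0) or np.any(self.CFA < 0):
            raise LandscapeError("DPA and CFA must be non-negative")
        bad = ~np.isin(self.forest_class, FOREST_CLASSES)
        if np.any(bad):
            labels = sorted(set(self.forest_class[bad].ravel().tolist()))
            raise LandscapeError(f"unknown forest class labels: {labels}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per cell x period, 1-based cell_id."""
        C, T = self.ncell, self.nperiod
        rows = []
        for t in range(T):
            rows.append(pd.DataFrame({
                "cell_id": np.arange(1, C + 1),
                "row": self.rows + 1,
                "col": self.cols + 1,
                "period": t + 1,
                "region": self.region,
                "landuse": self.landuse[:, t],
                "ALT": self.ALT, "DRY": self.DRY, "WET": self.WET,
                "MS": self.MS,
                "DPA": self.DPA[:, t], "FR": self.FR[:, t],
                "CFA": self.CFA[:, t],
                "forest_class": self.forest_class[:, t],
                "village": self.village_flag.astype(int),
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GridLandscape":
        """Rebuild a landscape from the long-format table of :meth:`to_frame`."""
        required = {"cell_id", "row", "col", "period", "region", "landuse",
                    "ALT", "DRY", "WET", "MS", "DPA", "FR", "CFA",
                    "forest_class", "village"}
        missing = required - set(df.columns)
        if missing:
            raise LandscapeError(f"missing columns: {sorted(missing)}")
        periods = np.sort(df["period"].unique())
        T = len(periods)
        p1 = df[df["period"] == periods[0]].sort_values("cell_id")
        if p1["cell_id"].duplicated().any():
            raise LandscapeError("duplicated cell_id within a period")
        nrow, ncol = int(p1["row"].max()), int(p1["col"].max())
        C = nrow * ncol
        if len(p1) != C:
            raise LandscapeError(
                f"non-rectangular grid: {len(p1)} cells for {nrow}x{ncol}")
        shape = (C, T)
        DPA = np.empty(shape); FR = np.empty(shape); CFA = np.empty(shape)
        landuse = np.empty(shape, dtype=object)
        fclass = np.empty(shape, dtype=object)
        for j, t in enumerate(periods):
            pt = df[df["period"] == t].sort_values("cell_id")
            if len(pt) != C:
                raise LandscapeError(f"period {t} has {len(pt)} cells, expected {C}")
            DPA[:, j] = pt["DPA"].to_numpy()
            FR[:, j] = pt["FR"].to_numpy()
            CFA[:, j] = pt["CFA"].to_numpy()
            landuse[:, j] = pt["landuse"].to_numpy()
            fclass[:, j] = pt["forest_class"].to_numpy()
        return cls(
            nrow=nrow, ncol=ncol,
            region=p1["region"].to_numpy(dtype=object),
            landuse=landuse,
            ALT=p1["ALT"].to_numpy(float), DRY=p1["DRY"].to_numpy(float),
            WET=p1["WET"].to_numpy(float), MS=p1["MS"].to_numpy(float),
            DPA=DPA, FR=FR, CFA=CFA, forest_class=fclass,
            village_flag=p1["village"].to_numpy().astype(bool),
        )


# ---------------------------------------------------------------------------
# Neighbour graph with river barriers


@dataclass
class NeighborGraph:
    """Moore adjacency with binary river-barrier weights.

    ``nbr[i]`` holds up to eight neighbour indices padded with -1;
    ``w[i, k]`` is 1 if dispersal between cell ``i`` and ``nbr[i, k]`` is
    possible and 0 if a river blocks the link. Weights are symmetric.
    """

    nrow: int
    ncol: int
    nbr: np.ndarray   # (C, 8) int, -1 padded
    w: np.ndarray     # (C, 8) float, 0 where padded
    deg: np.ndarray   # (C,) number of geometric neighbours

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for k in range(8):
            j = self.nbr[i, k]
            if j >= 0:
                out.append((int(j), float(self.w[i, k])))
        return out


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def cell_center(row: int, col: int) -> tuple[float, float]:
    """Centre of a 1-km cell in km coordinates (x east = col, y south = row)."""
    return (col + 0.5, row + 0.5)


def build_neighbor_graph(landscape: GridLandscape, rivers=None) -> NeighborGraph:
    """Moore-neighbourhood graph with river barriers.

    For each pair of adjacent cells the centre-to-centre segment is
    intersected with the river polylines. A link is severed (w = 0) when any
    part of the intersection lies in the strict interior of either endpoint
    cell, which keeps the graph symmetric; intersections exactly on a cell
    edge do not block.

    Parameters
    ----------
    rivers
        Iterable of shapely ``LineString`` (or a prepared geometry); empty or
        None means no barriers.
    """
    nrow, ncol = landscape.nrow, landscape.ncol
    C = nrow * ncol
    nbr = np.full((C, 8), -1, dtype=np.int64)
    w = np.zeros((C, 8))
    deg = np.zeros(C, dtype=np.int64)

    river_union = None
    if rivers is not None:
        geoms = list(rivers) if not hasattr(rivers, "geom_type") else [rivers]
        if geoms:
            river_union = shapely.union_all(geoms)
            if river_union.is_empty:
                river_union = None

    for i in range(C):
        r, c = divmod(i, ncol)
        k = 0
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrow and 0 <= cc < ncol):
                continue
            j = rr * ncol + cc
            nbr[i, k] = j
            w[i, k] = 1.0
            k += 1
        deg[i] = k

    if river_union is not None:
        for i in range(C):
            r, c = divmod(i, ncol)
            for k in range(deg[i]):
                j = nbr[i, k]
                if j < i:
                    continue  # handle each undirected link once
                rj, cj = divmod(int(j), ncol)
                seg = LineString([cell_center(r, c), cell_center(rj, cj)])
                inter = seg.intersection(river_union)
                if inter.is_empty:
                    continue
                blocked = _enters_interior(inter, rj, cj) or \
                    _enters_interior(inter, r, c)
                if blocked:
                    w[i, k] = 0.0
                    back = np.where(nbr[j] == i)[0][0]
                    w[j, back] = 0.0
    return NeighborGraph(nrow=nrow, ncol=ncol, nbr=nbr, w=w, deg=deg)


def _enters_interior(geom, row: int, col: int) -> bool:
    """True if any part of ``geom`` lies strictly inside cell (row, col)."""
    cell = box(col, row, col + 1.0, row + 1.0)
    # touches() is true when the intersection is confined to the boundary
    return geom.intersects(cell) and not geom.touches(cell)


# ---------------------------------------------------------------------------
# Covariate standardisation


@dataclass
class StandardizedCovariates:
    """Z-scored covariates with stored means/SDs for back-transformation.

    Static covariates ``ALT``/``DRY``/``WET``/``MS`` have shape ``(C,)``;
    the time-varying ``DPA``/``FR``/``CFA`` keep shape ``(C, T)`` and are
    standardised with a single mean/SD pooled over periods so that the one
    coefficient shared across periods stays interpretable. The SD uses the
    population (n-denominator) convention.
    """

    ALT: np.ndarray
    DRY: np.ndarray
    WET: np.ndarray
    MS: np.ndarray
    DPA: np.ndarray
    FR: np.ndarray
    CFA: np.ndarray
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    STATIC = ("ALT", "DRY", "WET", "MS")
    VARYING = ("DPA", "FR", "CFA")

    def back_transform(self, name: str) -> np.ndarray:
        """Recover the original covariate values for one column."""
        return getattr(self, name) * self.sds[name] + self.means[name]

    @property
    def ncell(self) -> int:
        return len(self.ALT)

    @property
    def nperiod(self) -> int:
        return self.DPA.shape[1]


def zscore(x: np.ndarray, name: str = "column") -> tuple[np.ndarray, float, float]:
    """Population z-score of a column; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    s = float(x.std())  # ddof=0
    if not np.isfinite(s) or s <= 0:
        raise LandscapeError(f"covariate {name!r} has zero variance; cannot standardize")
    return (x - m) / s, m, s


def standardize_covariates(landscape: GridLandscape) -> StandardizedCovariates:
    """Z-score all covariates (pooled over periods for the time-varying ones)."""
    out = {}
    means, sds = {}, {}
    for name in StandardizedCovariates.STATIC:
        z, m, s = zscore(getattr(landscape, name), name)
        out[name] = z
        means[name], sds[name] = m, s
    for name in StandardizedCovariates.VARYING:
        arr = getattr(landscape, name)
        z, m, s = zscore(arr.ravel(), name)
        out[name] = z.reshape(arr.shape)
        means[name], sds[name] = m, s
    return StandardizedCovariates(means=means, sds=sds, **out)


# ---------------------------------------------------------------------------
# Forest-type indicators


def forest_type_indicators(landscape: GridLandscape, period: int) -> pd.DataFrame:
    """Binary forest-type columns MGV/PT/LOWL/MONT/FRGM for one period.

    The majority forest class of a cell maps to exactly one of
    mangrove/peat/lowland/montane; generic forest ("other") is split into
    lowland vs montane at 500 m altitude. FRGM flags highly fragmented
    forest (forest area < 25 ha within the 1-km cell, i.e. FR < 0.25) and is
    set independently of the type flags.
    """
    cls = landscape.forest_class[:, period]
    bad = ~np.isin(cls, FOREST_CLASSES)
    if np.any(bad):
        raise LandscapeError(
            f"unknown forest class labels: {sorted(set(cls[bad].tolist()))}")
    montane = landscape.ALT >= MONTANE_ALTITUDE_M
    mgv = (cls == "mangrove")
    pt = (cls == "peat")
    lowl = (cls == "lowland") | ((cls == "other") & ~montane)
    mont = (cls == "montane") | ((cls == "other") & montane)
    frgm = landscape.FR[:, period] < FRAGMENT_THRESHOLD
    return pd.DataFrame({
        "MGV": mgv.astype(int), "PT": pt.astype(int),
        "LOWL": lowl.astype(int), "MONT": mont.astype(int),
        "FRGM": frgm.astype(int),
    })


# ---------------------------------------------------------------------------
# Forest patches


@dataclass
class PatchSet:
    """Connected forest patches (Moore adjacency) for one period."""

    labels: np.ndarray        # (C,) int, 0 = non-forest
    sizes_km2: np.ndarray     # (P,) patch areas
    nearest_km: np.ndarray    # (P,) edge-to-edge distance to nearest patch, NaN if single

    @property
    def npatch(self) -> int:
        return len(self.sizes_km2)


def connected_forest_patches(landscape: GridLandscape, period: int,
                             threshold: float = FRAGMENT_THRESHOLD) -> PatchSet:
    """Label contiguous forest (FR >= threshold) under 8-connectivity.

    Patch areas are in km2 (1 cell = 1 km2). The distance between two
    patches is the minimum over cell pairs of the Chebyshev centre distance
    minus 1 km, i.e. the width of the gap in grid cells; a two-cell gap
    between blocks gives 2 km.
    """
    mask = (landscape.FR[:, period] >= threshold).reshape(
        landscape.nrow, landscape.ncol)
    labels, npatch = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    flat = labels.ravel()
    if npatch == 0:
        return PatchSet(labels=flat, sizes_km2=np.array([]), nearest_km=np.array([]))
    sizes = np.bincount(flat)[1:].astype(float)
    nearest = np.full(npatch, np.nan)
    if npatch > 1:
        coords = [np.argwhere(labels == p + 1).astype(float) for p in range(npatch)]
        for a in range(npatch):
            best = np.inf
            for b in range(npatch):
                if a == b:
                    continue
                d = cdist(coords[a], coords[b], metric="chebyshev").min()
                best = min(best, d - 1.0)
            nearest[a] = best
    return PatchSet(labels=flat, sizes_km2=sizes, nearest_km=nearest)
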