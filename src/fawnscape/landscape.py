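"""Analysis grid construction and landscape covariates.

Builds the square-cell analysis grid (default 2115 m^2 per cell, the mean
telemetry error ellipse), labels vegetation patches, and computes the
point-level resource metrics: per-cell vegetation class proportions, area of
the containing patch, mean distance to the nearest three patches of the same
class, and distances to the nearest road and permanent water line.

Coordinates are planar metres in an already-projected system.  Rasters use a
lower-left origin with pixel (row, col) covering the half-open square
``[x0 + col*s, x0 + (col+1)*s) x [y0 + row*s, y0 + (row+1)*s)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint

__all__ = [
    "VEGETATION_CLASSES",
    "CategoricalRaster",
    "PatchSet",
    "LandscapeGrid",
    "Standardizer",
    "label_patches",
    "build_grid",
    "nearest3_patch_distance",
    "distance_to_lines",
    "standardize",
    "vif_screen",
    "minimum_convex_polygon",
    "draw_availability_points",
]

#: Vegetation classes, coded 1..8 in categorical rasters.
VEGETATION_CLASSES = (
    "lowland_forest",
    "deciduous_forest",
    "coniferous_forest",
    "mixed_forest",
    "grass_shrub",
    "pasture",
    "cropland",
    "wetland",
)

#: Default cell area: mean telemetry error ellipse of the study design (m^2).
DEFAULT_CELL_AREA_M2 = 2115.0

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class CategoricalRaster:
    """Categorical vegetation raster with class codes 1..n_classes."""

    values: np.ndarray           # (n_rows, n_cols) integer class codes
    origin: tuple[float, float]  # lower-left corner (x0, y0), metres
    pixel_size: float            # metres
    n_classes: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        x0, y0 = self.origin
        nr, nc = self.values.shape
        return (x0, y0, x0 + nc * self.pixel_size, y0 + nr * self.pixel_size)

    def pixel_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        s = self.pixel_size
        return x0 + (np.asarray(col) + 0.5) * s, y0 + (np.asarray(row) + 0.5) * s

    def class_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Class code of the pixel containing each point (half-open membership)."""
        row, col = self._rowcol(x, y)
        return self.values[row, col]

    def _rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - y0) / self.pixel_size).astype(int)
        nr, nc = self.values.shape
        if np.any((row < 0) | (row >= nr) | (col < 0) | (col >= nc)):
            raise ValueError("point outside raster extent")
        return row, col


@dataclass
class PatchSet:
    """4-connected vegetation patches of a categorical raster.

    ``labels`` assigns every pixel a global patch id in 1..n_patches; patch
    ids are contiguous and each patch belongs to exactly one class.
    """

    raster: CategoricalRaster
    labels: np.ndarray          # (n_rows, n_cols) global patch ids, 1-based
    patch_class: np.ndarray     # (n_patches,) class code per patch
    patch_area_km2: np.ndarray  # (n_patches,)
    boundary_xy: list           # per patch: (k, 2) array of boundary pixel centres

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)

    def patch_at(self, x, y) -> np.ndarray:
        row, col = self.raster._rowcol(x, y)
        return self.labels[row, col]


def label_patches(raster: CategoricalRaster) -> PatchSet:
    """Label 4-connected (rook) same-class patches.

    Rook connectivity is the conservative choice: diagonally touching pixels
    of the same class are distinct patches.
    """
    values = raster.values
    labels = np.zeros(values.shape, dtype=np.int64)
    patch_class: list[int] = []
    offset = 0
    for cls in np.unique(values):
        mask = values == cls
        lab, n = ndimage.label(mask, structure=_ROOK)
        labels[mask] = lab[mask] + offset
        patch_class.extend([int(cls)] * n)
        offset += n

    patch_class_arr = np.asarray(patch_class, dtype=np.int32)
    counts = np.bincount(labels.ravel(), minlength=offset + 1)[1:]
    area_km2 = counts * (raster.pixel_size**2) / 1e6

    # boundary pixels: pixels with at least one rook neighbour in another patch
    # (raster border pixels count as boundary)
    padded = np.pad(labels, 1, constant_values=0)
    interior = (
        (padded[:-2, 1:-1] == labels)
        & (padded[2:, 1:-1] == labels)
        & (padded[1:-1, :-2] == labels)
        & (padded[1:-1, 2:] == labels)
    )
    brow, bcol = np.nonzero(~interior)
    bx, by = raster.pixel_center(brow, bcol)
    blab = labels[brow, bcol]
    order = np.argsort(blab, kind="stable")
    blab, bx, by = blab[order], bx[order], by[order]
    splits = np.searchsorted(blab, np.arange(2, offset + 1))
    boundary_xy = [
        np.column_stack(p) for p in zip(np.split(bx, splits), np.split(by, splits))
    ]
    return PatchSet(raster, labels, patch_class_arr, area_km2, boundary_xy)


@dataclass
class LandscapeGrid:
    """Square-cell analysis grid with per-cell covariates.

    ``cells`` has one row per cell (row-major order) with columns:
    ``cell_id, row, col, x, y`` (centroid), ``prop_<class>`` for the 8
    vegetation classes, ``patch_area_km2, nearest_patch_km, dist_road_m,
    dist_water_m``.
    """

    origin: tuple[float, float]
    cell_side: float
    n_rows: int
    n_cols: int
    cells: pd.DataFrame = field(repr=False)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_side**2

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_index(self, x, y) -> np.ndarray:
        """Row-major cell id for points; half-open [x0, x0+side) membership."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.cell_side).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - y0) / self.cell_side).astype(int)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        if not np.all(ok):
            raise ValueError("point outside grid extent")
        return row * self.n_cols + col


def _overlap_matrix(n_cells: int, cell_side: float, n_pix: int, pixel_size: float) -> np.ndarray:
    """1-D overlap lengths between grid-cell intervals and pixel intervals."""
    out = np.zeros((n_cells, n_pix))
    c0 = np.arange(n_cells) * cell_side
    c1 = c0 + cell_side
    p0 = np.arange(n_pix) * pixel_size
    p1 = p0 + pixel_size
    lo = np.maximum(c0[:, None], p0[None, :])
    hi = np.minimum(c1[:, None], p1[None, :])
    np.maximum(hi - lo, 0.0, out=out)
    return out


def build_grid(
    raster: CategoricalRaster,
    roads: list[LineString] | None = None,
    water: list[LineString] | None = None,
    cell_area_m2: float = DEFAULT_CELL_AREA_M2,
    patches: PatchSet | None = None,
) -> LandscapeGrid:
    """Tile the raster extent with square cells and compute all covariates.

    Vegetation proportions are the exact area-weighted overlay of the raster
    pixels on each cell.  Patch metrics and line distances are evaluated at
    the geometric centroid of each cell.  Cells that would extend past the
    raster extent are dropped so every retained cell is fully covered.
    """
    if cell_area_m2 <= 0:
        raise ValueError("cell_area_m2 must be positive")
    side = float(np.sqrt(cell_area_m2))
    xmin, ymin, xmax, ymax = raster.extent
    n_rows = int((ymax - ymin) / side)
    n_cols = int((xmax - xmin) / side)
    if n_rows < 1 or n_cols < 1:
        raise ValueError("extent smaller than one grid cell")

    ry = _overlap_matrix(n_rows, side, raster.shape[0], raster.pixel_size)
    rx = _overlap_matrix(n_cols, side, raster.shape[1], raster.pixel_size)

    props = np.empty((n_rows * n_cols, raster.n_classes))
    for k in range(raster.n_classes):
        mask = (raster.values == k + 1).astype(float)
        overlay = ry @ mask @ rx.T  # (n_rows, n_cols) areas
        props[:, k] = overlay.ravel() / cell_area_m2

    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    cx = raster.origin[0] + (cols + 0.5) * side
    cy = raster.origin[1] + (rows + 0.5) * side

    cells = pd.DataFrame({"cell_id": np.arange(n_rows * n_cols), "row": rows, "col": cols,
                          "x": cx, "y": cy})
    for k, name in enumerate(VEGETATION_CLASSES[: raster.n_classes]):
        cells[f"prop_{name}"] = props[:, k]

    if patches is None:
        patches = label_patches(raster)
    pid = patches.patch_at(cx, cy)
    cells["patch_area_km2"] = patches.patch_area_km2[pid - 1]
    cells["nearest_patch_km"] = nearest3_patch_distance(
        np.column_stack([cx, cy]), patches
    )
    if roads is not None:
        cells["dist_road_m"] = distance_to_lines(np.column_stack([cx, cy]), roads)
    if water is not None:
        cells["dist_water_m"] = distance_to_lines(np.column_stack([cx, cy]), water)
    return LandscapeGrid((raster.origin[0], raster.origin[1]), side, n_rows, n_cols, cells)


def nearest3_patch_distance(
    points: np.ndarray, patches: PatchSet, k: int = 3
) -> np.ndarray:
    """Mean distance (km) from each point to the nearest k other same-class patches.

    The containing patch is excluded; the distance to a patch is the minimum
    Euclidean distance from the point to the patch's boundary pixel centres.
    With fewer than k other patches of the class, the mean is over those
    available; with none, NaN is returned (and a warning issued).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    own = patches.patch_at(points[:, 0], points[:, 1])
    own_class = patches.patch_class[own - 1]

    out = np.full(len(points), np.nan)
    n_missing = 0
    for cls in np.unique(own_class):
        sel = np.nonzero(own_class == cls)[0]
        class_pids = np.nonzero(patches.patch_class == cls)[0] + 1
        if len(class_pids) < 2:
            n_missing += len(sel)
            continue
        bxy = np.concatenate([patches.boundary_xy[p - 1] for p in class_pids])
        blab = np.concatenate(
            [np.full(len(patches.boundary_xy[p - 1]), p) for p in class_pids]
        )
        # min distance point -> each patch of the class, then mean of k smallest
        d2 = ((points[sel, None, :] - bxy[None, :, :]) ** 2).sum(axis=2)
        local = np.searchsorted(class_pids, blab)  # compact patch index
        dmin = np.full((len(sel), len(class_pids)), np.inf)
        np.minimum.at(dmin, (np.arange(len(sel))[:, None], local[None, :]), d2)
        dmin = np.sqrt(dmin)
        own_local = np.searchsorted(class_pids, own[sel])
        dmin[np.arange(len(sel)), own_local] = np.inf
        dmin.sort(axis=1)
        kk = min(k, len(class_pids) - 1)
        out[sel] = dmin[:, :kk].mean(axis=1) / 1000.0
    if n_missing:
        warnings.warn(
            f"{n_missing} points in classes with no other patch; nearest-patch "
            "distance set to NaN",
            stacklevel=2,
        )
    return out


def distance_to_lines(points: np.ndarray, lines: list[LineString]) -> np.ndarray:
    """Minimum Euclidean distance (m) from each point to a set of polylines."""
    if not lines:
        raise ValueError("empty polyline set")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    geoms = shapely.points(points[:, 0], points[:, 1])
    union = shapely.union_all([shapely.geometry.shape(l) if isinstance(l, dict) else l
                               for l in lines])
    return shapely.distance(geoms, union)


class Standardizer:
    """Column-wise z-scoring with frozen means and (sample) SDs.

    The fit sample's means/SDs are stored so that grid-cell covariates can be
    put on exactly the scale the model was fitted on.
    """

    def __init__(self) -> None:
        self.means: dict[str, float] = {}
        self.sds: dict[str, float] = {}
        self.dropped: list[str] = []

    def fit(self, table: pd.DataFrame, columns: list[str]) -> "Standardizer":
        for c in columns:
            x = table[c].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1))
            if sd <= 0 or not np.isfinite(sd):
                warnings.warn(f"zero-variance column dropped: {c}", stacklevel=2)
                self.dropped.append(c)
                continue
            self.means[c] = float(np.mean(x))
            self.sds[c] = sd
        return self

    @property
    def columns(self) -> list[str]:
        return list(self.means)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.columns:
            if c not in out.columns:
                raise KeyError(f"covariate missing from table: {c}")
            out[c] = (out[c].to_numpy(dtype=float) - self.means[c]) / self.sds[c]
        return out

    def fit_transform(self, table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
        return self.fit(table, columns).transform(table)


def standardize(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, Standardizer]:
    """z-score the named columns jointly over all rows (used and available)."""
    st = Standardizer()
    return st.fit_transform(table, columns), st


def vif_screen(
    table: pd.DataFrame, columns: list[str], threshold: float = 7.0
) -> pd.DataFrame:
    """Variance inflation factors; VIF_j = 1/(1-R2_j) from OLS of j on the rest.

    Returns a frame with columns ``covariate, vif, retained`` (retained is
    False where VIF >= threshold).  A perfectly collinear column yields an
    infinite VIF.
    """
    if len(columns) < 2:
        raise ValueError("need at least 2 covariates for a VIF screen")
    X = table[columns].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than covariates")
    vifs = []
    for j in range(X.shape[1]):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        vifs.append(np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2))
    out = pd.DataFrame({"covariate": columns, "vif": vifs})
    out["retained"] = out["vif"] < threshold
    return out


def minimum_convex_polygon(points: np.ndarray):
    """100% minimum convex polygon (convex hull) of a point set."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return MultiPoint(points).convex_hull


def draw_availability_points(
    points: np.ndarray, n: int, seed: int
) -> np.ndarray:
    """Uniform random points inside the MCP of the telemetry points.

    Availability is defined over the 100% minimum convex polygon of all fawn
    radiolocations; sampling is by rejection from the bounding box.
    """
    mcp = minimum_convex_polygon(points)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = mcp.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(max(2 * n, 64), 2))
        inside = shapely.contains_xy(mcp, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
    return out[:n]
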