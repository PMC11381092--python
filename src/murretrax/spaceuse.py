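"""Kernel utilization distributions, isopleths and Bhattacharyya overlap.

Foraging locations (DIVE-state fixes) are projected to an azimuthal
equidistant plane centred on the colony and smoothed with an isotropic
bivariate-normal kernel on a metric grid (800 m cells by default).  The
bandwidth is the ad hoc reference ("href") rule

    h = (sd_x + sd_y)/2 * n^(-1/6).

The p% isopleth is the smallest set of cells (ranked by density) holding p
of the probability mass; its area is the cell count times the cell area.
Bhattacharyya affinity between two UDs on a common grid is
BA = sum sqrt(p1*p2) * cell^2, ranging 0 (disjoint) to 1 (identical).
Following the convention of comparing overall foraging areas, BA is by
default computed on each UD masked to its 95% isopleth and renormalized;
the unmasked variant is one flag away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .geodesy import aeqd_project


@dataclass
class UtilizationDistribution:
    """Normalized density on a planar grid.

    ``density[iy, ix]`` is probability per m^2 at the cell centred on
    ``(x0 + (ix+0.5)*cell_m, y0 + (iy+0.5)*cell_m)``; sums to 1 when
    multiplied by cell_m^2.
    """

    grid_origin: tuple    # (x0, y0) metres, lower-left corner
    cell_m: float
    density: np.ndarray
    crs_note: str = "aeqd-sphere-6371km"

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if abs(self.mass() - 1.0) > 1e-6:
            raise ValueError("density must integrate to 1")

    def mass(self) -> float:
        return float(self.density.sum() * self.cell_m ** 2)

    def x_centers(self) -> np.ndarray:
        nx = self.density.shape[1]
        return self.grid_origin[0] + (np.arange(nx) + 0.5) * self.cell_m

    def y_centers(self) -> np.ndarray:
        ny = self.density.shape[0]
        return self.grid_origin[1] + (np.arange(ny) + 0.5) * self.cell_m


def foraging_points(sequences, deployments, config: PipelineConfig | None = None) -> np.ndarray:
    """DIVE-state fix locations as (n, 2) projected metres.

    Locations decoded as swimming, flying or at the colony are excluded;
    the caller pools per stratum (year x breeding stage) before calling.
    """
    config = config or PipelineConfig()
    lon0, lat0 = config.colony_lon_lat
    xs, ys = [], []
    for seq, dep in zip(sequences, deployments):
        mask = np.asarray(seq.states) == "DIVE"
        if not mask.any():
            continue
        lon = dep.fixes["lon"].to_numpy(dtype=float)[mask]
        lat = dep.fixes["lat"].to_numpy(dtype=float)[mask]
        x, y = aeqd_project(lon, lat, lon0, lat0)
        xs.append(x)
        ys.append(y)
    if not xs:
        raise ValueError("no DIVE-state fixes in this stratum")
    return np.column_stack([np.concatenate(xs), np.concatenate(ys)])


def href_bandwidth(points: np.ndarray) -> float:
    """Reference bandwidth h = mean(sd_x, sd_y) * n^(-1/6), metres."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least two points")
    sd = points.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("degenerate point set: zero spread")
    return float(sd.mean() * n ** (-1.0 / 6.0))


def kde_ud(points: np.ndarray, h: float, cell_m: float = 800.0,
           pad_factor: float = 3.0) -> UtilizationDistribution:
    """Gaussian-kernel UD of a point set on a metric grid.

    The grid pads the point bounding box by ``pad_factor * h`` on every
    side and the result is renormalized so truncation never breaks the
    unit-mass invariant.
    """
    points = np.asarray(points, dtype=float)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    xmin, ymin = points.min(axis=0) - pad_factor * h
    xmax, ymax = points.max(axis=0) + pad_factor * h
    if cell_m >= max(xmax - xmin, ymax - ymin):
        raise ValueError("cell size exceeds the domain extent")
    nx = int(np.ceil((xmax - xmin) / cell_m))
    ny = int(np.ceil((ymax - ymin) / cell_m))
    xc = xmin + (np.arange(nx) + 0.5) * cell_m
    yc = ymin + (np.arange(ny) + 0.5) * cell_m
    # separable kernel: density = Gy @ Gx^T / (2 pi h^2 n)
    gx = np.exp(-0.5 * ((xc[:, None] - points[None, :, 0]) / h) ** 2)
    gy = np.exp(-0.5 * ((yc[:, None] - points[None, :, 1]) / h) ** 2)
    dens = (gy @ gx.T) / (2.0 * np.pi * h ** 2 * len(points))
    dens /= dens.sum() * cell_m ** 2
    return UtilizationDistribution(grid_origin=(float(xmin), float(ymin)),
                                   cell_m=float(cell_m), density=dens)


def isopleth_mask(ud: UtilizationDistribution, fraction: float) -> np.ndarray:
    """Boolean grid: smallest cell set with cumulative mass >= fraction."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    p = ud.density.ravel() * ud.cell_m ** 2
    order = np.argsort(p)[::-1]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, fraction) + 1)
    mask = np.zeros(p.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.density.shape)


def isopleth_area(ud: UtilizationDistribution, fraction: float) -> float:
    """Area (km^2) of the ``fraction`` isopleth by ranked-cell accumulation."""
    return float(isopleth_mask(ud, fraction).sum() * ud.cell_m ** 2 / 1e6)


def _resample_to(ud: UtilizationDistribution, x0, y0, nx, ny, cell_m) -> np.ndarray:
    """Nearest-cell lookup of a (piecewise-constant) UD on a target grid."""
    xc = x0 + (np.arange(nx) + 0.5) * cell_m
    yc = y0 + (np.arange(ny) + 0.5) * cell_m
    ix = np.floor((xc - ud.grid_origin[0]) / ud.cell_m).astype(int)
    iy = np.floor((yc - ud.grid_origin[1]) / ud.cell_m).astype(int)
    out = np.zeros((ny, nx))
    okx = (ix >= 0) & (ix < ud.density.shape[1])
    oky = (iy >= 0) & (iy < ud.density.shape[0])
    out[np.ix_(oky, okx)] = ud.density[np.ix_(iy[oky], ix[okx])]
    return out


def _common_grid(ud1, ud2, allow_resample):
    same = (ud1.cell_m == ud2.cell_m
            and ud1.grid_origin == ud2.grid_origin
            and ud1.density.shape == ud2.density.shape)
    if same:
        return ud1.density.copy(), ud2.density.copy(), ud1.cell_m
    if not allow_resample:
        raise ValueError("UD grids differ; enable allow_resample to compare them")
    cell = min(ud1.cell_m, ud2.cell_m)
    x0 = min(ud1.grid_origin[0], ud2.grid_origin[0])
    y0 = min(ud1.grid_origin[1], ud2.grid_origin[1])
    x1 = max(ud1.grid_origin[0] + ud1.density.shape[1] * ud1.cell_m,
             ud2.grid_origin[0] + ud2.density.shape[1] * ud2.cell_m)
    y1 = max(ud1.grid_origin[1] + ud1.density.shape[0] * ud1.cell_m,
             ud2.grid_origin[1] + ud2.density.shape[0] * ud2.cell_m)
    nx = int(np.ceil((x1 - x0) / cell))
    ny = int(np.ceil((y1 - y0) / cell))
    p1 = _resample_to(ud1, x0, y0, nx, ny, cell)
    p2 = _resample_to(ud2, x0, y0, nx, ny, cell)
    return p1, p2, cell


def bhattacharyya(ud1: UtilizationDistribution, ud2: UtilizationDistribution,
                  mask_fraction: float | None = 0.95,
                  allow_resample: bool = True) -> float:
    """Bhattacharyya affinity between two UDs, in [0, 1].

    With ``mask_fraction`` set (default 0.95) each UD is first restricted
    to its own isopleth at that fraction and renormalized, so the index
    compares overall foraging areas; pass None for the unmasked affinity.
    """
    if mask_fraction is not None:
        m1 = isopleth_mask(ud1, mask_fraction)
        m2 = isopleth_mask(ud2, mask_fraction)
        ud1 = _masked_renorm(ud1, m1)
        ud2 = _masked_renorm(ud2, m2)
    p1, p2, cell = _common_grid(ud1, ud2, allow_resample)
    p1 = p1 / max(p1.sum() * cell ** 2, 1e-300)
    p2 = p2 / max(p2.sum() * cell ** 2, 1e-300)
    ba = float(np.sqrt(p1 * p2).sum() * cell ** 2)
    return float(np.clip(ba, 0.0, 1.0))


def _masked_renorm(ud: UtilizationDistribution, mask: np.ndarray) -> UtilizationDistribution:
    dens = np.where(mask, ud.density, 0.0)
    dens /= dens.sum() * ud.cell_m ** 2
    return UtilizationDistribution(grid_origin=ud.grid_origin, cell_m=ud.cell_m,
                                   density=dens, crs_note=ud.crs_note)


# ---------------------------------------------------------------------------
# text-format export

def write_ascii_grid(ud: UtilizationDistribution, path) -> None:
    """ESRI ASCII grid (density per m^2; row order north to south)."""
    ny, nx = ud.density.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcorner {ud.grid_origin[0]:.3f}\nyllcorner {ud.grid_origin[1]:.3f}\n")
        fh.write(f"cellsize {ud.cell_m:.3f}\nNODATA_value -9999\n")
        for row in ud.density[::-1]:
            fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")


def read_ascii_grid(path) -> UtilizationDistribution:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        dens = np.loadtxt(fh)
    dens = np.atleast_2d(dens)[::-1]
    return UtilizationDistribution(
        grid_origin=(hdr["xllcorner"], hdr["yllcorner"]),
        cell_m=hdr["cellsize"], density=dens)


def isopleth_polygons(ud: UtilizationDistribution, fraction: float):
    """Isopleth cell set as a shapely (multi)polygon, for GeoJSON export."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    mask = isopleth_mask(ud, fraction)
    x0, y0 = ud.grid_origin
    c = ud.cell_m
    boxes = [box(x0 + ix * c, y0 + iy * c, x0 + (ix + 1) * c, y0 + (iy + 1) * c)
             for iy, ix in zip(*np.nonzero(mask))]
    return unary_union(boxes)


def write_isopleth_geojson(ud: UtilizationDistribution, fractions, path) -> None:
    """One GeoJSON feature per isopleth fraction (projected-metre coords)."""
    import json

    from shapely.geometry import mapping

    features = []
    for f in fractions:
        poly = isopleth_polygons(ud, f)
        features.append({"type": "Feature",
                         "properties": {"fraction": f, "crs_note": ud.crs_note},
                         "geometry": mapping(poly)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
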