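"""Kernel utilisation distributions and 95% home ranges.

The kernel utilisation distribution (KUD) is the smoothed probability
density of relocating an animal at a point, estimated with an isotropic
bivariate Gaussian kernel. The smoothing parameter is the reference
bandwidth

    h_ref = sigma_hat * n^(-1/6),   sigma_hat = sqrt((var_x + var_y) / 2)

— the bivariate normal-reference rule that scales with the coordinate
spread and shrinks slowly with the number of relocations. The home range
at level p (default 0.95) is the smallest region capturing probability p:
the density threshold is found by accumulating grid cells from densest
down, and the iso-contour at that threshold is polygonised by marching
squares. Note the kernel inflates the true utilisation spread by ~h² per
axis, so KUD areas slightly overestimate the underlying 95% region and
converge to it as n grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure

from .airfield_geometry import SurfaceMap

logger = logging.getLogger(__name__)


def href_bandwidth(points) -> float:
    """Normal-reference bandwidth h_ref (metres) for a 2-D point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 10:
        raise ValueError("need at least 10 relocations for a bandwidth")
    var = pts.var(axis=0, ddof=1)
    sigma = float(np.sqrt(0.5 * (var[0] + var[1])))
    if sigma == 0.0:
        raise ValueError("all relocations identical; bandwidth undefined")
    return sigma * n ** (-1.0 / 6.0)


@dataclass
class GridConfig:
    n_cells: int = 200          # cells per axis before the cell-size cap
    margin_in_h: float = 3.0    # bounding-box expansion per side, in units of h
    max_cell_in_h: float = 0.5  # cell size refined until <= this fraction of h


@dataclass
class UtilisationDistribution:
    animal_id: str
    x: np.ndarray          # cell-centre eastings, length nx
    y: np.ndarray          # cell-centre northings, length ny
    density: np.ndarray    # (ny, nx) probability density per m^2
    h: float               # bandwidth, m
    n_points: int

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def total_probability(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class HomeRange:
    animal_id: str
    level: float
    geometry: MultiPolygon
    area_ha: float
    habitat_proportions: dict[str, float] = field(default_factory=dict)


def kernel_ud(
    points,
    h: float,
    animal_id: str = "",
    grid: GridConfig | None = None,
) -> UtilisationDistribution:
    """Gaussian-kernel density of relocations on a regular grid.

    The grid covers the point bounding box expanded by ``margin_in_h × h``
    per side and is refined until the cell size is at most
    ``max_cell_in_h × h``. The density is renormalised on the grid so that
    Σ density × cell_area = 1.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.asarray(points, dtype=float)
    grid = grid or GridConfig()
    margin = grid.margin_in_h * h
    x0, x1 = pts[:, 0].min() - margin, pts[:, 0].max() + margin
    y0, y1 = pts[:, 1].min() - margin, pts[:, 1].max() + margin
    nx = max(grid.n_cells, int(np.ceil((x1 - x0) / (grid.max_cell_in_h * h))))
    ny = max(grid.n_cells, int(np.ceil((y1 - y0) / (grid.max_cell_in_h * h))))
    xs = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    ys = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    if (xs[1] - xs[0]) > h or (ys[1] - ys[0]) > h:
        logger.warning("grid cell larger than bandwidth; contours will be coarse")

    # separable Gaussian: density = Ay^T @ Ax with per-point column factors
    ax = np.exp(-((xs[None, :] - pts[:, 0:1]) ** 2) / (2.0 * h * h))
    ay = np.exp(-((ys[None, :] - pts[:, 1:2]) ** 2) / (2.0 * h * h))
    density = (ay.T @ ax) / (pts.shape[0] * 2.0 * np.pi * h * h)

    cell_area = float((xs[1] - xs[0]) * (ys[1] - ys[0]))
    total = density.sum() * cell_area
    if total <= 0:
        raise ValueError("grid excludes all probability mass")
    density /= total
    return UtilisationDistribution(
        animal_id=animal_id, x=xs, y=ys, density=density, h=h, n_points=pts.shape[0]
    )


def _rings_to_multipolygon(rings: list[np.ndarray]) -> MultiPolygon:
    """Assemble closed contour rings into polygons with holes by containment parity."""
    polys = [Polygon(r) for r in rings if len(r) >= 4]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    polys = [p for p in polys if p.area > 0]
    polys.sort(key=lambda p: p.area, reverse=True)
    shells: list[Polygon] = []
    holes: list[Polygon] = []
    for p in polys:
        depth = sum(1 for q in polys if q.area > p.area and q.contains(p))
        (shells if depth % 2 == 0 else holes).append(p)
    geom = unary_union(shells)
    if holes:
        geom = geom.difference(unary_union(holes))
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def contour_home_range(
    ud: UtilisationDistribution, level: float = 0.95
) -> HomeRange:
    """Smallest region capturing ``level`` of the utilisation distribution.

    Grid cells are accumulated from densest downward until the target
    probability is reached; the density of the last admitted cell is the
    contour threshold, polygonised by marching squares.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    flat = np.sort(ud.density.ravel())[::-1]
    cum = np.cumsum(flat) * ud.cell_area
    idx = int(np.searchsorted(cum, level))
    threshold = float(flat[min(idx, flat.size - 1)])

    # pad with zeros so contours touching the grid edge close properly
    dx = float(ud.x[1] - ud.x[0])
    dy = float(ud.y[1] - ud.y[0])
    padded = np.pad(ud.density, 1, mode="constant")
    rings = []
    for contour in measure.find_contours(padded, threshold):
        # array coords (row=y, col=x), padded by one cell
        xy = np.column_stack(
            [
                ud.x[0] + (contour[:, 1] - 1.0) * dx,
                ud.y[0] + (contour[:, 0] - 1.0) * dy,
            ]
        )
        rings.append(xy)
    geom = _rings_to_multipolygon(rings)
    return HomeRange(
        animal_id=ud.animal_id,
        level=level,
        geometry=geom,
        area_ha=geom.area / 1e4,
    )


def habitat_composition(hr: HomeRange, smap: SurfaceMap) -> dict[str, float]:
    """Fraction of home-range area per habitat class.

    Area not covered by any mapped surface polygon — including area beyond
    the airfield boundary — is reported under ``"outside"``. Fractions sum
    to 1. The result is also stored on ``hr.habitat_proportions``.
    """
    total = hr.geometry.area
    if total <= 0:
        raise ValueError("home range has zero area")
    props: dict[str, float] = {}
    covered = 0.0
    classes = sorted({p.habitat_class for p in smap.polygons})
    for cls in classes:
        union = unary_union([p.geometry for p in smap.polygons if p.habitat_class == cls])
        a = hr.geometry.intersection(union).area
        props[cls] = a / total
        covered += a
    props["outside"] = max(0.0, (total - covered) / total)
    hr.habitat_proportions = props
    return props


def ud_to_ascii_grid(ud: UtilisationDistribution) -> str:
    """Serialise a UD as an ESRI ASCII grid (plain text)."""
    dx = float(ud.x[1] - ud.x[0])
    header = (
        f"ncols {ud.x.size}\n"
        f"nrows {ud.y.size}\n"
        f"xllcorner {ud.x[0] - dx / 2.0}\n"
        f"yllcorner {ud.y[0] - dx / 2.0}\n"
        f"cellsize {dx}\n"
        f"NODATA_value -9999\n"
    )
    body = "\n".join(
        " ".join(f"{v:.6e}" for v in row) for row in ud.density[::-1]
    )
    return header + body + "\n"
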