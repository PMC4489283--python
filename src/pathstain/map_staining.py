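"""Map staining: Voronoi territories around map entities, colored by data.

Every entity position on the map is a Voronoi site; the territory of an
entity is the convex polygon of canvas points closer to it than to any other
site.  Cells are clipped to the canvas rectangle, then post-processed to
avoid overly large polygons (sparse regions of a map otherwise produce huge
territories that dominate the picture): each cell is intersected with an
axis-aligned square centered on its site whose half-width defaults to
3x the median nearest-neighbor distance between sites.  Finally each cell is
filled with the color of its entity's data value, which makes large-scale
trends (e.g. a whole transcriptome) readable at the top zoom level where
individual entities are too small to inspect.

Bounded cells are obtained by reflecting the sites across the four canvas
edges before the Voronoi construction: every original site's cell is then
finite and its clip against the canvas is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .color_render import ColorScale, value_to_color
from .map_model import NetworkMap, canonical_symbol

__all__ = [
    "VoronoiCell",
    "StainingLayer",
    "compute_voronoi",
    "limit_cell_extent",
    "build_staining_layer",
    "staining_to_svg",
]

#: Fill used when a cell's entity has no mapped value: neutral light gray.
UNSTAINED_FILL = None
UNSTAINED_RENDER_COLOR = (230, 230, 230, 0)


@dataclass(frozen=True)
class VoronoiCell:
    """One entity territory.

    ``entity_ids`` lists every entity anchored at this site (coincident sites
    are merged); ``site_entity_id`` is the first of them.  ``polygon`` is a
    shapely Polygon, convex before extent limiting, always a subset of the
    canvas rectangle.
    """

    site_entity_id: str
    entity_ids: tuple[str, ...]
    site: tuple[float, float]
    polygon: Polygon
    clipped: bool = False

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def vertices(self) -> list[tuple[float, float]]:
        return list(self.polygon.exterior.coords)[:-1]


def _cell_polygon(site: np.ndarray, verts: np.ndarray, canvas_box: Polygon) -> Polygon:
    # convex cell: order vertices by angle around the site
    ang = np.arctan2(verts[:, 1] - site[1], verts[:, 0] - site[0])
    poly = Polygon(verts[np.argsort(ang)])
    return poly.intersection(canvas_box)


def compute_voronoi(
    sites: list[tuple[str, float, float]], canvas: tuple[float, float]
) -> list[VoronoiCell]:
    """Voronoi tessellation of the canvas by entity sites.

    The returned cells tile the canvas exactly (areas sum to width x height
    up to geometric tolerance) and every canvas point lies in the cell of its
    Euclidean-nearest site.  Coincident sites are merged into one cell owning
    all their entity ids.
    """
    width, height = canvas
    if not sites:
        raise ValueError("at least one site is required")
    for eid, x, y in sites:
        if not (0 <= x <= width and 0 <= y <= height):
            raise ValueError(
                f"site {eid!r} at ({x}, {y}) outside {width}x{height} canvas"
            )

    # merge coincident coordinates
    merged: dict[tuple[float, float], list[str]] = {}
    for eid, x, y in sites:
        merged.setdefault((float(x), float(y)), []).append(eid)
    coords = list(merged)
    owners = [tuple(merged[c]) for c in coords]
    canvas_box = box(0.0, 0.0, width, height)

    if len(coords) == 1:
        (x, y) = coords[0]
        return [
            VoronoiCell(
                site_entity_id=owners[0][0],
                entity_ids=owners[0],
                site=(x, y),
                polygon=canvas_box,
            )
        ]

    pts = np.asarray(coords, dtype=float)
    mirrored = np.vstack(
        [
            pts,
            pts * [-1, 1],                         # across x = 0
            pts * [-1, 1] + [2 * width, 0],        # across x = width
            pts * [1, -1],                         # across y = 0
            pts * [1, -1] + [0, 2 * height],       # across y = height
        ]
    )
    vor = Voronoi(mirrored)
    cells = []
    for i, (xy, eids) in enumerate(zip(pts, owners)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # pragma: no cover - mirrors guarantee finite
            raise RuntimeError(f"unbounded Voronoi cell for site {eids[0]!r}")
        poly = _cell_polygon(xy, vor.vertices[region], canvas_box)
        cells.append(
            VoronoiCell(
                site_entity_id=eids[0],
                entity_ids=eids,
                site=(float(xy[0]), float(xy[1])),
                polygon=poly,
            )
        )
    return cells


def _median_nn_distance(cells: list[VoronoiCell]) -> float:
    pts = np.asarray([c.site for c in cells], dtype=float)
    if len(pts) < 2:
        return math.inf
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    return float(np.median(np.sqrt(d2.min(axis=1))))


def limit_cell_extent(
    cells: list[VoronoiCell],
    radius_factor: float = 3.0,
    radius: float | None = None,
) -> list[VoronoiCell]:
    """Clip each cell to the square of half-width R centered on its site.

    R is ``radius`` when given, otherwise ``radius_factor`` times the median
    nearest-neighbor distance between sites — a scale-free rule that trims
    the oversized territories of isolated entities while leaving dense map
    regions untouched.  Contractive (output cells are subsets of inputs) and
    idempotent.
    """
    if radius is None:
        if radius_factor <= 0:
            raise ValueError("radius_factor must be positive")
        r = radius_factor * _median_nn_distance(cells)
    else:
        if radius <= 0:
            raise ValueError("radius must be positive")
        r = radius
    if math.isinf(r):
        return list(cells)
    out = []
    for cell in cells:
        x, y = cell.site
        clip = box(x - r, y - r, x + r, y + r)
        poly = cell.polygon.intersection(clip)
        changed = cell.clipped or abs(poly.area - cell.polygon.area) > 1e-9 * max(
            1.0, cell.polygon.area
        )
        out.append(replace(cell, polygon=poly, clipped=changed))
    return out


@dataclass
class StainingLayer:
    """Computed staining: cells plus a fill (RGBA or None=unstained) per cell."""

    cells: list[VoronoiCell]
    fills: list[tuple[int, int, int, int] | None]
    values: list[float | None]
    opacity: float
    background_mode: str = "bw"

    def __post_init__(self) -> None:
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError("opacity must be in [0, 1]")
        if self.background_mode not in ("bw", "color"):
            raise ValueError("background_mode must be 'bw' or 'color'")
        if len(self.fills) != len(self.cells) or len(self.values) != len(self.cells):
            raise ValueError("one fill and one value required per cell")


def build_staining_layer(
    nmap: NetworkMap,
    gene_values: dict[str, float],
    scale: ColorScale,
    opacity: float = 0.6,
    background_mode: str = "bw",
    radius_factor: float = 3.0,
) -> StainingLayer:
    """Stain the map by per-gene values.

    Every map entity is its own site (aliases of one gene get identical
    fills by construction).  An entity's value is the mean over its symbols
    that carry a value; entities with no valued symbol stay unstained —
    absence of data is a normal state, rendered as neutral light gray.
    The map decorations are meant to be drawn black-and-white underneath
    (``background_mode="bw"``) so entity colors do not mix with the stain.
    """
    values = {canonical_symbol(k): float(v) for k, v in gene_values.items()}
    sites = [(e.entity_id, e.position[0], e.position[1]) for e in nmap.entities]
    cells = compute_voronoi(sites, (nmap.canvas_width, nmap.canvas_height))
    cells = limit_cell_extent(cells, radius_factor=radius_factor)

    by_id = {e.entity_id: e for e in nmap.entities}
    fills: list[tuple[int, int, int, int] | None] = []
    cell_values: list[float | None] = []
    for cell in cells:
        vs = [
            values[s]
            for eid in cell.entity_ids
            for s in by_id[eid].hugo_symbols
            if s in values
        ]
        if vs:
            v = float(np.mean(vs))
            cell_values.append(v)
            fills.append(value_to_color(scale, v))
        else:
            cell_values.append(None)
            fills.append(UNSTAINED_FILL)
    return StainingLayer(
        cells=cells,
        fills=fills,
        values=cell_values,
        opacity=opacity,
        background_mode=background_mode,
    )


def _poly_points(poly: Polygon) -> str:
    return " ".join(f"{x:.2f},{y:.2f}" for x, y in poly.exterior.coords)


def staining_to_svg(layer: StainingLayer, canvas: tuple[float, float]) -> str:
    """Staining layer as a standalone SVG document (one <polygon> per cell)."""
    width, height = canvas
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:g}" '
        f'height="{height:g}" viewBox="0 0 {width:g} {height:g}">'
    ]
    for cell, fill in zip(layer.cells, layer.fills):
        if cell.polygon.is_empty:
            continue
        if fill is None:
            rgb, alpha = UNSTAINED_RENDER_COLOR[:3], 0.0
        else:
            rgb, alpha = fill[:3], layer.opacity * fill[3] / 255.0
        polys = getattr(cell.polygon, "geoms", [cell.polygon])
        for poly in polys:
            parts.append(
                f'<polygon points="{_poly_points(poly)}" '
                f'fill="rgb({rgb[0]},{rgb[1]},{rgb[2]})" fill-opacity="{alpha:.3f}" '
                f'stroke="none"><title>{cell.site_entity_id}</title></polygon>'
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
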