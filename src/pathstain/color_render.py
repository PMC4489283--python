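"""Color scales, rasterization, and the slippy-map tile pyramid.

Three kinds of color scale cover the internal data representations:

* ``gradient`` — ordered (value, RGBA) anchors with piecewise-linear
  interpolation, clamped outside the anchor range; the default for
  continuous data runs low=green, midpoint=white, high=red.
* ``ordered_palette`` — inclusive threshold bands for discrete ordered data;
  the default copy-number palette colors -1 and lower blue (loss), 0 neutral
  and +1 and higher yellow (amplification).
* ``category_palette`` — exact label lookup for discrete unordered data;
  the default mutation palette marks mutated genes cyan.

Rendering draws, back to front: staining polygons, the map background
(black-and-white whenever a staining layer is active, so entity decorations
do not mix with the stain colors), entities visible at the requested zoom,
and their overlays.  ``build_tile_pyramid`` emits 256x256 PNG tiles in the
Google Maps ``z/x/y`` layout: the canvas is scaled to fit the 256*2^z world
square (padded with white), so stitching a level and box-downsampling by two
reproduces the level above it.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .map_model import MapEntity, NetworkMap, visible_entities

__all__ = [
    "ColorScale",
    "TilePyramid",
    "value_to_color",
    "expression_scale",
    "COPY_NUMBER_SCALE",
    "MUTATION_PALETTE",
    "DEFAULT_MUTATION_GLYPH",
    "render_level",
    "render_world",
    "build_tile_pyramid",
]

RGBA = tuple[int, int, int, int]

GREEN: RGBA = (0, 200, 0, 255)
WHITE: RGBA = (255, 255, 255, 255)
RED: RGBA = (220, 0, 0, 255)
BLUE: RGBA = (40, 70, 220, 255)
YELLOW: RGBA = (240, 200, 0, 255)
CYAN: RGBA = (0, 255, 255, 255)
NEUTRAL: RGBA = (235, 235, 235, 255)


@dataclass(frozen=True)
class ColorScale:
    kind: str  # gradient | ordered_palette | category_palette
    anchors: tuple[tuple[float, RGBA], ...] = ()
    bands: tuple[tuple[float, float, RGBA], ...] = ()
    categories: tuple[tuple[str, RGBA], ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "gradient":
            vals = [v for v, _ in self.anchors]
            if len(vals) < 2 or any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError("gradient needs >= 2 strictly increasing anchors")
        elif self.kind == "ordered_palette":
            if not self.bands:
                raise ValueError("ordered palette needs >= 1 band")
            for lo, hi, _ in self.bands:
                if lo > hi:
                    raise ValueError(f"band ({lo}, {hi}) has lo > hi")
        elif self.kind == "category_palette":
            if not self.categories:
                raise ValueError("category palette needs >= 1 category")
        else:
            raise ValueError(f"unknown scale kind {self.kind!r}")

    @property
    def category_map(self) -> dict[str, RGBA]:
        return dict(self.categories)


def value_to_color(scale: ColorScale, value) -> RGBA:
    """Resolve a value to RGBA under a scale.

    Gradients interpolate linearly per channel between bracketing anchors and
    clamp outside the range; ordered palettes look the value up in the first
    band with ``lo <= value <= hi`` (inclusive thresholds); category palettes
    are exact lookups and raise on unknown labels.
    """
    if scale.kind == "gradient":
        v = float(value)
        anchors = scale.anchors
        if v <= anchors[0][0]:
            return anchors[0][1]
        if v >= anchors[-1][0]:
            return anchors[-1][1]
        for (v0, c0), (v1, c1) in zip(anchors, anchors[1:]):
            if v0 <= v <= v1:
                t = (v - v0) / (v1 - v0)
                return tuple(round(a + t * (b - a)) for a, b in zip(c0, c1))
        raise AssertionError("unreachable")  # pragma: no cover
    if scale.kind == "ordered_palette":
        v = float(value)
        for lo, hi, color in scale.bands:
            if lo <= v <= hi:
                return color
        raise ValueError(f"value {value!r} falls in no band of the ordered palette")
    # category
    try:
        return scale.category_map[str(value)]
    except KeyError:
        raise ValueError(
            f"unknown category label {value!r}; known: {sorted(scale.category_map)}"
        ) from None


def expression_scale(
    values, low: RGBA = GREEN, mid: RGBA = WHITE, high: RGBA = RED
) -> ColorScale:
    """Default continuous scale: data min -> green, median -> white, max -> red.

    The median midpoint keeps the white point robust to outliers.  Degenerate
    (constant) data gets a unit-width band around the single value.
    """
    arr = np.asarray([v for v in values if v is not None and not math.isnan(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("no finite values to build a scale from")
    vmin, vmed, vmax = float(arr.min()), float(np.median(arr)), float(arr.max())
    if vmin == vmax:
        return ColorScale("gradient", anchors=((vmin - 0.5, low), (vmin + 0.5, high)))
    anchors = [(vmin, low)]
    if vmin < vmed < vmax:
        anchors.append((vmed, mid))
    anchors.append((vmax, high))
    return ColorScale("gradient", anchors=tuple(anchors))


#: Discrete copy-number palette: loss is -1 and lower, amplification +1 and higher.
COPY_NUMBER_SCALE = ColorScale(
    "ordered_palette",
    bands=((-math.inf, -1.0, BLUE), (-1.0 + 1e-12, 1.0 - 1e-12, NEUTRAL), (1.0, math.inf, YELLOW)),
)

#: Default mutation colors (heatmap cells / glyph fills).
MUTATION_PALETTE = ColorScale(
    "category_palette", categories=(("mutated", CYAN), ("wt", (245, 245, 245, 255)))
)

#: Mutated genes default to cyan triangles.
DEFAULT_MUTATION_GLYPH: tuple[str, RGBA] = ("triangle", CYAN)

# entity-class fills for color background mode
_CLASS_COLORS: dict[str, RGBA] = {
    "protein": (186, 210, 240, 255),
    "gene": (205, 235, 188, 255),
    "rna": (222, 205, 240, 255),
    "microrna": (236, 210, 236, 255),
    "complex": (240, 224, 190, 255),
    "phenotype": (240, 200, 200, 255),
    "metabolite": (205, 232, 232, 255),
    "drug": (232, 232, 200, 255),
}
_CLASS_GRAY: RGBA = (210, 210, 210, 255)
_OUTLINE: RGBA = (90, 90, 90, 255)
_OUTLINE_GRAY: RGBA = (110, 110, 110, 255)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _scaled(p: tuple[float, float], s: float) -> tuple[float, float]:
    return (p[0] * s, p[1] * s)


def _draw_staining(draw: ImageDraw.ImageDraw, layer, s: float) -> None:
    for cell, fill in zip(layer.cells, layer.fills):
        if fill is None or cell.polygon.is_empty:
            continue
        alpha = int(round(layer.opacity * fill[3]))
        color = (fill[0], fill[1], fill[2], alpha)
        polys = getattr(cell.polygon, "geoms", None) or [cell.polygon]
        for poly in polys:
            pts = [_scaled(xy, s) for xy in poly.exterior.coords[:-1]]
            if len(pts) >= 3:
                draw.polygon(pts, fill=color)


def _glyph_points(shape: str, cx: float, cy: float, r: float) -> list[tuple[float, float]]:
    if shape == "triangle":
        return [(cx, cy - r), (cx - r, cy + r), (cx + r, cy + r)]
    if shape == "square":
        return [(cx - r, cy - r), (cx + r, cy - r), (cx + r, cy + r), (cx - r, cy + r)]
    if shape == "diamond":
        return [(cx, cy - r), (cx + r, cy), (cx, cy + r), (cx - r, cy)]
    if shape == "hexagon":
        return [
            (cx + r * math.cos(math.pi / 6 + i * math.pi / 3),
             cy + r * math.sin(math.pi / 6 + i * math.pi / 3))
            for i in range(6)
        ]
    raise ValueError(f"unknown glyph shape {shape!r}")


# 5 glyph anchor offsets around the entity bbox: 4 corners + top-center,
# as (fraction of w, fraction of h) from the entity center
_GLYPH_ANCHORS = ((-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5), (0.0, -0.75))


def _draw_overlay(draw: ImageDraw.ImageDraw, entity: MapEntity, ov, s: float) -> None:
    from . import overlays as _ov  # local import to avoid a module cycle

    cx, cy = entity.position[0] * s, entity.position[1] * s
    w, h = entity.bbox[0] * s, entity.bbox[1] * s
    if isinstance(ov, _ov.Marker):
        r = max(3.0, 5.0 * s)
        draw.polygon([(cx, cy), (cx - r, cy - 2 * r), (cx + r, cy - 2 * r)], fill=RED)
        draw.ellipse([cx - r, cy - 3 * r, cx + r, cy - r], fill=RED)
    elif isinstance(ov, _ov.HeatmapOverlay):
        cw, ch = ov.cell_size[0] * s, ov.cell_size[1] * s
        x0, y0 = cx - len(ov.col_labels) * cw / 2.0, cy + h / 2.0 + 1
        for i in range(len(ov.row_labels)):
            for j in range(len(ov.col_labels)):
                color = ov.colors[i][j] or (250, 250, 250, 255)
                draw.rectangle(
                    [x0 + j * cw, y0 + i * ch, x0 + (j + 1) * cw, y0 + (i + 1) * ch],
                    fill=color,
                    outline=(120, 120, 120, 255),
                )
    elif isinstance(ov, _ov.BarplotOverlay):
        bw = ov.bar_width * s
        x0 = cx - len(ov.bars) * bw / 2.0
        base = cy - h / 2.0 - 1
        for j, (_, value, color) in enumerate(ov.bars):
            bh = ov.bar_height(value) * s
            x1, x2 = x0 + j * bw, x0 + (j + 1) * bw - max(1.0, s)
            if bh >= 0:
                draw.rectangle([x1, base - bh, x2, base], fill=color)
            else:
                draw.rectangle([x1, base, x2, base - bh], fill=color)
    elif isinstance(ov, _ov.GlyphOverlay):
        for g in ov.glyphs:
            ax, ay = _GLYPH_ANCHORS[g.slot - 1]
            gx, gy = cx + ax * w, cy + ay * h
            r = g.size_px * s / 2.0
            if g.shape == "circle":
                draw.ellipse([gx - r, gy - r, gx + r, gy + r], fill=g.color)
            else:
                draw.polygon(_glyph_points(g.shape, gx, gy, r), fill=g.color)


def render_level(
    nmap: NetworkMap,
    staining_layer=None,
    overlays: dict[str, list] | None = None,
    zoom: int = 0,
    background_mode: str | None = None,
    scale: float | None = None,
    size: tuple[int, int] | None = None,
) -> Image.Image:
    """Rasterize the map (plus layers) at one zoom level.

    The canvas is native-resolution at ``zoom == max_zoom`` and halves per
    level above it; ``scale``/``size`` override this for tile rendering.
    ``zoom`` always controls semantic visibility.  Deterministic for fixed
    inputs.
    """
    if not (0 <= zoom <= nmap.max_zoom):
        raise ValueError(f"zoom {zoom} out of range [0, {nmap.max_zoom}]")
    s = scale if scale is not None else 2.0 ** (zoom - nmap.max_zoom)
    iw = size[0] if size else max(1, math.ceil(nmap.canvas_width * s))
    ih = size[1] if size else max(1, math.ceil(nmap.canvas_height * s))
    bw = background_mode == "bw" or (
        background_mode is None
        and staining_layer is not None
        and staining_layer.background_mode == "bw"
    )

    img = Image.new("RGBA", (iw, ih), WHITE)
    draw = ImageDraw.Draw(img, "RGBA")
    if staining_layer is not None:
        _draw_staining(draw, staining_layer, s)
    for e in visible_entities(nmap, zoom):
        x, y = e.position[0] * s, e.position[1] * s
        w2, h2 = e.bbox[0] * s / 2.0, e.bbox[1] * s / 2.0
        fill = _CLASS_GRAY if bw else _CLASS_COLORS.get(e.entity_class, _CLASS_GRAY)
        outline = _OUTLINE_GRAY if bw else _OUTLINE
        draw.rectangle([x - w2, y - h2, x + w2, y + h2], fill=fill, outline=outline)
    if overlays:
        visible = {e.entity_id: e for e in visible_entities(nmap, zoom)}
        for eid in sorted(overlays):
            if eid not in visible:
                continue
            for ov in overlays[eid]:
                _draw_overlay(draw, visible[eid], ov, s)
    return img.convert("RGB")


@dataclass(frozen=True)
class TilePyramid:
    out_dir: str
    max_zoom: int
    tile_size: int = 256

    def tile_path(self, z: int, x: int, y: int) -> str:
        return os.path.join(self.out_dir, str(z), str(x), f"{y}.png")


def render_world(
    nmap: NetworkMap,
    staining_layer=None,
    overlays: dict[str, list] | None = None,
    zoom: int = 0,
    tile_size: int = 256,
) -> Image.Image:
    """The full square world image for one pyramid level.

    The canvas is scaled (uniformly) so its longer side spans the
    ``tile_size * 2**zoom`` world, anchored top-left, padded white.
    """
    world = tile_size * (2 ** zoom)
    s = world / max(nmap.canvas_width, nmap.canvas_height)
    content = render_level(
        nmap,
        staining_layer,
        overlays,
        zoom=zoom,
        scale=s,
        size=(
            min(world, math.ceil(nmap.canvas_width * s)),
            min(world, math.ceil(nmap.canvas_height * s)),
        ),
    )
    img = Image.new("RGB", (world, world), WHITE[:3])
    img.paste(content, (0, 0))
    return img


def build_tile_pyramid(
    nmap: NetworkMap,
    staining_layer=None,
    overlays: dict[str, list] | None = None,
    out_dir: str = "tiles",
    tile_size: int = 256,
) -> TilePyramid:
    """Write PNG tiles ``out_dir/z/x/y.png`` for every level 0..max_zoom.

    Level z holds 4^z tiles; downsampling a stitched level by two (area
    average) reproduces the level above, up to resampling and semantic-zoom
    differences.
    """
    for z in range(nmap.max_zoom + 1):
        world_img = render_world(nmap, staining_layer, overlays, zoom=z, tile_size=tile_size)
        ntiles = 2 ** z
        for x in range(ntiles):
            os.makedirs(os.path.join(out_dir, str(z), str(x)), exist_ok=True)
            for y in range(ntiles):
                tile = world_img.crop(
                    (x * tile_size, y * tile_size, (x + 1) * tile_size, (y + 1) * tile_size)
                )
                tile.save(os.path.join(out_dir, str(z), str(x), f"{y}.png"))
    return TilePyramid(out_dir=out_dir, max_zoom=nmap.max_zoom, tile_size=tile_size)


def stitch_level(pyramid: TilePyramid, z: int) -> Image.Image:
    """Reassemble a level's tiles into its world image (for consistency checks)."""
    ts = pyramid.tile_size
    world = ts * (2 ** z)
    img = Image.new("RGB", (world, world))
    for x in range(2 ** z):
        for y in range(2 ** z):
            img.paste(Image.open(pyramid.tile_path(z, x, y)), (x * ts, y * ts))
    return img
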