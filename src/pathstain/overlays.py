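"""Marker, heatmap, barplot and glyph attachments anchored at entities.

Overlays are pure data: they bind entity positions to summarized values and
resolved colors, and are drawn by :mod:`pathstain.color_render`.  Where an
entity carries several valued symbols (a complex listing its components),
continuous channels take the mean and mutation channels take "any member
mutated", mirroring the sample-group rules.

Glyphs combine up to three visual channels (shape, color, size) that may be
bound to different data tables — e.g. shape from copy-number state, color
from expression — and at most five glyphs attach to one entity, each in one
of five fixed anchor slots around the entity box (four corners plus
top-center).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .color_render import (
    ColorScale,
    DEFAULT_MUTATION_GLYPH,
    MUTATION_PALETTE,
    RGBA,
    value_to_color,
)
from .map_model import MapEntity, NetworkMap, resolve_symbols, symbol_index
from .omics_data import DataTable, SampleGroup, is_mutated_label, summarize_group

__all__ = [
    "GLYPH_SHAPES",
    "MAX_GLYPHS",
    "Marker",
    "HeatmapOverlay",
    "BarplotOverlay",
    "Glyph",
    "GlyphOverlay",
    "GlyphCapacityError",
    "build_markers",
    "entity_value",
    "build_heatmap",
    "build_barplot",
    "attach_glyph",
    "glyph_size_from_value",
    "shape_for_ordered",
]

GLYPH_SHAPES = ("triangle", "square", "circle", "diamond", "hexagon")
MAX_GLYPHS = 5

_BAR_COLORS: tuple[RGBA, ...] = (
    (66, 114, 196, 255),
    (214, 114, 40, 255),
    (112, 173, 71, 255),
    (255, 192, 0, 255),
    (132, 60, 180, 255),
    (90, 180, 190, 255),
)


class GlyphCapacityError(ValueError):
    pass


@dataclass(frozen=True)
class Marker:
    """A Google-Maps-style pin at an entity position (search / gene-list hits)."""

    entity_id: str
    anchor: tuple[float, float]
    label: str


@dataclass(frozen=True)
class HeatmapOverlay:
    """A rectangular grid of colored cells: rows are data tables, columns are
    samples or sample groups."""

    entity_id: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: tuple[tuple[object, ...], ...]
    colors: tuple[tuple[RGBA | None, ...], ...]
    cell_size: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self) -> None:
        for grid in (self.values, self.colors):
            if len(grid) != len(self.row_labels) or any(
                len(r) != len(self.col_labels) for r in grid
            ):
                raise ValueError("heatmap grid is not rectangular")


@dataclass(frozen=True)
class BarplotOverlay:
    """Bars whose height is proportional to the value, normalized by the
    data table's global maximum magnitude so heights compare across the map.
    Negative values draw downward from the baseline."""

    entity_id: str
    bars: tuple[tuple[str, float, RGBA], ...]
    global_max: float
    max_height: float = 40.0
    bar_width: float = 8.0

    def __post_init__(self) -> None:
        if self.global_max <= 0:
            raise ValueError("global_max must be positive")

    def bar_height(self, value: float) -> float:
        """Signed height in px; |h(a)/h(b)| = |a/b| within one table."""
        if math.isnan(value):
            return 0.0
        return value / self.global_max * self.max_height


@dataclass(frozen=True)
class Glyph:
    shape: str
    color: RGBA
    size_px: float
    slot: int

    def __post_init__(self) -> None:
        if self.shape not in GLYPH_SHAPES:
            raise ValueError(f"unknown glyph shape {self.shape!r}; known: {GLYPH_SHAPES}")
        if not (1 <= self.slot <= MAX_GLYPHS):
            raise ValueError(f"glyph slot must be 1..{MAX_GLYPHS}")


@dataclass(frozen=True)
class GlyphOverlay:
    entity_id: str
    glyphs: tuple[Glyph, ...] = ()

    def __post_init__(self) -> None:
        if len(self.glyphs) > MAX_GLYPHS:
            raise GlyphCapacityError(
                f"entity {self.entity_id!r}: at most {MAX_GLYPHS} glyphs per entity"
            )
        slots = [g.slot for g in self.glyphs]
        if len(set(slots)) != len(slots):
            raise ValueError("glyph slots must be unique")


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_markers(
    nmap: NetworkMap, symbols: list[str]
) -> tuple[list[Marker], list[str]]:
    """One marker per matched entity occurrence, plus the unmatched symbols.

    A symbol present both as a free protein and inside a complex yields one
    marker on each occurrence.
    """
    matched, unmatched = resolve_symbols(nmap, symbols)
    markers = []
    for symbol in matched:
        for eid in matched[symbol]:
            e = nmap.entity(eid)
            markers.append(Marker(entity_id=eid, anchor=e.position, label=symbol))
    return markers, unmatched


def entity_value(
    table: DataTable, symbols: tuple[str, ...], column
):
    """Value of an entity in one table column (a sample id or a SampleGroup).

    Rows are selected by the entity's symbols; several valued symbols are
    combined by the representation rule (mean / any-mutated / mode-magnitude
    / any-member).  Returns None when the entity has no value.
    """
    rows = [s for s in symbols if s in table.values.index]
    if not rows:
        return None
    if isinstance(column, SampleGroup):
        series = summarize_group(table, column)
    elif column is None:  # set tables have a single implicit column
        series = table.values.iloc[:, 0]
    else:
        if column not in table.values.columns:
            raise KeyError(f"sample {column!r} not in table {table.name!r}")
        series = table.values[column]
    vals = [series[s] for s in rows]

    if table.internal_repr in ("continuous", "discrete_ordered"):
        arr = np.asarray([v for v in vals if not pd.isna(v)], dtype=float)
        if arr.size == 0:
            return None
        if table.internal_repr == "continuous":
            return float(arr.mean())
        uniq, counts = np.unique(arr, return_counts=True)
        tied = uniq[counts == counts.max()]
        return float(tied[np.argmax(np.abs(tied))])
    if table.internal_repr == "discrete_unordered":
        flags = [
            v if isinstance(v, (bool, np.bool_)) else is_mutated_label(str(v))
            for v in vals
            if v is not None
        ]
        return None if not flags else bool(any(flags))
    # set
    return bool(any(bool(v) for v in vals))


def _cell_color(table: DataTable, value, scale: ColorScale | None) -> RGBA | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if table.internal_repr in ("discrete_unordered", "set"):
        palette = scale or MUTATION_PALETTE
        return value_to_color(palette, "mutated" if value else "wt")
    if scale is None:
        raise ValueError(f"a color scale is required for table {table.name!r}")
    return value_to_color(scale, value)


def build_heatmap(
    entity: MapEntity,
    selections: list[tuple[DataTable, list]],
    scales: dict[str, ColorScale],
    cell_size: tuple[float, float] = (10.0, 10.0),
) -> HeatmapOverlay | None:
    """Heatmap grid for one entity: one row per table, one column per
    selected sample/group.  Returns None when the entity has no data in any
    selected table (callers skip such entities)."""
    if not selections:
        return None
    ncols = len(selections[0][1])
    if any(len(cols) != ncols for _, cols in selections):
        raise ValueError("all selections must request the same number of columns")
    row_labels, values, colors = [], [], []
    any_data = False
    for table, columns in selections:
        row_labels.append(table.name)
        row_v, row_c = [], []
        for col in columns:
            v = entity_value(table, entity.hugo_symbols, col)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                any_data = True
            row_v.append(v)
            row_c.append(_cell_color(table, v, scales.get(table.name)))
        values.append(tuple(row_v))
        colors.append(tuple(row_c))
    if not any_data:
        return None
    col_labels = tuple(
        c.group_id if isinstance(c, SampleGroup) else str(c) for c in selections[0][1]
    )
    return HeatmapOverlay(
        entity_id=entity.entity_id,
        row_labels=tuple(row_labels),
        col_labels=col_labels,
        values=tuple(values),
        colors=tuple(colors),
        cell_size=cell_size,
    )


def build_barplot(
    entity: MapEntity,
    table: DataTable,
    columns: list,
    colors: tuple[RGBA, ...] = _BAR_COLORS,
    max_height: float = 40.0,
    bar_width: float = 8.0,
) -> BarplotOverlay | None:
    """Barplot of a continuous table's values across samples/groups.

    Heights are normalized by the table-wide maximum magnitude (not the
    per-entity maximum) so bars are comparable across the whole map.
    """
    if table.internal_repr not in ("continuous", "discrete_ordered"):
        raise ValueError("barplots require numeric data")
    global_max = float(np.nanmax(np.abs(table.values.to_numpy(dtype=float))))
    if not (global_max > 0):
        global_max = 1.0
    bars = []
    any_data = False
    for j, col in enumerate(columns):
        v = entity_value(table, entity.hugo_symbols, col)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            v = math.nan
        else:
            any_data = True
        label = col.group_id if isinstance(col, SampleGroup) else str(col)
        bars.append((label, float(v), colors[j % len(colors)]))
    if not any_data:
        return None
    return BarplotOverlay(
        entity_id=entity.entity_id,
        bars=tuple(bars),
        global_max=global_max,
        max_height=max_height,
        bar_width=bar_width,
    )


def glyph_size_from_value(
    value: float, vmin: float, vmax: float, smin_px: float, smax_px: float
) -> float:
    """Affine map of a value onto a pixel-size range, clamped at both ends.

    Used e.g. to make glyph size proportional to mutation frequency.
    """
    if vmin >= vmax:
        raise ValueError(f"vmin ({vmin}) must be < vmax ({vmax})")
    if smin_px > smax_px:
        raise ValueError("smin_px must be <= smax_px")
    t = (value - vmin) / (vmax - vmin)
    return smin_px + min(1.0, max(0.0, t)) * (smax_px - smin_px)


def shape_for_ordered(value: float) -> str:
    """Default shape channel for discrete ordered values: the value (clamped
    to -2..+2) indexes the shape list, so each copy-number state reads as a
    distinct shape."""
    i = int(min(2, max(-2, round(value)))) + 2
    return GLYPH_SHAPES[i]


def attach_glyph(
    overlay: GlyphOverlay,
    shape: str | None = None,
    color: RGBA | None = None,
    size_px: float = 12.0,
    shape_from: tuple[DataTable, object] | None = None,
    color_from: tuple[DataTable, object, ColorScale] | None = None,
    size_from: tuple[DataTable, object, float, float, float, float] | None = None,
    symbols: tuple[str, ...] = (),
) -> GlyphOverlay:
    """Append one glyph in the next free slot (error past the 5-glyph cap).

    Each channel is either a constant (``shape``/``color``/``size_px``) or
    bound to a data table: ``shape_from=(table, column)`` maps the entity's
    value through :func:`shape_for_ordered`; ``color_from=(table, column,
    scale)`` through :func:`value_to_color`; ``size_from=(table, column,
    vmin, vmax, smin, smax)`` through :func:`glyph_size_from_value`.  The
    bound tables may differ per channel (e.g. shape from copy number, color
    from expression).
    """
    if len(overlay.glyphs) >= MAX_GLYPHS:
        raise GlyphCapacityError(
            f"entity {overlay.entity_id!r}: at most {MAX_GLYPHS} glyphs per entity"
        )
    if shape_from is not None:
        table, column = shape_from
        v = entity_value(table, symbols, column)
        if v is None:
            return overlay
        shape = shape_for_ordered(float(v))
    if color_from is not None:
        table, column, scale = color_from
        v = entity_value(table, symbols, column)
        if v is None:
            return overlay
        if table.internal_repr in ("discrete_unordered", "set"):
            color = value_to_color(scale or MUTATION_PALETTE, "mutated" if v else "wt")
        else:
            color = value_to_color(scale, v)
    if size_from is not None:
        table, column, vmin, vmax, smin, smax = size_from
        v = entity_value(table, symbols, column)
        if v is None:
            return overlay
        size_px = glyph_size_from_value(float(v), vmin, vmax, smin, smax)
    if shape is None:
        shape = DEFAULT_MUTATION_GLYPH[0]
    if color is None:
        color = DEFAULT_MUTATION_GLYPH[1]
    used = {g.slot for g in overlay.glyphs}
    slot = next(i for i in range(1, MAX_GLYPHS + 1) if i not in used)
    return replace(
        overlay, glyphs=overlay.glyphs + (Glyph(shape, color, float(size_px), slot),)
    )
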