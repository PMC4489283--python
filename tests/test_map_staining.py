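"""Voronoi territory geometry and value-to-territory staining."""

import math

import numpy as np
import pytest
from shapely.geometry import Point

import pathstain as ps
from pathstain.color_render import expression_scale
from pathstain.map_staining import (
    build_staining_layer,
    compute_voronoi,
    limit_cell_extent,
    staining_to_svg,
)


def random_sites(rng, n, width=800, height=600):
    xs = rng.uniform(1, width - 1, size=n)
    ys = rng.uniform(1, height - 1, size=n)
    return [(f"e{i}", float(x), float(y)) for i, (x, y) in enumerate(zip(xs, ys))]


def test_single_site_owns_whole_canvas():
    [cell] = compute_voronoi([("a", 123.0, 456.0)], (800, 600))
    assert cell.area == pytest.approx(480000)
    assert cell.site == (123.0, 456.0)


def test_two_sites_split_by_perpendicular_bisector():
    cells = compute_voronoi([("a", 1.0, 1.0), ("b", 3.0, 1.0)], (4, 2))
    areas = {c.site_entity_id: c.area for c in cells}
    assert areas["a"] == pytest.approx(4.0)
    assert areas["b"] == pytest.approx(4.0)
    # the dividing edge is x = 2
    for c in cells:
        xs = [x for x, _ in c.vertices]
        assert (min(xs), max(xs)) == ((0, 2) if c.site_entity_id == "a" else (2, 4))


def test_errors_on_empty_and_outside_sites():
    with pytest.raises(ValueError, match="at least one"):
        compute_voronoi([], (10, 10))
    with pytest.raises(ValueError, match="outside"):
        compute_voronoi([("a", 50.0, 5.0)], (10, 10))


def test_coincident_sites_merge():
    cells = compute_voronoi([("a", 5.0, 5.0), ("b", 5.0, 5.0)], (10, 10))
    assert len(cells) == 1
    assert cells[0].entity_ids == ("a", "b")


def test_site_inside_cell_and_tiling(grid_map):
    sites = [(e.entity_id, *e.position) for e in grid_map.entities]
    cells = compute_voronoi(sites, (grid_map.canvas_width, grid_map.canvas_height))
    total = sum(c.area for c in cells)
    canvas_area = grid_map.canvas_width * grid_map.canvas_height
    assert total == pytest.approx(canvas_area, rel=1e-6)
    for c in cells:
        assert c.polygon.buffer(1e-9).contains(Point(c.site))


def test_membership_agrees_with_nearest_site_oracle():
    rng = np.random.default_rng(5)
    for n in (3, 25, 120):
        sites = random_sites(rng, n)
        cells = compute_voronoi(sites, (800, 600))
        pts = np.column_stack([rng.uniform(0, 800, 2000), rng.uniform(0, 600, 2000)])
        xy = np.asarray([[x, y] for _, x, y in sites])
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        owner_by_cell = {c.site_entity_id: c for c in cells}
        ids = [s[0] for s in sites]
        for p, dists in zip(pts, d2):
            nearest = dists.min()
            # skip probes essentially equidistant to two sites (boundary)
            if np.sort(dists)[1] - nearest < 1e-6:
                continue
            cell = owner_by_cell[ids[int(dists.argmin())]]
            assert cell.polygon.buffer(1e-6).contains(Point(p))


def test_cells_are_interior_disjoint():
    rng = np.random.default_rng(9)
    cells = compute_voronoi(random_sites(rng, 40), (800, 600))
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            assert a.polygon.intersection(b.polygon).area < 1e-6


def test_extent_limit_square_rule():
    [cell] = compute_voronoi([("a", 400.0, 300.0)], (800, 600))
    [limited] = limit_cell_extent([cell], radius=10.0)
    assert limited.area == pytest.approx(400.0)  # 20 x 20 square
    assert limited.clipped
    minx, miny, maxx, maxy = limited.polygon.bounds
    assert (minx, miny, maxx, maxy) == (390, 290, 410, 310)


def test_extent_limit_infinite_factor_is_identity():
    rng = np.random.default_rng(2)
    cells = compute_voronoi(random_sites(rng, 20), (800, 600))
    same = limit_cell_extent(cells, radius_factor=math.inf)
    assert [c.polygon.wkt for c in same] == [c.polygon.wkt for c in cells]


def test_extent_limit_contractive_and_idempotent(grid_map):
    sites = [(e.entity_id, *e.position) for e in grid_map.entities]
    cells = compute_voronoi(sites, (grid_map.canvas_width, grid_map.canvas_height))
    limited = limit_cell_extent(cells, radius_factor=1.5)
    assert sum(c.area for c in limited) <= sum(c.area for c in cells) + 1e-6
    for raw, lim in zip(cells, limited):
        assert lim.polygon.difference(raw.polygon.buffer(1e-9)).area < 1e-6
    again = limit_cell_extent(limited, radius_factor=1.5)
    for a, b in zip(limited, again):
        assert abs(a.area - b.area) < 1e-9


def test_extent_limit_rejects_bad_factor():
    [cell] = compute_voronoi([("a", 5.0, 5.0)], (10, 10))
    with pytest.raises(ValueError):
        limit_cell_extent([cell], radius_factor=0.0)
    with pytest.raises(ValueError):
        limit_cell_extent([cell], radius=-1.0)


def test_empty_values_leave_all_cells_unstained(grid_map):
    scale = expression_scale([0.0, 1.0])
    layer = build_staining_layer(grid_map, {}, scale)
    assert all(f is None for f in layer.fills)


def test_minimum_value_gets_low_anchor_green(grid_map):
    genes = sorted(grid_map.all_symbols())
    values = {g: float(i + 1) for i, g in enumerate(genes)}
    scale = expression_scale(values.values())
    layer = build_staining_layer(grid_map, values, scale)
    low_gene = genes[0]
    by_id = {e.entity_id: e for e in grid_map.entities}
    low_color = scale.anchors[0][1]
    hits = 0
    for cell, fill in zip(layer.cells, layer.fills):
        syms = {s for eid in cell.entity_ids for s in by_id[eid].hugo_symbols}
        if syms == {low_gene}:
            assert fill == low_color
            hits += 1
    assert hits >= 1
    assert low_color[1] > low_color[0] and low_color[1] > low_color[2]  # green


def test_aliases_get_identical_fill(grid_map):
    by_id = {e.entity_id: e for e in grid_map.entities}
    genes = sorted(grid_map.all_symbols())
    values = {g: float(i) for i, g in enumerate(genes)}
    layer = build_staining_layer(grid_map, values, expression_scale(values.values()))
    fill_by_symbolset: dict[tuple, set] = {}
    for cell, fill in zip(layer.cells, layer.fills):
        syms = tuple(sorted({s for eid in cell.entity_ids for s in by_id[eid].hugo_symbols}))
        fill_by_symbolset.setdefault(syms, set()).add(fill)
    aliased = [s for s, fills in fill_by_symbolset.items() if len(s) == 1]
    assert any(len(ps.symbol_index(grid_map)[s[0]]) > 1 for s in aliased)
    for fills in fill_by_symbolset.values():
        assert len(fills) == 1  # same symbols => same color, wherever placed


def test_swapping_values_swaps_fills(grid_map):
    genes = sorted(grid_map.all_symbols())
    values = {g: float(i) for i, g in enumerate(genes)}
    scale = expression_scale(values.values())
    a, b = genes[2], genes[-3]
    swapped = dict(values)
    swapped[a], swapped[b] = values[b], values[a]
    l1 = build_staining_layer(grid_map, values, scale)
    l2 = build_staining_layer(grid_map, swapped, scale)
    by_id = {e.entity_id: e for e in grid_map.entities}
    for cell, f1, f2 in zip(l1.cells, l1.fills, l2.fills):
        syms = {s for eid in cell.entity_ids for s in by_id[eid].hugo_symbols}
        if syms == {a} or syms == {b}:
            assert f1 != f2
        elif not (syms & {a, b}):
            assert f1 == f2


def test_complex_entity_averages_member_values(tiny_map):
    values = {"TP53": 0.0, "MDM2": 4.0}
    scale = expression_scale([0.0, 2.0, 4.0])
    layer = build_staining_layer(tiny_map, values, scale)
    by_cell = {c.site_entity_id: v for c, v in zip(layer.cells, layer.values)}
    assert by_cell["cplx"] == pytest.approx(2.0)  # mean of the two member symbols
    assert by_cell["growth"] is None              # phenotype: no symbols, unstained


def test_svg_export_has_one_polygon_per_stained_cell(tiny_map):
    values = {"TP53": 1.0, "MDM2": 2.0}
    layer = build_staining_layer(tiny_map, values, expression_scale([1.0, 2.0]))
    svg = staining_to_svg(layer, (tiny_map.canvas_width, tiny_map.canvas_height))
    assert svg.count("<polygon") == len([c for c in layer.cells if not c.polygon.is_empty])
    assert svg.startswith("<svg")
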