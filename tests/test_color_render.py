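"""Color scales, raster determinism, semantic zoom, and the tile pyramid."""

import numpy as np
import pytest
from PIL import Image

import pathstain as ps
from pathstain.color_render import (
    COPY_NUMBER_SCALE,
    DEFAULT_MUTATION_GLYPH,
    MUTATION_PALETTE,
    ColorScale,
    build_tile_pyramid,
    expression_scale,
    render_level,
    render_world,
    stitch_level,
    value_to_color,
)


def test_gradient_interpolation_and_clamping():
    scale = ColorScale(
        "gradient", anchors=((0.0, (0, 0, 0, 255)), (10.0, (100, 200, 50, 255)))
    )
    assert value_to_color(scale, 0.0) == (0, 0, 0, 255)
    assert value_to_color(scale, 10.0) == (100, 200, 50, 255)
    assert value_to_color(scale, 5.0) == (50, 100, 25, 255)
    assert value_to_color(scale, -99.0) == (0, 0, 0, 255)   # clamped low
    assert value_to_color(scale, 99.0) == (100, 200, 50, 255)  # clamped high


def test_interior_anchor_hit_exactly():
    mid = (11, 22, 33, 255)
    scale = ColorScale(
        "gradient",
        anchors=((0.0, (0, 0, 0, 255)), (1.0, mid), (2.0, (255, 255, 255, 255))),
    )
    assert value_to_color(scale, 1.0) == mid


def test_gradient_monotone_per_channel():
    scale = expression_scale([0.0, 5.0, 10.0])
    colors = [value_to_color(scale, v) for v in np.linspace(0, 10, 41)]
    for ch in range(3):
        seq = [c[ch] for c in colors]
        diffs = np.diff(seq)
        assert (diffs >= 0).all() or (diffs <= 0).all() or (
            # green->white->red: channels are monotone within each half
            all(d >= 0 for d in np.diff(seq[:21])) and all(d <= 0 for d in np.diff(seq[20:]))
            or all(d <= 0 for d in np.diff(seq[:21])) and all(d >= 0 for d in np.diff(seq[20:]))
        )


def test_copy_number_bands_exhaustive_sweep():
    blue = value_to_color(COPY_NUMBER_SCALE, -1)
    yellow = value_to_color(COPY_NUMBER_SCALE, 1)
    neutral = value_to_color(COPY_NUMBER_SCALE, 0)
    assert blue[2] > blue[0]                     # loss is blue
    assert yellow[0] > 200 and yellow[2] < 100   # amplification is yellow
    for v in range(-5, 6):
        c = value_to_color(COPY_NUMBER_SCALE, v)
        if v <= -1:
            assert c == blue
        elif v >= 1:
            assert c == yellow
        else:
            assert c == neutral


def test_category_palette_and_unknown_label():
    assert value_to_color(MUTATION_PALETTE, "mutated") == (0, 255, 255, 255)
    with pytest.raises(ValueError, match="frameshift"):
        value_to_color(MUTATION_PALETTE, "frameshift")


def test_default_mutation_glyph_is_cyan_triangle():
    shape, color = DEFAULT_MUTATION_GLYPH
    assert shape == "triangle"
    assert color == (0, 255, 255, 255)


def test_expression_scale_anchors_min_median_max():
    scale = expression_scale([2.0, 4.0, 10.0])
    assert [v for v, _ in scale.anchors] == [2.0, 4.0, 10.0]
    low, mid, high = (c for _, c in scale.anchors)
    assert low[1] > low[0] and high[0] > high[1]  # green -> red
    assert mid == (255, 255, 255, 255)


def test_invalid_scales_rejected():
    with pytest.raises(ValueError):
        ColorScale("gradient", anchors=((1.0, (0, 0, 0, 255)),))
    with pytest.raises(ValueError):
        ColorScale("gradient", anchors=((1.0, (0,) * 4), (1.0, (0,) * 4)))
    with pytest.raises(ValueError):
        ColorScale("nope")


def test_bw_mode_renders_grayscale_only(grid_map):
    img = render_level(grid_map, zoom=grid_map.max_zoom, background_mode="bw")
    arr = np.asarray(img, dtype=int)
    assert (arr[..., 0] == arr[..., 1]).all() and (arr[..., 1] == arr[..., 2]).all()


def test_render_determinism(grid_map, expr_design):
    summary = ps.summarize_group(expr_design["table"], expr_design["groups"]["group=disease"])
    values = {g: float(v) for g, v in summary.items()}
    layer = ps.build_staining_layer(grid_map, values, expression_scale(values.values()))
    a = render_level(grid_map, layer, zoom=2)
    b = render_level(grid_map, layer, zoom=2)
    assert a.tobytes() == b.tobytes()


def test_semantic_zoom_reveals_entity(grid_map):
    staged = [e for e in grid_map.entities if e.min_zoom == 2]
    assert staged
    e = staged[0]
    img1 = render_level(grid_map, zoom=1, scale=1.0)
    img2 = render_level(grid_map, zoom=2, scale=1.0)
    x, y = int(e.position[0]), int(e.position[1])
    assert img1.getpixel((x, y)) == (255, 255, 255)  # hidden at zoom 1
    assert img2.getpixel((x, y)) != (255, 255, 255)  # drawn at zoom 2


def test_render_zoom_out_of_range(grid_map):
    with pytest.raises(ValueError, match="out of range"):
        render_level(grid_map, zoom=grid_map.max_zoom + 1)


@pytest.fixture(scope="module")
def pyramid(tmp_path_factory):
    nmap = ps.make_grid_map(ps.FixtureSpec(seed=11))
    genes = sorted(nmap.all_symbols())
    values = {g: float(i) for i, g in enumerate(genes)}
    layer = ps.build_staining_layer(nmap, values, expression_scale(values.values()))
    out = tmp_path_factory.mktemp("tiles")
    return nmap, layer, build_tile_pyramid(nmap, layer, out_dir=str(out))


def test_tile_counts_per_level(pyramid, tmp_path):
    import os

    nmap, _, pyr = pyramid
    for z in range(nmap.max_zoom + 1):
        count = sum(
            len(files)
            for _, _, files in os.walk(os.path.join(pyr.out_dir, str(z)))
        )
        assert count == 4 ** z
    tile = Image.open(pyr.tile_path(0, 0, 0))
    assert tile.size == (256, 256)


def test_stitched_levels_downsample_consistently(pyramid):
    nmap, _, pyr = pyramid
    for z in range(1, nmap.max_zoom + 1):
        stitched = stitch_level(pyr, z)
        down = stitched.resize(
            (stitched.width // 2, stitched.height // 2), Image.Resampling.BOX
        )
        above = stitch_level(pyr, z - 1)
        diff = np.abs(
            np.asarray(down, dtype=float) - np.asarray(above, dtype=float)
        )
        assert diff.mean() <= 2.0  # mean per-channel error <= 2/255


def test_world_render_matches_tiles(pyramid):
    nmap, layer, pyr = pyramid
    world = render_world(nmap, layer, zoom=1)
    tile = Image.open(pyr.tile_path(1, 0, 0))
    assert world.crop((0, 0, 256, 256)).tobytes() == tile.tobytes()
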