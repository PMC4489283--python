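# Methods

`pathstain` visualizes multi-omics measurements on top of a *positioned*
biological network map — a canvas of molecular entities (proteins, genes,
complexes, phenotypes, ...) each carrying HUGO/HGNC symbols, module
membership and a minimum zoom level. This note records the models,
conventions and numerical choices behind each stage, and what the synthetic
generators do and do not emulate.

## Map model and coordinates

Maps are self-contained JSON descriptors rather than a pathway-editor
format: the package's concern is data *on* a laid-out map, not layout
itself, and a JSON dialect keeps every stage testable without external
tooling. Coordinates are pixel units with the origin top-left and y
increasing downward (image convention), which matches both rasterization
and slippy-map tiling. Gene symbols are canonicalized by stripping
whitespace and uppercasing — HUGO symbols are conventionally uppercase, but
user files vary — and all matching is done on the canonical form. A complex
lists the symbols of its components, so a single uploaded gene row
decorates the free protein *and* every complex containing it. Entity-level
module tags must refer to declared modules; the module table is
authoritative for membership. Semantic zoom is a pure threshold rule
(`min_zoom <= zoom`), which makes visibility monotone in zoom by
construction.

## Data types and group summarization

Seven declared data types map onto four internal representations
(continuous, discrete ordered, discrete unordered, set); the representation
decides which visualizations apply and how a sample group collapses to one
value per gene:

* **continuous** — arithmetic mean over non-missing members (median, min,
  max selectable).
* **discrete unordered** (mutation) — true iff at least one non-missing
  member is mutated; a gene whose members are all missing stays missing.
  Any non-empty label other than `WT`/`0` (case-insensitive) counts as a
  mutation call; missing markers are `""`, `NA`, `NaN`, `N/A`
  (case-insensitive). Real variant tables encode calls in many vocabularies;
  "anything that is not explicitly wild-type" is the permissive reading and
  is documented rather than configurable.
* **discrete ordered** (copy number) — the mode, ties broken toward the
  value of largest magnitude (equal magnitudes resolve to the positive
  value). Rationale: for copy-number states the extreme call is the one a
  reader wants surfaced when a group is split.
* **set** — union of membership.

Duplicate gene rows are a hard error by default (`aggregate_duplicates=
"mean"` opts into averaging, continuous tables only): silent aggregation
hides upstream join mistakes. Group summaries are invariant under sample
column permutation and are checked against per-cell recomputation.

## Map staining

Each entity position is a Voronoi site; the entity's territory is the set
of canvas points nearer to it than to any other site. Implementation:
sites are reflected across the four canvas edges before the scipy Voronoi
construction, which makes every original site's cell finite with the canvas
edges as exact boundaries; cells are then intersected with the canvas
rectangle (shapely). Coincident sites are merged into one cell owning all
their entity ids. Tiling is conserved — cell areas sum to the canvas area
to ~1e-9 relative error in practice; the test tolerance is 1e-6 — and
membership is verified against a brute-force nearest-site oracle on random
probe points.

Sparse map regions otherwise produce huge territories that dominate the
picture, so cells are post-processed: each is clipped to the axis-aligned
square of half-width `R = radius_factor x median nearest-neighbor site
distance` centered on its site (`radius_factor` defaults to 3, an absolute
radius can be given instead). The rule is scale-free per map, contractive
and idempotent. A single-site map has no neighbor distance and is left
unclipped.

Every alias of a gene is its own site carrying the same value, so aliased
territories get identical fills wherever they sit. An entity with several
valued symbols (a complex) takes the mean. Entities with no value stay
*unstained* — rendered as neutral light gray at zero stain opacity, so
absence of data never masquerades as a mid-scale value. When staining is
active the map background defaults to black-and-white so entity decoration
colors do not mix with the stain.

## Color scales and rendering

* Continuous default: a three-anchor gradient, data minimum = green,
  midpoint = white, maximum = red. The midpoint is the *median* of the
  mapped values, keeping the white point robust to outliers. Interpolation
  is piecewise-linear per channel, clamped outside the anchors.
* Discrete copy number: threshold bands — blue for −1 and all lower values
  (loss), neutral for 0, yellow for +1 and higher (amplification), inclusive
  thresholds.
* Mutation: category palette; the default mutation glyph is a cyan triangle.

Rendering draws staining polygons, then the (gray or class-colored) entity
boxes of the entities visible at the requested zoom, then their overlays.
Barplot heights are normalized by the data table's global maximum magnitude
(not per entity) so bars compare across the map; negative values draw
downward. Glyphs occupy five fixed anchor slots around the entity box (four
corners plus top-center); the sixth attachment is an error. Rasters are
deterministic for fixed inputs (no anti-aliasing, no font dependence —
labels are not drawn).

The tile pyramid follows the Google-Maps convention: level *z* is a
`256·2^z` pixel world holding `4^z` PNG tiles at `z/x/y.png`; the canvas is
scaled uniformly to span the world's longer side, anchored top-left, padded
white. Downsampling a stitched level by two (area-average/box filter)
reproduces the level above it; the residual mean per-channel error (~1/255
on the fixture maps) comes from integer pixel rounding and from entities
that appear only at deeper semantic-zoom levels, whose footprint is a small
area fraction.

## Module enrichment

For an uploaded gene list the package computes, per module, the upper-tail
hypergeometric probability

    P(X >= k) = sum_{i=k..min(K,n)} C(K,i) C(N-K,n-i) / C(N,n)

with N the distinct symbols on the map, K the module's distinct symbols,
n the uploaded symbols found on the map, k the overlap. The universe is the
map rather than the genome because the question answered is "which module
*of this map* should I inspect next"; uploaded symbols absent from the map
are dropped from n and reported. Symbols count once per module regardless
of aliases. The tail probability is evaluated with scipy's log-space
survival function and matches exact rational enumeration to ~1e-16 for all
N ≤ 12. Benjamini–Hochberg q-values across the map's modules are emitted
alongside raw p-values; rows sort by ascending p with module id as the tie
break.

## Service and CLI

A session (random 128-bit hex token) holds a loaded map, imported tables,
defined groups and active layers; JSON commands (`load_map`,
`import_datatable`, `define_groups`, `set_staining`, `add_overlay`,
`render`, `enrich`, `list_hugo`) mutate only their session. The HTTP
transport is the standard library's `http.server` with one POST route per
action under `/commands/`; there is no authentication and sessions live
until shutdown (a desk tool, not a public service). The batch CLI records
each subcommand as a JSON command in a session log and replays the log
through the in-process service for artifact-producing subcommands, so CLI
and command-sequence outputs are identical by construction.

## Synthetic data

`make_grid_map` lays modules out as disjoint spatial blocks so that a
planted per-module effect produces a *contiguous* stained region whose mean
cell color is measurable per block. It includes staggered `min_zoom`
values, a configurable fraction of twice-placed symbols (aliases, placed
inside their module's block so module symbol sets stay clean), and one
complex sharing its members' symbols. `make_expression_table` draws
`baseline + group/module effect + N(0, sd)` per cell with defaults
mimicking log2 microarray intensities (baseline 8, sd 0.5); the standard
planted-signal condition used in the end-to-end checks is one module
shifted by +2.0 at sd 0.5 with 4 samples per group. `make_mutation_table`
draws Bernoulli MUT/WT calls. All generators are pure functions of their
spec and seed.

What the generators do *not* emulate: real pathway topology (no reaction
edges), realistic gene symbols, correlated expression structure,
heavy-tailed or batch-confounded noise, and mutation co-occurrence.
Passing the planted-signal checks therefore shows the pipeline propagates
a block-structured mean shift faithfully; it says nothing about power under
realistic covariance or annotation error.

## Problem sizes and numerics

The geometric checks use 20 random site sets of up to 200 sites on an
800×600 canvas with 10^4 probe points each; probes within 1e-6 of a cell
border are skipped (membership there is genuinely ambiguous in floating
point) and polygons are buffered by 1e-6 px for containment tests. The
enumeration check covers every hypergeometric configuration with N ≤ 12
(3184 cases). Tile consistency is checked to level 3 (a 2048-pixel world).
Fixture maps use 5 modules × 6 entities, aliasing rate 0.1, max zoom 3.

## Known limitations

* No pathway-format import (CellDesigner/SBGN/Cytoscape); maps must already
  be positioned and expressed in the JSON dialect.
* Reaction edges are not modeled or drawn; all five visualization modes
  need only entity positions.
* Rendering is deliberately plain (no anti-aliasing, no labels); the tile
  pyramid targets slippy-map viewers rather than publication graphics.
* Identifier conversion is out of scope: data rows must already use HUGO
  symbols.
* The enrichment universe is the map; results are not comparable to
  genome-universe enrichment tools.
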