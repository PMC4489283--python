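# pathstain

Visualize multi-omics data on top of positioned biological network maps.

Large pathway maps — hundreds to thousands of positioned molecular species
— are hard to read once quantitative data is attached to individual nodes:
per-node charts disappear at the zoom levels where the map as a whole is
visible. `pathstain` implements five graphical modes over one map model,
from per-node detail up to whole-map trends:

* **markers** — Google-Maps-style pins on every occurrence of a gene
  (including inside complexes);
* **heatmaps** — a grid per entity: rows are data tables, columns are
  samples or sample groups;
* **barplots** — bar heights proportional to values, normalized per data
  table so bars compare across the map;
* **glyphs** — up to five small shapes per entity whose shape, color and
  size channels can be bound to *different* tables (e.g. shape from copy
  number, color from expression, size from mutation frequency);
* **map staining** — the territory around each entity (its Voronoi cell,
  clipped to the canvas and extent-limited) is filled with the color of the
  entity's value, so a whole transcriptome projected on the map is readable
  at the top zoom level.

Around these sit typed tab-delimited data ingestion (expression, copy
number, mutation, gene lists — each with a representation-appropriate
group-summarization rule), hypergeometric module enrichment for gene lists,
semantic-zoom rendering into a 256 px `z/x/y.png` tile pyramid, a
session-based JSON command service, and a batch CLI. Intended users are
computational biologists with a laid-out map (as a JSON descriptor) and
matrices keyed by HUGO gene symbols.

## The statistics at the core

**Group summaries.** Continuous values average over the group (median/min/
max selectable); mutation data summarizes as "at least one member of the
group is mutated"; discrete copy number takes the mode with ties broken
toward the largest magnitude; gene lists take unions.

**Map staining.** The territory of entity *i* at position *p\_i* is the
Voronoi cell {x : ‖x − p\_i‖ ≤ ‖x − p\_j‖ ∀j}, intersected with the canvas
and with a square of half-width 3× the median nearest-neighbor site
distance (so isolated entities do not own half the canvas).

**Module enrichment.** For an uploaded list, each module is scored with the
upper-tail hypergeometric probability

    P(X ≥ k) = Σ_{i=k}^{min(K,n)} C(K,i) C(N−K, n−i) / C(N,n)

where N = distinct symbols on the map, K = the module's symbols, n = list
symbols found on the map, k = the overlap; Benjamini–Hochberg q-values are
reported alongside raw p.

## Worked example

Everything below runs from the built-in generators — no downloads. We make
a 5-module grid map, plant a +2.0 expression shift on module `mod3` in the
disease group (noise sd 0.5), stain the map with the disease-group means,
and ask the enrichment test to find the module back:

```python
import pathstain as ps
from pathstain.fixtures import FixtureSpec, make_grid_map, make_expression_table

nmap = make_grid_map(FixtureSpec(seed=11))
print(f"map: {nmap.name}: {len(nmap.entities)} entities, {len(nmap.modules)} modules")

matrix, annotation = make_expression_table(
    nmap, group_sizes={"disease": 4, "control": 4},
    module_effects={"disease": {"mod3": 2.0}}, noise_sd=0.5, seed=41)
table = ps.parse_data_table(matrix, "mrna_expression", name="EXPR")
groups = {g.group_id: g for g in ps.build_groups(ps.parse_annotation(annotation), "group")}
disease_mean = ps.summarize_group(table, groups["group=disease"])

values = {g: float(v) for g, v in disease_mean.items()}
scale = ps.expression_scale(values.values())          # min→green, median→white, max→red
layer = ps.build_staining_layer(nmap, values, scale)
print(f"staining: {len(layer.cells)} cells, "
      f"{sum(f is not None for f in layer.fills)} stained, "
      f"scale anchors at {[round(v, 2) for v, _ in scale.anchors]}")

by_id = {e.entity_id: e for e in nmap.entities}
planted = sorted({s for eid in nmap.module('mod3').member_ids
                  for s in by_id[eid].hugo_symbols})
for r in ps.module_enrichment(nmap, planted)[:3]:
    print(f"{r.module_id}\tN={r.N} K={r.K} n={r.n} k={r.k}\tp={r.p_value:.3g}\tq={r.q_value:.3g}")

img = ps.render_level(nmap, layer, zoom=2)
print(f"zoom-2 raster: {img.width}x{img.height}")
```

prints

```
map: grid-map-5x6-seed11: 34 entities, 5 modules
staining: 34 cells, 34 stained, scale anchors at [7.58, 8.07, 10.33]
mod3	N=30 K=6 n=6 k=6	p=1.68e-06	q=8.42e-06
mod0	N=30 K=6 n=6 k=0	p=1	q=1
mod1	N=30 K=6 n=6 k=0	p=1	q=1
zoom-2 raster: 400x300
```

The planted module ranks first: all k = 6 of its genes are in the n = 6
uploaded symbols, out of K = 6 module symbols in an N = 30 symbol map
universe — P(X ≥ 6) = 1/C(30,6)·... ≈ 1.7×10⁻⁶. Its block of the map
stains toward the red (high) anchor, while the baseline modules sit near
the white median anchor (8.07 ≈ the baseline of 8).

The same pipeline as shell commands:

```sh
pathstain import-map map.json
pathstain load-data expr.tsv --type mrna_expression --name EXPR
pathstain groups ann.tsv --factor group
pathstain stain --table EXPR --group group=disease --bw
pathstain render --zoom 2 --out out.png
pathstain tiles --out tiles/          # 256px PNG pyramid, tiles/z/x/y.png
pathstain enrich genes.txt
pathstain serve --port 8080           # JSON command endpoint
```

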