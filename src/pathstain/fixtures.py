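"""Deterministic generators for maps and omics tables.

These are first-class inputs, not test scaffolding: they emit exactly the
JSON map descriptors and tab-delimited matrices the rest of the pipeline
consumes, so every stage is exercisable without any external pathway or
cohort download.

``make_grid_map`` lays modules out as disjoint spatial blocks on a grid.
The block layout is intentional: when a data table up-shifts one module's
genes, its staining territory is a contiguous region whose mean cell color
can be measured, which is how the end-to-end planted-signal checks work.
Symbols are synthetic (GENE0001, ...), a configurable fraction are placed
twice (aliases), one complex shares its members' symbols, and ``min_zoom``
is staggered across entities so semantic zooming is exercised.

``make_expression_table`` draws values as baseline + per-module group effect
+ Gaussian noise; ``make_mutation_table`` draws Bernoulli MUT/WT labels.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .map_model import MapEntity, ModuleDef, NetworkMap

__all__ = [
    "FixtureSpec",
    "make_grid_map",
    "make_expression_table",
    "make_mutation_table",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_modules: int = 5
    entities_per_module: int = 6
    canvas: tuple[float, float] = (800.0, 600.0)
    max_zoom: int = 3
    aliasing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.entities_per_module < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.aliasing_rate <= 1.0):
            raise ValueError("aliasing_rate must be in [0, 1]")


def make_grid_map(spec: FixtureSpec) -> NetworkMap:
    """A synthetic map with modules as spatial blocks.

    Module m occupies one block of a near-square grid; its entities sit on a
    jittered sub-grid inside the block.  Entity i of a module has
    ``min_zoom = 0`` when i < 2 (so every module is visible at the top view)
    and ``i % (max_zoom + 1)`` otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    width, height = spec.canvas
    ncols = math.ceil(math.sqrt(spec.n_modules))
    nrows = math.ceil(spec.n_modules / ncols)
    bw, bh = width / ncols, height / nrows

    sub = math.ceil(math.sqrt(spec.entities_per_module))
    if bw / (sub + 1) < 4 or bh / (sub + 1) < 4:
        raise ValueError(
            f"{spec.entities_per_module} entities per module do not fit a "
            f"{bw:.0f}x{bh:.0f} block; enlarge the canvas"
        )

    entities: list[MapEntity] = []
    modules: list[ModuleDef] = []
    sym_counter = 0
    symbol_home: list[tuple[str, int]] = []  # (symbol, module index)
    for m in range(spec.n_modules):
        bx, by = (m % ncols) * bw, (m // ncols) * bh
        member_ids = []
        for i in range(spec.entities_per_module):
            sym_counter += 1
            symbol = f"GENE{sym_counter:04d}"
            gx, gy = i % sub, i // sub
            x = bx + (gx + 1) * bw / (sub + 1) + float(rng.uniform(-2, 2))
            y = by + (gy + 1) * bh / (sub + 1) + float(rng.uniform(-2, 2))
            x = min(max(x, 1.0), width - 1.0)
            y = min(max(y, 1.0), height - 1.0)
            eid = f"M{m}_E{i}"
            entities.append(
                MapEntity(
                    entity_id=eid,
                    label=symbol,
                    entity_class="protein",
                    hugo_symbols=(symbol,),
                    position=(round(x, 1), round(y, 1)),
                    bbox=(28.0, 14.0),
                    module_ids=(f"mod{m}",),
                    min_zoom=0 if i < 2 else i % (spec.max_zoom + 1),
                )
            )
            member_ids.append(eid)
            symbol_home.append((symbol, m))
        modules.append(
            ModuleDef(module_id=f"mod{m}", name=f"Module {m}", member_ids=tuple(member_ids))
        )

    # aliases: a fraction of symbols appear a second time, inside the same
    # module block so module symbol sets stay clean
    n_alias = int(spec.aliasing_rate * len(symbol_home))
    alias_idx = rng.choice(len(symbol_home), size=n_alias, replace=False)
    members_extra: dict[int, list[str]] = {}
    for j, idx in enumerate(sorted(int(i) for i in alias_idx)):
        symbol, m = symbol_home[idx]
        bx, by = (m % ncols) * bw, (m // ncols) * bh
        x = bx + float(rng.uniform(0.15, 0.85)) * bw
        y = by + float(rng.uniform(0.15, 0.85)) * bh
        eid = f"M{m}_ALIAS{j}"
        entities.append(
            MapEntity(
                entity_id=eid,
                label=f"{symbol}*",
                entity_class="protein",
                hugo_symbols=(symbol,),
                position=(round(min(max(x, 1.0), width - 1.0), 1),
                          round(min(max(y, 1.0), height - 1.0), 1)),
                bbox=(28.0, 14.0),
                module_ids=(f"mod{m}",),
                min_zoom=0,
            )
        )
        members_extra.setdefault(m, []).append(eid)

    # one complex sharing the symbols of module 0's first two entities
    cplx_syms = tuple(s for s, m in symbol_home if m == 0)[: min(2, spec.entities_per_module)]
    cx = (0 % ncols) * bw + bw * 0.5
    cy = (0 // ncols) * bh + bh * 0.5
    entities.append(
        MapEntity(
            entity_id="M0_CPLX",
            label=":".join(cplx_syms),
            entity_class="complex",
            hugo_symbols=cplx_syms,
            position=(round(min(cx + 3.0, width - 1.0), 1), round(min(cy + 3.0, height - 1.0), 1)),
            bbox=(40.0, 18.0),
            module_ids=("mod0",),
            min_zoom=0,
        )
    )
    members_extra.setdefault(0, []).append("M0_CPLX")

    modules = [
        ModuleDef(
            module_id=mod.module_id,
            name=mod.name,
            member_ids=mod.member_ids + tuple(members_extra.get(m, [])),
        )
        for m, mod in enumerate(modules)
    ]
    return NetworkMap(
        name=f"grid-map-{spec.n_modules}x{spec.entities_per_module}-seed{spec.seed}",
        canvas_width=width,
        canvas_height=height,
        max_zoom=spec.max_zoom,
        entities=tuple(entities),
        modules=tuple(modules),
    )


def _module_of_symbol(nmap: NetworkMap) -> dict[str, set[str]]:
    by_id = {e.entity_id: e for e in nmap.entities}
    out: dict[str, set[str]] = {}
    for mod in nmap.modules:
        for eid in mod.member_ids:
            for s in by_id[eid].hugo_symbols:
                out.setdefault(s, set()).add(mod.module_id)
    return out


def make_expression_table(
    nmap: NetworkMap,
    group_sizes: dict[str, int],
    module_effects: dict[str, dict[str, float]],
    baseline: float = 8.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[str, str]:
    """Tab-delimited expression matrix + sample annotation for a design.

    One gene row per distinct map symbol; samples named ``<group>_<i>``.
    ``values ~ baseline + sum(module effects for the sample's group over the
    gene's modules) + N(0, noise_sd)``.  Returns ``(matrix_text,
    annotation_text)``; the annotation has a single factor ``group``.
    The defaults mimic log2 microarray intensities (baseline 8, sd 0.5).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(nmap.all_symbols())
    if not genes:
        raise ValueError("map has no symbols")
    sym_mods = _module_of_symbol(nmap)
    samples = [
        (f"{group}_{i + 1}", group)
        for group in group_sizes
        for i in range(group_sizes[group])
    ]
    lines = ["GENE\t" + "\t".join(s for s, _ in samples)]
    for gene in genes:
        row = [gene]
        for _, group in samples:
            effect = sum(
                module_effects.get(group, {}).get(mid, 0.0)
                for mid in sym_mods.get(gene, ())
            )
            v = baseline + effect + (float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0)
            row.append(format(v, ".10g"))
        lines.append("\t".join(row))
    matrix_text = "\n".join(lines) + "\n"
    ann_lines = ["SAMPLE\tgroup"] + [f"{s}\t{g}" for s, g in samples]
    return matrix_text, "\n".join(ann_lines) + "\n"


def make_mutation_table(
    nmap: NetworkMap,
    frequency,
    samples,
    seed: int = 0,
) -> str:
    """Tab-delimited MUT/WT matrix with per-gene Bernoulli mutation calls.

    ``frequency`` is a single rate in [0, 1] or a per-gene dict (missing
    genes default to 0).  ``samples`` is a count (names S1..Sn) or an
    explicit list of sample ids, e.g. the ids of an expression table so the
    same annotation groups apply to both.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(nmap.all_symbols())
    freqs = (
        {g: float(frequency) for g in genes}
        if np.isscalar(frequency)
        else {g: float(frequency.get(g, 0.0)) for g in genes}
    )
    for g, f in freqs.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"frequency for {g} must be in [0, 1], got {f}")
    if isinstance(samples, (int, np.integer)):
        samples = [f"S{i + 1}" for i in range(samples)]
    else:
        samples = list(samples)
    lines = ["GENE\t" + "\t".join(samples)]
    for gene in genes:
        calls = rng.random(len(samples)) < freqs[gene]
        lines.append(gene + "\t" + "\t".join("MUT" if c else "WT" for c in calls))
    return "\n".join(lines) + "\n"
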