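"""Positioned network maps.

A :class:`NetworkMap` is the substrate every visualization mode draws on: a
pixel canvas (origin top-left, y increasing downward) carrying positioned
molecular entities (proteins, genes, complexes, phenotypes, ...), each tagged
with the HUGO/HGNC gene symbols it represents, the modules (pathway sections)
it belongs to, and the smallest zoom level at which it is drawn (semantic
zooming).  Maps are read from and written to a self-contained JSON descriptor
so the whole pipeline is testable without any pathway-editor file format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "ENTITY_CLASSES",
    "MapEntity",
    "ModuleDef",
    "NetworkMap",
    "MapValidationError",
    "canonical_symbol",
    "load_map",
    "loads_map",
    "save_map",
    "dumps_map",
    "symbol_index",
    "resolve_symbols",
    "visible_entities",
]

ENTITY_CLASSES = frozenset(
    {"protein", "gene", "rna", "microrna", "complex", "phenotype", "metabolite", "drug"}
)


class MapValidationError(ValueError):
    """A map descriptor violates a structural invariant; names the culprit id."""


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: whitespace-stripped, uppercased.

    HUGO symbols are conventionally uppercase; user files vary in case and
    stray whitespace, so all matching in the package is done on this form.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class MapEntity:
    """One positioned molecular species on the map.

    ``position`` is the anchor point (pixel units); ``bbox`` is the drawn
    width/height around it.  ``hugo_symbols`` may be empty (phenotypes); a
    complex lists the symbols of its components.  ``min_zoom`` is the
    smallest zoom level at which the entity is shown.
    """

    entity_id: str
    label: str
    entity_class: str
    hugo_symbols: tuple[str, ...] = ()
    position: tuple[float, float] = (0.0, 0.0)
    bbox: tuple[float, float] = (40.0, 20.0)
    module_ids: tuple[str, ...] = ()
    min_zoom: int = 0

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise MapValidationError(
                f"entity {self.entity_id!r}: unknown class {self.entity_class!r} "
                f"(expected one of {sorted(ENTITY_CLASSES)})"
            )
        # canonicalize + dedupe symbols, preserving first-seen order
        seen: dict[str, None] = {}
        for s in self.hugo_symbols:
            c = canonical_symbol(s)
            if c:
                seen.setdefault(c, None)
        object.__setattr__(self, "hugo_symbols", tuple(seen))
        if self.min_zoom < 0:
            raise MapValidationError(f"entity {self.entity_id!r}: min_zoom must be >= 0")


@dataclass(frozen=True)
class ModuleDef:
    """A named subset of map entities (e.g. a pathway section)."""

    module_id: str
    name: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise MapValidationError(f"module {self.module_id!r}: empty member list")


@dataclass(frozen=True)
class NetworkMap:
    name: str
    canvas_width: float
    canvas_height: float
    max_zoom: int
    entities: tuple[MapEntity, ...] = ()
    modules: tuple[ModuleDef, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.canvas_width <= 0 or self.canvas_height <= 0:
            raise MapValidationError("canvas dimensions must be positive")
        if self.max_zoom < 0:
            raise MapValidationError("max_zoom must be >= 0")
        seen_ids: set[str] = set()
        for e in self.entities:
            if e.entity_id in seen_ids:
                raise MapValidationError(f"duplicate entity_id {e.entity_id!r}")
            seen_ids.add(e.entity_id)
            x, y = e.position
            if not (0 <= x < self.canvas_width and 0 <= y < self.canvas_height):
                raise MapValidationError(
                    f"entity {e.entity_id!r}: position ({x}, {y}) outside "
                    f"{self.canvas_width}x{self.canvas_height} canvas"
                )
            if e.min_zoom > self.max_zoom:
                raise MapValidationError(
                    f"entity {e.entity_id!r}: min_zoom {e.min_zoom} exceeds map "
                    f"max_zoom {self.max_zoom}"
                )
        seen_mods: set[str] = set()
        for m in self.modules:
            if m.module_id in seen_mods:
                raise MapValidationError(f"duplicate module_id {m.module_id!r}")
            seen_mods.add(m.module_id)
            for mid in m.member_ids:
                if mid not in seen_ids:
                    raise MapValidationError(
                        f"module {m.module_id!r}: member {mid!r} is not an entity on the map"
                    )

    def entity(self, entity_id: str) -> MapEntity:
        for e in self.entities:
            if e.entity_id == entity_id:
                return e
        raise KeyError(entity_id)

    def module(self, module_id: str) -> ModuleDef:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def all_symbols(self) -> set[str]:
        """Distinct canonical symbols present anywhere on the map."""
        out: set[str] = set()
        for e in self.entities:
            out.update(e.hugo_symbols)
        return out


# ---------------------------------------------------------------------------
# JSON descriptor (de)serialization
#
# Top-level keys: name, canvas:{width,height,max_zoom},
#   entities:[{id,label,class,hugo,x,y,w,h,modules,min_zoom}],
#   modules:[{id,name,members}].
# `hugo` and `modules` default to [], `min_zoom` to 0.
# ---------------------------------------------------------------------------


def loads_map(descriptor_text: str) -> NetworkMap:
    """Parse a JSON map descriptor.

    Raises ``json.JSONDecodeError`` (carrying the byte position) on malformed
    JSON and :class:`MapValidationError` (naming the offending id) on
    invariant violations.
    """
    doc = json.loads(descriptor_text)
    canvas = doc.get("canvas", {})
    entities = []
    # modules listed on entities and in the modules table are reconciled:
    # the modules table is authoritative, entity-level tags are a convenience
    ent_mods: dict[str, list[str]] = {}
    for ed in doc.get("entities", []):
        eid = ed["id"]
        ent_mods[eid] = list(ed.get("modules", []))
        entities.append(
            MapEntity(
                entity_id=eid,
                label=ed.get("label", eid),
                entity_class=ed.get("class", "protein"),
                hugo_symbols=tuple(ed.get("hugo", [])),
                position=(float(ed["x"]), float(ed["y"])),
                bbox=(float(ed.get("w", 40)), float(ed.get("h", 20))),
                module_ids=tuple(ed.get("modules", [])),
                min_zoom=int(ed.get("min_zoom", 0)),
            )
        )
    modules = []
    declared = {md["id"] for md in doc.get("modules", [])}
    for md in doc.get("modules", []):
        members = list(md.get("members", []))
        extra = [eid for eid, mods in ent_mods.items() if md["id"] in mods and eid not in members]
        modules.append(
            ModuleDef(module_id=md["id"], name=md.get("name", md["id"]), member_ids=tuple(members + extra))
        )
    # entity-level module tags referring to undeclared modules are an error
    for eid, mods in ent_mods.items():
        for mid in mods:
            if mid not in declared:
                raise MapValidationError(
                    f"entity {eid!r}: references undeclared module {mid!r}"
                )
    return NetworkMap(
        name=doc.get("name", "unnamed"),
        canvas_width=float(canvas.get("width", 0)),
        canvas_height=float(canvas.get("height", 0)),
        max_zoom=int(canvas.get("max_zoom", 0)),
        entities=tuple(entities),
        modules=tuple(modules),
    )


def load_map(stream) -> NetworkMap:
    """Read a map descriptor from a text stream or file path."""
    if isinstance(stream, (str,)) and "\n" not in stream and stream.strip().startswith("{") is False:
        with open(stream, "r", encoding="utf-8") as fh:
            return loads_map(fh.read())
    if hasattr(stream, "read"):
        return loads_map(stream.read())
    return loads_map(stream)


def dumps_map(nmap: NetworkMap) -> str:
    """Serialize to the canonical descriptor form (sorted keys, 2-space indent).

    ``loads_map(dumps_map(m))`` reproduces ``m`` exactly, and ``dumps_map`` is
    byte-stable, so canonical descriptors round-trip bit-identically.
    """
    doc = {
        "name": nmap.name,
        "canvas": {
            "width": nmap.canvas_width,
            "height": nmap.canvas_height,
            "max_zoom": nmap.max_zoom,
        },
        "entities": [
            {
                "id": e.entity_id,
                "label": e.label,
                "class": e.entity_class,
                "hugo": list(e.hugo_symbols),
                "x": e.position[0],
                "y": e.position[1],
                "w": e.bbox[0],
                "h": e.bbox[1],
                "modules": list(e.module_ids),
                "min_zoom": e.min_zoom,
            }
            for e in nmap.entities
        ],
        "modules": [
            {"id": m.module_id, "name": m.name, "members": list(m.member_ids)}
            for m in nmap.modules
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def save_map(nmap: NetworkMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_map(nmap))


# ---------------------------------------------------------------------------
# Symbol lookup and zoom visibility
# ---------------------------------------------------------------------------


def symbol_index(nmap: NetworkMap) -> dict[str, list[str]]:
    """Map each canonical symbol to the ids of every entity carrying it.

    Entities sharing a symbol — aliases of the same protein, complexes listing
    it as a component, modified forms — all appear, which is what lets a
    single uploaded gene row decorate every occurrence on the map.
    """
    index: dict[str, list[str]] = {}
    for e in nmap.entities:
        for s in e.hugo_symbols:
            index.setdefault(s, []).append(e.entity_id)
    return index


def resolve_symbols(
    nmap: NetworkMap, symbols: list[str]
) -> tuple[dict[str, list[str]], list[str]]:
    """Split a symbol list into (matched symbol -> entity ids, unmatched).

    Input symbols are canonicalized and deduplicated first; matched and
    unmatched together partition the deduplicated input.
    """
    index = symbol_index(nmap)
    matched: dict[str, list[str]] = {}
    unmatched: list[str] = []
    seen: set[str] = set()
    for raw in symbols:
        s = canonical_symbol(raw)
        if not s or s in seen:
            continue
        seen.add(s)
        if s in index:
            matched[s] = list(index[s])
        else:
            unmatched.append(s)
    return matched, unmatched


def visible_entities(nmap: NetworkMap, zoom: int) -> list[MapEntity]:
    """Entities drawn at a zoom level: exactly those with ``min_zoom <= zoom``.

    Monotone in ``zoom`` by construction (semantic zooming only ever reveals).
    """
    if not (0 <= zoom <= nmap.max_zoom):
        raise ValueError(f"zoom {zoom} out of range [0, {nmap.max_zoom}]")
    return [e for e in nmap.entities if e.min_zoom <= zoom]
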