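"""Session-based JSON command service.

Mirrors a RESTful visualization server: a client opens a session (a unique
128-bit token), then issues JSON commands against it — load a map, import
data tables, define sample groups, configure staining and overlays, render,
run enrichment, or list the map's HUGO symbols.  All state lives in the
session; interleaved sessions never observe each other.

The HTTP transport (``serve``) is a thin layer on the standard library's
``http.server``: ``POST /session`` opens a session, ``POST
/commands/<action>`` with a JSON body ``{"session_id": ..., "params":
{...}}`` executes a command.  Everything the transport can do is available
in-process through :func:`execute_command`, which is also what the batch CLI
replays.
"""

from __future__ import annotations

import base64
import io
import json
import math
import secrets
from dataclasses import dataclass, field

import numpy as np

from . import color_render, enrichment, map_staining, overlays as ov
from .map_model import NetworkMap, loads_map, symbol_index
from .omics_data import (
    DataTable,
    SampleAnnotation,
    SampleGroup,
    build_groups,
    parse_annotation,
    parse_data_table,
    summarize_group,
)

__all__ = ["Session", "ServiceState", "create_session", "execute_command", "serve", "ACTIONS"]

ACTIONS = (
    "load_map",
    "import_datatable",
    "define_groups",
    "set_staining",
    "add_overlay",
    "render",
    "enrich",
    "list_hugo",
)


@dataclass
class Session:
    session_id: str
    nmap: NetworkMap | None = None
    tables: dict[str, DataTable] = field(default_factory=dict)
    annotation: SampleAnnotation | None = None
    groups: dict[str, SampleGroup] = field(default_factory=dict)
    staining: map_staining.StainingLayer | None = None
    overlays: dict[str, list] = field(default_factory=dict)


@dataclass
class ServiceState:
    sessions: dict[str, Session] = field(default_factory=dict)


def create_session(state: ServiceState) -> str:
    sid = secrets.token_hex(16)
    state.sessions[sid] = Session(session_id=sid)
    return sid


class CommandError(ValueError):
    def __init__(self, message: str, code: int = 400):
        super().__init__(message)
        self.code = code


def _require(params: dict, key: str):
    if key not in params:
        raise CommandError(f"missing required parameter {key!r}")
    return params[key]


def _require_map(session: Session) -> NetworkMap:
    if session.nmap is None:
        raise CommandError("no map loaded")
    return session.nmap


def _resolve_column(session: Session, table: DataTable, name: str | None):
    """A column spec is a defined group id, a sample id, or None (all samples)."""
    if name is None:
        return SampleGroup(group_id="all", members=tuple(table.samples))
    if name in session.groups:
        return session.groups[name]
    if name in table.values.columns:
        return name
    raise CommandError(f"{name!r} is neither a defined group nor a sample of {table.name!r}")


def _gene_values(session: Session, table: DataTable, column) -> dict[str, float]:
    if isinstance(column, SampleGroup):
        series = summarize_group(table, column)
    else:
        series = table.values[column]
    return {
        g: float(v)
        for g, v in series.items()
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    }


def _default_scale(table: DataTable, values: dict[str, float]) -> color_render.ColorScale:
    if table.internal_repr == "discrete_ordered":
        return color_render.COPY_NUMBER_SCALE
    return color_render.expression_scale(values.values())


# ---------------------------------------------------------------------------
# command handlers
# ---------------------------------------------------------------------------


def _cmd_load_map(session: Session, params: dict) -> dict:
    session.nmap = loads_map(_require(params, "descriptor"))
    session.staining = None
    session.overlays = {}
    return {"name": session.nmap.name, "entities": len(session.nmap.entities)}


def _cmd_import_datatable(session: Session, params: dict) -> dict:
    name = _require(params, "name")
    table = parse_data_table(
        _require(params, "text"),
        _require(params, "data_type"),
        name=name,
        aggregate_duplicates=params.get("aggregate_duplicates"),
    )
    session.tables[name] = table
    return {"name": name, "genes": len(table.genes), "samples": len(table.samples)}


def _cmd_define_groups(session: Session, params: dict) -> dict:
    session.annotation = parse_annotation(_require(params, "annotation"))
    factor = _require(params, "factor")
    groups = build_groups(session.annotation, factor)
    for g in groups:
        session.groups[g.group_id] = g
    return {"groups": {g.group_id: list(g.members) for g in groups}}


def _cmd_set_staining(session: Session, params: dict) -> dict:
    nmap = _require_map(session)
    table = session.tables.get(_require(params, "table"))
    if table is None:
        raise CommandError(f"table {params['table']!r} not imported")
    column = _resolve_column(session, table, params.get("group") or params.get("sample"))
    values = _gene_values(session, table, column)
    scale = _default_scale(table, values)
    session.staining = map_staining.build_staining_layer(
        nmap,
        values,
        scale,
        opacity=float(params.get("opacity", 0.6)),
        background_mode=params.get("background", "bw"),
        radius_factor=float(params.get("radius_factor", 3.0)),
    )
    stained = sum(1 for f in session.staining.fills if f is not None)
    return {"cells": len(session.staining.cells), "stained": stained}


def _cmd_add_overlay(session: Session, params: dict) -> dict:
    nmap = _require_map(session)
    kind = _require(params, "kind")
    added = 0
    if kind == "marker":
        markers, unmatched = ov.build_markers(nmap, _require(params, "symbols"))
        for m in markers:
            session.overlays.setdefault(m.entity_id, []).append(m)
        return {"markers": len(markers), "unmatched": unmatched}

    def table_of(key: str) -> DataTable:
        name = _require(params, key)
        if name not in session.tables:
            raise CommandError(f"table {name!r} not imported")
        return session.tables[name]

    if kind == "glyph":
        column_name = params.get("group") or params.get("sample")
        kwargs: dict = {}
        if "shape_from" in params:
            t = table_of("shape_from")
            kwargs["shape_from"] = (t, _resolve_column(session, t, column_name))
        if "color_from" in params:
            t = table_of("color_from")
            col = _resolve_column(session, t, column_name)
            scale = _default_scale(t, _gene_values(session, t, col)) if t.internal_repr in (
                "continuous", "discrete_ordered") else None
            kwargs["color_from"] = (t, col, scale)
        if "size_from" in params:
            t = table_of("size_from")
            col = _resolve_column(session, t, column_name)
            vals = list(_gene_values(session, t, col).values()) or [0.0, 1.0]
            vmin, vmax = min(vals), max(vals)
            if vmin == vmax:
                vmin, vmax = vmin - 0.5, vmax + 0.5
            kwargs["size_from"] = (t, col, vmin, vmax,
                                   float(params.get("size_min", 6.0)),
                                   float(params.get("size_max", 16.0)))
        if "shape" in params:
            kwargs["shape"] = params["shape"]
        if "color" in params:
            kwargs["color"] = tuple(params["color"])
        for e in nmap.entities:
            if not e.hugo_symbols:
                continue
            existing = next(
                (o for o in session.overlays.get(e.entity_id, []) if isinstance(o, ov.GlyphOverlay)),
                None,
            )
            base = existing or ov.GlyphOverlay(entity_id=e.entity_id)
            new = ov.attach_glyph(
                base, size_px=float(params.get("size", 12.0)), symbols=e.hugo_symbols, **kwargs
            )
            if new is base or new == base:
                continue
            lst = session.overlays.setdefault(e.entity_id, [])
            if existing is not None:
                lst[lst.index(existing)] = new
            else:
                lst.append(new)
            added += 1
        return {"glyphs": added}

    if kind == "heatmap":
        tables = [table_of_name(session, t) for t in _require(params, "tables")]
        col_names = _require(params, "columns")
        scales = {}
        selections = []
        for t in tables:
            cols = [_resolve_column(session, t, c) for c in col_names]
            selections.append((t, cols))
            if t.internal_repr in ("continuous", "discrete_ordered"):
                allv: dict[str, float] = {}
                for c in cols:
                    allv.update(_gene_values(session, t, c))
                scales[t.name] = _default_scale(t, allv)
        for e in nmap.entities:
            hm = ov.build_heatmap(e, selections, scales)
            if hm is not None:
                session.overlays.setdefault(e.entity_id, []).append(hm)
                added += 1
        return {"heatmaps": added}

    if kind == "barplot":
        t = table_of("table")
        cols = [_resolve_column(session, t, c) for c in _require(params, "columns")]
        for e in nmap.entities:
            bp = ov.build_barplot(e, t, cols)
            if bp is not None:
                session.overlays.setdefault(e.entity_id, []).append(bp)
                added += 1
        return {"barplots": added}

    raise CommandError(f"unknown overlay kind {kind!r}")


def table_of_name(session: Session, name: str) -> DataTable:
    if name not in session.tables:
        raise CommandError(f"table {name!r} not imported")
    return session.tables[name]


def _cmd_render(session: Session, params: dict) -> dict:
    nmap = _require_map(session)
    zoom = int(params.get("zoom", nmap.max_zoom))
    try:
        img = color_render.render_level(
            nmap,
            session.staining,
            session.overlays,
            zoom=zoom,
            background_mode=params.get("background"),
        )
    except ValueError as exc:
        raise CommandError(str(exc)) from None
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return {
        "format": "png",
        "width": img.width,
        "height": img.height,
        "data_base64": base64.b64encode(buf.getvalue()).decode("ascii"),
    }


def _cmd_enrich(session: Session, params: dict) -> dict:
    nmap = _require_map(session)
    genes = params.get("genes")
    if genes is None:
        genes = [ln.strip() for ln in _require(params, "text").splitlines() if ln.strip()]
    try:
        rows = enrichment.module_enrichment(nmap, genes)
    except ValueError as exc:
        raise CommandError(str(exc)) from None
    return {
        "rows": [
            {
                "module_id": r.module_id,
                "name": r.name,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in rows
        ]
    }


def _cmd_list_hugo(session: Session, params: dict) -> dict:
    nmap = _require_map(session)
    return {"symbols": sorted(nmap.all_symbols())}


_HANDLERS = {
    "load_map": _cmd_load_map,
    "import_datatable": _cmd_import_datatable,
    "define_groups": _cmd_define_groups,
    "set_staining": _cmd_set_staining,
    "add_overlay": _cmd_add_overlay,
    "render": _cmd_render,
    "enrich": _cmd_enrich,
    "list_hugo": _cmd_list_hugo,
}


def execute_command(state: ServiceState, session_id: str, command: dict) -> dict:
    """Dispatch one JSON command against a session.

    Responses always carry ``status`` plus either ``payload`` or ``error``
    (with an HTTP-style ``code``: 404 unknown session, 400 bad command).
    """
    session = state.sessions.get(session_id)
    if session is None:
        return {"status": "error", "code": 404, "error": f"unknown session {session_id!r}"}
    action = command.get("action")
    handler = _HANDLERS.get(action)
    if handler is None:
        return {
            "status": "error",
            "code": 400,
            "error": f"unknown action {action!r}; known: {list(ACTIONS)}",
        }
    params = command.get("params") or {}
    if not isinstance(params, dict):
        return {"status": "error", "code": 400, "error": "params must be an object"}
    try:
        payload = handler(session, params)
    except CommandError as exc:
        return {"status": "error", "code": exc.code, "error": str(exc)}
    except (ValueError, KeyError) as exc:
        return {"status": "error", "code": 400, "error": str(exc)}
    return {"status": "ok", "code": 200, "payload": payload}


# ---------------------------------------------------------------------------
# HTTP transport
# ---------------------------------------------------------------------------


def make_server(state: ServiceState, port: int = 8080):
    """Build (without starting) the HTTP server bound to localhost:port."""
    from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # quiet by default
            pass

        def _reply(self, code: int, doc: dict) -> None:
            body = json.dumps(doc).encode("utf-8")
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_POST(self) -> None:
            length = int(self.headers.get("Content-Length", 0))
            raw = self.rfile.read(length) if length else b"{}"
            try:
                doc = json.loads(raw or b"{}")
            except json.JSONDecodeError as exc:
                self._reply(400, {"status": "error", "code": 400, "error": f"bad JSON: {exc}"})
                return
            if self.path == "/session":
                self._reply(200, {"status": "ok", "code": 200,
                                  "payload": {"session_id": create_session(state)}})
                return
            if self.path.startswith("/commands/"):
                action = self.path[len("/commands/"):]
                resp = execute_command(
                    state,
                    doc.get("session_id", ""),
                    {"action": action, "params": doc.get("params", {})},
                )
                self._reply(resp["code"], resp)
                return
            self._reply(404, {"status": "error", "code": 404, "error": f"no route {self.path}"})

    return ThreadingHTTPServer(("127.0.0.1", port), Handler)


def serve(state: ServiceState | None = None, port: int = 8080) -> None:
    """Run the JSON command endpoint until interrupted."""
    server = make_server(state or ServiceState(), port=port)
    try:
        server.serve_forever()
    finally:
        server.server_close()
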