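"""Request pipeline and thin HTTP facade.

The pipeline order is fixed: parse -> query (if requested) -> layout (if
requested; independent of the query) -> highlight -> image.  All three
operation blocks are optional, but a request must carry at least one.
The HTTP facade accepts ``POST /<file_format>`` with a JSON body
``{file_content, layoutOptions?, imageOptions?, queryOptions?}`` and
mirrors the response of :func:`handle_request` as JSON.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Dict, List, Optional

from pydantic import ValidationError

from . import metrics, queries
from .io import ParseError, SourceFormat, read
from .io.elements import write_layout_json
from .layout import LayoutOptions, apply_geometry, layout as run_layout
from .queries import Direction, QueryError
from .raster import rasterize
from .style import HighlightSpec, StyleOptions
from .svg import render_svg

__all__ = ["ServiceRequest", "ServiceResponse", "handle_request", "serve", "make_server"]

QUERY_TYPES = {
    "neighborhood",
    "common_stream",
    "paths_between",
    "paths_from_to",
    "shortest_path",
    "degree",
    "closeness",
    "betweenness",
    "pagerank",
}


@dataclass
class ServiceRequest:
    file_format: str
    file_content: str
    layout_options: Optional[Dict[str, Any]] = None
    image_options: Optional[Dict[str, Any]] = None
    query_options: Optional[Dict[str, Any]] = None

    def validate(self) -> None:
        if not self.file_content:
            raise ValueError("file_content must be non-empty")
        SourceFormat(self.file_format)
        if (
            self.layout_options is None
            and self.image_options is None
            and self.query_options is None
        ):
            raise ValueError(
                "at least one of layout, image or query options must be present"
            )


@dataclass
class ServiceResponse:
    layout: Optional[Dict[str, Any]] = None
    image: Optional[str] = None
    query_result: Optional[Dict[str, Any]] = None
    warnings: List[str] = field(default_factory=list)
    errors: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "layout": self.layout,
                "image": self.image,
                "queryResult": self.query_result,
                "warnings": self.warnings,
                "errors": self.errors,
            }
        )


def _run_query(graph, options: Dict[str, Any]):
    """Returns (QueryResult or None, HighlightSpec, summary dict)."""
    opts = dict(options)
    qtype = opts.pop("type", None)
    if qtype not in QUERY_TYPES:
        raise QueryError(f"unknown query type {qtype!r}")

    if qtype in ("degree", "closeness", "betweenness", "pagerank"):
        unknown = set(opts) - {"decimals"}
        if unknown:
            raise QueryError(f"unknown query option keys: {sorted(unknown)}")
        report = metrics.compute(graph, metrics.Measure(qtype))
        metrics.annotate_with_centrality(graph, report, decimals=opts.get("decimals", 2))
        spec = HighlightSpec(node_thickness=dict(report.normalized))
        summary = {
            "measure": qtype,
            "raw": report.raw,
            "normalized": report.normalized,
        }
        return None, spec, summary

    known = {"direction", "k", "d", "sources", "targets", "limit_k", "additional_d"}
    unknown = set(opts) - known
    if unknown:
        raise QueryError(f"unknown query option keys: {sorted(unknown)}")
    direction = Direction(opts.get("direction", "downstream"))
    k = opts.get("k", opts.get("limit_k"))
    d = int(opts.get("d", opts.get("additional_d", 0)))
    sources = list(opts.get("sources", []))
    targets = list(opts.get("targets", []))

    if qtype == "neighborhood":
        result = queries.neighborhood(graph, sources, direction, k)
    elif qtype == "common_stream":
        result = queries.common_stream(graph, sources, direction, k)
    elif qtype == "paths_between":
        result = queries.paths_between(graph, sources, k if k is not None else 3,
                                       direction)
    elif qtype == "paths_from_to":
        if not targets:
            raise QueryError("paths_from_to requires a target set")
        result = queries.paths_from_to(graph, sources, targets, k, d, direction)
    else:
        if len(sources) != 1 or len(targets) != 1:
            raise QueryError("shortest_path requires one source and one target")
        result = queries.shortest_path(graph, sources[0], targets[0], direction)

    summary = {
        "seedNodes": sorted(result.seed_nodes),
        "resultNodes": sorted(result.result_nodes),
        "resultEdges": sorted(result.result_edges),
        "focusNodes": sorted(result.focus_nodes),
        "distances": result.distances,
        "paths": [list(p) for p in result.paths],
    }
    return result, HighlightSpec.from_query_result(result), summary


def handle_request(request: ServiceRequest) -> ServiceResponse:
    response = ServiceResponse()
    try:
        request.validate()
        report = read(request.file_content, request.file_format)
        graph = report.graph
        response.warnings.extend(report.warnings)

        highlight = HighlightSpec()
        if request.query_options is not None:
            _result, highlight, summary = _run_query(graph, request.query_options)
            response.query_result = summary

        if request.layout_options is not None:
            options = LayoutOptions(**request.layout_options)
            apply_geometry(graph, run_layout(graph, options))
            response.layout = json.loads(write_layout_json(graph))

        if request.image_options is not None:
            style = StyleOptions(**request.image_options)
            if any(n.geometry is None for n in graph.nodes.values()):
                response.warnings.append(
                    "image requested without coordinates; default layout applied"
                )
                apply_geometry(graph, run_layout(graph, LayoutOptions()))
            svg_text = render_svg(graph, highlight, style)
            if style.image_format == "svg":
                response.image = svg_text
            else:
                image = rasterize(svg_text, style)
                response.warnings.extend(image.warnings)
                response.image = base64.b64encode(image.data).decode("ascii")
    except (ParseError, QueryError, ValueError, ValidationError, KeyError) as exc:
        return ServiceResponse(errors=[str(exc)])
    return response


# ---------------------------------------------------------------------------
# HTTP facade
# ---------------------------------------------------------------------------

_USAGE = """<html><body><h1>pathway map service</h1>
<p>POST /sbgnml | /sbml | /graphml | /json with a JSON body:
{"file_content": "...", "layoutOptions": {...}, "imageOptions": {...},
"queryOptions": {...}}</p></body></html>"""


class _Handler(BaseHTTPRequestHandler):
    def log_message(self, fmt, *args):  # quiet by default
        pass

    def do_GET(self) -> None:
        if self.path != "/":
            self._send(404, json.dumps({"errors": ["unknown path"]}), "application/json")
            return
        self._send(200, _USAGE, "text/html")

    def do_POST(self) -> None:
        fmt = self.path.strip("/")
        try:
            SourceFormat(fmt)
        except ValueError:
            self._send(404, json.dumps({"errors": [f"unknown path {self.path!r}"]}),
                       "application/json")
            return
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length).decode("utf-8", errors="replace")
        try:
            payload = json.loads(body) if body else {}
            if not isinstance(payload, dict):
                raise ValueError("request body must be a JSON object")
            request = ServiceRequest(
                file_format=fmt,
                file_content=payload.get("file_content", ""),
                layout_options=payload.get("layoutOptions",
                                           payload.get("layout_options")),
                image_options=payload.get("imageOptions", payload.get("image_options")),
                query_options=payload.get("queryOptions", payload.get("query_options")),
            )
            request.validate()
        except (ValueError, KeyError) as exc:
            self._send(400, json.dumps({"errors": [str(exc)]}), "application/json")
            return
        response = handle_request(request)
        status = 200 if not response.errors else 400
        self._send(status, response.to_json(), "application/json")

    def _send(self, status: int, body: str, content_type: str) -> None:
        data = body.encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", content_type)
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)


def make_server(port: int = 0) -> ThreadingHTTPServer:
    """Bound but not yet serving; ``server_address[1]`` is the actual port."""
    return ThreadingHTTPServer(("127.0.0.1", port), _Handler)


def serve(port: int) -> None:
    """Run the HTTP endpoint until interrupted."""
    server = make_server(port)
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        pass
    finally:
        server.server_close()
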