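# pathmaps

Layout, mining and rendering of biological pathway maps — as a library, a
command-line tool and a thin HTTP service.

`pathmaps` parses pathway maps in four formats — SBGNML (process
description), SBML (Level 2/3 core, with optional layout-package
coordinates), GraphML (with nested graphs) and an elements-JSON dialect —
into a shared *compound graph* model: a directed multigraph whose nodes
additionally live in a containment forest (compartments and molecular
complexes contain other nodes). On top of that model it provides:

- **Graph mining queries** that are aware of compound structure
  (reaching a node also reaches its containment tree at no cost):
  `neighborhood`, `common_stream` (common regulators/targets),
  `paths_between` (bounded-length "missing links" among a seed set),
  `paths_from_to` (all near-shortest paths from a source set to a target
  set, with a length cap `k` and a shortest-path relaxation `d`) and
  `shortest_path`. Traversal direction is `downstream`, `upstream` or
  `both`.
- **Centralities**: degree, harmonic closeness, Brandes betweenness
  (undirected view) and PageRank (directed), each reported raw and
  normalized, with optional label annotation `"NAME (0.42)"` plus a
  highlight-thickness channel for rendering.
- **Automatic compound layout**: a seeded draft placement followed by a
  spring-embedder refinement with ideal-edge-length springs, short-range
  repulsion, parent gravity, a cooling schedule, sibling-overlap removal
  and disconnected-component packing. Compound rectangles are derived
  from their children plus padding, so containment holds by construction.
- **Rendering**: styled SVG (per-class shapes, `red_blue` or
  single-color shade schemes, class-specific arrowheads, query-role
  highlighting with green seeds / red results / yellow links,
  `result_only` cropping) and PNG/JPG rasterization of that SVG dialect
  via Pillow.
- **Fixtures**: a deterministic generator of synthetic pathway maps that
  can emit the same map in all four formats, plus canonical small graphs
  used as test oracles.

## Library quick start

```python
import pathmaps as pm

report = pm.read(open("map.sbgn").read(), "sbgnml")
graph = report.graph

result = pm.common_stream(graph, ["P1", "P2"], pm.Direction.DOWNSTREAM, limit_k=3)
pm.apply_geometry(graph, pm.layout(graph, pm.LayoutOptions(seed=1)))

svg = pm.render_svg(graph, pm.HighlightSpec.from_query_result(result),
                    pm.StyleOptions(scheme="red_blue"))
```

## CLI

```sh
# layout + SVG image of an SBGNML map
pathmaps --input map.sbgn --format sbgnml --layout \
         --layout-out layout.json --image map.svg

# highlighted 2-level upstream neighborhood
pathmaps --input map.json --format json --layout \
         --query neighborhood --sources P1 --direction upstream -k 2 \
         --image out.png

# near-shortest paths with relaxation d=2
pathmaps --input map.json --format json \
         --query paths_from_to --sources S --targets T -d 2

# batch mode: --input may be a directory (formats inferred by extension)
pathmaps --input maps/ --layout --layout-out layouts/

# regenerate the synthetic fixture pathway in all four formats
pathmaps --emit-fixtures fixtures/
```

Exit codes: `0` success, `1` processing error, `2` usage error.
`--config FILE` supplies `section.key = value` defaults (sections
`layout.` and `image.`); explicit flags override it.

## HTTP service

```sh
pathmaps --serve 3000
```

POST to `/<file_format>` (`sbgnml`, `sbml`, `graphml` or `json`) with a
JSON body; all three operation blocks are optional but at least one must
be present:

```sh
curl -X POST -H "Content-Type: application/json" --data '{
  "file_content": "...map text...",
  "layoutOptions": {"ideal_edge_length": 60},
  "imageOptions": {"image_format": "svg", "scheme": "red_blue"},
  "queryOptions": {"type": "common_stream", "sources": ["P1", "P2"]}
}' http://localhost:3000/sbgnml
```

The response carries `layout` (node-id → `{x, y, w, h}` centers),
`image` (SVG text, or base64 for raster formats), `queryResult`,
`warnings` and `errors`.

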