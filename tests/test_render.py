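import io
import xml.etree.ElementTree as ET

import pytest
from PIL import Image

from pathmaps.core import NodeClass, NodeGeometry
from pathmaps.fixtures import FixtureSpec, generate_pathway
from pathmaps.layout import LayoutOptions, apply_geometry, layout
from pathmaps.raster import RasterError, rasterize
from pathmaps.style import HighlightSpec, StyleOptions, node_style
from pathmaps.svg import RenderError, render_svg

from conftest import build_graph

SVG_NS = "{http://www.w3.org/2000/svg}"


def svg_root(text):
    return ET.fromstring(text)


def elements_by_class(root, cls):
    return [el for el in root.iter() if el.get("class") == cls]


@pytest.fixture
def laid_out_graph():
    g = generate_pathway(FixtureSpec(6, 3, 1, 1, seed=7))
    apply_geometry(g, layout(g, LayoutOptions(seed=7)))
    return g


class TestNodeStyle:
    def test_red_blue_scheme_colors(self):
        assert node_style(NodeClass.SIMPLE_CHEMICAL, "red_blue").fill == "#E53935"
        assert node_style(NodeClass.MACROMOLECULE, "red_blue").fill == "#1E88E5"

    def test_deterministic(self):
        a = node_style(NodeClass.COMPLEX, "single_color", "#884422")
        b = node_style(NodeClass.COMPLEX, "single_color", "#884422")
        assert a == b

    def test_single_color_base_passthrough_for_generic(self):
        spec = node_style(NodeClass.GENERIC, "single_color", "#888888")
        assert spec.fill == "#888888"  # zero lightness step

    def test_single_color_derives_distinct_shades(self):
        fills = {
            node_style(cls, "single_color", "#4A90D9").fill
            for cls in (NodeClass.MACROMOLECULE, NodeClass.SIMPLE_CHEMICAL,
                        NodeClass.COMPARTMENT, NodeClass.PROCESS)
        }
        assert len(fills) == 4

    def test_shape_mapping(self):
        assert node_style(NodeClass.MACROMOLECULE, "red_blue").shape == "rounded_rect"
        assert node_style(NodeClass.SIMPLE_CHEMICAL, "red_blue").shape == "stadium"
        assert node_style(NodeClass.COMPLEX, "red_blue").shape == "cut_rect"
        assert node_style(NodeClass.PROCESS, "red_blue").shape == "square"

    def test_unknown_class_falls_back(self):
        assert node_style("not-a-class", "red_blue").shape == "rect"


class TestRenderSvg:
    def test_empty_graph_is_valid_svg(self):
        from pathmaps.core import PathwayGraph

        text = render_svg(PathwayGraph(), style=StyleOptions(background="#FFFFFF"))
        root = svg_root(text)
        assert root.tag.endswith("svg")
        assert elements_by_class(root, "background")

    def test_missing_geometry_rejected(self):
        g = build_graph(["A"])
        with pytest.raises(RenderError):
            render_svg(g)

    def test_element_counts_exact(self, laid_out_graph):
        g = laid_out_graph
        root = svg_root(render_svg(g))
        assert len(elements_by_class(root, "node-shape")) == len(g.nodes)
        assert len(elements_by_class(root, "edge-path")) == len(g.edges)

    def test_zorder_compounds_before_descendants(self, laid_out_graph):
        g = laid_out_graph
        root = svg_root(render_svg(g))
        order = [el.get("data-id") for el in elements_by_class(root, "node-shape")]
        for nid in g.nodes:
            for desc in g.descendants(nid):
                assert order.index(nid) < order.index(desc)

    def test_highlight_stroke_width_linear(self):
        g = build_graph(["A", "B"])
        g.nodes["A"].geometry = NodeGeometry(0, 0, 40, 40)
        g.nodes["B"].geometry = NodeGeometry(100, 0, 40, 40)
        style = StyleOptions(highlight_width_range=(2.0, 10.0))
        hl = HighlightSpec(
            node_roles={"A": "result", "B": "result"},
            node_thickness={"A": 1.0, "B": 0.0},
        )
        root = svg_root(render_svg(g, hl, style))
        widths = {
            el.get("data-id"): float(el.get("stroke-width"))
            for el in elements_by_class(root, "node-shape")
        }
        assert widths["A"] == 10.0
        assert widths["B"] == 2.0

    def test_highlight_is_purely_additive(self, laid_out_graph):
        g = laid_out_graph
        assert render_svg(g, None) == render_svg(g, HighlightSpec())

    def test_role_colors_applied(self):
        g = build_graph(["A", "B"], [("e0", "A", "B")])
        g.nodes["A"].geometry = NodeGeometry(0, 0, 40, 40)
        g.nodes["B"].geometry = NodeGeometry(100, 0, 40, 40)
        style = StyleOptions()
        hl = HighlightSpec(node_roles={"A": "seed", "B": "result"}, edge_ids={"e0"})
        root = svg_root(render_svg(g, hl, style))
        strokes = {
            el.get("data-id"): el.get("stroke")
            for el in elements_by_class(root, "node-shape")
        }
        assert strokes["A"] == style.seed_color
        assert strokes["B"] == style.result_color
        edge = elements_by_class(root, "edge-path")[0]
        assert edge.get("stroke") == style.link_color

    def test_result_only_viewbox_shrinks(self):
        g = build_graph(["A", "B", "far"])
        g.nodes["A"].geometry = NodeGeometry(0, 0, 40, 40)
        g.nodes["B"].geometry = NodeGeometry(60, 0, 40, 40)
        g.nodes["far"].geometry = NodeGeometry(5000, 5000, 40, 40)
        hl = HighlightSpec(node_roles={"A": "seed", "B": "result"})
        full = svg_root(render_svg(g, hl, StyleOptions(result_only=False)))
        crop = svg_root(render_svg(g, hl, StyleOptions(result_only=True)))
        fw = float(full.get("viewBox").split()[2])
        cw = float(crop.get("viewBox").split()[2])
        assert cw < fw / 10
        assert cw == pytest.approx(60 + 40 + 2 * 20)  # span + margin

    def test_consumption_has_no_arrowhead(self):
        g = build_graph(
            ["A", ("p", "process"), "B"],
            [("c", "A", "p", "consumption"), ("pr", "p", "B", "production")],
        )
        for nid, x in zip(("A", "p", "B"), (0, 100, 200)):
            g.nodes[nid].geometry = NodeGeometry(x, 0, 40, 40)
        root = svg_root(render_svg(g))
        markers = {
            el.get("data-id"): el.get("marker-end")
            for el in elements_by_class(root, "edge-path")
        }
        assert markers["c"] is None
        assert markers["pr"] is not None


class TestRasterize:
    def test_transparent_png_for_no_background(self):
        from pathmaps.core import PathwayGraph

        text = render_svg(PathwayGraph(), style=StyleOptions())
        out = rasterize(text, StyleOptions(image_format="png", width=50, height=40))
        img = Image.open(io.BytesIO(out.data))
        assert img.size == (50, 40)
        assert img.getpixel((25, 20))[3] == 0  # fully transparent

    def test_jpg_substitutes_white_background_with_warning(self):
        from pathmaps.core import PathwayGraph

        text = render_svg(PathwayGraph(), style=StyleOptions())
        out = rasterize(text, StyleOptions(image_format="jpg", width=30, height=30))
        assert any("background" in w for w in out.warnings)
        img = Image.open(io.BytesIO(out.data))
        assert img.mode == "RGB"
        r, g, b = img.getpixel((15, 15))
        assert min(r, g, b) > 240

    def test_requested_dimensions_respected(self, laid_out_graph):
        text = render_svg(laid_out_graph)
        out = rasterize(text, StyleOptions(image_format="png", width=321, height=123))
        assert Image.open(io.BytesIO(out.data)).size == (321, 123)

    def test_drawn_content_present(self, laid_out_graph):
        text = render_svg(laid_out_graph)
        out = rasterize(
            text, StyleOptions(image_format="png", width=400, height=300,
                               background="#FFFFFF")
        )
        img = Image.open(io.BytesIO(out.data)).convert("RGB")
        colors = {img.getpixel((x, y)) for x in range(0, 400, 7) for y in range(0, 300, 7)}
        assert len(colors) > 3  # more than background + one shade

    def test_invalid_svg_rejected(self):
        with pytest.raises(RasterError):
            rasterize("<not-svg", StyleOptions(image_format="png"))

    def test_svg_format_rejected(self):
        with pytest.raises(RasterError):
            rasterize("<svg/>", StyleOptions(image_format="svg"))


class TestStyleOptions:
    def test_bad_hex_rejected(self):
        with pytest.raises(Exception):
            StyleOptions(base_color="red")

    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception):
            StyleOptions(bezier=True)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(Exception):
            StyleOptions(width=0)
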