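"""Visual style mapping: options, per-class shapes/colors, highlight roles."""

from __future__ import annotations

import colorsys
import re
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Set, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .core import NodeClass

__all__ = [
    "StyleOptions",
    "HighlightSpec",
    "NodeStyle",
    "node_style",
    "hex_to_rgb",
]

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


def hex_to_rgb(color: str) -> Tuple[int, int, int]:
    return int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16)


def _rgb_to_hex(rgb: Tuple[float, float, float]) -> str:
    return "#%02X%02X%02X" % tuple(max(0, min(255, round(c))) for c in rgb)


def _with_lightness(color: str, delta: float) -> str:
    """Shift the HLS lightness of a hex color by ``delta`` (clamped)."""
    r, g, b = (c / 255.0 for c in hex_to_rgb(color))
    h, l, s = colorsys.rgb_to_hls(r, g, b)
    l = max(0.0, min(1.0, l + delta))
    return _rgb_to_hex(tuple(255 * c for c in colorsys.hls_to_rgb(h, l, s)))


class StyleOptions(BaseModel):
    """Image construction options; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    scheme: Literal["single_color", "red_blue"] = "red_blue"
    base_color: str = "#4A90D9"
    background: Optional[str] = None
    image_format: Literal["svg", "png", "jpg"] = "svg"
    width: int = Field(default=800, gt=0)
    height: int = Field(default=600, gt=0)
    result_only: bool = False
    highlight_color: str = "#FFD700"
    highlight_width_range: Tuple[float, float] = (2.0, 10.0)
    seed_color: str = "#00CC00"
    result_color: str = "#FF4444"
    link_color: str = "#FFD700"

    @field_validator(
        "base_color", "highlight_color", "seed_color", "result_color", "link_color"
    )
    @classmethod
    def _valid_hex(cls, v: str) -> str:
        if not _HEX_RE.match(v):
            raise ValueError(f"not a #RRGGBB color: {v!r}")
        return v

    @field_validator("background")
    @classmethod
    def _valid_bg(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and not _HEX_RE.match(v):
            raise ValueError(f"not a #RRGGBB color: {v!r}")
        return v

    def role_color(self, role: str) -> str:
        return {"seed": self.seed_color, "result": self.result_color,
                "link": self.link_color}.get(role, self.highlight_color)


@dataclass
class HighlightSpec:
    """What to emphasize: per-node roles, edge ids, per-node thickness in [0,1]."""

    node_roles: Dict[str, str] = field(default_factory=dict)
    edge_ids: Set[str] = field(default_factory=set)
    node_thickness: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_query_result(cls, result) -> "HighlightSpec":
        roles: Dict[str, str] = {}
        for nid in result.result_nodes:
            roles[nid] = "link"
        for nid in result.focus_nodes:
            roles[nid] = "result"
        for nid in result.seed_nodes:
            roles[nid] = "seed"
        return cls(node_roles=roles, edge_ids=set(result.result_edges))


@dataclass(frozen=True)
class NodeStyle:
    shape: str  # rounded_rect | stadium | ellipse | rect | square | circle | cut_rect | hexagon
    fill: str
    stroke: str
    stroke_width: float


#: shape per node class
_SHAPES: Dict[NodeClass, str] = {
    NodeClass.MACROMOLECULE: "rounded_rect",
    NodeClass.SIMPLE_CHEMICAL: "stadium",
    NodeClass.NUCLEIC_ACID_FEATURE: "rounded_rect",
    NodeClass.UNSPECIFIED_ENTITY: "ellipse",
    NodeClass.COMPLEX: "cut_rect",
    NodeClass.COMPARTMENT: "rounded_rect",
    NodeClass.PROCESS: "square",
    NodeClass.ASSOCIATION: "circle",
    NodeClass.DISSOCIATION: "circle",
    NodeClass.PHENOTYPE: "hexagon",
    NodeClass.SOURCE_SINK: "circle",
    NodeClass.GENERIC: "rect",
}

#: red-blue scheme fills (red simple chemicals, blue macromolecules)
_RED_BLUE_FILLS: Dict[NodeClass, str] = {
    NodeClass.MACROMOLECULE: "#1E88E5",
    NodeClass.SIMPLE_CHEMICAL: "#E53935",
    NodeClass.NUCLEIC_ACID_FEATURE: "#5E8DE5",
    NodeClass.UNSPECIFIED_ENTITY: "#B0BEC5",
    NodeClass.COMPLEX: "#90A4AE",
    NodeClass.COMPARTMENT: "#F4F0E4",
    NodeClass.PROCESS: "#ECEFF1",
    NodeClass.ASSOCIATION: "#616161",
    NodeClass.DISSOCIATION: "#FAFAFA",
    NodeClass.PHENOTYPE: "#AB47BC",
    NodeClass.SOURCE_SINK: "#FAFAFA",
    NodeClass.GENERIC: "#CFD8DC",
}

#: lightness offsets applied to the base color in the single-color scheme
_LIGHTNESS_STEPS: Dict[NodeClass, float] = {
    NodeClass.MACROMOLECULE: 0.00,
    NodeClass.SIMPLE_CHEMICAL: 0.12,
    NodeClass.NUCLEIC_ACID_FEATURE: 0.06,
    NodeClass.UNSPECIFIED_ENTITY: 0.18,
    NodeClass.COMPLEX: -0.08,
    NodeClass.COMPARTMENT: 0.30,
    NodeClass.PROCESS: 0.24,
    NodeClass.ASSOCIATION: -0.20,
    NodeClass.DISSOCIATION: 0.24,
    NodeClass.PHENOTYPE: -0.12,
    NodeClass.SOURCE_SINK: 0.24,
    NodeClass.GENERIC: 0.00,
}


def node_style(
    node_class: NodeClass,
    scheme: str = "red_blue",
    base_color: str = "#4A90D9",
) -> NodeStyle:
    """Deterministic shape + fill + border spec for a node class."""
    try:
        node_class = NodeClass(node_class)
    except ValueError:
        node_class = NodeClass.GENERIC
    shape = _SHAPES[node_class]
    if scheme == "red_blue":
        fill = _RED_BLUE_FILLS[node_class]
    else:
        fill = _with_lightness(base_color, _LIGHTNESS_STEPS[node_class])
    stroke = _with_lightness(fill, -0.25)
    stroke_width = 3.0 if node_class is NodeClass.COMPARTMENT else 1.5
    return NodeStyle(shape=shape, fill=fill, stroke=stroke, stroke_width=stroke_width)
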