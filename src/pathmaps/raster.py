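"""Rasterization of the SVG dialect produced by :mod:`pathmaps.svg`.

This is not a general SVG renderer: it draws exactly the element subset
our own writer emits (rect/ellipse/circle/polygon/line/straight path/
text, plus ``marker-end`` arrowheads) with Pillow.  The map is scaled to
fit the requested canvas, preserving aspect ratio by letterboxing.
"""

from __future__ import annotations

import io
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from PIL import Image, ImageDraw

from .style import StyleOptions, hex_to_rgb

__all__ = ["RenderedImage", "rasterize", "RasterError"]


class RasterError(ValueError):
    pass


@dataclass
class RenderedImage:
    image_format: str  # "svg" | "png" | "jpg"
    data: bytes
    warnings: List[str] = field(default_factory=list)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _color(value: Optional[str], fallback=None):
    if value is None or value == "none":
        return fallback
    return hex_to_rgb(value) + (255,)


def rasterize(svg_text: str, style: Optional[StyleOptions] = None) -> RenderedImage:
    """Render SVG text to PNG or JPG bytes at ``style.width x style.height``."""
    style = style or StyleOptions(image_format="png")
    if style.image_format == "svg":
        raise RasterError("rasterize requires image_format png or jpg")
    try:
        root = ET.fromstring(svg_text)
    except ET.ParseError as exc:
        raise RasterError(f"invalid SVG: {exc}") from exc
    if _local(root.tag) != "svg":
        raise RasterError("not an SVG document")

    warnings: List[str] = []
    W, H = style.width, style.height
    vb = root.get("viewBox")
    if vb:
        vx, vy, vw, vh = (float(p) for p in vb.replace(",", " ").split())
    else:
        vx, vy, vw, vh = 0.0, 0.0, float(W), float(H)
    vw, vh = max(vw, 1e-6), max(vh, 1e-6)
    scale = min(W / vw, H / vh)
    ox = (W - vw * scale) / 2.0 - vx * scale
    oy = (H - vh * scale) / 2.0 - vy * scale

    def T(x: float, y: float) -> Tuple[float, float]:
        return (x * scale + ox, y * scale + oy)

    background = _color(style.background, (0, 0, 0, 0))
    if style.image_format == "jpg" and style.background is None:
        background = (255, 255, 255, 255)
        warnings.append("jpg requires an opaque background; substituted white")
    img = Image.new("RGBA", (W, H), background)
    draw = ImageDraw.Draw(img)

    markers: Dict[str, ET.Element] = {}
    for defs in root:
        if _local(defs.tag) == "defs":
            for marker in defs:
                mid = marker.get("id")
                if mid:
                    markers[mid] = marker

    for el in root:
        tag = _local(el.tag)
        if tag == "defs":
            continue
        _draw_element(draw, el, T, scale, markers)

    buf = io.BytesIO()
    if style.image_format == "png":
        img.save(buf, format="PNG")
    else:
        flat = Image.new("RGB", (W, H), background[:3])
        flat.paste(img, mask=img.split()[3])
        flat.save(buf, format="JPEG", quality=90)
    return RenderedImage(image_format=style.image_format, data=buf.getvalue(),
                         warnings=warnings)


def _draw_element(draw, el, T, scale, markers, offset=(0.0, 0.0), angle=0.0) -> None:
    """Draw one element; ``offset``/``angle`` place marker content."""
    tag = _local(el.tag)

    def P(x: float, y: float) -> Tuple[float, float]:
        if angle or offset != (0.0, 0.0):
            ca, sa = math.cos(angle), math.sin(angle)
            x, y = x * ca - y * sa + offset[0], x * sa + y * ca + offset[1]
        return T(x, y)

    fill = _color(el.get("fill"), (0, 0, 0, 255) if tag == "text" else None)
    stroke = _color(el.get("stroke"))
    sw = max(1, round(float(el.get("stroke-width", "1")) * scale)) if stroke else 0

    if tag == "rect":
        x, y = float(el.get("x", 0)), float(el.get("y", 0))
        w, h = float(el.get("width", 0)), float(el.get("height", 0))
        rx = float(el.get("rx", 0))
        p1, p2 = P(x, y), P(x + w, y + h)
        box = (min(p1[0], p2[0]), min(p1[1], p2[1]), max(p1[0], p2[0]), max(p1[1], p2[1]))
        if rx > 0:
            draw.rounded_rectangle(box, radius=rx * scale, fill=fill, outline=stroke, width=sw)
        else:
            draw.rectangle(box, fill=fill, outline=stroke, width=sw)
    elif tag in ("ellipse", "circle"):
        cx, cy = float(el.get("cx", 0)), float(el.get("cy", 0))
        if tag == "circle":
            rx = ry = float(el.get("r", 0))
        else:
            rx, ry = float(el.get("rx", 0)), float(el.get("ry", 0))
        c = P(cx, cy)
        draw.ellipse(
            (c[0] - rx * scale, c[1] - ry * scale, c[0] + rx * scale, c[1] + ry * scale),
            fill=fill, outline=stroke, width=sw,
        )
    elif tag == "polygon":
        pts = [
            P(float(pair.split(",")[0]), float(pair.split(",")[1]))
            for pair in el.get("points", "").split()
        ]
        if len(pts) >= 3:
            draw.polygon(pts, fill=fill, outline=stroke)
    elif tag == "line":
        p1 = P(float(el.get("x1", 0)), float(el.get("y1", 0)))
        p2 = P(float(el.get("x2", 0)), float(el.get("y2", 0)))
        draw.line([p1, p2], fill=stroke or fill, width=max(sw, 1))
    elif tag == "path":
        points = _parse_path(el.get("d", ""))
        if len(points) >= 2:
            draw.line([T(*pt) for pt in points], fill=stroke or (0, 0, 0, 255),
                      width=max(sw, 1))
            _draw_marker(draw, el, points, T, scale, markers)
    elif tag == "text":
        x, y = float(el.get("x", 0)), float(el.get("y", 0))
        text = el.text or ""
        px, py = P(x, y)
        tw = draw.textlength(text)
        draw.text((px - tw / 2, py - 6), text, fill=fill)


def _parse_path(d: str) -> List[Tuple[float, float]]:
    """Straight-segment path data: ``M x y L x y [L x y ...]``."""
    tokens = d.replace(",", " ").split()
    points: List[Tuple[float, float]] = []
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if t in ("M", "L"):
            points.append((float(tokens[i + 1]), float(tokens[i + 2])))
            i += 3
        else:
            i += 1  # ignore anything else (we never emit it)
    return points


def _draw_marker(draw, el, points, T, scale, markers) -> None:
    ref = el.get("marker-end", "")
    if not ref.startswith("url(#"):
        return
    marker = markers.get(ref[5:-1])
    if marker is None:
        return
    (x1, y1), (x2, y2) = points[-2], points[-1]
    angle = math.atan2(y2 - y1, x2 - x1)
    ref_x = float(marker.get("refX", 0))
    ref_y = float(marker.get("refY", 0))
    ca, sa = math.cos(angle), math.sin(angle)
    # marker origin so that (refX, refY) lands on the path end
    off = (x2 - (ref_x * ca - ref_y * sa), y2 - (ref_x * sa + ref_y * ca))
    for child in marker:
        _draw_element(draw, child, T, scale, markers, offset=off, angle=angle)
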