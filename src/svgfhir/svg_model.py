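"""Constrained SVG annotation model.

Medical-image graphic annotations are recorded as a small, well-defined
subset of W3C SVG 1.1: six geometric shape kinds (rect, circle, ellipse,
line, polyline, polygon) plus one optional background ``image`` element,
all expressed in DICOM pixel coordinates (origin top-left, x = column,
y = row — SVG and DICOM agree on this orientation). Styling is limited
to an RGB stroke, a stroke width, and ``fill:none``; browsers render the
subset directly, and the tight grammar keeps serialization canonical so
base64 payloads derived from a document are byte-stable.

The module provides parsing/serialization (:func:`parse_svg`,
:func:`serialize_svg`), subset validation as data
(:func:`validate_subset`), and 2-D affine coordinate transforms between
viewer-canvas and DICOM-pixel space (:class:`AffineTransform2D`,
:func:`apply_transform`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from lxml import etree

from .errors import (
    NonInvertibleTransformError,
    SubsetViolationError,
    SvgParseError,
    UnsupportedTransformError,
    ValidationError,
    Violation,
)

SVG_NS = "http://www.w3.org/2000/svg"
XLINK_NS = "http://www.w3.org/1999/xlink"

#: shape kind -> geometry attribute names, in canonical output order
_GEOMETRY_ATTRS = {
    "rect": ("x", "y", "width", "height"),
    "circle": ("cx", "cy", "r"),
    "ellipse": ("cx", "cy", "rx", "ry"),
    "line": ("x1", "y1", "x2", "y2"),
    "polyline": ("points",),
    "polygon": ("points",),
}

_IMAGE_ATTRS = {"x", "y", "width", "height", "href"}
_SVG_ROOT_ATTRS = {"width", "height", "viewBox", "version"}
_STYLE_PROPS = ("stroke", "stroke-width", "fill")


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StrokeStyle:
    """Stroke colour/width; fill is always ``none`` in this subset."""

    stroke_rgb: tuple[int, int, int] = (255, 255, 0)
    stroke_width: float = 2.0
    fill: str = "none"

    def validate(self, where: str = "style") -> list[Violation]:
        out = []
        for ch in self.stroke_rgb:
            if not (isinstance(ch, int) and 0 <= ch <= 255):
                out.append(Violation(where, "stroke-rgb-range",
                                     f"channel {ch!r} outside 0-255"))
        if not self.stroke_width > 0:
            out.append(Violation(where, "stroke-width-positive",
                                 f"stroke_width={self.stroke_width}"))
        if self.fill != "none":
            out.append(Violation(where, "fill-none", f"fill={self.fill!r}"))
        return out

    def to_css(self) -> str:
        r, g, b = self.stroke_rgb
        return (f"stroke:rgb({r},{g},{b}); "
                f"stroke-width:{_fmt(self.stroke_width)}; fill:{self.fill}")


@dataclass(frozen=True)
class SvgShape:
    """One geometric annotation shape.

    ``geometry`` holds the kind-specific parameters: scalars for
    rect/circle/ellipse/line under the SVG attribute names, and a
    ``points`` tuple of (x, y) pairs for polyline/polygon. Coordinates
    are DICOM pixel units.
    """

    kind: str
    geometry: dict
    style: StrokeStyle = field(default_factory=StrokeStyle)

    @property
    def points(self) -> tuple[tuple[float, float], ...]:
        return self.geometry.get("points", ())

    def validate(self, where: str | None = None) -> list[Violation]:
        w = where or self.kind
        out = list(self.style.validate(f"{w}/style"))
        if self.kind not in _GEOMETRY_ATTRS:
            return out + [Violation(w, "unknown-kind", self.kind)]
        if self.kind in ("polyline", "polygon"):
            pts = self.points
            minimum = 2 if self.kind == "polyline" else 3
            if len(pts) < minimum:
                out.append(Violation(w, "too-few-points",
                                     f"{len(pts)} < {minimum}"))
            if self.kind == "polygon" and len(pts) >= 2 and pts[0] == pts[-1]:
                out.append(Violation(w, "explicit-closure",
                                     "polygon must not repeat its first point"))
        else:
            for name in _GEOMETRY_ATTRS[self.kind]:
                if name not in self.geometry:
                    out.append(Violation(w, "missing-geometry", name))
            for name in ("width", "height", "r", "rx", "ry"):
                v = self.geometry.get(name)
                if v is not None and v < 0:
                    out.append(Violation(w, "negative-extent", f"{name}={v}"))
        return out


def rect(x: float, y: float, width: float, height: float,
         style: StrokeStyle | None = None) -> SvgShape:
    return SvgShape("rect", {"x": x, "y": y, "width": width, "height": height},
                    style or StrokeStyle())


def circle(cx: float, cy: float, r: float,
           style: StrokeStyle | None = None) -> SvgShape:
    return SvgShape("circle", {"cx": cx, "cy": cy, "r": r}, style or StrokeStyle())


def ellipse(cx: float, cy: float, rx: float, ry: float,
            style: StrokeStyle | None = None) -> SvgShape:
    return SvgShape("ellipse", {"cx": cx, "cy": cy, "rx": rx, "ry": ry},
                    style or StrokeStyle())


def line(x1: float, y1: float, x2: float, y2: float,
         style: StrokeStyle | None = None) -> SvgShape:
    return SvgShape("line", {"x1": x1, "y1": y1, "x2": x2, "y2": y2},
                    style or StrokeStyle())


def polyline(points, style: StrokeStyle | None = None) -> SvgShape:
    return SvgShape("polyline", {"points": tuple((float(x), float(y)) for x, y in points)},
                    style or StrokeStyle())


def polygon(points, style: StrokeStyle | None = None) -> SvgShape:
    return SvgShape("polygon", {"points": tuple((float(x), float(y)) for x, y in points)},
                    style or StrokeStyle())


@dataclass(frozen=True)
class SvgAnnotationDocument:
    """An annotation canvas in DICOM pixel units plus its ordered shapes.

    ``background_href`` records the background image reference of a
    standalone page (Example-script-1 style); annotation payloads stored
    in FHIR strip it, since the image link lives in ``Observation.focus``.
    """

    canvas_width: int
    canvas_height: int
    shapes: tuple[SvgShape, ...] = ()
    background_href: str | None = None

    def validate(self) -> list[Violation]:
        out = []
        if not (isinstance(self.canvas_width, int) and self.canvas_width > 0):
            out.append(Violation("svg/width", "positive-integer",
                                 repr(self.canvas_width)))
        if not (isinstance(self.canvas_height, int) and self.canvas_height > 0):
            out.append(Violation("svg/height", "positive-integer",
                                 repr(self.canvas_height)))
        for i, s in enumerate(self.shapes):
            out.extend(s.validate(f"shapes[{i}]/{s.kind}"))
        return out

    def without_background(self) -> "SvgAnnotationDocument":
        return replace(self, background_href=None)

    def with_background(self, href: str) -> "SvgAnnotationDocument":
        return replace(self, background_href=href)


# --------------------------------------------------------------------------
# affine transforms


@dataclass(frozen=True)
class AffineTransform2D:
    """Point map (x, y) -> (a*x + c*y + e, b*x + d*y + f).

    The six-parameter convention matches the SVG/canvas ``matrix()``
    transform; ``e``/``f`` are the translation.
    """

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0
    e: float = 0.0
    f: float = 0.0

    def determinant(self) -> float:
        return self.a * self.d - self.b * self.c

    def apply(self, x: float, y: float) -> tuple[float, float]:
        return (self.a * x + self.c * y + self.e,
                self.b * x + self.d * y + self.f)


IDENTITY = AffineTransform2D()


def scaling(sx: float, sy: float | None = None) -> AffineTransform2D:
    sy = sx if sy is None else sy
    return AffineTransform2D(sx, 0.0, 0.0, sy, 0.0, 0.0)


def translation(tx: float, ty: float) -> AffineTransform2D:
    return AffineTransform2D(1.0, 0.0, 0.0, 1.0, tx, ty)


def compose(t1: AffineTransform2D, t2: AffineTransform2D) -> AffineTransform2D:
    """Transform applying ``t1`` first, then ``t2``."""
    return AffineTransform2D(
        a=t2.a * t1.a + t2.c * t1.b,
        b=t2.b * t1.a + t2.d * t1.b,
        c=t2.a * t1.c + t2.c * t1.d,
        d=t2.b * t1.c + t2.d * t1.d,
        e=t2.a * t1.e + t2.c * t1.f + t2.e,
        f=t2.b * t1.e + t2.d * t1.f + t2.f,
    )


def invert(t: AffineTransform2D) -> AffineTransform2D:
    det = t.determinant()
    if det == 0 or not math.isfinite(det):
        raise NonInvertibleTransformError(f"determinant is {det}")
    ia, ib = t.d / det, -t.b / det
    ic, id_ = -t.c / det, t.a / det
    return AffineTransform2D(
        a=ia, b=ib, c=ic, d=id_,
        e=-(ia * t.e + ic * t.f),
        f=-(ib * t.e + id_ * t.f),
    )


def _axis_form(t: AffineTransform2D, tol: float = 1e-9) -> str:
    """Classify the linear part: 'diagonal' (scale/flip), 'antidiagonal'
    (90-degree rotation composed with scale/flip), or 'shear'."""
    if abs(t.b) <= tol and abs(t.c) <= tol:
        return "diagonal"
    if abs(t.a) <= tol and abs(t.d) <= tol:
        return "antidiagonal"
    return "shear"


def apply_transform(doc: SvgAnnotationDocument,
                    t: AffineTransform2D) -> SvgAnnotationDocument:
    """Map every defining coordinate of ``doc`` through ``t``.

    Rects, circles and ellipses only survive axis-preserving transforms
    (scalings, flips, quarter-turn rotations, translations); a general
    rotation or shear would carry them off the rect/ellipse grammar, so
    those raise :class:`UnsupportedTransformError` — convert the shape
    to a polygon first if that is intended. Stroke width is a display
    property and is never rescaled. The canvas extent is left unchanged:
    the transform re-expresses coordinates (viewer canvas to DICOM pixel
    space), it does not resize the target image.
    """
    if t.determinant() == 0:
        raise NonInvertibleTransformError("transform is singular")
    form = _axis_form(t)
    shapes = []
    for shape in doc.shapes:
        g = shape.geometry
        if shape.kind in ("line", "polyline", "polygon"):
            if shape.kind == "line":
                x1, y1 = t.apply(g["x1"], g["y1"])
                x2, y2 = t.apply(g["x2"], g["y2"])
                ng = {"x1": x1, "y1": y1, "x2": x2, "y2": y2}
            else:
                ng = {"points": tuple(t.apply(x, y) for x, y in g["points"])}
        elif form == "shear":
            raise UnsupportedTransformError(
                f"transform shears a {shape.kind}; convert it to a polygon "
                "before applying a general affine map")
        elif shape.kind == "rect":
            (xa, ya) = t.apply(g["x"], g["y"])
            (xb, yb) = t.apply(g["x"] + g["width"], g["y"] + g["height"])
            ng = {"x": min(xa, xb), "y": min(ya, yb),
                  "width": abs(xb - xa), "height": abs(yb - ya)}
        elif shape.kind == "circle":
            scale = math.sqrt(abs(t.determinant()))
            sx = math.hypot(t.a, t.b)
            sy = math.hypot(t.c, t.d)
            if abs(sx - sy) > 1e-9 * max(sx, sy):
                raise UnsupportedTransformError(
                    "anisotropic scale on a circle; use an ellipse or polygon")
            cx, cy = t.apply(g["cx"], g["cy"])
            ng = {"cx": cx, "cy": cy, "r": g["r"] * scale}
        else:  # ellipse
            cx, cy = t.apply(g["cx"], g["cy"])
            if form == "diagonal":
                rx, ry = g["rx"] * abs(t.a), g["ry"] * abs(t.d)
            else:  # quarter turn: the semi-axes swap roles
                rx, ry = g["ry"] * abs(t.c), g["rx"] * abs(t.b)
            ng = {"cx": cx, "cy": cy, "rx": rx, "ry": ry}
        shapes.append(SvgShape(shape.kind, ng, shape.style))
    return replace(doc, shapes=tuple(shapes))


# --------------------------------------------------------------------------
# parsing


def _local(tag) -> str:
    if not isinstance(tag, str):  # comments, PIs
        return ""
    return tag.rsplit("}", 1)[-1]


def _attr_local(name: str) -> str:
    return name.rsplit("}", 1)[-1]


def _parse_number(text: str, where: str, sink: list[Violation]) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        sink.append(Violation(where, "not-a-number", repr(text)))
        return 0.0


def _parse_points(text: str, where: str, sink: list[Violation]):
    tokens = [tk for tk in re.split(r"[\s,]+", (text or "").strip()) if tk]
    if len(tokens) % 2 != 0:
        sink.append(Violation(where, "odd-coordinate-count", text or ""))
        return ()
    vals = [_parse_number(tk, where, sink) for tk in tokens]
    return tuple((vals[i], vals[i + 1]) for i in range(0, len(vals), 2))


def _parse_style(text: str | None, where: str, sink: list[Violation]) -> StrokeStyle:
    if text is None:
        return StrokeStyle()
    rgb: tuple[int, int, int] = (255, 255, 0)
    width = 2.0
    fill = "none"
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" not in chunk:
            sink.append(Violation(where, "malformed-style", chunk))
            continue
        key, _, value = chunk.partition(":")
        key, value = key.strip(), value.strip()
        if key == "stroke":
            m = re.fullmatch(r"rgb\(\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*\)", value)
            if not m:
                sink.append(Violation(where, "unsupported-stroke", value))
                continue
            rgb = tuple(int(g) for g in m.groups())  # type: ignore[assignment]
            if any(ch > 255 for ch in rgb):
                sink.append(Violation(where, "stroke-rgb-range", value))
        elif key == "stroke-width":
            width = _parse_number(value, where, sink)
            if not width > 0:
                sink.append(Violation(where, "stroke-width-positive", value))
                width = 1.0
        elif key == "fill":
            fill = value
            if value != "none":
                sink.append(Violation(where, "fill-none", value))
                fill = "none"
        else:
            sink.append(Violation(where, "unsupported-style-property", key))
    return StrokeStyle(rgb, width, fill)


def _int_dimension(root, name: str, sink: list[Violation]) -> int:
    raw = root.get(name)
    if raw is None:
        sink.append(Violation(f"svg/{name}", "missing-dimension"))
        return 1
    try:
        value = int(str(raw).strip().removesuffix("px"))
    except ValueError:
        sink.append(Violation(f"svg/{name}", "not-an-integer", repr(raw)))
        return 1
    if value <= 0:
        sink.append(Violation(f"svg/{name}", "positive-integer", repr(raw)))
        return 1
    return value


def _read_document(text: str | bytes):
    """Shared walker: returns (document, violations). XML-level failures
    still raise; subset problems are collected."""
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise SvgParseError(f"malformed XML: {exc}") from exc
    if _local(root.tag) != "svg":
        raise SvgParseError(f"root element is <{_local(root.tag)}>, expected <svg>")

    violations: list[Violation] = []
    for name in root.attrib:
        ln = _attr_local(name)
        if ln not in _SVG_ROOT_ATTRS and not ln.startswith("xmlns"):
            violations.append(Violation(f"svg/@{ln}", "unsupported-attribute"))
    width = _int_dimension(root, "width", violations)
    height = _int_dimension(root, "height", violations)

    background: str | None = None
    shapes: list[SvgShape] = []
    for pos, el in enumerate(root):
        tag = _local(el.tag)
        where = f"svg[{pos}]/{tag}" if tag else f"svg[{pos}]"
        if not tag:
            continue  # comments
        if tag == "image":
            href = None
            for name, value in el.attrib.items():
                ln = _attr_local(name)
                if ln == "href":
                    href = value
                elif ln not in _IMAGE_ATTRS:
                    violations.append(Violation(f"{where}/@{ln}",
                                                "unsupported-attribute"))
            if href is None:
                violations.append(Violation(where, "image-missing-href"))
            elif background is not None:
                violations.append(Violation(where, "multiple-background-images"))
            else:
                background = href
            continue
        if tag not in _GEOMETRY_ATTRS:
            violations.append(Violation(where, "unsupported-element", tag))
            continue
        geometry: dict = {}
        style_text = None
        for name, value in el.attrib.items():
            ln = _attr_local(name)
            if ln == "style":
                style_text = value
            elif ln in _GEOMETRY_ATTRS[tag]:
                if ln == "points":
                    geometry["points"] = _parse_points(value, f"{where}/@points",
                                                       violations)
                else:
                    geometry[ln] = _parse_number(value, f"{where}/@{ln}",
                                                 violations)
            else:
                violations.append(Violation(f"{where}/@{ln}",
                                            "unsupported-attribute"))
        style = _parse_style(style_text, f"{where}/@style", violations)
        for name in _GEOMETRY_ATTRS[tag]:
            if name not in geometry:
                violations.append(Violation(where, "missing-geometry", name))
                geometry.setdefault(name, () if name == "points" else 0.0)
        shape = SvgShape(tag, geometry, style)
        violations.extend(shape.validate(where))
        shapes.append(shape)

    doc = SvgAnnotationDocument(width, height, tuple(shapes), background)
    return doc, violations


def parse_svg(text: str | bytes) -> SvgAnnotationDocument:
    """Parse constrained SVG text into a document.

    Raises :class:`SvgParseError` on malformed XML or a non-``svg``
    root and :class:`SubsetViolationError` when the markup steps outside
    the supported subset.
    """
    doc, violations = _read_document(text)
    if violations:
        raise SubsetViolationError(violations)
    return doc


def validate_subset(text: str | bytes) -> list[Violation]:
    """List every subset violation in ``text``; empty iff :func:`parse_svg`
    accepts it. XML-level failures are reported as violations too."""
    try:
        _, violations = _read_document(text)
    except SvgParseError as exc:
        return [Violation("svg", "not-parseable", str(exc))]
    return violations


# --------------------------------------------------------------------------
# serialization


def _fmt(value: float) -> str:
    """Shortest exact decimal form; integral values print without a dot."""
    if isinstance(value, int):
        return str(value)
    if math.isfinite(value) and value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(float(value))


def _fmt_points(points) -> str:
    return " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)


def serialize_svg(doc: SvgAnnotationDocument) -> str:
    """Canonical writer: geometry attributes before style, shortest exact
    decimals, stable namespace declarations. ``parse_svg`` inverts it
    field-for-field, which makes base64 payloads deterministic."""
    problems = doc.validate()
    if problems:
        raise ValidationError(problems)
    parts = [
        f'<svg width="{doc.canvas_width}" height="{doc.canvas_height}" '
        f'xmlns="{SVG_NS}" xmlns:xlink="{XLINK_NS}">'
    ]
    if doc.background_href is not None:
        href = _xml_escape(doc.background_href)
        parts.append(
            f'  <image x="0" y="0" width="{doc.canvas_width}" '
            f'height="{doc.canvas_height}" xlink:href="{href}"/>'
        )
    for shape in doc.shapes:
        attrs = []
        if shape.kind in ("polyline", "polygon"):
            attrs.append(f'points="{_fmt_points(shape.points)}"')
        else:
            for name in _GEOMETRY_ATTRS[shape.kind]:
                attrs.append(f'{name}="{_fmt(shape.geometry[name])}"')
        attrs.append(f'style="{shape.style.to_css()}"')
        parts.append(f'  <{shape.kind} {" ".join(attrs)}/>')
    parts.append("</svg>")
    return "\n".join(parts)


def _xml_escape(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))
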