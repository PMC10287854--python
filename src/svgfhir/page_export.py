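"""Standalone HTML export of annotated images.

An exported page needs neither a FHIR nor a DICOMweb server to view:
each annotated image becomes one inline SVG block (background ``image``
element followed by the annotation shapes), and the complete FHIR
resource list is embedded in a ``<script type="application/json">``
block so downstream tooling can recover the structured data from the
page itself. With a resolver that returns data URIs the page is fully
self-contained and can be mailed across sites that run neither server.
"""

from __future__ import annotations

import base64
from dataclasses import replace
from html import escape
from pathlib import Path
from typing import Callable

from .errors import UnresolvedImageError, ValidationError
from .report_graph import ReportGraph, collect_annotations, graph_to_json
from .svg_model import SvgAnnotationDocument, serialize_svg

_PAGE_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; }}
figure {{ display: inline-block; margin: 0.5em; }}
svg {{ border: 1px solid #ccc; }}
</style>
</head>
<body>
<h1>{title}</h1>
{body}
</body>
</html>
"""


def image_to_data_uri(path: str | Path) -> str:
    """Base64 data URI for a JPEG/PNG file on disk."""
    path = Path(path)
    suffix = path.suffix.lower().lstrip(".")
    mime = {"jpg": "image/jpeg", "jpeg": "image/jpeg",
            "png": "image/png"}.get(suffix, "application/octet-stream")
    payload = base64.b64encode(path.read_bytes()).decode("ascii")
    return f"data:{mime};base64,{payload}"


def export_single_page(image_source: str,
                       doc: SvgAnnotationDocument,
                       title: str = "Image annotation") -> str:
    """One image, one inline SVG overlay.

    The inline SVG re-parses under the annotation subset with
    ``background_href`` equal to ``image_source``.
    """
    problems = doc.validate()
    if problems:
        raise ValidationError(problems)
    svg = serialize_svg(replace(doc, background_href=image_source))
    return _PAGE_TEMPLATE.format(title=escape(title), body=svg)


def export_report_page(
    g: ReportGraph,
    image_resolver: Callable[[str], str],
    title: str = "Imaging report",
) -> str:
    """Render a whole report graph as one static page.

    ``image_resolver`` maps each annotation focus URL to a local image
    source (data URI or relative path); a miss raises
    :class:`UnresolvedImageError`. Annotations sharing an image are
    drawn in one SVG block, in collection order; the full FHIR resource
    list rides along as embedded JSON.
    """
    collected = collect_annotations(g)

    per_image: dict[str, SvgAnnotationDocument] = {}
    for _ann, doc, url in collected:
        if url in per_image:
            merged = per_image[url]
            per_image[url] = replace(
                merged, shapes=merged.shapes + doc.shapes)
        else:
            per_image[url] = doc

    sections: list[str] = []
    if g.report.conclusion:
        sections.append(f"<p>{escape(g.report.conclusion)}</p>")
    findings_text = [f.valueString for f in g.findings if f.valueString]
    if findings_text:
        items = "\n".join(f"<li>{escape(t)}</li>" for t in findings_text)
        sections.append(f"<ul>\n{items}\n</ul>")
    for url, doc in per_image.items():
        try:
            source = image_resolver(url)
        except KeyError:
            raise UnresolvedImageError(url) from None
        if source is None:
            raise UnresolvedImageError(url)
        svg = serialize_svg(replace(doc, background_href=source))
        sections.append(f"<figure>\n{svg}\n</figure>")

    fhir_json = graph_to_json(g).replace("</", "<\\/")
    sections.append(
        '<script type="application/json" id="fhir-resources">\n'
        f"{fhir_json}\n</script>")
    return _PAGE_TEMPLATE.format(title=escape(title),
                                 body="\n".join(sections))
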