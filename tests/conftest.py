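from __future__ import annotations

import pytest
from hypothesis import strategies as st

from svgfhir import (
    DicomImageRef,
    StrokeStyle,
    SvgAnnotationDocument,
    build_wado_url,
    circle,
    ellipse,
    line,
    parse_svg,
    polygon,
    polyline,
    rect,
)

#: the worked example: a 512x512 canvas, a background image, and one
#: yellow rectangle outlining a lesion on an MRI slice
EXAMPLE_SVG = """\
<svg width="512" height="512" xmlns="http://www.w3.org/2000/svg"
     xmlns:xlink="http://www.w3.org/1999/xlink">
  <image x="0" y="0" width="512" height="512" xlink:href="medicalImage.jpg"/>
  <rect x="207" y="124" width="71" height="66"
        style="stroke:rgb(255,255,0); stroke-width:2; fill:none"/>
</svg>
"""

WADO_BASE = "https://dicomweb.example.org/dicomweb"


@pytest.fixture
def example_doc() -> SvgAnnotationDocument:
    return parse_svg(EXAMPLE_SVG)


@pytest.fixture
def instance_url() -> str:
    return build_wado_url(WADO_BASE, DicomImageRef("1.2.3", "1.2.3.4",
                                                   "1.2.3.4.5"))


# --------------------------------------------------------------------------
# hypothesis strategies

_coord = st.floats(min_value=0, max_value=2048, allow_nan=False,
                   allow_infinity=False)
_extent = st.floats(min_value=0, max_value=1024, allow_nan=False,
                    allow_infinity=False)

styles = st.builds(
    StrokeStyle,
    st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)),
    st.floats(min_value=0.5, max_value=20, allow_nan=False),
    st.just("none"),
)

_point = st.tuples(_coord, _coord)


def _open_ring(points):
    return len(points) < 2 or points[0] != points[-1]


shapes = st.one_of(
    st.builds(rect, _coord, _coord, _extent, _extent, styles),
    st.builds(circle, _coord, _coord, _extent, styles),
    st.builds(ellipse, _coord, _coord, _extent, _extent, styles),
    st.builds(line, _coord, _coord, _coord, _coord, styles),
    st.builds(polyline, st.lists(_point, min_size=2, max_size=8), styles),
    st.builds(polygon,
              st.lists(_point, min_size=3, max_size=8).filter(_open_ring),
              styles),
)

documents = st.builds(
    SvgAnnotationDocument,
    st.integers(1, 4096),
    st.integers(1, 4096),
    st.lists(shapes, max_size=6).map(tuple),
    st.one_of(st.none(), st.just("medicalImage.jpg")),
)

uids = st.lists(st.integers(0, 10 ** 6), min_size=2, max_size=4).map(
    lambda parts: ".".join(str(p) for p in [2, 25, *parts]))

image_refs = st.builds(
    DicomImageRef, uids, uids, uids,
    st.one_of(st.none(), st.integers(1, 500)),
)
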