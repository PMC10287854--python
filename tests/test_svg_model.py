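"""SVG subset parsing, canonical serialization, and affine transforms."""

from __future__ import annotations

import xml.etree.ElementTree as stdlib_etree

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svgfhir import (
    AffineTransform2D,
    IDENTITY,
    StrokeStyle,
    SvgAnnotationDocument,
    apply_transform,
    compose,
    invert,
    parse_svg,
    polygon,
    rect,
    scaling,
    serialize_svg,
    translation,
    validate_subset,
)
from svgfhir.errors import (
    NonInvertibleTransformError,
    SubsetViolationError,
    SvgParseError,
    UnsupportedTransformError,
    ValidationError,
)

from conftest import EXAMPLE_SVG, documents


class TestParse:
    def test_worked_example(self, example_doc):
        """The MRI rectangle example parses exactly: canvas, background,
        one yellow rect at (207, 124) sized 71x66 with stroke width 2."""
        assert example_doc.canvas_width == 512
        assert example_doc.canvas_height == 512
        assert example_doc.background_href == "medicalImage.jpg"
        (shape,) = example_doc.shapes
        assert shape.kind == "rect"
        assert shape.geometry == {"x": 207, "y": 124, "width": 71, "height": 66}
        assert shape.style == StrokeStyle((255, 255, 0), 2.0, "none")

    def test_empty_svg(self):
        doc = parse_svg('<svg width="10" height="10" '
                        'xmlns="http://www.w3.org/2000/svg"/>')
        assert doc.shapes == ()
        assert doc.background_href is None

    def test_polygon_against_stdlib_parser(self):
        """Cross-check point extraction against a generic XML parser."""
        pts = [(10.5, 20), (30, 40), (50, 60.25), (70, 80), (15, 90)]
        doc = SvgAnnotationDocument(100, 100, (polygon(pts),))
        text = serialize_svg(doc)
        root = stdlib_etree.fromstring(text)
        (poly,) = [el for el in root
                   if el.tag.endswith("polygon")]
        raw = poly.get("points").replace(",", " ").split()
        expected = [(float(raw[i]), float(raw[i + 1]))
                    for i in range(0, len(raw), 2)]
        assert list(parse_svg(text).shapes[0].points) == expected == \
            [(float(x), float(y)) for x, y in pts]

    def test_malformed_xml(self):
        with pytest.raises(SvgParseError):
            parse_svg("<svg width='1' height='1'")

    def test_wrong_root(self):
        with pytest.raises(SvgParseError, match="expected <svg>"):
            parse_svg("<html/>")

    def test_unsupported_element_named(self):
        with pytest.raises(SubsetViolationError) as err:
            parse_svg('<svg width="5" height="5"><path d="M0 0"/></svg>')
        assert any("path" in v.location for v in err.value.violations)


class TestValidateSubset:
    def test_worked_example_clean(self):
        assert validate_subset(EXAMPLE_SVG) == []

    def test_path_element_flagged(self):
        out = validate_subset('<svg width="5" height="5"><path d="M0 0"/></svg>')
        assert len(out) == 1
        assert "path" in out[0].location

    def test_three_violations_in_document_order(self):
        text = ('<svg width="5" height="5">'
                '<path d="M0 0"/><text>x</text><g/></svg>')
        out = validate_subset(text)
        assert [v.detail for v in out] == ["path", "text", "g"]

    def test_agrees_with_parse(self):
        good = '<svg width="5" height="5"><circle cx="1" cy="1" r="1"/></svg>'
        assert validate_subset(good) == []
        parse_svg(good)  # must not raise


class TestSerialize:
    def test_round_trip_worked_example(self, example_doc):
        assert parse_svg(serialize_svg(example_doc)) == example_doc

    def test_empty_document(self):
        doc = SvgAnnotationDocument(1, 1)
        assert parse_svg(serialize_svg(doc)) == doc

    def test_invalid_document_rejected(self):
        bad = SvgAnnotationDocument(100, 100, (rect(0, 0, -5, 5),))
        with pytest.raises(ValidationError):
            serialize_svg(bad)

    def test_no_trailing_zeros(self):
        text = serialize_svg(SvgAnnotationDocument(10, 10, (rect(1.0, 2.5, 3.0, 4.0),)))
        assert 'x="1"' in text and 'y="2.5"' in text

    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(documents)
    def test_parse_serialize_identity(self, doc):
        """parse . serialize is the identity on valid documents."""
        assert parse_svg(serialize_svg(doc)) == doc


class TestTransforms:
    def test_invert_identity(self):
        assert invert(IDENTITY) == IDENTITY

    def test_reciprocal_scales_compose_to_identity(self):
        assert compose(scaling(2), scaling(0.5)) == IDENTITY

    def test_compose_order(self):
        # scale then translate differs from translate then scale
        t = compose(scaling(2), translation(1, 1))
        assert t.apply(1, 1) == (3, 3)
        t = compose(translation(1, 1), scaling(2))
        assert t.apply(1, 1) == (4, 4)

    def test_singular_matrix_rejected(self):
        with pytest.raises(NonInvertibleTransformError):
            invert(AffineTransform2D(1, 2, 2, 4, 0, 0))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.tuples(*(st.floats(-50, 50, allow_nan=False) for _ in range(6)))
           .map(lambda p: AffineTransform2D(*p))
           .filter(lambda t: abs(t.determinant()) > 1e-3))
    def test_invert_is_two_sided_inverse(self, t):
        for product in (compose(t, invert(t)), compose(invert(t), t)):
            for got, want in zip(
                    (product.a, product.b, product.c, product.d,
                     product.e, product.f),
                    (1, 0, 0, 1, 0, 0)):
                assert got == pytest.approx(want, abs=1e-9)


class TestApplyTransform:
    def test_identity_returns_equal_document(self, example_doc):
        assert apply_transform(example_doc, IDENTITY) == example_doc

    def test_scale_by_two_on_worked_example_rect(self, example_doc):
        # corners (207,124) and (278,190) scale to (414,248) and (556,380)
        out = apply_transform(example_doc, scaling(2))
        assert out.shapes[0].geometry == {
            "x": 414, "y": 248, "width": 142, "height": 132}

    def test_stroke_width_not_scaled(self, example_doc):
        out = apply_transform(example_doc, scaling(10))
        assert out.shapes[0].style.stroke_width == 2.0

    def test_flip_renormalizes_rect(self):
        doc = SvgAnnotationDocument(100, 100, (rect(10, 10, 20, 30),))
        out = apply_transform(doc, AffineTransform2D(-1, 0, 0, 1, 100, 0))
        assert out.shapes[0].geometry == {
            "x": 70, "y": 10, "width": 20, "height": 30}

    def test_shear_on_rect_rejected(self):
        doc = SvgAnnotationDocument(100, 100, (rect(0, 0, 10, 10),))
        with pytest.raises(UnsupportedTransformError, match="polygon"):
            apply_transform(doc, AffineTransform2D(1, 0.5, 0, 1, 0, 0))

    def test_shear_on_polygon_allowed(self):
        doc = SvgAnnotationDocument(100, 100,
                                    (polygon([(0, 0), (10, 0), (0, 10)]),))
        out = apply_transform(doc, AffineTransform2D(1, 0.5, 0, 1, 0, 0))
        assert out.shapes[0].points == ((0, 0), (10, 5), (0, 10))

    def test_preserves_kind_multiset(self):
        from svgfhir.fixtures import gen_annotation_doc
        doc = gen_annotation_doc(5, n_shapes=6)
        out = apply_transform(doc, compose(scaling(3), translation(-7, 11)))
        assert [s.kind for s in out.shapes] == [s.kind for s in doc.shapes]

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(documents,
           st.tuples(st.sampled_from([0.25, 0.5, 1, 2, 4]),
                     st.booleans(), st.booleans(),
                     st.floats(-100, 100, allow_nan=False),
                     st.floats(-100, 100, allow_nan=False)))
    def test_inverse_composition_restores_document(self, doc, params):
        """Applying t then its inverse restores every coordinate to 1e-9."""
        s, fx, fy, tx, ty = params
        t = AffineTransform2D(-s if fx else s, 0, 0, -s if fy else s, tx, ty)
        back = apply_transform(apply_transform(doc, t), invert(t))
        assert len(back.shapes) == len(doc.shapes)
        for a, b in zip(back.shapes, doc.shapes):
            assert a.kind == b.kind
            for key, value in b.geometry.items():
                if key == "points":
                    for (x1, y1), (x2, y2) in zip(a.points, value):
                        assert x1 == pytest.approx(x2, abs=1e-9)
                        assert y1 == pytest.approx(y2, abs=1e-9)
                else:
                    assert a.geometry[key] == pytest.approx(value, abs=1e-9)
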