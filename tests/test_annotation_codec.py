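"""Base64 encapsulation of SVG annotations in FHIR Observations."""

from __future__ import annotations

import base64
import binascii

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svgfhir import (
    CodingStub,
    FhirReference,
    ObservationResource,
    SvgAnnotationDocument,
    build_wado_url,
    decode_annotation,
    encode_annotation,
    rect,
    scaling,
    serialize_svg,
    validate_annotation,
    validate_resource,
)
from svgfhir.errors import (
    IncompleteAnnotationError,
    MissingValueError,
    PayloadEncodingError,
    SubsetViolationError,
    UrlFormatError,
)

from conftest import WADO_BASE, documents, image_refs


class TestEncode:
    def test_worked_example_round_trips_without_background(
            self, example_doc, instance_url):
        obs = encode_annotation(example_doc, instance_url)
        doc, url = decode_annotation(obs)
        assert url == instance_url
        # the payload carries only SVG geometry: no background image ref
        assert doc.background_href is None
        assert doc.shapes == example_doc.shapes
        assert doc.shapes[0].geometry == {"x": 207, "y": 124,
                                          "width": 71, "height": 66}

    def test_defaults(self, example_doc, instance_url):
        obs = encode_annotation(example_doc, instance_url)
        assert obs.status == "final"
        assert obs.code.code == "image-annotation-svg"
        assert obs.focus[0].target == instance_url
        assert validate_resource(obs) == []
        assert validate_annotation(obs) == []

    def test_code_override(self, example_doc, instance_url):
        code = CodingStub("http://loinc.org", "59776-5")
        obs = encode_annotation(example_doc, instance_url, code=code)
        assert obs.code == code

    def test_empty_document(self, instance_url):
        doc = SvgAnnotationDocument(64, 64)
        out, _ = decode_annotation(encode_annotation(doc, instance_url))
        assert out == doc

    def test_payload_matches_independent_base64_encoder(self, instance_url):
        doc = SvgAnnotationDocument(100, 100, (rect(1, 2, 3, 4),))
        obs = encode_annotation(doc, instance_url)
        raw = serialize_svg(doc).encode("utf-8")
        expected = binascii.b2a_base64(raw, newline=False).decode("ascii")
        assert obs.valueString == expected

    def test_viewer_transform_applied_before_encoding(self, instance_url):
        # viewer canvas at half resolution: canvas -> pixel is scale by 2
        doc = SvgAnnotationDocument(256, 256, (rect(10, 20, 30, 40),))
        obs = encode_annotation(doc, instance_url, viewer_transform=scaling(2))
        out, _ = decode_annotation(obs)
        assert out.shapes[0].geometry == {"x": 20, "y": 40,
                                          "width": 60, "height": 80}

    def test_non_instance_url_rejected(self, example_doc):
        with pytest.raises(UrlFormatError):
            encode_annotation(example_doc, f"{WADO_BASE}/studies/1.2.3")


class TestDecode:
    def test_garbage_payload(self):
        obs = ObservationResource(id="a", status="final",
                                  code=CodingStub(code="c"),
                                  focus=[FhirReference("http://x/studies/1"
                                                       "/series/1/instances/1")],
                                  valueString="!!!")
        with pytest.raises(PayloadEncodingError):
            decode_annotation(obs)

    def test_missing_payload(self):
        obs = ObservationResource(id="a", status="final",
                                  code=CodingStub(code="c"))
        with pytest.raises(MissingValueError):
            decode_annotation(obs)

    def test_missing_focus(self, example_doc, instance_url):
        obs = encode_annotation(example_doc, instance_url)
        obs.focus = []
        with pytest.raises(IncompleteAnnotationError):
            decode_annotation(obs)

    def test_payload_failing_subset_validation(self, instance_url):
        payload = base64.b64encode(
            b'<svg width="5" height="5" xmlns="http://www.w3.org/2000/svg">'
            b'<path d="M0 0"/></svg>').decode()
        obs = ObservationResource(id="a", status="final",
                                  code=CodingStub(code="c"),
                                  focus=[FhirReference(instance_url)],
                                  valueString=payload)
        with pytest.raises(SubsetViolationError):
            decode_annotation(obs)

    def test_hand_built_observation_with_example_rect(self, instance_url):
        svg = ('<svg width="512" height="512" '
               'xmlns="http://www.w3.org/2000/svg">'
               '<rect x="207" y="124" width="71" height="66" '
               'style="stroke:rgb(255,255,0); stroke-width:2; fill:none"/>'
               '</svg>')
        obs = ObservationResource(
            id="4961", status="final", code=CodingStub(code="c"),
            focus=[FhirReference(instance_url)],
            valueString=base64.b64encode(svg.encode()).decode())
        doc, _ = decode_annotation(obs)
        assert doc.shapes[0].geometry == {"x": 207, "y": 124,
                                          "width": 71, "height": 66}

    def test_base64binary_slot_accepted(self, example_doc, instance_url):
        obs = encode_annotation(example_doc, instance_url)
        obs.extras["valueBase64Binary"] = obs.valueString
        obs.valueString = None
        doc, url = decode_annotation(obs)
        assert doc.shapes == example_doc.shapes
        assert url == instance_url


class TestRoundTripProperty:
    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(documents, image_refs)
    def test_decode_encode_identity(self, doc, ref):
        """decode . encode restores the background-stripped document and
        the focus URL, for every generated document and image ref."""
        url = build_wado_url(WADO_BASE, ref)
        out, out_url = decode_annotation(encode_annotation(doc, url))
        assert out == doc.without_background()
        assert out_url == url

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(documents, image_refs)
    def test_encoding_deterministic(self, doc, ref):
        url = build_wado_url(WADO_BASE, ref)
        first = encode_annotation(doc, url)
        second = encode_annotation(doc, url)
        assert first.valueString == second.valueString

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(documents, image_refs)
    def test_encoded_observation_is_valid(self, doc, ref):
        obs = encode_annotation(doc, build_wado_url(WADO_BASE, ref))
        assert validate_resource(obs) == []
        assert validate_annotation(obs) == []
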