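"""Encapsulate SVG annotations in FHIR Observations and decode them back.

FHIR resources are JSON/XML and raw SVG markup embedded in them would
break server-side parsing, so the annotation document is serialized
canonically, UTF-8 encoded, and base64-wrapped into
``Observation.valueString``. The annotated image is not referenced from
inside the SVG: the payload carries geometry only, and the image link
lives exclusively in ``Observation.focus`` as a WADO-RS instance URL.

Encoding is deterministic — equal documents yield byte-identical
payloads — because the SVG writer is canonical and base64 uses the
standard alphabet without line wrapping.
"""

from __future__ import annotations

import base64
import binascii

from .dicomweb_map import parse_wado_url
from .errors import (
    IncompleteAnnotationError,
    MissingValueError,
    PayloadEncodingError,
    SubsetViolationError,
    ValidationError,
    Violation,
)
from .fhir_model import (
    CodingStub,
    FhirReference,
    ObservationResource,
    default_annotation_code,
)
from .svg_model import (
    AffineTransform2D,
    SvgAnnotationDocument,
    apply_transform,
    parse_svg,
    serialize_svg,
    validate_subset,
)

#: alias: an annotation Observation is an ObservationResource whose
#: valueString holds the base64 SVG payload and whose focus[0] is the
#: WADO-RS URL of the annotated image.
AnnotationObservation = ObservationResource


def encode_annotation(
    doc: SvgAnnotationDocument,
    image_url: str,
    subject: FhirReference | None = None,
    code: CodingStub | None = None,
    viewer_transform: AffineTransform2D | None = None,
    observation_id: str = "",
    status: str = "final",
) -> AnnotationObservation:
    """Wrap an annotation document into a FHIR Observation.

    ``viewer_transform``, when given, maps viewer-canvas coordinates to
    DICOM pixel coordinates and is applied before encoding, so the
    stored payload is always in image pixels. Any background image
    reference is stripped: the payload contains only SVG geometry.
    """
    problems = doc.validate()
    if problems:
        raise ValidationError(problems)
    parse_wado_url(image_url)  # raises UrlFormatError if not instance-level
    if viewer_transform is not None:
        doc = apply_transform(doc, viewer_transform)
    payload = serialize_svg(doc.without_background())
    value = base64.b64encode(payload.encode("utf-8")).decode("ascii")
    return ObservationResource(
        id=observation_id,
        status=status,
        code=code or default_annotation_code(),
        subject=subject,
        focus=[FhirReference(image_url)],
        valueString=value,
    )


def decode_annotation(
    obs: ObservationResource,
) -> tuple[SvgAnnotationDocument, str]:
    """Recover the annotation document and its image URL from an
    Observation.

    The payload is looked for in ``valueString`` (base64 text, the
    canonical slot) and, failing that, in a ``valueBase64Binary`` slot —
    base64-binary-valued data is just a special kind of string, so both
    spellings decode identically.
    """
    raw = obs.valueString
    if raw is None:
        raw = obs.extras.get("valueBase64Binary")
    if raw is None:
        raise MissingValueError(
            f"Observation {obs.id or '?'} carries no annotation payload")
    try:
        text = base64.b64decode(raw, validate=True).decode("utf-8")
    except (binascii.Error, ValueError) as exc:
        raise PayloadEncodingError(
            f"valueString of Observation {obs.id or '?'} is not valid "
            f"base64/UTF-8: {exc}") from exc
    doc = parse_svg(text)  # raises SubsetViolationError on bad content
    if not obs.focus:
        raise IncompleteAnnotationError(
            f"Observation {obs.id or '?'} has no focus image reference")
    return doc, obs.focus[0].target


def validate_annotation(obs: ObservationResource) -> list[Violation]:
    """AnnotationObservation invariants as data: the payload must decode
    to subset-clean SVG and the focus must be a WADO-RS instance URL."""
    out = list(obs.validate())
    raw = obs.valueString or obs.extras.get("valueBase64Binary")
    if raw is None:
        out.append(Violation("valueString", "missing-payload"))
    else:
        try:
            text = base64.b64decode(raw, validate=True).decode("utf-8")
        except (binascii.Error, ValueError) as exc:
            out.append(Violation("valueString", "invalid-base64", str(exc)))
        else:
            out.extend(validate_subset(text))
    if not obs.focus:
        out.append(Violation("focus", "missing-focus"))
    else:
        from .errors import UrlFormatError
        try:
            parse_wado_url(obs.focus[0].target)
        except UrlFormatError as exc:
            out.append(Violation("focus[0]", "not-wado-instance-url", str(exc)))
    return out
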