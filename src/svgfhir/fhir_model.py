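"""Minimal in-memory model of the FHIR R4 resource subset the scheme uses.

Six resource types carry the whole imaging-annotation workflow:
Observation (annotations and findings), DiagnosticReport, ImagingStudy,
ServiceRequest and Encounter. Each is a plain dataclass with a lossless
JSON mapping — unknown JSON fields are kept in an ``extras`` slot and
re-emitted verbatim, so resources produced by fuller FHIR stacks survive
a round trip through this package.

Terminology is deliberately open: annotation Observations default to a
package-defined coding (``image-annotation-svg``) that callers override
with whatever code system their site uses.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .errors import FormatError, UnsupportedTypeError, Violation

#: DICOM UID grammar: dotted decimal components, no leading zeros issue
#: ignored (test UIDs use the 2.25 root), at most 64 characters.
_UID_RE = re.compile(r"\d+(\.\d+)*")

DEFAULT_ANNOTATION_CODE_SYSTEM = "urn:svgfhir:codes"
DEFAULT_ANNOTATION_CODE = "image-annotation-svg"

_SUPPORTED_REFERENCE_TYPES = {
    "Observation", "DiagnosticReport", "ImagingStudy",
    "ServiceRequest", "Encounter", "Patient", "Practitioner", "Organization",
}


def is_valid_uid(uid: str) -> bool:
    return bool(uid) and len(uid) <= 64 and _UID_RE.fullmatch(uid) is not None


@dataclass(frozen=True)
class FhirReference:
    """Reference string: relative ``Type/id`` or an absolute URL."""

    target: str

    def validate(self, where: str = "reference") -> list[Violation]:
        t = self.target
        if not t:
            return [Violation(where, "empty-reference")]
        if t.startswith(("http://", "https://", "urn:")):
            return []
        if "/" in t:
            rtype, _, rid = t.partition("/")
            if rtype in _SUPPORTED_REFERENCE_TYPES and rid:
                return []
        return [Violation(where, "malformed-reference", t)]

    @property
    def is_absolute(self) -> bool:
        return self.target.startswith(("http://", "https://", "urn:"))


@dataclass(frozen=True)
class CodingStub:
    system: str | None = None
    code: str = ""
    display: str | None = None

    def validate(self, where: str = "code") -> list[Violation]:
        if not self.code:
            return [Violation(where, "empty-code")]
        return []


def default_annotation_code() -> CodingStub:
    return CodingStub(DEFAULT_ANNOTATION_CODE_SYSTEM, DEFAULT_ANNOTATION_CODE,
                      "SVG image annotation")


@dataclass
class ObservationResource:
    id: str = ""
    status: str = "final"
    code: CodingStub = field(default_factory=CodingStub)
    subject: FhirReference | None = None
    focus: list[FhirReference] = field(default_factory=list)
    derivedFrom: list[FhirReference] = field(default_factory=list)
    valueString: str | None = None
    extras: dict = field(default_factory=dict)

    resource_type = "Observation"

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        if not self.status:
            out.append(Violation("status", "empty-status"))
        out.extend(self.code.validate("code"))
        if self.subject:
            out.extend(self.subject.validate("subject"))
        for i, ref in enumerate(self.focus):
            out.extend(ref.validate(f"focus[{i}]"))
        for i, ref in enumerate(self.derivedFrom):
            out.extend(ref.validate(f"derivedFrom[{i}]"))
        value_slots = [k for k in self.extras if k.startswith("value")]
        if self.valueString is not None:
            value_slots.append("valueString")
        if len(value_slots) > 1:
            out.append(Violation("value[x]", "multiple-value-slots",
                                 ", ".join(sorted(value_slots))))
        return out


@dataclass
class DiagnosticReportResource:
    id: str = ""
    status: str = "final"
    code: CodingStub = field(default_factory=CodingStub)
    subject: FhirReference | None = None
    result: list[FhirReference] = field(default_factory=list)
    imagingStudy: list[FhirReference] = field(default_factory=list)
    conclusion: str | None = None
    extras: dict = field(default_factory=dict)

    resource_type = "DiagnosticReport"

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        if not self.status:
            out.append(Violation("status", "empty-status"))
        out.extend(self.code.validate("code"))
        if self.subject:
            out.extend(self.subject.validate("subject"))
        for i, ref in enumerate(self.result):
            out.extend(ref.validate(f"result[{i}]"))
        for i, ref in enumerate(self.imagingStudy):
            out.extend(ref.validate(f"imagingStudy[{i}]"))
        return out


@dataclass
class ImagingStudySeries:
    series_uid: str
    modality: str
    instance_uids: list[str] = field(default_factory=list)


@dataclass
class ImagingStudyResource:
    id: str = ""
    study_uid: str = ""
    endpoint: str | None = None
    numberOfSeries: int = 0
    numberOfInstances: int = 0
    series: list[ImagingStudySeries] = field(default_factory=list)
    subject: FhirReference | None = None
    extras: dict = field(default_factory=dict)

    resource_type = "ImagingStudy"

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        if not is_valid_uid(self.study_uid):
            out.append(Violation("study_uid", "invalid-uid", self.study_uid))
        if self.numberOfSeries != len(self.series):
            out.append(Violation("numberOfSeries", "count-mismatch",
                                 f"{self.numberOfSeries} != {len(self.series)}"))
        actual = sum(len(s.instance_uids) for s in self.series)
        if self.numberOfInstances != actual:
            out.append(Violation("numberOfInstances", "count-mismatch",
                                 f"{self.numberOfInstances} != {actual}"))
        for i, s in enumerate(self.series):
            if not is_valid_uid(s.series_uid):
                out.append(Violation(f"series[{i}].uid", "invalid-uid",
                                     s.series_uid))
            for j, uid in enumerate(s.instance_uids):
                if not is_valid_uid(uid):
                    out.append(Violation(f"series[{i}].instance[{j}]",
                                         "invalid-uid", uid))
        return out


@dataclass
class ServiceRequestResource:
    id: str = ""
    status: str = "active"
    intent: str = "order"
    code: CodingStub = field(default_factory=CodingStub)
    subject: FhirReference = field(default_factory=lambda: FhirReference(""))
    requester: FhirReference | None = None
    identifier: str | None = None
    extras: dict = field(default_factory=dict)

    resource_type = "ServiceRequest"

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        if not self.status:
            out.append(Violation("status", "empty-status"))
        if not self.intent:
            out.append(Violation("intent", "empty-intent"))
        out.extend(self.code.validate("code"))
        out.extend(self.subject.validate("subject"))
        if self.requester:
            out.extend(self.requester.validate("requester"))
        return out


@dataclass
class EncounterResource:
    id: str = ""
    status: str = "planned"
    subject: FhirReference = field(default_factory=lambda: FhirReference(""))
    basedOn: FhirReference | None = None
    planned_start: str | None = None
    extras: dict = field(default_factory=dict)

    resource_type = "Encounter"

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        if not self.status:
            out.append(Violation("status", "empty-status"))
        out.extend(self.subject.validate("subject"))
        if self.basedOn:
            out.extend(self.basedOn.validate("basedOn"))
        return out


AnyResource = (ObservationResource | DiagnosticReportResource
               | ImagingStudyResource | ServiceRequestResource
               | EncounterResource)


def validate_resource(resource: AnyResource) -> list[Violation]:
    """Structural validation as data; empty list means all invariants hold."""
    return resource.validate()


# --------------------------------------------------------------------------
# JSON mapping


def _ref_out(ref: FhirReference) -> dict:
    return {"reference": ref.target}


def _ref_in(obj, where: str) -> FhirReference:
    if not isinstance(obj, dict) or "reference" not in obj:
        raise FormatError(f"{where}: expected a Reference object")
    return FhirReference(obj["reference"])


def _code_out(code: CodingStub) -> dict:
    coding: dict = {}
    if code.system:
        coding["system"] = code.system
    coding["code"] = code.code
    if code.display:
        coding["display"] = code.display
    return {"coding": [coding]}


def _code_in(obj) -> CodingStub:
    if not isinstance(obj, dict):
        return CodingStub()
    codings = obj.get("coding") or [{}]
    first = codings[0]
    return CodingStub(first.get("system"), first.get("code", ""),
                      first.get("display"))


def _pop(payload: dict, key: str, default=None):
    return payload.pop(key, default)


def resource_to_dict(resource: AnyResource) -> dict:
    """FHIR R4 JSON shape (as a dict) for any modelled resource."""
    out: dict = {"resourceType": resource.resource_type}
    if resource.id:
        out["id"] = resource.id
    if isinstance(resource, ObservationResource):
        out["status"] = resource.status
        out["code"] = _code_out(resource.code)
        if resource.subject:
            out["subject"] = _ref_out(resource.subject)
        if resource.focus:
            out["focus"] = [_ref_out(r) for r in resource.focus]
        if resource.derivedFrom:
            out["derivedFrom"] = [_ref_out(r) for r in resource.derivedFrom]
        if resource.valueString is not None:
            out["valueString"] = resource.valueString
    elif isinstance(resource, DiagnosticReportResource):
        out["status"] = resource.status
        out["code"] = _code_out(resource.code)
        if resource.subject:
            out["subject"] = _ref_out(resource.subject)
        if resource.result:
            out["result"] = [_ref_out(r) for r in resource.result]
        if resource.imagingStudy:
            out["imagingStudy"] = [_ref_out(r) for r in resource.imagingStudy]
        if resource.conclusion is not None:
            out["conclusion"] = resource.conclusion
    elif isinstance(resource, ImagingStudyResource):
        out["status"] = resource.extras.get("status", "available")
        out["identifier"] = [{"system": "urn:dicom:uid",
                              "value": f"urn:oid:{resource.study_uid}"}]
        if resource.subject:
            out["subject"] = _ref_out(resource.subject)
        if resource.endpoint:
            out["endpoint"] = [{"reference": resource.endpoint}]
        out["numberOfSeries"] = resource.numberOfSeries
        out["numberOfInstances"] = resource.numberOfInstances
        out["series"] = [
            {"uid": s.series_uid,
             "modality": {"code": s.modality},
             "instance": [{"uid": uid} for uid in s.instance_uids]}
            for s in resource.series
        ]
    elif isinstance(resource, ServiceRequestResource):
        out["status"] = resource.status
        out["intent"] = resource.intent
        if resource.identifier:
            out["identifier"] = [{"value": resource.identifier}]
        out["code"] = _code_out(resource.code)
        out["subject"] = _ref_out(resource.subject)
        if resource.requester:
            out["requester"] = _ref_out(resource.requester)
    elif isinstance(resource, EncounterResource):
        out["status"] = resource.status
        out["subject"] = _ref_out(resource.subject)
        if resource.basedOn:
            out["basedOn"] = [_ref_out(resource.basedOn)]
        if resource.planned_start:
            out["period"] = {"start": resource.planned_start}
    else:  # pragma: no cover
        raise UnsupportedTypeError(type(resource).__name__)
    for key, value in resource.extras.items():
        if key not in out:
            out[key] = value
    return out


def resource_to_json(resource: AnyResource, indent: int | None = 2) -> str:
    return json.dumps(resource_to_dict(resource), indent=indent,
                      ensure_ascii=False)


def resource_from_dict(payload: dict) -> AnyResource:
    if not isinstance(payload, dict):
        raise FormatError("resource JSON must be an object")
    payload = dict(payload)
    rtype = _pop(payload, "resourceType")
    if rtype is None:
        raise FormatError("missing resourceType")
    rid = _pop(payload, "id", "") or ""
    if rtype == "Observation":
        res: AnyResource = ObservationResource(
            id=rid,
            status=_pop(payload, "status", "") or "",
            code=_code_in(_pop(payload, "code")),
            subject=(_ref_in(payload.pop("subject"), "subject")
                     if "subject" in payload else None),
            focus=[_ref_in(r, "focus") for r in _pop(payload, "focus", [])],
            derivedFrom=[_ref_in(r, "derivedFrom")
                         for r in _pop(payload, "derivedFrom", [])],
            valueString=_pop(payload, "valueString"),
            extras=payload,
        )
    elif rtype == "DiagnosticReport":
        res = DiagnosticReportResource(
            id=rid,
            status=_pop(payload, "status", "") or "",
            code=_code_in(_pop(payload, "code")),
            subject=(_ref_in(payload.pop("subject"), "subject")
                     if "subject" in payload else None),
            result=[_ref_in(r, "result") for r in _pop(payload, "result", [])],
            imagingStudy=[_ref_in(r, "imagingStudy")
                          for r in _pop(payload, "imagingStudy", [])],
            conclusion=_pop(payload, "conclusion"),
            extras=payload,
        )
    elif rtype == "ImagingStudy":
        idents = _pop(payload, "identifier", [])
        study_uid = ""
        for ident in idents:
            value = ident.get("value", "")
            study_uid = value.removeprefix("urn:oid:")
            if study_uid:
                break
        endpoints = _pop(payload, "endpoint", [])
        series = [
            ImagingStudySeries(
                series_uid=s.get("uid", ""),
                modality=(s.get("modality") or {}).get("code", ""),
                instance_uids=[i.get("uid", "") for i in s.get("instance", [])],
            )
            for s in _pop(payload, "series", [])
        ]
        status = _pop(payload, "status", "available")
        res = ImagingStudyResource(
            id=rid,
            study_uid=study_uid,
            endpoint=endpoints[0]["reference"] if endpoints else None,
            numberOfSeries=_pop(payload, "numberOfSeries", 0),
            numberOfInstances=_pop(payload, "numberOfInstances", 0),
            series=series,
            subject=(_ref_in(payload.pop("subject"), "subject")
                     if "subject" in payload else None),
            extras=payload,
        )
        if status != "available":
            res.extras["status"] = status
    elif rtype == "ServiceRequest":
        idents = _pop(payload, "identifier", [])
        res = ServiceRequestResource(
            id=rid,
            status=_pop(payload, "status", "") or "",
            intent=_pop(payload, "intent", "") or "",
            code=_code_in(_pop(payload, "code")),
            subject=_ref_in(_pop(payload, "subject", {"reference": ""}),
                            "subject"),
            requester=(_ref_in(payload.pop("requester"), "requester")
                       if "requester" in payload else None),
            identifier=idents[0].get("value") if idents else None,
            extras=payload,
        )
    elif rtype == "Encounter":
        based_on = _pop(payload, "basedOn", [])
        period = _pop(payload, "period", {})
        res = EncounterResource(
            id=rid,
            status=_pop(payload, "status", "") or "",
            subject=_ref_in(_pop(payload, "subject", {"reference": ""}),
                            "subject"),
            basedOn=_ref_in(based_on[0], "basedOn") if based_on else None,
            planned_start=period.get("start") if period else None,
            extras=payload,
        )
    else:
        raise UnsupportedTypeError(f"unsupported resourceType {rtype!r}")
    return res


def resource_from_json(text: str) -> AnyResource:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    return resource_from_dict(payload)


# --------------------------------------------------------------------------
# XML emission (thin alternate writer; JSON stays canonical)

FHIR_XML_NS = "http://hl7.org/fhir"


def resource_to_xml(resource: AnyResource) -> str:
    """FHIR XML for the modelled fields, built generically from the JSON
    shape (attributes carry primitive values, per the FHIR XML rules)."""
    from lxml import etree

    payload = resource_to_dict(resource)
    rtype = payload.pop("resourceType")
    root = etree.Element(f"{{{FHIR_XML_NS}}}{rtype}", nsmap={None: FHIR_XML_NS})

    def emit(parent, name, value):
        if isinstance(value, dict):
            el = etree.SubElement(parent, f"{{{FHIR_XML_NS}}}{name}")
            for k, v in value.items():
                emit(el, k, v)
        elif isinstance(value, list):
            for item in value:
                emit(parent, name, item)
        else:
            el = etree.SubElement(parent, f"{{{FHIR_XML_NS}}}{name}")
            el.set("value", str(value))

    for key, value in payload.items():
        emit(root, key, value)
    return etree.tostring(root, pretty_print=True, encoding="unicode")
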