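"""DICOMweb URL grammar and resource mapping.

Covers the three touch points between the FHIR side of the workflow and
the DICOMweb server:

* WADO-RS instance URLs (``{base}/studies/S/series/E/instances/I`` with
  an optional ``/frames/k``) — built and parsed exactly, since the
  annotation ``Observation.focus`` must identify a single image;
* QIDO-RS query URLs with a deterministic, whitelisted filter set;
* mapping a stored DICOM study's metadata onto a FHIR ImagingStudy, and
  a ServiceRequest + Encounter pair onto a UPS-RS worklist item.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from urllib.parse import quote

from .errors import (
    InconsistentOrderError,
    UnsupportedAttributeError,
    UrlFormatError,
    ValidationError,
    Violation,
)
from .fhir_model import (
    CodingStub,
    EncounterResource,
    ImagingStudyResource,
    ImagingStudySeries,
    ServiceRequestResource,
    is_valid_uid,
)

#: QIDO filter attributes accepted by default; extend via the
#: ``extra_attributes`` argument of :func:`build_qido_query`.
QIDO_ATTRIBUTE_WHITELIST = frozenset(
    {"PatientID", "StudyInstanceUID", "AccessionNumber", "Modality"})

_WADO_INSTANCE_RE = re.compile(
    r"^(?P<base>.+?)/studies/(?P<study>[\d.]+)/series/(?P<series>[\d.]+)"
    r"/instances/(?P<instance>[\d.]+)(?:/frames/(?P<frame>\d+))?/?$"
)


@dataclass(frozen=True)
class DicomImageRef:
    """Identifies one DICOM image (optionally one frame of it)."""

    study_uid: str
    series_uid: str
    instance_uid: str
    frame: int | None = None

    def validate(self) -> list[Violation]:
        out = []
        for name, uid in (("study_uid", self.study_uid),
                          ("series_uid", self.series_uid),
                          ("instance_uid", self.instance_uid)):
            if not is_valid_uid(uid):
                out.append(Violation(name, "invalid-uid", uid))
        if self.frame is not None and self.frame < 1:
            out.append(Violation("frame", "frame-number-positive",
                                 str(self.frame)))
        return out


@dataclass
class DicomSeriesRecord:
    series_uid: str
    modality: str
    rows: int
    columns: int
    instance_uids: list[str] = field(default_factory=list)


@dataclass
class DicomStudyRecord:
    """Plain metadata record standing in for a stored DICOM study."""

    study_uid: str
    patient_id: str
    series: list[DicomSeriesRecord] = field(default_factory=list)
    accession: str | None = None

    def validate(self) -> list[Violation]:
        out = []
        if not is_valid_uid(self.study_uid):
            out.append(Violation("study_uid", "invalid-uid", self.study_uid))
        if not self.series:
            out.append(Violation("series", "at-least-one-series"))
        for i, s in enumerate(self.series):
            if not is_valid_uid(s.series_uid):
                out.append(Violation(f"series[{i}].series_uid", "invalid-uid",
                                     s.series_uid))
            if not s.instance_uids:
                out.append(Violation(f"series[{i}]", "at-least-one-instance"))
            if s.rows <= 0 or s.columns <= 0:
                out.append(Violation(f"series[{i}]", "positive-dimensions",
                                     f"rows={s.rows} columns={s.columns}"))
        return out

    def to_dict(self) -> dict:
        return {
            "study_uid": self.study_uid,
            "patient_id": self.patient_id,
            "accession": self.accession,
            "series": [
                {"series_uid": s.series_uid, "modality": s.modality,
                 "rows": s.rows, "columns": s.columns,
                 "instance_uids": list(s.instance_uids)}
                for s in self.series
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DicomStudyRecord":
        return cls(
            study_uid=payload["study_uid"],
            patient_id=payload["patient_id"],
            accession=payload.get("accession"),
            series=[DicomSeriesRecord(
                series_uid=s["series_uid"], modality=s["modality"],
                rows=s["rows"], columns=s["columns"],
                instance_uids=list(s["instance_uids"]))
                for s in payload.get("series", [])],
        )


@dataclass
class UpsWorklistItem:
    """UPS-RS worklist item in SCHEDULED state (creation only)."""

    patient_ref: str
    procedure_code: CodingStub
    input_order_id: str
    accession: str | None = None
    scheduled_datetime: str | None = None
    state: str = "SCHEDULED"

    def to_dict(self) -> dict:
        """JSON form using DICOM UPS keyword field names."""
        code: dict = {"CodeValue": self.procedure_code.code}
        if self.procedure_code.system:
            code["CodingSchemeDesignator"] = self.procedure_code.system
        if self.procedure_code.display:
            code["CodeMeaning"] = self.procedure_code.display
        out = {
            "ProcedureStepState": self.state,
            "PatientID": self.patient_ref,
            "ScheduledWorkitemCodeSequence": [code],
            "ReferencedRequestSequence": [
                {"RequestedProcedureID": self.input_order_id}
            ],
        }
        if self.accession is not None:
            out["AccessionNumber"] = self.accession
        if self.scheduled_datetime is not None:
            out["ScheduledProcedureStepStartDateTime"] = self.scheduled_datetime
        return out

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


# --------------------------------------------------------------------------
# URL construction / parsing


def _normalize_base(base: str) -> str:
    base = base.rstrip("/")
    if not base.startswith(("http://", "https://")):
        raise UrlFormatError(f"base must be an absolute http(s) URL: {base!r}")
    return base


def build_wado_url(base: str, ref: DicomImageRef) -> str:
    """WADO-RS retrieve URL for one instance (or frame)."""
    problems = ref.validate()
    if problems:
        raise ValidationError(problems)
    base = _normalize_base(base)
    url = (f"{base}/studies/{ref.study_uid}/series/{ref.series_uid}"
           f"/instances/{ref.instance_uid}")
    if ref.frame is not None:
        url += f"/frames/{ref.frame}"
    return url


def parse_wado_url(url: str) -> tuple[str, DicomImageRef]:
    """Exact inverse of :func:`build_wado_url`.

    Study- or series-level URLs are rejected: an annotation focus must
    name one image.
    """
    m = _WADO_INSTANCE_RE.match(url)
    if not m:
        raise UrlFormatError(
            f"not an instance-level WADO-RS URL: {url!r}")
    ref = DicomImageRef(
        study_uid=m.group("study"),
        series_uid=m.group("series"),
        instance_uid=m.group("instance"),
        frame=int(m.group("frame")) if m.group("frame") else None,
    )
    problems = ref.validate()
    if problems:
        raise UrlFormatError("; ".join(str(v) for v in problems))
    return m.group("base"), ref


def build_qido_query(base: str, level: str, filters: dict[str, str],
                     extra_attributes: frozenset[str] = frozenset()) -> str:
    """QIDO-RS search URL with a sorted, percent-encoded query string."""
    if level not in ("studies", "series", "instances"):
        raise UrlFormatError(f"unknown QIDO level {level!r}")
    allowed = QIDO_ATTRIBUTE_WHITELIST | extra_attributes
    unknown = sorted(set(filters) - allowed)
    if unknown:
        raise UnsupportedAttributeError(
            f"unsupported QIDO attribute(s): {', '.join(unknown)}")
    url = f"{_normalize_base(base)}/{level}"
    if filters:
        query = "&".join(
            f"{key}={quote(str(filters[key]), safe='.')}"
            for key in sorted(filters))
        url += f"?{query}"
    return url


# --------------------------------------------------------------------------
# resource mapping


def study_to_imagingstudy(study: DicomStudyRecord, endpoint: str,
                          resource_id: str = "") -> ImagingStudyResource:
    """Map stored-study metadata onto a FHIR ImagingStudy.

    Series order and modality are preserved 1:1; the series/instance
    counts are computed from the record, never taken on trust.
    """
    problems = study.validate()
    if problems:
        raise ValidationError(problems)
    series = [ImagingStudySeries(s.series_uid, s.modality,
                                 list(s.instance_uids))
              for s in study.series]
    return ImagingStudyResource(
        id=resource_id or f"imagingstudy-{study.study_uid.rsplit('.', 1)[-1]}",
        study_uid=study.study_uid,
        endpoint=_normalize_base(endpoint),
        numberOfSeries=len(series),
        numberOfInstances=sum(len(s.instance_uids) for s in series),
        series=series,
        subject=None,
    )


def order_to_ups(sr: ServiceRequestResource,
                 enc: EncounterResource) -> UpsWorklistItem:
    """Map an imaging order (ServiceRequest) plus its scheduled Encounter
    onto a UPS-RS worklist item in SCHEDULED state.

    The two resources must agree on the patient, either via
    ``Encounter.basedOn`` naming the ServiceRequest or via an identical
    subject reference.
    """
    linked = (enc.basedOn is not None and sr.id
              and enc.basedOn.target == f"ServiceRequest/{sr.id}")
    same_subject = sr.subject.target and sr.subject.target == enc.subject.target
    if not (linked or same_subject):
        raise InconsistentOrderError(
            f"Encounter {enc.id or '?'} is not linked to ServiceRequest "
            f"{sr.id or '?'} and their subjects differ "
            f"({sr.subject.target!r} vs {enc.subject.target!r})")
    if linked and enc.subject.target and sr.subject.target \
            and enc.subject.target != sr.subject.target:
        raise InconsistentOrderError(
            f"subject mismatch: {sr.subject.target!r} vs {enc.subject.target!r}")
    return UpsWorklistItem(
        patient_ref=sr.subject.target,
        procedure_code=sr.code,
        input_order_id=sr.id,
        accession=sr.identifier,
        scheduled_datetime=enc.planned_start,
    )
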