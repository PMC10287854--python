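"""Convert simplified CAD structured-report content into a report graph.

Computer-aided detection systems (mammography CAD in particular) emit
DICOM Structured Reports whose content tree carries device/procedure
context, referenced images and, per detection, an outline of the marked
region. This module consumes a documented JSON dialect of that content
("content-tree lite": patient, referenced images with their pixel
dimensions, findings with contour point lists) and produces the same
linked FHIR structure a radiologist's manual annotations would: one
polygon annotation Observation per finding, one finding Observation per
detection, one DiagnosticReport tying them together, and one
ImagingStudy per distinct study among the referenced images.

Each contour is rendered as a single closed SVG polygon — operating
points, certainty scores and verification flags present in full CAD SRs
are outside this dialect and are ignored with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .annotation_codec import encode_annotation
from .dicomweb_map import DicomImageRef, build_wado_url
from .errors import FormatError, ValidationError, Violation
from .fhir_model import FhirReference, ImagingStudyResource, ImagingStudySeries
from .report_graph import ReportGraph, assemble_report, make_finding
from .svg_model import StrokeStyle, SvgAnnotationDocument, SvgShape, polygon

logger = logging.getLogger(__name__)

_KNOWN_DOC_FIELDS = {"patient_id", "referenced_images", "findings",
                     "device", "method"}
_KNOWN_IMAGE_FIELDS = {"study_uid", "series_uid", "instance_uid", "frame",
                       "rows", "columns"}
_KNOWN_FINDING_FIELDS = {"label", "image_index", "contour"}

#: package default contour style: yellow stroke, 2 px
DEFAULT_CAD_STYLE = StrokeStyle((255, 255, 0), 2.0, "none")


@dataclass(frozen=True)
class CadReferencedImage:
    ref: DicomImageRef
    rows: int
    columns: int


@dataclass(frozen=True)
class CadFinding:
    label: str
    image_index: int
    contour: tuple[tuple[float, float], ...]


@dataclass
class CadDocument:
    patient_id: str
    referenced_images: list[CadReferencedImage] = field(default_factory=list)
    findings: list[CadFinding] = field(default_factory=list)
    device: str | None = None
    method: str | None = None

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        for i, img in enumerate(self.referenced_images):
            out.extend(Violation(f"referenced_images[{i}].{v.location}",
                                 v.rule, v.detail)
                       for v in img.ref.validate())
            if img.rows <= 0 or img.columns <= 0:
                out.append(Violation(f"referenced_images[{i}]",
                                     "positive-dimensions",
                                     f"rows={img.rows} columns={img.columns}"))
        for i, f in enumerate(self.findings):
            where = f"findings[{i}]"
            if not (0 <= f.image_index < len(self.referenced_images)):
                out.append(Violation(where, "image-index-range",
                                     str(f.image_index)))
                continue
            if len(f.contour) < 3:
                out.append(Violation(where, "contour-too-short",
                                     f"{len(f.contour)} < 3"))
            img = self.referenced_images[f.image_index]
            for j, (x, y) in enumerate(f.contour):
                if not (0 <= x <= img.columns and 0 <= y <= img.rows):
                    out.append(Violation(
                        f"{where}.contour[{j}]", "point-out-of-bounds",
                        f"({x}, {y}) outside [0,{img.columns}]x[0,{img.rows}]"))
        return out


def _warn_unknown(payload: dict, known: set, where: str) -> None:
    for key in sorted(set(payload) - known):
        logger.warning("ignoring unrecognized CAD field %s.%s", where, key)


def load_cad_document(text: str) -> CadDocument:
    """Parse the content-tree-lite JSON dialect into a typed document."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError("$: expected a JSON object")
    if "patient_id" not in payload:
        raise FormatError("$.patient_id: required")
    _warn_unknown(payload, _KNOWN_DOC_FIELDS, "$")
    images = []
    for i, img in enumerate(payload.get("referenced_images", [])):
        where = f"$.referenced_images[{i}]"
        for req in ("study_uid", "series_uid", "instance_uid", "rows",
                    "columns"):
            if req not in img:
                raise FormatError(f"{where}.{req}: required")
        _warn_unknown(img, _KNOWN_IMAGE_FIELDS, where)
        images.append(CadReferencedImage(
            ref=DicomImageRef(img["study_uid"], img["series_uid"],
                              img["instance_uid"], img.get("frame")),
            rows=int(img["rows"]), columns=int(img["columns"])))
    findings = []
    for i, f in enumerate(payload.get("findings", [])):
        where = f"$.findings[{i}]"
        for req in ("label", "image_index", "contour"):
            if req not in f:
                raise FormatError(f"{where}.{req}: required")
        _warn_unknown(f, _KNOWN_FINDING_FIELDS, where)
        contour = tuple((float(p[0]), float(p[1])) for p in f["contour"])
        if len(contour) < 3:
            raise FormatError(f"{where}.contour: at least 3 points required, "
                              f"got {len(contour)}")
        findings.append(CadFinding(str(f["label"]), int(f["image_index"]),
                                   contour))
    doc = CadDocument(
        patient_id=str(payload["patient_id"]),
        referenced_images=images,
        findings=findings,
        device=payload.get("device"),
        method=payload.get("method"),
    )
    problems = doc.validate()
    if problems:
        raise FormatError("; ".join(f"$.{v.location}: {v.rule}"
                                    for v in problems))
    return doc


def contour_to_polygon(f: CadFinding, style: StrokeStyle) -> SvgShape:
    """Closed polygon from the contour, dropping an explicit closing
    point (SVG polygon closure is implicit)."""
    points = f.contour
    if len(points) >= 2 and points[0] == points[-1]:
        points = points[:-1]
    return polygon(points, style)


def convert_cad(
    cad: CadDocument,
    wado_base: str,
    subject: FhirReference,
    style: StrokeStyle = DEFAULT_CAD_STYLE,
) -> ReportGraph:
    """Build the full FHIR report graph for a CAD result.

    Per finding: one annotation Observation whose canvas matches the
    referenced image's columns x rows and whose focus is the image's
    WADO-RS URL, plus one finding Observation (label in ``valueString``)
    derived from it. All findings hang off one DiagnosticReport; one
    ImagingStudy is emitted per distinct study UID among the referenced
    images, with device/method context carried once at report level.
    """
    problems = cad.validate()
    if problems:
        raise ValidationError(problems)

    annotations = []
    findings = []
    for i, f in enumerate(cad.findings, start=1):
        img = cad.referenced_images[f.image_index]
        doc = SvgAnnotationDocument(
            canvas_width=img.columns, canvas_height=img.rows,
            shapes=(contour_to_polygon(f, style),))
        ann = encode_annotation(
            doc, build_wado_url(wado_base, img.ref), subject=subject,
            observation_id=f"cad-annotation-{i}")
        annotations.append(ann)
        findings.append(make_finding(f.label, [ann], subject=subject,
                                     finding_id=f"cad-finding-{i}"))

    studies = []
    seen_uids: list[str] = []
    for img in cad.referenced_images:
        if img.ref.study_uid not in seen_uids:
            seen_uids.append(img.ref.study_uid)
    for k, study_uid in enumerate(seen_uids, start=1):
        series: dict[str, ImagingStudySeries] = {}
        for img in cad.referenced_images:
            if img.ref.study_uid != study_uid:
                continue
            s = series.setdefault(
                img.ref.series_uid,
                ImagingStudySeries(img.ref.series_uid, "MG", []))
            if img.ref.instance_uid not in s.instance_uids:
                s.instance_uids.append(img.ref.instance_uid)
        series_list = list(series.values())
        studies.append(ImagingStudyResource(
            id=f"cad-study-{k}",
            study_uid=study_uid,
            endpoint=wado_base.rstrip("/"),
            numberOfSeries=len(series_list),
            numberOfInstances=sum(len(s.instance_uids) for s in series_list),
            series=series_list,
            subject=subject,
        ))

    context = [f"CAD device: {cad.device}"] if cad.device else []
    if cad.method:
        context.append(f"method: {cad.method}")
    return assemble_report(
        findings, studies, subject=subject,
        conclusion="; ".join(context) or None,
        annotations=annotations,
        report_id="cad-report-1",
    )
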