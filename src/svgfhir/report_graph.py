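"""Report / finding / annotation / image linkage.

The scheme links four resource layers by FHIR references, always in the
same direction:

* ``DiagnosticReport.result`` → finding Observations,
* finding ``Observation.derivedFrom`` → annotation Observations,
* annotation ``Observation.focus`` → WADO-RS image URL, whose study UID
  must belong to one of the report's ImagingStudy resources.

A :class:`ReportGraph` holds one report plus its findings, annotations
and imaging studies, and resolves references in memory. Findings may
carry zero annotations and reports zero findings; an annotation may be
shared by several findings (the reference structure is a DAG, not a
tree). Reverse indices are derived, never serialized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .annotation_codec import decode_annotation, validate_annotation
from .dicomweb_map import parse_wado_url
from .errors import (
    AmbiguityError,
    FormatError,
    SvgFhirError,
    UnidentifiedResourceError,
    UrlFormatError,
    Violation,
)
from .fhir_model import (
    CodingStub,
    DiagnosticReportResource,
    FhirReference,
    ImagingStudyResource,
    ObservationResource,
    resource_from_dict,
    resource_to_dict,
)
from .svg_model import SvgAnnotationDocument


@dataclass
class ReportGraph:
    report: DiagnosticReportResource
    findings: list[ObservationResource] = field(default_factory=list)
    annotations: list[ObservationResource] = field(default_factory=list)
    imaging_studies: list[ImagingStudyResource] = field(default_factory=list)

    def resolution_map(self) -> dict[str, object]:
        """Reference string ("Type/id") → contained resource."""
        out: dict[str, object] = {}
        for res in self.all_resources():
            if res.id:
                key = f"{res.resource_type}/{res.id}"
                if key in out:
                    raise AmbiguityError(f"duplicate resource id {key}")
                out[key] = res
        return out

    def all_resources(self):
        yield self.report
        yield from self.findings
        yield from self.annotations
        yield from self.imaging_studies


def make_finding(
    description: str | CodingStub,
    annotations: list[ObservationResource],
    subject: FhirReference | None = None,
    finding_id: str = "",
    status: str = "final",
) -> ObservationResource:
    """Finding Observation deriving from the given annotations, in order.

    A plain-text description lands in ``valueString`` with a generic
    finding code; a CodingStub becomes the Observation code itself.
    """
    refs = []
    for ann in annotations:
        if not ann.id:
            raise UnidentifiedResourceError(
                "annotation has no id; assign ids before linking")
        refs.append(FhirReference(f"Observation/{ann.id}"))
    if isinstance(description, CodingStub):
        code, value = description, None
    else:
        code = CodingStub("urn:svgfhir:codes", "image-finding", "Image finding")
        value = description
    return ObservationResource(
        id=finding_id,
        status=status,
        code=code,
        subject=subject,
        derivedFrom=refs,
        valueString=value,
    )


def assemble_report(
    findings: list[ObservationResource],
    imaging_studies: list[ImagingStudyResource],
    subject: FhirReference | None = None,
    conclusion: str | None = None,
    annotations: list[ObservationResource] | None = None,
    report_id: str = "report-1",
    code: CodingStub | None = None,
) -> ReportGraph:
    """Build the full linked graph around a new DiagnosticReport.

    ``annotations`` is the pool from which the findings' ``derivedFrom``
    references are satisfied; only referenced annotations are kept, in
    first-reference order, so the graph holds exactly the transitive
    closure of the report.
    """
    pool: dict[str, ObservationResource] = {}
    for ann in annotations or []:
        if not ann.id:
            raise UnidentifiedResourceError("annotation without id")
        if ann.id in pool:
            raise AmbiguityError(f"duplicate annotation id {ann.id}")
        pool[ann.id] = ann
    seen_findings: set[str] = set()
    for f in findings:
        if not f.id:
            raise UnidentifiedResourceError("finding without id")
        if f.id in seen_findings:
            raise AmbiguityError(f"duplicate finding id {f.id}")
        seen_findings.add(f.id)
    used: list[ObservationResource] = []
    used_ids: set[str] = set()
    for f in findings:
        for ref in f.derivedFrom:
            _, _, ann_id = ref.target.partition("/")
            if ann_id in pool and ann_id not in used_ids:
                used.append(pool[ann_id])
                used_ids.add(ann_id)
    report = DiagnosticReportResource(
        id=report_id,
        status="final",
        code=code or CodingStub("urn:svgfhir:codes", "imaging-report",
                                "Imaging report"),
        subject=subject,
        result=[FhirReference(f"Observation/{f.id}") for f in findings],
        imagingStudy=[FhirReference(f"ImagingStudy/{s.id}")
                      for s in imaging_studies],
        conclusion=conclusion,
    )
    return ReportGraph(report, list(findings), used, list(imaging_studies))


def validate_graph(g: ReportGraph) -> list[Violation]:
    """Check every linkage invariant; one record per dangling reference,
    study-UID mismatch, or reference cycle."""
    out: list[Violation] = []
    try:
        resolution = g.resolution_map()
    except AmbiguityError as exc:
        return [Violation("graph", "duplicate-id", str(exc))]

    finding_keys = {f"Observation/{f.id}" for f in g.findings if f.id}
    annotation_keys = {f"Observation/{a.id}" for a in g.annotations if a.id}
    study_uids = {s.study_uid for s in g.imaging_studies}

    for i, ref in enumerate(g.report.result):
        if ref.target not in finding_keys:
            out.append(Violation(f"report.result[{i}]", "dangling-reference",
                                 ref.target))
    for f in g.findings:
        for i, ref in enumerate(f.derivedFrom):
            if ref.target not in annotation_keys:
                out.append(Violation(
                    f"finding[{f.id}].derivedFrom[{i}]",
                    "dangling-reference", ref.target))
    for i, ref in enumerate(g.report.imagingStudy):
        if ref.target not in resolution:
            out.append(Violation(f"report.imagingStudy[{i}]",
                                 "dangling-reference", ref.target))
    for ann in g.annotations:
        problems = validate_annotation(ann)
        out.extend(Violation(f"annotation[{ann.id}].{v.location}",
                             v.rule, v.detail) for v in problems)
        if ann.focus:
            try:
                _, ref = parse_wado_url(ann.focus[0].target)
            except UrlFormatError:
                continue  # already reported above
            if ref.study_uid not in study_uids:
                out.append(Violation(
                    f"annotation[{ann.id}].focus", "study-uid-unknown",
                    f"study {ref.study_uid} not among the report's "
                    "imaging studies"))

    # cycle detection over Observation derivedFrom edges
    obs = {f"Observation/{o.id}": o for o in (*g.findings, *g.annotations)
           if o.id}
    colour: dict[str, int] = {}

    def visit(key: str) -> bool:
        state = colour.get(key, 0)
        if state == 1:
            return True
        if state == 2 or key not in obs:
            return False
        colour[key] = 1
        hit = any(visit(ref.target) for ref in obs[key].derivedFrom)
        colour[key] = 2
        return hit

    for key in obs:
        if colour.get(key, 0) == 0 and visit(key):
            out.append(Violation(key, "reference-cycle",
                                 "derivedFrom chain revisits this Observation"))
    return out


def collect_annotations(
    g: ReportGraph,
    finding_id: str | None = None,
) -> list[tuple[ObservationResource, SvgAnnotationDocument, str]]:
    """Decode every annotation reachable from the report (or from one
    finding), in report.result order then derivedFrom order. Shared
    annotations are returned once, at their first reachable position."""
    by_key = {f"Observation/{a.id}": a for a in g.annotations if a.id}
    findings_by_key = {f"Observation/{f.id}": f for f in g.findings if f.id}
    if finding_id is not None:
        wanted = [findings_by_key.get(f"Observation/{finding_id}")]
        if wanted[0] is None:
            raise UnidentifiedResourceError(
                f"no finding with id {finding_id!r} in the graph")
    else:
        wanted = [findings_by_key[r.target] for r in g.report.result
                  if r.target in findings_by_key]
    out = []
    seen: set[str] = set()
    for f in wanted:
        for ref in f.derivedFrom:
            if ref.target in seen or ref.target not in by_key:
                continue
            seen.add(ref.target)
            ann = by_key[ref.target]
            try:
                doc, url = decode_annotation(ann)
            except SvgFhirError as exc:
                exc.args = (f"annotation {ann.id}: {exc}",)
                raise
            out.append((ann, doc, url))
    return out


# --------------------------------------------------------------------------
# flat-list serialization (minimal collection-Bundle wrapper)


def graph_to_dict(g: ReportGraph) -> dict:
    return {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": resource_to_dict(r)} for r in g.all_resources()],
    }


def graph_to_json(g: ReportGraph, indent: int | None = 2) -> str:
    return json.dumps(graph_to_dict(g), indent=indent, ensure_ascii=False)


def graph_from_dict(payload: dict) -> ReportGraph:
    if payload.get("resourceType") != "Bundle":
        raise FormatError("expected a Bundle with resourceType 'Bundle'")
    report = None
    findings: list[ObservationResource] = []
    annotations: list[ObservationResource] = []
    studies: list[ImagingStudyResource] = []
    observations: list[ObservationResource] = []
    for i, entry in enumerate(payload.get("entry", [])):
        res = resource_from_dict(entry.get("resource", {}))
        if isinstance(res, DiagnosticReportResource):
            if report is not None:
                raise FormatError("Bundle holds more than one DiagnosticReport")
            report = res
        elif isinstance(res, ObservationResource):
            observations.append(res)
        elif isinstance(res, ImagingStudyResource):
            studies.append(res)
        else:
            raise FormatError(
                f"entry[{i}]: {res.resource_type} does not belong in a "
                "report graph")
    if report is None:
        raise FormatError("Bundle holds no DiagnosticReport")
    # findings are the observations the report references; the rest are
    # annotations (payload-carrying observations referenced by findings)
    finding_keys = {r.target for r in report.result}
    for obs in observations:
        key = f"Observation/{obs.id}"
        (findings if key in finding_keys else annotations).append(obs)
    return ReportGraph(report, findings, annotations, studies)


def graph_from_json(text: str) -> ReportGraph:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    return graph_from_dict(payload)
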