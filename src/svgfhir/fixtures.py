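"""Deterministic synthetic fixtures for offline testing.

No public imaging archive accompanies the scheme, so every test input
is generated: DICOM study metadata records, annotation documents, CAD
content trees, order/encounter pairs, complete report graphs, and small
procedurally drawn background images. Everything is a pure function of
a seed — UIDs derive from SHA-256 of (seed, path) under the ``2.25.``
UUID-style root, geometry comes from ``random.Random(seed)`` — so the
same call yields byte-identical output on any platform.

The generated data exercises the structural space (multi-series
studies, every shape kind, multi-finding CAD reports across several
studies) but makes no attempt at anatomical realism: backgrounds are
gradients with a marker dot, not tissue.
"""

from __future__ import annotations

import hashlib
import json
import random
from pathlib import Path

from .cad_convert import CadDocument, CadFinding, CadReferencedImage
from .dicomweb_map import (
    DicomImageRef,
    DicomSeriesRecord,
    DicomStudyRecord,
    build_wado_url,
)
from .errors import ParameterError
from .fhir_model import (
    CodingStub,
    EncounterResource,
    FhirReference,
    ServiceRequestResource,
)
from .svg_model import (
    StrokeStyle,
    SvgAnnotationDocument,
    circle,
    ellipse,
    line,
    polygon,
    polyline,
    rect,
)

DEFAULT_WADO_BASE = "https://dicomweb.example.org/dicomweb"

_MODALITIES = ("CT", "MR", "MG", "CR", "US")


def make_uid(seed: int, *path) -> str:
    """Deterministic DICOM UID under the 2.25 (UUID-derived) root.

    The numeric tail is the decimal form of a SHA-256 prefix of
    ``seed/path``; total length stays well under the 64-character limit.
    """
    digest = hashlib.sha256(
        "/".join([str(seed), *map(str, path)]).encode()).digest()
    return f"2.25.{int.from_bytes(digest[:16], 'big')}"


def gen_study(seed: int, n_series: int = 2, instances_per_series: int = 3,
              rows: int = 512, columns: int = 512) -> DicomStudyRecord:
    if min(n_series, instances_per_series, rows, columns) < 1:
        raise ParameterError("all study parameters must be >= 1")
    rng = random.Random(seed)
    series = []
    for s in range(n_series):
        series.append(DicomSeriesRecord(
            series_uid=make_uid(seed, "series", s),
            modality=rng.choice(_MODALITIES),
            rows=rows, columns=columns,
            instance_uids=[make_uid(seed, "instance", s, i)
                           for i in range(instances_per_series)],
        ))
    return DicomStudyRecord(
        study_uid=make_uid(seed, "study"),
        patient_id=f"P{seed:04d}",
        accession=f"A{seed:06d}",
        series=series,
    )


def _rand_style(rng: random.Random) -> StrokeStyle:
    return StrokeStyle(
        (rng.randrange(256), rng.randrange(256), rng.randrange(256)),
        float(rng.randint(1, 5)), "none")


def _rand_points(rng: random.Random, n: int, w: int, h: int):
    pts = set()
    while len(pts) < n:
        pts.add((round(rng.uniform(0, w), 1), round(rng.uniform(0, h), 1)))
    return sorted(pts)  # stable, and never closes on itself


def gen_annotation_doc(seed: int, n_shapes: int = 3,
                       canvas: tuple[int, int] = (512, 512)
                       ) -> SvgAnnotationDocument:
    """Document with ``n_shapes`` shapes cycling through all six kinds,
    all geometry inside the canvas."""
    w, h = canvas
    if n_shapes < 0 or w < 1 or h < 1:
        raise ParameterError("n_shapes must be >= 0 and canvas positive")
    rng = random.Random(seed)
    kinds = ("rect", "circle", "ellipse", "line", "polyline", "polygon")
    shapes = []
    for i in range(n_shapes):
        kind = kinds[i % len(kinds)]
        style = _rand_style(rng)
        if kind == "rect":
            x = round(rng.uniform(0, w * 0.6), 1)
            y = round(rng.uniform(0, h * 0.6), 1)
            shapes.append(rect(x, y, round(rng.uniform(1, w - x), 1),
                               round(rng.uniform(1, h - y), 1), style))
        elif kind == "circle":
            r = round(rng.uniform(1, min(w, h) / 4), 1)
            shapes.append(circle(round(rng.uniform(r, w - r), 1),
                                 round(rng.uniform(r, h - r), 1), r, style))
        elif kind == "ellipse":
            rx = round(rng.uniform(1, w / 4), 1)
            ry = round(rng.uniform(1, h / 4), 1)
            shapes.append(ellipse(round(rng.uniform(rx, w - rx), 1),
                                  round(rng.uniform(ry, h - ry), 1),
                                  rx, ry, style))
        elif kind == "line":
            x1, y1 = _rand_points(rng, 1, w, h)[0]
            x2, y2 = _rand_points(rng, 1, w, h)[0]
            shapes.append(line(x1, y1, x2, y2, style))
        elif kind == "polyline":
            shapes.append(polyline(_rand_points(rng, rng.randint(2, 6), w, h),
                                   style))
        else:
            shapes.append(polygon(_rand_points(rng, rng.randint(3, 8), w, h),
                                  style))
    return SvgAnnotationDocument(w, h, tuple(shapes))


def _contour(rng: random.Random, columns: int, rows: int, n_points: int):
    """Roughly elliptical closed contour inside the image bounds."""
    import math
    cx = rng.uniform(columns * 0.3, columns * 0.7)
    cy = rng.uniform(rows * 0.3, rows * 0.7)
    a = rng.uniform(columns * 0.05, columns * 0.2)
    b = rng.uniform(rows * 0.05, rows * 0.2)
    pts = []
    for k in range(n_points):
        theta = 2 * math.pi * k / n_points
        wobble = rng.uniform(0.85, 1.15)
        x = min(max(cx + a * wobble * math.cos(theta), 0), columns)
        y = min(max(cy + b * wobble * math.sin(theta), 0), rows)
        pts.append((round(x, 1), round(y, 1)))
    return tuple(pts)


def gen_cad(seed: int, n_findings: int = 2, n_images: int = 2,
            rows: int = 1024, columns: int = 832,
            n_studies: int = 1) -> CadDocument:
    """CAD content tree: ``n_images`` referenced images spread over
    ``n_studies`` studies, findings assigned to images round-robin."""
    if n_findings < 0 or n_images < 1 or n_studies < 1:
        raise ParameterError("n_findings >= 0, n_images/n_studies >= 1")
    rng = random.Random(seed)
    images = []
    for i in range(n_images):
        study_idx = i % n_studies
        images.append(CadReferencedImage(
            ref=DicomImageRef(
                study_uid=make_uid(seed, "cad-study", study_idx),
                series_uid=make_uid(seed, "cad-series", study_idx, i),
                instance_uid=make_uid(seed, "cad-sop", i)),
            rows=rows, columns=columns))
    findings = [
        CadFinding(label=f"Detected mass {k + 1}",
                   image_index=k % n_images,
                   contour=_contour(rng, columns, rows, rng.randint(8, 40)))
        for k in range(n_findings)
    ]
    return CadDocument(
        patient_id=f"P{seed:04d}",
        referenced_images=images,
        findings=findings,
        device="SyntheticCAD workstation",
        method="contour detection (synthetic)",
    )


def cad_to_dict(cad: CadDocument) -> dict:
    """Content-tree-lite JSON form of a CAD document."""
    return {
        "patient_id": cad.patient_id,
        "device": cad.device,
        "method": cad.method,
        "referenced_images": [
            {"study_uid": img.ref.study_uid,
             "series_uid": img.ref.series_uid,
             "instance_uid": img.ref.instance_uid,
             **({"frame": img.ref.frame} if img.ref.frame else {}),
             "rows": img.rows, "columns": img.columns}
            for img in cad.referenced_images
        ],
        "findings": [
            {"label": f.label, "image_index": f.image_index,
             "contour": [[x, y] for x, y in f.contour]}
            for f in cad.findings
        ],
    }


def gen_workflow(seed: int) -> tuple[ServiceRequestResource,
                                     EncounterResource, DicomStudyRecord]:
    """Order → appointment → stored-study triple for one synthetic exam."""
    rng = random.Random(seed)
    study = gen_study(seed)
    sr = ServiceRequestResource(
        id=f"sr-{seed}",
        status="active",
        intent="order",
        code=CodingStub("urn:svgfhir:procedures",
                        rng.choice(("CT-HEAD", "MR-BRAIN", "MG-SCREEN")),
                        "Synthetic imaging procedure"),
        subject=FhirReference(f"Patient/{study.patient_id}"),
        requester=FhirReference("Practitioner/req-1"),
        identifier=study.accession,
    )
    enc = EncounterResource(
        id=f"enc-{seed}",
        status="planned",
        subject=FhirReference(f"Patient/{study.patient_id}"),
        basedOn=FhirReference(f"ServiceRequest/sr-{seed}"),
        planned_start=(f"2021-0{rng.randint(1, 9)}-"
                       f"{rng.randint(10, 28)}T{rng.randint(8, 16):02d}:00:00Z"),
    )
    return sr, enc, study


def gen_report_graph(seed: int, n_findings: int = 3, n_annotations: int = 5,
                     n_images: int = 3,
                     wado_base: str = DEFAULT_WADO_BASE):
    """Complete linked scenario: one study, ``n_images`` annotated
    images, ``n_annotations`` annotations distributed round-robin over
    images and findings."""
    from .annotation_codec import encode_annotation
    from .report_graph import assemble_report, make_finding

    if n_findings < 0 or n_annotations < 0 or n_images < 1:
        raise ParameterError("counts must be >= 0 (images >= 1)")
    study = gen_study(seed, n_series=1, instances_per_series=n_images)
    subject = FhirReference(f"Patient/{study.patient_id}")
    instance_uids = study.series[0].instance_uids
    annotations = []
    for i in range(n_annotations):
        doc = gen_annotation_doc(seed * 1000 + i, n_shapes=1,
                                 canvas=(study.series[0].columns,
                                         study.series[0].rows))
        url = build_wado_url(wado_base, DicomImageRef(
            study.study_uid, study.series[0].series_uid,
            instance_uids[i % n_images]))
        annotations.append(encode_annotation(
            doc, url, subject=subject, observation_id=f"ann-{seed}-{i + 1}"))
    findings = []
    for j in range(n_findings):
        mine = annotations[j::n_findings] if n_findings else []
        findings.append(make_finding(
            f"Synthetic finding {j + 1}", mine, subject=subject,
            finding_id=f"finding-{seed}-{j + 1}"))
    from .dicomweb_map import study_to_imagingstudy
    imaging = study_to_imagingstudy(study, wado_base,
                                    resource_id=f"study-{seed}")
    return assemble_report(findings, [imaging], subject=subject,
                           conclusion="Synthetic imaging report",
                           annotations=annotations,
                           report_id=f"report-{seed}")


def gen_image(seed: int, rows: int = 128, columns: int = 128,
              marker: tuple[float, float] | None = None) -> bytes:
    """Small synthetic grayscale PNG: smooth gradient plus a bright
    marker dot (stand-in for a rendered DICOM frame)."""
    from PIL import Image, ImageDraw

    rng = random.Random(seed)
    phase = rng.uniform(0, 64)
    img = Image.new("L", (columns, rows))
    img.putdata([int(96 + 64 * ((x + y + phase) % 256) / 256)
                 for y in range(rows) for x in range(columns)])
    if marker is not None:
        draw = ImageDraw.Draw(img)
        mx, my = marker
        draw.ellipse([mx - 4, my - 4, mx + 4, my + 4], fill=255)
    import io
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def write_fixture_bundle(out_dir: str | Path, seed: int) -> dict[str, Path]:
    """Write a complete fixture set to disk; returns name → path."""
    from .report_graph import graph_to_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    study = gen_study(seed)
    paths["study"] = out / "study_record.json"
    paths["study"].write_text(json.dumps(study.to_dict(), indent=2))

    cad = gen_cad(seed)
    paths["cad"] = out / "cad_document.json"
    paths["cad"].write_text(json.dumps(cad_to_dict(cad), indent=2))

    graph = gen_report_graph(seed)
    paths["graph"] = out / "report_graph.json"
    paths["graph"].write_text(graph_to_json(graph))

    from .svg_model import serialize_svg
    doc = gen_annotation_doc(seed)
    paths["svg"] = out / "annotation.svg"
    paths["svg"].write_text(serialize_svg(doc))

    images = out / "images"
    images.mkdir(exist_ok=True)
    from .annotation_codec import decode_annotation
    for i, ann in enumerate(graph.annotations, start=1):
        _doc, url = decode_annotation(ann)
        name = url.rsplit("/", 1)[-1]
        path = images / f"{name}.png"
        if not path.exists():
            path.write_bytes(gen_image(seed + i, 128, 128))
        paths[f"image-{i}"] = path
    return paths
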