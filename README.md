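# svgfhir

Graphic annotations on medical images — the rectangle a radiologist draws
around a lesion, the contour a mammography CAD system emits — are
traditionally stored as DICOM Presentation States or Structured Reports,
formats most web developers cannot parse in a browser. `svgfhir`
implements the web-native alternative: annotations are a constrained
subset of W3C SVG in DICOM pixel coordinates, stored base64-encoded in a
FHIR `Observation.valueString`, with the annotated image identified by a
DICOMweb WADO-RS URL in `Observation.focus`. Findings, reports and
images are then tied together with ordinary FHIR references:

```
DiagnosticReport.result       →  finding Observation
Observation.derivedFrom       →  annotation Observation
Observation.focus             →  {wado}/studies/S/series/E/instances/I
DiagnosticReport.imagingStudy →  ImagingStudy (one per DICOM study)
```

The package is for medical-imaging-informatics developers who need to
produce, validate, convert or ship this linked structure without a live
FHIR or DICOMweb server: everything is a pure transformation over JSON,
XML and HTML text, testable offline on synthetic fixtures.

What it covers:

* **SVG subset model** (`svg_model`) — rect, circle, ellipse, line,
  polyline, polygon plus one background image element; parsing,
  byte-stable canonical serialization, subset validation, and 2-D affine
  transforms between viewer-canvas and DICOM pixel coordinates.
* **FHIR subset** (`fhir_model`) — Observation, DiagnosticReport,
  ImagingStudy, ServiceRequest, Encounter as plain dataclasses with
  lossless JSON round trips (unknown fields are preserved).
* **Annotation codec** (`annotation_codec`) — deterministic base64
  encapsulation into `valueString`, decoding, invariant checks.
* **Report graph** (`report_graph`) — build, validate and traverse the
  report→finding→annotation→image linkage; Bundle-style serialization.
* **DICOMweb mapping** (`dicomweb_map`) — WADO-RS/QIDO-RS URL grammar,
  DICOM study → ImagingStudy, ServiceRequest+Encounter → UPS-RS
  worklist item.
* **CAD conversion** (`cad_convert`) — simplified CAD structured-report
  content (contours per detection) into the same FHIR graph.
* **Page export** (`page_export`) — self-contained HTML with inline SVG
  overlays and the FHIR resources embedded as JSON.
* **Fixtures** (`fixtures`) — deterministic synthetic studies,
  annotations, CAD documents and images, seeded and reproducible.

## Worked example

Encapsulate a rectangle annotation (a 71×66-pixel box at (207, 124) on
a 512×512 image) into a FHIR Observation and decode it back:

```python
from svgfhir import (parse_svg, encode_annotation, decode_annotation,
                     build_wado_url, DicomImageRef)

svg = """<svg width="512" height="512" xmlns="http://www.w3.org/2000/svg"
     xmlns:xlink="http://www.w3.org/1999/xlink">
  <image x="0" y="0" width="512" height="512" xlink:href="medicalImage.jpg"/>
  <rect x="207" y="124" width="71" height="66"
        style="stroke:rgb(255,255,0); stroke-width:2; fill:none"/>
</svg>"""

doc = parse_svg(svg)
url = build_wado_url("https://pacs.example.org/dicomweb",
                     DicomImageRef("1.2.3", "1.2.3.4", "1.2.3.4.5"))
obs = encode_annotation(doc, url)
print("focus:      ", obs.focus[0].target)
print("valueString:", obs.valueString[:48] + "...")

decoded, image_url = decode_annotation(obs)
rect = decoded.shapes[0]
print("rect:       ", rect.geometry)
print("stroke:     ", rect.style.stroke_rgb, "width", rect.style.stroke_width)
```

prints

```
focus:       https://pacs.example.org/dicomweb/studies/1.2.3/series/1.2.3.4/instances/1.2.3.4.5
valueString: PHN2ZyB3aWR0aD0iNTEyIiBoZWlnaHQ9IjUxMiIgeG1sbnM9...
rect:        {'x': 207.0, 'y': 124.0, 'width': 71.0, 'height': 66.0}
stroke:      (255, 255, 0) width 2.0
```

The geometry survives bit-exactly; the background image reference is
stripped from the payload (the image link lives only in `focus`), and
the `valueString` is the base64 of the canonical SVG serialization, so
equal documents always produce identical payloads.

The same flow is available from the shell:

```sh
svgfhir gen-fixtures --out fx --seed 42
svgfhir encode --in fx/annotation.svg --out obs.json \
    --focus-url https://pacs.example.org/dicomweb/studies/1.2.3/series/1.2.3.4/instances/1.2.3.4.5
svgfhir decode --in obs.json --out roundtrip.svg
svgfhir convert-cad --in fx/cad_document.json --out bundle.json \
    --wado-base https://pacs.example.org/dicomweb --subject Patient/P0042
svgfhir export-page --in fx/report_graph.json --out report.html \
    --image-dir fx/images
```

`report.html` is a standalone page: each annotated image becomes one
inline SVG block with the shapes drawn over a base64 data-URI image,
and the complete FHIR resource list rides along in a
`<script type="application/json">` block.

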