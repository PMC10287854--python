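# Methods

## The data scheme

`svgfhir` implements a web-native representation for graphic annotations
on medical images and for the structures that carry them through an
imaging workflow. The core idea is separation of concerns across two
RESTful servers: bulk pixel data lives on a DICOMweb server and is
addressed by WADO-RS URLs; everything the workflow produces *about*
those images — orders, appointments, study metadata, annotations,
findings, reports — is FHIR resources in JSON (or XML) on a FHIR server.
An annotation is a small SVG document; because FHIR resources are
themselves JSON/XML, raw SVG markup embedded in a string field would
corrupt or be corrupted by server-side parsing, so the SVG text is
base64-encoded into `Observation.valueString`. The annotated image is
never referenced from inside the SVG: the payload is pure geometry, and
the image link lives in `Observation.focus` as an instance-level WADO-RS
URL. Findings reference annotations through `Observation.derivedFrom`,
reports reference findings through `DiagnosticReport.result` and studies
through `DiagnosticReport.imagingStudy`. All links point in that one
direction; reverse indices are computed in memory and never serialized.

## Coordinate conventions and transforms

Annotation geometry is expressed in DICOM pixel coordinates: origin at
the top-left pixel corner, x along columns, y along rows, 0-based. SVG
uses the same orientation, so a stored annotation renders correctly with
no flip. A viewer that zooms, pans or flips works in its own canvas
coordinates; `AffineTransform2D` (the six-parameter SVG `matrix()`
convention, (x, y) → (a·x + c·y + e, b·x + d·y + f)) converts canvas
geometry to pixel geometry before encoding, and back for display.
Transforms compose and invert exactly (closed-form 2×2 inverse; a
singular matrix raises).

Two deliberate choices here:

* **Axis-preserving maps only for analytic shapes.** A general rotation
  or shear does not map an axis-aligned `rect` (or an axis-aligned
  ellipse) onto another one, so `apply_transform` accepts, for
  rect/circle/ellipse, only transforms whose linear part is diagonal or
  anti-diagonal — scalings, axis flips, quarter-turn rotations, plus any
  translation. Anything else raises an unsupported-transform error and
  suggests converting the shape to a polygon, which transforms freely.
  Circles additionally require a uniform scale (tolerance 1e-9
  relative); anisotropic scaling of a circle must go through an ellipse.
* **Stroke width is display style, not geometry.** A "2-pixel yellow
  border" stays 2 pixels under any zoom; transforms never rescale it.

## The SVG subset

Full W3C SVG is far larger than annotation needs and no two renderers
support all of it, so the package pins an explicit subset: the six shape
kinds (`rect`, `circle`, `ellipse`, `line`, `polyline`, `polygon`), at
most one background `image` element, and styling restricted to
`stroke:rgb(r,g,b)`, `stroke-width` and `fill:none`. Polygons never
repeat their first point (closure is implicit in SVG); polylines need at
least 2 points, polygons 3. Everything else — paths, text, CSS classes,
groups — is a subset violation, reported as data by `validate_subset`
(element/attribute name and position) rather than an exception, so a
validator can list all problems at once.

Serialization is canonical and byte-stable: geometry attributes in a
fixed order before style, shortest exact decimal formatting (integral
values print without a decimal point, others use the shortest
representation that round-trips the float exactly), fixed namespace
declarations. This matters because the base64 payload of an annotation
is derived from the serialization: canonical bytes make encoding
deterministic, payloads comparable, and de-duplication possible.
`parse ∘ serialize` is the identity on valid documents (property-tested
over generated documents of every shape kind).

A parsed shape with no `style` attribute receives the package default
(yellow, width 2, no fill) — the same default used for CAD contours.

## FHIR modelling choices

Only the six resource types the scheme touches are modelled, as plain
dataclasses with explicit JSON mappers. Reading preserves unknown
top-level fields in an `extras` dict and re-emits them, so the package
can round-trip resources written by richer FHIR implementations without
understanding them. `ImagingStudy` keeps the spec-level fields
(study UID via a `urn:dicom:uid` identifier, endpoint, series with
modality and instance UIDs) and enforces that `numberOfSeries` /
`numberOfInstances` equal the actual counts. FHIR's `Observation.focus`
is a list; the first entry is treated as the annotated image. XML
emission is a thin generic writer over the same JSON shape (primitives
as `value=` attributes); JSON is canonical for all tests.

Terminology is out of scope by design: annotation Observations carry a
package-default coding (`urn:svgfhir:codes` / `image-annotation-svg`),
findings `image-finding`, both overridable per call, because real
deployments will substitute LOINC/RadLex/SNOMED codes of their own.

The decoder accepts the payload from `valueString` (canonical) or from
a `valueBase64Binary` slot, since base64-binary-valued data is just a
special kind of string; the encoder always writes `valueString`.

## Report graph and CAD conversion

`validate_graph` checks, returning one record per problem: every
`report.result` reference resolves to a finding in the graph; every
finding `derivedFrom` resolves to an annotation; every annotation
decodes cleanly and its focus URL's study UID belongs to one of the
graph's ImagingStudy resources; no `derivedFrom` cycles exist
(depth-first three-colour search). Findings without annotations and
reports without findings are legal; an annotation may be shared by
several findings (the graph is a DAG, not a tree).

CAD results arrive as a documented "content-tree lite" JSON dialect —
patient, referenced images with pixel dimensions, findings with contour
point lists — standing in for full DICOM SR content trees, whose
remaining attributes (operating point, certainty, verified flags) are
outside this dialect and are ignored with a logged warning. Each
contour becomes one closed SVG polygon (an explicit duplicate closing
point is dropped), on a canvas sized to the referenced image's
columns × rows; each detection becomes one finding whose label lands in
`valueString`; one ImagingStudy is emitted per distinct study UID among
the referenced images (modality fixed to MG, the mammography case this
dialect models). Device and method strings are carried once, in the
report's `conclusion`, rather than duplicated per finding; FHIR R4's
DiagnosticReport has no dedicated slot for them and inventing an
extension was judged heavier than the text it would carry. Conversion
conserves counts exactly: findings in equals findings and annotations
out.

## Page export

Exported pages are static HTML5: one inline SVG block per annotated
image (background `image` element first, then the shapes in collection
order — report.result order, then derivedFrom order), plus the complete
resource list in a `<script type="application/json">` block (with `</`
escaped) so the structured data travels with the page. Image resolution
is a caller-supplied contract from focus URL to data URI or file path;
with data URIs the page needs no server of any kind. Converting DICOM
pixel data to a browser-renderable JPEG/PNG is the resolver's job, not
the exporter's. When several annotations target one image their shapes
merge into a single SVG block; the canvas of the first annotation wins
(fixture and CAD paths always agree on the image's own dimensions).

## Synthetic fixtures

No public dataset accompanies the scheme, so the generators in
`fixtures` produce every input: study metadata records (UIDs derived
from SHA-256 of seed and path under the `2.25.` UUID-style root, so
they are grammar-valid without registration and identical on every
platform), annotation documents cycling through all six shape kinds
with geometry inside the canvas, CAD documents with wobbled-ellipse
contours inside image bounds, order/encounter pairs, and complete
report graphs. Default sizes mirror the worked example and the
mammography case: 512×512 canvases, 2-series × 3-instance studies,
1024×832 CAD images, 2 findings on 2 images for the CAD scenario, and a
3-findings / 5-annotations / 3-images reporting scenario. Background
"images" are procedural gradients with a marker dot — visually
checkable, but not anatomy. Passing tests therefore demonstrate
structural and numerical correctness of the scheme (linkage, payload
round trips, count conservation, URL grammar), not robustness to the
long tail of real-world DICOM metadata or real SR content trees.

## Numerical and degenerate-input notes

* Geometry round trips are exact: floats serialize via shortest-repr,
  so parse(serialize(x)) == x bitwise; no tolerance is needed anywhere
  in the codec path.
* Transform identities are checked at 1e-12 per element for
  well-conditioned compose/invert and 1e-9 per coordinate after a
  forward-inverse round trip on documents.
* Zero-extent shapes (width/height/r = 0) are valid degenerate
  annotations; negative extents are invariant violations.
* Empty documents, empty reports, findings without annotations and CAD
  documents without findings are all legal and covered by tests.

## Known limitations

Network transport is entirely out of scope — every operation is a pure
text transformation; retrieval happens behind the resolver contract.
Only the SVG-in-Observation storage route is implemented (not
presentation-state or SR brokering), UPS-RS modelling stops at item
creation in SCHEDULED state, rendered-resource windowing/LUT pipelines
and patient-coordinate (3-D) registration are not modelled, and the
exported pages are static markup without interactive pan/zoom.
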