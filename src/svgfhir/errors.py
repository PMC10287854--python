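"""Exception hierarchy and the shared violation record.

Validators report problems as :class:`Violation` lists (data, not
exceptions); operations that cannot produce a result raise one of the
exceptions below.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Violation:
    """One structural-validation failure.

    location
        Where the problem is: an element/attribute name, a field path,
        or a reference string.
    rule
        Short identifier of the violated rule.
    detail
        Human-readable explanation.
    """

    location: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        msg = f"{self.location}: {self.rule}"
        return f"{msg} ({self.detail})" if self.detail else msg


class SvgFhirError(Exception):
    """Base class for all package errors."""


class SvgParseError(SvgFhirError):
    """Input is not well-formed XML or the root element is not ``svg``."""


class SubsetViolationError(SvgFhirError):
    """SVG input uses elements/attributes outside the supported subset."""

    def __init__(self, violations: list[Violation]):
        self.violations = list(violations)
        names = ", ".join(v.location for v in self.violations)
        super().__init__(f"SVG subset violations: {names}")


class ValidationError(SvgFhirError):
    """An object breaks its type invariants."""

    def __init__(self, violations: list[Violation] | str):
        if isinstance(violations, str):
            self.violations = [Violation("", "invalid", violations)]
            super().__init__(violations)
        else:
            self.violations = list(violations)
            super().__init__("; ".join(str(v) for v in self.violations))


class NonInvertibleTransformError(SvgFhirError):
    """Affine transform has zero determinant."""


class UnsupportedTransformError(SvgFhirError):
    """Transform would shear a rect/circle/ellipse; convert to polygon first."""


class UrlFormatError(SvgFhirError):
    """URL does not match the DICOMweb grammar at the required level."""


class UnsupportedAttributeError(SvgFhirError):
    """QIDO filter attribute outside the declared whitelist."""


class FormatError(SvgFhirError):
    """Structured input (JSON) does not match the documented schema."""


class UnsupportedTypeError(FormatError):
    """JSON resourceType outside the modelled set."""


class MissingValueError(SvgFhirError):
    """Observation carries no annotation payload."""


class PayloadEncodingError(SvgFhirError):
    """Annotation payload is not valid base64 / UTF-8."""


class IncompleteAnnotationError(SvgFhirError):
    """Annotation Observation lacks a focus image reference."""


class UnidentifiedResourceError(SvgFhirError):
    """A resource that must be referenced has no id."""


class AmbiguityError(SvgFhirError):
    """Two resources in one graph share an id."""


class InconsistentOrderError(SvgFhirError):
    """ServiceRequest and Encounter disagree on the subject."""


class UnresolvedImageError(SvgFhirError):
    """Page export could not resolve an image URL to a local source."""

    def __init__(self, url: str):
        self.url = url
        super().__init__(f"no image source available for {url}")


class ParameterError(SvgFhirError):
    """Fixture-generator parameters out of range."""
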