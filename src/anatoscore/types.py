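"""Domain types for anatomical error annotations of generated human images.

The annotation unit is one rater's assessment of one image. Errors are
counted per (anatomical region, error type, severity) cell against the
number of body parts of that region present — or expected present — in
the image, which caps every error proportion at 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator


class BodyRegion(enum.Enum):
    """The five annotated anatomical regions, in fixed vectorization order."""

    FACE = "face"
    TORSO = "torso"
    HANDS = "hands"
    LIMBS = "limbs"
    FEET = "feet"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ErrorType(enum.Enum):
    """The five anatomical error categories, in fixed vectorization order.

    proportion: misshaped or disproportionate parts (e.g. limbs too short);
    extra: additional parts (e.g. six fingers); orientation: anatomically
    implausible part orientation; configuration: disjointed, displaced or
    fused parts; missing: absent parts.
    """

    PROPORTION = "proportion"
    EXTRA = "extra"
    ORIENTATION = "orientation"
    CONFIGURATION = "configuration"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Severity(enum.Enum):
    """Ordinal error severity: a (low) < b (medium) < c (severe)."""

    A = "a"
    B = "b"
    C = "c"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def rank(self) -> int:
        return _SEVERITY_RANK[self]


_SEVERITY_RANK = {Severity.A: 0, Severity.B: 1, Severity.C: 2}

REGIONS: tuple[BodyRegion, ...] = tuple(BodyRegion)
ERROR_TYPES: tuple[ErrorType, ...] = tuple(ErrorType)
SEVERITIES: tuple[Severity, ...] = tuple(Severity)

#: Canonical per-person part counts; a region's expected count can never
#: exceed person_count times this anatomical maximum.
PARTS_PER_PERSON: dict[BodyRegion, int] = {
    BodyRegion.FACE: 1,
    BodyRegion.TORSO: 1,
    BodyRegion.HANDS: 2,
    BodyRegion.LIMBS: 4,
    BodyRegion.FEET: 2,
}


class AnnotationSchemaError(ValueError):
    """Raised when annotation data violates the schema or its invariants."""


@dataclass(frozen=True)
class ErrorRecord:
    """Count of parts in one region showing one error type at one severity."""

    region: BodyRegion
    error_type: ErrorType
    severity: Severity
    count: int

    def __post_init__(self) -> None:
        if not isinstance(self.count, int) or isinstance(self.count, bool):
            raise AnnotationSchemaError(f"error count must be an integer, got {self.count!r}")
        if self.count < 0:
            raise AnnotationSchemaError(f"error count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class RegionExpectation:
    """Number of parts of a region present, or expected present, in an image.

    This is the denominator of the error proportion. Zero is legitimate: a
    region can be entirely out of frame (e.g. feet in a portrait crop).
    """

    region: BodyRegion
    expected_count: int

    def __post_init__(self) -> None:
        if not isinstance(self.expected_count, int) or isinstance(self.expected_count, bool):
            raise AnnotationSchemaError(
                f"expected_count must be an integer, got {self.expected_count!r}"
            )
        if self.expected_count < 0:
            raise AnnotationSchemaError(f"expected_count must be >= 0, got {self.expected_count}")


@dataclass
class ImageAnnotation:
    """One annotator's full error assessment of one generated image.

    ``errors`` is sparse: a missing (region, error_type, severity) cell means
    a count of zero. ``expectations`` must cover all five regions.
    """

    image_id: str
    model: str
    prompt: str
    annotator: str
    person_count: int
    expectations: list[RegionExpectation]
    errors: list[ErrorRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.person_count < 1:
            raise AnnotationSchemaError(
                f"{self.image_id}: person_count must be >= 1, got {self.person_count}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.image_id, self.annotator)

    def expected_count(self, region: BodyRegion) -> int:
        for exp in self.expectations:
            if exp.region is region:
                return exp.expected_count
        raise AnnotationSchemaError(f"{self.image_id}: no expectation for region {region.value}")

    def error_count(self, region: BodyRegion, error_type: ErrorType, severity: Severity) -> int:
        for rec in self.errors:
            if rec.region is region and rec.error_type is error_type and rec.severity is severity:
                return rec.count
        return 0

    def violations(self) -> list[str]:
        """Invariant violations of this single annotation (empty list if valid)."""
        out: list[str] = []
        where = f"image {self.image_id!r} annotator {self.annotator!r}"

        seen_regions: set[BodyRegion] = set()
        for exp in self.expectations:
            if exp.region in seen_regions:
                out.append(f"{where}: duplicate expectation for region {exp.region.value}")
            seen_regions.add(exp.region)
            ceiling = self.person_count * PARTS_PER_PERSON[exp.region]
            if exp.expected_count > ceiling:
                out.append(
                    f"{where}: expected_count {exp.expected_count} for region "
                    f"{exp.region.value} exceeds anatomical maximum {ceiling} "
                    f"for {self.person_count} person(s)"
                )
        for region in REGIONS:
            if region not in seen_regions:
                out.append(f"{where}: missing expectation for region {region.value}")

        seen_cells: set[tuple[BodyRegion, ErrorType, Severity]] = set()
        for rec in self.errors:
            cell = (rec.region, rec.error_type, rec.severity)
            if cell in seen_cells:
                out.append(
                    f"{where}: duplicate error record for "
                    f"({rec.region.value}, {rec.error_type.value}, {rec.severity.value})"
                )
            seen_cells.add(cell)
            if rec.region not in seen_regions:
                out.append(
                    f"{where}: error record for region {rec.region.value} "
                    "has no region expectation"
                )

        # count ceiling: summed over severities, errors in a cell cannot
        # outnumber the parts present in that region
        if not any(v.startswith(f"{where}: duplicate error") for v in out):
            for region in seen_regions:
                m = self.expected_count(region)
                for etype in ERROR_TYPES:
                    total = sum(self.error_count(region, etype, sev) for sev in SEVERITIES)
                    if total > m:
                        out.append(
                            f"{where}: total error count {total} for "
                            f"({region.value}, {etype.value}) exceeds expected part "
                            f"count {m}"
                        )
        return out


@dataclass
class AnnotationSet:
    """A collection of image annotations with derived label metadata."""

    annotations: list[ImageAnnotation]

    @property
    def models(self) -> list[str]:
        return sorted({a.model for a in self.annotations})

    @property
    def prompts(self) -> list[str]:
        return sorted({a.prompt for a in self.annotations})

    @property
    def annotators(self) -> list[str]:
        return sorted({a.annotator for a in self.annotations})

    @property
    def image_ids(self) -> list[str]:
        return sorted({a.image_id for a in self.annotations})

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[ImageAnnotation]:
        return iter(self.annotations)

    def doubled_image_ids(self) -> list[str]:
        """Image ids annotated by two or more distinct annotators."""
        raters: dict[str, set[str]] = {}
        for a in self.annotations:
            raters.setdefault(a.image_id, set()).add(a.annotator)
        return sorted(i for i, r in raters.items() if len(r) >= 2)

    def sorted(self) -> "AnnotationSet":
        """Copy with canonical (image_id, annotator) ordering, errors sorted."""
        region_order = {r: i for i, r in enumerate(REGIONS)}
        type_order = {t: i for i, t in enumerate(ERROR_TYPES)}
        sev_order = {s: i for i, s in enumerate(SEVERITIES)}

        def sort_one(a: ImageAnnotation) -> ImageAnnotation:
            return ImageAnnotation(
                image_id=a.image_id,
                model=a.model,
                prompt=a.prompt,
                annotator=a.annotator,
                person_count=a.person_count,
                expectations=sorted(a.expectations, key=lambda e: region_order[e.region]),
                errors=sorted(
                    a.errors,
                    key=lambda r: (
                        region_order[r.region],
                        type_order[r.error_type],
                        sev_order[r.severity],
                    ),
                ),
            )

        return AnnotationSet(sorted((sort_one(a) for a in self.annotations), key=lambda a: a.key))


def validate(annotation_set: AnnotationSet) -> list[str]:
    """Check every invariant of a set; return human-readable violations.

    An empty list means the set is fully consistent. Violations name the
    offending image, annotator and field; this function never raises.
    """
    out: list[str] = []
    seen: set[tuple[str, str]] = set()
    for a in annotation_set.annotations:
        if a.key in seen:
            out.append(
                f"duplicate annotation: image {a.image_id!r} annotator {a.annotator!r} "
                "appears more than once"
            )
        seen.add(a.key)
        out.extend(a.violations())
    return out


def annotations_from_counts(
    image_id: str,
    model: str,
    prompt: str,
    annotator: str,
    person_count: int,
    expected: dict[BodyRegion, int],
    counts: dict[tuple[BodyRegion, ErrorType, Severity], int] | None = None,
) -> ImageAnnotation:
    """Convenience constructor from plain dictionaries; zero counts dropped."""
    errors = [
        ErrorRecord(region=r, error_type=t, severity=s, count=c)
        for (r, t, s), c in (counts or {}).items()
        if c != 0
    ]
    expectations = [
        RegionExpectation(region=r, expected_count=expected.get(r, 0)) for r in REGIONS
    ]
    return ImageAnnotation(
        image_id=image_id,
        model=model,
        prompt=prompt,
        annotator=annotator,
        person_count=person_count,
        expectations=expectations,
        errors=errors,
    )
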