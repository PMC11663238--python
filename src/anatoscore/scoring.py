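"""Error-proportion and severity-weighted cumulative scoring.

For one annotation, each of the 25 (region, error type) cells yields a
proportion of errors per severity k:

    PE_(ij)k = n_(ij)k / m_i

where n is the error count and m the number of parts of region i present
(PE = 0 when m = 0, i.e. the region is out of frame). The cumulative
score of the image is the severity-weighted contraction over all cells:

    C = sum_i sum_j (w_a PE_(ij)a + w_b PE_(ij)b + w_c PE_(ij)c)

with default weights w_a=0.2, w_b=0.5, w_c=1.0 down-weighting mild
errors. C lies in [0, 25 w_c]. Each image then receives an overall
severity level (low / medium / high) by comparing its score with the 0.5
and 0.75 quantiles of its *own annotator's* score distribution, which
absorbs between-annotator differences in strictness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ERROR_TYPES,
    REGIONS,
    SEVERITIES,
    AnnotationSchemaError,
    AnnotationSet,
    BodyRegion,
    ErrorType,
    ImageAnnotation,
    Severity,
)

SEVERITY_LEVELS = ("low", "medium", "high")

Cell = tuple[BodyRegion, ErrorType, Severity]


@dataclass(frozen=True)
class WeightConfig:
    """Severity weights and overall-severity quantile thresholds."""

    w_a: float = 0.2
    w_b: float = 0.5
    w_c: float = 1.0
    q_low: float = 0.5
    q_high: float = 0.75

    def __post_init__(self) -> None:
        for name in ("w_a", "w_b", "w_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.q_low < self.q_high < 1):
            raise ValueError("quantiles must satisfy 0 < q_low < q_high < 1")
        if not (self.w_a <= self.w_b <= self.w_c):
            warnings.warn(
                "severity weights are not monotone (w_a <= w_b <= w_c); "
                "severe errors will not dominate the cumulative score",
                stacklevel=2,
            )

    @property
    def weights(self) -> dict[Severity, float]:
        return {Severity.A: self.w_a, Severity.B: self.w_b, Severity.C: self.w_c}


@dataclass
class ScoreResult:
    """Cumulative score of one annotation with its per-cell proportions."""

    image_id: str
    annotator: str
    model: str
    prompt: str
    cumulative: float
    per_cell: dict[Cell, float] = field(default_factory=dict)


def proportion_of_errors(
    annotation: ImageAnnotation,
    region: BodyRegion,
    error_type: ErrorType,
    severity: Severity,
) -> float:
    """Fraction of the region's parts showing this error at this severity.

    Returns 0 for a region with expected count 0 (region not visible);
    validation upstream guarantees the count is then also 0.
    """
    m = annotation.expected_count(region)
    if m == 0:
        return 0.0
    n = annotation.error_count(region, error_type, severity)
    if n > m:
        raise AnnotationSchemaError(
            f"image {annotation.image_id!r}: count {n} exceeds expected {m} for "
            f"({region.value}, {error_type.value}, {severity.value}); "
            "validate the set before scoring"
        )
    return n / m


def cumulative_score(
    annotation: ImageAnnotation, weights: WeightConfig | None = None
) -> ScoreResult:
    """Severity-weighted sum of error proportions over all 25 cells."""
    weights = weights or WeightConfig()
    w = weights.weights
    per_cell: dict[Cell, float] = {}
    total = 0.0
    for region in REGIONS:
        m = annotation.expected_count(region)
        for etype in ERROR_TYPES:
            cell_total = 0
            for sev in SEVERITIES:
                n = annotation.error_count(region, etype, sev)
                cell_total += n
                pe = 0.0 if m == 0 else n / m
                per_cell[(region, etype, sev)] = pe
                total += w[sev] * pe
            if cell_total > m:
                raise AnnotationSchemaError(
                    f"image {annotation.image_id!r}: total count {cell_total} exceeds "
                    f"expected {m} for ({region.value}, {etype.value}); "
                    "validate the set before scoring"
                )
    return ScoreResult(
        image_id=annotation.image_id,
        annotator=annotation.annotator,
        model=annotation.model,
        prompt=annotation.prompt,
        cumulative=total,
        per_cell=per_cell,
    )


def score_set(
    annotation_set: AnnotationSet, weights: WeightConfig | None = None
) -> list[ScoreResult]:
    """Score every annotation in a set."""
    weights = weights or WeightConfig()
    return [cumulative_score(a, weights) for a in annotation_set]


def overall_severity(
    scores: list[ScoreResult], weights: WeightConfig | None = None
) -> dict[tuple[str, str], str]:
    """Categorize each scored image as low / medium / high severity.

    Thresholds are per annotator: the q_low (default 0.5) and q_high
    (default 0.75) quantiles of that annotator's own cumulative-score
    distribution (linear interpolation between order statistics). A score
    at or below the low quantile is ``low``, at or below the high quantile
    ``medium``, above it ``high``; each annotator's thresholds never touch
    another annotator's images.
    """
    weights = weights or WeightConfig()
    by_annotator: dict[str, list[ScoreResult]] = {}
    for s in scores:
        by_annotator.setdefault(s.annotator, []).append(s)

    out: dict[tuple[str, str], str] = {}
    for annotator, group in by_annotator.items():
        if len(group) < 2:
            raise ValueError(
                f"annotator {annotator!r} has {len(group)} scored image(s); "
                "at least 2 are required to form quantile thresholds"
            )
        values = np.array([s.cumulative for s in group])
        q_lo, q_hi = np.quantile(values, [weights.q_low, weights.q_high])
        for s in group:
            if s.cumulative <= q_lo:
                level = "low"
            elif s.cumulative <= q_hi:
                level = "medium"
            else:
                level = "high"
            out[(s.image_id, s.annotator)] = level
    return out


def scores_frame(
    scores: list[ScoreResult], weights: WeightConfig | None = None
) -> pd.DataFrame:
    """Tabulate scores (and severity levels) as a tidy DataFrame."""
    levels = overall_severity(scores, weights)
    return pd.DataFrame(
        {
            "image_id": [s.image_id for s in scores],
            "model": [s.model for s in scores],
            "prompt": [s.prompt for s in scores],
            "annotator": [s.annotator for s in scores],
            "cumulative": [s.cumulative for s in scores],
            "severity_level": [levels[(s.image_id, s.annotator)] for s in scores],
        }
    ).sort_values(["image_id", "annotator"], ignore_index=True)
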