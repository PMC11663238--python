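"""Inter-rater reliability via Krippendorff's alpha.

alpha = 1 - D_o / D_e, where D_o is the disagreement observed between
raters within units and D_e the disagreement expected if values were
assigned to units at random. Both are computed from the coincidence
matrix: every ordered pair of values assigned to the same unit by two
different raters contributes 1/(m_u - 1) (m_u = number of values in the
unit), so units with more raters are not overweighted and missing values
are handled naturally. Units observed by fewer than two raters carry no
pairable information and are dropped.

Three difference functions are provided, one per measurement level:
nominal (0/1 mismatch), ordinal (squared cumulative rank-frequency
distance), interval (squared numeric difference). Alpha is 1 for perfect
agreement, 0 for chance-level agreement and can go negative for
systematic disagreement.

Agreement on an annotation set is assessed pairwise per annotator pair,
on the three study variants of the data: the cumulative score per image
(interval), the overall severity level per image (ordinal), and a binary
error indicator per (image, region x error-type cell) (nominal).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Literal

import numpy as np

from .scoring import SEVERITY_LEVELS, ScoreResult, WeightConfig, overall_severity
from .types import ERROR_TYPES, REGIONS, SEVERITIES, AnnotationSet

Level = Literal["nominal", "ordinal", "interval"]
Variant = Literal["cumulative_score", "overall_severity", "binary_category"]

VARIANTS: tuple[Variant, ...] = ("cumulative_score", "overall_severity", "binary_category")


class UndefinedAlphaError(ValueError):
    """Alpha is undefined: no pairable units, or no value diversity (D_e = 0)."""


@dataclass
class ReliabilityMatrix:
    """Units-by-raters value table with missing entries allowed."""

    units: list[Hashable]
    raters: list[str]
    values: dict[tuple[Hashable, str], float | int | str]
    level: Level
    #: for ordinal data: category order, low to high; inferred if omitted
    ordinal_order: tuple | None = None

    def unit_values(self, unit: Hashable) -> list:
        return [
            self.values[(unit, r)] for r in self.raters if (unit, r) in self.values
        ]

    def restrict(self, raters: list[str]) -> "ReliabilityMatrix":
        """Sub-matrix containing only the given raters' values."""
        keep = set(raters)
        values = {(u, r): v for (u, r), v in self.values.items() if r in keep}
        units = [u for u in self.units if any((u, r) in values for r in raters)]
        return ReliabilityMatrix(
            units=units,
            raters=list(raters),
            values=values,
            level=self.level,
            ordinal_order=self.ordinal_order,
        )


@dataclass
class AgreementResult:
    """Pairwise alphas for one data variant, with their average."""

    variant: Variant
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    n_units: dict[tuple[str, str], int] = field(default_factory=dict)
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def average(self) -> float:
        if not self.pairwise:
            return float("nan")
        return float(np.mean(list(self.pairwise.values())))


def _category_index(matrix: ReliabilityMatrix, observed: list) -> dict:
    """Map observed values to integer category codes in analysis order."""
    distinct = set(observed)
    if matrix.level == "ordinal":
        if matrix.ordinal_order is not None:
            order = [v for v in matrix.ordinal_order if v in distinct]
            leftover = distinct - set(order)
            if leftover:
                raise ValueError(f"ordinal_order does not cover values {sorted(leftover)!r}")
        else:
            order = sorted(distinct)
        return {v: i for i, v in enumerate(order)}
    if matrix.level == "interval":
        return {v: i for i, v in enumerate(sorted(distinct))}
    return {v: i for i, v in enumerate(sorted(distinct, key=repr))}


def _distance_matrix(matrix: ReliabilityMatrix, categories: list, n_c: np.ndarray) -> np.ndarray:
    """Squared difference delta^2(c, k) between category codes c, k."""
    k = len(categories)
    if matrix.level == "nominal":
        return 1.0 - np.eye(k)
    if matrix.level == "interval":
        vals = np.asarray(categories, dtype=float)
        return (vals[:, None] - vals[None, :]) ** 2
    # ordinal: squared difference of mean cumulative coincidence frequencies;
    # delta(c,k) = (sum_{g=c..k} n_g - (n_c + n_k)/2)^2 with n from the
    # coincidence-matrix marginals
    cum = np.concatenate([[0.0], np.cumsum(n_c)])
    out = np.zeros((k, k))
    for c in range(k):
        for d in range(c + 1, k):
            between = cum[d + 1] - cum[c]  # sum of n_g for g in [c, d]
            out[c, d] = out[d, c] = (between - (n_c[c] + n_c[d]) / 2.0) ** 2
    return out


def coincidence_matrix(matrix: ReliabilityMatrix) -> tuple[np.ndarray, list]:
    """Coincidence counts o_ck over pairable values, plus category order."""
    pairable = [
        vs for u in matrix.units if len(vs := matrix.unit_values(u)) >= 2
    ]
    if not pairable:
        raise UndefinedAlphaError("no unit has two or more observed values")
    index = _category_index(matrix, [v for vs in pairable for v in vs])
    k = len(index)
    o = np.zeros((k, k))
    for vs in pairable:
        m_u = len(vs)
        w = 1.0 / (m_u - 1)
        for a, b in itertools.permutations(range(m_u), 2):
            o[index[vs[a]], index[vs[b]]] += w
    categories = [None] * k
    for v, i in index.items():
        categories[i] = v
    return o, categories


def krippendorff_alpha(matrix: ReliabilityMatrix) -> float:
    """Krippendorff's alpha for the matrix at its measurement level.

    Raises :class:`UndefinedAlphaError` when no unit is pairable or all
    pairable values are identical (expected disagreement zero).
    """
    o, categories = coincidence_matrix(matrix)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    if len(categories) < 2:
        raise UndefinedAlphaError(
            "all pairable values are identical; expected disagreement is zero"
        )
    delta = _distance_matrix(matrix, categories, n_c)
    d_o = float((o * delta).sum()) / n
    d_e = float((np.outer(n_c, n_c) * delta).sum()) / (n * (n - 1))
    if d_e == 0:
        raise UndefinedAlphaError("expected disagreement is zero; alpha undefined")
    return 1.0 - d_o / d_e


# ---------------------------------------------------------------------------
# Study variants


def build_variant_matrix(
    annotation_set: AnnotationSet,
    scores: list[ScoreResult],
    variant: Variant,
    weights: WeightConfig | None = None,
    doubled_only: bool = True,
) -> ReliabilityMatrix:
    """Reliability data for one of the three agreement variants.

    cumulative_score: one interval-level unit per image, value = cumulative
    score. overall_severity: one ordinal-level unit per image, value in
    low < medium < high (thresholds from each annotator's full score
    distribution). binary_category: one nominal-level unit per
    (image, region, error type) cell, value 1 if the cell has any error of
    any severity, else 0. Only multiply-annotated images carry pairable
    information; single-annotated images are excluded by default.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    doubled = set(annotation_set.doubled_image_ids())
    if not doubled:
        raise UndefinedAlphaError("annotation set contains no double-annotated images")
    raters = annotation_set.annotators

    if variant == "cumulative_score":
        values = {
            (s.image_id, s.annotator): s.cumulative
            for s in scores
            if not doubled_only or s.image_id in doubled
        }
        units = sorted({u for (u, _) in values})
        return ReliabilityMatrix(units=units, raters=raters, values=values, level="interval")

    if variant == "overall_severity":
        levels = overall_severity(scores, weights)  # thresholds use all images
        values = {
            (image_id, annotator): level
            for (image_id, annotator), level in levels.items()
            if not doubled_only or image_id in doubled
        }
        units = sorted({u for (u, _) in values})
        return ReliabilityMatrix(
            units=units,
            raters=raters,
            values=values,
            level="ordinal",
            ordinal_order=SEVERITY_LEVELS,
        )

    # binary_category: severity-blind error indicator per cell
    values = {}
    for a in annotation_set:
        if doubled_only and a.image_id not in doubled:
            continue
        for region in REGIONS:
            for etype in ERROR_TYPES:
                present = any(
                    a.error_count(region, etype, sev) > 0 for sev in SEVERITIES
                )
                unit = (a.image_id, region.value, etype.value)
                values[(unit, a.annotator)] = int(present)
    units = sorted({u for (u, _) in values})
    return ReliabilityMatrix(units=units, raters=raters, values=values, level="nominal")


def pairwise_agreement(
    annotation_set: AnnotationSet,
    scores: list[ScoreResult],
    variant: Variant,
    weights: WeightConfig | None = None,
) -> AgreementResult:
    """Alpha per annotator pair, on the units both members annotated.

    Pairs sharing no units are omitted; pairs whose alpha is undefined
    (e.g. both raters agree on a single constant value) are flagged in
    ``undefined_pairs`` rather than raising. The average is the arithmetic
    mean over the defined pairwise alphas.
    """
    matrix = build_variant_matrix(annotation_set, scores, variant, weights)
    result = AgreementResult(variant=variant)
    for r1, r2 in itertools.combinations(matrix.raters, 2):
        sub = matrix.restrict([r1, r2])
        shared = [u for u in sub.units if len(sub.unit_values(u)) == 2]
        if not shared:
            continue
        result.n_units[(r1, r2)] = len(shared)
        try:
            result.pairwise[(r1, r2)] = krippendorff_alpha(sub)
        except UndefinedAlphaError:
            result.undefined_pairs.append((r1, r2))
    if not result.pairwise and not result.undefined_pairs:
        raise UndefinedAlphaError("no annotator pair shares any double-annotated unit")
    return result
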