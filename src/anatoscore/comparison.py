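"""Group aggregations and Welch two-sample comparisons of scored sets.

Groups are formed by model, prompt, error type or anatomical region.
Model/prompt groups partition whole annotations, so they carry a
cumulative-score mean and sample variance alongside unweighted
per-severity sums of error proportions; error-type/region groups slice
within annotations, so only the per-severity sums are meaningful there.
The unweighted severity aggregates A, B, C of a model group satisfy the
identity (w_a A + w_b B + w_c C) / n = mean cumulative score, which ties
the per-severity view back to the per-image view.

Location differences between groups use Welch's unequal-variance t-test
with Welch-Satterthwaite degrees of freedom. Every annotation — including
both copies of a double-annotated image — enters as one observation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoreResult, WeightConfig
from .types import Severity

Dimension = str  # {"model", "prompt", "error_type", "region"}

DIMENSIONS = ("model", "prompt", "error_type", "region")


@dataclass
class GroupSummary:
    dimension: Dimension
    label: str
    n: int
    mean: float  # NaN for error_type/region groups (score is per image)
    variance: float  # sample variance (n-1); NaN likewise
    severity_aggregates: dict[Severity, float]


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def mean_from_severity_aggregates(
    aggregates: dict[Severity, float], n: int, weights: WeightConfig | None = None
) -> float:
    """Mean cumulative score implied by unweighted severity aggregates.

    Contracts the per-severity sums of error proportions with the severity
    weights and divides by the number of annotations.
    """
    weights = weights or WeightConfig()
    w = weights.weights
    return sum(w[s] * aggregates.get(s, 0.0) for s in Severity) / n


def summarize(scores: list[ScoreResult], dimension: Dimension) -> list[GroupSummary]:
    """Per-group annotation counts, score moments and severity aggregates."""
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    if not scores:
        return []

    if dimension in ("model", "prompt"):
        groups: dict[str, list[ScoreResult]] = {}
        for s in scores:
            label = s.model if dimension == "model" else s.prompt
            groups.setdefault(label, []).append(s)
        out = []
        for label in sorted(groups):
            members = groups[label]
            values = np.array([s.cumulative for s in members])
            agg = {sev: 0.0 for sev in Severity}
            for s in members:
                for (_, _, sev), pe in s.per_cell.items():
                    agg[sev] += pe
            out.append(
                GroupSummary(
                    dimension=dimension,
                    label=label,
                    n=len(members),
                    mean=float(values.mean()),
                    variance=float(values.var(ddof=1)) if len(members) > 1 else float("nan"),
                    severity_aggregates=agg,
                )
            )
        return out

    # error_type / region: sum PE over the complementary cell index
    agg_by_label: dict[str, dict[Severity, float]] = {}
    for s in scores:
        for (region, etype, sev), pe in s.per_cell.items():
            label = etype.value if dimension == "error_type" else region.value
            agg_by_label.setdefault(label, {sv: 0.0 for sv in Severity})[sev] += pe
    return [
        GroupSummary(
            dimension=dimension,
            label=label,
            n=len(scores),
            mean=float("nan"),
            variance=float("nan"),
            severity_aggregates=agg_by_label[label],
        )
        for label in sorted(agg_by_label)
    ]


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dimension": [s.dimension for s in summaries],
            "label": [s.label for s in summaries],
            "n": [s.n for s in summaries],
            "mean": [s.mean for s in summaries],
            "variance": [s.variance for s in summaries],
            "agg_a": [s.severity_aggregates[Severity.A] for s in summaries],
            "agg_b": [s.severity_aggregates[Severity.B] for s in summaries],
            "agg_c": [s.severity_aggregates[Severity.C] for s in summaries],
        }
    )


def welch_t(
    mean1: float, var1: float, n1: int, mean2: float, var2: float, n2: int
) -> WelchResult:
    """Welch's t from summary statistics (sample variances, n-1 denominator)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if var1 < 0 or var2 < 0:
        raise ValueError("variances must be non-negative")
    if var1 == 0 and var2 == 0:
        raise ValueError("both variances are zero; t is undefined")
    se1, se2 = var1 / n1, var2 / n2
    se = math.sqrt(se1 + se2)
    t = (mean1 - mean2) / se
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=t, df=df, p=min(p, 1.0))


_comparisons_run = 0


def compare_groups(
    scores: list[ScoreResult], dimension: Dimension, label1: str, label2: str
) -> WelchResult:
    """Welch test on the cumulative scores of two model or prompt groups.

    Raw (uncorrected) p-values are reported; a warning is emitted once
    more than three comparisons have been run in a session, as a reminder
    that many uncorrected tests inflate false positives.
    """
    if dimension not in ("model", "prompt"):
        raise ValueError("group comparisons are defined for dimension 'model' or 'prompt'")
    summaries = {s.label: s for s in summarize(scores, dimension)}
    for label in (label1, label2):
        if label not in summaries:
            raise ValueError(f"no {dimension} group labelled {label!r}")
    g1, g2 = summaries[label1], summaries[label2]
    global _comparisons_run
    _comparisons_run += 1
    if _comparisons_run == 4:
        warnings.warn(
            "more than 3 uncorrected comparisons run; p-values are raw and "
            "not adjusted for multiple testing",
            stacklevel=2,
        )
    return welch_t(g1.mean, g1.variance, g1.n, g2.mean, g2.variance, g2.n)


def reproduce_reference_statistics(
    scores: list[ScoreResult],
    annotation_set,
    weights: WeightConfig | None = None,
) -> dict[str, float]:
    """Headline statistics of a fully annotated study-style dataset.

    Returns the mean cumulative score of the hardest prompt group
    ("five people sunbathing on a beach" in the study design), the
    severity-c aggregate of the best model group, and the average
    binary-category pairwise alpha — the three quantities a re-analysis of
    the deposited study annotations is expected to reproduce.
    """
    from .agreement import pairwise_agreement

    weights = weights or WeightConfig()
    by_prompt = {s.label: s for s in summarize(scores, "prompt")}
    by_model = {s.label: s for s in summarize(scores, "model")}
    out: dict[str, float] = {}
    for label, s in by_prompt.items():
        out[f"prompt_mean[{label}]"] = s.mean
    for label, s in by_model.items():
        out[f"model_mean[{label}]"] = s.mean
        out[f"model_agg_c[{label}]"] = s.severity_aggregates[Severity.C]
    out["binary_category_average_alpha"] = pairwise_agreement(
        annotation_set, scores, "binary_category", weights
    ).average
    return out
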