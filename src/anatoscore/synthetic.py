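"""Synthetic annotation sets with the statistical structure of the study.

The generator emulates an annotation campaign over images produced by
several text-to-image models from a panel of prompts: per (region, error
type) cell, the number of erroneous parts is Binomial(m, rate x prompt
difficulty) where m is the number of parts of the region visible in the
image, and the drawn errors are split across severities a/b/c by the
model's severity mix. Splitting a single binomial draw multinomially
keeps the per-cell error total at or below m by construction, so every
generated set validates cleanly.

Images are dealt to annotators with the allocation module; a doubled
image's second annotation is the first one re-read with per-cell presence
flip noise epsilon, which spans inter-rater agreement from alpha = 1
(epsilon = 0) down to chance level (epsilon = 0.5 on symmetric cells).

``study_design_config`` mirrors the study's campaign shape — 3 models x
10 prompts x 8 images, 4 annotators, 25% double annotation — with
per-model rates and severity mixes and per-prompt difficulties chosen to
resemble the published campaign (a clearly stronger commercial model,
group scenes several times harder than a parent-and-child portrait).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allocation import AllocationPlan, allocate
from .scoring import WeightConfig, cumulative_score, score_set
from .types import (
    ERROR_TYPES,
    PARTS_PER_PERSON,
    REGIONS,
    SEVERITIES,
    AnnotationSet,
    BodyRegion,
    ErrorRecord,
    ErrorType,
    ImageAnnotation,
    RegionExpectation,
    Severity,
)

Cell = tuple[BodyRegion, ErrorType]


@dataclass(frozen=True)
class ModelProfile:
    """Error behaviour of one generative model.

    ``rate`` is the per-cell probability that a visible part shows the
    error (uniform scalar, or a per-(region, error_type) mapping);
    ``severity_mix`` is the (a, b, c) split of drawn errors.
    """

    label: str
    rate: float | dict[Cell, float] = 0.08
    severity_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)

    def __post_init__(self) -> None:
        mix = np.asarray(self.severity_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ValueError("severity_mix must be three non-negative shares summing to 1")

    def cell_rate(self, region: BodyRegion, error_type: ErrorType) -> float:
        if isinstance(self.rate, dict):
            return float(self.rate.get((region, error_type), 0.0))
        return float(self.rate)


@dataclass(frozen=True)
class PromptProfile:
    """Scene described by one prompt: cast size, difficulty, framing."""

    label: str
    person_count: int = 1
    difficulty: float = 1.0
    #: per-region fraction of anatomically possible parts in frame
    visibility: dict[BodyRegion, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.person_count < 1:
            raise ValueError("person_count must be >= 1")
        if self.difficulty <= 0:
            raise ValueError("difficulty must be positive")
        for region, v in self.visibility.items():
            if not 0 <= v <= 1:
                raise ValueError(f"visibility for {region.value} must be in [0, 1]")

    def expected_parts(self, region: BodyRegion) -> int:
        vis = self.visibility.get(region, 1.0)
        return int(round(self.person_count * PARTS_PER_PERSON[region] * vis))


@dataclass(frozen=True)
class SyntheticConfig:
    models: tuple[ModelProfile, ...]
    prompts: tuple[PromptProfile, ...]
    n_images_per_model_prompt: int = 8
    annotators: tuple[str, ...] = ("ann1", "ann2", "ann3", "ann4")
    double_fraction: float = 0.25
    annotator_noise: float = 0.1  # per-cell presence flip probability epsilon
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models or not self.prompts:
            raise ValueError("at least one model and one prompt required")
        if not 0 <= self.annotator_noise <= 1:
            raise ValueError("annotator_noise must be in [0, 1]")
        if self.n_images_per_model_prompt < 1:
            raise ValueError("n_images_per_model_prompt must be >= 1")


@dataclass
class GenerationResult:
    annotation_set: AnnotationSet
    plan: AllocationPlan
    #: (image_id, annotator) keys of re-read (noise-perturbed) annotations
    redrawn: set[tuple[str, str]]


def study_design_config(seed: int = 0, annotator_noise: float = 0.1) -> SyntheticConfig:
    """Campaign configuration mirroring the study: 3 models x 10 prompts x 8
    images, 4 annotators, 25% double annotation.

    The commercial-model stand-in has a low error rate and a mild,
    a-dominated severity mix; the two open-model stand-ins err two to
    three times more often with severity mixes tilted toward severe
    errors. Group scenes (beach, volleyball) are the hardest prompts and
    a parent holding a baby the easiest; difficulties average 1 so model
    rates keep their meaning as campaign-wide per-part error rates.
    """
    models = (
        ModelProfile("dalle3", rate=0.076, severity_mix=(0.54, 0.27, 0.19)),
        ModelProfile("sdxl", rate=0.124, severity_mix=(0.34, 0.30, 0.36)),
        ModelProfile("cascade", rate=0.137, severity_mix=(0.30, 0.29, 0.41)),
    )
    raw = [
        ("athlete performing salto", 1, 1.20, {}),
        ("person jogging", 1, 0.70, {}),
        ("mother or father holding a baby", 2, 0.50, {BodyRegion.FEET: 0.5}),
        ("couple hugging", 2, 0.80, {}),
        ("two people wrestling in an arena", 2, 1.10, {}),
        ("old couple in a sauna", 2, 0.90, {BodyRegion.FEET: 0.5}),
        ("physician examining a patient", 2, 0.80, {}),
        ("people eating pizza", 4, 1.20, {BodyRegion.FEET: 0.25}),
        ("five people sunbathing on a beach", 5, 2.40, {}),
        ("five people playing volleyball", 5, 2.00, {}),
    ]
    mean_difficulty = sum(d for _, _, d, _ in raw) / len(raw)
    prompts = tuple(
        PromptProfile(label, persons, difficulty / mean_difficulty, visibility)
        for label, persons, difficulty, visibility in raw
    )
    return SyntheticConfig(
        models=models, prompts=prompts, seed=seed, annotator_noise=annotator_noise
    )


def _draw_annotation(
    image_id: str,
    model: ModelProfile,
    prompt: PromptProfile,
    annotator: str,
    rng: np.random.Generator,
) -> ImageAnnotation:
    errors: list[ErrorRecord] = []
    expectations = []
    for region in REGIONS:
        m = prompt.expected_parts(region)
        expectations.append(RegionExpectation(region=region, expected_count=m))
        if m == 0:
            continue
        for etype in ERROR_TYPES:
            p = min(model.cell_rate(region, etype) * prompt.difficulty, 1.0)
            n = int(rng.binomial(m, p))
            if n == 0:
                continue
            split = rng.multinomial(n, model.severity_mix)
            for sev, k in zip(SEVERITIES, split):
                if k > 0:
                    errors.append(
                        ErrorRecord(region=region, error_type=etype, severity=sev, count=int(k))
                    )
    return ImageAnnotation(
        image_id=image_id,
        model=model.label,
        prompt=prompt.label,
        annotator=annotator,
        person_count=prompt.person_count,
        expectations=expectations,
        errors=errors,
    )


def _reread_with_noise(
    original: ImageAnnotation,
    model: ModelProfile,
    annotator: str,
    epsilon: float,
    rng: np.random.Generator,
) -> ImageAnnotation:
    """Second annotator's reading: per-cell presence flipped with prob epsilon.

    A flipped occupied cell loses all its errors; a flipped empty cell
    gains a single error with severity drawn from the model's mix.
    """
    counts: dict[tuple[BodyRegion, ErrorType, Severity], int] = {}
    for rec in original.errors:
        counts[(rec.region, rec.error_type, rec.severity)] = rec.count
    new_errors: list[ErrorRecord] = []
    for region in REGIONS:
        m = original.expected_count(region)
        for etype in ERROR_TYPES:
            cell = [(sev, counts.get((region, etype, sev), 0)) for sev in SEVERITIES]
            present = any(c > 0 for _, c in cell)
            flip = rng.random() < epsilon
            if present and not flip:
                new_errors.extend(
                    ErrorRecord(region=region, error_type=etype, severity=sev, count=c)
                    for sev, c in cell
                    if c > 0
                )
            elif not present and flip and m >= 1:
                sev = SEVERITIES[int(rng.choice(3, p=model.severity_mix))]
                new_errors.append(
                    ErrorRecord(region=region, error_type=etype, severity=sev, count=1)
                )
            # present and flip -> cell cleared; absent and not flip -> stays empty
    return ImageAnnotation(
        image_id=original.image_id,
        model=original.model,
        prompt=original.prompt,
        annotator=annotator,
        person_count=original.person_count,
        expectations=list(original.expectations),
        errors=new_errors,
    )


def generate(config: SyntheticConfig, return_details: bool = False):
    """Draw a full annotation set; deterministic for a given config seed.

    With ``return_details=True`` a :class:`GenerationResult` is returned,
    exposing the allocation plan and which annotations are noisy re-reads.
    """
    rng = np.random.default_rng(config.seed)
    model_by_label = {m.label: m for m in config.models}
    prompt_by_label = {p.label: p for p in config.prompts}

    images = [
        (f"img-{mi:02d}-{pi:02d}-{k:02d}", m.label, p.label)
        for mi, m in enumerate(config.models)
        for pi, p in enumerate(config.prompts)
        for k in range(config.n_images_per_model_prompt)
    ]
    plan = allocate(
        images,
        config.annotators,
        double_fraction=config.double_fraction,
        seed=int(rng.integers(2**31)),
    )

    raters_of: dict[str, list[str]] = {}
    for image_id, annotator in plan.assignments:
        raters_of.setdefault(image_id, []).append(annotator)

    annotations: list[ImageAnnotation] = []
    redrawn: set[tuple[str, str]] = set()
    for image_id, model_label, prompt_label in images:
        model = model_by_label[model_label]
        prompt = prompt_by_label[prompt_label]
        raters = sorted(raters_of[image_id])
        first = _draw_annotation(image_id, model, prompt, raters[0], rng)
        annotations.append(first)
        for other in raters[1:]:
            second = _reread_with_noise(first, model, other, config.annotator_noise, rng)
            annotations.append(second)
            redrawn.add((image_id, other))

    annotation_set = AnnotationSet(annotations).sorted()
    if return_details:
        return GenerationResult(annotation_set=annotation_set, plan=plan, redrawn=redrawn)
    return annotation_set


def expected_cumulative_score(
    config: SyntheticConfig, model: ModelProfile, weights: WeightConfig | None = None
) -> float:
    """Closed-form E[C] for a fresh (non re-read) annotation of this model.

    E[PE] for a visible cell equals the cell's effective error rate, so
    E[C] = mean over prompts of sum over visible cells of
    min(rate x difficulty, 1) x (mix . weights). With a uniform rate r,
    full visibility, difficulty 1 and a pure severity-c mix this reduces
    to 25 r.
    """
    weights = weights or WeightConfig()
    w = np.array([weights.w_a, weights.w_b, weights.w_c])
    mix_weight = float(np.dot(model.severity_mix, w))
    total = 0.0
    for prompt in config.prompts:
        for region in REGIONS:
            if prompt.expected_parts(region) == 0:
                continue
            for etype in ERROR_TYPES:
                p = min(model.cell_rate(region, etype) * prompt.difficulty, 1.0)
                total += p * mix_weight
    return total / len(config.prompts)


def recover(
    config: SyntheticConfig,
    generated: AnnotationSet | GenerationResult,
    weights: WeightConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Compare a generated set against the generator's own parameters.

    Returns a ``models`` table (per-model empirical mean cumulative score
    of fresh annotations vs the closed-form expectation, with standard
    error and z) and an ``agreement`` table (pairwise binary-category
    alpha on the doubled subset next to the configured flip noise). Large
    |z| or alpha far from the noise-implied level flags a generator or
    scoring defect.
    """
    from .agreement import pairwise_agreement

    weights = weights or WeightConfig()
    if isinstance(generated, GenerationResult):
        aset, redrawn = generated.annotation_set, generated.redrawn
    else:
        aset, redrawn = generated, set()

    rows = []
    for model in config.models:
        fresh = [
            a for a in aset
            if a.model == model.label and (a.image_id, a.annotator) not in redrawn
        ]
        values = np.array([cumulative_score(a, weights).cumulative for a in fresh])
        expected = expected_cumulative_score(config, model, weights)
        se = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else np.nan
        rows.append(
            {
                "model": model.label,
                "n": len(values),
                "empirical_mean": values.mean(),
                "expected_mean": expected,
                "se": se,
                "z": (values.mean() - expected) / se if se and se > 0 else np.nan,
            }
        )
    models_df = pd.DataFrame(rows)

    scores = score_set(aset, weights)
    agreement_rows = []
    try:
        result = pairwise_agreement(aset, scores, "binary_category", weights)
        for (r1, r2), alpha in sorted(result.pairwise.items()):
            agreement_rows.append(
                {
                    "annotator_1": r1,
                    "annotator_2": r2,
                    "binary_alpha": alpha,
                    "n_units": result.n_units[(r1, r2)],
                    "configured_noise": config.annotator_noise,
                }
            )
    except Exception:  # no doubled images: agreement table left empty
        pass
    agreement_df = pd.DataFrame(
        agreement_rows,
        columns=["annotator_1", "annotator_2", "binary_alpha", "n_units", "configured_noise"],
    )
    return {"models": models_df, "agreement": agreement_df}
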