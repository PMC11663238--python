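"""Shared fixtures: small handmade annotations and a study-shaped synthetic set."""

import pytest

from anatoscore import (
    AnnotationSet,
    BodyRegion,
    ErrorType,
    Severity,
    annotations_from_counts,
    generate,
    score_set,
    study_design_config,
)

FULL_EXPECTED_1P = {
    BodyRegion.FACE: 1,
    BodyRegion.TORSO: 1,
    BodyRegion.HANDS: 2,
    BodyRegion.LIMBS: 4,
    BodyRegion.FEET: 2,
}


def make_annotation(image_id="img-1", annotator="ann1", model="dalle3",
                    prompt="person jogging", person_count=1,
                    expected=None, counts=None):
    return annotations_from_counts(
        image_id=image_id,
        model=model,
        prompt=prompt,
        annotator=annotator,
        person_count=person_count,
        expected=expected if expected is not None else dict(FULL_EXPECTED_1P),
        counts=counts or {},
    )


@pytest.fixture
def hand_config_annotation():
    """One person; one of two hands has a severe configuration error,
    the face has a mild proportion error."""
    return make_annotation(
        counts={
            (BodyRegion.HANDS, ErrorType.CONFIGURATION, Severity.C): 1,
            (BodyRegion.FACE, ErrorType.PROPORTION, Severity.A): 1,
        }
    )


@pytest.fixture(scope="session")
def study_config():
    return study_design_config(seed=20260928)


@pytest.fixture(scope="session")
def study_result(study_config):
    return generate(study_config, return_details=True)


@pytest.fixture(scope="session")
def study_set(study_result) -> AnnotationSet:
    return study_result.annotation_set


@pytest.fixture(scope="session")
def study_scores(study_set):
    return score_set(study_set)
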