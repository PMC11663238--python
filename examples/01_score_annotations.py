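"""Score a single annotated image.

Builds one annotation by hand — a single person whose face shows a mild
proportion error and one of whose two hands has a severe configuration
error — and prints the per-cell error proportions and the weighted
cumulative score.
"""

from anatoscore import (
    BodyRegion,
    ErrorType,
    Severity,
    annotations_from_counts,
    cumulative_score,
    proportion_of_errors,
)

annotation = annotations_from_counts(
    image_id="demo-001",
    model="dalle3",
    prompt="person jogging",
    annotator="reviewer-1",
    person_count=1,
    expected={
        BodyRegion.FACE: 1,
        BodyRegion.TORSO: 1,
        BodyRegion.HANDS: 2,
        BodyRegion.LIMBS: 4,
        BodyRegion.FEET: 2,
    },
    counts={
        (BodyRegion.FACE, ErrorType.PROPORTION, Severity.A): 1,
        (BodyRegion.HANDS, ErrorType.CONFIGURATION, Severity.C): 1,
    },
)

pe_face = proportion_of_errors(annotation, BodyRegion.FACE, ErrorType.PROPORTION, Severity.A)
pe_hand = proportion_of_errors(annotation, BodyRegion.HANDS, ErrorType.CONFIGURATION, Severity.C)
result = cumulative_score(annotation)

print(f"PE(face, proportion, a) = {pe_face}    # the 1 face present is affected")
print(f"PE(hands, configuration, c) = {pe_hand}  # 1 of 2 hands affected")
print(f"cumulative score C = {result.cumulative:.2f}")
print("= 0.2 * 1.0 (mild, down-weighted) + 1.0 * 0.5 (severe, full weight)")
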