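"""Randomized, constrained allocation of images to annotators.

Builds the study-sized manifest (3 models x 10 prompts x 8 images),
allocates it to four annotators with 25% double annotation, and audits
the balance guarantees.
"""

from collections import Counter

from anatoscore import allocate, check_plan

images = [
    (f"img-{m}-{p:02d}-{k}", f"model-{m}", f"prompt-{p:02d}")
    for m in range(3)
    for p in range(10)
    for k in range(8)
]
annotators = ["ann1", "ann2", "ann3", "ann4"]

plan = allocate(images, annotators, double_fraction=0.25, seed=2024)

loads = Counter(a for _, a in plan.assignments)
print(f"{len(images)} images -> {len(plan.assignments)} annotation slots")
print(f"doubled images: {len(plan.doubled)} (each with two distinct annotators)")
print(f"loads: {dict(sorted(loads.items()))}")

per_model = Counter((a, plan.images[i][0]) for i, a in plan.assignments)
print("per-annotator model shares (fair share 25 each):")
for ann in annotators:
    shares = {f"model-{m}": per_model[(ann, f"model-{m}")] for m in range(3)}
    print(f"  {ann}: {shares}")

problems = check_plan(plan, images, annotators, 0.25)
print(f"audit: {'all constraints satisfied' if not problems else problems}")
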