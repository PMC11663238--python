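"""Seeded, constrained randomization of images to annotators.

Every image is annotated once, except a configurable fraction that is
double-annotated by two distinct annotators for reliability assessment.
The plan balances total load across annotators to within one annotation
and stratifies over generator models and prompts, so no annotator's view
of a model or prompt is systematically enriched.

The algorithm deals annotation slots cyclically to a seeded random
rotation of the annotators, with slots sorted so each model forms a
contiguous block (which makes per-model shares and total loads exact to
within one by construction) and a doubled image's two slots are adjacent
(which makes its annotators distinct). Per-prompt shares are then
balanced by a seeded swap-based repair pass that exchanges same-model
slots between annotators, preserving all constraints already satisfied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class AllocationPlan:
    assignments: list[tuple[str, str]]  # (image_id, annotator)
    doubled: set[str]
    seed: int
    images: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (model, prompt)

    def load(self, annotator: str) -> int:
        return sum(1 for _, a in self.assignments if a == annotator)

    def annotators_of(self, image_id: str) -> set[str]:
        return {a for i, a in self.assignments if i == image_id}


def _round_half_even(x: float) -> int:
    return int(round(x))


def _stratified_doubled(
    images: list[tuple[str, str, str]], n_doubled: int, rng: np.random.Generator
) -> set[str]:
    """Pick doubled images spread over (model, prompt) cells by proportion."""
    cells: dict[tuple[str, str], list[str]] = {}
    for image_id, model, prompt in images:
        cells.setdefault((model, prompt), []).append(image_id)
    n_images = len(images)
    keys = sorted(cells)
    quotas = {k: n_doubled * len(cells[k]) / n_images for k in keys}
    counts = {k: math.floor(quotas[k]) for k in keys}
    remaining = n_doubled - sum(counts.values())
    # largest remainder, random tie-break
    order = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), rng.random()))
    for k in order:
        if remaining <= 0:
            break
        if counts[k] < len(cells[k]):
            counts[k] += 1
            remaining -= 1
    # spill-over if some cells were saturated
    while remaining > 0:
        spill = [k for k in keys if counts[k] < len(cells[k])]
        if not spill:
            raise ValueError("cannot double more images than exist")
        k = spill[int(rng.integers(len(spill)))]
        counts[k] += 1
        remaining -= 1
    doubled: set[str] = set()
    for k in keys:
        members = sorted(cells[k])
        picked = rng.choice(len(members), size=counts[k], replace=False)
        doubled.update(members[i] for i in picked)
    return doubled


def allocate(
    images: Iterable[tuple[str, str, str]],
    annotators: Sequence[str],
    double_fraction: float = 0.25,
    seed: int = 0,
) -> AllocationPlan:
    """Assign images (tuples ``(image_id, model, prompt)``) to annotators.

    Guarantees, for any input: per-annotator total loads within +/-1 of
    each other; per-annotator share of every model and every prompt within
    +/-1 of the proportional share; exactly ``round(double_fraction *
    n_images)`` images assigned to two distinct annotators, chosen by
    stratified sampling over (model, prompt) cells; identical output for
    identical ``seed``.
    """
    images = list(images)
    annotators = list(annotators)
    if not images:
        raise ValueError("no images to allocate")
    if len(set(i for i, _, _ in images)) != len(images):
        raise ValueError("duplicate image_id in manifest")
    if not (0 <= double_fraction < 1):
        raise ValueError("double_fraction must be in [0, 1)")
    if len(annotators) != len(set(annotators)):
        raise ValueError("duplicate annotator labels")
    n_doubled = _round_half_even(double_fraction * len(images))
    if len(annotators) < 2 and n_doubled > 0:
        raise ValueError("double annotation requires at least 2 annotators")
    if not annotators:
        raise ValueError("at least one annotator required")

    rng = np.random.default_rng(seed)
    doubled = _stratified_doubled(images, n_doubled, rng)

    # slot order: models contiguous, prompts contiguous within models,
    # image order shuffled within cells; a doubled image's slots adjacent
    by_cell: dict[tuple[str, str], list[str]] = {}
    for image_id, model, prompt in images:
        by_cell.setdefault((model, prompt), []).append(image_id)
    slots: list[str] = []
    for key in sorted(by_cell):
        members = sorted(by_cell[key])
        rng.shuffle(members)
        for image_id in members:
            slots.append(image_id)
            if image_id in doubled:
                slots.append(image_id)

    perm = list(annotators)
    rng.shuffle(perm)
    offset = int(rng.integers(len(annotators)))
    assigned = [perm[(t + offset) % len(annotators)] for t in range(len(slots))]

    meta = {image_id: (model, prompt) for image_id, model, prompt in images}
    _repair_prompt_balance(slots, assigned, meta, doubled, rng, annotators)

    plan = AllocationPlan(
        assignments=sorted(zip(slots, assigned)),
        doubled=doubled,
        seed=seed,
        images=meta,
    )
    return plan


def _repair_prompt_balance(
    slots: list[str],
    assigned: list[str],
    meta: dict[str, tuple[str, str]],
    doubled: set[str],
    rng: np.random.Generator,
    annotators: Sequence[str],
    max_rounds: int = 10_000,
) -> None:
    """Swap same-model slots between annotators until per-prompt shares fit.

    A swap exchanges the annotators of two slots from the same model but
    different prompts, leaving loads and model shares untouched; swaps
    that would give a doubled image twice the same annotator are rejected.
    Mutates ``assigned`` in place.
    """
    annotators = list(annotators)
    n_a = len(annotators)
    prompt_total: dict[str, int] = {}
    for image_id in slots:
        prompt_total[meta[image_id][1]] = prompt_total.get(meta[image_id][1], 0) + 1
    count: dict[tuple[str, str], int] = {}
    for image_id, a in zip(slots, assigned):
        p = meta[image_id][1]
        count[(a, p)] = count.get((a, p), 0) + 1

    def dev(a: str, p: str) -> float:
        return abs(count.get((a, p), 0) - prompt_total[p] / n_a)

    def objective() -> float:
        return sum(
            max(0.0, dev(a, p) - 1.0) for a in annotators for p in prompt_total
        )

    # partner slot index of each doubled slot, to keep annotators distinct
    positions: dict[str, list[int]] = {}
    for idx, image_id in enumerate(slots):
        positions.setdefault(image_id, []).append(idx)

    def distinct_ok(idx: int, new_annotator: str) -> bool:
        image_id = slots[idx]
        if image_id not in doubled:
            return True
        return all(
            assigned[other] != new_annotator
            for other in positions[image_id]
            if other != idx
        )

    def swap_delta(i: int, j: int) -> float:
        """Objective change if slots i and j exchanged their annotators."""
        a_i, a_j = assigned[i], assigned[j]
        p_i, p_j = meta[slots[i]][1], meta[slots[j]][1]
        after = (
            max(0.0, abs(count.get((a_i, p_i), 0) - 1 - prompt_total[p_i] / n_a) - 1)
            + max(0.0, abs(count.get((a_i, p_j), 0) + 1 - prompt_total[p_j] / n_a) - 1)
            + max(0.0, abs(count.get((a_j, p_i), 0) + 1 - prompt_total[p_i] / n_a) - 1)
            + max(0.0, abs(count.get((a_j, p_j), 0) - 1 - prompt_total[p_j] / n_a) - 1)
        )
        before = (
            max(0.0, dev(a_i, p_i) - 1)
            + max(0.0, dev(a_i, p_j) - 1)
            + max(0.0, dev(a_j, p_i) - 1)
            + max(0.0, dev(a_j, p_j) - 1)
        )
        return after - before

    def apply_swap(i: int, j: int) -> None:
        a_i, a_j = assigned[i], assigned[j]
        p_i, p_j = meta[slots[i]][1], meta[slots[j]][1]
        assigned[i], assigned[j] = a_j, a_i
        count[(a_i, p_i)] = count.get((a_i, p_i), 0) - 1
        count[(a_i, p_j)] = count.get((a_i, p_j), 0) + 1
        count[(a_j, p_i)] = count.get((a_j, p_i), 0) + 1
        count[(a_j, p_j)] = count.get((a_j, p_j), 0) - 1

    rounds = 0
    while objective() > 1e-9 and rounds < max_rounds:
        rounds += 1
        violations = [
            (a, p)
            for a in annotators
            for p in prompt_total
            if dev(a, p) > 1.0 + 1e-9
        ]
        a_v, p_v = violations[int(rng.integers(len(violations)))]
        overfull = count.get((a_v, p_v), 0) > prompt_total[p_v] / n_a
        if overfull:
            # move one of a_v's p_v slots out, taking a different prompt back
            candidates = [
                i for i, (im, an) in enumerate(zip(slots, assigned))
                if an == a_v and meta[im][1] == p_v
            ]
        else:
            # pull a p_v slot from another annotator, giving one of ours back
            candidates = [
                i for i, (im, an) in enumerate(zip(slots, assigned))
                if an != a_v and meta[im][1] == p_v
            ]
        rng.shuffle(candidates)
        improved = False
        for i in candidates:
            model_i = meta[slots[i]][0]
            if overfull:
                partners = [
                    j for j, (im, an) in enumerate(zip(slots, assigned))
                    if an != a_v and meta[im][0] == model_i and meta[im][1] != p_v
                ]
            else:
                partners = [
                    j for j, (im, an) in enumerate(zip(slots, assigned))
                    if an == a_v and meta[im][0] == model_i and meta[im][1] != p_v
                ]
            rng.shuffle(partners)
            for j in partners:
                if not (distinct_ok(i, assigned[j]) and distinct_ok(j, assigned[i])):
                    continue
                if swap_delta(i, j) < -1e-9:
                    apply_swap(i, j)
                    improved = True
                    break
            if improved:
                break
        if not improved:
            # sideways kick on a violating slot to escape a plateau
            i = candidates[0] if candidates else int(rng.integers(len(slots)))
            model_i = meta[slots[i]][0]
            partners = [
                j for j, (im, an) in enumerate(zip(slots, assigned))
                if an != assigned[i]
                and meta[im][0] == model_i
                and meta[im][1] != meta[slots[i]][1]
            ]
            rng.shuffle(partners)
            for j in partners:
                if not (distinct_ok(i, assigned[j]) and distinct_ok(j, assigned[i])):
                    continue
                if swap_delta(i, j) <= 1e-9:  # non-worsening only
                    apply_swap(i, j)
                    break
    if objective() > 1e-9:
        raise RuntimeError(
            "allocation repair did not converge; per-prompt stratification "
            "within +/-1 could not be reached for this configuration"
        )


def check_plan(
    plan: AllocationPlan,
    images: Iterable[tuple[str, str, str]],
    annotators: Sequence[str],
    double_fraction: float,
) -> list[str]:
    """Audit a plan against the allocation guarantees; empty list if clean."""
    images = list(images)
    problems: list[str] = []
    n_doubled = _round_half_even(double_fraction * len(images))
    raters_of: dict[str, list[str]] = {}
    for image_id, annotator in plan.assignments:
        raters_of.setdefault(image_id, []).append(annotator)

    doubled_found = {i for i, r in raters_of.items() if len(r) == 2 and len(set(r)) == 2}
    for image_id, r in raters_of.items():
        if len(r) not in (1, 2):
            problems.append(f"image {image_id!r} has {len(r)} assignments")
        if len(r) == 2 and len(set(r)) != 2:
            problems.append(f"doubled image {image_id!r} assigned twice to {r[0]!r}")
    if len(doubled_found) != n_doubled or plan.doubled != doubled_found:
        problems.append(
            f"doubled set mismatch: expected {n_doubled}, found {len(doubled_found)}"
        )
    missing = {i for i, _, _ in images} - set(raters_of)
    if missing:
        problems.append(f"unassigned images: {sorted(missing)[:5]}")

    loads = [sum(1 for _, a in plan.assignments if a == ann) for ann in annotators]
    if loads and max(loads) - min(loads) > 1:
        problems.append(f"loads not balanced within 1: {dict(zip(annotators, loads))}")

    meta = {i: (m, p) for i, m, p in images}
    n_a = len(annotators)
    for dim in (0, 1):
        totals: dict[str, int] = {}
        per: dict[tuple[str, str], int] = {}
        for image_id, annotator in plan.assignments:
            label = meta[image_id][dim]
            totals[label] = totals.get(label, 0) + 1
            per[(annotator, label)] = per.get((annotator, label), 0) + 1
        for label, total in totals.items():
            for annotator in annotators:
                c = per.get((annotator, label), 0)
                if abs(c - total / n_a) > 1 + 1e-9:
                    what = "model" if dim == 0 else "prompt"
                    problems.append(
                        f"{what} {label!r}: annotator {annotator!r} holds {c} of "
                        f"{total} (fair share {total / n_a:.2f})"
                    )
    return problems
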