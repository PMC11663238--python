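"""Krippendorff's alpha against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from anatoscore import (
    ReliabilityMatrix,
    UndefinedAlphaError,
    build_variant_matrix,
    generate,
    krippendorff_alpha,
    pairwise_agreement,
    score_set,
    study_design_config,
)

from oracle import alpha_bruteforce


def matrix_from_units(units, level, raters=("r1", "r2"), ordinal_order=None):
    values = {}
    for u, vs in enumerate(units):
        for r, v in zip(raters, vs):
            if v is not None:
                values[(u, r)] = v
    return ReliabilityMatrix(
        units=list(range(len(units))),
        raters=list(raters),
        values=values,
        level=level,
        ordinal_order=ordinal_order,
    )


class TestAlphaCore:
    def test_perfect_agreement_is_one(self):
        m = matrix_from_units([(0, 0), (1, 1), (0, 0), (1, 1)], "nominal")
        assert krippendorff_alpha(m) == pytest.approx(1.0)

    def test_matches_bruteforce_on_all_small_binary_matrices(self):
        """Exact equality with direct pair enumeration on every two-rater
        binary matrix of up to 4 units, missing entries included."""
        patterns = [
            (0, 0), (0, 1), (1, 0), (1, 1),
            (0, None), (1, None), (None, 0), (None, 1),
        ]
        checked = 0
        for n_units in range(1, 5):
            for combo in itertools.product(patterns, repeat=n_units):
                m = matrix_from_units(list(combo), "nominal")
                observed = [[v for v in vs if v is not None] for vs in combo]
                try:
                    expected = alpha_bruteforce(observed, "nominal")
                except (ValueError, ZeroDivisionError):
                    with pytest.raises(UndefinedAlphaError):
                        krippendorff_alpha(m)
                    continue
                assert krippendorff_alpha(m) == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked > 100

    @pytest.mark.parametrize("level", ["nominal", "ordinal", "interval"])
    def test_matches_bruteforce_on_random_multirater_matrices(self, level):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_units = int(rng.integers(2, 8))
            n_raters = int(rng.integers(2, 5))
            units = []
            for _ in range(n_units):
                vs = [
                    int(rng.integers(0, 4)) if rng.random() > 0.25 else None
                    for _ in range(n_raters)
                ]
                units.append(tuple(vs))
            raters = [f"r{i}" for i in range(n_raters)]
            m = matrix_from_units(units, level, raters=raters)
            clean = [[v for v in vs if v is not None] for vs in units]
            try:
                expected = alpha_bruteforce(clean, level)
            except (ValueError, ZeroDivisionError):
                with pytest.raises(UndefinedAlphaError):
                    krippendorff_alpha(m)
                continue
            assert krippendorff_alpha(m) == pytest.approx(expected, abs=1e-10)

    def test_interval_alpha_invariant_under_affine_transform(self):
        rng = np.random.default_rng(3)
        units = [(float(rng.normal()), float(rng.normal() * 0.3 + 1)) for _ in range(20)]
        base = krippendorff_alpha(matrix_from_units(units, "interval"))
        shifted = [(2.5 * x - 7, 2.5 * y - 7) for x, y in units]
        assert krippendorff_alpha(matrix_from_units(shifted, "interval")) == pytest.approx(base)

    def test_constant_values_undefined(self):
        with pytest.raises(UndefinedAlphaError):
            krippendorff_alpha(matrix_from_units([(1, 1), (1, 1)], "nominal"))

    def test_no_pairable_unit_is_error(self):
        with pytest.raises(UndefinedAlphaError):
            krippendorff_alpha(matrix_from_units([(0, None), (None, 1)], "nominal"))

    def test_nominal_two_rater_limit_is_2p_minus_1(self):
        """With uniform binary marginals and agreement probability p the
        two-rater nominal alpha converges to 2p - 1."""
        rng = np.random.default_rng(11)
        for p in (0.9, 0.6):
            first = rng.integers(0, 2, size=2000)
            agree = rng.random(2000) < p
            second = np.where(agree, first, 1 - first)
            m = matrix_from_units(list(zip(first.tolist(), second.tolist())), "nominal")
            assert krippendorff_alpha(m) == pytest.approx(2 * p - 1, abs=0.05)


class TestVariantMatrices:
    def test_unit_counts_for_study_design(self, study_set, study_scores):
        cumulative = build_variant_matrix(study_set, study_scores, "cumulative_score")
        assert len(cumulative.units) == 60
        assert cumulative.level == "interval"
        binary = build_variant_matrix(study_set, study_scores, "binary_category")
        assert len(binary.units) == 60 * 25
        assert binary.level == "nominal"
        severity = build_variant_matrix(study_set, study_scores, "overall_severity")
        assert severity.level == "ordinal"
        assert len(severity.units) == 60

    def test_single_annotated_images_excluded(self, study_set, study_scores):
        m = build_variant_matrix(study_set, study_scores, "cumulative_score")
        doubled = set(study_set.doubled_image_ids())
        assert set(m.units) == doubled

    def test_binary_variant_is_severity_blind(self, study_set, study_scores):
        m = build_variant_matrix(study_set, study_scores, "binary_category")
        doubled = set(study_set.doubled_image_ids())
        for a in study_set:
            if a.image_id not in doubled:
                continue
            for rec in a.errors[:3]:
                unit = (a.image_id, rec.region.value, rec.error_type.value)
                assert m.values[(unit, a.annotator)] == 1


class TestPairwiseAgreement:
    def test_duplicate_annotations_give_alpha_one(self):
        """Noise-free duplication makes value-based agreement exact. The
        overall-severity variant stays slightly below 1: labels come from
        each annotator's own quantile thresholds, so identical scores near
        a threshold can be labelled differently by the two annotators."""
        cfg = study_design_config(seed=5, annotator_noise=0.0)
        aset = generate(cfg)
        scores = score_set(aset)
        for variant in ("cumulative_score", "binary_category"):
            result = pairwise_agreement(aset, scores, variant)
            for alpha in result.pairwise.values():
                assert alpha == pytest.approx(1.0)
            assert result.average == pytest.approx(1.0)
        severity = pairwise_agreement(aset, scores, "overall_severity")
        assert severity.average > 0.8

    def test_independent_annotations_give_near_zero_alpha(self):
        """Monte-Carlo null: two raters flipping independent fair coins on
        500 shared units have chance-level agreement."""
        rng = np.random.default_rng(29)
        units = [
            (int(rng.integers(0, 2)), int(rng.integers(0, 2))) for _ in range(500)
        ]
        m = matrix_from_units(units, "nominal")
        assert abs(krippendorff_alpha(m)) < 0.1

    def test_study_design_yields_at_most_six_pairs(self, study_set, study_scores):
        result = pairwise_agreement(study_set, study_scores, "cumulative_score")
        assert len(result.pairwise) + len(result.undefined_pairs) <= 6
        for (r1, r2), alpha in result.pairwise.items():
            assert r1 < r2 and -1.0 <= alpha <= 1.0 + 1e-12

    def test_average_is_mean_of_pairwise(self, study_set, study_scores):
        result = pairwise_agreement(study_set, study_scores, "binary_category")
        assert result.average == pytest.approx(np.mean(list(result.pairwise.values())))
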