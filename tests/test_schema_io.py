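"""Schema validation and file round-trip behaviour."""

import csv

import pytest

from anatoscore import (
    AnnotationSchemaError,
    AnnotationSet,
    BodyRegion,
    ErrorRecord,
    ErrorType,
    Severity,
    read_annotations,
    validate,
    write_annotations,
)

from conftest import make_annotation


class TestDomainTypes:
    def test_taxonomy_sizes_and_order(self):
        assert [r.value for r in BodyRegion] == ["face", "torso", "hands", "limbs", "feet"]
        assert [t.value for t in ErrorType] == [
            "proportion", "extra", "orientation", "configuration", "missing",
        ]
        assert [s.value for s in Severity] == ["a", "b", "c"]
        assert Severity.A.rank < Severity.B.rank < Severity.C.rank

    def test_negative_counts_rejected(self):
        with pytest.raises(AnnotationSchemaError):
            ErrorRecord(BodyRegion.FACE, ErrorType.EXTRA, Severity.A, -1)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            Severity("d")
        with pytest.raises(ValueError):
            BodyRegion("tail")


class TestValidate:
    def test_consistent_set_is_clean(self, study_set):
        assert validate(study_set) == []

    def test_count_exceeding_denominator_flagged(self):
        ann = make_annotation(
            counts={(BodyRegion.HANDS, ErrorType.CONFIGURATION, Severity.C): 3}
        )
        problems = validate(AnnotationSet([ann]))
        assert len(problems) == 1
        assert "hands" in problems[0] and "configuration" in problems[0]

    def test_error_in_invisible_region_flagged(self):
        expected = {r: (0 if r is BodyRegion.FACE else 2) for r in BodyRegion}
        ann = make_annotation(
            expected=expected,
            counts={(BodyRegion.FACE, ErrorType.PROPORTION, Severity.A): 1},
        )
        problems = validate(AnnotationSet([ann]))
        assert any("face" in p for p in problems)

    def test_expectation_above_anatomical_maximum_flagged(self):
        ann = make_annotation(expected={**dict.fromkeys(BodyRegion, 1), BodyRegion.HANDS: 3})
        problems = validate(AnnotationSet([ann]))
        assert any("anatomical maximum" in p for p in problems)

    def test_duplicate_image_annotator_flagged(self):
        ann = make_annotation()
        problems = validate(AnnotationSet([ann, make_annotation()]))
        assert any("duplicate annotation" in p for p in problems)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_write_read_identity_on_study_set(self, study_set, tmp_path, fmt):
        path = tmp_path / f"set.{fmt}"
        write_annotations(study_set, path)
        assert read_annotations(path) == study_set.sorted()

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_two_writes_byte_identical(self, study_set, tmp_path, fmt):
        p1, p2 = tmp_path / f"a.{fmt}", tmp_path / f"b.{fmt}"
        write_annotations(study_set, p1)
        write_annotations(study_set, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_set_gives_header_only_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_annotations(AnnotationSet([]), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("image_id,")

    def test_zero_error_image_reads_back_with_all_zero_counts(self, tmp_path):
        path = tmp_path / "one.csv"
        write_annotations(AnnotationSet([make_annotation()]), path)
        aset = read_annotations(path)
        (ann,) = aset.annotations
        assert ann.errors == []
        assert all(
            ann.error_count(r, t, s) == 0
            for r in BodyRegion for t in ErrorType for s in Severity
        )


class TestReadErrors:
    def test_unknown_severity_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow("image_id model prompt annotator person_count region error_type severity count".split())
            w.writerow(["i1", "m", "p", "a1", 1, "hands", "extra", "d", 1])
        with pytest.raises(AnnotationSchemaError, match="severity"):
            read_annotations(path)

    def test_count_over_denominator_rejected_with_cell_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow("image_id model prompt annotator person_count region error_type severity count".split())
            w.writerow(["i1", "m", "p", "a1", 1, "hands", "_expected", "_", 2])
            w.writerow(["i1", "m", "p", "a1", 1, "hands", "configuration", "c", 3])
        with pytest.raises(AnnotationSchemaError, match="hands.*configuration"):
            read_annotations(path)

    def test_duplicate_error_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow("image_id model prompt annotator person_count region error_type severity count".split())
            w.writerow(["i1", "m", "p", "a1", 1, "hands", "extra", "a", 1])
            w.writerow(["i1", "m", "p", "a1", 1, "hands", "extra", "a", 1])
        with pytest.raises(AnnotationSchemaError, match="duplicate"):
            read_annotations(path)


class TestCorruptionFuzz:
    def test_single_field_corruption_never_crashes(self, tmp_path):
        """Any one-field mutation either still reads validly or raises the
        schema error — never an unhandled crash."""
        import random

        from anatoscore import generate
        from anatoscore.synthetic import ModelProfile, PromptProfile, SyntheticConfig

        cfg = SyntheticConfig(
            models=(ModelProfile("m", rate=0.2),),
            prompts=(PromptProfile("p", person_count=2),),
            n_images_per_model_prompt=4,
            annotators=("x", "y"),
            double_fraction=0.5,
            seed=11,
        )
        base = tmp_path / "base.csv"
        write_annotations(generate(cfg), base)
        rows = base.read_text().splitlines()
        rng = random.Random(0)
        corruptions = ["-1", "999", "d", "tail", "", "NaN", "_expected", "extra"]
        for trial in range(200):
            i = rng.randrange(1, len(rows))
            fields = rows[i].split(",")
            j = rng.randrange(len(fields))
            fields[j] = rng.choice(corruptions)
            mutated = rows[:i] + [",".join(fields)] + rows[i + 1:]
            victim = tmp_path / "fuzz.csv"
            victim.write_text("\n".join(mutated) + "\n")
            try:
                aset = read_annotations(victim)
                assert validate(aset) == []
            except AnnotationSchemaError:
                pass
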