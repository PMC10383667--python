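"""Data model, label encoding, splitting and TSV round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ibdsig import (
    CONTROL_VS_IBD,
    UC_VS_CD,
    ExpressionStudy,
    encode_labels,
    read_study,
    split_train_test,
    write_study,
)
from ibdsig.study import (
    REGIONS,
    DuplicateIdError,
    NonNumericValueError,
    RaggedRowError,
    SingleClassError,
    StudyError,
    UnknownRegionError,
    LabelScheme,
    read_split,
    write_split,
)


def _mini_study(labels=("UC", "control", "CD", "UC")):
    n = len(labels)
    return ExpressionStudy(
        gene_ids=["g1", "g2", "g3"],
        expression=np.arange(3 * n, dtype=float).reshape(3, n),
        labels=np.array(labels, dtype=object),
        age=np.array([40] * n),
        sex=np.array([0, 1] * (n // 2) + [0] * (n % 2)),
        region=np.array([REGIONS[i % 7] for i in range(n)], dtype=object),
        sample_ids=[f"s{i}" for i in range(n)],
    )


class TestEncodeLabels:
    def test_control_vs_ibd_mapping(self):
        study = _mini_study(("UC", "control", "CD"))
        y, kept = encode_labels(study, CONTROL_VS_IBD)
        assert y.tolist() == [1, 0, 1]
        assert kept.tolist() == [0, 1, 2]

    def test_uc_vs_cd_drops_controls(self):
        study = _mini_study(("UC", "control", "CD"))
        y, kept = encode_labels(study, UC_VS_CD)
        assert y.tolist() == [0, 1]
        assert kept.tolist() == [0, 2]

    def test_single_class_is_an_error(self):
        study = _mini_study(("control", "control", "control"))
        with pytest.raises(SingleClassError):
            encode_labels(study, CONTROL_VS_IBD)

    def test_reencoding_kept_subset_is_stable(self):
        study = _mini_study(("UC", "control", "CD", "UC"))
        y1, kept = encode_labels(study, CONTROL_VS_IBD)
        y2, kept2 = encode_labels(study, CONTROL_VS_IBD)
        assert np.array_equal(y1, y2) and np.array_equal(kept, kept2)

    def test_bad_scheme_rejected(self):
        with pytest.raises(StudyError):
            LabelScheme("broken", {"control": 0})


class TestSplit:
    def test_counts_and_partition(self):
        study = _mini_study(tuple(["UC", "control"] * 5))
        kept = np.arange(10)
        sp = split_train_test(study, kept, fraction=0.8, seed=3)
        assert len(sp.train) == 8 and len(sp.test) == 2
        assert set(sp.train) | set(sp.test) == set(kept)
        assert not set(sp.train) & set(sp.test)

    def test_deterministic(self):
        study = _mini_study(tuple(["UC", "control"] * 5))
        kept = np.arange(10)
        a = split_train_test(study, kept, seed=9)
        b = split_train_test(study, kept, seed=9)
        assert a.train.tolist() == b.train.tolist()
        assert a.test.tolist() == b.test.tolist()

    def test_cohort_scale_rounding(self):
        # round(0.8 * 2490) = 1992 train, 498 test
        labels = tuple(np.repeat(["control", "UC", "CD"], [461, 872, 1157]))
        study = _mini_study(labels)
        sp = split_train_test(study, np.arange(2490), fraction=0.8, seed=0)
        assert len(sp.train) == 1992 and len(sp.test) == 498

    def test_stratified_split_covers_all_classes(self):
        labels = tuple(["control"] * 4 + ["UC"] * 8 + ["CD"] * 8)
        study = _mini_study(labels)
        sp = split_train_test(study, np.arange(20), seed=2)
        for half in (sp.train, sp.test):
            assert set(study.labels[half]) == {"control", "UC", "CD"}

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_bad_fraction(self, fraction):
        study = _mini_study()
        with pytest.raises(StudyError):
            split_train_test(study, np.arange(4), fraction=fraction, seed=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, seed):
        study = _mini_study(tuple(["UC", "control", "CD"] * 4))
        kept = np.arange(12)
        sp = split_train_test(study, kept, seed=seed)
        assert sorted(sp.train.tolist() + sp.test.tolist()) == kept.tolist()

    def test_split_roundtrip(self, tmp_path):
        study = _mini_study(tuple(["UC", "control"] * 5))
        sp = split_train_test(study, np.arange(10), seed=1)
        write_split(sp, study.sample_ids, tmp_path / "split.csv")
        back = read_split(tmp_path / "split.csv", study.sample_ids)
        assert back.train.tolist() == sorted(sp.train.tolist())


label_st = st.sampled_from(["control", "UC", "CD"])


@st.composite
def studies(draw):
    m = draw(st.integers(1, 6))
    n = draw(st.integers(2, 8))
    labels = draw(st.lists(label_st, min_size=n, max_size=n))
    vals = draw(st.lists(
        st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False, width=64),
        min_size=m * n, max_size=m * n))
    ages = draw(st.lists(st.integers(19, 82), min_size=n, max_size=n))
    sexes = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    regions = draw(st.lists(st.sampled_from(REGIONS), min_size=n, max_size=n))
    return ExpressionStudy(
        gene_ids=[f"g{i}" for i in range(m)],
        expression=np.array(vals, dtype=float).reshape(m, n),
        labels=np.array(labels, dtype=object),
        age=np.array(ages),
        sex=np.array(sexes),
        region=np.array(regions, dtype=object),
        sample_ids=[f"s{j}" for j in range(n)],
    )


class TestTsvRoundTrip:
    @given(study=studies())
    @settings(max_examples=40, deadline=None)
    def test_roundtrip_identity(self, study, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "study.tsv"
        write_study(study, path)
        back = read_study(path)
        assert back.gene_ids == study.gene_ids
        assert back.sample_ids == study.sample_ids
        assert np.array_equal(back.expression, study.expression)
        assert back.labels.tolist() == study.labels.tolist()
        assert back.age.tolist() == study.age.tolist()
        assert back.sex.tolist() == study.sex.tolist()
        assert back.region.tolist() == study.region.tolist()

    def test_non_numeric_age_names_row_and_column(self, tmp_path):
        study = _mini_study()
        path = tmp_path / "s.tsv"
        write_study(study, path)
        text = path.read_text().replace("age\t40", "age\tabc", 1)
        path.write_text(text)
        with pytest.raises(NonNumericValueError, match="age.*s0"):
            read_study(path)

    def test_duplicate_gene_id(self, tmp_path):
        study = _mini_study()
        path = tmp_path / "s.tsv"
        write_study(study, path)
        path.write_text(path.read_text().replace("g2\t", "g1\t", 1))
        with pytest.raises(DuplicateIdError, match="g1"):
            read_study(path)

    def test_ragged_gene_row(self, tmp_path):
        study = _mini_study()
        path = tmp_path / "s.tsv"
        write_study(study, path)
        lines = path.read_text().splitlines()
        lines[-1] = "\t".join(lines[-1].split("\t")[:-1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(RaggedRowError, match="g3"):
            read_study(path)

    def test_unknown_region(self, tmp_path):
        study = _mini_study()
        path = tmp_path / "s.tsv"
        write_study(study, path)
        path.write_text(path.read_text().replace("Rectum", "Elbow", 1))
        with pytest.raises(UnknownRegionError, match="Elbow"):
            read_study(path)


class TestInvariants:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(DuplicateIdError):
            ExpressionStudy(
                gene_ids=["g1"],
                expression=np.zeros((1, 2)),
                labels=np.array(["UC", "CD"], dtype=object),
                age=np.array([30, 40]),
                sex=np.array([0, 1]),
                region=np.array(["Rectum", "Cecum"], dtype=object),
                sample_ids=["a", "a"],
            )

    def test_nonfinite_expression_rejected(self):
        with pytest.raises(StudyError):
            ExpressionStudy(
                gene_ids=["g1"],
                expression=np.array([[np.nan, 1.0]]),
                labels=np.array(["UC", "CD"], dtype=object),
                age=np.array([30, 40]),
                sex=np.array([0, 1]),
                region=np.array(["Rectum", "Cecum"], dtype=object),
                sample_ids=["a", "b"],
            )

    def test_region_codes_follow_fixed_order(self):
        study = _mini_study(("UC", "control", "CD", "UC"))
        codes = study.region_codes()
        assert codes.tolist() == [REGIONS.index(r) for r in study.region]
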