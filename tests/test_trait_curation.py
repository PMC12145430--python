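"""Curation: ambiguity removal, multi-state decomposition, gap binarization,
marker-conflict filtering, variance filtering, stratified splitting."""

import numpy as np
import pandas as pd
import pytest

from phenoforest.annotations_io import FeatureMatrix
from phenoforest.errors import ValidationError
from phenoforest.trait_curation import (
    AMBIGUOUS,
    IN_GAP,
    MARKER_CONFLICT,
    NO_SINGLE_VALUE,
    BinaryTraitDataset,
    GapBinarizerConfig,
    MarkerFilterConfig,
    TraitLabelRecord,
    binarize_with_gap,
    canonicalize_oxygen_state,
    decompose_multistate,
    filter_marker_conflicts,
    read_trait_table,
    remove_ambiguous,
    train_test_split,
    variance_filter,
)


def rec(strain, state=None, value=None, trait="t"):
    return TraitLabelRecord(strain, trait, state=state, value=value)


class TestOxygenVocabulary:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("obligate anaerobe", "anaerobe"),
            ("Obligate Aerobe", "aerobe"),
            ("microaerotolerant", "other"),
            ("aerotolerant", "other"),
            ("microaerophile", "other"),
            ("facultative anaerobe", "facultative"),
            ("facultative aerobe", "facultative"),
            ("aerobe", "aerobe"),
            ("  ANAEROBIC ", "anaerobe"),
        ],
    )
    def test_canonical_groups(self, raw, expected):
        assert canonicalize_oxygen_state(raw) == expected

    def test_unknown_term_lists_vocabulary(self):
        with pytest.raises(ValidationError, match="aerotolerant"):
            canonicalize_oxygen_state("oxygen-loving")


class TestRemoveAmbiguous:
    def test_contradictory_labels_excluded(self):
        ds = remove_ambiguous(
            [rec("A", "motile"), rec("A", "non-motile"), rec("B", "motile")],
            positive_states={"motile"},
        )
        assert ds.excluded == {"A": AMBIGUOUS}
        assert ds.positives == {"B"}

    def test_duplicates_collapse(self):
        ds = remove_ambiguous(
            [rec("A", "motile"), rec("A", "motile")], positive_states={"motile"}
        )
        assert ds.positives == {"A"} and not ds.excluded

    def test_no_strain_silently_dropped(self):
        records = [rec(s, st) for s, st in
                   [("A", "x"), ("A", "y"), ("B", "x"), ("C", "y"), ("C", "y")]]
        ds = remove_ambiguous(records, positive_states={"x"})
        assert ds.strains == {"A", "B", "C"}

    def test_empty_input_yields_empty_dataset(self):
        ds = remove_ambiguous([], positive_states={"x"})
        assert not ds.strains


class TestDecomposeMultistate:
    def test_intermediate_is_negative(self):
        ds = decompose_multistate([rec("F", "facultative anaerobe")], "aerobe")
        assert ds.negatives == {"F"}

    def test_target_group_positive(self):
        ds = decompose_multistate([rec("A", "anaerobe")], "anaerobe")
        assert ds.positives == {"A"}

    def test_dual_listed_strain_excluded(self):
        ds = decompose_multistate(
            [rec("X", "aerobe"), rec("X", "obligate anaerobe")], "aerobe"
        )
        assert ds.excluded == {"X": AMBIGUOUS}

    def test_synonyms_within_one_group_are_not_ambiguous(self):
        ds = decompose_multistate(
            [rec("X", "aerobe"), rec("X", "obligate aerobe")], "aerobe"
        )
        assert ds.positives == {"X"}

    def test_invalid_target(self):
        with pytest.raises(ValidationError):
            decompose_multistate([rec("A", "aerobe")], "facultative")


class TestGapBinarization:
    CFG = GapBinarizerConfig(40.0, 5.0)

    @pytest.mark.parametrize(
        "value,outcome",
        [(37.0, "neg"), (39.999, "neg"), (40.0, "gap"), (42.0, "gap"),
         (44.999, "gap"), (45.0, "pos"), (65.0, "pos")],
    )
    def test_half_open_gap_edges(self, value, outcome):
        ds = binarize_with_gap([rec("A", value=value)], self.CFG)
        if outcome == "pos":
            assert ds.positives == {"A"}
        elif outcome == "neg":
            assert ds.negatives == {"A"}
        else:
            assert ds.excluded == {"A": IN_GAP}

    def test_discordant_values_ambiguous(self):
        ds = binarize_with_gap([rec("A", value=37), rec("A", value=60)], self.CFG)
        assert ds.excluded == {"A": AMBIGUOUS}

    def test_concordant_values_keep_class(self):
        ds = binarize_with_gap([rec("A", value=50), rec("A", value=60)], self.CFG)
        assert ds.positives == {"A"}

    def test_range_reports_excluded_without_single_value(self):
        ds = binarize_with_gap([rec("A", state="4-65")], self.CFG)
        assert ds.excluded == {"A": NO_SINGLE_VALUE}

    def test_non_numeric_state_is_an_error(self):
        with pytest.raises(ValidationError):
            binarize_with_gap([rec("A", state="warm")], self.CFG)

    def test_gap_retains_no_strain_inside_band(self):
        rng = np.random.default_rng(3)
        records = [rec(f"S{i}", value=float(v))
                   for i, v in enumerate(rng.uniform(20, 70, 200))]
        ds = binarize_with_gap(records, self.CFG)
        for strain in ds.positives | ds.negatives:
            v = next(r.value for r in records if r.strain_id == strain)
            assert not (40 <= v < 45)
        assert ds.strains == {r.strain_id for r in records}

    def test_zero_gap_width_rejected(self):
        with pytest.raises(ValidationError):
            GapBinarizerConfig(40.0, 0.0)


class TestMarkerFilter:
    def _matrix(self, rows):
        markers = [f"PF{j:05d}" for j in range(1, 4)]
        return FeatureMatrix(
            pd.DataFrame(rows, index=list("ABCD"), columns=markers)
        ), frozenset(markers)

    def test_conflicting_negative_excluded_positives_kept(self):
        matrix, markers = self._matrix(
            [[1, 1, 1], [1, 1, 1], [1, 0, 0], [0, 0, 0]]
        )
        ds = BinaryTraitDataset("t", frozenset("A"), frozenset("BCD"))
        out = filter_marker_conflicts(ds, matrix, MarkerFilterConfig(markers, 3))
        assert out.excluded == {"B": MARKER_CONFLICT}
        assert out.positives == {"A"}
        assert out.negatives == {"C", "D"}

    def test_below_threshold_negative_retained(self):
        matrix, markers = self._matrix(
            [[1, 1, 1], [1, 1, 0], [0, 0, 0], [0, 0, 0]]
        )
        ds = BinaryTraitDataset("t", frozenset("A"), frozenset("BCD"))
        out = filter_marker_conflicts(ds, matrix, MarkerFilterConfig(markers, 3))
        assert not out.excluded

    def test_missing_marker_warns_not_errors(self, caplog):
        matrix, markers = self._matrix(
            [[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]]
        )
        cfg = MarkerFilterConfig(markers | {"PF99999"}, 4)
        ds = BinaryTraitDataset("t", frozenset("A"), frozenset("BCD"))
        with caplog.at_level("WARNING"):
            out = filter_marker_conflicts(ds, matrix, cfg)
        assert "PF99999" in caplog.text
        assert not out.excluded  # B has only 3 of the 4 queried markers

    def test_never_touches_positives_never_grows_negatives(self):
        rng = np.random.default_rng(5)
        matrix = FeatureMatrix(pd.DataFrame(
            (rng.random((30, 6)) < 0.5).astype(int),
            index=[f"S{i}" for i in range(30)],
            columns=[f"PF{j:05d}" for j in range(6)],
        ))
        strains = matrix.strain_ids
        ds = BinaryTraitDataset("t", frozenset(strains[:10]), frozenset(strains[10:]))
        cfg = MarkerFilterConfig(frozenset(matrix.feature_ids[:4]), 3)
        out = filter_marker_conflicts(ds, matrix, cfg)
        assert out.positives == ds.positives
        assert out.negatives <= ds.negatives
        assert out.strains == ds.strains


class TestVarianceFilter:
    def test_presence_fraction_window(self):
        # columns with p = 0, 0.5, 0.1, 0.2 among the dataset strains
        data = pd.DataFrame(
            {
                "PF00001": [0] * 10,
                "PF00002": [1] * 5 + [0] * 5,
                "PF00003": [1] + [0] * 9,
                "PF00004": [1, 1] + [0] * 8,
            },
            index=[f"S{i}" for i in range(10)],
        )
        matrix = FeatureMatrix(data)
        ds = BinaryTraitDataset(
            "t", frozenset(data.index[:5]), frozenset(data.index[5:])
        )
        out = variance_filter(matrix, ds, t=0.2)
        assert out.feature_ids == ["PF00002", "PF00004"]

    def test_threshold_half_rejected(self, tiny_matrix, tiny_dataset):
        with pytest.raises(ValidationError):
            variance_filter(tiny_matrix, tiny_dataset, t=0.5)

    def test_computed_on_dataset_strains_only(self):
        # feature constant within the dataset but variable outside it
        data = pd.DataFrame(
            {"PF00001": [1, 1, 0, 0], "PF00002": [1, 0, 1, 0]},
            index=["A", "B", "C", "D"],
        )
        matrix = FeatureMatrix(data)
        ds = BinaryTraitDataset("t", frozenset("A"), frozenset("B"))
        out = variance_filter(matrix, ds, t=0.2)
        assert out.feature_ids == ["PF00002"]
        assert out.strain_ids == ["A", "B", "C", "D"]  # rows untouched


class TestTrainTestSplit:
    def _dataset(self, n_pos, n_neg):
        return BinaryTraitDataset(
            "t",
            frozenset(f"P{i}" for i in range(n_pos)),
            frozenset(f"N{i}" for i in range(n_neg)),
        )

    def test_exact_stratification(self):
        train, test = train_test_split(self._dataset(80, 120), 0.2, seed=1)
        assert (test.n_pos, test.n_neg) == (16, 24)
        assert (train.n_pos, train.n_neg) == (64, 96)

    def test_partition_and_determinism(self):
        ds = self._dataset(13, 29)
        t1 = train_test_split(ds, 0.25, seed=7)
        t2 = train_test_split(ds, 0.25, seed=7)
        assert t1[0].positives == t2[0].positives
        assert t1[1].negatives == t2[1].negatives
        union = t1[0].positives | t1[0].negatives | t1[1].positives | t1[1].negatives
        assert union == ds.positives | ds.negatives
        assert not (t1[0].positives | t1[0].negatives) & (
            t1[1].positives | t1[1].negatives
        )

    def test_zero_fraction_gives_full_train(self):
        train, test = train_test_split(self._dataset(5, 5), 0.0, seed=0)
        assert test.n_pos == test.n_neg == 0
        assert train.n_pos == train.n_neg == 5

    def test_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            train_test_split(self._dataset(1, 10), 0.2, seed=0)


class TestCompositionAndIO:
    def test_exclusion_only_operations_commute_on_classes(self):
        """Ambiguity removal and marker filtering both only remove strains;
        the final classes do not depend on which exclusion is noticed first."""
        rng = np.random.default_rng(11)
        markers = [f"PF{j:05d}" for j in range(5)]
        strains = [f"S{i}" for i in range(40)]
        matrix = FeatureMatrix(pd.DataFrame(
            (rng.random((40, 5)) < 0.5).astype(int), index=strains, columns=markers
        ))
        records = []
        for i, s in enumerate(strains):
            records.append(rec(s, "pos" if i % 3 else "neg"))
            if i % 7 == 0:  # contradictory second record
                records.append(rec(s, "neg" if i % 3 else "pos"))
        cfg = MarkerFilterConfig(frozenset(markers), 4)
        ds = remove_ambiguous(records, positive_states={"pos"})
        once = filter_marker_conflicts(ds, matrix, cfg)
        twice = filter_marker_conflicts(once, matrix, cfg)
        assert (once.positives, once.negatives) == (twice.positives, twice.negatives)
        # ambiguity re-checked on the filtered strains changes nothing
        kept_records = [r for r in records
                        if r.strain_id in once.positives | once.negatives]
        ds2 = remove_ambiguous(kept_records, positive_states={"pos"})
        assert ds2.positives == once.positives
        assert ds2.negatives == once.negatives

    def test_trait_table_round_trip_with_ranges(self, tmp_path):
        path = tmp_path / "labels.tsv"
        pd.DataFrame(
            [
                {"strain_id": "A", "trait": "temp", "value": "37.5", "source": "a"},
                {"strain_id": "B", "trait": "temp", "value": "4-65", "source": "b"},
                {"strain_id": "C", "trait": "motility", "value": "motile", "source": "c"},
            ]
        ).to_csv(path, sep="\t", index=False)
        records = read_trait_table(path, numeric_traits={"temp"})
        assert records[0].value == 37.5
        assert records[1].state == "4-65" and records[1].value is None
        assert records[2].state == "motile"


class TestDatasetInvariants:
    def test_class_overlap_rejected(self):
        with pytest.raises(ValidationError):
            BinaryTraitDataset("t", frozenset("AB"), frozenset("BC"))

    def test_excluded_strain_cannot_hold_a_class(self):
        with pytest.raises(ValidationError):
            BinaryTraitDataset("t", frozenset("A"), frozenset("B"), {"A": AMBIGUOUS})
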