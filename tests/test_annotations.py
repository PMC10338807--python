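"""Cohort filters and label-generation rules, checked against brute-force
enumeration over all rating combinations."""

import itertools
import json

import numpy as np
import pytest

from nodulenet.annotations import (
    EXCLUDED,
    AnnotationError,
    MatchConfig,
    NoduleRecord,
    ReaderAnnotation,
    binarize_semantic,
    filter_individual_cohort,
    filter_panel_cohort,
    group_to_nodules,
    individual_label,
    panel_label,
    parse_annotations,
    semantic_labels,
)
from nodulenet.network import SEMANTIC_FEATURES


def make_ann(reader="r0", key="n0", scan="s0", center=(8, 8, 8),
             malignancy=3, scores=None, mask=None):
    scores = scores or {f: 3 for f in SEMANTIC_FEATURES}
    return ReaderAnnotation(reader_id=reader, nodule_key=key, scan_id=scan,
                            center=center, mask=mask, malignancy=malignancy,
                            semantic_scores=scores)


class TestIndividualLabel:
    @pytest.mark.parametrize("rating,label", [(1, 0), (2, 0), (3, 0),
                                              (4, 1), (5, 1)])
    def test_threshold_between_three_and_four(self, rating, label):
        assert individual_label(rating) == label

    def test_monotone_in_rating(self):
        labels = [individual_label(r) for r in range(1, 6)]
        assert labels == sorted(labels)

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(AnnotationError):
            individual_label(bad)


class TestPanelLabel:
    def test_mean_exactly_three_excluded(self):
        assert panel_label([3, 3, 3]) == EXCLUDED

    def test_mean_above_three_malignant(self):
        assert panel_label([5, 5, 4, 4]) == 1  # mean 4.5

    def test_mean_below_three_benign(self):
        assert panel_label([1, 2, 2, 3]) == 0  # mean 2.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ratings = list(rng.integers(1, 6, rng.integers(1, 5)))
            perm = list(rng.permutation(ratings))
            assert panel_label(ratings) == panel_label(perm)

    def test_empty_rejected(self):
        with pytest.raises(AnnotationError):
            panel_label([])

    def test_exhaustive_four_reader_enumeration(self):
        """All 5^4 rating vectors against an independent mean-rule recount."""
        for ratings in itertools.product(range(1, 6), repeat=4):
            mean = sum(ratings) / 4.0
            expected = EXCLUDED if mean == 3 else int(mean > 3)
            assert panel_label(list(ratings)) == expected
            # and every reader's individual label matches the 4/5 rule
            for r in ratings:
                assert individual_label(r) == int(r >= 4)


class TestSemanticBinarization:
    @pytest.mark.parametrize("score,expected", [(5, 0), (6, 1), (1, 0)])
    def test_calcification_six_versus_rest(self, score, expected):
        assert binarize_semantic("calcification", score) == expected

    @pytest.mark.parametrize("feature", [f for f in SEMANTIC_FEATURES
                                         if f != "calcification"])
    def test_other_features_split_at_four(self, feature):
        hi = 4 if feature == "internalStructure" else 5
        for score in range(1, hi + 1):
            assert binarize_semantic(feature, score) == int(score >= 4)

    def test_unknown_feature_rejected(self):
        with pytest.raises(AnnotationError):
            binarize_semantic("contrast", 3)

    def test_out_of_range_rejected_not_clamped(self):
        with pytest.raises(AnnotationError):
            binarize_semantic("internalStructure", 5)
        with pytest.raises(AnnotationError):
            binarize_semantic("margin", 6)

    def test_semantic_labels_covers_all_eight(self):
        scores = {f: 4 if f != "internalStructure" else 4
                  for f in SEMANTIC_FEATURES}
        scores["calcification"] = 6
        labels = semantic_labels(scores)
        assert set(labels) == set(SEMANTIC_FEATURES)
        assert all(v in (0, 1) for v in labels.values())


class TestGrouping:
    def test_shared_key_groups_into_one_record(self):
        anns = [make_ann(reader=f"r{i}") for i in range(4)]
        records = group_to_nodules(anns)
        assert len(records) == 1
        assert records[0].n_readers == 4
        assert not records[0].ambiguous

    def test_nearby_centers_grouped_without_keys(self):
        a = make_ann(reader="r0", key=None, center=(10, 10, 10))
        b = make_ann(reader="r1", key=None, center=(12, 10, 10))
        records = group_to_nodules(a.__class__ and [a, b],
                                   MatchConfig(distance_threshold=5))
        assert len(records) == 1

    def test_distant_centers_split_without_keys(self):
        a = make_ann(reader="r0", key=None, center=(10, 10, 10))
        b = make_ann(reader="r1", key=None, center=(40, 10, 10))
        assert len(group_to_nodules([a, b])) == 2

    def test_same_key_far_apart_flagged_ambiguous_not_raised(self):
        a = make_ann(reader="r0", center=(10, 10, 10))
        b = make_ann(reader="r1", center=(50, 10, 10))  # 40 voxels apart
        records = group_to_nodules([a, b])
        assert len(records) == 1
        assert records[0].ambiguous


class TestIndividualCohort:
    def rec(self, readers, thickness):
        anns = [make_ann(reader=f"r{i}") for i in range(readers)]
        return NoduleRecord(nodule_id="n0", scan_id="s0",
                            slice_thickness=thickness, annotations=anns)

    def test_two_readers_contribute_nothing(self):
        assert filter_individual_cohort([self.rec(2, 1.75)]) == []

    def test_thick_slices_contribute_nothing(self):
        assert filter_individual_cohort([self.rec(4, 3.0)]) == []

    def test_qualifying_record_contributes_every_annotation(self):
        kept = filter_individual_cohort([self.rec(4, 1.75)])
        assert len(kept) == 4

    def test_output_size_is_sum_over_qualifying_records(self):
        records = [self.rec(r, t) for r, t in
                   [(4, 1.75), (3, 2.5), (2, 1.0), (4, 3.5)]]
        kept = filter_individual_cohort(records)
        assert len(kept) == 4 + 3

    def test_missing_thickness_rejected(self):
        with pytest.raises(AnnotationError):
            filter_individual_cohort([self.rec(4, None)])


class TestPanelCohort:
    def test_mean_three_records_dropped(self):
        anns = [make_ann(reader=f"r{i}", malignancy=3) for i in range(4)]
        rec = NoduleRecord("n0", "s0", 1.75, anns)
        assert filter_panel_cohort([rec]) == []

    def test_other_records_kept(self):
        anns = [make_ann(reader=f"r{i}", malignancy=4) for i in range(4)]
        rec = NoduleRecord("n0", "s0", 1.75, anns)
        assert filter_panel_cohort([rec]) == [rec]


XML_TEMPLATE = """<?xml version="1.0"?>
<annotationFile>
 <header>
  <scanId>s0</scanId>
  <volumeShape>24 24 8</volumeShape>
  <sliceThickness>1.75</sliceThickness>
 </header>
 {sessions}
</annotationFile>
"""

SESSION = """<readingSession>
 <radiologistId>{reader}</radiologistId>
 <nodule>
  <noduleId>n0</noduleId>
  <characteristics>
   <subtlety>3</subtlety><internalStructure>1</internalStructure>
   <calcification>6</calcification><sphericity>3</sphericity>
   <margin>3</margin><lobulation>3</lobulation>
   <spiculation>3</spiculation><texture>3</texture>
   <malignancy>{malignancy}</malignancy>
  </characteristics>
  <roi>
   <sliceIndex>4</sliceIndex>
   <edgeMap><xCoord>10</xCoord><yCoord>10</yCoord></edgeMap>
   <edgeMap><xCoord>14</xCoord><yCoord>10</yCoord></edgeMap>
   <edgeMap><xCoord>14</xCoord><yCoord>14</yCoord></edgeMap>
   <edgeMap><xCoord>10</xCoord><yCoord>14</yCoord></edgeMap>
  </roi>
 </nodule>
</readingSession>"""


class TestXMLParsing:
    def test_zero_nodules_gives_empty_list(self, tmp_path):
        doc = tmp_path / "empty.xml"
        doc.write_text(XML_TEMPLATE.format(sessions=""))
        assert parse_annotations(doc) == []

    def test_single_reader_fixture_round_trip(self, tmp_path):
        doc = tmp_path / "one.xml"
        doc.write_text(XML_TEMPLATE.format(
            sessions=SESSION.format(reader="r0", malignancy=4)))
        anns = parse_annotations(doc)
        assert len(anns) == 1
        assert anns[0].malignancy == 4
        assert anns[0].reader_id == "r0"
        assert anns[0].mask.shape == (24, 24, 8)
        assert anns[0].mask.sum() > 0
        assert anns[0].mask[12, 12, 4] == 1

    def test_malformed_document_names_problem(self, tmp_path):
        doc = tmp_path / "broken.xml"
        doc.write_text("<annotationFile><header></annotationFile>")
        with pytest.raises(AnnotationError):
            parse_annotations(doc)

    def test_out_of_range_rating_rejected(self, tmp_path):
        doc = tmp_path / "bad.xml"
        doc.write_text(XML_TEMPLATE.format(
            sessions=SESSION.format(reader="r0", malignancy=7)))
        with pytest.raises(AnnotationError):
            parse_annotations(doc)


class TestManifestParsing:
    def test_manifest_round_trip_identity(self, tmp_path):
        from nodulenet.synthetic import PhantomConfig, build_dataset

        cfg = PhantomConfig(n_nodules=2, readers=2, cube_side=16, seed=5)
        manifest = build_dataset(cfg, tmp_path)
        anns = parse_annotations(manifest)
        assert len(anns) == 4
        doc = json.loads(manifest.read_text())
        for ann, rec in zip(anns, doc["annotations"]):
            assert ann.reader_id == rec["reader_id"]
            assert ann.malignancy == rec["malignancy"]
            assert ann.semantic_scores == rec["semantic_scores"]
            assert list(ann.center) == rec["center"]
            assert ann.mask is not None and ann.mask.shape == (16, 16, 16)

    def test_missing_field_names_annotation(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps({"annotations": [{"reader_id": "r0"}]}))
        with pytest.raises(AnnotationError, match="#0"):
            parse_annotations(bad)
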