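from itertools import combinations_with_replacement

import pytest

from splicestage import (EndLabel, classify_pair, classify_sample, label_end,
                         mapping_distance)
from splicestage.classification import LABELS, categorize


class TestLabelEnd:
    def test_exonic(self, gene_g):
        # 1-based [150,160] inside exon 1
        lab = label_end([(149, 160)], gene_g)
        assert lab.kind == "ex" and lab.exons == (1,)

    def test_intronic(self, gene_g):
        lab = label_end([(219, 260)], gene_g)
        assert lab.kind == "int" and lab.introns == (1,)

    def test_boundary(self, gene_g):
        # 1-based [195,205] crosses the exon1/intron1 border
        lab = label_end([(194, 205)], gene_g)
        assert lab.kind == "ex-int"
        assert lab.exons == (1,) and lab.introns == (1,)

    def test_annotated_junction(self, gene_g):
        # 1-based [190,200]+[301,310]: gap is exactly intron 1
        lab = label_end([(189, 200), (300, 310)], gene_g)
        assert lab.kind == "ex-ex" and lab.junctions == (1,)

    def test_non_annotated_gap_is_other(self, gene_g):
        lab = label_end([(189, 200), (319, 330)], gene_g)
        assert lab.kind == "other"

    def test_outside(self, gene_g):
        assert label_end([(0, 50)], gene_g).kind == "outside"


class TestMappingDistance:
    def test_gap(self):
        # end1 ends at 1-based 199, end2 starts at 300
        assert mapping_distance([(150, 199)], [(299, 350)]) == 100

    def test_overlap_clamped(self):
        assert mapping_distance([(150, 260)], [(200, 300)]) == 0

    def test_adjacent(self):
        # end1 ends at 200, end2 starts at 201 (1-based)
        assert mapping_distance([(150, 200)], [(200, 250)]) == 0


# the full documented decision table: unordered pair -> (within, outside);
# (ex, ex) depends on whether both ends share one exon
EXPECTED = {
    ("ex-int", "ex-int"): ("pre", "pre"),
    ("ex-int", "int"): ("pre", "pre"),
    ("ex", "ex-int"): ("pre", "pre"),
    ("ex-ex", "ex-int"): ("intermediate", "intermediate"),
    ("int", "int"): ("pre", "intermediate"),
    ("ex", "int"): ("pre", "intermediate"),
    ("ex-ex", "int"): ("intermediate", "intermediate"),
    ("ex-ex", "ex-ex"): ("post", "post"),
    ("ex", "ex-ex"): ("post", "post"),
}


def test_decision_table_total_and_documented():
    """All 10 unordered label pairs x {within, outside} map to exactly the
    documented category (exhaustive enumeration)."""
    pairs = list(combinations_with_replacement(sorted(LABELS), 2))
    assert len(pairs) == 10
    for a, b in pairs:
        for within in (True, False):
            if (a, b) == ("ex", "ex"):
                assert categorize(a, b, within, same_feature=True) == "unknown"
                assert categorize(a, b, within, same_feature=False) == "post"
            else:
                expected = EXPECTED[(a, b)][0 if within else 1]
                assert categorize(a, b, within) == expected
                assert categorize(b, a, within) == expected  # symmetry


@pytest.mark.parametrize(
    "l1, l2, dist, category, large",
    [
        (EndLabel("ex-int", exons=(1,), introns=(1,)),
         EndLabel("ex-ex", junctions=(2,)), 100, "intermediate", False),
        (EndLabel("ex", exons=(1,)), EndLabel("ex", exons=(1,)), 10,
         "unknown", False),
        (EndLabel("int", introns=(1,)), EndLabel("int", introns=(1,)), 80,
         "pre", False),
        (EndLabel("int", introns=(1,)), EndLabel("int", introns=(2,)), 900,
         "intermediate", True),
        (EndLabel("other"), EndLabel("ex", exons=(1,)), 50,
         "unclassified", False),
    ],
)
def test_classify_pair(l1, l2, dist, category, large):
    pair = classify_pair(l1, l2, dist)
    assert pair.category == category
    assert pair.large is large


def test_raising_distance_threshold_never_demotes_pre():
    """Growing the 'within' window only moves pairs out of the
    outside-branch (intermediate) toward pre, never the reverse."""
    labels = [EndLabel("int", introns=(1,)), EndLabel("int", introns=(2,)),
              EndLabel("ex", exons=(1,)), EndLabel("ex-ex", junctions=(1,)),
              EndLabel("ex-int", exons=(1,), introns=(1,))]
    for l1 in labels:
        for l2 in labels:
            for dist in (0, 100, 649, 650, 651, 2000):
                lo = classify_pair(l1, l2, dist, expected_distance=650)
                hi = classify_pair(l1, l2, dist, expected_distance=1200)
                if lo.category == "pre":
                    assert hi.category == "pre"


class TestClassifySample:
    def test_pure_mature_has_no_pre(self, mature_sample):
        res = classify_sample(mature_sample.sam_path,
                              mature_sample.locus.model)
        counts = res.summary().set_index("category")["count"]
        assert counts["pre"] == 0
        assert counts["post"] > 0

    def test_pure_unspliced_has_no_post(self, unspliced_sample):
        res = classify_sample(unspliced_sample.sam_path,
                              unspliced_sample.locus.model)
        counts = res.summary().set_index("category")["count"]
        assert counts["post"] == 0
        assert counts["pre"] > 0

    def test_category_conservation(self, mixture_sample):
        res = classify_sample(mixture_sample.sam_path,
                              mixture_sample.locus.model)
        counts = res.summary().set_index("category")["count"]
        assert counts.sum() == len(res.pairs)
        fractions = res.summary()["fraction"]
        assert fractions.sum() == pytest.approx(1.0)

    def test_mixture_matches_molecule_truth_oracle(self, mixture_sample):
        """Pipeline categories equal the categories derived directly from
        each molecule's known structure, pair by pair."""
        res = classify_sample(mixture_sample.sam_path,
                              mixture_sample.locus.model)
        truth = mixture_sample.truth.set_index("name")["category"]
        assert len(res.pairs) == len(truth)
        for pair in res.pairs:
            assert pair.category == truth[pair.name]
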