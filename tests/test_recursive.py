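import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicestage import (classify_events, consensus_peaks, extract_gaps,
                         gap_peaks, junction_matrix, motif_analysis,
                         motif_summary)
from splicestage.recursive import (GapPeakSet, exclude_novel_exon_events,
                                   flag_novel_exons)


class TestExtractGaps:
    def test_annotated_intron_gap_excluded(self, gene_g, sam_writer):
        sam = sam_writer([("r1", 0, 190, "11M100N10M")])  # gap == intron 1
        assert extract_gaps(sam, gene_g) == []

    def test_intra_intronic_gap_emitted(self, gene_g, sam_writer):
        # 1-based [190,200] + [260,270]: gap [201,259] inside intron 1
        sam = sam_writer([("r1", 0, 190, "11M59N11M")])
        assert extract_gaps(sam, gene_g) == [(200, 259)]

    def test_unsplit_read_yields_nothing(self, gene_g, sam_writer):
        sam = sam_writer([("r1", 0, 150, "20M")])
        assert extract_gaps(sam, gene_g) == []


class TestGapPeaks:
    def test_peaks_at_gap_boundaries(self):
        ps = gap_peaks([(200, 259)] * 3, "chrT")
        assert ps.plus == {200: 3}
        assert ps.minus == {259: 3}
        assert ps.excluded == frozenset()

    def test_shared_start_end_position_excluded(self):
        # 1-based gaps [201,259] and [260,300]: position 260 is an end of
        # the first and the start of the second under the derivative
        # convention, so it is excluded
        ps = gap_peaks([(200, 259), (259, 300)], "chrT")
        assert ps.excluded == frozenset({259})
        assert ps.active_plus() == {200: 1}
        assert ps.active_minus() == {300: 1}

    def test_empty(self):
        ps = gap_peaks([], "chrT")
        assert ps.active_plus() == {} and ps.active_minus() == {}

    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 80)),
                    min_size=0, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_gap_conservation(self, raw):
        """Sum of positive magnitudes = sum of negative magnitudes =
        number of gaps (each gap opens once and closes once)."""
        gaps = [(s, s + w) for s, w in raw]
        ps = gap_peaks(gaps, "chrT")
        assert sum(ps.plus.values()) == len(gaps)
        assert sum(ps.minus.values()) == len(gaps)


class TestWiggleRoundTrip:
    def test_identity_and_byte_stability(self, tmp_path):
        ps = gap_peaks([(200, 259)] * 3 + [(310, 340)] * 2, "chrT")
        w1 = tmp_path / "a.wig"
        ps.to_wiggle(w1)
        back = GapPeakSet.from_wiggle(w1)
        assert back.chrom == "chrT"
        assert back.active_plus() == ps.active_plus()
        assert back.active_minus() == ps.active_minus()
        w2 = tmp_path / "b.wig"
        back.to_wiggle(w2)
        assert w1.read_bytes() == w2.read_bytes()


class TestConsensus:
    def _ps(self, plus, minus):
        return GapPeakSet("chrT", plus, minus, sum(plus.values()))

    def test_summed_magnitude(self):
        sets = [self._ps({201: 3}, {260: 3}), self._ps({201: 2}, {260: 2}),
                self._ps({201: 4}, {260: 4})]
        cons = consensus_peaks(sets, min_samples=3)
        assert cons.plus == {201: (3, 9)}
        assert cons.minus == {260: (3, 9)}

    def test_insufficient_samples_dropped(self):
        sets = [self._ps({201: 3}, {}), self._ps({201: 2}, {}),
                self._ps({}, {})]
        cons = consensus_peaks(sets, min_samples=3)
        assert cons.plus == {}

    def test_sign_disagreement_not_pooled(self):
        sets = [self._ps({201: 3}, {}), self._ps({}, {201: 3})]
        cons = consensus_peaks(sets, min_samples=2)
        assert cons.plus == {} and cons.minus == {}

    def test_singletons_below_min_magnitude_ignored(self):
        sets = [self._ps({201: 1}, {260: 1})] * 3
        cons = consensus_peaks(sets, min_samples=3, min_magnitude=2)
        assert cons.plus == {} and cons.minus == {}

    def test_min_samples_exceeds_n_raises(self):
        with pytest.raises(ValueError, match="min_samples"):
            consensus_peaks([self._ps({}, {})], min_samples=2)


class TestJunctionMatrix:
    def test_annotated_donor_to_intronic_acceptor(self, gene_g, sam_writer):
        # 5 identical reads split from the end of exon 1 into intron 1
        sam = sam_writer([(f"r{i}", 0, 191, "10M60N10M") for i in range(5)])
        ps = gap_peaks(extract_gaps(sam, gene_g), "chrT")
        cons = consensus_peaks([ps], min_samples=1)
        jm = junction_matrix([sam], cons, gene_g)
        assert len(jm.events) == 1
        ev = jm.events.iloc[0]
        assert (ev["gap_start"], ev["gap_end"]) == (200, 260)
        assert ev["donor"] == 200 and ev["acceptor"] == 261
        assert ev["total"] == 5
        assert ev["donor_annotated"] and not ev["acceptor_annotated"]
        typed = classify_events(jm, gene_g)
        assert typed.iloc[0]["event_type"] == "5'-recursive"
        mat = jm.matrix()
        assert mat.loc[261, 200] == 5

    def test_inner_event_two_novel_sites(self, gene_g, sam_writer):
        sam = sam_writer([(f"r{i}", 0, 211, "10M50N10M") for i in range(3)])
        ps = gap_peaks(extract_gaps(sam, gene_g), "chrT")
        cons = consensus_peaks([ps], min_samples=1)
        typed = classify_events(junction_matrix([sam], cons, gene_g), gene_g)
        assert typed.iloc[0]["event_type"] == "inner"

    def test_shared_annotated_acceptor_grouped(self, gene_g, sam_writer):
        # two distinct donors joined to the annotated acceptor of intron 1
        # (first base of exon 2 at 1-based 301, gap end 300)
        rows = [(f"a{i}", 0, 211, "10M80N10M") for i in range(3)]   # gap (220,300)
        rows += [(f"b{i}", 0, 241, "10M50N10M") for i in range(3)]  # gap (250,300)
        sam = sam_writer(rows)
        ps = gap_peaks(extract_gaps(sam, gene_g), "chrT")
        cons = consensus_peaks([ps], min_samples=1)
        typed = classify_events(junction_matrix([sam], cons, gene_g), gene_g)
        assert set(typed["event_type"]) == {"3'-recursive"}
        assert typed["multi_step_group"].nunique() == 1
        assert typed["multi_step_group"].notna().all()

    def test_no_reads_at_consensus_pair(self, gene_g, sam_writer):
        sam = sam_writer([("r1", 0, 150, "20M")])
        cons = consensus_peaks([gap_peaks([], "chrT")], min_samples=1)
        jm = junction_matrix([sam], cons, gene_g)
        assert jm.events.empty


class TestMotifs:
    def _fasta(self, tmp_path, seq):
        path = tmp_path / "g.fa"
        path.write_text(">chrT\n" + "\n".join(
            seq[i:i + 60] for i in range(0, len(seq), 60)) + "\n")
        return path

    def test_plus_strand_motifs(self, gene_g, sam_writer, tmp_path):
        seq = list("A" * 1000)
        seq[200:202] = "GT"    # first two gap bases after donor at 0-based 200
        seq[258:260] = "AG"    # last two gap bases before acceptor
        fasta = self._fasta(tmp_path, "".join(seq))
        sam = sam_writer([(f"r{i}", 0, 191, "10M60N10M") for i in range(3)])
        ps = gap_peaks(extract_gaps(sam, gene_g), "chrT")
        cons = consensus_peaks([ps], min_samples=1)
        jm = junction_matrix([sam], cons, gene_g)
        ev = motif_analysis(classify_events(jm, gene_g), fasta, gene_g)
        assert ev.iloc[0]["donor_motif"] == "GT"
        assert ev.iloc[0]["acceptor_motif"] == "AG"
        assert ev.iloc[0]["canonical"]

    def test_minus_strand_motifs_reverse_complemented(self, gene_g_minus,
                                                      sam_writer, tmp_path):
        # transcription runs right->left: the gap's genomic-right side is
        # the donor; plant revcomp(GT)=AC at the right edge and
        # revcomp(AG)=CT at the left edge of the gap (200, 260)
        seq = list("A" * 1000)
        seq[258:260] = "AC"
        seq[200:202] = "CT"
        fasta = self._fasta(tmp_path, "".join(seq))
        sam = sam_writer([(f"r{i}", 0, 191, "10M60N10M") for i in range(3)])
        ps = gap_peaks(extract_gaps(sam, gene_g_minus), "chrT")
        cons = consensus_peaks([ps], min_samples=1)
        jm = junction_matrix([sam], cons, gene_g_minus)
        ev = motif_analysis(classify_events(jm, gene_g_minus), fasta,
                            gene_g_minus)
        assert ev.iloc[0]["donor_motif"] == "GT"
        assert ev.iloc[0]["acceptor_motif"] == "AG"

    def test_summary_omits_double_novel_events(self, gene_g, sam_writer,
                                               tmp_path):
        fasta = self._fasta(tmp_path, "A" * 1000)
        rows = [(f"r{i}", 0, 191, "10M60N10M") for i in range(3)]   # 1 novel
        rows += [(f"q{i}", 0, 211, "10M30N10M") for i in range(3)]  # 2 novel
        sam = sam_writer(rows)
        ps = gap_peaks(extract_gaps(sam, gene_g), "chrT")
        cons = consensus_peaks([ps], min_samples=1)
        jm = junction_matrix([sam], cons, gene_g)
        ev = motif_analysis(classify_events(jm, gene_g), fasta, gene_g)
        summary = motif_summary(ev)
        assert summary["n_events"].sum() == 1


class TestNovelExonFlag:
    def _setup(self, gene_g, sam_writer):
        # putative exon inside intron 1: splits (200,240) and (270,300)
        rows = [(f"a{i}", 0, 191, "10M40N10M") for i in range(4)]
        rows += [(f"b{i}", 0, 261, "10M30N10M") for i in range(4)]
        sam = sam_writer(rows)
        ps = gap_peaks(extract_gaps(sam, gene_g), "chrT")
        return sam, consensus_peaks([ps], min_samples=1)

    def test_high_coverage_interval_flagged_and_excluded(self, gene_g,
                                                         sam_writer):
        sam, cons = self._setup(gene_g, sam_writer)
        lo, hi = gene_g.span
        depth = np.ones(hi - lo, dtype=np.int64)
        depth[240 - lo:270 - lo] = 10   # the between-peak interval
        flagged = flag_novel_exons(cons, depth, gene_g, ratio=2.0)
        assert len(flagged) == 1
        row = flagged.iloc[0]
        assert (row["start"], row["end"]) == (241, 270)
        assert row["flagged"]
        jm = junction_matrix([sam], cons, gene_g)
        events = classify_events(jm, gene_g)
        remaining = exclude_novel_exon_events(events, flagged)
        assert remaining.empty

    def test_background_interval_not_flagged(self, gene_g, sam_writer):
        _, cons = self._setup(gene_g, sam_writer)
        lo, hi = gene_g.span
        depth = np.ones(hi - lo, dtype=np.int64)
        flagged = flag_novel_exons(cons, depth, gene_g, ratio=2.0)
        assert not flagged["flagged"].any()

    def test_no_peak_pairs_empty(self, gene_g):
        from splicestage.recursive import ConsensusPeaks
        lo, hi = gene_g.span
        flagged = flag_novel_exons(ConsensusPeaks({}, {}),
                                   np.ones(hi - lo, dtype=np.int64), gene_g)
        assert flagged.empty
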