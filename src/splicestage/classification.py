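"""Splicing-stage classification of paired-end reads.

Each aligned read end is labeled by the annotation feature(s) it maps to
(``ex``, ``int``, ``ex-ex``, ``ex-int``); a read pair additionally gets a
*mapping distance* (the inner genomic distance between its two ends) and
is classified into the pre-, intermediate- or post-splicing stage, or
``unknown`` (both ends in one exon, uninformative) / ``unclassified``
(ends that fit no label, e.g. split across a non-annotated gap — those
are retained for the recursive-splicing analysis).

The decision table (unordered label pairs x within/outside the expected
mapping distance) is::

    (ex-int, ex-int | int | ex)   any        -> pre
    (ex-int, ex-ex)               any        -> intermediate
    (int,    int)                 within     -> pre
    (int,    int)                 outside    -> intermediate
    (int,    ex)                  within     -> pre
    (int,    ex)                  outside    -> intermediate
    (int,    ex-ex)               any        -> intermediate
    (ex-ex,  ex-ex | ex)          any        -> post
    (ex,     ex)   same exon      any        -> unknown
    (ex,     ex)   different exons any       -> post

Pairs with a mapping distance at or above the large-distance threshold
(default 650 bp) additionally carry a ``large`` flag, independent of
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .gene_model import GeneModel, Interval

LABELS = ("int", "ex", "ex-ex", "ex-int")
CATEGORIES = ("pre", "intermediate", "post", "unknown", "unclassified")

#: default thresholds: the expected inner mapping distance separating the
#: "within" and "outside" buckets, and the large-distance flag cutoff.
DEFAULT_EXPECTED_DISTANCE = 650
DEFAULT_LARGE_DISTANCE = 650


@dataclass(frozen=True)
class EndLabel:
    """Label of one aligned read end.

    ``kind`` is one of ``int``, ``ex``, ``ex-ex``, ``ex-int`` or the
    bookkeeping kinds ``other`` (split across a non-annotated gap) and
    ``outside`` (escapes the gene span).  Feature indices are 1-based in
    transcription order; ``junctions`` lists introns whose annotated
    junction the end spans (``ex-ex`` only).
    """

    kind: str
    exons: tuple[int, ...] = ()
    introns: tuple[int, ...] = ()
    junctions: tuple[int, ...] = ()


@dataclass(frozen=True)
class ClassifiedPair:
    name: str
    end1: EndLabel
    end2: EndLabel
    distance: int | None
    category: str
    large: bool


def merge_segments(blocks: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/touching blocks into maximal contiguous segments."""
    blocks = sorted(blocks)
    out: list[list[int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def aligned_segments(read: pysam.AlignedSegment) -> list[Interval]:
    """Contiguous reference segments of an alignment; N (skip) operations
    separate segments, deletions extend them."""
    segs: list[Interval] = []
    pos = read.reference_start
    cur_start = pos
    open_seg = False
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            if not open_seg:
                cur_start = pos
                open_seg = True
            pos += length
        elif op == 3:  # N closes the segment
            if open_seg:
                segs.append((cur_start, pos))
                open_seg = False
            pos += length
        # I, S, H, P do not consume reference
    if open_seg:
        segs.append((cur_start, pos))
    return merge_segments(segs)


def label_end(segments: Sequence[Interval], model: GeneModel) -> EndLabel:
    """Label one read end from its contiguous aligned segments (0-based
    half-open, sorted)."""
    if not segments:
        return EndLabel("outside")
    lo, hi = model.span
    for s, e in segments:
        if s < lo or e > hi:
            return EndLabel("outside")

    def contig_features(seg: Interval) -> tuple[tuple[int, ...], tuple[int, ...]]:
        feats = model.overlapped_features(*seg)
        ex = tuple(i for k, i in feats if k == "exon")
        intr = tuple(i for k, i in feats if k == "intron")
        return ex, intr

    if len(segments) == 1:
        ex, intr = contig_features(segments[0])
        if intr and not ex:
            return EndLabel("int", introns=intr)
        if ex and not intr:
            # a contiguous segment inside the gene span touching >1 exon
            # would have to cross an intron, so ex is a single index here
            return EndLabel("ex", exons=ex)
        return EndLabel("ex-int", exons=ex, introns=intr)

    # split end: every gap must exactly match an annotated intron and every
    # aligned segment must be purely exonic, otherwise the end is routed to
    # the recursive-splicing analysis as "other"
    junctions: list[int] = []
    exons: list[int] = []
    for a, b in zip(segments, segments[1:]):
        gap = (a[1], b[0])
        idx = model.intron_index.get(gap)
        if idx is None:
            return EndLabel("other")
        junctions.append(idx)
    for seg in segments:
        ex, intr = contig_features(seg)
        if intr:
            return EndLabel("other")
        exons.extend(ex)
    return EndLabel("ex-ex", exons=tuple(dict.fromkeys(exons)),
                    junctions=tuple(junctions))


def mapping_distance(end1_segments: Sequence[Interval],
                     end2_segments: Sequence[Interval]) -> int:
    """Inner genomic distance between two aligned ends (0 if they touch or
    overlap)."""
    s1 = (min(s for s, _ in end1_segments), max(e for _, e in end1_segments))
    s2 = (min(s for s, _ in end2_segments), max(e for _, e in end2_segments))
    left, right = sorted((s1, s2))
    return max(0, right[0] - left[1])


def categorize(kind_a: str, kind_b: str, within: bool,
               same_feature: bool = False) -> str:
    """Category for an unordered label pair; pure function of the pair, the
    distance bucket and (for ex/ex) whether both ends share one exon."""
    kinds = frozenset((kind_a, kind_b))
    if kinds & {"other", "outside"}:
        return "unclassified"
    if "ex-int" in kinds:
        return "intermediate" if "ex-ex" in kinds else "pre"
    if kinds == {"int"}:
        return "pre" if within else "intermediate"
    if kinds == {"int", "ex"}:
        return "pre" if within else "intermediate"
    if kinds == {"int", "ex-ex"}:
        return "intermediate"
    if kinds in ({"ex-ex"}, {"ex-ex", "ex"}):
        return "post"
    if kinds == {"ex"}:
        return "unknown" if same_feature else "post"
    raise ValueError(f"unhandled label pair {kind_a!r}, {kind_b!r}")


def classify_pair(end1: EndLabel, end2: EndLabel, distance: int | None,
                  *, expected_distance: int = DEFAULT_EXPECTED_DISTANCE,
                  large_distance: int = DEFAULT_LARGE_DISTANCE,
                  name: str = "") -> ClassifiedPair:
    """Classify one read pair from its two end labels and mapping distance."""
    large = distance is not None and distance >= large_distance
    if distance is None or {end1.kind, end2.kind} & {"other", "outside"}:
        return ClassifiedPair(name, end1, end2, distance, "unclassified", large)
    within = distance < expected_distance
    same = (end1.kind == end2.kind == "ex" and end1.exons == end2.exons)
    cat = categorize(end1.kind, end2.kind, within, same)
    return ClassifiedPair(name, end1, end2, distance, cat, large)


@dataclass
class ClassificationResult:
    """All classified pairs of one sample over one gene."""

    gene_id: str
    sample: str
    pairs: list[ClassifiedPair] = field(default_factory=list)
    n_unpaired: int = 0
    n_offtarget: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": p.name,
                "label1": p.end1.kind,
                "label2": p.end2.kind,
                "distance": p.distance,
                "category": p.category,
                "large": p.large,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows, columns=["name", "label1", "label2", "distance", "category",
                           "large"]
        )

    def summary(self) -> pd.DataFrame:
        """Per-category counts, fractions of classified pairs, and counts of
        large-distance pairs."""
        total = len(self.pairs)
        rows = []
        for cat in CATEGORIES:
            sub = [p for p in self.pairs if p.category == cat]
            rows.append(
                {
                    "sample": self.sample,
                    "category": cat,
                    "count": len(sub),
                    "fraction": len(sub) / total if total else 0.0,
                    "large_count": sum(p.large for p in sub),
                }
            )
        return pd.DataFrame(rows)

    def read_names(self, category: str) -> list[str]:
        return [p.name for p in self.pairs if p.category == category]


def classify_sample(alignments: str | Path, model: GeneModel, *,
                    expected_distance: int = DEFAULT_EXPECTED_DISTANCE,
                    large_distance: int = DEFAULT_LARGE_DISTANCE,
                    sample: str = "") -> ClassificationResult:
    """Classify every read pair of a SAM/BAM file against one gene.

    Secondary and supplementary alignments are ignored; reads whose mate
    never appears are counted as unpaired; pairs with no overlap with the
    gene span are counted as off-target and skipped.
    """
    ends: dict[str, dict[int, tuple[str, list[Interval]]]] = {}
    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                continue
            mate = 0 if read.is_read1 else 1
            ends.setdefault(read.query_name, {})[mate] = (
                read.reference_name, aligned_segments(read)
            )

    result = ClassificationResult(model.gene_id, sample or Path(alignments).stem)
    lo, hi = model.span
    for name, mates in ends.items():
        if len(mates) != 2:
            result.n_unpaired += 1
            continue
        (chrom1, segs1), (chrom2, segs2) = mates[0], mates[1]
        overlaps = any(
            chrom == model.chrom and any(s < hi and lo < e for s, e in segs)
            for chrom, segs in ((chrom1, segs1), (chrom2, segs2))
        )
        if not overlaps:
            result.n_offtarget += 1
            continue
        if chrom1 != chrom2 or chrom1 != model.chrom:
            l1 = label_end(segs1, model) if chrom1 == model.chrom else EndLabel("outside")
            l2 = label_end(segs2, model) if chrom2 == model.chrom else EndLabel("outside")
            result.pairs.append(classify_pair(l1, l2, None, name=name,
                                              expected_distance=expected_distance,
                                              large_distance=large_distance))
            continue
        l1 = label_end(segs1, model)
        l2 = label_end(segs2, model)
        dist = mapping_distance(segs1, segs2)
        result.pairs.append(
            classify_pair(l1, l2, dist, name=name,
                          expected_distance=expected_distance,
                          large_distance=large_distance)
        )
    return result
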