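"""Recursive (multi-step) splicing detection from split-read gaps.

An intron removed in several steps leaves intermediate molecules whose
reads are split across non-annotated gaps.  The detector:

1. extracts every split-read gap except those exactly matching an
   annotated intron (those reflect ordinary complete splicing);
2. builds the *inverted coverage* (per-position count of gaps covering
   the position) and its derivative; positive peaks mark split starts,
   negative peaks split ends; positions that are simultaneously a start
   and an end are excluded; peaks are written per sample as a signed
   wiggle track;
3. forms a cross-sample consensus (same position, same sign, present in
   >= min_samples samples, each with at least a minimal magnitude) with
   the summed magnitude reported;
4. re-extracts the supporting reads to recover donor-acceptor
   *connections* (lost in the per-position track) into a donor x acceptor
   junction matrix;
5. types each junction (5'-recursive: annotated donor + intra-intronic
   acceptor; 3'-recursive: annotated acceptor; inner: two novel sites),
   groups junctions sharing an annotated site as multi-step candidates,
   extracts the flanking GT/AG dinucleotide motifs, and flags putative
   novel exons (between-peak intervals with elevated coverage), which
   are removed from the recursive event list.

Derivative convention: with inverted coverage ``c``, the derivative at
position p is ``c[p] - c[p-1]``; a gap occupying 0-based half-open
``[s, e)`` therefore yields a +peak at s and a -peak at e.  Reported
junction coordinates are the 1-based splice-site bases: donor = last
aligned base before the gap, acceptor = first aligned base after it
(transcription sense; on the minus strand the genomic-right side is the
donor).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .classification import aligned_segments
from .gene_model import GeneModel, Interval
from .wiggle import read_wiggle, write_wiggle

DEFAULT_MIN_MAGNITUDE = 2
DEFAULT_NOVEL_EXON_RATIO = 2.0

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gaps(alignments: str | Path, model: GeneModel) -> list[Interval]:
    """All split-read gaps over the gene, 0-based half-open, excluding gaps
    exactly matching an annotated intron.  Read ends are treated
    independently; each retained gap is emitted once per read end."""
    gaps: list[Interval] = []
    annotated = set(model.introns)
    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != model.chrom:
                continue
            segs = aligned_segments(read)
            for a, b in zip(segs, segs[1:]):
                gap = (a[1], b[0])
                if gap not in annotated:
                    gaps.append(gap)
    return gaps


@dataclass
class GapPeakSet:
    """Signed derivative peaks of the inverted gap coverage of one sample.

    ``plus``/``minus`` map 0-based positions to magnitudes *before* the
    both-start-and-end exclusion; :meth:`active_plus`/:meth:`active_minus`
    apply it.  ``n_gaps`` is the number of retained gaps.
    """

    chrom: str
    plus: dict[int, int]
    minus: dict[int, int]
    n_gaps: int

    @property
    def excluded(self) -> frozenset[int]:
        return frozenset(self.plus) & frozenset(self.minus)

    def active_plus(self) -> dict[int, int]:
        return {p: m for p, m in self.plus.items() if p not in self.excluded}

    def active_minus(self) -> dict[int, int]:
        return {p: m for p, m in self.minus.items() if p not in self.excluded}

    def to_wiggle(self, path: str | Path) -> None:
        """Signed peak track, 1-based positions: +magnitude at split starts,
        -magnitude at split ends."""
        entries: dict[int, int] = {}
        for p, m in self.active_plus().items():
            entries[p + 1] = m
        for p, m in self.active_minus().items():
            entries[p + 1] = -m
        write_wiggle(entries, self.chrom, path)

    @classmethod
    def from_wiggle(cls, path: str | Path) -> "GapPeakSet":
        chrom, entries = read_wiggle(path)
        plus = {p - 1: v for p, v in entries.items() if v > 0}
        minus = {p - 1: -v for p, v in entries.items() if v < 0}
        return cls(chrom, plus, minus, n_gaps=sum(plus.values()))


def gap_peaks(gaps: Iterable[Interval], chrom: str) -> GapPeakSet:
    """Derivative peaks of the inverted coverage of a set of gaps."""
    plus: Counter[int] = Counter()
    minus: Counter[int] = Counter()
    n = 0
    for s, e in gaps:
        plus[s] += 1
        minus[e] += 1
        n += 1
    return GapPeakSet(chrom, dict(plus), dict(minus), n)


@dataclass
class ConsensusPeaks:
    """Cross-sample consensus: 0-based position -> (n_samples, summed
    magnitude), separately for split starts (plus) and ends (minus)."""

    plus: dict[int, tuple[int, int]]
    minus: dict[int, tuple[int, int]]


def consensus_peaks(peaksets: Sequence[GapPeakSet], min_samples: int,
                    min_magnitude: int = DEFAULT_MIN_MAGNITUDE
                    ) -> ConsensusPeaks:
    """Retain peak positions supported (same sign, magnitude >=
    ``min_magnitude``) in at least ``min_samples`` samples; the reported
    value is the magnitude summed over the supporting samples."""
    if min_samples > len(peaksets):
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of samples "
            f"({len(peaksets)})"
        )

    def collect(side: str) -> dict[int, tuple[int, int]]:
        support: dict[int, list[int]] = {}
        for ps in peaksets:
            active = ps.active_plus() if side == "plus" else ps.active_minus()
            for p, m in active.items():
                if m >= min_magnitude:
                    support.setdefault(p, []).append(m)
        return {p: (len(ms), sum(ms)) for p, ms in support.items()
                if len(ms) >= min_samples}

    return ConsensusPeaks(collect("plus"), collect("minus"))


def consensus_to_wiggle(consensus: ConsensusPeaks, chrom: str,
                        path: str | Path) -> None:
    entries: dict[int, int] = {}
    for p, (_, total) in consensus.plus.items():
        entries[p + 1] = total
    for p, (_, total) in consensus.minus.items():
        entries[p + 1] = -total
    write_wiggle(entries, chrom, path)


@dataclass
class JunctionMatrix:
    """Donor x acceptor split-read support for all consensus junctions.

    ``events`` has one row per junction with its gap coordinates (0-based
    half-open), 1-based donor/acceptor splice-site bases, per-sample read
    counts, total count, number of supporting samples and annotation
    flags.
    """

    gene_id: str
    events: pd.DataFrame

    def matrix(self) -> pd.DataFrame:
        """Acceptor-rows x donor-columns count matrix (0 where no reads)."""
        if self.events.empty:
            return pd.DataFrame()
        return self.events.pivot_table(index="acceptor", columns="donor",
                                       values="total", aggfunc="sum",
                                       fill_value=0)


def junction_matrix(alignments: Sequence[str | Path],
                    consensus: ConsensusPeaks,
                    model: GeneModel,
                    sample_names: Sequence[str] | None = None
                    ) -> JunctionMatrix:
    """Re-extract split reads whose gap boundaries both hit consensus peaks
    and tally them per (donor, acceptor) junction."""
    names = list(sample_names) if sample_names else [
        Path(p).stem for p in alignments
    ]
    annotated = set(model.introns)
    counts: dict[Interval, Counter[str]] = {}
    for name, path in zip(names, alignments):
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for read in fh:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.reference_name != model.chrom:
                    continue
                segs = aligned_segments(read)
                for a, b in zip(segs, segs[1:]):
                    gap = (a[1], b[0])
                    if gap in annotated:
                        continue
                    if gap[0] in consensus.plus and gap[1] in consensus.minus:
                        counts.setdefault(gap, Counter())[name] += 1

    donor_set = set(model.donor_sites)
    acceptor_set = set(model.acceptor_sites)
    rows = []
    for (gs, ge), per_sample in sorted(counts.items()):
        # transcription-sense splice-site bases, 1-based
        if model.strand == "+":
            donor, acceptor = gs, ge + 1
        else:
            donor, acceptor = ge + 1, gs
        rec = {
            "gene": model.gene_id,
            "gap_start": gs,
            "gap_end": ge,
            "donor": donor,
            "acceptor": acceptor,
            "donor_annotated": donor in donor_set,
            "acceptor_annotated": acceptor in acceptor_set,
            "n_samples": sum(1 for c in per_sample.values() if c > 0),
            "total": sum(per_sample.values()),
        }
        for name in names:
            rec[f"reads_{name}"] = per_sample.get(name, 0)
        rows.append(rec)
    cols = ["gene", "gap_start", "gap_end", "donor", "acceptor",
            "donor_annotated", "acceptor_annotated", "n_samples", "total"] + [
        f"reads_{n}" for n in names
    ]
    return JunctionMatrix(model.gene_id, pd.DataFrame(rows, columns=cols))


def classify_events(jm: JunctionMatrix, model: GeneModel) -> pd.DataFrame:
    """Type each junction and group candidate multi-step chains.

    Types: ``5'-recursive`` (annotated donor, novel acceptor),
    ``3'-recursive`` (novel donor, annotated acceptor), ``inner`` (two
    novel sites) and ``exon-skipping`` (both sites annotated, i.e. an
    exon-skipping junction rather than an intra-intronic event).
    Junctions sharing one annotated donor or acceptor are marked as a
    multi-step group.
    """
    events = jm.events.copy()
    if events.empty:
        events["event_type"] = pd.Series(dtype=str)
        events["multi_step_group"] = pd.Series(dtype=object)
        return events

    def typ(row):
        if row["donor_annotated"] and row["acceptor_annotated"]:
            return "exon-skipping"
        if row["donor_annotated"]:
            return "5'-recursive"
        if row["acceptor_annotated"]:
            return "3'-recursive"
        return "inner"

    events["event_type"] = events.apply(typ, axis=1)
    events["multi_step_group"] = None
    for side in ("donor", "acceptor"):
        annotated = events[events[f"{side}_annotated"]]
        for site, grp in annotated.groupby(side):
            if len(grp) >= 2:
                events.loc[grp.index, "multi_step_group"] = f"{side}@{site}"
    return events


def motif_analysis(events: pd.DataFrame, genome: str | Path | Fasta,
                   model: GeneModel) -> pd.DataFrame:
    """Extract splice-site dinucleotides for every event.

    ``donor_motif`` = first two gap bases 3' of the donor (GT when
    canonical), ``acceptor_motif`` = last two gap bases 5' of the acceptor
    (AG when canonical), both in transcription sense (reverse-complemented
    on the minus strand), plus the two flanking retained bases on each
    side.  Events whose motif window runs off the contig are skipped with
    a warning column set.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    seq = fasta[model.chrom]
    contig_len = len(seq)

    out = events.copy()
    donor_motifs, acceptor_motifs = [], []
    donor_flanks, acceptor_flanks = [], []
    ok_flags = []
    for _, row in out.iterrows():
        gs, ge = int(row["gap_start"]), int(row["gap_end"])
        if gs - 2 < 0 or ge + 2 > contig_len:
            donor_motifs.append("")
            acceptor_motifs.append("")
            donor_flanks.append("")
            acceptor_flanks.append("")
            ok_flags.append(False)
            continue
        left_in = str(seq[gs:gs + 2]).upper()       # first two gap bases
        right_in = str(seq[ge - 2:ge]).upper()      # last two gap bases
        left_out = str(seq[gs - 2:gs]).upper()
        right_out = str(seq[ge:ge + 2]).upper()
        if model.strand == "+":
            donor_motifs.append(left_in)
            acceptor_motifs.append(right_in)
            donor_flanks.append(left_out)
            acceptor_flanks.append(right_out)
        else:
            donor_motifs.append(revcomp(right_in))
            acceptor_motifs.append(revcomp(left_in))
            donor_flanks.append(revcomp(right_out))
            acceptor_flanks.append(revcomp(left_out))
        ok_flags.append(True)
    out["donor_motif"] = donor_motifs
    out["acceptor_motif"] = acceptor_motifs
    out["donor_flank"] = donor_flanks
    out["acceptor_flank"] = acceptor_flanks
    out["motif_ok"] = ok_flags
    out["donor_canonical"] = out["donor_motif"] == "GT"
    out["acceptor_canonical"] = out["acceptor_motif"] == "AG"
    out["canonical"] = out["donor_canonical"] & out["acceptor_canonical"]
    return out


def motif_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Percentage of canonical motifs at the *novel* site of events with
    exactly one non-annotated splice site, stratified by the number of
    supporting samples.  Events with two novel sites are omitted (they are
    more likely novel exons than recursive intermediates)."""
    if events.empty:
        return pd.DataFrame(
            columns=["n_samples", "n_events", "pct_canonical_donor",
                     "pct_canonical_acceptor"]
        )
    one_novel = events[
        events["motif_ok"]
        & (events["donor_annotated"] != events["acceptor_annotated"])
    ]
    rows = []
    for n, grp in one_novel.groupby("n_samples"):
        novel_donor = grp[~grp["donor_annotated"]]
        novel_acceptor = grp[~grp["acceptor_annotated"]]
        rows.append(
            {
                "n_samples": n,
                "n_events": len(grp),
                "pct_canonical_donor": 100.0 * novel_donor["donor_canonical"].mean()
                if len(novel_donor) else float("nan"),
                "pct_canonical_acceptor":
                    100.0 * novel_acceptor["acceptor_canonical"].mean()
                    if len(novel_acceptor) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def flag_novel_exons(consensus: ConsensusPeaks, depth: np.ndarray,
                     model: GeneModel,
                     ratio: float = DEFAULT_NOVEL_EXON_RATIO) -> pd.DataFrame:
    """Flag putative novel exons: intra-intronic intervals bounded by a
    -peak and the next +peak whose median coverage exceeds ``ratio`` times
    the containing intron's median coverage."""
    lo, _ = model.span
    minus_positions = sorted(consensus.minus)
    plus_positions = sorted(consensus.plus)
    rows = []
    for i, (isv, iev) in enumerate(model.introns, start=1):
        intron_med = float(np.median(depth[isv - lo:iev - lo]))
        for e in minus_positions:
            if not (isv < e < iev):
                continue
            nxt = [p for p in plus_positions if e < p <= iev]
            if not nxt:
                continue
            s2 = nxt[0]
            seg = depth[e - lo:s2 - lo]
            med = float(np.median(seg)) if len(seg) else 0.0
            flagged = intron_med > 0 and med > ratio * intron_med
            rows.append(
                {
                    "intron": i,
                    "start": e + 1,       # 1-based inclusive interval
                    "end": s2,
                    "median": med,
                    "intron_median": intron_med,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(
        rows, columns=["intron", "start", "end", "median", "intron_median",
                       "flagged"]
    )


def exclude_novel_exon_events(events: pd.DataFrame,
                              flagged: pd.DataFrame) -> pd.DataFrame:
    """Drop events whose gap abuts a flagged novel-exon interval (the
    flanking splits that define the putative exon)."""
    if events.empty or flagged.empty:
        return events
    flg = flagged[flagged["flagged"]]
    if flg.empty:
        return events
    bad_ends = set(flg["start"] - 1)    # gap_end == interval start - 1 (0-based)
    bad_starts = set(flg["end"])        # gap_start == interval end (0-based)
    keep = ~(events["gap_end"].isin(bad_ends)
             | events["gap_start"].isin(bad_starts))
    return events[keep].reset_index(drop=True)


@dataclass
class RecursiveResults:
    peaksets: list[GapPeakSet]
    consensus: ConsensusPeaks
    junctions: JunctionMatrix
    events: pd.DataFrame
    novel_exons: pd.DataFrame
    summary: pd.DataFrame


def detect_recursive(alignments: Sequence[str | Path], model: GeneModel, *,
                     genome: str | Path | Fasta | None = None,
                     min_samples: int | None = None,
                     min_magnitude: int = DEFAULT_MIN_MAGNITUDE,
                     novel_exon_ratio: float = DEFAULT_NOVEL_EXON_RATIO,
                     depth: np.ndarray | None = None,
                     sample_names: Sequence[str] | None = None
                     ) -> RecursiveResults:
    """Full recursive-splicing analysis across samples.

    ``depth`` (per-base coverage over the gene span, summed over samples)
    is recomputed from the alignments when not supplied; the genome FASTA
    is optional and enables motif extraction.
    """
    from .splice_site_index import per_base_depth

    if min_samples is None:
        min_samples = len(alignments)
    peaksets = [gap_peaks(extract_gaps(p, model), model.chrom)
                for p in alignments]
    consensus = consensus_peaks(peaksets, min_samples, min_magnitude)
    jm = junction_matrix(alignments, consensus, model, sample_names)
    events = classify_events(jm, model)
    if genome is not None and not events.empty:
        events = motif_analysis(events, genome, model)
    if depth is None:
        depth = np.zeros(model.span[1] - model.span[0], dtype=np.int64)
        for p in alignments:
            depth += per_base_depth(p, model)
    novel = flag_novel_exons(consensus, depth, model, novel_exon_ratio)
    events = exclude_novel_exon_events(events, novel)
    summary = motif_summary(events) if "motif_ok" in events.columns else \
        pd.DataFrame()
    return RecursiveResults(peaksets, consensus, jm, events, novel, summary)
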