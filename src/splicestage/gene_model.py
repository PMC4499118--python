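"""Gene models: ordered exon/intron structure derived from GTF annotation.

A :class:`GeneModel` describes one reference transcript of one gene: its
exons in transcription order, the introns derived as the gaps between
consecutive exons, and the annotated donor/acceptor coordinates of every
splice junction.  Everything downstream (read labeling, splice-site
indices, splicing-order inference, recursive-splicing detection) queries
this structure.

Coordinate conventions
----------------------
Internally all intervals are 0-based half-open on the genomic forward
strand.  The GTF/SAM interface and every *reported* coordinate use the
1-based inclusive convention.  Exon and intron *numbering* follows
transcription order: on the minus strand exon 1 is the genomically
rightmost exon.  Genomic coordinates are never flipped, only indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: 0-based half-open genomic interval.
Interval = tuple[int, int]


class AnnotationError(ValueError):
    """A gene model could not be derived from the annotation."""


class GeneNotFoundError(AnnotationError):
    """One or more requested gene ids are absent from the GTF."""

    def __init__(self, gene_ids: Iterable[str]):
        self.gene_ids = tuple(gene_ids)
        super().__init__(
            "gene id(s) not found in annotation: " + ", ".join(self.gene_ids)
        )


class SingleExonError(AnnotationError):
    """The chosen transcript has fewer than two exons, so no introns exist."""

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id}: no introns (transcript has <2 exons)")


class ChromosomeMismatchError(ValueError):
    """A query interval lies on a different chromosome than the gene."""


@dataclass(frozen=True)
class Located:
    """Result of :meth:`GeneModel.locate`.

    ``kind`` is ``"exon"``, ``"intron"``, ``"boundary"`` (the interval
    straddles at least one exon/intron border) or ``"outside"``.
    ``features`` lists every (kind, 1-based index) touched, in genomic
    order.
    """

    kind: str
    index: int | None = None
    features: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one gene on one reference transcript.

    Parameters
    ----------
    exons
        0-based half-open genomic intervals in *transcription* order
        (exon 1 first; on the minus strand exon 1 has the highest
        genomic coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if len(self.exons) < 2:
            raise SingleExonError(self.gene_id)
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(f"invalid exon interval ({s}, {e})")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if not ordered:
            raise AnnotationError(
                f"gene {self.gene_id}: exons not in transcription order for "
                f"strand {self.strand}"
            )
        for i in range(len(self.exons) - 1):
            a, b = self.exons[i], self.exons[i + 1]
            left, right = (a, b) if self.strand == "+" else (b, a)
            if left[1] >= right[0]:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons {i + 1} and {i + 2} overlap or touch"
                )

    # -- structure ---------------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @cached_property
    def introns(self) -> tuple[Interval, ...]:
        """Introns in transcription order, 0-based half-open."""
        out = []
        for i in range(self.n_introns):
            a, b = self.exons[i], self.exons[i + 1]
            out.append((a[1], b[0]) if self.strand == "+" else (b[1], a[0]))
        return tuple(out)

    @cached_property
    def span(self) -> Interval:
        """Genomic extent of the gene, 0-based half-open."""
        return (
            min(s for s, _ in self.exons),
            max(e for _, e in self.exons),
        )

    def exon(self, i: int) -> Interval:
        """1-based accessor, transcription order."""
        return self.exons[i - 1]

    def intron(self, i: int) -> Interval:
        """1-based accessor, transcription order."""
        return self.introns[i - 1]

    @cached_property
    def intron_index(self) -> Mapping[Interval, int]:
        """Genomic intron interval -> 1-based transcription index."""
        return {iv: i + 1 for i, iv in enumerate(self.introns)}

    @cached_property
    def donor_sites(self) -> tuple[int, ...]:
        """1-based genomic coordinate of the last exonic base 5' of each
        intron (transcription sense), one per intron in transcription order."""
        out = []
        for s, e in self.introns:
            out.append(s if self.strand == "+" else e + 1)
        return tuple(out)

    @cached_property
    def acceptor_sites(self) -> tuple[int, ...]:
        """1-based genomic coordinate of the first exonic base 3' of each
        intron (transcription sense)."""
        out = []
        for s, e in self.introns:
            out.append(e + 1 if self.strand == "+" else s)
        return tuple(out)

    @cached_property
    def annotated_junctions(self) -> frozenset[tuple[int, int]]:
        """(donor, acceptor) 1-based coordinate pairs, one per intron."""
        return frozenset(zip(self.donor_sites, self.acceptor_sites))

    # -- queries -----------------------------------------------------------

    def locate(self, start: int, end: int, chrom: str | None = None) -> Located:
        """Locate a 1-based inclusive interval within the gene structure."""
        if chrom is not None and chrom != self.chrom:
            raise ChromosomeMismatchError(
                f"interval on {chrom}, gene {self.gene_id} on {self.chrom}"
            )
        s, e = start - 1, end  # to 0-based half-open
        lo, hi = self.span
        if s < lo or e > hi:
            return Located("outside")
        feats = self.overlapped_features(s, e)
        if len(feats) == 1:
            kind, idx = feats[0]
            return Located(kind, idx, feats)
        return Located("boundary", None, feats)

    def overlapped_features(self, s: int, e: int) -> tuple[tuple[str, int], ...]:
        """All (kind, index) features overlapping 0-based half-open (s, e),
        in genomic order."""
        hits: list[tuple[int, str, int]] = []
        for i, (fs, fe) in enumerate(self.exons):
            if fs < e and s < fe:
                hits.append((fs, "exon", i + 1))
        for i, (fs, fe) in enumerate(self.introns):
            if fs < e and s < fe:
                hits.append((fs, "intron", i + 1))
        hits.sort()
        return tuple((k, i) for _, k, i in hits)

    # -- GTF I/O -----------------------------------------------------------

    def to_gtf(self, path: str | Path) -> None:
        """Write this model as an Ensembl-dialect GTF (gene/transcript/exon)."""
        Path(path).write_text(self.to_gtf_text())

    def to_gtf_text(self) -> str:
        tid = self.transcript_id or f"{self.gene_id}.t1"
        lo, hi = self.span
        attrs = f'gene_id "{self.gene_id}"; transcript_id "{tid}";'
        lines = [
            _gtf_line(self.chrom, "gene", lo + 1, hi, self.strand,
                      f'gene_id "{self.gene_id}";'),
            _gtf_line(self.chrom, "transcript", lo + 1, hi, self.strand, attrs),
        ]
        for i, (s, e) in enumerate(self.exons):
            lines.append(
                _gtf_line(self.chrom, "exon", s + 1, e, self.strand,
                          f'{attrs} exon_number "{i + 1}";')
            )
        return "\n".join(lines) + "\n"


def _gtf_line(chrom: str, feature: str, start1: int, end1: int, strand: str,
              attrs: str) -> str:
    return "\t".join(
        [chrom, "splicestage", feature, str(start1), str(end1), ".", strand,
         ".", attrs]
    )


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def load_annotation(
    gtf_path: str | Path,
    gene_ids: Sequence[str],
    transcript_overrides: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Load one :class:`GeneModel` per requested gene from a GTF file.

    The reference transcript of each gene is the one with the most exons
    (ties broken by lexicographically smallest transcript id) unless an
    explicit transcript id is given in ``transcript_overrides``.

    Raises
    ------
    GeneNotFoundError
        if any requested gene id is absent.
    SingleExonError
        if a chosen transcript has fewer than two exons.
    """
    overrides = dict(transcript_overrides or {})
    wanted = set(gene_ids)
    # (gene_id, transcript_id) -> list of (chrom, strand, start0, end)
    exons: dict[tuple[str, str], list[tuple[str, str, int, int]]] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "exon":
                continue
            attrs = _parse_attributes(cols[8])
            gid = attrs.get("gene_id")
            if gid not in wanted:
                continue
            tid = attrs.get("transcript_id", f"{gid}.t1")
            exons.setdefault((gid, tid), []).append(
                (cols[0], cols[6], int(cols[3]) - 1, int(cols[4]))
            )
    found = {g for g, _ in exons}
    missing = sorted(wanted - found)
    if missing:
        raise GeneNotFoundError(missing)

    models = []
    for gid in gene_ids:
        tids = sorted(t for g, t in exons if g == gid)
        if gid in overrides:
            if overrides[gid] not in tids:
                raise GeneNotFoundError([f"{gid}/{overrides[gid]}"])
            tid = overrides[gid]
        else:
            tid = max(tids, key=lambda t: (len(exons[(gid, t)]), t))
            # most exons wins; on a tie prefer the smallest transcript id
            best_n = len(exons[(gid, tid)])
            tid = min(t for t in tids if len(exons[(gid, t)]) == best_n)
        recs = exons[(gid, tid)]
        chroms = {c for c, *_ in recs}
        strands = {st for _, st, *_ in recs}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(f"gene {gid}: exons on multiple chroms/strands")
        chrom, strand = chroms.pop(), strands.pop()
        ivals = sorted(((s, e) for _, _, s, e in recs),
                       reverse=(strand == "-"))
        if len(ivals) < 2:
            raise SingleExonError(gid)
        models.append(GeneModel(gid, chrom, strand, tuple(ivals), tid))
    return models


def load_gene(gtf_path: str | Path, gene_id: str,
              transcript_id: str | None = None) -> GeneModel:
    """Convenience wrapper around :func:`load_annotation` for one gene."""
    overrides = {gene_id: transcript_id} if transcript_id else None
    return load_annotation(gtf_path, [gene_id], overrides)[0]
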