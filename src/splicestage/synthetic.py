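"""Synthetic multi-intron locus and paired-end reads from splicing
intermediates.

The generator emulates what a nuclear RNA extract looks like to a
splice-aware aligner: a mixture of unspliced, partially spliced (in a
configurable removal order), recursive-intermediate and mature molecules
of one gene, fragmented and paired-end sequenced.  Canonical GT/AG
dinucleotides are planted at every annotated and every planted
intra-intronic splice site.  Alongside the SAM it writes a truth table
with, per read pair, the source molecule structure, the stage category
the pair should classify into, and the exact split-gap coordinates of
each end — the oracle for every downstream check.

Partially spliced molecules use snapshot semantics: the set of removed
introns is a prefix of the configured removal-order permutation, the
minimal model of a co-transcriptional splicing snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .gene_model import GeneModel, Interval

STAGES = ("unspliced", "partial", "mature")
_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Inconsistent simulation configuration (e.g. a planted splice site
    outside its intron)."""


@dataclass(frozen=True)
class RecursiveSpec:
    """A planted intra-intronic acceptor: molecules still containing
    ``intron`` carry, with probability ``usage``, a partial gap from the
    annotated donor to the acceptor at transcription offset
    ``acceptor_offset`` (bases from the intron's 5' end)."""

    intron: int
    acceptor_offset: int
    usage: float


@dataclass(frozen=True)
class NovelExonSpec:
    """A planted cryptic exon inside ``intron``: with probability
    ``usage`` a molecule containing the intron instead retains only the
    ``length``-base interval starting ``start_offset`` bases into the
    intron (transcription sense), with both flanking pieces spliced
    out."""

    intron: int
    start_offset: int
    length: int
    usage: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated sample.

    Defaults describe a mid-sized gene sampled in a nuclear-RNA-like
    mixture: 7 exons, introns of a few hundred to ~1.5 kb, a 100-bp
    paired-end library with a 300 +/- 80 bp fragment-size distribution
    (min 200), and a 30/40/30 unspliced/partial/mature stage mixture.
    """

    n_exons: int = 7
    exon_length: tuple[int, int] = (120, 200)
    intron_length: tuple[int, int] = (700, 1500)
    exon_lengths: tuple[int, ...] | None = None
    intron_lengths: tuple[int, ...] | None = None
    strand: str = "+"
    chrom: str = "chrSim"
    gene_id: str = "GENE1"
    pad: int = 1000

    mix_unspliced: float = 0.3
    mix_partial: float = 0.4
    mix_mature: float = 0.3
    order_overrides: tuple[tuple[int, int], ...] = ()
    retention: Mapping[int, float] = field(default_factory=dict)
    exon_skip: Mapping[int, float] = field(default_factory=dict)
    recursive: tuple[RecursiveSpec, ...] = ()
    novel_exons: tuple[NovelExonSpec, ...] = ()

    fragment_mean: float = 300.0
    fragment_sd: float = 80.0
    fragment_min: int = 200
    read_length: int = 100
    n_pairs: int = 10_000
    n_molecules: int = 2000
    noise_gaps: int = 0
    mismatch_rate: float = 0.0

    seed: int = 0
    locus_seed: int = 7

    def __post_init__(self) -> None:
        mix = self.mix_unspliced + self.mix_partial + self.mix_mature
        if abs(mix - 1.0) > 1e-9:
            raise SimulationError(f"stage mixture sums to {mix}, not 1")
        for frac in (self.mix_unspliced, self.mix_partial, self.mix_mature):
            if frac < 0:
                raise SimulationError("negative mixture fraction")
        for spec in self.recursive:
            if not 0 <= spec.usage <= 1:
                raise SimulationError("recursive usage outside [0, 1]")

    @property
    def n_introns(self) -> int:
        return self.n_exons - 1

    def removal_order(self) -> list[int]:
        """Intron removal order: sequential 5'->3' with each override
        (j, i) moving intron j immediately before intron i."""
        order = list(range(1, self.n_introns + 1))
        for j, i in self.order_overrides:
            order.remove(j)
            order.insert(order.index(i), j)
        return order


@dataclass
class Locus:
    model: GeneModel
    sequence: str
    fasta_path: Path | None = None
    gtf_path: Path | None = None


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    for k, base in enumerate(motif):
        seq[pos + k] = base


def _plant_gap_motifs(seq: np.ndarray, gap: Interval, strand: str) -> None:
    """Plant GT at the transcription start and AG at the transcription end
    of a spliced-out gap (reverse-complemented genomically on '-')."""
    gs, ge = gap
    if strand == "+":
        _plant(seq, gs, "GT")
        _plant(seq, ge - 2, "AG")
    else:
        _plant(seq, ge - 2, "AC")   # revcomp(GT)
        _plant(seq, gs, "CT")       # revcomp(AG)


def _intron_prefix(model: GeneModel, intron: int, length: int) -> Interval:
    """Genomic interval of the first ``length`` transcription-sense bases
    of an intron."""
    s, e = model.intron(intron)
    if not 0 < length < e - s:
        raise SimulationError(
            f"intron {intron} prefix of {length} bases does not fit its "
            f"{e - s}-base length"
        )
    return (s, s + length) if model.strand == "+" else (e - length, e)


def _intron_sub(model: GeneModel, intron: int, start: int,
                length: int) -> Interval:
    """Genomic interval of intron bases [start, start+length) in
    transcription sense."""
    s, e = model.intron(intron)
    if not (0 <= start and start + length <= e - s):
        raise SimulationError(
            f"interval [{start}, {start + length}) outside intron {intron} "
            f"of length {e - s}"
        )
    if model.strand == "+":
        return (s + start, s + start + length)
    return (e - start - length, e - start)


def simulate_locus(config: SimConfig, out_dir: str | Path | None = None
                   ) -> Locus:
    """Build the synthetic gene locus: random sequence with canonical
    GT/AG planted at all annotated and planted splice sites, plus GTF and
    FASTA files when ``out_dir`` is given.  Deterministic under
    ``config.locus_seed``."""
    rng = np.random.default_rng(config.locus_seed)
    n_ex, n_in = config.n_exons, config.n_introns
    if config.exon_lengths is not None:
        if len(config.exon_lengths) != n_ex:
            raise SimulationError("exon_lengths does not match n_exons")
        ex_lens = list(config.exon_lengths)
    else:
        ex_lens = list(rng.integers(config.exon_length[0],
                                    config.exon_length[1] + 1, n_ex))
    if config.intron_lengths is not None:
        if len(config.intron_lengths) != n_in:
            raise SimulationError("intron_lengths does not match n_exons - 1")
        in_lens = list(config.intron_lengths)
    else:
        in_lens = list(rng.integers(config.intron_length[0],
                                    config.intron_length[1] + 1, n_in))

    # genomic layout, ascending coordinates
    ex_lens = [int(v) for v in ex_lens]
    in_lens = [int(v) for v in in_lens]
    exons_genomic: list[Interval] = []
    pos = config.pad
    for i in range(n_ex):
        exons_genomic.append((pos, pos + ex_lens[i]))
        pos += ex_lens[i]
        if i < n_in:
            pos += in_lens[i]
    genome_len = pos + config.pad

    exons = tuple(exons_genomic if config.strand == "+"
                  else exons_genomic[::-1])
    model = GeneModel(config.gene_id, config.chrom, config.strand, exons)

    seq = rng.choice(_BASES, genome_len)
    for iv in model.introns:
        _plant_gap_motifs(seq, iv, config.strand)
    for spec in config.recursive:
        gap = _intron_prefix(model, spec.intron, spec.acceptor_offset)
        _plant_gap_motifs(seq, gap, config.strand)
    for spec in config.novel_exons:
        iv = model.intron(spec.intron)
        if spec.start_offset + spec.length >= iv[1] - iv[0]:
            raise SimulationError("novel exon does not fit inside its intron")
        g1 = _intron_sub(model, spec.intron, 0, spec.start_offset)
        g2_start = spec.start_offset + spec.length
        g2 = _intron_sub(model, spec.intron, g2_start,
                         (iv[1] - iv[0]) - g2_start)
        _plant_gap_motifs(seq, g1, config.strand)
        _plant_gap_motifs(seq, g2, config.strand)
    sequence = "".join(seq)

    fasta_path = gtf_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta_path = out_dir / "genome.fa"
        with open(fasta_path, "w") as fh:
            fh.write(f">{config.chrom}\n")
            for k in range(0, genome_len, 60):
                fh.write(sequence[k:k + 60] + "\n")
        gtf_path = out_dir / "annotation.gtf"
        model.to_gtf(gtf_path)
    return Locus(model, sequence, fasta_path, gtf_path)


@dataclass
class Molecule:
    """One RNA molecule: the genomic intervals it retains, which introns
    are (fully) removed, its stage and any recursive partial gaps."""

    kept: tuple[Interval, ...]
    removed_introns: frozenset[int]
    stage: str
    recursive_introns: tuple[int, ...] = ()
    novel_exon_introns: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.kept)


def simulate_molecules(locus: Locus, config: SimConfig,
                       rng: np.random.Generator) -> list[Molecule]:
    """Draw a molecule pool from the configured stage mixture."""
    model = locus.model
    n_in = model.n_introns
    order = config.removal_order()
    span = model.span
    probs = [config.mix_unspliced, config.mix_partial, config.mix_mature]
    stages = rng.choice(3, size=config.n_molecules, p=probs)

    molecules = []
    for stage_idx in stages:
        stage = STAGES[stage_idx]
        if stage == "unspliced":
            removed: set[int] = set()
        elif stage == "mature":
            removed = set(range(1, n_in + 1))
        else:
            k = int(rng.integers(1, n_in)) if n_in > 1 else 1
            removed = set(order[:k])
        for i in list(removed):
            r = config.retention.get(i, 0.0)
            if r and rng.random() < r:
                removed.discard(i)
        removed_ivals = [model.intron(i) for i in removed]
        for ex, rate in config.exon_skip.items():
            if 1 < ex < model.n_exons and rate and \
                    {ex - 1, ex} <= removed and rng.random() < rate:
                removed_ivals.append(model.exon(ex))
        rec_hits = []
        for spec in config.recursive:
            if spec.intron not in removed and rng.random() < spec.usage:
                removed_ivals.append(
                    _intron_prefix(model, spec.intron, spec.acceptor_offset)
                )
                rec_hits.append(spec.intron)
        novel_hits = []
        for spec in config.novel_exons:
            if spec.intron not in removed and rng.random() < spec.usage:
                iv = model.intron(spec.intron)
                removed_ivals.append(
                    _intron_sub(model, spec.intron, 0, spec.start_offset)
                )
                g2_start = spec.start_offset + spec.length
                removed_ivals.append(
                    _intron_sub(model, spec.intron, g2_start,
                                (iv[1] - iv[0]) - g2_start)
                )
                novel_hits.append(spec.intron)
        kept = _subtract(span, sorted(removed_ivals))
        molecules.append(
            Molecule(tuple(kept), frozenset(removed), stage,
                     tuple(rec_hits), tuple(novel_hits))
        )
    return molecules


def _subtract(span: Interval, removed: Sequence[Interval]) -> list[Interval]:
    kept = []
    pos = span[0]
    for s, e in removed:
        if s > pos:
            kept.append((pos, s))
        pos = max(pos, e)
    if pos < span[1]:
        kept.append((pos, span[1]))
    return kept


def _mol_blocks(kept: Sequence[Interval], cum: np.ndarray, a: int,
                b: int) -> list[Interval]:
    """Map molecule coordinates [a, b) onto genomic blocks."""
    blocks = []
    i = int(np.searchsorted(cum, a, side="right")) - 1
    pos = a
    while pos < b:
        seg_s, seg_e = kept[i]
        off = pos - int(cum[i])
        take = min(b - pos, (seg_e - seg_s) - off)
        blocks.append((seg_s + off, seg_s + off + take))
        pos += take
        i += 1
    return blocks


# independent truth labeling: per-base feature codes instead of interval
# arithmetic, and a literal copy of the documented decision table
def _feature_map(model: GeneModel) -> np.ndarray:
    lo, hi = model.span
    fmap = np.zeros(hi - lo, dtype=np.int32)
    for i, (s, e) in enumerate(model.exons, start=1):
        fmap[s - lo:e - lo] = i
    for i, (s, e) in enumerate(model.introns, start=1):
        fmap[s - lo:e - lo] = -i
    return fmap


def _truth_label(blocks: Sequence[Interval], model: GeneModel,
                 fmap: np.ndarray) -> tuple[str, tuple[int, ...]]:
    """(kind, exon indices) of one end, from per-base feature codes."""
    lo, hi = model.span
    for s, e in blocks:
        if s < lo or e > hi:
            return "outside", ()
    if len(blocks) == 1:
        codes = set(np.unique(fmap[blocks[0][0] - lo:blocks[0][1] - lo]))
        if all(c > 0 for c in codes) and len(codes) == 1:
            return "ex", (int(codes.pop()),)
        if all(c < 0 for c in codes) and len(codes) == 1:
            return "int", ()
        return "ex-int", ()
    intron_set = set(model.introns)
    for a, b in zip(blocks, blocks[1:]):
        if (a[1], b[0]) not in intron_set:
            return "other", ()
    exon_codes = []
    for s, e in blocks:
        codes = set(np.unique(fmap[s - lo:e - lo]))
        if any(c <= 0 for c in codes):
            return "other", ()
        exon_codes.extend(int(c) for c in codes)
    return "ex-ex", tuple(exon_codes)


_TRUTH_TABLE = {
    # sorted label pair -> (category within, category outside)
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


def _truth_category(k1: str, k2: str, within: bool, same_exon: bool) -> str:
    if "other" in (k1, k2) or "outside" in (k1, k2):
        return "unclassified"
    pair = tuple(sorted((k1, k2)))
    if pair == ("ex", "ex"):
        return "unknown" if same_exon else "post"
    w, o = _TRUTH_TABLE[pair]
    return w if within else o


@dataclass
class SimSample:
    locus: Locus
    molecules: list[Molecule]
    sam_path: Path
    truth: pd.DataFrame
    truth_path: Path


def simulate_reads(locus: Locus, molecules: Sequence[Molecule],
                   config: SimConfig, rng: np.random.Generator,
                   out_dir: str | Path, sample: str = "sample",
                   expected_distance: int = 650,
                   large_distance: int = 650) -> SimSample:
    """Sample read pairs from the molecule pool, write a coordinate-sorted
    SAM and the truth table (TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = locus.model
    fmap = _feature_map(model)
    seq = locus.sequence
    rl = config.read_length

    lengths = np.array([m.length for m in molecules], dtype=float)
    probs = lengths / lengths.sum()
    mol_idx = rng.choice(len(molecules), size=config.n_pairs, p=probs)

    records = []   # (pos, qname, flag, cigar, blocks, mate_pos, tlen)
    truth_rows = []
    n_resampled = 0
    for p, mi in enumerate(mol_idx):
        mol = molecules[mi]
        mol_len = mol.length
        frag = 0
        for _ in range(50):
            frag = int(round(rng.normal(config.fragment_mean,
                                        config.fragment_sd)))
            if config.fragment_min <= frag <= mol_len:
                break
        else:
            n_resampled += 1
            frag = min(mol_len, max(config.fragment_min, 2 * rl))
            frag = min(frag, mol_len)
        start = int(rng.integers(0, mol_len - frag + 1))
        cum = np.cumsum([0] + [e - s for s, e in mol.kept[:-1]])
        rl1 = min(rl, frag)
        rl2 = min(rl, frag)
        b1 = _mol_blocks(mol.kept, cum, start, start + rl1)
        b2 = _mol_blocks(mol.kept, cum, start + frag - rl2, start + frag)
        qname = f"sim{p:07d}"

        k1, ex1 = _truth_label(b1, model, fmap)
        k2, ex2 = _truth_label(b2, model, fmap)
        left1, right1 = b1[0][0], b1[-1][1]
        left2, right2 = b2[0][0], b2[-1][1]
        dist = max(0, left2 - right1) if left2 >= left1 \
            else max(0, left1 - right2)
        same_exon = (k1 == k2 == "ex" and ex1 == ex2)
        category = _truth_category(k1, k2, dist < expected_distance, same_exon)
        truth_rows.append(
            {
                "name": qname,
                "molecule": int(mi),
                "stage": mol.stage,
                "introns_removed": ",".join(
                    str(i) for i in sorted(mol.removed_introns)
                ),
                "recursive_introns": ",".join(
                    str(i) for i in mol.recursive_introns
                ),
                "category": category,
                "distance": dist,
                "large": dist >= large_distance,
                "gaps1": _fmt_gaps(b1),
                "gaps2": _fmt_gaps(b2),
            }
        )
        outer_left = min(left1, left2)
        outer_right = max(right1, right2)
        tlen = outer_right - outer_left
        records.append((left1, qname, 99, b1, left2, tlen))
        records.append((left2, qname, 147, b2, left1, -tlen))

    # singleton noise gaps: unpaired split reads at random intra-intronic
    # positions, one read each
    for j in range(config.noise_gaps):
        intron = int(rng.integers(1, model.n_introns + 1))
        s, e = model.intron(intron)
        ilen = e - s
        if ilen < 120:
            continue
        gap_len = int(rng.integers(40, min(400, ilen - 60)))
        gs = int(rng.integers(s + 25, e - gap_len - 25))
        b = [(gs - 20, gs), (gs + gap_len, gs + gap_len + 20)]
        records.append((b[0][0], f"noise{j:04d}", 0, b, -1, 0))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": config.chrom, "LN": len(seq)}],
        }
    )
    sam_path = out_dir / f"{sample}.sam"
    mismatch = config.mismatch_rate
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for pos, qname, flag, blocks, mate_pos, tlen in sorted(
                records, key=lambda r: (r[0], r[1], r[2])):
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            cigar = []
            for bi, (bs, be) in enumerate(blocks):
                if bi:
                    cigar.append((3, bs - blocks[bi - 1][1]))
                cigar.append((0, be - bs))
            a.cigartuples = cigar
            bases = "".join(seq[bs:be] for bs, be in blocks)
            if mismatch > 0:
                arr = np.array(list(bases))
                hits = rng.random(len(arr)) < mismatch
                if hits.any():
                    arr[hits] = rng.choice(_BASES, int(hits.sum()))
                    bases = "".join(arr)
            a.query_sequence = bases
            a.query_qualities = pysam.qualitystring_to_array("I" * len(bases))
            if flag & 0x1:
                a.next_reference_id = 0
                a.next_reference_start = mate_pos
                a.template_length = tlen
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            out.write(a)

    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / f"{sample}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimSample(locus, list(molecules), sam_path, truth, truth_path)


def _fmt_gaps(blocks: Sequence[Interval]) -> str:
    gaps = [f"{a[1]}:{b[0]}" for a, b in zip(blocks, blocks[1:])]
    return ";".join(gaps)


def simulate_sample(config: SimConfig, out_dir: str | Path,
                    sample: str = "sample") -> SimSample:
    """Simulate locus + molecules + reads for one sample; the locus
    depends only on ``locus_seed`` so samples differing only in ``seed``
    share a byte-identical locus."""
    locus = simulate_locus(config, out_dir)
    rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(locus, config, rng)
    return simulate_reads(locus, molecules, config, rng, out_dir, sample)


def simulate_samples(config: SimConfig, out_dir: str | Path,
                     n_samples: int, base_seed: int | None = None
                     ) -> list[SimSample]:
    """Simulate several samples of one locus, with per-sample seeds
    ``base_seed + k`` (default: ``config.seed + k``)."""
    base = config.seed if base_seed is None else base_seed
    return [
        simulate_sample(replace(config, seed=(base + k) % 2**31), out_dir,
                        sample=f"sample{k + 1}")
        for k in range(n_samples)
    ]
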