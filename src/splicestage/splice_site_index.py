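"""Splice Site Index (SSI) and per-feature coverage.

For every intron *i* the SSI is computed separately at its 5' and 3'
splice sites from junction/boundary-spanning read ends::

    SSI = ex-ex / (ex-ex + ex-int)

where ``ex-ex`` counts reads split exactly across the annotated
exon_i-exon_{i+1} junction and ``ex-int`` counts contiguous reads
crossing the corresponding exon-intron boundary.  SSI is 1 when the
intron is always spliced out at that site, 0 when it is never spliced,
and NA when no informative reads exist.  A minimal anchor (default 3
bases on each side of the boundary/junction) suppresses one-base
overhang noise; the notion of "spanning" requires the anchor on both
sides.

Median per-base coverage of every exon and intron complements the SSI:
a retained intron shows high coverage together with low SSI5 and SSI3,
exon skipping shows low exon coverage with low SSI3 of the upstream and
low SSI5 of the downstream intron.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .classification import aligned_segments
from .gene_model import GeneModel

DEFAULT_ANCHOR = 3


class InsufficientDataError(ValueError):
    """Too few introns with defined SSI on both sites to rank retention."""


def _iter_read_segments(alignments: str | Path, model: GeneModel):
    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != model.chrom:
                continue
            yield aligned_segments(read)


def count_boundary_reads(alignments: str | Path, model: GeneModel,
                         anchor: int = DEFAULT_ANCHOR) -> pd.DataFrame:
    """Count boundary- and junction-spanning read ends per intron.

    Ends of a pair are counted independently; one end can contribute to
    every distinct site it genuinely spans.  Returns a DataFrame indexed
    by 1-based intron number with columns ``ex_ex``, ``ex_int_5`` and
    ``ex_int_3``.
    """
    n = model.n_introns
    ex_ex = np.zeros(n, dtype=int)
    ex_int_5 = np.zeros(n, dtype=int)
    ex_int_3 = np.zeros(n, dtype=int)

    # 0-based genomic boundary positions (between base b-1 and base b),
    # assigned to the transcription-sense 5'/3' side of each intron
    b5 = []
    b3 = []
    for s, e in model.introns:
        if model.strand == "+":
            b5.append(s)
            b3.append(e)
        else:
            b5.append(e)
            b3.append(s)

    for segments in _iter_read_segments(alignments, model):
        for seg_s, seg_e in segments:
            for i in range(n):
                if seg_s <= b5[i] - anchor and seg_e >= b5[i] + anchor:
                    ex_int_5[i] += 1
                if seg_s <= b3[i] - anchor and seg_e >= b3[i] + anchor:
                    ex_int_3[i] += 1
        for a, b in zip(segments, segments[1:]):
            idx = model.intron_index.get((a[1], b[0]))
            if idx is not None:
                s, e = model.intron(idx)
                if a[0] <= s - anchor and b[1] >= e + anchor:
                    ex_ex[idx - 1] += 1

    return pd.DataFrame(
        {"ex_ex": ex_ex, "ex_int_5": ex_int_5, "ex_int_3": ex_int_3},
        index=pd.RangeIndex(1, n + 1, name="intron"),
    )


def compute_ssi(counts: pd.DataFrame) -> pd.DataFrame:
    """Fill SSI5/SSI3 columns; NA where the denominator is zero.

    Scale-invariant: multiplying all counts by a positive constant leaves
    the SSI values unchanged.
    """
    out = counts.copy()
    for side in ("5", "3"):
        denom = out["ex_ex"] + out[f"ex_int_{side}"]
        out[f"ssi{side}"] = np.where(denom > 0, out["ex_ex"] / denom.where(denom > 0),
                                     np.nan)
    return out


def per_base_depth(alignments: str | Path, model: GeneModel) -> np.ndarray:
    """Per-base read depth over the gene span (aligned blocks only; skip
    gaps contribute nothing; duplicates are kept)."""
    lo, hi = model.span
    depth = np.zeros(hi - lo, dtype=np.int64)
    for segments in _iter_read_segments(alignments, model):
        for s, e in segments:
            s, e = max(s, lo), min(e, hi)
            if s < e:
                depth[s - lo:e - lo] += 1
    return depth


def feature_medians(depth: np.ndarray, model: GeneModel
                    ) -> tuple[pd.Series, pd.Series]:
    """Median per-base depth of every exon and intron (transcription-order
    1-based index)."""
    lo, _ = model.span

    def med(iv):
        s, e = iv
        return float(np.median(depth[s - lo:e - lo]))

    exon_med = pd.Series([med(iv) for iv in model.exons],
                         index=pd.RangeIndex(1, model.n_exons + 1, name="exon"))
    intron_med = pd.Series([med(iv) for iv in model.introns],
                           index=pd.RangeIndex(1, model.n_introns + 1,
                                               name="intron"))
    return exon_med, intron_med


def median_coverage(alignments: str | Path, model: GeneModel
                    ) -> tuple[pd.Series, pd.Series]:
    """Median exon/intron coverage of one sample."""
    return feature_medians(per_base_depth(alignments, model), model)


@dataclass
class SpliceSiteTable:
    """Per-intron junction/boundary counts, SSI values and feature medians."""

    gene_id: str
    sites: pd.DataFrame        # intron-indexed: counts + ssi5/ssi3
    exon_medians: pd.Series
    intron_medians: pd.Series

    @classmethod
    def from_alignments(cls, alignments: str | Path, model: GeneModel,
                        anchor: int = DEFAULT_ANCHOR) -> "SpliceSiteTable":
        counts = count_boundary_reads(alignments, model, anchor)
        sites = compute_ssi(counts)
        exon_med, intron_med = median_coverage(alignments, model)
        return cls(model.gene_id, sites, exon_med, intron_med)

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        out["intron_median"] = self.intron_medians
        out["exon_up_median"] = self.exon_medians.reindex(out.index).values
        out["exon_down_median"] = self.exon_medians.reindex(out.index + 1).values
        return out.reset_index().assign(gene=self.gene_id)


def rank_intron_retention(table: SpliceSiteTable | pd.DataFrame,
                          alpha: float = 0.1,
                          min_defined: int = 3) -> pd.DataFrame:
    """Rank introns by their likelihood of retention.

    The retention magnitude of intron *i* is the joint lowness of its two
    splice-site indices, ``mean(1 - SSI5, 1 - SSI3)`` (a retained intron
    is unspliced at both sites).  The p-value is the empirical fraction of
    the other introns with a magnitude at least as large.  The absolute
    SSI asymmetry ``|SSI5 - SSI3|`` is reported as a separate column since
    it indicates alternative events (e.g. exon skipping) rather than
    retention.  Output is sorted by descending magnitude, ties broken by
    ascending intron index; the top intron is flagged ``candidate`` when
    its p-value is below ``alpha``.
    """
    sites = table.sites if isinstance(table, SpliceSiteTable) else table
    defined = sites.dropna(subset=["ssi5", "ssi3"])
    if len(defined) < min_defined:
        raise InsufficientDataError(
            f"only {len(defined)} introns with defined SSI on both sites "
            f"(need >= {min_defined})"
        )
    mag = ((1 - defined["ssi5"]) + (1 - defined["ssi3"])) / 2.0
    asym = (defined["ssi5"] - defined["ssi3"]).abs()
    pvals = []
    for i in defined.index:
        others = mag.drop(i)
        pvals.append(float((others >= mag[i]).mean()))
    out = pd.DataFrame(
        {
            "intron": defined.index,
            "magnitude": mag.values,
            "asymmetry": asym.values,
            "p_value": pvals,
        }
    )
    out = out.sort_values(["magnitude", "intron"],
                          ascending=[False, True]).reset_index(drop=True)
    top = out["magnitude"].iloc[0]
    out["candidate"] = (
        (out["magnitude"] == top) & (out["p_value"] < alpha) & (out["magnitude"] > 0)
    )
    return out
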