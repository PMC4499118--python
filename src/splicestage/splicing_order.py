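"""Detection of non-sequentially spliced adjacent intron pairs.

Two independent lines of evidence are combined:

* **Coverage-based.** A nascent intron that stays in the transcript
  longer accumulates more coverage; if the downstream intron *i+1* is
  removed before the upstream intron *i*, its median coverage is lower.
  Per sample, the difference ``delta = median(intron_{i+1}) -
  median(intron_i)`` is computed for every adjacent pair, the negative
  deltas are collected, and pairs at or below their first quartile Q1
  (linear-interpolation quantile) are flagged as candidates.

* **Read-based.** A pair with one end split across the junction of
  intron *i* and the mate inside intron *i+1* supports *sequential*
  removal (i before i+1); one end inside intron *i* with the mate split
  across the junction of intron *i+1* supports *non-sequential* removal.
  The splice-ratio ``seq / (seq + non-seq)`` is close to 1 for
  sequentially spliced pairs and close to 0 otherwise.

A pair is called non-sequential when it is a coverage candidate in at
least ``min_samples`` RNA samples, its splice-ratio (where read evidence
exists) stays below the cutoff in those samples, and it is *not* a
coverage candidate in the DNA control (DNA does not splice, so a
coverage difference there marks a technical artifact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ClassificationResult

DEFAULT_RATIO_CUTOFF = 0.5


def adjacent_deltas(intron_medians: pd.Series) -> pd.DataFrame:
    """Median-coverage differences between adjacent introns.

    ``pair`` = i means the (intron_i, intron_{i+1}) pair;
    ``delta = median(intron_{i+1}) - median(intron_i)``.
    """
    med = intron_medians.sort_index()
    n = len(med)
    pairs = np.arange(1, n)
    delta = med.values[1:] - med.values[:-1]
    return pd.DataFrame({"pair": pairs, "delta": delta})


def coverage_candidates(intron_medians: pd.Series,
                        quartile: str = "Q1") -> pd.DataFrame:
    """Flag adjacent pairs whose delta is at or below the quartile cutoff
    of the negative deltas.

    ``quartile`` selects the 25% (Q1, default) or 75% (Q3) percentile of
    the negative deltas, computed with linear interpolation.  With no
    negative deltas the candidate set is empty.
    """
    if quartile not in ("Q1", "Q3"):
        raise ValueError(f"quartile must be 'Q1' or 'Q3', got {quartile!r}")
    df = adjacent_deltas(intron_medians)
    if len(df) < 4:
        warnings.warn(
            f"only {len(df)} adjacent intron pairs; the quartile cutoff is "
            "unstable", stacklevel=2
        )
    neg = df.loc[df["delta"] < 0, "delta"].values
    if len(neg) == 0:
        cutoff = np.nan
        candidate = np.zeros(len(df), dtype=bool)
    else:
        q = 25 if quartile == "Q1" else 75
        cutoff = float(np.percentile(neg, q))
        candidate = (df["delta"] <= cutoff) & (df["delta"] < 0)
    return df.assign(cutoff=cutoff, candidate=candidate)


def splice_ratio(result: ClassificationResult,
                 pair: int) -> tuple[int, int, float]:
    """Sequential/non-sequential read-pair counts and splice-ratio for the
    adjacent intron pair (``pair``, ``pair + 1``).

    Returns ``(seq, nonseq, ratio)``; ratio is NaN when no informative
    pairs exist.
    """
    i, j = pair, pair + 1
    seq = nonseq = 0
    for p in result.pairs:
        for a, b in ((p.end1, p.end2), (p.end2, p.end1)):
            if a.kind == "ex-ex" and i in a.junctions and \
                    b.kind == "int" and b.introns == (j,):
                seq += 1
                break
            if a.kind == "int" and a.introns == (i,) and \
                    b.kind == "ex-ex" and j in b.junctions:
                nonseq += 1
                break
    total = seq + nonseq
    ratio = seq / total if total else float("nan")
    return seq, nonseq, ratio


def evidence_table(result: ClassificationResult,
                   intron_medians: pd.Series,
                   quartile: str = "Q1") -> pd.DataFrame:
    """Per-adjacent-pair order evidence of one sample: coverage delta with
    Q1 candidacy plus read-based counts and splice-ratio."""
    cov = coverage_candidates(intron_medians, quartile)
    seqs, nonseqs, ratios = [], [], []
    for pair in cov["pair"]:
        s, ns, r = splice_ratio(result, int(pair))
        seqs.append(s)
        nonseqs.append(ns)
        ratios.append(r)
    return cov.assign(seq=seqs, nonseq=nonseqs, ratio=ratios)


@dataclass
class OrderCalls:
    """Cross-sample non-sequential splicing calls plus the correlation
    between the coverage- and read-based evidence."""

    calls: pd.DataFrame
    pearson_r: float
    spearman_r: float


def call_nonsequential(samples: Mapping[str, pd.DataFrame],
                       control: pd.DataFrame | None = None, *,
                       min_samples: int,
                       ratio_cutoff: float = DEFAULT_RATIO_CUTOFF) -> OrderCalls:
    """Combine per-sample evidence tables into final non-sequential calls.

    A pair is called when (a) it is a coverage candidate in at least
    ``min_samples`` RNA samples, (b) in every flagged sample that has read
    evidence the splice-ratio is below ``ratio_cutoff`` (the requirement
    is waived for samples without informative read pairs), and (c) it is
    not a coverage candidate in the DNA control.
    """
    if min_samples > len(samples):
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of RNA samples "
            f"({len(samples)})"
        )
    names = list(samples)
    pairs = sorted(set().union(*(set(df["pair"]) for df in samples.values())))
    control_flagged = set()
    if control is not None:
        control_flagged = set(control.loc[control["candidate"], "pair"])

    rows = []
    for pair in pairs:
        n_flagged = 0
        ratio_ok = True
        per_sample = {}
        for name in names:
            df = samples[name]
            row = df.loc[df["pair"] == pair]
            if row.empty:
                continue
            row = row.iloc[0]
            per_sample[name] = row
            if row["candidate"]:
                n_flagged += 1
                if row["seq"] + row["nonseq"] > 0 and not (
                        row["ratio"] < ratio_cutoff):
                    ratio_ok = False
        control_flag = pair in control_flagged
        called = n_flagged >= min_samples and ratio_ok and not control_flag
        rec = {"pair": pair, "n_flagged": n_flagged,
               "control_flag": control_flag, "called": called}
        for name in names:
            row = per_sample.get(name)
            rec[f"delta_{name}"] = row["delta"] if row is not None else np.nan
            rec[f"ratio_{name}"] = row["ratio"] if row is not None else np.nan
        rows.append(rec)
    calls = pd.DataFrame(rows)

    # correlation between the two evidence types, pooled over samples
    deltas, ratios = [], []
    for df in samples.values():
        ok = df.dropna(subset=["ratio"])
        deltas.extend(ok["delta"])
        ratios.extend(ok["ratio"])
    if len(deltas) >= 2 and np.std(deltas) > 0 and np.std(ratios) > 0:
        pearson = float(stats.pearsonr(deltas, ratios).statistic)
        spearman = float(stats.spearmanr(deltas, ratios).statistic)
    else:
        pearson = spearman = float("nan")
    return OrderCalls(calls, pearson, spearman)
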