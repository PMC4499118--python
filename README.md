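# splicestage

Splicing-stage analysis of nuclear pre-mRNA RNA-seq.

Standard RNA-seq pipelines analyze the *end product* of splicing: they
work from exonic and junction reads and cannot handle the mixtures of
pre-mRNA and mature mRNA found in nuclear RNA extracts. `splicestage`
is built for exactly those mixtures. From a coordinate-sorted paired-end
alignment (SAM/BAM, split reads encoded as CIGAR `N` operations) and a
gene annotation (Ensembl-dialect GTF), it:

1. **classifies read pairs by splicing stage.** Each aligned end is
   labeled `ex` (exonic), `int` (intronic), `ex-int` (exon–intron
   boundary) or `ex-ex` (annotated exon–exon junction); the label pair
   plus the inner mapping distance between the ends assigns the pair to
   the *pre-*, *intermediate-* or *post-splicing* category (or
   *unknown* when both ends sit in one exon, which is uninformative);

2. **computes the Splice Site Index** per intron *i*, separately at its
   5′ and 3′ splice sites:

   SSI = ex–ex / (ex–ex + ex–int)

   where *ex–ex* counts reads split exactly across the annotated
   junction and *ex–int* counts contiguous reads crossing the
   corresponding exon–intron boundary. SSI = 1 means the site is always
   spliced, 0 never; low SSI⁵ and SSI³ on the same intron together with
   high intron coverage indicate retention, and a ranking module scores
   introns for retention likelihood;

3. **infers the local order of intron removal** from two independent
   signals: median-coverage differences between adjacent introns
   (delta = median(intron_{i+1}) − median(intron_i), with a first-quartile
   cutoff over the negative deltas) and the read-based *splice-ratio*
   seq/(seq + non-seq) from pairs linking one intron to its neighbor's
   junction. Calls require consistency across samples and survival of a
   DNA negative control (DNA does not splice, so DNA coverage
   differences mark technical artifacts);

4. **detects recursive (multi-step) splicing**: the *inverted coverage*
   of split-read gaps (annotated junctions excluded) is differentiated,
   signed peaks mark split starts/ends, cross-sample consensus peaks are
   re-connected into a donor × acceptor junction matrix, events are
   typed (5′-recursive / 3′-recursive / inner), GT/AG motif canonicality
   is scored from the genome FASTA, and between-peak intervals with
   elevated coverage are flagged as putative novel exons and removed
   from the recursive list.

A synthetic-data module generates a configurable multi-intron locus and
paired-end reads from mixtures of splicing intermediates (unspliced /
partially spliced in an arbitrary order / recursive / mature, with
retention, exon skipping and cryptic exons), together with a per-pair
truth table — so the whole pipeline is testable without downloads.

## Worked example

```python
from splicestage import (SimConfig, simulate_sample, classify_sample,
                         SpliceSiteTable)

cfg = SimConfig(n_pairs=10_000, seed=7)          # 30/40/30 unspliced/partial/mature
sample = simulate_sample(cfg, "demo", sample="nuclear1")
model = sample.locus.model

result = classify_sample(sample.sam_path, model)
print(result.summary().to_string(index=False))

table = SpliceSiteTable.from_alignments(sample.sam_path, model)
print(table.sites.round(3).to_string())
```

prints

```
  sample     category  count  fraction  large_count
nuclear1          pre   8713    0.8713           37
nuclear1 intermediate     97    0.0097           13
nuclear1         post   1190    0.1190          773
nuclear1      unknown      0    0.0000            0
nuclear1 unclassified      0    0.0000            0
        ex_ex  ex_int_5  ex_int_3   ssi5   ssi3
intron
1         186        79       108  0.702  0.633
2         290       154       159  0.653  0.646
3         275       184       199  0.599  0.580
4         233       242       230  0.491  0.503
5         204       263       296  0.437  0.408
6          83       303       159  0.215  0.343
```

The pre-splicing fraction (87%) reflects the intron-rich nuclear-like
mixture (long unspliced molecules contribute most fragments), and the
SSI profile decreases from intron 1 to intron 6: under sequential
5′→3′ removal, downstream introns are spliced in fewer molecules at any
snapshot, so fewer of their boundary-spanning reads are junction reads.

The same stages are available from the shell:

```bash
splicestage simulate --out demo --seed 7 --name nuclear1
splicestage classify demo/nuclear1.sam --gtf demo/annotation.gtf \
    --gene GENE1 --out classification.tsv
splicestage run run_config.yaml        # full multi-sample pipeline
```

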