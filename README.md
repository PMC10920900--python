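# splicefate

Variant effect prediction through splicing: given a gene model, a
variant, per-nucleotide splice-site probabilities, and a per-residue
conservation track, `splicefate` predicts missplicing events,
reconstructs the aberrant mature transcripts and proteins they imply,
and scores the variant by how much its predicted proteome diverges from
the reference in evolutionarily conserved regions. It also implements
the cohort-level statistics used to validate such scores: permutation
depletion tests, exact hypergeometric tails, mutation-volume-controlled
gene overrepresentation, driver enrichment, and PPV/ROC benchmarking.

It is written for computational biologists triaging large somatic or
clinical variant sets — in particular the apparently silent variants
(intronic, synonymous, UTR) whose effect runs through splicing rather
than through the amino-acid sequence.

## Model

1. **Events.** A pluggable engine assigns each nucleotide donor and
   acceptor probabilities for the reference and mutant sequence. Within
   ±2,500 nt of the variant, an annotated site whose probability drops
   by ≥ 0.5 is *missed*; an unannotated position that rises by ≥ 0.5 is
   *discovered* (cryptic). Indels are compared through a coordinate map
   (deleted bases vs 0; inserted bases reported as anchor+offset).
2. **Isoforms.** Surviving plus discovered sites form a 5'→3' pool;
   candidate transcripts are all alternating donor→acceptor chains under
   a greedy rule set (same-type sites never connect; adjacent same-type
   sites are exclusive branch options; paths start with a donor and end
   with an acceptor). Novel exons > 2,000 nt discard the isoform.
3. **Proteins.** The reference start codon is reused if it survives
   intact; otherwise a Kozak-context scorer (or any plugged-in
   predictor) picks a new AUG. The stop is the first in-frame
   terminator; nonstop transcripts are flagged.
4. **Score.** One global alignment (match +1, mismatch −1, gap open −3,
   gap extend 0, free C-terminal gaps) yields insertion/deletion events.
   With c(i, W) the windowed, max-normalized conservation of the
   reference protein (W = 75 residues), a deletion of length Dw adds
   max(1, Dw/W)·c(j, W) at each deleted residue j, an insertion of
   length Iw adds max(1, Iw/W)·c(anchor, W); a sliding window of length
   W sums the contributions and the score is the maximum of that penalty
   vector, S_pathogenicity = max_i S(i). Gene level is weakest-link:
   mean over a transcript's isoforms, max over transcripts. The top 5%
   of event-positive variants are called deleterious.

A deterministic PWM engine (consensus donor/acceptor motifs + logistic)
stands in for a neural predictor at toy scale, and a fixture module
generates genes, conservation tables, and variant cohorts with known
ground truth in standard formats (FASTA/GTF/VCF/TSV). See
`docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

`examples/01_score_a_missplicing_variant.py` builds a three-intron toy
gene, breaks the GT of its first donor with an SNV, and scores it:

```
gene G00 (+ strand), variant ctg1:262T>A
  event: missed_donor at gene-local 160 (p 0.99 -> 0.21, delta -0.78)
  isoform 0: 3 exons, 937 nt, protein 55 aa, divergence 36.1
  gene-level score (mean over isoforms, max over transcripts): 36.1
```

The donor loss retains the first intron, the reading frame hits an early
stop (a 225-aa protein collapses to 55 aa), and the truncation overlaps
conserved sequence, giving a positive divergence score; a variant with
no events scores 0. The other examples cover cohort statistics
(`02`, printing a depletion null mean ≈ 420 and exact hypergeometric
tail 2.57e-16 for the stated counts), synthetic-cohort benchmarking
(`03`), and file-based I/O plus the CLI (`04`).

A thin command line wraps the same API:

```bash
splicefate fixtures generate --seed 3 --out fixtures/
splicefate score --genome fixtures/genome.fa --gtf fixtures/annotation.gtf \
    --vcf fixtures/variants.vcf --conservation fixtures/conservation \
    --gene G00 --out results/
```

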