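# Methods

`splicefate` models the consequence chain of a single genomic variant
through splicing: probability tracks → missplicing events → candidate
mature transcripts → proteins → a conservation-weighted divergence score
→ cohort statistics. This note records the model, its assumptions, the
tunable parameters, and the design choices made where the design was
genuinely open.

## Coordinate model

All internal coordinates are 0-based, half-open, on the gene's sense
strand; position 0 is the 5' end of the pre-mRNA regardless of genomic
strand. GTF (1-based inclusive) and VCF (1-based, anchor-base indel
convention) are converted at the I/O boundary. A donor site is the first
intronic base (the G of the GU motif) and an acceptor the last intronic
base (the G of AG), so an intron is the inclusive interval
`[donor, acceptor]`. Indels are applied on the plus-strand genomic frame,
where the VCF anchor convention is defined, and flipped back to the sense
frame, so both strands behave identically. The mutant↔reference
coordinate map is total: deleted reference bases map to nothing, inserted
mutant bases are addressed as (nearest upstream mapped base, offset).
Variants whose analysis window would extend past the gene are analyzed
with the window clamped to the available sequence.

## Probability engines and event detection

An engine is any deterministic function from a nucleotide sequence to two
per-base probability tracks (donor, acceptor). Production-scale neural
predictors plug in through `register_engine`; the package ships a
synthetic position-weight-matrix engine used by the tests and the
fixture generator. It scores a 9-nt donor context (consensus
`CAG|GTAAGT`, the GT dinucleotide dominating the weight mass) and a 23-nt
acceptor context (18-nt polypyrimidine tract + `CAG|GA`, the AG
dominating), each squashed through a logistic, so consensus sites score
~0.98, one broken core dinucleotide drops a site below ~0.35, and random
background stays well under 0.5. The engine needs 20 nt of flanking
context and is seed-free.

Detection compares reference and mutant tracks position-wise through the
coordinate map within ±`window_radius` (default 2,500 nt) of the
variant. A drop of at least `threshold` (default 0.5; 0.25 is the
sensitive preset for RNA-seq comparisons) at an annotated site is a
*missed* site; a rise of at least `threshold` at an unannotated position
is a *discovered* (cryptic) site. Deleted reference positions are
compared against probability 0, and inserted mutant positions against
reference probability 0 (reported via anchor+offset). Unannotated
positions already strong in the reference cannot be assessed and are
never reported as discovered; this exclusion uses a fixed
`ref_site_cutoff` of 0.5 rather than the detection threshold itself so
that lowering the threshold can only add events (monotonicity) —
otherwise the 0.25 preset would paradoxically drop events that the 0.5
setting reports.

## Isoform construction

Surviving annotated sites (annotated minus missed, carried into the
mutant frame) plus discovered sites form a 5'→3' pool. Candidate
transcripts are the alternating donor→acceptor chains produced by a
greedy walk: sites connect sequentially 5'→3'; same-type sites never
connect; a maximal run of same-type sites with no opposite-type site
between them ("adjacent" sites) is a set of equal but mutually exclusive
branch options; a path must start with a donor and end with an acceptor,
so a leading acceptor run is skipped and a trailing unmatched donor is
dropped (the final exon runs to the transcript end). Because runs
strictly alternate, every path uses exactly one member per interior run
and the path count is bounded by the product of run lengths. Enumeration
is capped at `max_isoforms` (default 64) in deterministic 5'→3'
branching order; an empty pool yields the single unspliced path (full
intron retention). Discovered sites outside the annotated transcript
span are not used — paths stay within the transcript's boundaries.

Assembly removes each intron inclusively and concatenates the remaining
exons. An exon absent from the reference exon set and longer than
`max_novel_exon` (default 2,000 nt — fewer than 1% of annotated human
exons are longer) marks the isoform as discarded: it is reported but
excluded from scoring, reflecting the low biological plausibility of
such transcripts surviving decay.

## Translation model

The reference start codon is reused when it survives contiguously in the
mature transcript — all three bases present, adjacent across any novel
junction, and still ATG ("disturbed" is operationalized as the negation
of exactly that). Otherwise a pluggable start-site predictor chooses an
AUG; the default scores every AUG in the 5'-most 500 nt by a Kozak
position-weight profile (the −3 purine and +4 G dominating), ties
breaking 5'-most. An upstream fallback AUG is permitted and the choice is
recorded. The stop is the first in-frame canonical terminator; absent
one, the transcript is flagged `nonstop` and translated to the last full
codon. Internal N codons translate to X. mRNA decay (NMD) is *not*
modeled as a filter: premature stops and nonstop states are annotations
only. A transcript with no AUG yields no protein and is scored as a full
loss (below).

## Divergence scoring

One optimal global pairwise alignment is computed per candidate protein
(Biopython `PairwiseAligner`): match +1, mismatch −1, gap open −3, gap
extend 0, and gaps at the C-terminal ends free, so truncations are
visible as events without wrecking the alignment. These parameters
suppress ad-hoc gap scatter; the gap events extracted from the alignment
are the scored objects. Mismatches are extracted and reported but carry
no penalty — the score measures insertion/deletion-driven loss.

Per-residue evolutionary rates (Rate4Site convention: higher = faster
evolving) are converted to conservation `C(j) = max(r) − r_j`, which is
non-negative with "conserved = large" as the normalization requires; the
rate tables themselves never state this transform, so it is fixed here
once. `C` is smoothed by a windowed mean of length `W` and normalized by
the maximal windowed mean, giving `c(i, W) ∈ [0, 1]` with max exactly 1;
a constant track degenerates to `c ≡ 1`, and windows clamp at the
protein's edges (mean over present positions). `W` defaults to 75
residues, a typical protein-domain length (median of annotated domain
lengths). Even/odd handling: the window spans `floor(W/2)` residues on
each side of the center.

A deletion of length `Dw` contributes `max(1, Dw/W) · c(j, W)` at every
deleted reference residue `j` (default *per-position* attribution; an
*anchor* mode contributing once per event sits behind a config switch —
per-position is the default because only the summed form produces scores
on the scale the window sum implies for large truncations). An insertion
of length `Iw` contributes `max(1, Iw/W) · c(anchor, W)` at the residue
preceding the inserted block. A sliding window of length `W` sums these
contributions into the penalty vector `S`, over reference coordinates,
and the divergence score is `max_i S(i)`. For uniform conservation and a
single deletion this closes to `min(W, Dw) · max(1, Dw/W)`, which the
tests verify for `Dw` = 1…300. An unchanged protein scores exactly 0.

Aggregation is weakest-link: the mean over a transcript's viable
(non-discarded) isoforms, then the max over transcripts — a variant is
described by the most dysfunctional protein ensemble it can generate.
When every isoform of every transcript is discarded, the result is
flagged `no-viable-isoform` rather than silently scored.

Score scale: absolute thresholds on this score depend on the
conservation transform and attribution mode, so deleterious calls are
made by cohort percentile (default: top 5% of event-positive variants);
an absolute-threshold mode is available for calibrated settings.

## Cohort statistics

Depletion of population-observed variants in a predicted subset is
tested by permutation — draw subsets of the observed size uniformly
without replacement (sampled as hypergeometric counts, which is the same
distribution), p-value the fraction of draws with an equal or smaller
flagged count — and exactly, by the hypergeometric lower tail evaluated
in a numerically stable form. Permutation p-values use the add-one
convention `(extreme + 1)/(iterations + 1)` so they are never 0 and are
conservative (super-uniform) under the null; a floored result displays
as `<1/iterations`. Enrichment tests are one-sided upper tail.

Gene-level overrepresentation controls for mutation-volume bias: genes
are split into 5 rank-based quantile bins by unique-mutation count (ties
broken by gene id for determinism), sorted within bins by the
missplicing or deleterious ratio, and the top `⌈top_percent · bin⌉` of
each bin unioned. Driver enrichment of a selected set uses permutation
draws of equal-size gene sets plus the exact upper tail. Benchmarking
computes PPV at incremental score percentiles (ambiguous labels excluded
from the denominator) and ROC/AUC over pathogenic-vs-benign labels.
Survival-group construction (affected = ≥1 deleterious variant in a gene
set; unaffected = no missplicing variant in that set; optional
mutation-volume percentile matching) emits a two-column patient table;
the Kaplan–Meier fit itself is standard and delegated to survival
libraries.

## Synthetic fixtures

The fixture generator emulates the structural conditions the pipeline
needs — not realistic human sequence statistics. Defaults: a handful of
genes with 3–5 exons of 120–240 nt and introns of 150–300 nt, alternating
strands; consensus motifs at every annotated junction; a planted
Kozak/ATG in exon 1 and a planted stop in the last exon with intermediate
in-frame stops edited out (edits always to C, which can never create a
stop, and never inside a planted motif); "broken" cryptic motifs one
substitution from consensus planted mid-intron; conservation either
uniform or with 0.2-rate domains of 40–75 residues on a rate-1.0
background. Cohorts mix site-destroying SNVs (break a GT/AG), site-
creating SNVs (repair a broken motif), and neutral controls re-drawn at
generation time until they produce zero detection events. Everything is
a pure function of spec + seed; identical specs give byte-identical
files, written in the same FASTA/GTF/VCF/TSV formats the pipeline reads
so the I/O paths are exercised.

What passing tests therefore show: the machinery — coordinates, event
logic, enumeration, translation, scoring, statistics — is correct on
inputs whose ground truth is known exactly. What they do not show:
performance under a learned probability engine on real genomes, where
site strength, context effects, and annotation noise are far richer than
a PWM.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: toy genes of
1–3 kb, cohorts of 100–200 variants, permutation tests at 1,000
iterations (10,000 where a mean-convergence check needs it), oracle
sweeps of 500–1,000 random instances. Probability comparisons use exact
inclusive thresholds (`delta ≤ −θ`, `delta ≥ +θ`; a single inclusive
convention since prose "or more"/"more than" conflict); alignment
co-optimal ties are resolved by taking the aligner's first reported
alignment, which is deterministic; enumeration truncation order, bin tie
breaks, and TIS ties are all deterministic as described above. The
divergence of an empty variant protein is computed without running the
aligner (single full-length deletion).

## Known limitations

- Single-variant analysis only; co-occurring variants in one gene are
  not modeled jointly.
- No isoform abundance or likelihood estimates; all enumerated paths are
  equally weighted in the per-transcript mean.
- No NMD efficiency model; truncation severity enters only through the
  deletion penalty.
- Non-AUG starts and selenocysteine are out of scope.
- The synthetic engine is a testing instrument, not a splice-site
  predictor for real sequence.
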