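"""Score one splice-site-destroying SNV end to end.

Builds a toy multi-exon gene whose junctions carry consensus motifs,
introduces an SNV that breaks the GT dinucleotide of the first donor,
and runs the full pipeline: event detection, isoform reconstruction,
translation, and conservation-weighted divergence scoring.
"""

from splicefate import FixtureSpec, Variant, generate_toy_gene, score_variant

toy = generate_toy_gene(FixtureSpec(seed=1), 0)
gene = toy.gene
donor = min(gene.primary_transcript.donors)
variant = Variant(gene.contig, gene.genomic_start + donor + 1, "T", "A")

conservation = {tid: df["rate"].to_numpy() for tid, df in toy.conservation.items()}
report = score_variant(gene, variant, conservation)

print(f"gene {gene.gene_id} ({gene.strand} strand), variant {variant.id_string()}")
for e in report.events:
    print(f"  event: {e.kind} at gene-local {e.ref_position} "
          f"(p {e.ref_p:.2f} -> {e.mut_p:.2f}, delta {e.delta:+.2f})")
for iso in report.isoforms:
    n_aa = len(iso.translation.protein) if iso.translation else 0
    print(f"  isoform {iso.isoform_index}: {len(iso.mature.exons)} exons, "
          f"{len(iso.mature.sequence)} nt, protein {n_aa} aa, "
          f"divergence {iso.score:.1f}")
print(f"  gene-level score (mean over isoforms, max over transcripts): "
      f"{report.score:.1f}")
print("A positive score means the aberrant proteome diverges from the "
      "reference in conserved regions; 0 means no functional change.")
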