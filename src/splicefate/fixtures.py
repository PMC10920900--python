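"""Deterministic synthetic fixtures: toy genes, conservation, variant cohorts.

Every generator is a pure function of a :class:`FixtureSpec` (seed
included), so identical specs produce byte-identical FASTA/GTF/VCF/TSV
output.  Toy genes carry consensus donor/acceptor motifs recognized by
the synthetic probability engine, a planted Kozak/ATG start, a clean ORF
(no premature in-frame stops) ending at a planted stop codon, and
"broken" cryptic motifs one substitution away from consensus.  Cohorts
mix three variant classes with known ground truth: site-destroying SNVs
(break the GT/AG of an annotated site), site-creating SNVs (complete a
broken cryptic motif), and neutral SNVs verified at generation time to
produce no detection events.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import DetectionConfig, detect_missplicing
from .engine import SyntheticPWMEngine, engine_predict
from .errors import InputError
from .genome import (
    CoordinateMap,
    GeneModel,
    TranscriptAnnotation,
    Variant,
    apply_variant,
    reverse_complement,
)
from .isoforms import SplicePath, assemble_transcript
from .translate import locate_tts, translate

_PAD = 100  # plain background padding between the gene and the contig ends


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a small but structurally complete cohort: a handful
    of multi-exon genes on both strands, domain-structured conservation,
    and a cohort in which roughly a third of variants destroy an
    annotated site, a third create a cryptic site, and a third are
    neutral controls.
    """

    seed: int = 0
    n_genes: int = 6
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (120, 240)
    intron_length: tuple[int, int] = (150, 300)
    planted_cryptic_rate: float = 0.35   # fraction of variants creating a site
    planted_destroy_rate: float = 0.35   # fraction destroying an annotated site
    planted_site_strength: float = 0.9   # minimum engine probability of planted sites
    conservation_profile: str = "domain-peaks"  # or "uniform"
    n_patients: int = 20
    mutations_per_patient: int = 5
    cryptic_candidates_per_gene: int = 4

    def __post_init__(self) -> None:
        if self.exon_length[0] < 60 or self.intron_length[0] < 100:
            raise InputError("exons must be >= 60 nt and introns >= 100 nt "
                             "to hold planted motifs, start and stop contexts")
        if self.exons_per_gene[0] < 2:
            raise InputError("toy genes need at least 2 exons")
        if self.planted_cryptic_rate + self.planted_destroy_rate > 1.0:
            raise InputError("planted variant fractions exceed 1")
        if self.conservation_profile not in {"uniform", "domain-peaks"}:
            raise InputError(f"unknown conservation profile {self.conservation_profile!r}")


@dataclass(frozen=True)
class CrypticCandidate:
    """A planted near-consensus motif one SNV away from a strong site."""

    site_kind: str          # donor | acceptor
    site_position: int      # gene-local sense position of the would-be site
    fix_position: int       # gene-local sense position of the activating SNV
    fix_ref: str
    fix_alt: str


@dataclass
class ToyGene:
    gene: GeneModel
    contig_sequence: str            # plus-strand contig, padded
    cryptic_candidates: list[CrypticCandidate]
    conservation: dict[str, pd.DataFrame] = field(default_factory=dict)
    protein: str = ""


_ENGINE = SyntheticPWMEngine()
_STOPS = ("TAA", "TAG", "TGA")


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _write_motif(seq: list[str], start: int, motif: str) -> None:
    seq[start : start + len(motif)] = list(motif)


def generate_toy_gene(spec: FixtureSpec, gene_index: int = 0) -> ToyGene:
    """Build one toy gene: sequence, annotation, conservation, cryptic motifs.

    Genes alternate strand with their index.  Annotated sites carry full
    consensus motifs (engine probability ~0.98); the ORF spans from a
    planted Kozak/ATG in the first exon to a planted stop in the last
    exon with intermediate in-frame stops edited out.
    """
    rng = np.random.default_rng((spec.seed, 1, gene_index))
    n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
    exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, n_exons)
    intron_lens = rng.integers(spec.intron_length[0], spec.intron_length[1] + 1,
                               max(n_exons - 1, 0))

    exons: list[tuple[int, int]] = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    length = pos
    seq = _random_seq(rng, length)

    protected: list[tuple[int, int]] = []  # gene-local intervals no edit may touch
    donor_c, donor_off = _ENGINE.DONOR_CONSENSUS, _ENGINE.DONOR_OFFSET
    acc_c, acc_off = _ENGINE.ACCEPTOR_CONSENSUS, _ENGINE.ACCEPTOR_OFFSET
    for (s0, e0), (s1, _) in zip(exons[:-1], exons[1:]):
        donor = e0                      # first intronic base
        acceptor = s1 - 1               # last intronic base
        _write_motif(seq, donor - donor_off, donor_c)
        _write_motif(seq, acceptor - acc_off, acc_c)
        protected.append((donor - donor_off, donor - donor_off + len(donor_c)))
        protected.append((acceptor - acc_off, acceptor - acc_off + len(acc_c)))

    # broken cryptic motifs mid-intron, >= 25 nt clear of the real sites
    candidates: list[CrypticCandidate] = []
    for i in range(len(intron_lens)):
        if len(candidates) >= spec.cryptic_candidates_per_gene:
            break
        intron_start, intron_end = exons[i][1], exons[i + 1][0]
        lo, hi = intron_start + 30, intron_end - 55
        if hi <= lo:
            continue
        for kind in ("donor", "acceptor"):
            if len(candidates) >= spec.cryptic_candidates_per_gene:
                break
            at = int(rng.integers(lo, hi))
            if kind == "donor":
                broken = donor_c[:4] + "A" + donor_c[5:]  # GT -> GA
                _write_motif(seq, at, broken)
                site = at + donor_off
                cand = CrypticCandidate("donor", site, site + 1, "A", "T")
                protected.append((at, at + len(broken)))
            else:
                broken = acc_c[:19] + "C" + acc_c[20:]    # AG -> CG
                _write_motif(seq, at, broken)
                site = at + acc_off
                cand = CrypticCandidate("acceptor", site, site - 1, "C", "A")
                protected.append((at, at + len(broken)))
            candidates.append(cand)
            lo = at + 60
            if lo >= hi:
                break

    # plant the start codon with a strong Kozak context in exon 1
    e1s = exons[0][0]
    _write_motif(seq, e1s + 12, "GCCACCATGG")
    protected.append((e1s + 12, e1s + 22))
    tis = e1s + 18

    def in_protected(p: int) -> bool:
        return any(a <= p < b for a, b in protected)

    # reference mature positions, used to carve a clean ORF
    mature_pos = [p for s, e in exons for p in range(s, e)]
    tis_idx = mature_pos.index(tis)
    last_s, last_e = exons[-1]
    stop_idx = None
    for idx in range(tis_idx + 3, len(mature_pos) - 2, 3):
        p0, p1, p2 = mature_pos[idx : idx + 3]
        if p0 >= last_s + 9 and p2 < last_e - 15:
            stop_idx = idx  # keep advancing: use the last eligible codon
    if stop_idx is None:
        raise InputError("last exon too short to place a stop codon")
    for off, base in enumerate("TAA"):
        seq[mature_pos[stop_idx + off]] = base
    protected.append((mature_pos[stop_idx], mature_pos[stop_idx] + 3))
    tts = mature_pos[stop_idx]

    # edit out premature in-frame stops (a C never creates a new stop)
    for idx in range(tis_idx, stop_idx, 3):
        codon_pos = [mature_pos[idx + k] for k in range(3)]
        if "".join(seq[p] for p in codon_pos) in _STOPS:
            editable = [p for p in codon_pos if not in_protected(p)]
            seq[editable[0]] = "C"

    strand = "+" if gene_index % 2 == 0 else "-"
    gene_sense = "".join(seq)
    transcript = TranscriptAnnotation(
        transcript_id=f"G{gene_index:02d}T1", exons=tuple(exons),
        tis=tis, tts=tts, is_primary=True,
    )
    contig = f"ctg{gene_index + 1}"
    pad_rng = np.random.default_rng((spec.seed, 2, gene_index))
    left = "".join(_random_seq(pad_rng, _PAD))
    right = "".join(_random_seq(pad_rng, _PAD))
    plus = gene_sense if strand == "+" else reverse_complement(gene_sense)
    gene = GeneModel(
        gene_id=f"G{gene_index:02d}", contig=contig, strand=strand,
        genomic_start=_PAD + 1, genomic_end=_PAD + length,
        pre_mrna=gene_sense, transcripts=(transcript,),
    )
    mature_seq = "".join(gene_sense[s:e] for s, e in exons)
    protein = translate(mature_seq, tis_idx, stop_idx)

    toy = ToyGene(
        gene=gene, contig_sequence=left + plus + right,
        cryptic_candidates=candidates, protein=protein,
    )
    toy.conservation[transcript.transcript_id] = _conservation_table(
        spec, gene_index, protein
    )
    return toy


def _conservation_table(spec: FixtureSpec, gene_index: int, protein: str) -> pd.DataFrame:
    """Per-residue relative evolutionary rates (higher = faster-evolving)."""
    n = len(protein)
    rates = np.ones(n)
    if spec.conservation_profile == "domain-peaks":
        rng = np.random.default_rng((spec.seed, 3, gene_index))
        n_domains = max(1, n // 150)
        for _ in range(n_domains):
            width = int(rng.integers(40, 76))
            start = int(rng.integers(0, max(1, n - width)))
            rates[start : start + width] = 0.2
    return pd.DataFrame({
        "pos": np.arange(1, n + 1),
        "residue": list(protein),
        "rate": rates,
    })


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _local_to_genomic(gene: GeneModel, pos: int, ref: str, alt: str
                      ) -> tuple[int, str, str]:
    """Sense-frame SNV -> plus-strand genomic SNV."""
    if gene.strand == "+":
        return gene.genomic_start + pos, ref, alt
    comp = str.maketrans("ACGT", "TGCA")
    return gene.genomic_end - pos, ref.translate(comp), alt.translate(comp)


def _is_neutral(gene: GeneModel, variant: Variant, cfg: DetectionConfig) -> bool:
    ref_track = engine_predict(_ENGINE, gene.pre_mrna)
    mut_seq, cmap = apply_variant(gene, variant)
    mut_track = engine_predict(_ENGINE, mut_seq)
    events = detect_missplicing(
        ref_track, mut_track, cmap, gene.annotated_donors,
        gene.annotated_acceptors, cfg, gene.genomic_to_local(variant.position),
    )
    return not events


def generate_cohort(
    spec: FixtureSpec, genes: list[ToyGene]
) -> tuple[list[Variant], pd.DataFrame]:
    """Draw a cohort of SNVs with ground-truth missplicing labels.

    Returns the variants plus a truth table (one row per variant) whose
    ``expected_kind`` is missed_donor / missed_acceptor /
    discovered_donor / discovered_acceptor / none and whose
    ``site_position`` is the affected gene-local site (-1 for neutral).
    Neutral variants are re-drawn until detection on the toy gene yields
    zero events, so they are controls by construction.
    """
    rng = np.random.default_rng((spec.seed, 4))
    cfg = DetectionConfig()
    n_total = spec.n_patients * spec.mutations_per_patient
    variants: list[Variant] = []
    rows: list[dict] = []
    for i in range(n_total):
        patient = f"P{i % spec.n_patients:03d}"
        toy = genes[int(rng.integers(len(genes)))]
        gene = toy.gene
        u = rng.random()
        kind = ("create" if u < spec.planted_cryptic_rate
                else "destroy" if u < spec.planted_cryptic_rate + spec.planted_destroy_rate
                else "neutral")
        if kind == "create" and not toy.cryptic_candidates:
            kind = "neutral"

        if kind == "destroy":
            tx = gene.primary_transcript
            sites = sorted((d, "donor") for d in tx.donors)
            sites += sorted((a, "acceptor") for a in tx.acceptors)
            site, site_kind = sites[int(rng.integers(len(sites)))]
            if site_kind == "donor":
                local, ref, alt = site + 1, "T", "A"   # break the GT
            else:
                local, ref, alt = site, "G", "C"       # break the AG
            expected = f"missed_{site_kind}"
        elif kind == "create":
            cand = toy.cryptic_candidates[int(rng.integers(len(toy.cryptic_candidates)))]
            local, ref, alt = cand.fix_position, cand.fix_ref, cand.fix_alt
            site, expected = cand.site_position, f"discovered_{cand.site_kind}"
        else:
            site, expected = -1, "none"
            for _ in range(25):
                tx = gene.primary_transcript
                es, ee = tx.exons[int(rng.integers(len(tx.exons)))]
                local = int(rng.integers(es + 25, ee - 25))
                ref = gene.pre_mrna[local]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                gpos, gref, galt = _local_to_genomic(gene, local, ref, alt)
                if _is_neutral(gene, Variant(gene.contig, gpos, gref, galt), cfg):
                    break
            else:
                raise InputError("could not draw a neutral control variant")

        gpos, gref, galt = _local_to_genomic(gene, local, ref, alt)
        variants.append(Variant(gene.contig, gpos, gref, galt, patient_id=patient))
        rows.append({
            "contig": gene.contig, "position": gpos, "ref": gref, "alt": galt,
            "patient_id": patient, "gene_id": gene.gene_id,
            "expected_kind": expected, "site_position": site,
        })
    return variants, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk fixture set in standard formats
# ---------------------------------------------------------------------------

def _gtf_interval(gene: GeneModel, start: int, end: int) -> tuple[int, int]:
    """Gene-local half-open -> 1-based inclusive genomic, strand-aware."""
    if gene.strand == "+":
        return gene.genomic_start + start, gene.genomic_start + end - 1
    return gene.genomic_end - (end - 1), gene.genomic_end - start


def gtf_text(toys: list[ToyGene]) -> str:
    lines = []
    for toy in toys:
        g = toy.gene
        attr_g = f'gene_id "{g.gene_id}";'
        lines.append("\t".join([
            g.contig, "splicefate", "gene", str(g.genomic_start),
            str(g.genomic_end), ".", g.strand, ".", attr_g,
        ]))
        for tx in g.transcripts:
            attr = (f'gene_id "{g.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'is_primary "{1 if tx.is_primary else 0}";')
            s, e = _gtf_interval(g, *tx.span)
            lines.append("\t".join([g.contig, "splicefate", "transcript",
                                    str(s), str(e), ".", g.strand, ".", attr]))
            for es, ee in tx.exons:
                s, e = _gtf_interval(g, es, ee)
                lines.append("\t".join([g.contig, "splicefate", "exon",
                                        str(s), str(e), ".", g.strand, ".", attr]))
            for feat, pos in (("start_codon", tx.tis), ("stop_codon", tx.tts)):
                if pos is None:
                    continue
                s, e = _gtf_interval(g, pos, pos + 3)
                lines.append("\t".join([g.contig, "splicefate", feat,
                                        str(s), str(e), ".", g.strand, ".", attr]))
    return "\n".join(lines) + "\n"


def fasta_text(toys: list[ToyGene]) -> str:
    chunks = []
    for toy in toys:
        chunks.append(f">{toy.gene.contig}")
        s = toy.contig_sequence
        chunks.extend(s[i : i + 70] for i in range(0, len(s), 70))
    return "\n".join(chunks) + "\n"


def vcf_text(toys: list[ToyGene], variants: list[Variant]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={t.gene.contig},length={len(t.contig_sequence)}>"
              for t in toys]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        lines.append("\t".join([
            v.contig, str(v.position), v.patient_id or ".",
            v.ref_allele, v.alt_allele, ".", "PASS", ".",
        ]))
    return "\n".join(lines) + "\n"


def write_fixtures(spec: FixtureSpec, out_dir: str) -> dict[str, str]:
    """Generate a full fixture set and write it in standard formats.

    Produces genome.fa, annotation.gtf, variants.vcf, truth.tsv and one
    Rate4Site-style conservation TSV per transcript under conservation/.
    Returns the path of each artifact.
    """
    toys = [generate_toy_gene(spec, i) for i in range(spec.n_genes)]
    variants, truth = generate_cohort(spec, toys)
    os.makedirs(os.path.join(out_dir, "conservation"), exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gtf": os.path.join(out_dir, "annotation.gtf"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(fasta_text(toys))
    with open(paths["gtf"], "w") as fh:
        fh.write(gtf_text(toys))
    with open(paths["vcf"], "w") as fh:
        fh.write(vcf_text(toys, variants))
    truth.to_csv(paths["truth"], sep="\t", index=False)
    for toy in toys:
        for tid, table in toy.conservation.items():
            p = os.path.join(out_dir, "conservation", f"{tid}.tsv")
            table.to_csv(p, sep="\t", index=False, header=False)
    return paths


def reference_fixed_point(toy: ToyGene) -> tuple[str, str]:
    """(annotated mature mRNA, annotated protein) for the primary transcript.

    Used to assert that the unmutated pipeline reproduces the annotation
    byte-for-byte.
    """
    tx = toy.gene.primary_transcript
    path = SplicePath(tuple(
        (d, a) for d, a in zip(sorted(tx.donors), sorted(tx.acceptors))
    ))
    mature = assemble_transcript(path, toy.gene.pre_mrna, tx.span, tx.exons)
    pos = mature.positions()
    tis_idx = pos.index(tx.tis)
    tts_idx = locate_tts(mature.sequence, tis_idx)
    return mature.sequence, translate(mature.sequence, tis_idx, tts_idx)
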