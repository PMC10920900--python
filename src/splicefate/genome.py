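"""Gene models, variants, and the gene-local coordinate frame.

All internal coordinates are 0-based, half-open, on the gene's *sense*
strand: position 0 is the 5' end of the pre-mRNA regardless of genomic
strand.  GTF (1-based inclusive) and VCF (1-based, anchor-base indel
convention) are converted at the I/O boundary.  A donor is the first
intronic base (the G of the GU motif); an acceptor is the last intronic
base (the G of the AG motif), so an intron is ``[donor, acceptor]``
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import (
    GeneNotFoundError,
    InputError,
    MalformedAnnotationError,
    ReferenceMismatchError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript of a gene, in the gene-local sense frame.

    ``exons`` are sorted, non-overlapping half-open intervals.  ``donors``
    and ``acceptors`` are derived from exon boundaries: the donor of
    intron k is the base immediately after exon k, the acceptor the base
    immediately before exon k+1.  ``tis``/``tts`` are the positions of the
    A of the start codon and the first base of the stop codon (``None``
    for non-coding transcripts).
    """

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    tis: int | None = None
    tts: int | None = None
    is_primary: bool = False

    @property
    def donors(self) -> frozenset[int]:
        return frozenset(end for _, end in self.exons[:-1])

    @property
    def acceptors(self) -> frozenset[int]:
        return frozenset(start - 1 for start, _ in self.exons[1:])

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def validate(self, gene_length: int) -> None:
        if not self.exons:
            raise MalformedAnnotationError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end <= gene_length):
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: exon [{start},{end}) outside gene span"
                )
            if start <= prev_end - 1 or start < prev_end:
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = end
        if len(self.donors) != len(self.exons) - 1:
            raise MalformedAnnotationError(f"{self.transcript_id}: duplicated junction")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its pre-mRNA (sense strand) and transcript annotations."""

    gene_id: str
    contig: str
    strand: str
    genomic_start: int  # 1-based inclusive
    genomic_end: int  # 1-based inclusive
    pre_mrna: str
    transcripts: tuple[TranscriptAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise MalformedAnnotationError(f"unknown strand {self.strand!r}")
        if len(self.pre_mrna) != self.genomic_end - self.genomic_start + 1:
            raise MalformedAnnotationError(
                f"{self.gene_id}: pre_mrna length != genomic span length"
            )
        for t in self.transcripts:
            t.validate(len(self.pre_mrna))

    def __len__(self) -> int:
        return len(self.pre_mrna)

    @property
    def annotated_donors(self) -> frozenset[int]:
        return frozenset().union(*(t.donors for t in self.transcripts)) if self.transcripts else frozenset()

    @property
    def annotated_acceptors(self) -> frozenset[int]:
        return frozenset().union(*(t.acceptors for t in self.transcripts)) if self.transcripts else frozenset()

    @property
    def primary_transcript(self) -> TranscriptAnnotation:
        for t in self.transcripts:
            if t.is_primary:
                return t
        return self.transcripts[0]

    def genomic_to_local(self, pos: int) -> int:
        """Map a 1-based genomic position to the gene-local sense frame."""
        if not (self.genomic_start <= pos <= self.genomic_end):
            raise InputError(f"position {pos} outside gene span")
        if self.strand == "+":
            return pos - self.genomic_start
        return self.genomic_end - pos

    def plus_frame_sequence(self) -> str:
        return self.pre_mrna if self.strand == "+" else reverse_complement(self.pre_mrna)


@dataclass(frozen=True)
class Variant:
    """A genomic variant in VCF convention (1-based, anchor-base indels)."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    patient_id: str | None = None

    @property
    def variant_class(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        if len(self.alt_allele) > len(self.ref_allele):
            return "insertion"
        return "deletion"

    def validate(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or any(b not in "ACGTN" for b in allele.upper()):
                raise InputError(f"bad allele {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise InputError("ref allele equals alt allele")
        if self.variant_class == "insertion" and not self.alt_allele.startswith(self.ref_allele):
            raise InputError("insertion alt must begin with the anchor (ref) base(s)")
        if self.variant_class == "deletion" and not self.ref_allele.startswith(self.alt_allele):
            raise InputError("deletion ref must begin with the anchor (alt) base(s)")

    def id_string(self) -> str:
        return f"{self.contig}:{self.position}{self.ref_allele}>{self.alt_allele}"


class CoordinateMap:
    """Positional correspondence between a mutant and reference sequence.

    ``mut_to_ref[i]`` is the reference position of mutant position ``i``,
    or -1 for inserted bases; ``ref_to_mut[j]`` is the mutant position of
    reference position ``j``, or -1 for deleted bases.  Inserted positions
    are reported via the nearest upstream mapped base (anchor) plus a
    1-based offset.
    """

    def __init__(self, mut_to_ref: np.ndarray, ref_length: int):
        self.mut_to_ref = np.asarray(mut_to_ref, dtype=np.int64)
        ref_to_mut = np.full(ref_length, -1, dtype=np.int64)
        mapped = self.mut_to_ref >= 0
        ref_to_mut[self.mut_to_ref[mapped]] = np.nonzero(mapped)[0]
        self.ref_to_mut = ref_to_mut

    def __len__(self) -> int:
        return len(self.mut_to_ref)

    def anchor_of(self, mut_pos: int) -> tuple[int | None, int]:
        """For an inserted mutant position, (reference anchor, offset >= 1).

        For a mapped position, (its reference position, 0).
        """
        if self.mut_to_ref[mut_pos] >= 0:
            return int(self.mut_to_ref[mut_pos]), 0
        i = mut_pos
        while i >= 0 and self.mut_to_ref[i] < 0:
            i -= 1
        anchor = int(self.mut_to_ref[i]) if i >= 0 else None
        return anchor, mut_pos - i

    @classmethod
    def identity(cls, length: int) -> "CoordinateMap":
        return cls(np.arange(length, dtype=np.int64), length)


def apply_variant(gene: GeneModel, variant: Variant) -> tuple[str, CoordinateMap]:
    """Apply one variant to a gene's pre-mRNA.

    The edit is performed on the plus-strand genomic frame (where the VCF
    anchor-base convention is defined) and the result is flipped back to
    the gene-local sense frame, so indels behave identically on either
    strand.  Returns the mutant sense-strand sequence and the mutant→
    reference coordinate map in the sense frame.
    """
    variant.validate()
    if variant.contig != gene.contig:
        raise InputError(f"variant contig {variant.contig} != gene contig {gene.contig}")
    if not (gene.genomic_start <= variant.position <= gene.genomic_end):
        raise InputError("variant outside gene span")

    plus = gene.plus_frame_sequence()
    pos0 = variant.position - gene.genomic_start
    ref, alt = variant.ref_allele.upper(), variant.alt_allele.upper()
    if plus[pos0 : pos0 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"{variant.id_string()}: genome has {plus[pos0:pos0 + len(ref)]!r}, "
            f"variant claims {ref!r}"
        )

    mut_plus = plus[:pos0] + alt + plus[pos0 + len(ref) :]
    # anchor (first) base of alt maps to pos0; extra alt bases are inserted
    m2r = np.concatenate(
        [
            np.arange(pos0 + 1, dtype=np.int64),
            np.full(len(alt) - 1, -1, dtype=np.int64),
            np.arange(pos0 + len(ref), len(plus), dtype=np.int64),
        ]
    )
    if gene.strand == "-":
        mut_sense = reverse_complement(mut_plus)
        flipped = np.full(len(m2r), -1, dtype=np.int64)
        mapped = m2r >= 0
        flipped[mapped] = len(plus) - 1 - m2r[mapped]
        m2r = flipped[::-1].copy()
    else:
        mut_sense = mut_plus
    return mut_sense, CoordinateMap(m2r, len(plus))


# ---------------------------------------------------------------------------
# I/O boundary: GTF + FASTA -> GeneModel; VCF/TSV -> variants
# ---------------------------------------------------------------------------

def _feature_to_local(gene_start: int, gene_end: int, strand: str,
                      start: int, end: int) -> tuple[int, int]:
    """1-based inclusive genomic interval -> gene-local half-open."""
    if strand == "+":
        return start - gene_start, end - gene_start + 1
    return gene_end - end, gene_end - start + 1


def load_annotation(gtf_path: str, fasta_path: str, gene_id: str) -> GeneModel:
    """Build a :class:`GeneModel` for one gene from a GTF and genome FASTA.

    Exon records must carry transcript ids; coding transcripts must have
    ``start_codon``/``stop_codon`` records.  Minus-strand genes are
    reverse-complemented so gene-local position 0 is the 5' end.
    """
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise GeneNotFoundError(f"gene {gene_id!r} not in {gtf_path}") from exc
    if gene.strand not in {"+", "-"}:
        raise MalformedAnnotationError(f"{gene_id}: unknown strand {gene.strand!r}")

    with Fasta(fasta_path, as_raw=True, sequence_always_upper=True) as fasta:
        plus_seq = str(fasta[gene.seqid][gene.start - 1 : gene.end])
    pre_mrna = plus_seq if gene.strand == "+" else reverse_complement(plus_seq)

    transcripts = []
    for tx in db.children(gene, featuretype="transcript", order_by="start"):
        exons = []
        for exon in db.children(tx, featuretype="exon"):
            if not (gene.start <= exon.start and exon.end <= gene.end):
                raise MalformedAnnotationError(
                    f"{tx.id}: exon {exon.start}-{exon.end} outside gene span"
                )
            exons.append(_feature_to_local(gene.start, gene.end, gene.strand,
                                           exon.start, exon.end))
        exons.sort()
        tis = tts = None
        for sc in db.children(tx, featuretype="start_codon"):
            s, _ = _feature_to_local(gene.start, gene.end, gene.strand, sc.start, sc.end)
            tis = s
        for sc in db.children(tx, featuretype="stop_codon"):
            s, _ = _feature_to_local(gene.start, gene.end, gene.strand, sc.start, sc.end)
            tts = s
        primary = tx.attributes.get("is_primary", ["0"])[0] in {"1", "true", "True"}
        transcripts.append(
            TranscriptAnnotation(
                transcript_id=tx.id, exons=tuple(exons), tis=tis, tts=tts,
                is_primary=primary,
            )
        )
    if not transcripts:
        raise MalformedAnnotationError(f"{gene_id}: no transcripts")
    if not any(t.is_primary for t in transcripts):
        transcripts[0] = TranscriptAnnotation(
            transcript_id=transcripts[0].transcript_id,
            exons=transcripts[0].exons, tis=transcripts[0].tis,
            tts=transcripts[0].tts, is_primary=True,
        )
    return GeneModel(
        gene_id=gene_id,
        contig=gene.seqid,
        strand=gene.strand,
        genomic_start=gene.start,
        genomic_end=gene.end,
        pre_mrna=pre_mrna,
        transcripts=tuple(transcripts),
    )


def read_variants(path: str) -> list[Variant]:
    """Read variants from a VCF or a 4-column TSV (contig, pos, ref, alt)."""
    if path.endswith((".vcf", ".vcf.gz")):
        import pysam

        out = []
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    out.append(Variant(rec.chrom, rec.pos, rec.ref, alt,
                                       patient_id=rec.id if rec.id != "." else None))
        return out
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["contig", "position", "ref_allele", "alt_allele"],
                     dtype={"contig": str})
    return [
        Variant(r.contig, int(r.position), r.ref_allele, r.alt_allele)
        for r in df.itertuples()
    ]
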