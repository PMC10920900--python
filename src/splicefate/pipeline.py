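"""End-to-end per-variant scoring: events → isoforms → proteins → score.

Each variant is analyzed in isolation: predict reference and mutant
probability tracks, detect missplicing events in the ±window around the
variant, rebuild candidate mature transcripts per annotated transcript,
translate them, and score each candidate protein's divergence from the
reference protein under the transcript's conservation track.  Scores
aggregate weakest-link (mean over isoforms, max over transcripts).  A
variant with no detected events scores 0 and emits no isoforms.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .detect import DetectionConfig, MissplicingEvent, detect_missplicing
from .divergence import (
    AlignmentParams,
    GeneScore,
    aggregate_scores,
    align_proteins,
    full_loss_result,
    score_events,
    smooth_conservation,
)
from .engine import SpliceEngine, engine_predict, get_engine
from .errors import InputError, SpliceFateError
from .genome import CoordinateMap, GeneModel, TranscriptAnnotation, Variant, apply_variant
from .isoforms import (
    DEFAULT_MAX_ISOFORMS,
    DEFAULT_MAX_NOVEL_EXON,
    MatureTranscript,
    SplicePath,
    assemble_transcript,
    build_site_pool,
    enumerate_isoforms,
)
from .translate import TranslationResult, locate_tts, translate, translate_mature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the scoring pipeline.

    Defaults are the validated operating point: detection delta 0.5 in a
    ±2,500-nt window, novel exons over 2,000 nt discarded, conservation
    window W = 75 residues, and the top 5% of event-positive variants
    called deleterious.
    """

    engine: str = "synthetic"
    threshold: float = 0.5
    window_radius: int = 2500
    ref_site_cutoff: float = 0.5
    max_novel_exon: int = DEFAULT_MAX_NOVEL_EXON
    conservation_window: int = 75
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    attribution_mode: str = "per_position"
    max_isoforms: int = DEFAULT_MAX_ISOFORMS
    deleterious_top_percent: float = 0.05
    seed: int = 0

    @property
    def detection(self) -> DetectionConfig:
        return DetectionConfig(
            threshold=self.threshold,
            window_radius=self.window_radius,
            ref_site_cutoff=self.ref_site_cutoff,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "alignment" in raw:
            raw["alignment"] = AlignmentParams(**raw["alignment"])
        return cls(**raw)


@dataclass
class IsoformReport:
    """One candidate isoform of one transcript."""

    transcript_id: str
    isoform_index: int
    mature: MatureTranscript
    translation: TranslationResult | None
    score: float | None  # None when the isoform was discarded


@dataclass
class VariantReport:
    """Everything the pipeline derived for one variant."""

    variant: Variant
    gene_id: str
    events: list[MissplicingEvent] = field(default_factory=list)
    isoforms: list[IsoformReport] = field(default_factory=list)
    gene_score: GeneScore | None = None
    score: float = 0.0
    error: str | None = None


def reference_products(gene: GeneModel) -> dict[str, tuple[MatureTranscript, str, int]]:
    """Annotated mature transcript, protein and mature-frame TIS per transcript."""
    out: dict[str, tuple[MatureTranscript, str, int]] = {}
    for tx in gene.transcripts:
        if tx.tis is None:
            continue
        path = SplicePath(tuple(zip(sorted(tx.donors), sorted(tx.acceptors))))
        mature = assemble_transcript(path, gene.pre_mrna, tx.span, tx.exons)
        tis_idx = mature.positions().index(tx.tis)
        tts_idx = locate_tts(mature.sequence, tis_idx)
        out[tx.transcript_id] = (mature, translate(mature.sequence, tis_idx, tts_idx), tis_idx)
    return out


def _map_position(cmap: CoordinateMap, ref_pos: int, direction: int) -> int | None:
    """Nearest surviving mutant position at/after (+1) or at/before (-1)."""
    n = len(cmap.ref_to_mut)
    p = ref_pos
    while 0 <= p < n:
        m = int(cmap.ref_to_mut[p])
        if m >= 0:
            return m
        p += direction
    return None


def _mutant_span(cmap: CoordinateMap, span: tuple[int, int]) -> tuple[int, int] | None:
    lo = _map_position(cmap, span[0], +1)
    hi = _map_position(cmap, span[1] - 1, -1)
    if lo is None or hi is None or hi < lo:
        return None
    return lo, hi + 1


def _mutant_exons(cmap: CoordinateMap, tx: TranscriptAnnotation
                  ) -> tuple[tuple[int, int], ...]:
    out = []
    for s, e in tx.exons:
        ms, me = int(cmap.ref_to_mut[s]), int(cmap.ref_to_mut[e - 1])
        if ms >= 0 and me >= 0:
            out.append((ms, me + 1))
    return tuple(out)


def score_variant(
    gene: GeneModel,
    variant: Variant,
    conservation: dict[str, np.ndarray],
    cfg: PipelineConfig | None = None,
    engine: SpliceEngine | None = None,
    ref_track=None,
) -> VariantReport:
    """Run the full pipeline for one variant of one gene.

    ``conservation`` maps transcript id to the per-residue rate vector of
    that transcript's reference protein.  ``ref_track`` may carry a
    precomputed reference probability track to amortize batch runs.
    """
    cfg = cfg or PipelineConfig()
    engine = engine or get_engine(cfg.engine)
    report = VariantReport(variant=variant, gene_id=gene.gene_id)

    if ref_track is None:
        ref_track = engine_predict(engine, gene.pre_mrna)
    mut_seq, cmap = apply_variant(gene, variant)
    mut_track = engine_predict(engine, mut_seq)
    events = detect_missplicing(
        ref_track, mut_track, cmap,
        gene.annotated_donors, gene.annotated_acceptors,
        cfg.detection, gene.genomic_to_local(variant.position),
    )
    report.events = events
    if not events:
        return report

    references = reference_products(gene)
    per_isoform: dict[str, list[float]] = {}
    for tx in gene.transcripts:
        if tx.transcript_id not in references:
            continue
        _, ref_protein, _ = references[tx.transcript_id]
        rates = conservation.get(tx.transcript_id)
        if rates is None:
            raise InputError(f"no conservation track for {tx.transcript_id}")
        if len(rates) != len(ref_protein):
            raise InputError(
                f"conservation length {len(rates)} != protein length "
                f"{len(ref_protein)} for {tx.transcript_id}"
            )
        track = smooth_conservation(np.asarray(rates, dtype=float),
                                    cfg.conservation_window)
        span = _mutant_span(cmap, tx.span)
        if span is None:
            continue
        ref_exons_mut = _mutant_exons(cmap, tx)
        tis_mut = None
        if tx.tis is not None:
            ms = [int(cmap.ref_to_mut[tx.tis + k]) for k in range(3)]
            if all(m >= 0 for m in ms):
                tis_mut = (ms[0], ms[1], ms[2])

        pool = build_site_pool(tx, events, cmap)
        scores: list[float] = []
        for k, path in enumerate(enumerate_isoforms(pool, cfg.max_isoforms)):
            mature = assemble_transcript(path, mut_seq, span, ref_exons_mut,
                                         cfg.max_novel_exon)
            if mature.discarded:
                report.isoforms.append(IsoformReport(
                    tx.transcript_id, k, mature, None, None))
                continue
            tr = translate_mature(mature, tis_mut)
            if tr is None:
                s = full_loss_result(track, cfg.attribution_mode).S_pathogenicity
            elif tr.protein == ref_protein:
                s = 0.0
            else:
                _, gap_events, _ = align_proteins(ref_protein, tr.protein,
                                                  cfg.alignment)
                s = score_events(gap_events, track,
                                 cfg.attribution_mode).S_pathogenicity
            scores.append(s)
            report.isoforms.append(IsoformReport(tx.transcript_id, k, mature, tr, s))
        per_isoform[tx.transcript_id] = scores

    if per_isoform:
        report.gene_score = aggregate_scores(per_isoform)
        gs = report.gene_score.gene_score
        report.score = 0.0 if np.isnan(gs) else gs
        if report.gene_score.no_viable_isoform:
            logger.warning("%s: all isoforms discarded", variant.id_string())
    return report


def score_cohort(
    genes: list[GeneModel],
    variants: list[Variant],
    conservation: dict[str, dict[str, np.ndarray]],
    cfg: PipelineConfig | None = None,
) -> list[VariantReport]:
    """Score a cohort, matching variants to genes by contig and span.

    Each variant is processed in isolation; a per-variant failure is
    captured in that variant's report without aborting the batch.
    """
    cfg = cfg or PipelineConfig()
    engine = get_engine(cfg.engine)
    ref_tracks = {g.gene_id: engine_predict(engine, g.pre_mrna) for g in genes}
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)

    reports: list[VariantReport] = []
    for v in variants:
        gene = next(
            (g for g in by_contig.get(v.contig, ())
             if g.genomic_start <= v.position <= g.genomic_end),
            None,
        )
        if gene is None:
            reports.append(VariantReport(variant=v, gene_id="",
                                         error="no gene overlaps variant"))
            continue
        try:
            reports.append(score_variant(
                gene, v, conservation.get(gene.gene_id, {}), cfg,
                engine=engine, ref_track=ref_tracks[gene.gene_id],
            ))
        except SpliceFateError as exc:
            reports.append(VariantReport(variant=v, gene_id=gene.gene_id,
                                         error=str(exc)))
    return reports


def classify_deleterious(
    scores: dict[str, float],
    top_percent: float = 0.05,
    absolute_threshold: float | None = None,
) -> set[str]:
    """Flag the highest-scoring variants as predicted deleterious.

    ``scores`` should contain only variants with at least one missplicing
    event (event-free variants are never deleterious).  By default the
    cut is the (1 − top_percent) percentile of the scores; passing
    ``absolute_threshold`` switches to a fixed score cut.
    """
    if not scores:
        raise InputError("no scores to classify")
    values = np.array(list(scores.values()))
    if absolute_threshold is not None:
        cut = absolute_threshold
    else:
        cut = float(np.percentile(values, 100 * (1 - top_percent)))
        if values.min() == values.max():
            logger.warning("all scores equal: every variant is at the cut")
    return {v for v, s in scores.items() if s >= cut}


# ---------------------------------------------------------------------------
# TSV/FASTA report writers
# ---------------------------------------------------------------------------

def events_table(reports: list[VariantReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for e in r.events:
            rows.append({
                "gene": r.gene_id, "variant": r.variant.id_string(),
                "kind": e.kind,
                "position": e.ref_position if e.ref_position is not None
                else f"{e.anchor}+{e.insertion_offset}",
                "ref_p": round(e.ref_p, 4), "mut_p": round(e.mut_p, 4),
                "delta": round(e.delta, 4),
            })
    return pd.DataFrame(rows, columns=["gene", "variant", "kind", "position",
                                       "ref_p", "mut_p", "delta"])


def scores_table(reports: list[VariantReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "gene": r.gene_id, "variant": r.variant.id_string(),
            "patient": r.variant.patient_id or "",
            "n_events": len(r.events), "score": round(r.score, 4),
            "error": r.error or "",
        })
    return pd.DataFrame(rows, columns=["gene", "variant", "patient",
                                       "n_events", "score", "error"])


def write_outputs(reports: list[VariantReport], out_dir: str,
                  cfg: PipelineConfig | None = None) -> None:
    """Write events.tsv, scores.tsv, isoforms.fa, proteins.fa (+ config)."""
    os.makedirs(out_dir, exist_ok=True)
    events_table(reports).to_csv(os.path.join(out_dir, "events.tsv"),
                                 sep="\t", index=False)
    scores_table(reports).to_csv(os.path.join(out_dir, "scores.tsv"),
                                 sep="\t", index=False)
    with open(os.path.join(out_dir, "isoforms.fa"), "w") as iso, \
         open(os.path.join(out_dir, "proteins.fa"), "w") as prot:
        for r in reports:
            for i in r.isoforms:
                name = f"{r.gene_id}|{r.variant.id_string()}|{i.transcript_id}|iso{i.isoform_index}"
                iso.write(f">{name}{'|discarded' if i.mature.discarded else ''}\n")
                iso.write(i.mature.sequence + "\n")
                if i.translation is not None:
                    prot.write(f">{name}|{i.translation.tis_source}\n")
                    prot.write(i.translation.protein + "\n")
    if cfg is not None:
        cfg.to_yaml(os.path.join(out_dir, "config.yaml"))


def read_conservation_dir(path: str) -> dict[str, np.ndarray]:
    """Load per-transcript rate vectors from <transcript_id>.tsv files."""
    out = {}
    for name in sorted(os.listdir(path)):
        if name.endswith(".tsv"):
            df = pd.read_csv(os.path.join(path, name), sep="\t", header=None,
                             names=["pos", "residue", "rate"])
            out[name[:-4]] = df["rate"].to_numpy(dtype=float)
    return out
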