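"""Greedy construction of candidate mature transcripts from a splice-site pool.

Given the surviving annotated sites plus any discovered (cryptic) sites,
candidate transcripts are enumerated under four rules:

1. sites are introduced and connected sequentially 5'→3';
2. sites of the same type are never connected to each other;
3. adjacent same-type sites (a maximal run with no opposite-type site
   between them) are equal but mutually exclusive continuation options —
   each member of a run seeds one branch;
4. a splice path starts with a donor and ends with an acceptor (a leading
   acceptor is skipped; a trailing unmatched donor is dropped and the
   final exon runs to the transcript end).

Because runs of same-type sites strictly alternate along the pool, every
path uses exactly one member of each interior run, so the number of
distinct paths is at most the product of run lengths.  Isoforms whose
novel exons (exons absent from the reference exon set) exceed the
``max_novel_exon`` filter are flagged as discarded; they are reported but
excluded from scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby

from .detect import MissplicingEvent
from .errors import InvalidPathError
from .genome import CoordinateMap, TranscriptAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MAX_NOVEL_EXON = 2000
DEFAULT_MAX_ISOFORMS = 64


@dataclass(frozen=True, order=True)
class SpliceSite:
    """One splice site in the mutant frame."""

    position: int
    kind: str  # donor | acceptor
    origin: str = "annotated"  # annotated | discovered


@dataclass(frozen=True)
class SpliceSitePool:
    """Sorted (5'→3', mutant frame) pool of usable splice sites."""

    sites: tuple[SpliceSite, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if positions != sorted(positions):
            raise InvalidPathError("pool must be sorted 5'->3'")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class SplicePath:
    """An ordered chain of (donor, acceptor) introns; empty = unspliced."""

    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for donor, acceptor in self.introns:
            if donor >= acceptor:
                raise InvalidPathError(f"intron ({donor},{acceptor}) reversed")
            if donor <= prev_end:
                raise InvalidPathError("introns overlap or are unsorted")
            prev_end = acceptor


@dataclass(frozen=True)
class MatureTranscript:
    """A spliced transcript in the mutant frame."""

    exons: tuple[tuple[int, int], ...]
    sequence: str
    source_path: SplicePath
    discarded: bool = False
    discard_reason: str | None = None

    def positions(self) -> list[int]:
        """Mutant-frame genomic position of every mature-transcript base."""
        out: list[int] = []
        for start, end in self.exons:
            out.extend(range(start, end))
        return out


def build_site_pool(
    transcript: TranscriptAnnotation,
    events: list[MissplicingEvent],
    coordinate_map: CoordinateMap | None = None,
) -> SpliceSitePool:
    """Pool = (annotated sites − missed sites) ∪ discovered sites.

    Annotated positions are carried into the mutant frame through the
    coordinate map (identity when no map is given); annotated sites whose
    base was deleted are excluded even without an explicit missed event.
    Discovered sites outside the transcript span are ignored — paths are
    restricted to the annotated transcript boundaries.
    """
    missed = {
        (e.ref_position, e.site_kind) for e in events if e.kind.startswith("missed")
    }

    def to_mut(ref_pos: int) -> int | None:
        if coordinate_map is None:
            return ref_pos
        m = int(coordinate_map.ref_to_mut[ref_pos])
        return m if m >= 0 else None

    span_lo = to_mut(transcript.span[0])
    span_hi_ref = transcript.span[1] - 1
    span_hi = to_mut(span_hi_ref)
    sites: list[SpliceSite] = []
    for kind, annotated in (("donor", transcript.donors),
                            ("acceptor", transcript.acceptors)):
        for ref_pos in annotated:
            if (ref_pos, kind) in missed:
                continue
            mut_pos = to_mut(ref_pos)
            if mut_pos is not None:
                sites.append(SpliceSite(mut_pos, kind, "annotated"))
    for e in events:
        if not e.discovered or e.mut_position is None:
            continue
        if span_lo is not None and span_hi is not None and not (
            span_lo <= e.mut_position <= span_hi
        ):
            continue
        sites.append(SpliceSite(e.mut_position, e.site_kind, "discovered"))
    return SpliceSitePool(tuple(sorted(sites)))


def enumerate_isoforms(
    pool: SpliceSitePool, max_isoforms: int = DEFAULT_MAX_ISOFORMS
) -> list[SplicePath]:
    """Enumerate all splice paths the four rules admit (see module docstring).

    An empty pool (or one with no usable donor) yields the single empty
    path, i.e. full retention of the transcript span.  When the branch
    count exceeds ``max_isoforms`` the first ``max_isoforms`` paths in
    deterministic 5'→3' branching order are kept and a warning is logged.
    """
    sites = pool.sites

    def chains(i: int, expect: str):
        # find the first site of the expected kind at or after index i
        j = i
        while j < len(sites) and sites[j].kind != expect:
            j += 1
        if j == len(sites):
            yield ()
            return
        # the maximal same-type run containing sites[j]
        k = j
        while k < len(sites) and sites[k].kind == expect:
            k += 1
        for m in range(j, k):
            other = "acceptor" if expect == "donor" else "donor"
            for rest in chains(m + 1, other):
                yield (sites[m].position,) + rest

    paths: list[SplicePath] = []
    seen: set[tuple[tuple[int, int], ...]] = set()
    truncated = False
    for chain in chains(0, "donor"):
        if len(chain) % 2:  # trailing unmatched donor: drop it
            chain = chain[:-1]
        introns = tuple(zip(chain[::2], chain[1::2]))
        if introns in seen:
            continue
        seen.add(introns)
        if len(paths) >= max_isoforms:
            truncated = True
            break
        paths.append(SplicePath(introns))
    if truncated:
        logger.warning(
            "isoform enumeration truncated at %d paths", max_isoforms
        )
    return paths


def assemble_transcript(
    path: SplicePath,
    mut_sequence: str,
    transcript_span: tuple[int, int],
    reference_exons: tuple[tuple[int, int], ...] | None = None,
    max_novel_exon: int = DEFAULT_MAX_NOVEL_EXON,
) -> MatureTranscript:
    """Splice the introns of ``path`` out of the transcript span.

    Introns are removed inclusively ([donor, acceptor]); exons are the
    complement within ``transcript_span`` (mutant frame, half-open).  An
    exon absent from ``reference_exons`` that is longer than
    ``max_novel_exon`` marks the isoform as discarded.
    """
    start, end = transcript_span
    if not (0 <= start < end <= len(mut_sequence)):
        raise InvalidPathError("transcript span outside sequence")
    for donor, acceptor in path.introns:
        if not (start <= donor and acceptor < end):
            raise InvalidPathError("intron outside transcript span")

    exons: list[tuple[int, int]] = []
    cursor = start
    for donor, acceptor in path.introns:
        if donor > cursor:
            exons.append((cursor, donor))
        cursor = acceptor + 1
    if end > cursor:
        exons.append((cursor, end))

    sequence = "".join(mut_sequence[s:e] for s, e in exons)
    discarded = False
    reason = None
    known = set(reference_exons or ())
    for exon in exons:
        if exon not in known and exon[1] - exon[0] > max_novel_exon:
            discarded = True
            reason = (
                f"novel exon [{exon[0]},{exon[1]}) length "
                f"{exon[1] - exon[0]} > {max_novel_exon}"
            )
            break
    return MatureTranscript(
        exons=tuple(exons), sequence=sequence, source_path=path,
        discarded=discarded, discard_reason=reason,
    )


def run_structure(pool: SpliceSitePool) -> list[tuple[str, int]]:
    """(kind, run length) for each maximal same-type run — path-count bound."""
    return [(k, len(list(g))) for k, g in groupby(pool.sites, key=lambda s: s.kind)]
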