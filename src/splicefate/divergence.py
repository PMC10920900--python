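"""Conservation-weighted functional divergence between two proteins.

The score is built in four steps:

1. one optimal global pairwise alignment (match +1, mismatch −1, gap open
   −3, gap extend 0, terminal gaps at the protein 3' ends free) yields the
   deletion and insertion events between reference and variant;
2. per-residue evolutionary rates are converted to conservation
   (``C(j) = r_max − r_j``), smoothed with a length-W windowed mean and
   normalized by the maximal windowed mean, giving ``c(i, W) ∈ [0, 1]``;
3. every deleted reference residue j contributes
   ``max(1, Dw/W) · c(j, W)`` and every insertion of length Iw contributes
   ``max(1, Iw/W) · c(anchor, W)`` at its anchor; a sliding window of
   length W sums these contributions into the penalty vector ``S``;
4. the divergence score is ``max_i S(i)``; per-gene aggregation is
   weakest-link: mean over a transcript's isoforms, max over transcripts.

W defaults to 75 residues, a typical protein domain length.  Mismatches
are extracted and reported but carry no penalty — the score measures
insertion/deletion-driven loss.  A variant with no protein at all is
scored as a deletion of the full reference protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import InputError, InternalConsistencyError

DEFAULT_WINDOW = 75

_AA = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = 0.0
    free_terminal_gaps: bool = True


@dataclass(frozen=True)
class GapEvent:
    """A maximal deletion or insertion run from one optimal alignment.

    ``ref_start`` is a reference-protein position; for insertions it is
    the residue immediately preceding the inserted block (clamped to 0
    for an insertion before the first residue).
    """

    kind: str  # deletion | insertion
    ref_start: int
    length: int


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if params.free_terminal_gaps:
        # gaps at the C-terminal end of either protein are free, so
        # truncations are visible as events but do not wreck the score
        aligner.open_right_insertion_score = 0.0
        aligner.extend_right_insertion_score = 0.0
        aligner.open_right_deletion_score = 0.0
        aligner.extend_right_deletion_score = 0.0
    return aligner


def align_proteins(
    reference: str,
    variant: str,
    params: AlignmentParams | None = None,
) -> tuple[float, list[GapEvent], list[int]]:
    """Align two proteins and extract gap events and mismatch positions.

    Returns (alignment score, gap events, reference positions of
    mismatches).  An empty variant is treated as a single deletion of the
    whole reference without running the aligner.
    """
    params = params or AlignmentParams()
    if not reference:
        raise InputError("empty reference protein")
    for name, seq in (("reference", reference), ("variant", variant)):
        bad = set(seq) - _AA
        if bad:
            raise InputError(f"{name} protein has non-amino-acid symbols {sorted(bad)}")
    if not variant:
        return 0.0, [GapEvent("deletion", 0, len(reference))], []

    aligner = _make_aligner(params)
    alignment = aligner.align(reference, variant)[0]
    t_blocks, q_blocks = (np.asarray(b) for b in alignment.aligned)

    events: list[GapEvent] = []
    mismatches: list[int] = []
    prev_t = prev_q = 0
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if t0 > prev_t:
            events.append(GapEvent("deletion", prev_t, t0 - prev_t))
        if q0 > prev_q:
            events.append(GapEvent("insertion", max(prev_t - 1, 0), q0 - prev_q))
        for i in range(t1 - t0):
            if reference[t0 + i] != variant[q0 + i]:
                mismatches.append(t0 + i)
        prev_t, prev_q = t1, q1
    if len(reference) > prev_t:
        events.append(GapEvent("deletion", prev_t, len(reference) - prev_t))
    if len(variant) > prev_q:
        events.append(GapEvent("insertion", max(prev_t - 1, 0), len(variant) - prev_q))
    return float(alignment.score), events, mismatches


@dataclass(frozen=True)
class ConservationTrack:
    """Smoothed, normalized conservation over a reference protein."""

    raw_rate: np.ndarray
    C: np.ndarray
    W: int
    c: np.ndarray
    C_star: float

    def __len__(self) -> int:
        return len(self.c)


def _windowed(values: np.ndarray, W: int, reduce: str) -> np.ndarray:
    """Windowed sum or mean over [i - W//2, i + W//2], clamped at edges."""
    half = W // 2
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    sums = csum[hi] - csum[lo]
    if reduce == "sum":
        return sums
    return sums / (hi - lo)


def smooth_conservation(
    raw_rate: np.ndarray | list[float], W: int = DEFAULT_WINDOW
) -> ConservationTrack:
    """Turn per-residue evolutionary rates into the normalized track c(i, W).

    Rates follow the relative-rate convention (higher = faster-evolving),
    so conservation is ``C(j) = max(r) − r_j``.  Windows are clamped at
    the sequence edges (mean over present positions).  A constant track
    degenerates to c ≡ 1.
    """
    raw = np.asarray(raw_rate, dtype=float)
    if raw.ndim != 1 or len(raw) < 1:
        raise InputError("conservation rates must be a non-empty vector")
    if W < 1:
        raise InputError("W must be >= 1")
    C = raw.max() - raw
    C_win = _windowed(C, W, "mean")
    C_star = float(C_win.max())
    c = C_win / C_star if C_star > 0 else np.ones_like(C_win)
    return ConservationTrack(raw_rate=raw, C=C, W=W, c=c, C_star=C_star)


def uniform_track(length: int, W: int = DEFAULT_WINDOW) -> ConservationTrack:
    """Track with c ≡ 1 (every residue equally conserved)."""
    return smooth_conservation(np.zeros(length), W)


@dataclass(frozen=True)
class DivergenceResult:
    """Penalty vectors and the final divergence score for one comparison."""

    S_del: np.ndarray
    S_ins: np.ndarray
    S: np.ndarray
    S_pathogenicity: float
    attribution_mode: str


def score_events(
    events: list[GapEvent],
    track: ConservationTrack,
    mode: str = "per_position",
) -> DivergenceResult:
    """Apply the penalty model to extracted gap events.

    ``per_position`` (default): every deleted reference residue carries
    its event's length factor times its own conservation; ``anchor``: one
    contribution per event at the event's start.  Insertions always
    contribute once at their anchor.  The penalty vector S sums
    contributions over the sliding window of length W.
    """
    if mode not in {"per_position", "anchor"}:
        raise InputError(f"unknown attribution mode {mode!r}")
    n, W = len(track), track.W
    s_del = np.zeros(n)
    s_ins = np.zeros(n)
    for e in events:
        factor = max(1.0, e.length / W)
        if e.kind == "deletion":
            if e.ref_start + e.length > n:
                raise InternalConsistencyError("deletion event beyond track end")
            if mode == "per_position":
                span = slice(e.ref_start, e.ref_start + e.length)
                s_del[span] += factor * track.c[span]
            else:
                s_del[e.ref_start] += factor * track.c[e.ref_start]
        elif e.kind == "insertion":
            if e.ref_start >= n:
                raise InternalConsistencyError("insertion anchor beyond track end")
            s_ins[e.ref_start] += factor * track.c[e.ref_start]
        else:
            raise InputError(f"unknown event kind {e.kind!r}")
    S = _windowed(s_del + s_ins, W, "sum")
    return DivergenceResult(
        S_del=s_del, S_ins=s_ins, S=S,
        S_pathogenicity=float(S.max()), attribution_mode=mode,
    )


def full_loss_result(track: ConservationTrack, mode: str = "per_position") -> DivergenceResult:
    """Score for an isoform that produces no protein: full reference deletion."""
    return score_events([GapEvent("deletion", 0, len(track))], track, mode)


@dataclass(frozen=True)
class GeneScore:
    """Weakest-link aggregation of isoform scores to the gene level."""

    per_isoform: dict[str, tuple[float, ...]]
    per_transcript: dict[str, float] = field(default_factory=dict)
    gene_score: float = 0.0
    no_viable_isoform: bool = False


def aggregate_scores(per_isoform: dict[str, list[float]]) -> GeneScore:
    """Mean over each transcript's isoforms, max over transcripts.

    Transcripts whose isoforms were all discarded (empty list) are
    skipped; if nothing viable remains the result is flagged.
    """
    per_transcript = {
        tid: float(np.mean(scores)) for tid, scores in per_isoform.items() if scores
    }
    if not per_transcript:
        return GeneScore(
            per_isoform={t: tuple(s) for t, s in per_isoform.items()},
            per_transcript={}, gene_score=float("nan"), no_viable_isoform=True,
        )
    return GeneScore(
        per_isoform={t: tuple(s) for t, s in per_isoform.items()},
        per_transcript=per_transcript,
        gene_score=max(per_transcript.values()),
    )
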