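"""Translation modeling for candidate mature transcripts.

The reference start codon is reused whenever it survives contiguously in
the mature transcript (not deleted, not split by a novel junction, not
mutated).  Otherwise a pluggable TIS predictor proposes a new AUG; the
default is a Kozak-context position-weight scorer.  The termination site
is always the first in-frame canonical stop codon; transcripts with no
in-frame stop are flagged ``nonstop`` and translated to the last full
codon.  mRNA decay is not modeled — premature stops and nonstop states
are annotations, not filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

from Bio.Seq import Seq

from .isoforms import MatureTranscript

STOP_CODONS = {"TAA", "TAG", "TGA"}


class TISPredictor(Protocol):
    """Contract for start-site predictors (a trained model can slot in here)."""

    def predict(self, sequence: str) -> int | None:
        """Return the transcript position of the chosen AUG, or None."""


# Kozak context weights, positions -6..-1 then +4..+5 relative to the A of AUG.
# The -3 purine and +4 G dominate, as in the classical consensus gccRccAUGG.
_KOZAK_UP = [  # positions -6..-1
    {"G": 0.4, "C": 0.4},
    {"C": 0.6},
    {"C": 0.6},
    {"A": 3.0, "G": 2.0},  # -3: purine is the strongest determinant
    {"C": 0.8},
    {"C": 0.8},
]
_KOZAK_DOWN = [{"G": 2.0}, {"C": 0.3, "G": 0.3}]  # +4, +5


@dataclass(frozen=True)
class KozakTISPredictor:
    """Score every AUG in the 5'-most ``scan_limit`` nt by Kozak context.

    Ties break to the 5'-most AUG.  Returns None when the scanned region
    contains no AUG at all.
    """

    scan_limit: int = 500

    def score(self, sequence: str, pos: int) -> float:
        total = 0.0
        for off, table in zip(range(-6, 0), _KOZAK_UP):
            j = pos + off
            if 0 <= j < len(sequence):
                total += table.get(sequence[j], 0.0)
        for off, table in zip(range(3, 5), _KOZAK_DOWN):
            j = pos + off
            if j < len(sequence):
                total += table.get(sequence[j], 0.0)
        return total

    def predict(self, sequence: str) -> int | None:
        limit = min(len(sequence), self.scan_limit)
        best: tuple[float, int] | None = None
        for pos in range(limit - 2):
            if sequence[pos : pos + 3] == "ATG":
                s = self.score(sequence, pos)
                if best is None or s > best[0]:
                    best = (s, pos)
        return best[1] if best else None


@dataclass(frozen=True)
class TranslationResult:
    """Protein emitted from one mature transcript."""

    tis: int
    tts: int | None
    protein: str
    tis_source: str  # reference | fallback
    nonstop: bool


def locate_tis(
    mature: MatureTranscript,
    reference_tis: tuple[int, int, int] | None,
    fallback: TISPredictor | None = None,
) -> tuple[int, str] | None:
    """Pick the translation start within the mature transcript.

    ``reference_tis`` gives the mutant-frame genomic positions of the
    reference start codon's three bases (None if any base was deleted).
    The reference start is reused only if all three bases are present and
    adjacent in the mature transcript and still read ATG.
    """
    if not mature.sequence:
        return None
    if reference_tis is not None:
        index = {p: i for i, p in enumerate(mature.positions())}
        idxs = [index.get(p) for p in reference_tis]
        if None not in idxs and idxs[1] == idxs[0] + 1 and idxs[2] == idxs[0] + 2:
            if mature.sequence[idxs[0] : idxs[0] + 3] == "ATG":
                return idxs[0], "reference"
    predictor = fallback or KozakTISPredictor()
    pos = predictor.predict(mature.sequence)
    if pos is None:
        return None
    return pos, "fallback"


def locate_tts(sequence: str, tis: int) -> int | None:
    """First in-frame canonical stop codon at or after ``tis``; None if absent."""
    for pos in range(tis, len(sequence) - 2, 3):
        if sequence[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def translate(sequence: str, tis: int, tts: int | None) -> str:
    """Standard-code translation of [tis, tts); stop excluded, N codons -> X."""
    end = tts if tts is not None else tis + ((len(sequence) - tis) // 3) * 3
    orf = sequence[tis:end]
    return str(Seq(orf).translate())


def translate_mature(
    mature: MatureTranscript,
    reference_tis: tuple[int, int, int] | None,
    fallback: TISPredictor | None = None,
) -> TranslationResult | None:
    """Full translation model; None means no AUG anywhere (no protein)."""
    located = locate_tis(mature, reference_tis, fallback)
    if located is None:
        return None
    tis, source = located
    tts = locate_tts(mature.sequence, tis)
    return TranslationResult(
        tis=tis,
        tts=tts,
        protein=translate(mature.sequence, tis, tts),
        tis_source=source,
        nonstop=tts is None,
    )
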