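"""Pluggable per-nucleotide splice-site probability engines.

An engine maps a nucleotide sequence to two probability tracks (donor and
acceptor, one value per base).  The production engine slot is designed for
a neural predictor served behind the same contract; the built-in
``synthetic`` engine is a deterministic position-weight-matrix scorer used
for testing and for fully self-contained toy analyses.

The synthetic engine scores a 9-nt donor context (3 exonic + GT + 4
intronic, consensus ``CAG|GTAAGT``) and a 23-nt acceptor context
(18-nt polypyrimidine tract + ``CAG`` ending at the acceptor G + 2 exonic,
consensus ``T``*18 + ``CAG|GA``) and squashes the additive PWM score
through a logistic, so a planted consensus site scores ~0.98 and random
background stays well below 0.5.  It is seed-free and versioned by its
weight tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .errors import InputError

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ProbabilityTrack:
    """Per-nucleotide donor/acceptor probabilities for one sequence."""

    donor_p: np.ndarray
    acceptor_p: np.ndarray
    frame: str = "reference"

    def __post_init__(self) -> None:
        for arr in (self.donor_p, self.acceptor_p):
            if arr.ndim != 1 or len(arr) != len(self.donor_p):
                raise InputError("track vectors must be 1-D and equal length")
            if len(arr) and (arr.min() < 0.0 or arr.max() > 1.0):
                raise InputError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.donor_p)


class SpliceEngine(Protocol):
    """Contract every probability engine satisfies."""

    name: str
    context: int  # flanking nucleotides the engine needs for full accuracy

    def predict(self, sequence: str) -> ProbabilityTrack: ...


def _encode(sequence: str) -> np.ndarray:
    if not sequence:
        raise InputError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise InputError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    return np.array([_CODE[b] for b in seq], dtype=np.int64)


def _pwm_scan(codes: np.ndarray, weights: np.ndarray, left: int, right: int,
              midpoint: float, scale: float) -> np.ndarray:
    """Score every position with a PWM whose window spans [i-left, i+right]."""
    w = left + right + 1
    padded = np.full(len(codes) + left + right, 4, dtype=np.int64)  # out-of-range = N
    padded[left : left + len(codes)] = codes
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    scores = weights[np.arange(w)[None, :], windows].sum(axis=1)
    return 1.0 / (1.0 + np.exp(-(scores - midpoint) / scale))


def _donor_weights() -> np.ndarray:
    # columns: A C G T N, rows: positions -3..+5 around the donor base
    consensus = "CAGGTAAGT"
    w = np.full((9, 5), -1.0)
    for i, base in enumerate(consensus):
        w[i, _CODE[base]] = 1.0
    # the GT dinucleotide (window rows 3, 4) dominates the score
    for i in (3, 4):
        w[i] = -6.0
        w[i, _CODE[consensus[i]]] = 3.0
    return w


def _acceptor_weights() -> np.ndarray:
    # rows: positions -20..+2 around the acceptor base (the G of AG)
    w = np.zeros((23, 5))
    w[:18] = -0.5                      # polypyrimidine tract
    w[:18, _CODE["C"]] = 0.5
    w[:18, _CODE["T"]] = 0.5
    for i, base in zip((18, 21, 22), "CGA"):
        w[i] = -1.0
        w[i, _CODE[base]] = 1.0
    for i, base in zip((19, 20), "AG"):   # the AG dinucleotide dominates
        w[i] = -8.0
        w[i, _CODE[base]] = 4.0
    return w


@dataclass
class SyntheticPWMEngine:
    """Deterministic PWM splice-site scorer (see module docstring)."""

    name: str = "synthetic"
    context: int = 20
    donor_midpoint: float = 6.0
    donor_scale: float = 1.5
    acceptor_midpoint: float = 10.0
    acceptor_scale: float = 2.5
    _donor_w: np.ndarray = field(default_factory=_donor_weights, repr=False)
    _acceptor_w: np.ndarray = field(default_factory=_acceptor_weights, repr=False)

    # consensus strings exposed so fixture generators can plant real sites
    DONOR_CONSENSUS = "CAGGTAAGT"       # donor base at index 3
    DONOR_OFFSET = 3
    ACCEPTOR_CONSENSUS = "T" * 18 + "CAGGA"  # acceptor base at index 20
    ACCEPTOR_OFFSET = 20

    def predict(self, sequence: str) -> ProbabilityTrack:
        codes = _encode(sequence)
        donor = _pwm_scan(codes, self._donor_w, 3, 5,
                          self.donor_midpoint, self.donor_scale)
        acceptor = _pwm_scan(codes, self._acceptor_w, 20, 2,
                             self.acceptor_midpoint, self.acceptor_scale)
        return ProbabilityTrack(donor_p=donor, acceptor_p=acceptor)


_REGISTRY: dict[str, Callable[[], SpliceEngine]] = {}


def register_engine(name: str, factory: Callable[[], SpliceEngine]) -> None:
    _REGISTRY[name] = factory


def get_engine(name: str) -> SpliceEngine:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise InputError(
            f"no engine named {name!r} is registered "
            f"(available: {sorted(_REGISTRY)}); external predictors must be "
            f"registered via register_engine()"
        ) from None


register_engine("synthetic", SyntheticPWMEngine)


def engine_predict(engine: SpliceEngine, sequence: str) -> ProbabilityTrack:
    """Run an engine on one sequence (thin validated wrapper)."""
    track = engine.predict(sequence)
    if len(track) != len(sequence):
        raise InputError(f"engine {engine.name} returned a track of wrong length")
    return track
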