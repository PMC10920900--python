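"""Missplicing event detection from reference-vs-mutant probability deltas.

A *missed* site is an annotated donor/acceptor whose probability drops by
at least the detection threshold; a *discovered* (cryptic) site is an
unannotated position whose probability rises by at least the threshold.
Deltas are taken position-wise through the mutant→reference coordinate
map, so indels are compared in the reference frame: deleted reference
positions are compared against a mutant probability of 0, and inserted
mutant positions against a reference probability of 0 (reported via
anchor + offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ProbabilityTrack
from .errors import InputError, InternalConsistencyError
from .genome import CoordinateMap


@dataclass(frozen=True)
class DetectionConfig:
    """Detection thresholds.

    ``threshold`` is the probability delta that calls an event (0.5 is the
    validated default; 0.25 is the sensitive preset used when comparing to
    RNA-seq-derived cryptic sites).  ``ref_site_cutoff`` excludes
    unannotated positions already predicted strongly in the reference —
    such sites cannot be assessed and are never reported as discovered.
    It is a fixed cutoff rather than the detection threshold itself so
    that lowering the threshold only ever adds events.
    """

    threshold: float = 0.5
    window_radius: int = 2500
    ref_site_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise InputError("threshold must be in (0, 1]")
        if self.window_radius <= 0:
            raise InputError("window_radius must be positive")


@dataclass(frozen=True)
class MissplicingEvent:
    """One missed or discovered splice site.

    ``ref_position`` is gene-local (reference frame); it is ``None`` for
    sites inside inserted sequence, which are located by ``anchor`` (the
    nearest upstream mapped reference base) plus ``insertion_offset``.
    ``mut_position`` is the corresponding mutant-frame position (``None``
    for missed sites that were deleted outright).
    """

    kind: str  # missed_donor | missed_acceptor | discovered_donor | discovered_acceptor
    ref_position: int | None
    mut_position: int | None
    ref_p: float
    mut_p: float
    delta: float
    anchor: int | None = None
    insertion_offset: int | None = None

    @property
    def site_kind(self) -> str:
        return "donor" if self.kind.endswith("donor") else "acceptor"

    @property
    def discovered(self) -> bool:
        return self.kind.startswith("discovered")


def detect_missplicing(
    ref_track: ProbabilityTrack,
    mut_track: ProbabilityTrack,
    coordinate_map: CoordinateMap,
    annotated_donors: frozenset[int] | set[int],
    annotated_acceptors: frozenset[int] | set[int],
    cfg: DetectionConfig,
    variant_position: int,
) -> list[MissplicingEvent]:
    """Compare reference and mutant tracks inside the analysis window.

    ``variant_position`` is the gene-local reference-frame anchor of the
    variant; only positions within ``cfg.window_radius`` of it (clamped to
    the gene) are examined.  Each position can yield at most one donor
    event and one acceptor event.
    """
    n_ref = len(coordinate_map.ref_to_mut)
    n_mut = len(coordinate_map.mut_to_ref)
    if len(ref_track) != n_ref or len(mut_track) != n_mut:
        raise InternalConsistencyError("track lengths do not match coordinate map")

    lo = max(0, variant_position - cfg.window_radius)
    hi = min(n_ref - 1, variant_position + cfg.window_radius)
    theta = cfg.threshold

    events: list[MissplicingEvent] = []
    for site_kind, annotated in (("donor", annotated_donors),
                                 ("acceptor", annotated_acceptors)):
        ref_p = ref_track.donor_p if site_kind == "donor" else ref_track.acceptor_p
        mut_p = mut_track.donor_p if site_kind == "donor" else mut_track.acceptor_p

        for j in range(lo, hi + 1):
            mj = int(coordinate_map.ref_to_mut[j])
            pm = float(mut_p[mj]) if mj >= 0 else 0.0
            pr = float(ref_p[j])
            delta = pm - pr
            if j in annotated and delta <= -theta:
                events.append(MissplicingEvent(
                    kind=f"missed_{site_kind}", ref_position=j,
                    mut_position=mj if mj >= 0 else None,
                    ref_p=pr, mut_p=pm, delta=delta))
            elif j not in annotated and pr < cfg.ref_site_cutoff and delta >= theta:
                events.append(MissplicingEvent(
                    kind=f"discovered_{site_kind}", ref_position=j,
                    mut_position=mj, ref_p=pr, mut_p=pm, delta=delta))

        # inserted mutant positions: reference probability is 0 by definition
        for i in np.nonzero(coordinate_map.mut_to_ref < 0)[0]:
            anchor, offset = coordinate_map.anchor_of(int(i))
            if anchor is None or not (lo <= anchor <= hi):
                continue
            pm = float(mut_p[i])
            if pm >= theta:
                events.append(MissplicingEvent(
                    kind=f"discovered_{site_kind}", ref_position=None,
                    mut_position=int(i), ref_p=0.0, mut_p=pm, delta=pm,
                    anchor=anchor, insertion_offset=offset))
    return events
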