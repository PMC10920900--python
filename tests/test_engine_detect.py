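"""Synthetic probability engine and missplicing event detection."""

import numpy as np
import pytest

from splicefate.detect import DetectionConfig, MissplicingEvent, detect_missplicing
from splicefate.engine import ProbabilityTrack, SyntheticPWMEngine, engine_predict, get_engine
from splicefate.errors import InputError, InternalConsistencyError
from splicefate.genome import CoordinateMap, GeneModel, Variant, apply_variant

ENGINE = SyntheticPWMEngine()


class TestSyntheticEngine:
    def test_planted_consensus_donor_scores_high(self):
        seq = "C" * 50 + ENGINE.DONOR_CONSENSUS + "C" * 50
        track = engine_predict(ENGINE, seq)
        assert track.donor_p[50 + ENGINE.DONOR_OFFSET] >= 0.9

    def test_planted_consensus_acceptor_scores_high(self):
        seq = "C" * 50 + ENGINE.ACCEPTOR_CONSENSUS + "C" * 50
        track = engine_predict(ENGINE, seq)
        assert track.acceptor_p[50 + ENGINE.ACCEPTOR_OFFSET] >= 0.9

    def test_poly_a_is_flat(self):
        track = engine_predict(ENGINE, "A" * 300)
        assert track.donor_p.max() <= 0.05
        assert track.acceptor_p.max() <= 0.05

    def test_determinism_bitwise(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        t1, t2 = engine_predict(ENGINE, seq), engine_predict(ENGINE, seq)
        assert (t1.donor_p == t2.donor_p).all()
        assert (t1.acceptor_p == t2.acceptor_p).all()

    def test_alphabet_and_registry_errors(self):
        with pytest.raises(InputError):
            ENGINE.predict("ACGU")
        with pytest.raises(InputError):
            get_engine("neural-adapter")  # external predictors must be registered
        assert get_engine("synthetic").name == "synthetic"


def _track(donor, acceptor=None):
    donor = np.asarray(donor, dtype=float)
    acc = np.asarray(acceptor, dtype=float) if acceptor is not None else np.zeros_like(donor)
    return ProbabilityTrack(donor_p=donor, acceptor_p=acc)


class TestDetection:
    cfg = DetectionConfig(threshold=0.5, window_radius=100)

    def test_missed_donor_at_annotated_site(self):
        ref = _track([0.0, 0.9, 0.0])
        mut = _track([0.0, 0.2, 0.0])
        ev = detect_missplicing(ref, mut, CoordinateMap.identity(3), {1}, set(),
                                self.cfg, 1)
        assert [e.kind for e in ev] == ["missed_donor"]
        assert ev[0].delta == pytest.approx(-0.7)

    def test_discovered_donor_at_unannotated_site(self):
        ref = _track([0.05, 0.0])
        mut = _track([0.70, 0.0])
        ev = detect_missplicing(ref, mut, CoordinateMap.identity(2), set(), set(),
                                self.cfg, 0)
        assert [e.kind for e in ev] == ["discovered_donor"]
        assert ev[0].delta == pytest.approx(0.65)

    def test_subthreshold_delta_is_silent(self):
        ref = _track([0.1])
        mut = _track([0.5])
        assert detect_missplicing(ref, mut, CoordinateMap.identity(1), set(),
                                  set(), self.cfg, 0) == []

    def test_null_identical_tracks_no_events(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        ref = _track(p, p[::-1])
        ev = detect_missplicing(ref, ref, CoordinateMap.identity(50),
                                {10}, {20}, self.cfg, 25)
        assert ev == []

    def test_deleted_annotated_site_is_missed(self):
        """A deletion removing a strong donor registers as a missed site."""
        gene = GeneModel(gene_id="G", contig="c", strand="+", genomic_start=1,
                         genomic_end=10, pre_mrna="ACGTACGTAC")
        _, cmap = apply_variant(gene, Variant("c", 4, "TACG", "T"))
        ref = _track([0, 0, 0, 0, 0.95, 0, 0, 0, 0, 0])
        mut = _track(np.zeros(7))
        ev = detect_missplicing(ref, mut, cmap, {4}, set(), self.cfg, 4)
        assert [e.kind for e in ev] == ["missed_donor"]
        assert ev[0].mut_position is None and ev[0].ref_position == 4

    def test_discovered_site_inside_insertion_reports_anchor(self):
        gene = GeneModel(gene_id="G", contig="c", strand="+", genomic_start=1,
                         genomic_end=6, pre_mrna="ACGTAC")
        _, cmap = apply_variant(gene, Variant("c", 3, "G", "GTT"))
        mut_d = np.zeros(8)
        mut_d[3] = 0.8  # first inserted base
        ev = detect_missplicing(_track(np.zeros(6)), _track(mut_d), cmap,
                                set(), set(), self.cfg, 2)
        (e,) = ev
        assert e.kind == "discovered_donor"
        assert e.ref_position is None
        assert (e.anchor, e.insertion_offset) == (2, 1)

    def test_strong_reference_site_never_discovered(self):
        ref = _track([0.45])
        mut = _track([0.99])
        ev05 = detect_missplicing(ref, mut, CoordinateMap.identity(1), set(),
                                  set(), DetectionConfig(0.5, 100), 0)
        assert [e.kind for e in ev05] == ["discovered_donor"]
        strong = detect_missplicing(_track([0.55]), _track([0.99]),
                                    CoordinateMap.identity(1), set(), set(),
                                    DetectionConfig(0.25, 100), 0)
        assert strong == []

    def test_threshold_monotonicity(self):
        """Every event at θ=0.5 is also present at θ=0.25."""
        rng = np.random.default_rng(7)
        n = 200
        ref = _track(rng.random(n), rng.random(n))
        mut = _track(rng.random(n), rng.random(n))
        cmap = CoordinateMap.identity(n)
        donors, acceptors = {10, 50, 90}, {30, 70}
        args = (ref, mut, cmap, donors, acceptors)
        loose = detect_missplicing(*args, DetectionConfig(0.25, 300), n // 2)
        tight = detect_missplicing(*args, DetectionConfig(0.5, 300), n // 2)
        key = lambda e: (e.kind, e.ref_position)
        assert {key(e) for e in tight} <= {key(e) for e in loose}

    def test_events_outside_window_excluded(self):
        n = 50
        ref_d = np.zeros(n)
        ref_d[40] = 0.9
        mut_d = np.zeros(n)
        ev = detect_missplicing(_track(ref_d), _track(mut_d),
                                CoordinateMap.identity(n), {40}, set(),
                                DetectionConfig(0.5, 10), 5)
        assert ev == []  # position 40 is beyond 5 ± 10

    def test_track_map_length_mismatch(self):
        with pytest.raises(InternalConsistencyError):
            detect_missplicing(_track([0.1]), _track([0.1]),
                               CoordinateMap.identity(2), set(), set(),
                               self.cfg, 0)

    def test_one_position_can_host_donor_and_acceptor_events(self):
        ref = _track([0.9], [0.8])
        mut = _track([0.1], [0.1])
        ev = detect_missplicing(ref, mut, CoordinateMap.identity(1), {0}, {0},
                                self.cfg, 0)
        assert sorted(e.kind for e in ev) == ["missed_acceptor", "missed_donor"]
        assert len(ev) == len({(e.kind, e.ref_position) for e in ev})
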