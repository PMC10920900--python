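"""Alignment event extraction, conservation smoothing, and penalty scoring."""

import numpy as np
import pytest

from oracles import enumerate_optimal_alignments
from splicefate.divergence import (
    GapEvent,
    aggregate_scores,
    align_proteins,
    full_loss_result,
    score_events,
    smooth_conservation,
    uniform_track,
)
from splicefate.errors import InputError, InternalConsistencyError


class TestAlignment:
    def test_identical_sequences(self):
        score, events, mismatches = align_proteins("MKTAYIAKQR", "MKTAYIAKQR")
        assert score == 10 and events == [] and mismatches == []

    def test_internal_deletion(self):
        score, events, _ = align_proteins("MKTAYIAKQR", "MKTAKQR")
        assert [(e.kind, e.length) for e in events] == [("deletion", 3)]
        assert score == 7 - 3  # 7 matches, one gap opening

    def test_terminal_truncation_not_penalized(self):
        """A C-terminal deletion is reported but costs nothing."""
        score, events, _ = align_proteins("MKTAYIAKQR", "MKTAY")
        assert score == 5
        assert events == [GapEvent("deletion", 5, 5)]

    def test_empty_variant_is_full_deletion(self):
        score, events, _ = align_proteins("MKTAY", "")
        assert events == [GapEvent("deletion", 0, 5)]

    def test_bad_symbols_rejected(self):
        with pytest.raises(InputError):
            align_proteins("MKT", "MK1")

    def test_matches_enumeration_oracle(self):
        """Extracted events are an optimal alignment's events (exhaustive)."""
        rng = np.random.default_rng(99)
        aa = np.array(list("ACDE"))
        for _ in range(150):
            a = "".join(rng.choice(aa, size=rng.integers(1, 7)))
            b = "".join(rng.choice(aa, size=rng.integers(1, 7)))
            score, events, mism = align_proteins(a, b)
            best, optimal = enumerate_optimal_alignments(a, b)
            assert score == pytest.approx(best)
            key = (tuple(sorted((e.kind, e.ref_start, e.length) for e in events)),
                   tuple(mism))
            assert key in optimal


class TestConservationSmoothing:
    def test_constant_rates_degenerate_to_one(self):
        track = smooth_conservation(np.full(100, 3.7), W=75)
        assert np.allclose(track.c, 1.0)

    def test_single_conserved_peak(self):
        rates = np.ones(200)
        rates[90:110] = 0.1  # slow-evolving stretch
        track = smooth_conservation(rates, W=25)
        peak = int(np.argmax(track.c))
        assert 90 <= peak <= 110
        assert track.c.max() == 1.0

    def test_window_larger_than_protein(self):
        track = smooth_conservation(np.array([1.0, 2.0, 3.0]), W=75)
        assert np.allclose(track.c, 1.0)  # one clamped window everywhere

    def test_normalization_property(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            rates = rng.random(int(rng.integers(2, 400)))
            track = smooth_conservation(rates, W=int(rng.integers(1, 100)))
            assert track.c.max() == pytest.approx(1.0)
            assert track.c.min() >= 0.0


def _sliding_window_oracle(per_pos, W):
    """Brute-force windowed sum, re-derived positionwise."""
    n = len(per_pos)
    half = W // 2
    return max(
        sum(per_pos[j] for j in range(max(0, i - half), min(n, i + half + 1)))
        for i in range(n)
    )


class TestScoring:
    def test_no_events_scores_zero(self):
        track = uniform_track(200)
        assert score_events([], track).S_pathogenicity == 0.0

    @pytest.mark.parametrize("dw,expected", [(75, 75.0), (150, 150.0), (30, 30.0)])
    def test_uniform_single_deletion_examples(self, dw, expected):
        track = uniform_track(400, W=75)
        res = score_events([GapEvent("deletion", 50, dw)], track)
        assert res.S_pathogenicity == pytest.approx(expected)

    def test_closed_form_over_full_length_range(self):
        """S = min(W, Dw) · max(1, Dw/W) for uniform conservation, one deletion."""
        W = 75
        track = uniform_track(700, W=W)
        for dw in range(1, 301):
            res = score_events([GapEvent("deletion", 100, dw)], track)
            closed = min(W, dw) * max(1, dw / W)
            assert res.S_pathogenicity == pytest.approx(closed)
            # independent positionwise oracle
            per_pos = np.zeros(700)
            per_pos[100:100 + dw] = max(1, dw / W)
            assert res.S_pathogenicity == pytest.approx(
                _sliding_window_oracle(per_pos, W))

    def test_monotone_in_deletion_length(self):
        track = uniform_track(900, W=75)
        scores = [score_events([GapEvent("deletion", 10, dw)], track).S_pathogenicity
                  for dw in range(1, 250, 7)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_insertion_contributes_at_anchor(self):
        track = uniform_track(300, W=75)
        res = score_events([GapEvent("insertion", 150, 75)], track)
        assert res.S_pathogenicity == pytest.approx(1.0)  # one anchor contribution
        res2 = score_events([GapEvent("insertion", 150, 150)], track)
        assert res2.S_pathogenicity == pytest.approx(2.0)

    def test_anchor_attribution_mode(self):
        track = uniform_track(300, W=75)
        res = score_events([GapEvent("deletion", 100, 150)], track, mode="anchor")
        assert res.S_pathogenicity == pytest.approx(2.0)

    def test_conservation_weights_the_penalty(self):
        rates = np.ones(300)
        rates[100:175] = 0.0  # conserved domain
        track = smooth_conservation(rates, W=75)
        in_domain = score_events([GapEvent("deletion", 110, 30)], track)
        outside = score_events([GapEvent("deletion", 10, 30)], track)
        assert in_domain.S_pathogenicity > outside.S_pathogenicity

    def test_event_beyond_track_rejected(self):
        with pytest.raises(InternalConsistencyError):
            score_events([GapEvent("deletion", 90, 20)], uniform_track(100))

    def test_no_protein_scores_as_full_loss(self):
        track = uniform_track(150, W=75)
        res = full_loss_result(track)
        assert res.S_pathogenicity == pytest.approx(75 * (150 / 75))


class TestAggregation:
    def test_mean_then_max(self):
        gs = aggregate_scores({"T1": [2.0, 4.0], "T2": [1.0]})
        assert gs.per_transcript == {"T1": 3.0, "T2": 1.0}
        assert gs.gene_score == 3.0

    def test_single_isoform_identity(self):
        assert aggregate_scores({"T1": [7.5]}).gene_score == 7.5

    def test_zero_scores(self):
        assert aggregate_scores({"T1": [0.0, 0.0]}).gene_score == 0.0

    def test_all_discarded_flagged(self):
        gs = aggregate_scores({"T1": []})
        assert gs.no_viable_isoform and np.isnan(gs.gene_score)
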