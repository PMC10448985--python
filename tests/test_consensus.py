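import logging
from dataclasses import replace

import numpy as np
import pytest

from cdscan import consensus
from cdscan.sequence_io import PredictionTrack

from conftest import oracle_adjust, oracle_enumerate, oracle_scan_motifs, random_dna


def track_of(labels, valid_start=0, valid_end=None):
    labels = np.asarray(labels, dtype=np.uint8)
    if valid_end is None:
        valid_end = len(labels)
    return PredictionTrack("s", labels, valid_start, valid_end)


def pad(seq, total, fill="A"):
    return seq + fill * (total - len(seq))


class TestScanMotifs:
    def test_hand_scan_atgtaa(self):
        m = consensus.scan_motifs("ATGTAA")
        assert m.starts.tolist() == [0]
        assert m.stops.tolist() == [3]
        assert m.donors.tolist() == [2]  # the GT of ...G T... at index 2
        assert m.acceptors.tolist() == []

    def test_hand_scan_caggt(self):
        m = consensus.scan_motifs("CAGGT")
        assert m.acceptors.tolist() == [0]
        assert m.donors.tolist() == [3]

    def test_all_n_empty(self):
        m = consensus.scan_motifs("NNNN")
        assert all(len(a) == 0 for a in
                   (m.starts, m.stops, m.acceptors, m.donors))

    def test_matches_oracle(self, rng):
        seq = random_dna(rng, 400, with_n=0.05)
        m = consensus.scan_motifs(seq)
        ref = oracle_scan_motifs(seq)
        assert m.starts.tolist() == ref["start"]
        assert m.stops.tolist() == ref["stop"]
        assert m.acceptors.tolist() == ref["acceptor"]
        assert m.donors.tolist() == ref["donor"]


class TestEnumerate:
    def test_single_candidate(self):
        # ATG at 4, TAA at 24 -> single-type interior [4, 27), L=23
        seq = pad("AAAAATG" + "C" * 17 + "TAACCCC", 40)
        cfg = consensus.ConsensusConfig(lmin=10, lmax=40)
        cands = consensus.enumerate_potential_cds(seq, cfg)
        singles = [c for c in cands if c.cds_type == "single"]
        assert len(singles) == 1
        c = singles[0]
        assert (c.start, c.end, c.length) == (4, 27, 23)
        assert c.left_motif == ("ATG", 4)
        assert c.right_motif == ("stop", 24)

    def test_strict_lmin_exclusion(self):
        seq = pad("ATG" + "C" * 7 + "TAA", 40)  # L = 13
        assert not consensus.enumerate_potential_cds(
            seq, consensus.ConsensusConfig(lmin=13, lmax=40))
        assert consensus.enumerate_potential_cds(
            seq, consensus.ConsensusConfig(lmin=12, lmax=40))

    def test_strict_lmax_exclusion(self):
        seq = pad("ATG" + "C" * 7 + "TAA", 40)  # L = 13
        assert not consensus.enumerate_potential_cds(
            seq, consensus.ConsensusConfig(lmin=5, lmax=13))
        assert consensus.enumerate_potential_cds(
            seq, consensus.ConsensusConfig(lmin=5, lmax=14))

    def test_internal_candidate_fig_layout(self):
        # YAG ... 10 nt interior ... GT
        seq = pad("CCCCAG" + "A" * 10 + "GTCCC", 40, fill="C")
        cfg = consensus.ConsensusConfig(lmin=5, lmax=50)
        internal = [c for c in consensus.enumerate_potential_cds(seq, cfg)
                    if c.cds_type == "internal"]
        assert any((c.start, c.end) == (6, 16) and c.length == 10
                   for c in internal)

    def test_sorted_longest_first(self, rng):
        seq = random_dna(rng, 500)
        cands = consensus.enumerate_potential_cds(
            seq, consensus.ConsensusConfig(lmin=20, lmax=200))
        lengths = [c.length for c in cands]
        assert lengths == sorted(lengths, reverse=True)

    def test_matches_oracle(self, rng):
        seq = random_dna(rng, 400)
        cfg = consensus.ConsensusConfig(lmin=15, lmax=120)
        got = [(c.start, c.end, c.cds_type)
               for c in consensus.enumerate_potential_cds(seq, cfg)]
        ref = [(r.start, r.end, r.cds_type)
               for r in oracle_enumerate(seq, 15, 120)]
        assert got == ref


class TestScoreRegion:
    def region(self, start, end):
        return consensus.PotentialCds(start, end, "internal",
                                      ("YAG", start - 3), ("GT", end))

    def test_counting(self):
        labels = [0] * 10 + [1, 1, 1, 1, 1, 1, 0, 0, 0, 0] + [0] * 10
        scored = consensus.score_region(self.region(10, 20), track_of(labels))
        assert (scored.n1, scored.n0) == (6, 4)
        assert scored.ratio == pytest.approx(1.5)

    def test_all_one_infinite_ratio(self):
        scored = consensus.score_region(self.region(5, 15),
                                        track_of([1] * 30))
        assert scored.ratio == np.inf

    def test_all_zero(self):
        scored = consensus.score_region(self.region(5, 15),
                                        track_of([0] * 30))
        assert scored.ratio == 0.0

    def test_clipped_to_valid_range(self):
        track = track_of([1] * 30, valid_start=10, valid_end=20)
        scored = consensus.score_region(self.region(5, 15), track)
        assert (scored.n1, scored.n0) == (5, 0)


def fig1_fixture():
    """An internal candidate of interior length 10 with 6 coding votes."""
    seq = pad("CCCCAG" + "A" * 10 + "GTCCC", 40, fill="C")
    labels = np.zeros(40, dtype=np.uint8)
    labels[6:12] = 1  # six 1s inside the interior [6, 16)
    labels[20] = 1    # a stray 1 outside any candidate
    return seq, track_of(labels)


class TestAdjust:
    def test_flip_up_above_threshold(self):
        seq, initial = fig1_fixture()
        cfg = consensus.ConsensusConfig(lmin=5, lmax=50, threshold=1.0)
        adjusted, accepted = consensus.adjust_predictions(seq, initial, cfg)
        assert len(accepted) == 1
        assert adjusted.labels[6:16].all()

    def test_flip_down_below_threshold(self):
        seq, initial = fig1_fixture()
        cfg = consensus.ConsensusConfig(lmin=5, lmax=50, threshold=2.0)
        adjusted, accepted = consensus.adjust_predictions(seq, initial, cfg)
        assert not accepted
        assert not adjusted.labels.any()

    def test_outside_ones_zeroed(self):
        seq, initial = fig1_fixture()
        cfg = consensus.ConsensusConfig(lmin=5, lmax=50, threshold=1.0)
        adjusted, _ = consensus.adjust_predictions(seq, initial, cfg)
        assert adjusted.labels[20] == 0

    def test_equality_rejected(self):
        seq, initial = fig1_fixture()
        cfg = consensus.ConsensusConfig(lmin=5, lmax=50, threshold=1.5)
        _, accepted = consensus.adjust_predictions(seq, initial, cfg)
        assert not accepted  # ratio 6/4 == threshold -> strict rule rejects

    def test_nested_containment_precedence(self):
        # two ATGs and two TAAs give four nested single-type candidates;
        # with every label 1 all have infinite ratio, but only the longest
        # is accepted and the contained ones are never tested
        seq = pad("ATG" + "C" * 10 + "ATG" + "C" * 5 + "TAACC" + "TAA", 60)
        labels = np.ones(60, dtype=np.uint8)
        cfg = consensus.ConsensusConfig(lmin=3, lmax=50, threshold=0.5)
        _, accepted = consensus.adjust_predictions(seq, track_of(labels), cfg)
        assert [(c.start, c.end) for c in accepted] == [(0, 29)]

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(120, 420))
            seq = random_dna(rng, n)
            labels = (rng.random(n) < 0.4).astype(np.uint8)
            track = track_of(labels, valid_start=10, valid_end=n - 10)
            lmin = int(rng.choice([5, 20, 40]))
            lmax = int(rng.choice([80, 150, 400]))
            th = float(rng.choice([0.5, 1.0, 2.0]))
            cfg = consensus.ConsensusConfig(lmin=lmin, lmax=lmax, threshold=th)
            adjusted, accepted = consensus.adjust_predictions(seq, track, cfg)
            ref_adjusted, ref_accepted = oracle_adjust(seq, track, lmin, lmax, th)
            np.testing.assert_array_equal(adjusted.labels, ref_adjusted.labels)
            assert [(c.start, c.end) for c in accepted] == \
                [(r.start, r.end) for r in ref_accepted]

    def test_single_candidate_idempotent(self):
        seq, initial = fig1_fixture()
        cfg = consensus.ConsensusConfig(lmin=5, lmax=50, threshold=1.0)
        adj1, acc1 = consensus.adjust_predictions(seq, initial, cfg)
        adj2, acc2 = consensus.adjust_predictions(seq, adj1, cfg)
        np.testing.assert_array_equal(adj1.labels, adj2.labels)
        assert [(c.start, c.end) for c in acc1] == \
            [(c.start, c.end) for c in acc2]

    def test_reapplication_never_shrinks_coding_set(self, rng):
        # strict idempotence does not hold under partial-overlap acceptance,
        # but the adjusted coding set can only grow on re-application
        for _ in range(20):
            n = int(rng.integers(150, 450))
            seq = random_dna(rng, n)
            labels = (rng.random(n) < 0.5).astype(np.uint8)
            track = track_of(labels)
            cfg = consensus.ConsensusConfig(lmin=10, lmax=200, threshold=1.0)
            adj1, _ = consensus.adjust_predictions(seq, track, cfg)
            adj2, _ = consensus.adjust_predictions(seq, adj1, cfg)
            assert np.all(adj2.labels >= adj1.labels)


class TestCodingFraction:
    def test_extremes(self):
        assert consensus.coding_fraction(track_of([0] * 10)) == 0.0
        assert consensus.coding_fraction(track_of([1] * 10)) == 1.0

    def test_quarter(self):
        labels = np.zeros(100, dtype=np.uint8)
        labels[:25] = 1
        assert consensus.coding_fraction(track_of(labels)) == 0.25

    def test_empty_valid_range_errors(self):
        with pytest.raises(ValueError, match="empty valid range"):
            consensus.coding_fraction(track_of([1, 0], 1, 1))


class TestSweep:
    def make_case(self, rng, n=4000):
        seq = random_dna(rng, n)
        labels = (rng.random(n) < 0.5).astype(np.uint8)
        return seq, track_of(labels)

    def test_stops_at_first_qualifying_threshold(self, rng):
        seq, initial = self.make_case(rng)
        cfg = consensus.ConsensusConfig(
            lmin=20, lmax=200, target_coding_fraction=0.15,
            fraction_margin=0.1)
        res = consensus.fraction_targeted_sweep(seq, initial, cfg)
        # recompute the trajectory independently and walk the stopping rule
        for th, frac in res.trajectory:
            adj, _ = consensus.adjust_predictions(
                seq, initial, replace(cfg, threshold=th))
            assert consensus.coding_fraction(adj) == pytest.approx(frac)
        qualifying = [th for th, frac in res.trajectory if frac <= 0.25]
        assert res.threshold == qualifying[0]
        assert all(frac > 0.25 for _, frac in res.trajectory[:-1])

    def test_immediate_stop_at_lowest_threshold(self):
        seq = pad("CCCCAG" + "A" * 10 + "GTCCC", 40, fill="C")
        initial = track_of(np.zeros(40, dtype=np.uint8))
        cfg = consensus.ConsensusConfig(
            lmin=5, lmax=50, target_coding_fraction=0.3)
        res = consensus.fraction_targeted_sweep(seq, initial, cfg)
        assert res.threshold == cfg.threshold_grid[0]
        assert not res.exhausted

    def test_exhaustion_warns_and_returns_grid_max(self, caplog):
        # all-1 initial labels: every candidate has infinite ratio at any
        # threshold, so the fraction never drops to the target
        seq = pad("CCCCAG" + "A" * 10 + "GTCCC", 40, fill="C")
        initial = track_of(np.ones(40, dtype=np.uint8))
        cfg = consensus.ConsensusConfig(
            lmin=5, lmax=50, target_coding_fraction=0.01,
            fraction_margin=0.01)
        with caplog.at_level(logging.WARNING, logger="cdscan.consensus"):
            res = consensus.fraction_targeted_sweep(seq, initial, cfg)
        assert res.exhausted
        assert res.threshold == cfg.threshold_grid[-1]
        assert "exhausted" in caplog.text

    def test_monotone_fraction_in_threshold(self, rng):
        seq, initial = self.make_case(rng, n=6000)
        cfg = consensus.ConsensusConfig(lmin=40, lmax=400,
                                        target_coding_fraction=0.01,
                                        fraction_margin=0.0)
        res = consensus.fraction_targeted_sweep(seq, initial, cfg)
        fracs = [f for _, f in res.trajectory]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestConfig:
    def test_bad_lengths(self):
        with pytest.raises(ValueError):
            consensus.ConsensusConfig(lmin=400, lmax=40)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            consensus.ConsensusConfig(threshold_grid=[1.0, 1.0, 2.0])

    def test_default_grid_covers_reported_range(self):
        grid = consensus.default_threshold_grid()
        assert grid[0] == 0.5
        for t in range(1, 31):
            assert float(t) in grid


def test_maximal_runs_are_motif_bounded(rng):
    """Every maximal 1-run in an adjusted track is an accepted interior."""
    from cdscan.sensors import MOTIF_FAMILIES

    for _ in range(10):
        n = int(rng.integers(300, 600))
        seq = random_dna(rng, n)
        labels = (rng.random(n) < 0.5).astype(np.uint8)
        cfg = consensus.ConsensusConfig(lmin=10, lmax=150, threshold=1.0)
        adjusted, accepted = consensus.adjust_predictions(
            seq, track_of(labels), cfg)
        padded = np.r_[0, adjusted.labels, 0]
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        union = np.zeros(n, dtype=np.uint8)
        for c in accepted:
            union[c.start:c.end] = 1
        np.testing.assert_array_equal(adjusted.labels, union)
        for s, e in zip(starts, ends):
            left_ok = seq[s:s + 3] == "ATG" or (
                s >= 3 and seq[s - 3] in "CT" and seq[s - 2:s] == "AG")
            right_ok = seq[e:e + 2] == "GT" or (
                seq[e - 3:e] in MOTIF_FAMILIES["stop"])
            assert left_ok and right_ok
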