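"""Sequence construction: count balance, repeat bans, octave span,
regularity structure and transition matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import predgeom as pg
from predgeom.sequences import (
    OCTAVE_INDEX_SPAN,
    Sequence,
    ToneSet,
    _legal_unordered_triples,
    default_toneset,
)


class TestToneSet:
    def test_default_alphabet(self):
        ts = default_toneset()
        assert ts.n == 12
        assert ts.frequencies_hz[0] == 261.63
        assert ts.frequencies_hz[-1] == 932.33
        assert all(b > a for a, b in zip(ts.frequencies_hz, ts.frequencies_hz[1:]))

    def test_rejects_bad_alphabets(self):
        with pytest.raises(ValueError):
            ToneSet(tuple(range(1, 12)), tuple("abcdefghijk"))  # 11 tones
        freqs = list(default_toneset().frequencies_hz)
        freqs[3], freqs[4] = freqs[4], freqs[3]
        with pytest.raises(ValueError):
            ToneSet(tuple(freqs), default_toneset().labels)


class TestGeneration:
    @pytest.mark.parametrize("regularity", ["high", "low"])
    def test_small_sequence_satisfies_all_invariants(self, regularity):
        seq = pg.generate_sequence(regularity, 8, seed=0)
        report = pg.validate_sequence(seq)
        assert report.ok, report.failures()
        # brute-force scan of every adjacent pair
        for t in range(len(seq) - 1):
            assert seq.tones[t] != seq.tones[t + 1]
        trips = seq.triplets()
        for k in range(trips.shape[0] - 1):
            assert not np.array_equal(trips[k], trips[k + 1])
        for trip in trips:
            assert trip.max() - trip.min() <= OCTAVE_INDEX_SPAN

    def test_high_regularity_structure(self, hr_seq):
        counts = np.bincount(hr_seq.tones, minlength=12)
        assert counts.max() == counts.min() == len(hr_seq) // 12
        inv = hr_seq.triplet_inventory()
        assert len(inv) == 4
        # the 4 types disjointly cover the alphabet
        assert sorted(t for trip in inv for t in trip) == list(range(12))

    def test_determinism(self):
        a = pg.generate_sequence("low", 16, seed=5)
        b = pg.generate_sequence("low", 16, seed=5)
        assert np.array_equal(a.tones, b.tones)
        c = pg.generate_sequence("high", 16, seed=5, variant=1)
        d = pg.generate_sequence("high", 16, seed=5, variant=1)
        assert np.array_equal(c.tones, d.tones)

    def test_variants_rotate_triplet_types(self):
        base = pg.generate_sequence("high", 16, seed=2, variant=0)
        rot = pg.generate_sequence("high", 16, seed=2, variant=1)
        inv0 = {frozenset(t) for t in base.triplet_inventory()}
        inv1 = {frozenset(t) for t in rot.triplet_inventory()}
        assert inv0 == inv1  # same unordered types, different order
        assert not np.array_equal(base.tones, rot.tones)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pg.generate_sequence("high", 6, seed=0)  # not divisible by 4
        with pytest.raises(ValueError):
            pg.generate_sequence("medium", 8, seed=0)
        with pytest.raises(ValueError):
            pg.generate_sequence("low", 0, seed=0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_triplets=st.sampled_from([4, 8, 12, 20]),
        regularity=st.sampled_from(["high", "low"]),
    )
    def test_property_count_balance_and_entropy_order(self, seed, n_triplets, regularity):
        seq = pg.generate_sequence(regularity, n_triplets, seed=seed)
        counts = np.bincount(seq.tones, minlength=12)
        assert counts.max() - counts.min() == 0
        assert pg.validate_sequence(seq).ok

    def test_transition_entropy_high_below_low(self, hr_seq, lr_seq):
        h_hr = pg.transition_matrix(hr_seq).mean_row_entropy()
        h_lr = pg.transition_matrix(lr_seq).mean_row_entropy()
        assert h_hr < h_lr


class TestTransitionMatrix:
    def test_deterministic_cycle(self):
        seq = Sequence(
            np.array([0, 1, 2, 0, 1, 2, 0]),
            np.zeros(7, dtype=int),
            "low",
        )
        tm = pg.transition_matrix(seq)
        assert tm.probabilities[0, 1] == 1.0
        assert tm.probabilities[1, 2] == 1.0
        assert tm.probabilities[2, 0] == 1.0
        assert tm.counts.sum() == 6
        assert np.count_nonzero(tm.probabilities) == 3

    def test_zero_diagonal_and_row_normalisation(self, hr_seq):
        tm = pg.transition_matrix(hr_seq)
        assert np.all(np.diag(tm.counts) == 0)
        rows = tm.probabilities[~tm.empty_rows].sum(axis=1)
        np.testing.assert_allclose(rows, 1.0)

    def test_high_regularity_supports_only_legal_successors(self, hr_seq):
        # enumerate legal successor sets from the triplet inventory
        inv = hr_seq.triplet_inventory()
        legal = set()
        for trip in inv:
            legal.add((trip[0], trip[1]))
            legal.add((trip[1], trip[2]))
            for other in inv:
                if other != trip:
                    legal.add((trip[2], other[0]))
        tm = pg.transition_matrix(hr_seq)
        observed = set(zip(*np.nonzero(tm.counts)))
        assert observed <= {(int(a), int(b)) for a, b in legal}

    def test_too_short(self):
        seq = Sequence(np.array([3]), np.array([0]), "low")
        with pytest.raises(ValueError):
            pg.transition_matrix(seq)


class TestValidation:
    def test_consecutive_repeat_reported_with_position(self):
        seq = Sequence(np.array([5, 5, 1, 2, 3, 4]), np.repeat([0, 1], 3), "low")
        report = pg.validate_sequence(seq)
        assert not report.ok
        assert report.failures()["no_consecutive_tone_repeat"] == 1

    def test_octave_span_failure(self):
        # C4, D4, F#5 spans indices 0..9 (ratio 739.99/261.63 > 2)
        seq = Sequence(
            np.array([0, 1, 9, 2, 3, 4]), np.repeat([0, 1], 3), "low"
        )
        report = pg.validate_sequence(seq)
        assert not report.ok
        assert report.failures()["octave_span"] == 0

    def test_legal_triple_enumeration_matches_bruteforce(self):
        triples = _legal_unordered_triples()
        brute = [
            (a, b, c)
            for a in range(12)
            for b in range(a + 1, 12)
            for c in range(b + 1, 12)
            if max(a, b, c) - min(a, b, c) <= 6
        ]
        assert triples == brute
        assert len(triples) == 110
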