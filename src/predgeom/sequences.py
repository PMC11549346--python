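"""Regularity-controlled tone-triplet sequences.

Two auditory streams built from a 12-tone whole-tone alphabet (C, D, E,
F#, G#, A# over two octaves): a *high-regularity* stream that recycles 4
fixed triplet types, and a *low-regularity* stream whose triplets are
resampled continuously.  Both streams balance tone counts exactly, forbid
immediate tone and triplet repeats, and keep every triplet within one
octave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ToneSet",
    "Sequence",
    "TransitionMatrix",
    "default_toneset",
    "generate_sequence",
    "transition_matrix",
    "validate_sequence",
]

#: Equal-tempered frequencies of C, D, E, F#, G#, A# in the 4th and 5th
#: piano octaves (Hz).
DEFAULT_FREQS = (
    261.63, 293.66, 329.63, 369.99, 415.30, 466.16,
    523.25, 587.33, 659.26, 739.99, 830.61, 932.33,
)
DEFAULT_LABELS = (
    "C4", "D4", "E4", "F#4", "G#4", "A#4",
    "C5", "D5", "E5", "F#5", "G#5", "A#5",
)

TONE_DURATION_S = 0.300
TONE_SOA_S = 0.333  # stimulus onset asynchrony: 300 ms tone + 33 ms gap

#: Adjacent alphabet entries are one whole tone (2 semitones) apart, so an
#: octave spans 6 index steps.  The octave constraint is evaluated on this
#: lattice rather than on raw frequency ratios: equal temperament puts the
#: printed exact-octave pair at ratio 2.00002, which a literal ``<= 2``
#: would spuriously reject.
OCTAVE_INDEX_SPAN = 6


@dataclass(frozen=True)
class ToneSet:
    """The tone alphabet: 12 strictly increasing frequencies with labels."""

    frequencies_hz: tuple[float, ...] = DEFAULT_FREQS
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        f = self.frequencies_hz
        if len(f) != 12 or len(self.labels) != 12:
            raise ValueError("a ToneSet holds exactly 12 tones")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("frequencies must be strictly increasing")
        if any(x <= 0 for x in f):
            raise ValueError("frequencies must be positive")

    @property
    def n(self) -> int:
        return 12


def default_toneset() -> ToneSet:
    return ToneSet()


@dataclass
class Sequence:
    """An ordered tone stream with its triplet segmentation.

    ``tones[k]`` is the alphabet index of the k-th presented tone and
    ``triplet_ids[k]`` the ordinal of the triplet it belongs to.  Onsets
    are spaced at the 333 ms stimulus onset asynchrony.
    """

    tones: np.ndarray
    triplet_ids: np.ndarray
    regularity: str
    toneset: ToneSet = field(default_factory=default_toneset)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tones = np.asarray(self.tones, dtype=np.int64)
        self.triplet_ids = np.asarray(self.triplet_ids, dtype=np.int64)
        if self.regularity not in ("high", "low"):
            raise ValueError("regularity must be 'high' or 'low'")
        if self.tones.shape != self.triplet_ids.shape:
            raise ValueError("tones and triplet_ids must be parallel")

    def __len__(self) -> int:
        return int(self.tones.size)

    @property
    def n_triplets(self) -> int:
        return len(self) // 3

    @property
    def tone_onsets_s(self) -> np.ndarray:
        return np.arange(len(self)) * TONE_SOA_S

    def triplets(self) -> np.ndarray:
        """The sequence reshaped to (n_triplets, 3) tone indices."""
        return self.tones.reshape(-1, 3)

    def triplet_inventory(self) -> list[tuple[int, int, int]]:
        """Distinct ordered triplets, in order of first appearance."""
        seen: dict[tuple[int, int, int], None] = {}
        for trip in self.triplets():
            seen.setdefault(tuple(int(t) for t in trip), None)
        return list(seen)


def _octave_ok(triple: tuple[int, int, int] | np.ndarray) -> bool:
    return int(max(triple)) - int(min(triple)) <= OCTAVE_INDEX_SPAN


def _partition_into_triplet_types(
    rng: np.random.Generator, max_tries: int = 10_000
) -> list[tuple[int, int, int]]:
    """Partition the 12 tones into 4 disjoint ordered octave-legal triples.

    Rejection sampling over random permutations; the exact-count constraint
    (each tone 200x with 4 types x 200 tokens) forces disjoint coverage.
    """
    for _ in range(max_tries):
        perm = rng.permutation(12)
        types = [tuple(int(t) for t in perm[i : i + 3]) for i in (0, 3, 6, 9)]
        if all(_octave_ok(tp) for tp in types):
            return types
    raise RuntimeError("could not partition tones into octave-legal triplet types")


def _arrange_tokens(
    rng: np.random.Generator,
    tokens: list[int],
    max_passes: int = 1000,
) -> list[int] | None:
    """Shuffle triplet-type tokens, then repair adjacent duplicates by swaps."""
    order = list(rng.permutation(np.asarray(tokens)))
    for _ in range(max_passes):
        bad = [i for i in range(len(order) - 1) if order[i] == order[i + 1]]
        if not bad:
            return [int(t) for t in order]
        for i in bad:
            # swap the offending token with a random compatible position
            for j in rng.permutation(len(order)):
                j = int(j)
                if abs(j - i) <= 1:
                    continue
                ok_here = order[j] != order[i + 1] and (i == 0 or order[j] != order[i - 1])
                left = order[j - 1] if j > 0 else None
                right = order[j + 1] if j < len(order) - 1 else None
                ok_there = order[i + 1] != left and order[i + 1] != right
                if ok_here and ok_there:
                    order[i + 1], order[j] = order[j], order[i + 1]
                    break
    return None


def _generate_high(
    rng: np.random.Generator, n_triplets: int, variant: int
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    if n_triplets % 4:
        raise ValueError(
            "high-regularity streams need n_triplets divisible by 4 so the "
            "4 triplet types can balance tone counts"
        )
    types = _partition_into_triplet_types(rng)
    if variant:
        # counterbalanced within-triplet tone orders: cyclic rotation
        k = variant % 3
        types = [tp[k:] + tp[:k] for tp in types]
    per_type = n_triplets // 4
    tokens = [t for t in range(4) for _ in range(per_type)]
    for _ in range(50):
        order = _arrange_tokens(rng, tokens)
        if order is not None:
            tones = np.array([tone for tok in order for tone in types[tok]])
            return tones, types
    raise RuntimeError("failed to arrange triplet tokens without adjacent repeats")


def _legal_unordered_triples(n_tones: int = 12) -> list[tuple[int, int, int]]:
    """All unordered tone triples with distinct tones inside one octave."""
    out = []
    for a in range(n_tones):
        for b in range(a + 1, n_tones):
            for c in range(b + 1, n_tones):
                if c - a <= OCTAVE_INDEX_SPAN:
                    out.append((a, b, c))
    return out


def _order_triple(
    rng: np.random.Generator,
    triple: tuple[int, int, int],
    prev: tuple[int, int, int] | None,
) -> tuple[int, int, int] | None:
    """Random within-triplet order avoiding a boundary tone repeat and an
    exact repeat of the previous ordered triplet."""
    perms = [
        (triple[i], triple[j], triple[k])
        for i, j, k in (
            (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
        )
    ]
    ok = [
        p
        for p in perms
        if prev is None or (p[0] != prev[-1] and p != prev)
    ]
    if not ok:
        return None
    return ok[int(rng.integers(len(ok)))]


def _endgame_dfs(
    rng: np.random.Generator,
    quota: np.ndarray,
    prev: tuple[int, int, int] | None,
    triples: list[tuple[int, int, int]],
    budget: list[int],
) -> list[tuple[int, int, int]] | None:
    """Exact completion of the final triplets by randomised backtracking."""
    if quota.sum() == 0:
        return []
    if budget[0] <= 0:
        return None
    budget[0] -= 1
    cands = [t for t in triples if all(quota[x] > 0 for x in t)]
    rng.shuffle(cands)
    for tri in cands:
        ordered = _order_triple(rng, tri, prev)
        if ordered is None:
            continue
        for x in tri:
            quota[x] -= 1
        rest = _endgame_dfs(rng, quota, ordered, triples, budget)
        for x in tri:
            quota[x] += 1
        if rest is not None:
            return [ordered] + rest
    return None


def _generate_low(
    rng: np.random.Generator, n_triplets: int, max_restarts: int = 500
) -> np.ndarray:
    """Draw each triplet fresh under the octave and exact-count constraints.

    Each triplet is anchored on the tone with the largest remaining quota
    (edge tones of the alphabet belong to fewer octave-legal triples and
    would otherwise accumulate), with the two partners sampled
    quota-weighted from the legal set; the final triplets are completed
    exactly by a randomised backtracking search, with full restarts for
    the rare residual jams.
    """
    if n_triplets % 4:
        raise ValueError("n_triplets must be divisible by 4 to balance 12 tones")
    quota_each = n_triplets * 3 // 12
    triples = _legal_unordered_triples()
    by_tone: dict[int, list[tuple[int, int, int]]] = {t: [] for t in range(12)}
    for tri in triples:
        for t in tri:
            by_tone[t].append(tri)
    endgame_at = min(8, n_triplets)  # solve the last few triplets exactly
    for _ in range(max_restarts):
        quota = np.full(12, quota_each, dtype=np.int64)
        out: list[tuple[int, int, int]] = []
        ok = True
        while n_triplets - len(out) > endgame_at:
            prev = out[-1] if out else None
            anchor = int(rng.choice(np.flatnonzero(quota == quota.max())))
            cands = [
                tri
                for tri in by_tone[anchor]
                if all(quota[x] > 0 for x in tri)
            ]
            if not cands:
                ok = False
                break
            w = np.array(
                [
                    float(np.prod([quota[x] for x in tri if x != anchor]))
                    for tri in cands
                ]
            )
            tri = cands[int(rng.choice(len(cands), p=w / w.sum()))]
            ordered = _order_triple(rng, tri, prev)
            if ordered is None:
                continue
            out.append(ordered)
            for x in tri:
                quota[x] -= 1
        if not ok:
            continue
        tail = _endgame_dfs(
            rng, quota, out[-1] if out else None, triples, budget=[20000]
        )
        if tail is None:
            continue
        out.extend(tail)
        return np.array([t for trip in out for t in trip])
    raise RuntimeError("low-regularity construction failed after bounded restarts")


def generate_sequence(
    regularity: str,
    n_triplets: int = 800,
    seed: int = 0,
    toneset: ToneSet | None = None,
    variant: int = 0,
) -> Sequence:
    """Generate one tone stream of the requested regularity.

    Parameters
    ----------
    regularity:
        ``"high"`` — 4 fixed triplet types, disjointly covering the 12
        tones, each repeated ``n_triplets/4`` times in shuffled order.
        ``"low"`` — every triplet drawn fresh under the octave constraint
        with per-tone quota accounting.
    n_triplets:
        Number of triplets; must be a positive multiple of 4 so each tone
        can occur equally often (the reference design uses 800, i.e. 2400
        tones with every tone appearing exactly 200 times).
    seed:
        Seed for the construction RNG; identical arguments reproduce the
        identical stream.
    variant:
        Counterbalancing of the within-triplet tone order (0, 1 or 2;
        cyclic rotations of each triplet type). Analyses are
        variant-agnostic.
    """
    if regularity not in ("high", "low"):
        raise ValueError("regularity must be 'high' or 'low'")
    if n_triplets <= 0 or n_triplets % 4:
        raise ValueError("n_triplets must be a positive multiple of 4")
    toneset = toneset or default_toneset()
    rng = np.random.default_rng(seed)
    if regularity == "high":
        tones, _types = _generate_high(rng, n_triplets, variant)
    else:
        tones = _generate_low(rng, n_triplets)
    triplet_ids = np.repeat(np.arange(n_triplets), 3)
    return Sequence(tones, triplet_ids, regularity, toneset, seed)


@dataclass
class TransitionMatrix:
    """First-order tone-transition counts and row-normalised probabilities."""

    counts: np.ndarray
    probabilities: np.ndarray
    empty_rows: np.ndarray  # rows with no outgoing transitions (all-zero)

    def row_entropy(self) -> np.ndarray:
        """Shannon entropy (nats) of each defined probability row."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        return h

    def mean_row_entropy(self) -> float:
        h = self.row_entropy()
        return float(h[~self.empty_rows].mean())


def transition_matrix(seq: Sequence) -> TransitionMatrix:
    """Count i→j transitions between consecutive tones and normalise rows."""
    tones = seq.tones
    if tones.size < 2:
        raise ValueError("need at least 2 tones for a transition matrix")
    n = seq.toneset.n
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (tones[:-1], tones[1:]), 1)
    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    probs = np.zeros((n, n), dtype=float)
    nz = ~empty
    probs[nz] = counts[nz] / row_sums[nz, None]
    return TransitionMatrix(counts, probs, empty)


@dataclass
class ValidationReport:
    """Pass/fail per construction constraint, with first offending position."""

    checks: dict[str, tuple[bool, int | None]]

    @property
    def ok(self) -> bool:
        return all(passed for passed, _ in self.checks.values())

    def failures(self) -> dict[str, int | None]:
        return {k: pos for k, (passed, pos) in self.checks.items() if not passed}


def validate_sequence(seq: Sequence, toneset: ToneSet | None = None) -> ValidationReport:
    """Check every construction constraint on an arbitrary stream.

    Report-only: never raises. Checks length divisibility, tone-count
    balance, consecutive tone repeats, consecutive identical triplets, the
    octave span of every triplet and (for high regularity) the 4-type
    inventory.
    """
    toneset = toneset or seq.toneset
    checks: dict[str, tuple[bool, int | None]] = {}
    tones = seq.tones

    checks["length_divisible_by_3"] = (tones.size % 3 == 0, None if tones.size % 3 == 0 else int(tones.size))

    counts = np.bincount(tones, minlength=toneset.n)
    balanced = counts.max() == counts.min()
    checks["tone_count_balance"] = (bool(balanced), None if balanced else int(np.argmax(counts)))

    rep = np.flatnonzero(tones[:-1] == tones[1:])
    checks["no_consecutive_tone_repeat"] = (rep.size == 0, int(rep[0]) + 1 if rep.size else None)

    if tones.size % 3 == 0 and tones.size >= 6:
        trips = tones.reshape(-1, 3)
        same = np.flatnonzero((trips[:-1] == trips[1:]).all(axis=1))
        checks["no_consecutive_identical_triplet"] = (
            same.size == 0,
            int(same[0]) + 1 if same.size else None,
        )
        spans = trips.max(axis=1) - trips.min(axis=1)
        bad = np.flatnonzero(spans > OCTAVE_INDEX_SPAN)
        checks["octave_span"] = (bad.size == 0, int(bad[0]) if bad.size else None)
        if seq.regularity == "high":
            n_types = len(seq.triplet_inventory())
            checks["four_triplet_types"] = (n_types == 4, None if n_types == 4 else n_types)
    return ValidationReport(checks)


def sequence_to_frame(seq: Sequence):
    """Tidy per-tone table (position, tone index, label, frequency, triplet, onset)."""
    import pandas as pd

    ts = seq.toneset
    return pd.DataFrame(
        {
            "position": np.arange(len(seq)),
            "tone_index": seq.tones,
            "note_label": [ts.labels[t] for t in seq.tones],
            "freq_hz": [ts.frequencies_hz[t] for t in seq.tones],
            "triplet_id": seq.triplet_ids,
            "onset_s": seq.tone_onsets_s,
        }
    )
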