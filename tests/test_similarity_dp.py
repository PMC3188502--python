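import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupscan import (
    Background,
    max_similarity_pairs,
    random_motif,
    sample_markov,
    sequence_information,
    similarity_information,
    total_similarity_information,
)
from dupscan.seq_io import ALPHABET, Motif, encode
from dupscan.similarity_dp import _pair_match_counts


# ---------------------------------------------------------------------------
# Information measures


def test_sequence_information_zero_when_motif_equals_background(uniform_bg):
    motif = Motif(name="flat", freq=np.full((5, 4), 0.25))
    nats, bits = sequence_information(motif, uniform_bg)
    assert nats == pytest.approx(0.0, abs=1e-12)
    assert bits == pytest.approx(0.0, abs=1e-12)


def test_sequence_information_deterministic_motif(uniform_bg):
    freq = np.full((7, 4), 1e-12)
    freq[:, 0] = 1 - 3e-12
    motif = Motif(name="det", freq=freq / freq.sum(axis=1, keepdims=True))
    nats, bits = sequence_information(motif, uniform_bg)
    assert nats == pytest.approx(7 * np.log(4), rel=1e-6)
    assert bits == pytest.approx(14.0, rel=1e-6)


def test_sequence_information_matches_exhaustive_sum(uniform_bg):
    """Per-position relative entropy equals the sum over all 64 sequences of
    Q(a) ln(Q(a)/P0(a)) (product-form exhaustive oracle)."""
    motif = random_motif("M3", length=3, seed=5)
    nats, _ = sequence_information(motif, uniform_bg)
    total = 0.0
    for a in itertools.product(range(4), repeat=3):
        Q = np.prod([motif.freq[i, ai] for i, ai in enumerate(a)])
        P0 = 0.25**3
        total += Q * np.log(Q / P0)
    assert nats == pytest.approx(total, abs=1e-12)


@pytest.mark.parametrize(
    "q,q0,ell,expected",
    [
        (0.25, 0.25, 7, 0.0),
        (1.0, 0.25, 7, 7 * np.log(4)),
        (0.0, 0.5, 3, 3 * np.log(2)),
    ],
)
def test_similarity_information_closed_forms(q, q0, ell, expected):
    assert similarity_information(q, q0, ell) == pytest.approx(expected, abs=1e-12)


def test_similarity_information_nonnegative_zero_iff_background():
    for q in np.linspace(0.01, 0.99, 23):
        h = similarity_information(float(q), 0.25, 7)
        if abs(q - 0.25) < 1e-12:
            assert h == pytest.approx(0.0, abs=1e-12)
        else:
            assert h > 0


def test_similarity_information_matches_simulated_pairs(uniform_bg, rng):
    """Empirical H from motif-drawn pairs matches H of the analytic match
    probability within Monte-Carlo error."""
    from dupscan.synthetic_data import sample_from_motif

    motif = random_motif("peaked", length=7, seed=9, peak_lo=0.8, peak_hi=0.9)
    analytic_q = float(np.mean(np.sum(motif.freq**2, axis=1)))
    n = 20000
    a = sample_from_motif(motif, n, rng)
    b = sample_from_motif(motif, n, rng)
    emp_q = float((a == b).mean())
    se = np.sqrt(analytic_q * (1 - analytic_q) / (7 * n))
    assert abs(emp_q - analytic_q) < 4 * se
    h_emp = similarity_information(emp_q, 0.25, 7)
    h_ana = similarity_information(analytic_q, 0.25, 7)
    assert h_emp == pytest.approx(h_ana, rel=0.05)


def test_pair_information_bounded_by_twice_motif_information(uniform_bg, rng):
    """Sites drawn from a motif carry similarity information between 0 and
    twice the motif information (the rule of thumb is about half of I per
    site, asserted only as a bound)."""
    from dupscan.synthetic_data import sample_from_motif

    motif = random_motif("M", length=7, seed=21)
    I, _ = sequence_information(motif, uniform_bg)
    q = float(np.mean(np.sum(motif.freq**2, axis=1)))
    H = similarity_information(q, 0.25, 7)
    assert 0 < H < 2 * I


# ---------------------------------------------------------------------------
# DP selection


def _brute_force_optimum(seq: str, r: int, ell: int, q_c: float) -> float:
    s = encode(seq)
    counts = _pair_match_counts(s, r, ell)
    xs = np.nonzero(counts >= int(np.ceil(q_c * ell - 1e-9)))[0]
    best = 0.0
    for k in range(len(xs) + 1):
        for comb in itertools.combinations(xs, k):
            if all(comb[i + 1] - comb[i] >= ell for i in range(len(comb) - 1)):
                best = max(best, sum(counts[x] / ell for x in comb))
    return best


def _dp_total(seq: str, r: int, ell: int, q_c: float) -> float:
    ps = max_similarity_pairs(seq, r, ell, q_c)
    counts = _pair_match_counts(encode(seq), r, ell)
    return sum(counts[x] / ell for x in ps.positions)


def test_planted_identical_pair_is_recovered(rng):
    seq = list("".join(rng.choice(list("ACGT"), size=150)))
    seq[40:47] = "GATTACA"
    seq[70:77] = "GATTACA"
    ps = max_similarity_pairs("".join(seq), r=30, ell=7, q_c=6 / 7)
    assert 40 in ps.positions
    assert all(
        _pair_match_counts(encode("".join(seq)), 30, 7)[x] >= 6 for x in ps.positions
    )


def test_sequence_too_short_gives_empty_set():
    ps = max_similarity_pairs("ACGTACGTA", r=5, ell=5, q_c=0.8)  # len == r+ell-1
    assert ps.n == 0 and ps.positions == []


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_dp_equals_brute_force_on_random_inputs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 36))
    seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    r = int(rng.integers(1, 6))
    ell = int(rng.integers(2, 5))
    q_c = float(rng.choice([0.5, 2 / 3, 0.75, 1.0]))
    assert _dp_total(seq, r, ell, q_c) == pytest.approx(
        _brute_force_optimum(seq, r, ell, q_c), abs=1e-12
    )


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_dp_constraints_and_dominates_greedy(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 120))))
    r = int(rng.integers(1, 10))
    ell = int(rng.integers(2, 8))
    q_c = float(rng.choice([0.5, 0.75, 1.0]))
    ps = max_similarity_pairs(seq, r, ell, q_c)
    counts = _pair_match_counts(encode(seq), r, ell)
    min_m = int(np.ceil(q_c * ell - 1e-9))
    # constraints hold
    for a, b in zip(ps.positions, ps.positions[1:]):
        assert b - a >= ell
    assert all(counts[x] >= min_m for x in ps.positions)
    # greedy left-to-right never beats the DP
    greedy, last = 0.0, -ell
    for x in range(len(counts)):
        if counts[x] >= min_m and x - last >= ell:
            greedy += counts[x] / ell
            last = x
    assert _dp_total(seq, r, ell, q_c) >= greedy - 1e-12


# ---------------------------------------------------------------------------
# Null-calibrated information


@pytest.fixture(scope="module")
def markov_null():
    bg = Background.uniform()
    rng = np.random.default_rng(77)
    data = sample_markov(bg, 800, 6, rng)
    nulls = [sample_markov(bg, 800, 6, rng) for _ in range(60)]
    return data, nulls


def test_null_data_gives_information_consistent_with_zero(markov_null):
    data, nulls = markov_null
    ps = total_similarity_information(data, r=20, ell=7, null_ensemble=nulls)
    assert ps.z_information is not None
    assert abs(ps.z_information) < 3.5


def test_planted_pairs_recovered_with_expected_information(markov_null):
    data, nulls = markov_null
    planted = []
    for i, s in enumerate(data):
        s = list(s)
        left = 100 + 37 * i
        s[left + 20 : left + 27] = s[left : left + 7]  # exact copy at lag 20
        planted.append("".join(s))
    ps = total_similarity_information(planted, r=20, ell=7, null_ensemble=nulls)
    assert ps.delta_n == pytest.approx(6, abs=3 * max(ps.sd_n0, 1.0))
    assert ps.total_information > 0
    expected = ps.delta_n * ps.pair_information / ps.segment_length
    assert ps.total_information == pytest.approx(expected, rel=1e-12)


def test_single_achievable_threshold_is_returned(markov_null):
    data, nulls = markov_null
    ps = total_similarity_information(data, r=10, ell=7, null_ensemble=nulls, q_c=1.0)
    assert ps.q_c == pytest.approx(1.0)


def test_empty_null_ensemble_raises(markov_null):
    data, _ = markov_null
    with pytest.raises(ValueError, match="null"):
        total_similarity_information(data, r=10, ell=7, null_ensemble=[])


def test_information_invariant_under_nucleotide_relabeling(markov_null):
    """Relabeling nucleotides (preserving the uniform background) leaves
    I_tilde unchanged."""
    data, nulls = markov_null
    trans = str.maketrans("ACGT", "TGCA")
    ps1 = total_similarity_information(data, r=15, ell=6, null_ensemble=nulls)
    ps2 = total_similarity_information(
        [s.translate(trans) for s in data],
        r=15,
        ell=6,
        null_ensemble=[[s.translate(trans) for s in rz] for rz in nulls],
    )
    assert ps1.n == ps2.n
    assert ps1.total_information == pytest.approx(ps2.total_information, rel=1e-9)
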