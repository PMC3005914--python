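"""Motif autocorrelation: occurrence counting, pair probabilities,
covariance periodograms, permutation-null period calling."""

import numpy as np
import pytest

from nucvarseq import autocorr
from nucvarseq.dna import dinucleotide_shuffle, reverse_complement
from tests.conftest import random_seqs


def test_motif_occurrences_examples():
    assert autocorr.motif_occurrences("CACACA", "CA") == [0, 2, 4]
    assert autocorr.motif_occurrences("CATG", "CA", pair_revcomp=True) == [0, 2]
    assert autocorr.motif_occurrences("GGGG", "CA") == []
    with pytest.raises(ValueError):
        autocorr.motif_occurrences("ACGT", "")


def test_worked_example_cacaca():
    # L=6, l=2: P_X = 3/5; k=2: pairs (0,2),(2,4) -> N=2 over 6-2-2+1=3
    assert autocorr.single_probability("CACACA", "CA") == pytest.approx(3 / 5)
    assert autocorr.pair_probability("CACACA", "CA", 2) == pytest.approx(2 / 3)
    assert autocorr.covariance("CACACA", "CA", 2) == pytest.approx(23 / 75)
    assert autocorr.pair_probability("CACACA", "CA", 1) == 0.0
    with pytest.raises(ValueError):
        autocorr.pair_probability("CACACA", "CA", 5)  # no pairs fit


def test_saturated_motif_has_zero_covariance():
    for k in (1, 2):
        assert autocorr.covariance("AAAA", "AA", k) == pytest.approx(0.0)
    assert autocorr.single_probability("AAAA", "AA") == 1.0


def test_probabilities_bounded(rng):
    for seq in random_seqs(rng, 20, 40):
        for k in range(1, 30):
            if len(seq) - k - 2 + 1 >= 1:
                p = autocorr.pair_probability(seq, "CA", k, pair_revcomp=True)
                assert 0.0 <= p <= 1.0


def brute_force_pair_count(seq, motif, k, pair_revcomp):
    targets = {motif}
    if pair_revcomp:
        targets.add(reverse_complement(motif))
    l = len(motif)
    hits = lambda i: seq[i : i + l] in targets
    return sum(
        1
        for i in range(len(seq) - l - k + 1)
        if hits(i) and hits(i + k)
    )


def test_pair_count_matches_brute_force_oracle(rng):
    seqs = random_seqs(rng, 60, 50)
    for seq in seqs:
        for motif in ("A", "CA", "TG", "CAG"):
            for k in (1, 2, 3, 5, 10):
                if len(seq) - k - len(motif) + 1 < 1:
                    continue
                for pr in (False, True):
                    assert autocorr.pair_count(seq, motif, k, pr) == \
                        brute_force_pair_count(seq, motif, k, pr)


def test_mean_periodogram_identical_sequences():
    seq = "CACGTACACGTACACGTACA"
    pg = autocorr.mean_periodogram([seq] * 5, "CA", k_max=10)
    for k, c in zip(pg.distances, pg.mean_covariance):
        assert c == pytest.approx(autocorr.covariance(seq, "CA", int(k)))
    assert np.all(pg.n_contributing == 5)
    with pytest.raises(ValueError):
        autocorr.mean_periodogram([], "CA")


def test_short_sequences_excluded_per_k():
    pg = autocorr.mean_periodogram(["CACACA", "CACACACACA"], "CA", k_max=7)
    # k up to 4 computable for the 6-mer (L-k-l+1>=1 -> k<=4), up to 7 for the 10-mer
    by_k = dict(zip(pg.distances, pg.n_contributing))
    assert by_k[4] == 2 and by_k[5] == 1 and by_k[7] == 1


def test_flank_changes_only_denominators(rng):
    seq = "".join(rng.choice(list("ACGT"), size=40))
    flanked = "GG" + seq + "GGG"  # flanks free of CA/TG
    for k in (2, 3, 5):
        n = autocorr.pair_count(seq, "CA", k, pair_revcomp=True)
        assert autocorr.pair_count(flanked, "CA", k, pair_revcomp=True) == n
        L2 = len(flanked)
        n_x = len(autocorr.motif_occurrences(flanked, "CA", pair_revcomp=True))
        expected = n / (L2 - k - 2 + 1) - (n_x / (L2 - 2 + 1)) ** 2
        assert autocorr.covariance(flanked, "CA", k, pair_revcomp=True) == \
            pytest.approx(expected)


def test_revcomp_pairing_symmetry(rng):
    seqs = random_seqs(rng, 15, 60)
    rc = [reverse_complement(s) for s in seqs]
    pg1 = autocorr.mean_periodogram(seqs, "CA", k_max=10, pair_revcomp=True)
    pg2 = autocorr.mean_periodogram(rc, "CA", k_max=10, pair_revcomp=True)
    assert np.allclose(pg1.mean_covariance, pg2.mean_covariance)


def test_random_sequences_have_near_zero_mean_covariance(rng):
    seqs = random_seqs(rng, 400, 80)
    pg = autocorr.mean_periodogram(seqs, "CA", k_max=8, pair_revcomp=True)
    # the per-sequence covariance is mean-zero up to O(1/L) bias; with 400
    # sequences the set mean should be small at every k >= motif length
    for k, c in zip(pg.distances, pg.mean_covariance):
        if k >= 2:
            assert abs(c) < 0.01


def test_dinucleotide_shuffle_preserves_composition(rng):
    seq = "".join(rng.choice(list("ACGT"), size=100))
    shuf = dinucleotide_shuffle(seq, rng)
    assert shuf != seq  # overwhelmingly likely at this length
    assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def dinucs(s):
        out = {}
        for a, b in zip(s, s[1:]):
            out[a + b] = out.get(a + b, 0) + 1
        return out

    assert dinucs(shuf) == dinucs(seq)


def test_call_periods_planted_vs_null(rng):
    period_seqs = []
    for _ in range(60):
        s = list(rng.choice(list("ACGT"), size=80))
        start = int(rng.integers(0, 80 - 16))
        s[start : start + 16] = list("CA" * 8)
        period_seqs.append("".join(s))
    pg = autocorr.call_periods(
        period_seqs, "CA", k_max=8, pair_revcomp=True, n_permutations=60, seed=0
    )
    assert {2, 4, 6} <= set(pg.called_periods)
    even = {k: c for k, c in zip(pg.distances, pg.mean_covariance)}
    assert even[2] > even[3] and even[4] > even[5]

    null_seqs = random_seqs(rng, 60, 80)
    pg0 = autocorr.call_periods(
        null_seqs, "CA", k_max=8, pair_revcomp=True, n_permutations=60, seed=0
    )
    assert not ({2, 4, 6} & set(pg0.called_periods))
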