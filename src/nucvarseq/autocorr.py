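"""Motif autocorrelation periodograms.

For a motif X of length l in a sequence S of length L, the probability of
finding an X–X pair at start-to-start distance k is estimated as

    P_XX(k) = N_XX(k) / (L - k - l + 1),

where N_XX(k) counts position pairs (i, i+k) carrying occurrences at both
ends, and the single-occurrence probability is P_X = N_X / (L - l + 1).
The covariance C_XX(k) = P_XX(k) - P_X^2 is zero in expectation for
independent placements; a positive peak at k means X–X pairs at that
spacing are enriched over chance. The periodogram of a sequence set is the
per-k mean of the per-sequence covariances.

A motif may be paired with its reverse complement (the CA/TG convention):
an occurrence is then a hit of either member, counted over the union set.
Period calling uses a per-k permutation null from dinucleotide-preserving
shuffles of the same sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dna import dinucleotide_shuffle, reverse_complement


def motif_occurrences(seq: str, motif: str, pair_revcomp: bool = False) -> list[int]:
    """Sorted start positions of ``motif`` (and, if ``pair_revcomp``, its
    reverse complement) in ``seq``; overlapping occurrences included."""
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = seq.upper()
    targets = {motif.upper()}
    if pair_revcomp:
        targets.add(reverse_complement(motif.upper()))
    l = len(motif)
    return [i for i in range(len(seq) - l + 1) if seq[i : i + l] in targets]


def _occurrence_indicator(seq: str, motif: str, pair_revcomp: bool) -> np.ndarray:
    ind = np.zeros(len(seq) - len(motif) + 1, dtype=np.float64)
    ind[motif_occurrences(seq, motif, pair_revcomp)] = 1.0
    return ind


def pair_count(seq: str, motif: str, k: int, pair_revcomp: bool = False) -> int:
    """N_XX(k): number of position pairs (i, i+k) with occurrences at both."""
    ind = _occurrence_indicator(seq, motif, pair_revcomp)
    if not 1 <= k <= len(ind) - 1:
        raise ValueError(f"distance k={k} out of range for L={len(seq)}")
    return int(np.dot(ind[:-k], ind[k:]))


def pair_probability(seq: str, motif: str, k: int, pair_revcomp: bool = False) -> float:
    """P_XX(k) = N_XX(k) / (L - k - l + 1)."""
    L, l = len(seq), len(motif)
    n_pairs = L - k - l + 1
    if n_pairs < 1:
        raise ValueError(f"no (i, i+{k}) pairs fit in a {L} bp sequence")
    return pair_count(seq, motif, k, pair_revcomp) / n_pairs


def single_probability(seq: str, motif: str, pair_revcomp: bool = False) -> float:
    """P_X = N_X / (L - l + 1)."""
    n_windows = len(seq) - len(motif) + 1
    if n_windows < 1:
        raise ValueError("motif longer than sequence")
    return len(motif_occurrences(seq, motif, pair_revcomp)) / n_windows


def covariance(seq: str, motif: str, k: int, pair_revcomp: bool = False) -> float:
    """C_XX(k) = P_XX(k) - P_X^2."""
    return pair_probability(seq, motif, k, pair_revcomp) - single_probability(
        seq, motif, pair_revcomp
    ) ** 2


def _sequence_covariances(seq: str, motif: str, ks: np.ndarray, pair_revcomp: bool):
    """Covariance at every distance in ``ks`` computable for this sequence."""
    L, l = len(seq), len(motif)
    ind = _occurrence_indicator(seq, motif, pair_revcomp)
    p_x = ind.mean()
    out = np.full(len(ks), np.nan)
    for j, k in enumerate(ks):
        n_pairs = L - k - l + 1  # >= 1 iff k <= L - l
        if n_pairs >= 1:
            out[j] = np.dot(ind[:-k], ind[k:]) / n_pairs - p_x**2
    return out


@dataclass
class Periodogram:
    motif: str
    pair_revcomp: bool
    distances: np.ndarray          # k values
    mean_covariance: np.ndarray    # C̄_XX(k)
    n_contributing: np.ndarray     # sequences contributing per k
    null_quantile: np.ndarray | None = None  # per-k permutation threshold
    called_periods: list[int] | None = None

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "k": self.distances,
                "mean_covariance": self.mean_covariance,
                "n_contributing": self.n_contributing,
            }
        )
        if self.null_quantile is not None:
            df["null_quantile"] = self.null_quantile
            df["called"] = df["k"].isin(self.called_periods or [])
        return df


def mean_periodogram(
    seqs: list[str], motif: str, k_max: int = 50, pair_revcomp: bool = False
) -> Periodogram:
    """Average the per-sequence covariance functions over a sequence set.

    Sequences too short to provide any (i, i+k) pair at a given k are
    excluded from that k's mean and reflected in ``n_contributing``.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    ks = np.arange(1, k_max + 1)
    total = np.zeros(len(ks))
    n = np.zeros(len(ks), dtype=np.int64)
    for seq in seqs:
        c = _sequence_covariances(seq, motif, ks, pair_revcomp)
        mask = ~np.isnan(c)
        total[mask] += c[mask]
        n[mask] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    keep = n > 0
    return Periodogram(
        motif=motif,
        pair_revcomp=pair_revcomp,
        distances=ks[keep],
        mean_covariance=mean[keep],
        n_contributing=n[keep],
    )


def call_periods(
    seqs: list[str],
    motif: str,
    k_max: int = 10,
    pair_revcomp: bool = False,
    n_permutations: int = 200,
    quantile: float = 0.99,
    seed: int = 0,
) -> Periodogram:
    """Periodogram with permutation-null period calling.

    The null preserves each sequence's dinucleotide composition (hence the
    motif's occurrence count for dinucleotide motifs) while destroying any
    spacing preference: each permutation replicate shuffles every sequence
    with the Altschul–Erikson algorithm and recomputes the mean periodogram.
    A distance k is called a period when the observed mean covariance
    exceeds the null's ``quantile`` at that k.
    """
    obs = mean_periodogram(seqs, motif, k_max, pair_revcomp)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(obs.distances)))
    for p in range(n_permutations):
        shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
        pg = mean_periodogram(shuffled, motif, k_max, pair_revcomp)
        null[p] = pg.mean_covariance
    thresh = np.quantile(null, quantile, axis=0)
    obs.null_quantile = thresh
    obs.called_periods = [
        int(k) for k, c, t in zip(obs.distances, obs.mean_covariance, thresh) if c > t
    ]
    return obs
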