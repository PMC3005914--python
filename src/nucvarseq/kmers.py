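"""Canonical k-mer featurization.

Each DNA sequence is represented by counts of canonical k-mers — a k-mer and
its reverse complement collapsed onto one feature — for k = 1..k_max. With
the default k_max = 6 this yields 2 + 10 + 32 + 136 + 512 + 2080 = 2772
features. Counts are normalized per k to relative window frequencies, so a
sequence's k-block sums to one and vectors are comparable across lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import BASES, encode, reverse_complement


def canonical_kmer(s: str) -> str:
    """Return the canonical representative of ``{s, revcomp(s)}``.

    The representative is the lexicographically smaller of the pair, so
    ``canonical_kmer`` is idempotent and strand-symmetric.
    """
    s = s.upper()
    if any(c not in BASES for c in s):
        raise ValueError(f"k-mer contains non-ACGT base: {s!r}")
    rc = reverse_complement(s)
    return s if s <= rc else rc


def _code_of(kmer: str) -> int:
    c = 0
    for b in kmer:
        c = c * 4 + BASES.index(b)
    return c


def _kmer_of(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class KmerIndex:
    """Feature index over canonical k-mers for k = 1..k_max.

    ``kmers`` lists the canonical strings in feature order (k ascending,
    then lexicographic). ``code_to_slot[k]`` maps every 2-bit-packed k-mer
    code (0..4**k-1) to its global feature slot, which is what makes
    vectorized counting possible.
    """

    k_max: int
    kmers: list[str] = field(default_factory=list)
    offsets: list[int] = field(default_factory=list)  # feature offset per k
    code_to_slot: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.kmers)

    def block(self, k: int) -> slice:
        """Feature-slot slice covering all canonical k-mers of one k."""
        lo = self.offsets[k - 1]
        hi = self.offsets[k] if k < self.k_max else self.n_features
        return slice(lo, hi)

    def slot(self, kmer: str) -> int:
        k = len(kmer)
        return int(self.code_to_slot[k][_code_of(canonical_kmer(kmer))])


def build_index(k_max: int = 6) -> KmerIndex:
    """Enumerate canonical k-mers for k = 1..k_max in deterministic order.

    Raises ``ValueError`` unless 1 <= k_max <= 8.
    """
    if not 1 <= k_max <= 8:
        raise ValueError(f"k_max must be in 1..8, got {k_max}")
    idx = KmerIndex(k_max=k_max)
    for k in range(1, k_max + 1):
        idx.offsets.append(len(idx.kmers))
        canon: dict[str, int] = {}
        lookup = np.empty(4**k, dtype=np.int32)
        # enumerate codes in lexicographic order of the k-mer string
        for code in range(4**k):
            km = _kmer_of(code, k)
            c = canonical_kmer(km)
            if c not in canon:
                canon[c] = idx.offsets[-1] + len(canon)
                idx.kmers.append(c)
            lookup[code] = canon[c]
        idx.code_to_slot[k] = lookup
    return idx


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer code of every length-k window plus a validity mask."""
    n_win = len(codes) - k + 1
    if n_win < 1:
        raise ValueError("sequence shorter than k")
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = (win.astype(np.int64) * powers).sum(axis=1)
    return vals, valid


def count_kmers(seq: str, k: int) -> tuple[dict[str, int], int]:
    """Slide a width-k window over ``seq``, counting canonical k-mers.

    Returns ``(counts, n_skipped)`` where ``counts`` maps canonical k-mer to
    occurrence count and ``n_skipped`` is the number of windows skipped for
    containing an ambiguous base. Counted + skipped windows = L - k + 1.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    codes = encode(seq)
    vals, valid = _window_codes(codes, k)
    counts: dict[str, int] = {}
    for code, cnt in zip(*np.unique(vals[valid], return_counts=True)):
        c = canonical_kmer(_kmer_of(int(code), k))
        counts[c] = counts.get(c, 0) + int(cnt)
    return counts, int((~valid).sum())


def featurize(seq: str, index: KmerIndex) -> np.ndarray:
    """Canonical k-mer frequency vector of one sequence.

    For each k, canonical counts are divided by the number of valid
    (ambiguity-free) windows of that k, so each k-block of an N-free
    sequence sums to exactly one.
    """
    if len(seq) < index.k_max:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than k_max={index.k_max}"
        )
    codes = encode(seq)
    vec = np.zeros(index.n_features, dtype=np.float64)
    for k in range(1, index.k_max + 1):
        vals, valid = _window_codes(codes, k)
        slots = index.code_to_slot[k][vals[valid]]
        np.add.at(vec, slots, 1.0)
        n_valid = int(valid.sum())
        if n_valid:
            vec[index.block(k)] /= n_valid
    return vec


@dataclass
class LabeledDataset:
    """Feature matrix with ±1 labels and per-row sequence ids."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.ids):
            raise ValueError("rows, labels and ids must align")


def featurize_dataset(
    seqs: list[tuple[str, str, int]], index: KmerIndex
) -> LabeledDataset:
    """Featurize ``(id, sequence, label)`` triples; row order is preserved."""
    rows, ys, ids = [], [], []
    for sid, seq, label in seqs:
        try:
            rows.append(featurize(seq, index))
        except ValueError as e:
            raise ValueError(f"sequence {sid!r}: {e}") from e
        ys.append(label)
        ids.append(sid)
    X = np.vstack(rows) if rows else np.empty((0, index.n_features))
    return LabeledDataset(X=X, y=np.asarray(ys, dtype=np.int64), ids=ids)


def write_features_tsv(data: LabeledDataset, index: KmerIndex, path) -> None:
    import pandas as pd

    df = pd.DataFrame(data.X, columns=index.kmers)
    df.insert(0, "label", data.y)
    df.insert(0, "id", data.ids)
    df.to_csv(path, sep="\t", index=False)
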