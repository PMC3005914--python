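"""Small DNA helpers shared across modules: encoding, reverse complement,
and a dinucleotide-composition-preserving shuffle."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; ambiguous/other bytes -> -1. Lowercase (soft-masked)
# bases are valid for counting; masking policy is handled upstream in prep.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0,C=1,G=2,T=3; anything else -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide composition.

    Altschul–Erikson algorithm: the sequence is an Eulerian walk on the
    4-vertex graph whose edges are its dinucleotides. A uniform shuffle is
    obtained by fixing, for each vertex other than the final one, a random
    "last exit" edge such that the last-exit edges form a tree toward the
    final vertex, then permuting each vertex's remaining exits.

    Only A/C/G/T sequences are supported; sequences of length < 3 are
    returned unchanged (nothing to shuffle).
    """
    n = len(seq)
    if n < 3:
        return seq
    if encode(seq).min() < 0:
        raise ValueError("dinucleotide_shuffle requires an unambiguous ACGT sequence")

    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]

    # Pick last-exit edges until they form a tree rooted at `last`.
    while True:
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_exit:
            rest.remove(last_exit[v])
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
        if v in last_exit:
            rest.append(last_exit[v])
        shuffled[v] = rest

    out = [seq[0]]
    pos = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
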