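"""Data preparation for nucleosome-call sequence sets.

Steps: standardize every called nucleosome interval to a fixed length
(default 150 bp) about its midpoint; deduplicate the gene table by probe id;
build TSS-vicinity windows (default 10 kb upstream / 2 kb downstream);
keep nucleosomes whose midpoint falls in a window; extract their genomic
sequences; and draw balanced training subsets per variant contrast.

Coordinates are 0-based half-open (BED convention) throughout; the TSS
column in the gene table is a 0-based position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    start: int
    end: int
    variant: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    probe_id: str | None = None


@dataclass(frozen=True)
class TssWindow:
    chrom: str
    start: int
    end: int
    gene_id: str


def standardize_length(call: NucleosomeCall, target: int = 150) -> NucleosomeCall:
    """Truncate/extend ``call`` to exactly ``target`` bp about its midpoint.

    When the interval's parity differs from the target's, the extra base goes
    to the right (3' in genome coordinates). Idempotent for length == target.
    The result may have a negative start; use ``standardize_calls`` to drop
    intervals that would leave chromosome bounds.
    """
    if target <= 0:
        raise ValueError("target length must be positive")
    new_start = (call.start + call.end - target + 1) // 2
    return replace(call, start=new_start, end=new_start + target)


def standardize_calls(
    calls: list[NucleosomeCall],
    chrom_sizes: dict[str, int],
    target: int = 150,
) -> tuple[list[NucleosomeCall], int]:
    """Standardize all calls, excluding (and counting) any whose standardized
    interval would extend past its chromosome's bounds."""
    kept, excluded = [], 0
    for call in calls:
        std = standardize_length(call, target)
        if std.start < 0 or std.end > chrom_sizes.get(std.chrom, 0):
            excluded += 1
        else:
            kept.append(std)
    return kept, excluded


def dedup_genes(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Drop genes without a probe id or on random/haplotype contigs; keep one
    gene (the first in input order) per probe id."""
    seen: set[str] = set()
    out = []
    for g in genes:
        if not g.probe_id:
            continue
        name = g.chrom.lower()
        if "random" in name or "_hap" in name:
            continue
        if g.probe_id in seen:
            continue
        seen.add(g.probe_id)
        out.append(g)
    return out


def build_tss_windows(
    genes: list[GeneRecord],
    upstream: int = 10_000,
    downstream: int = 2_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[TssWindow]:
    """TSS-vicinity windows, strand-aware: [tss-upstream, tss+downstream) on
    +, mirrored on -. Clipped at chromosome bounds when sizes are given."""
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be non-negative")
    if upstream + downstream == 0:
        raise ValueError("window extents are both zero: empty windows")
    windows = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream, g.tss + upstream
        start = max(start, 0)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes.get(g.chrom, end))
        if start < end:
            windows.append(TssWindow(g.chrom, start, end, g.gene_id))
    return windows


def filter_to_windows(
    calls: list[NucleosomeCall], windows: list[TssWindow]
) -> list[NucleosomeCall]:
    """Keep calls whose midpoint lies inside at least one window.

    Membership is by midpoint (single unambiguous assignment). Output order
    follows the input; a call overlapping several windows appears once.
    """
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end)
    kept = []
    for call in calls:
        tree = trees.get(call.chrom)
        if tree is not None and tree.overlaps_point(call.midpoint):
            kept.append(call)
    return kept


@dataclass
class ExtractionStats:
    n_extracted: int = 0
    n_ambiguous: int = 0
    n_masked: int = 0


def extract_sequences(
    calls: list[NucleosomeCall],
    genome,
    mask_fraction: float = 0.5,
) -> tuple[list[tuple[str, str, str]], ExtractionStats]:
    """Extract the genomic sequence of every call.

    ``genome`` is a mapping of chromosome name to sequence, or a FASTA path
    (read through pyfaidx). Sequences containing ambiguous bases (N) are
    excluded and counted, as are sequences with more than ``mask_fraction``
    soft-masked (lowercase) bases. Returns uppercase sequences as
    ``(id, sequence, variant)`` triples plus exclusion counters.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        genome = {name: str(fa[name][:]) for name in fa.keys()}
    stats = ExtractionStats()
    out = []
    for i, call in enumerate(calls):
        if call.chrom not in genome:
            raise KeyError(f"chromosome {call.chrom!r} missing from genome")
        seq = genome[call.chrom][call.start : call.end]
        if len(seq) != call.end - call.start:
            raise ValueError(f"call {call} extends past chromosome end")
        n_lower = sum(c.islower() for c in seq)
        upper = seq.upper()
        if any(c not in "ACGT" for c in upper):
            stats.n_ambiguous += 1
            continue
        if n_lower > mask_fraction * len(seq):
            stats.n_masked += 1
            continue
        out.append((f"{call.chrom}:{call.start}-{call.end}_{i}", upper, call.variant))
        stats.n_extracted += 1
    return out, stats


def make_training_pairs(
    seqs_by_variant: dict[str, list[tuple[str, str]]],
    class_a: str,
    class_b: str,
    n_a: int,
    n_b: int,
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Sample, without replacement, ``n_a`` class-A sequences (label +1) and
    ``n_b`` class-B sequences (label -1). Deterministic under ``seed``.

    ``seqs_by_variant`` maps variant name to ``(id, sequence)`` pairs.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str, int]] = []
    for variant, n, label in ((class_a, n_a, 1), (class_b, n_b, -1)):
        pool = seqs_by_variant.get(variant, [])
        if len(pool) < n:
            raise ValueError(
                f"requested {n} sequences of variant {variant!r}, "
                f"only {len(pool)} available"
            )
        picks = rng.choice(len(pool), size=n, replace=False)
        out.extend((pool[i][0], pool[i][1], label) for i in picks)
    return out


def group_by_variant(
    triples: list[tuple[str, str, str]]
) -> dict[str, list[tuple[str, str]]]:
    """Regroup extract_sequences output by variant label."""
    out: dict[str, list[tuple[str, str]]] = {}
    for sid, seq, variant in triples:
        out.setdefault(variant, []).append((sid, seq))
    return out


# ---------------------------------------------------------------------------
# Readers


def read_bed_calls(path) -> list[NucleosomeCall]:
    """Read nucleosome calls from BED; the name column holds the variant."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        NucleosomeCall(str(r[0]), int(r[1]), int(r[2]), str(r[3]))
        for r in df.itertuples(index=False)
    ]


def read_gene_table(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    out = []
    for r in df.itertuples(index=False):
        probe = r.probe_id if isinstance(r.probe_id, str) and r.probe_id else None
        out.append(GeneRecord(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss), probe))
    return out


def read_genome_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def variant_counts(calls: list[NucleosomeCall]) -> dict[str, int]:
    return dict(Counter(c.variant for c in calls))
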