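"""Synthetic sequence sets and a miniature genome fixture.

The generator emulates the statistical structure of two-class nucleosomal
sequence sets: fixed-length (default 150 bp) DNA drawn from a configurable
background, with class-differential Poisson insertion of chosen motifs
(e.g. CA/TG-family vs AT-rich) and an optional planted periodic run of a
motif at a fixed start-to-start spacing. Everything is deterministic under
the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dna import BASES

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
#: human-like 40% GC preset
GC40_BACKGROUND = (0.30, 0.20, 0.20, 0.30)

VARIANTS = ("double", "h2az_only", "h33_only")


@dataclass
class PlantedPeriod:
    """A tandem/periodic run of ``motif`` planted into class-1 sequences.

    ``spacing`` is the start-to-start distance between consecutive copies,
    so spacing == len(motif) gives a contiguous tandem run. ``fraction`` of
    class-1 sequences carry the run at a uniformly random start.
    """

    motif: str
    spacing: int
    copies: int
    fraction: float = 1.0

    @property
    def span(self) -> int:
        return (self.copies - 1) * self.spacing + len(self.motif)


@dataclass
class SyntheticSpec:
    """Parameters of a two-class synthetic sequence experiment."""

    n_per_class: int
    seq_length: int = 150
    background_freqs: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    enriched_motifs_class1: list[tuple[str, float]] = field(default_factory=list)
    enriched_motifs_class2: list[tuple[str, float]] = field(default_factory=list)
    planted_period: PlantedPeriod | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        if any(f < 0 for f in self.background_freqs):
            raise ValueError("background_freqs must be non-negative")
        for motifs in (self.enriched_motifs_class1, self.enriched_motifs_class2):
            expected_bases = 0.0
            for motif, rate in motifs:
                if rate < 0:
                    raise ValueError(f"negative insertion rate for {motif!r}")
                if len(motif) > self.seq_length:
                    raise ValueError(
                        f"motif {motif!r} longer than seq_length={self.seq_length}"
                    )
                expected_bases += rate * len(motif)
            if expected_bases > self.seq_length:
                raise ValueError(
                    "expected planted bases exceed sequence length "
                    f"({expected_bases:.1f} > {self.seq_length})"
                )
        if self.planted_period is not None:
            p = self.planted_period
            if not 0 <= p.fraction <= 1:
                raise ValueError("planted_period fraction must be in [0, 1]")
            if p.spacing < 1 or p.copies < 1:
                raise ValueError("planted_period spacing and copies must be >= 1")
            if p.span > self.seq_length:
                raise ValueError(
                    f"planted run spans {p.span} bp > seq_length={self.seq_length}"
                )


def _background(rng: np.random.Generator, n: int, length: int, freqs) -> list[list[str]]:
    draws = rng.choice(list(BASES), size=(n, length), p=list(freqs))
    return [list(row) for row in draws]


def _insert_motifs(seq: list[str], motifs, rng: np.random.Generator) -> None:
    # Poisson number of copies per motif; each copy overwrites the background
    # at a uniform start. Overlaps between insertions are allowed.
    for motif, rate in motifs:
        if rate == 0:
            continue
        for _ in range(rng.poisson(rate)):
            start = int(rng.integers(0, len(seq) - len(motif) + 1))
            seq[start : start + len(motif)] = list(motif)


def _plant_period(seq: list[str], p: PlantedPeriod, rng: np.random.Generator) -> None:
    start = int(rng.integers(0, len(seq) - p.span + 1))
    for c in range(p.copies):
        s = start + c * p.spacing
        seq[s : s + len(p.motif)] = list(p.motif)


def generate_class_sequences(
    spec: SyntheticSpec,
) -> tuple[list[str], list[str]]:
    """Generate the two labeled sequence sets described by ``spec``.

    Returns ``(class1, class2)``, each a list of ``n_per_class`` sequences of
    ``seq_length`` bp. Class-1 sequences receive class-1 motif insertions and
    (if configured) the planted periodic run; class-2 sequences receive
    class-2 insertions. Identical spec + seed gives identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out: list[list[str]] = []
    for cls, motifs in ((1, spec.enriched_motifs_class1), (2, spec.enriched_motifs_class2)):
        seqs = _background(rng, spec.n_per_class, spec.seq_length, spec.background_freqs)
        for seq in seqs:
            _insert_motifs(seq, motifs, rng)
            if cls == 1 and spec.planted_period is not None:
                if rng.random() < spec.planted_period.fraction:
                    _plant_period(seq, spec.planted_period, rng)
        out.append(["".join(s) for s in seqs])
    return out[0], out[1]


def as_labeled_triples(
    class1: list[str], class2: list[str], label1: int = 1, label2: int = -1
) -> list[tuple[str, str, int]]:
    """Flatten two classes into (id, sequence, label) triples for featurization."""
    triples = [(f"c1_{i}", s, label1) for i, s in enumerate(class1)]
    triples += [(f"c2_{i}", s, label2) for i, s in enumerate(class2)]
    return triples


# ---------------------------------------------------------------------------
# Genome fixture


@dataclass
class GenomeFixture:
    """A miniature genome with labeled nucleosome calls and a gene table.

    chromosomes: name -> DNA string
    nucleosomes: (chrom, start, end, variant) with 0-based half-open coords
    genes: (gene_id, chrom, strand, tss, probe_id)
    """

    chromosomes: dict[str, str]
    nucleosomes: list[tuple[str, int, int, str]]
    genes: list[tuple[str, str, str, int, str]]

    def validate(self) -> None:
        for chrom, start, end, variant in self.nucleosomes:
            L = len(self.chromosomes[chrom])
            if not (0 <= start < end <= L):
                raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
            if variant not in VARIANTS:
                raise ValueError(f"unknown variant {variant!r}")
        for _, chrom, strand, tss, _ in self.genes:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if not 0 <= tss < len(self.chromosomes[chrom]):
                raise ValueError("TSS out of chromosome bounds")


def generate_genome_fixture(
    n_chrom: int = 2,
    chrom_length: int = 50_000,
    n_nucleosomes: int = 200,
    n_genes: int = 20,
    seed: int = 0,
) -> GenomeFixture:
    """Random genome fixture: uniform-background chromosomes, nucleosome
    intervals of 80-220 bp with variant labels, genes with random strand and
    TSS. Deterministic under ``seed``."""
    if chrom_length < 200:
        raise ValueError("chrom_length must be >= 200")
    if min(n_chrom, n_nucleosomes, n_genes) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": "".join(rng.choice(list(BASES), size=chrom_length))
        for i in range(n_chrom)
    }
    names = list(chroms)
    nucs = []
    for _ in range(n_nucleosomes):
        chrom = names[rng.integers(len(names))]
        length = int(rng.integers(80, 221))
        start = int(rng.integers(0, chrom_length - length + 1))
        variant = VARIANTS[rng.integers(len(VARIANTS))]
        nucs.append((chrom, start, start + length, variant))
    genes = []
    for g in range(n_genes):
        chrom = names[rng.integers(len(names))]
        strand = "+-"[rng.integers(2)]
        tss = int(rng.integers(0, chrom_length))
        genes.append((f"gene{g}", chrom, strand, tss, f"probe{g}"))
    fx = GenomeFixture(chromosomes=chroms, nucleosomes=nucs, genes=genes)
    fx.validate()
    return fx


def write_fixture(fixture: GenomeFixture, directory) -> dict[str, Path]:
    """Write the fixture as genome.fa (<=80-col FASTA), nucleosomes.bed
    (BED6, variant in the name column) and genes.tsv. Returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": d / "genome.fa",
        "bed": d / "nucleosomes.bed",
        "genes": d / "genes.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for name, seq in fixture.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["bed"], "w") as fh:
        for chrom, start, end, variant in fixture.nucleosomes:
            fh.write(f"{chrom}\t{start}\t{end}\t{variant}\t0\t+\n")
    with open(paths["genes"], "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tprobe_id\n")
        for gene_id, chrom, strand, tss, probe in fixture.genes:
            fh.write(f"{gene_id}\t{chrom}\t{strand}\t{tss}\t{probe}\n")
    return paths


def write_sequence_fasta(path, triples: list[tuple[str, str, int]]) -> None:
    """Write (id, seq, label) triples as FASTA with the label in the header."""
    with open(path, "w") as fh:
        for sid, seq, label in triples:
            fh.write(f">{sid} label={label:+d}\n{seq}\n")
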