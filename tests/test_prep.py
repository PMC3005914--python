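"""Preparation stage: length standardization, TSS windows, extraction,
training-pair subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucvarseq import prep, synthetic
from nucvarseq.prep import GeneRecord, NucleosomeCall, TssWindow


@pytest.mark.parametrize(
    "start,end,expected",
    [
        (1000, 1150, (1000, 1150)),  # already 150 bp
        (1000, 1200, (1025, 1175)),  # truncation about midpoint 1100
        (1000, 1100, (975, 1125)),   # extension about midpoint 1050
    ],
)
def test_standardize_length_examples(start, end, expected):
    call = NucleosomeCall("chr1", start, end, "double")
    std = prep.standardize_length(call, 150)
    assert (std.start, std.end) == expected
    assert std.end - std.start == 150


def test_standardize_length_rejects_bad_target():
    with pytest.raises(ValueError):
        prep.standardize_length(NucleosomeCall("chr1", 0, 10, "double"), 0)


@given(start=st.integers(0, 10_000), length=st.integers(1, 400))
@settings(max_examples=200, deadline=None)
def test_standardize_length_idempotent(start, length):
    call = NucleosomeCall("chr1", start, start + length, "double")
    once = prep.standardize_length(call, 150)
    twice = prep.standardize_length(once, 150)
    assert (once.start, once.end) == (twice.start, twice.end)
    assert once.end - once.start == 150
    # shares the original midpoint to within the parity rule (right-biased)
    assert abs((once.start + once.end) / 2 - call.midpoint) <= 0.5


def test_standardize_calls_excludes_boundary_clips():
    calls = [
        NucleosomeCall("chr1", 10, 60, "double"),      # would extend below 0
        NucleosomeCall("chr1", 500, 650, "double"),    # fine
        NucleosomeCall("chr1", 940, 990, "double"),    # would extend past 1000
    ]
    kept, excluded = prep.standardize_calls(calls, {"chr1": 1000}, 150)
    assert excluded == 2
    assert [(c.start, c.end) for c in kept] == [(500, 650)]


def test_dedup_genes_rules():
    genes = [
        GeneRecord("g1", "chr1", "+", 100, "P1"),
        GeneRecord("g2", "chr1", "+", 200, "P1"),        # duplicate probe
        GeneRecord("g3", "chr1", "-", 300, None),        # no probe
        GeneRecord("g4", "chr1_random", "+", 400, "P2"),
        GeneRecord("g5", "chr6_hap1", "+", 500, "P3"),
        GeneRecord("g6", "chr2", "-", 600, "P4"),
    ]
    out = prep.dedup_genes(genes)
    assert [g.gene_id for g in out] == ["g1", "g6"]  # first per probe retained
    assert prep.dedup_genes([]) == []


@pytest.mark.parametrize(
    "strand,expected",
    [("+", (40_000, 52_000)), ("-", (48_000, 60_000))],
)
def test_tss_windows_strand_aware(strand, expected):
    g = GeneRecord("g", "chr1", strand, 50_000, "P")
    (w,) = prep.build_tss_windows([g], 10_000, 2_000)
    assert (w.start, w.end) == expected
    assert w.end - w.start == 12_000


def test_tss_windows_degenerate_rejected():
    g = GeneRecord("g", "chr1", "+", 100, "P")
    with pytest.raises(ValueError):
        prep.build_tss_windows([g], 0, 0)
    with pytest.raises(ValueError):
        prep.build_tss_windows([g], -5, 100)


def test_filter_to_windows_matches_brute_force(fixture_genome):
    fx, _ = fixture_genome
    sizes = {c: len(s) for c, s in fx.chromosomes.items()}
    calls = [prep.NucleosomeCall(*t) for t in fx.nucleosomes]
    std, _ = prep.standardize_calls(calls, sizes, 150)
    genes = prep.dedup_genes([GeneRecord(*g) for g in fx.genes])
    windows = prep.build_tss_windows(genes, 2_000, 500, sizes)
    kept = prep.filter_to_windows(std, windows)
    # O(n*m) oracle: midpoint-in-window scan
    expected = [
        c
        for c in std
        if any(
            w.chrom == c.chrom and w.start <= c.midpoint < w.end for w in windows
        )
    ]
    assert kept == expected
    assert len(kept) > 0
    # calls on a chromosome without windows are dropped
    lone = [NucleosomeCall("chrZ", 0, 150, "double")]
    assert prep.filter_to_windows(lone, windows) == []


def test_extract_sequences_substring_and_exclusions():
    genome = {"chr1": "ACGT" * 100 + "N" * 10 + "acgt" * 50}
    calls = [
        NucleosomeCall("chr1", 0, 8, "double"),
        NucleosomeCall("chr1", 398, 412, "double"),   # spans the Ns
        NucleosomeCall("chr1", 410, 430, "double"),   # fully soft-masked
    ]
    triples, stats_ = prep.extract_sequences(calls, genome)
    assert len(triples) == 1
    assert triples[0][1] == "ACGTACGT"
    assert stats_.n_ambiguous == 1
    assert stats_.n_masked == 1
    with pytest.raises(KeyError, match="chrX"):
        prep.extract_sequences([NucleosomeCall("chrX", 0, 5, "double")], genome)


def test_extract_sequences_roundtrip_on_fixture(fixture_genome):
    fx, paths = fixture_genome
    calls = [prep.NucleosomeCall(*t) for t in fx.nucleosomes[:20]]
    triples, _ = prep.extract_sequences(calls, paths["fasta"])
    for (sid, seq, variant), call in zip(triples, calls):
        assert seq == fx.chromosomes[call.chrom][call.start : call.end].upper()
        assert variant == call.variant


def test_make_training_pairs_sampling():
    pools = {
        "double": [(f"d{i}", "ACGT") for i in range(40)],
        "h2az_only": [(f"z{i}", "ACGT") for i in range(25)],
    }
    out = prep.make_training_pairs(pools, "double", "h2az_only", 20, 20, seed=1)
    labels = [l for _, _, l in out]
    assert labels.count(1) == 20 and labels.count(-1) == 20
    ids = [i for i, _, _ in out]
    assert len(set(ids)) == len(ids)  # no within-class duplicates
    assert out == prep.make_training_pairs(pools, "double", "h2az_only", 20, 20, seed=1)
    assert out != prep.make_training_pairs(pools, "double", "h2az_only", 20, 20, seed=2)
    with pytest.raises(ValueError, match="25"):
        prep.make_training_pairs(pools, "double", "h2az_only", 20, 30, seed=1)
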