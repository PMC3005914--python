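#!/usr/bin/env python
"""Run the preparation funnel on the simulated genome fixture.

Mirrors the real-data preparation: standardize every nucleosome call to
150 bp about its midpoint, deduplicate the gene table, build TSS windows
(10 kb upstream / 2 kb downstream), keep nucleosomes whose midpoint falls
inside a window, extract their sequences, and report the record counts at
every stage — the structural analogue of the real funnel. Requires
01_simulate_datasets.py to have run.
"""

import json
from pathlib import Path

from nucvarseq import prep

SCRATCH = Path("scratch/data/fixture")
RESULTS = Path("results")


def main():
    genome = prep.read_genome_fasta(SCRATCH / "genome.fa")
    sizes = {c: len(s) for c, s in genome.items()}
    calls = prep.read_bed_calls(SCRATCH / "nucleosomes.bed")
    std, n_clipped = prep.standardize_calls(calls, sizes, target=150)
    genes = prep.dedup_genes(prep.read_gene_table(SCRATCH / "genes.tsv"))
    windows = prep.build_tss_windows(genes, 10_000, 2_000, sizes)
    kept = prep.filter_to_windows(std, windows)
    triples, stats = prep.extract_sequences(kept, genome)

    funnel = {
        "input_calls": len(calls),
        "standardized": len(std),
        "clipped_at_boundaries": n_clipped,
        "genes_after_dedup": len(genes),
        "tss_windows": len(windows),
        "in_tss_windows": len(kept),
        "extracted": stats.n_extracted,
        "excluded_ambiguous": stats.n_ambiguous,
        "excluded_masked": stats.n_masked,
        "by_variant": prep.variant_counts(kept),
    }
    (RESULTS / "prep_funnel.json").write_text(json.dumps(funnel, indent=2))
    for k, v in funnel.items():
        print(f"{k}: {v}")


if __name__ == "__main__":
    main()
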