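#!/usr/bin/env python
"""Generate the synthetic study inputs.

Three artifacts, all seed-controlled:
  * a null two-class set (no planted signal) — the negative control,
  * a planted-signal set (CA/TG + CAG enrichment and spacing-2 CA runs in
    the "double" class; AT-rich motifs in the "h2az_only" class),
  * a miniature genome fixture (FASTA + BED + gene table) for the prep stage.

Sequence FASTAs and the fixture are written under scratch/ (they are
regenerable from the seeds); a small manifest of what was generated goes to
results/.
"""

import json
from pathlib import Path

from nucvarseq import synthetic

SEED = 42
SCRATCH = Path("scratch/data")
RESULTS = Path("results")

NULL_SPEC = synthetic.SyntheticSpec(n_per_class=300, seed=SEED)

PLANTED_SPEC = synthetic.SyntheticSpec(
    n_per_class=300,
    seed=SEED,
    enriched_motifs_class1=[("CA", 6.0), ("CAG", 2.0)],
    enriched_motifs_class2=[("AAT", 2.0), ("TA", 3.0)],
    planted_period=synthetic.PlantedPeriod("CA", spacing=2, copies=8, fraction=0.5),
)


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    manifest = {"seed": SEED}

    for name, spec in (("null", NULL_SPEC), ("planted", PLANTED_SPEC)):
        c1, c2 = synthetic.generate_class_sequences(spec)
        path = SCRATCH / f"{name}_sequences.fa"
        synthetic.write_sequence_fasta(path, synthetic.as_labeled_triples(c1, c2))
        manifest[name] = {
            "n_per_class": spec.n_per_class,
            "seq_length": spec.seq_length,
            "class1_motifs": spec.enriched_motifs_class1,
            "class2_motifs": spec.enriched_motifs_class2,
            "planted_period": (
                None
                if spec.planted_period is None
                else vars(spec.planted_period)
            ),
            "fasta": str(path),
        }
        print(f"{name}: wrote {2 * spec.n_per_class} sequences to {path}")

    fx = synthetic.generate_genome_fixture(
        n_chrom=2, chrom_length=50_000, n_nucleosomes=400, n_genes=30, seed=SEED
    )
    paths = synthetic.write_fixture(fx, SCRATCH / "fixture")
    manifest["fixture"] = {k: str(v) for k, v in paths.items()}
    print(f"fixture: {len(fx.chromosomes)} chromosomes, "
          f"{len(fx.nucleosomes)} nucleosomes, {len(fx.genes)} genes")

    (RESULTS / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
    print("manifest -> results/simulation_manifest.json")


if __name__ == "__main__":
    main()
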