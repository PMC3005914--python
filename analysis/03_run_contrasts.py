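#!/usr/bin/env python
"""Run the full analysis on the planted-signal and null datasets.

For each dataset: canonical k-mer featurization (2,772 features), 10-fold
cross-validated RBF-SVM with the t-test against the 0.5 baseline,
Fisher-score motif ranking, and CA/TG autocorrelation periodograms with
permutation-null period calling, computed on each class's full pool.

Expected outcome: the planted contrast shows AUC well above 0.5 with
CA-family motifs at the top of the F-score table (direction "+") and called
periods {2, 4, 6} in the enriched class only; the null contrast shows no
called periods and a single-replicate AUC near 0.5 (one 10-fold CV run
fluctuates by a few hundredths; the replicated average sits at 0.5).
"""

import logging
import sys
from importlib import import_module
from pathlib import Path

from nucvarseq import pipeline

sys.path.insert(0, str(Path(__file__).parent))
sim = import_module("01_simulate_datasets")  # reuse the study specs/seed


def config_for(name, spec):
    return pipeline.RunConfig(
        synthetic_spec=spec,
        contrasts=[
            pipeline.ContrastConfig(f"{name}_double_vs_h2az", "double", "h2az_only", 300, 300)
        ],
        autocorr_motifs=["CA"],
        autocorr_k_max=10,
        autocorr_permutations=200,
        seed=sim.SEED,
        out_dir=f"results/run_{name}",
    )


def main():
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    for name, spec in (("planted", sim.PLANTED_SPEC), ("null", sim.NULL_SPEC)):
        print(f"=== {name} contrast ===")
        bundles = pipeline.run(config_for(name, spec))
        for bname, b in bundles.items():
            cv = b["cv"]
            print(f"{bname}: mean AUC {cv['mean_auc']:.3f} (SD {cv['sd_auc']:.3f}), "
                  f"t={cv['t_statistic']:.2f}, p={cv['p_value']:.2e}")
            print(b["fscore_top20"].head(5).to_string(index=False))
            for key, pg in b["periodograms"].items():
                print(f"  {key}: called periods {pg.called_periods}")


if __name__ == "__main__":
    main()
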