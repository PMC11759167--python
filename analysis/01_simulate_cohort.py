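#!/usr/bin/env python
"""Simulate the synthetic study cohort every later step analyzes.

Generates (a) a 2x2 factorial RNA-seq count matrix — four arms (control,
UVSSR, ozone, co-exposure) x 3 replicates, negative-binomial counts, 2,000
genes of which 20% carry planted effects split evenly over the eight
interaction components — and (b) an L*-style phenotype table (5 replicates
per arm) in which each single stressor darkens the tissue and co-exposure
darkens it further. Writes counts, design, ground truth and phenotype under
results/data/.
"""

from pathlib import Path

import synfact as sf
from synfact import io
from synfact.simulate import write_truth

SEED = 20260922
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = sf.SimulationConfig(n_genes=2000, dispersion=0.05, seed=SEED)
    cm, design, truth = sf.simulate_counts(cfg)
    io.write_counts(cm, OUT / "counts.tsv")
    io.write_design(design, OUT / "design.tsv")
    write_truth(truth, OUT / "truth.tsv")
    n_planted = int((truth["component"] != "null").sum())
    print(f"counts: {cm.n_genes} genes x {cm.n_samples} samples")
    print(f"planted effect genes: {n_planted} "
          f"({n_planted / cm.n_genes:.0%}, 8 components x {n_planted // 8})")

    ph = sf.simulate_phenotype(
        (60.0, 55.0, 55.0, 50.0), sd=1.0, replicates=5, seed=SEED + 1
    )
    io.write_phenotype(ph, OUT / "phenotype.tsv")
    print("phenotype: L*-style lightness, arms control/uvssr/ozone/co = "
          "60/55/55/50, sd 1.0, 5 replicates per arm")
    print(f"wrote {OUT}/counts.tsv, design.tsv, truth.tsv, phenotype.tsv")


if __name__ == "__main__":
    main()
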