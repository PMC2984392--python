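#!/usr/bin/env python
"""Simulate the pooled case-control study and write its raw artifacts.

Emulates the design this package models: 1418 depression cases (all blood
DNA) and 1301 controls (roughly 10/28 blood, the rest cheek-swab DNA),
stratified by sex and a three-level BMI-band covariate, randomly pooled at
~48 individuals per pool, three pools hybridized in duplicate. The SNP
panel is scaled to 2,000 markers so the full analysis chain runs in
seconds. Writes the cohort tables, pool design and probe intensities under
results/sim/.
"""

from pathlib import Path

from snpmap import SimulationConfig, build_pools, simulate_cohort, simulate_intensities
from snpmap.io import write_cohort, write_design, write_intensities

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

CONFIG = SimulationConfig(n_snps=2000, seed=2010)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(CONFIG)
    design = build_pools(cohort, CONFIG)
    matrix = simulate_intensities(design, cohort, CONFIG)

    write_cohort(cohort, OUT)
    write_design(design, OUT / "design.tsv")
    write_intensities(matrix, OUT / "intensities.tsv")

    n_case = sum(p.phenotype == "case" for p in design.pools)
    n_ctrl = len(design.pools) - n_case
    sizes = [p.size for p in design.pools]
    print(f"cohort: {CONFIG.n_cases} cases + {CONFIG.n_controls} controls, "
          f"{CONFIG.n_snps} SNPs")
    print(f"pools: {len(design.pools)} ({n_case} case / {n_ctrl} control), "
          f"mean size {sum(sizes) / len(sizes):.2f}")
    print(f"hybridizations: {matrix.n_hybridizations} "
          f"({CONFIG.n_technical_replicates} pools in duplicate)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
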