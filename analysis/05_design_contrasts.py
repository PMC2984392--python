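#!/usr/bin/env python
"""Array-design and sample-quality contrasts.

Quantifies the three design factors that make pooled allelotyping harder on
a high-density chip: (1) losing mismatch probes (PM-only scoring slumps
toward 0.5 and loses accuracy that MM subtraction would recover), (2) low
probe redundancy (6-8 probes per SNP vs 24 or 40 on older designs), and
(3) DNA quality (blood vs cheek-swab presets). Writes
results/design_contrasts.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from snpmap import (
    SimulationConfig,
    allelotype,
    build_pools,
    simulate_cohort,
    simulate_intensities,
)
from snpmap.validation import ras_truth_correlation

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2010


def run(label, **overrides):
    params = dict(
        n_cases=480, n_controls=480, n_snps=1000, seed=SEED,
        case_blood_fraction=1.0, control_blood_fraction=1.0,
    )
    params.update(overrides)
    cfg = SimulationConfig(**params)
    cohort = simulate_cohort(cfg)
    design = build_pools(cohort, cfg)
    matrix = simulate_intensities(design, cohort, cfg)
    mode = "mm_subtracted" if overrides.get("has_mismatch_probes") else "pm_only"
    ras = allelotype(matrix, mode=mode)
    r = float(np.nanmean(list(ras_truth_correlation(ras, design, cohort).values())))
    return {"condition": label, "ras_truth_r": r}


def main() -> None:
    rows = [
        run("pm_only_6-8_probes (high-density default)"),
        run("mm_subtracted_6-8_probes", has_mismatch_probes=True),
        run("pm_only_24_probes", probes_per_snp_min=24, probes_per_snp_max=24),
        run("pm_only_40_probes", probes_per_snp_min=40, probes_per_snp_max=40),
        run("buccal_quality_6-8_probes", case_blood_fraction=0.0,
            control_blood_fraction=0.0),
    ]
    table = pd.DataFrame(rows)
    ROOT.mkdir(parents=True, exist_ok=True)
    table.to_csv(ROOT / "design_contrasts.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nHigher probe redundancy and mismatch subtraction both raise the")
    print("RAS-vs-truth correlation; degraded (cheek-swab) DNA lowers it.")
    print(f"wrote {ROOT / 'design_contrasts.tsv'}")


if __name__ == "__main__":
    main()
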