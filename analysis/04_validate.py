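#!/usr/bin/env python
"""Validation statistics on a 110-SNP follow-up panel.

Computes the three checks a pooled allelotyping study reports: technical-
and biological-replicate correlations, RAS-vs-truth Pearson r per
(phenotype, DNA source) stratum, and the ratio-of-ratios concordance of
the control/case frequency ratio (overall and split by control DNA
source). Writes the report tables and scatter plots under
results/validation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from snpmap import build_report, select_followup_subset
from snpmap._rng import stage_rng
from snpmap.io import read_cohort, read_design, read_ras
from snpmap.validation import plot_ras_vs_truth

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "sim")
    design = read_design(ROOT / "sim" / "design.tsv", cohort)
    ras = read_ras(ROOT / "ras.tsv")
    scan = pd.read_csv(ROOT / "gwas.tsv", sep="\t")

    subset = select_followup_subset(scan, subset_size=110,
                                    rng=stage_rng(2010, "followup-subset"))
    report = build_report(ras, design, cohort, subset)

    outdir = ROOT / "validation"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in report.to_frames().items():
        frame.to_csv(outdir / f"validation_{name}.tsv", sep="\t", index=False)
    plot_ras_vs_truth(ras, design, cohort, str(outdir))

    tech = [r for rs in report.technical_replicate_correlations.values() for r in rs]
    print(f"technical replicate pairwise r: "
          f"{', '.join(f'{r:.3f}' for r in tech)} (mean {np.mean(tech):.3f})")
    for group, r in sorted(report.biological_replicate_mean_correlations.items()):
        print(f"biological replicates {group}: mean pairwise r = {r:.3f}")
    print("RAS vs true frequency (110-SNP panel):")
    for stratum, r in sorted(report.ras_truth_correlation.items()):
        print(f"  {stratum}: r = {r:.3f}")
    print("ratio of ratios (control/case, truth vs RAS):")
    for stratum, rr in report.ratio_of_ratios.items():
        print(f"  {stratum}: mean {rr['mean']:.3f}, SD {rr['sd']:.3f}, "
              f"{rr['pct_within_1sd']:.1f}% within 1 SD (n={rr['n_snps']})")
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
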