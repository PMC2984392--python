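"""Validation statistics for a pooled allelotyping experiment.

Three analyses quantify how well pool RAS scores track the allele
frequencies that individual genotyping of the pool members would report:

* replicate correlations — Pearson r between the RAS vectors of technical
  replicate arrays of one pool, and mean pairwise r among biological
  replicate pools of the same phenotypic cell;
* RAS-vs-truth correlation per stratum (phenotype x DNA source), between
  SNP-level mean RAS and the true weighted pooled frequency;
* the ratio-of-ratios concordance statistic: per SNP,
  R = (f_ctrl / f_case) / (RAS_ctrl / RAS_case), where f are group mean
  allele frequencies from genotypes and RAS are group mean pool scores.
  R = 1 means the pools perfectly estimate the control/case frequency
  ratio even when absolute RAS scores are biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allelotype import RASTable
from .cohort import Cohort, PoolDesign, true_pool_frequencies

__all__ = [
    "ValidationReport",
    "replicate_correlation",
    "ras_truth_correlation",
    "ratio_of_ratios",
    "select_followup_subset",
    "build_report",
]

log = logging.getLogger(__name__)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over jointly finite entries; NaN when undefined (fewer than
    two points or a constant vector)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ValidationReport:
    technical_replicate_correlations: dict[str, list[float]] = field(default_factory=dict)
    biological_replicate_mean_correlations: dict[str, float] = field(default_factory=dict)
    ras_truth_correlation: dict[str, float] = field(default_factory=dict)
    ratio_of_ratios: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        tech = pd.DataFrame(
            [(pid, i + 1, r) for pid, rs in self.technical_replicate_correlations.items()
             for i, r in enumerate(rs)],
            columns=["pool_id", "pair", "pearson_r"],
        )
        bio = pd.DataFrame(
            list(self.biological_replicate_mean_correlations.items()),
            columns=["replicate_group", "mean_pairwise_r"],
        )
        truth = pd.DataFrame(
            list(self.ras_truth_correlation.items()), columns=["stratum", "pearson_r"]
        )
        rr = pd.DataFrame(
            [{"stratum": k, **v} for k, v in self.ratio_of_ratios.items()]
        )
        return {"technical_replicates": tech, "biological_replicates": bio,
                "ras_truth_correlation": truth, "ratio_of_ratios": rr}


def replicate_correlation(
    ras: RASTable,
    grouping: str = "technical",
    design: Optional[PoolDesign] = None,
) -> dict[str, list[float]] | dict[str, float]:
    """Pairwise Pearson correlations among replicate RAS vectors.

    ``technical``: per pool hybridized to several arrays, all pairwise r
    between its arrays' RAS vectors. ``biological``: pools are collapsed to
    one RAS vector each, grouped by the design's replicate_group, and the
    mean pairwise r per group is returned. Constant vectors make r
    undefined; such pairs are skipped with a warning.
    """
    if grouping == "technical":
        pool_ids = ras.hybridizations["pool_id"].to_numpy()
        out: dict[str, list[float]] = {}
        for pid in dict.fromkeys(pool_ids):
            rows = ras.values[pool_ids == pid]
            if len(rows) < 2:
                continue
            rs = []
            for i, j in combinations(range(len(rows)), 2):
                r = _pearson(rows[i], rows[j])
                if np.isnan(r):
                    log.warning("constant RAS vector; skipping replicate pair of pool %s", pid)
                else:
                    rs.append(r)
            if rs:
                out[pid] = rs
        return out

    if grouping == "biological":
        if design is None:
            raise ValueError("biological grouping requires the pool design")
        pool_ids, values = ras.pool_level()
        group_of = {p.pool_id: p.replicate_group for p in design.pools}
        means: dict[str, float] = {}
        groups: dict[str, list[int]] = {}
        for i, pid in enumerate(pool_ids):
            g = group_of.get(pid)
            if g is not None:
                groups.setdefault(g, []).append(i)
        for g, idxs in groups.items():
            if len(idxs) < 2:
                continue
            rs = []
            for i, j in combinations(idxs, 2):
                r = _pearson(values[i], values[j])
                if np.isnan(r):
                    log.warning("constant RAS vector; skipping pool pair in group %s", g)
                else:
                    rs.append(r)
            if rs:
                means[g] = float(np.mean(rs))
        return means

    raise ValueError(f"unknown grouping: {grouping!r}")


def _strata(design: PoolDesign) -> dict[str, list[int]]:
    """Pools grouped by (phenotype, dna_source) — the study's validation
    strata (cases-blood, controls-blood, controls-buccal)."""
    out: dict[str, list[int]] = {}
    for i, p in enumerate(design.pools):
        out.setdefault(f"{p.phenotype}-{p.dna_source}", []).append(i)
    return out


def ras_truth_correlation(
    ras: RASTable,
    design: PoolDesign,
    cohort: Cohort,
    snp_subset: Optional[Sequence[str]] = None,
    min_snps: int = 3,
) -> dict[str, float]:
    """Per-stratum Pearson r between SNP-level mean RAS and true frequency.

    For each (phenotype, dna_source) stratum, RAS scores are averaged across
    the stratum's pools per SNP and correlated with the mean weighted pooled
    allele frequency of those pools. Strata with fewer than ``min_snps``
    scored SNPs are reported as NaN (not computable).
    """
    pool_ids, values = ras.pool_level()
    pos = {pid: i for i, pid in enumerate(pool_ids)}
    truth = true_pool_frequencies(design, cohort)
    if snp_subset is not None:
        keep = np.isin(ras.snp_ids, np.asarray(snp_subset, dtype=object))
    else:
        keep = np.ones(ras.n_snps, dtype=bool)
    snp_idx_cohort = np.array([cohort.snp_index(s) for s in ras.snp_ids[keep]], dtype=int)

    out: dict[str, float] = {}
    for stratum, pool_rows in _strata(design).items():
        ras_rows = [pos[design.pools[i].pool_id] for i in pool_rows if design.pools[i].pool_id in pos]
        if not ras_rows:
            continue
        with np.errstate(invalid="ignore"):
            mean_ras = np.nanmean(values[np.ix_(ras_rows, np.flatnonzero(keep))], axis=0)
        mean_truth = truth[np.ix_(pool_rows, snp_idx_cohort)].mean(axis=0)
        n_ok = int(np.sum(np.isfinite(mean_ras)))
        if n_ok < min_snps:
            log.warning("stratum %s has %d scored SNPs (<%d); not computable", stratum, n_ok, min_snps)
            out[stratum] = float("nan")
            continue
        out[stratum] = _pearson(mean_ras, mean_truth)
    return out


def ratio_of_ratios(
    ras: RASTable,
    design: PoolDesign,
    cohort: Cohort,
    snp_subset: Sequence[str],
    control_sources: Optional[Sequence[str]] = None,
    epsilon: float = 1e-6,
) -> dict[str, float]:
    """Concordance of the control/case frequency ratio, RAS vs genotypes.

    Per SNP in ``snp_subset``: R = (f_ctrl / f_case) / (RAS_ctrl / RAS_case),
    where f is the mean over the group's pools of the weighted pooled allele
    frequency from genotypes, and RAS is the mean over the same pools of the
    pool-level score — a matched construction, so a perfect estimator gives
    R = 1 exactly whatever the pool sizes.
    ``control_sources`` restricts the control side to pools of the given DNA
    sources (cases always use every case pool, as in a blood-only or
    buccal-only control comparison). SNPs with any guard denominator below
    ``epsilon`` are excluded and counted.

    Returns mean(R), sample SD(R), the percentage of SNPs with
    |R - mean| <= SD, the number of SNPs used and the number excluded.
    """
    pool_ids, values = ras.pool_level()
    pos = {pid: i for i, pid in enumerate(pool_ids)}

    case_pools = [p for p in design.pools if p.phenotype == "case"]
    ctrl_pools = [p for p in design.pools if p.phenotype == "control"]
    if control_sources is not None:
        ctrl_pools = [p for p in ctrl_pools if p.dna_source in control_sources]
    if not case_pools or not ctrl_pools:
        raise ValueError("ratio_of_ratios needs at least one pool on each side")

    snp_idx = np.array([cohort.snp_index(s) for s in snp_subset], dtype=int)
    truth = true_pool_frequencies(design, cohort)
    pool_row = {p.pool_id: i for i, p in enumerate(design.pools)}
    case_rows_truth = [pool_row[p.pool_id] for p in case_pools]
    ctrl_rows_truth = [pool_row[p.pool_id] for p in ctrl_pools]
    f_case = truth[np.ix_(case_rows_truth, snp_idx)].mean(axis=0)
    f_ctrl = truth[np.ix_(ctrl_rows_truth, snp_idx)].mean(axis=0)

    snp_pos = {s: j for j, s in enumerate(ras.snp_ids)}
    cols = np.array([snp_pos[s] for s in snp_subset], dtype=int)
    case_rows = [pos[p.pool_id] for p in case_pools]
    ctrl_rows = [pos[p.pool_id] for p in ctrl_pools]
    with np.errstate(invalid="ignore"):
        ras_case = np.nanmean(values[np.ix_(case_rows, cols)], axis=0)
        ras_ctrl = np.nanmean(values[np.ix_(ctrl_rows, cols)], axis=0)

    ok = (
        np.isfinite(ras_case) & np.isfinite(ras_ctrl)
        & (f_case >= epsilon) & (ras_case >= epsilon) & (ras_ctrl >= epsilon)
    )
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        log.warning("ratio_of_ratios: %d SNP(s) excluded by the denominator guard", n_excluded)
    R = (f_ctrl[ok] / f_case[ok]) / (ras_ctrl[ok] / ras_case[ok])
    n = int(R.size)
    if n == 0:
        return {"mean": float("nan"), "sd": float("nan"), "pct_within_1sd": float("nan"),
                "n_snps": 0, "n_excluded": n_excluded}
    mean = float(np.mean(R))
    sd = float(np.std(R, ddof=1)) if n > 1 else 0.0
    pct = float(100.0 * np.sum(np.abs(R - mean) <= sd) / n)
    return {"mean": mean, "sd": sd, "pct_within_1sd": pct, "n_snps": n, "n_excluded": n_excluded}


def select_followup_subset(
    scan: pd.DataFrame, subset_size: int = 110, rng: Optional[np.random.Generator] = None
) -> list[str]:
    """Choose SNPs for confirmatory follow-up: every genome-wide-significant
    SNP (smallest p first), padded with a random draw from the remaining
    non-excluded SNPs up to ``subset_size``."""
    if rng is None:
        rng = np.random.default_rng(0)
    eligible = scan[~scan["excluded_by_maf"]]
    top = eligible[eligible["genomewide_significant"]].head(subset_size)
    chosen = top["snp_id"].tolist()
    rest = eligible[~eligible["snp_id"].isin(chosen)]["snp_id"].to_numpy()
    n_fill = min(subset_size - len(chosen), len(rest))
    if n_fill > 0:
        chosen += rng.choice(rest, size=n_fill, replace=False).tolist()
    return chosen


def build_report(
    ras: RASTable,
    design: PoolDesign,
    cohort: Cohort,
    snp_subset: Sequence[str],
    epsilon: float = 1e-6,
) -> ValidationReport:
    """Run all three validation analyses and assemble the report.

    The ratio-of-ratios statistic is reported for all controls together and
    separately for blood-only and buccal-only control pools (when present).
    """
    report = ValidationReport()
    report.technical_replicate_correlations = replicate_correlation(ras, "technical")
    report.biological_replicate_mean_correlations = replicate_correlation(
        ras, "biological", design=design
    )
    report.ras_truth_correlation = ras_truth_correlation(ras, design, cohort, snp_subset=snp_subset)
    sources_present = {p.dna_source for p in design.pools if p.phenotype == "control"}
    report.ratio_of_ratios["all-controls"] = ratio_of_ratios(
        ras, design, cohort, snp_subset, epsilon=epsilon
    )
    for src in sorted(sources_present):
        if len(sources_present) > 1:
            report.ratio_of_ratios[f"{src}-controls"] = ratio_of_ratios(
                ras, design, cohort, snp_subset, control_sources=[src], epsilon=epsilon
            )
    return report


def plot_ras_vs_truth(
    ras: RASTable,
    design: PoolDesign,
    cohort: Cohort,
    outdir: str,
    snp_subset: Optional[Sequence[str]] = None,
) -> list[str]:
    """Scatter of SNP-level mean RAS against true pooled frequency, one panel
    per stratum; returns the written file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    pool_ids, values = ras.pool_level()
    pos = {pid: i for i, pid in enumerate(pool_ids)}
    truth = true_pool_frequencies(design, cohort)
    keep = (
        np.isin(ras.snp_ids, np.asarray(snp_subset, dtype=object))
        if snp_subset is not None else np.ones(ras.n_snps, dtype=bool)
    )
    snp_idx_cohort = np.array([cohort.snp_index(s) for s in ras.snp_ids[keep]], dtype=int)
    paths = []
    for stratum, pool_rows in _strata(design).items():
        ras_rows = [pos[design.pools[i].pool_id] for i in pool_rows]
        with np.errstate(invalid="ignore"):
            x = truth[np.ix_(pool_rows, snp_idx_cohort)].mean(axis=0)
            y = np.nanmean(values[np.ix_(ras_rows, np.flatnonzero(keep))], axis=0)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(x, y, s=8, alpha=0.5)
        ax.plot([0, 1], [0, 1], "r--", lw=1)
        ax.set_xlabel("true pooled allele frequency")
        ax.set_ylabel("mean RAS score")
        ax.set_title(f"{stratum} (r = {_pearson(x, y):.3f})")
        path = str(Path(outdir) / f"ras_vs_truth_{stratum}.png")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
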