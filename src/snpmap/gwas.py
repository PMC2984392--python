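"""Pool-level case-control genome scan on RAS scores.

Per SNP, case pools and control pools are compared with an independent
two-sample Student's t-test (pooled variance; Welch optional) on pool-level
RAS scores, after collapsing technical replicate arrays to one value per
pool. SNPs whose RAS-estimated minor allele frequency falls below a
threshold are excluded from significance flagging; the genome-wide
significance cutoff defaults to 7.2e-8.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .allelotype import RASTable
from .cohort import PoolDesign

__all__ = ["estimate_maf", "pool_t_test", "run_scan", "ScanError"]

log = logging.getLogger(__name__)

#: smallest positive p reported when the pooled variance is exactly zero
#: but the group means differ (an infinitely strong, degenerate signal)
P_DEGENERATE = np.nextafter(0.0, 1.0)


class ScanError(ValueError):
    """The design cannot support the case/control scan."""


def estimate_maf(ras: RASTable, snp_id: str | None = None) -> float | np.ndarray:
    """RAS-based minor allele frequency estimate.

    f-hat is the mean RAS across all hybridizations (arrays, not collapsed
    pools); the MAF is min(f-hat, 1 - f-hat). With ``snp_id`` given, a single
    float; otherwise the full per-SNP vector (NaN where no entry is scored).
    """
    with np.errstate(invalid="ignore"):
        fhat = np.nanmean(ras.values, axis=0)
    maf = np.minimum(fhat, 1.0 - fhat)
    if snp_id is None:
        return maf
    idx = np.flatnonzero(ras.snp_ids == snp_id)
    if idx.size == 0:
        raise KeyError(f"unknown SNP id: {snp_id!r}")
    val = maf[idx[0]]
    if np.isnan(val):
        raise ValueError(f"no scored entries for SNP {snp_id!r}")
    return float(val)


def _t_test_matrix(
    x: np.ndarray, y: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sample t-test down the columns of x (cases) and y
    (controls); NaN entries are omitted per column.

    Returns (t, df, p). Degenerate columns — zero variance in both groups —
    give t = 0, p = 1 when the means agree, and t = +/-inf with the smallest
    positive p when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = np.sum(~np.isnan(x), axis=0).astype(float)
    n2 = np.sum(~np.isnan(y), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(x, axis=0)
        m2 = np.nanmean(y, axis=0)
        v1 = np.nanvar(x, axis=0, ddof=1)
        v2 = np.nanvar(y, axis=0, ddof=1)

    if equal_var:
        df = n1 + n2 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            a, b = v1 / n1, v2 / n2
            se = np.sqrt(a + b)
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))

    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.full_like(t, np.nan)
    testable = (n1 >= 2) & (n2 >= 2)
    ok = testable & (se > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # zero pooled variance: identical constant groups vs separated constants
    degen = testable & ~(se > 0)
    same = degen & (diff == 0)
    apart = degen & (diff != 0)
    t[~testable] = np.nan
    t[same], p[same] = 0.0, 1.0
    t[apart] = np.sign(diff[apart]) * np.inf
    p[apart] = P_DEGENERATE
    if equal_var and np.any(apart):
        log.warning(
            "%d SNP(s) had zero pooled variance with unequal means; "
            "reporting the smallest positive p-value", int(np.sum(apart))
        )
    if not equal_var:
        df = np.where(ok, df, n1 + n2 - 2)
    return t, df, p


def pool_t_test(
    case_ras: np.ndarray, control_ras: np.ndarray, equal_var: bool = True
) -> tuple[float, float, float]:
    """Independent two-sample Student's t-test on pool-level RAS values.

    Pooled-variance t with df = n1 + n2 - 2 and a two-sided p from the t
    distribution; requires at least two pools per group.
    """
    x = np.asarray(case_ras, dtype=float)
    y = np.asarray(control_ras, dtype=float)
    if np.sum(~np.isnan(x)) < 2 or np.sum(~np.isnan(y)) < 2:
        raise ScanError("pool_t_test requires >= 2 pools per group")
    t, df, p = _t_test_matrix(x[:, None], y[:, None], equal_var=equal_var)
    return float(t[0]), float(df[0]), float(p[0])


def run_scan(
    ras: RASTable,
    design: PoolDesign,
    maf_threshold: float = 0.05,
    alpha_gw: float = 7.2e-8,
    welch: bool = False,
    maf_table: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-SNP case vs control t-test over pool-level RAS scores.

    Technical replicate arrays are averaged into one value per pool first, so
    the pool count (not the array count) sets the degrees of freedom. Every
    SNP gets a row; SNPs with estimated MAF below ``maf_threshold`` carry the
    ``excluded_by_maf`` flag and never the significance flag. The result is
    sorted by p ascending. ``maf_table`` (snp_id -> MAF) substitutes an
    external MAF source for the RAS-based estimate.
    """
    pool_ids, values = ras.pool_level()
    phenotype = design.phenotypes()
    unknown = [pid for pid in pool_ids if pid not in phenotype]
    if unknown:
        raise ScanError(f"pools missing from design: {unknown}")
    is_case = np.array([phenotype[pid] == "case" for pid in pool_ids])
    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ScanError(
            f"scan requires >= 2 pools per group (got {n_case} case, {n_ctrl} control)"
        )

    t, df, p = _t_test_matrix(values[is_case], values[~is_case], equal_var=not welch)
    with np.errstate(invalid="ignore"):
        mean_cases = np.nanmean(values[is_case], axis=0)
        mean_controls = np.nanmean(values[~is_case], axis=0)

    if maf_table is not None:
        maf = pd.Series(ras.snp_ids).map(maf_table).to_numpy(dtype=float)
    else:
        maf = np.asarray(estimate_maf(ras))
    excluded = maf < maf_threshold
    n_missing = int(np.isnan(p).sum())
    if n_missing:
        log.warning("%d SNP(s) had no scored pools and were skipped", n_missing)

    result = pd.DataFrame(
        {
            "snp_id": ras.snp_ids,
            "mean_ras_cases": mean_cases,
            "mean_ras_controls": mean_controls,
            "t_statistic": t,
            "df": df,
            "p_value": p,
            "estimated_maf": maf,
            "excluded_by_maf": excluded,
            "genomewide_significant": (~excluded) & (p <= alpha_gw),
        }
    )
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)
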