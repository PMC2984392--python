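"""Relative allele signal (RAS) scoring of pooled hybridizations.

A pool's RAS score for a SNP is the ratio of allele-A signal to total
signal, A/(A+B), which estimates the pool's allele-A frequency. Two modes
are supported: PM-only (arrays without mismatch probes, where shared
background biases RAS toward 0.5) and mismatch-subtraction (earlier array
generations, where MM intensities estimate the nonspecific background and
are subtracted from PM before forming the ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .intensities import IntensityMatrix

__all__ = [
    "RASTable",
    "ModeError",
    "ras_pm_only",
    "ras_mm_subtracted",
    "allelotype",
]

Mode = Literal["pm_only", "mm_subtracted"]
Summarization = Literal["mean_of_ratios", "ratio_of_sums"]


class ModeError(ValueError):
    """Requested scoring mode is incompatible with the available channels."""


@dataclass
class RASTable:
    """RAS scores per hybridization x SNP.

    ``values[h, s]`` is the RAS score of hybridization h at SNP s, or NaN
    when every probe of the SNP was dropped (zero total signal);
    ``probes_used[h, s]`` counts the probes contributing to the score.
    """

    hybridizations: pd.DataFrame  # columns: pool_id, array_id
    snp_ids: np.ndarray
    values: np.ndarray  # (n_hyb, n_snps), NaN = missing
    probes_used: np.ndarray  # (n_hyb, n_snps) int
    mode: Mode

    @property
    def n_hybridizations(self) -> int:
        return len(self.hybridizations)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def pool_level(self) -> tuple[list[str], np.ndarray]:
        """Collapse technical replicates: mean RAS per pool_id (NaN-aware).

        Arrays are repeated measures of one pool, so downstream tests operate
        on one value per pool. Returns (pool_ids, (n_pools, n_snps) values).
        """
        pool_ids = self.hybridizations["pool_id"].to_numpy()
        uniq = list(dict.fromkeys(pool_ids))
        out = np.empty((len(uniq), self.n_snps))
        with np.errstate(invalid="ignore"):
            for i, pid in enumerate(uniq):
                rows = self.values[pool_ids == pid]
                out[i] = np.nanmean(rows, axis=0) if len(rows) else np.nan
        return uniq, out

    def to_frame(self) -> pd.DataFrame:
        """Long table (pool_id, array_id, snp_id, ras, probes_used, mode);
        missing scores are written as empty fields."""
        n_hyb, n_snps = self.values.shape
        return pd.DataFrame(
            {
                "pool_id": np.repeat(self.hybridizations["pool_id"].to_numpy(), n_snps),
                "array_id": np.repeat(self.hybridizations["array_id"].to_numpy(), n_snps),
                "snp_id": np.tile(self.snp_ids, n_hyb),
                "ras": self.values.ravel(),
                "probes_used": self.probes_used.ravel(),
                "mode": self.mode,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RASTable":
        hybs = frame[["pool_id", "array_id"]].drop_duplicates().reset_index(drop=True)
        snp_ids = frame["snp_id"].unique()
        hyb_pos = {t: i for i, t in enumerate(zip(hybs["pool_id"], hybs["array_id"]))}
        snp_pos = {s: j for j, s in enumerate(snp_ids)}
        values = np.full((len(hybs), len(snp_ids)), np.nan)
        probes_used = np.zeros((len(hybs), len(snp_ids)), dtype=int)
        rows = [hyb_pos[t] for t in zip(frame["pool_id"], frame["array_id"])]
        cols = [snp_pos[s] for s in frame["snp_id"]]
        values[rows, cols] = frame["ras"].to_numpy()
        probes_used[rows, cols] = frame["probes_used"].to_numpy()
        mode = str(frame["mode"].iloc[0]) if len(frame) else "pm_only"
        return cls(
            hybridizations=hybs,
            snp_ids=np.asarray(snp_ids, dtype=object),
            values=values,
            probes_used=probes_used,
            mode=mode,  # type: ignore[arg-type]
        )


def _summarize(a: np.ndarray, b: np.ndarray, summarization: Summarization) -> tuple[float, int]:
    """Score one SNP from per-probe allele-A / allele-B signals.

    Probes with zero total signal are dropped; (NaN, 0) when none remain.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    valid = denom > 0
    n_used = int(valid.sum())
    if n_used == 0:
        return math.nan, 0
    if summarization == "mean_of_ratios":
        return float(np.mean(a[valid] / denom[valid])), n_used
    return float(a[valid].sum() / denom[valid].sum()), n_used


def ras_pm_only(
    pm_a: Sequence[float],
    pm_b: Sequence[float],
    summarization: Summarization = "mean_of_ratios",
) -> tuple[float, int]:
    """PM-only RAS for one SNP: mean over probes of PM_A/(PM_A+PM_B).

    Returns (ras, probes_used); ras is NaN when every probe has zero total
    signal. ``summarization='ratio_of_sums'`` instead forms the ratio of
    summed intensities.
    """
    return _summarize(np.asarray(pm_a), np.asarray(pm_b), summarization)


def ras_mm_subtracted(
    pm_a: Sequence[float],
    pm_b: Sequence[float],
    mm_a: Sequence[float],
    mm_b: Sequence[float],
    summarization: Summarization = "mean_of_ratios",
) -> tuple[float, int]:
    """Mismatch-subtraction RAS: per probe a = max(PM_A - MM_A, 0),
    b = max(PM_B - MM_B, 0), then scored as a/(a+b) like the PM-only mode."""
    a = np.maximum(np.asarray(pm_a, dtype=float) - np.asarray(mm_a, dtype=float), 0.0)
    b = np.maximum(np.asarray(pm_b, dtype=float) - np.asarray(mm_b, dtype=float), 0.0)
    return _summarize(a, b, summarization)


def allelotype(
    matrix: IntensityMatrix,
    mode: Mode = "pm_only",
    summarization: Summarization = "mean_of_ratios",
) -> RASTable:
    """Score every hybridization x SNP of an intensity matrix.

    Vectorized over the flat probe axis; produces one RAS entry per
    hybridization and SNP with the per-SNP probe count actually used.
    """
    if mode == "mm_subtracted" and not matrix.has_mismatch:
        raise ModeError("mm_subtracted mode requires MM_A/MM_B channels")
    if mode not in ("pm_only", "mm_subtracted"):
        raise ModeError(f"unknown mode: {mode!r}")

    if mode == "pm_only":
        a, b = matrix.pm_a, matrix.pm_b
    else:
        a = np.maximum(matrix.pm_a - matrix.mm_a, 0.0)
        b = np.maximum(matrix.pm_b - matrix.mm_b, 0.0)

    n_hyb, n_snps = matrix.n_hybridizations, matrix.n_snps
    if n_hyb == 0 or n_snps == 0:
        return RASTable(
            hybridizations=matrix.hybridizations,
            snp_ids=matrix.snp_ids,
            values=np.empty((n_hyb, n_snps)),
            probes_used=np.zeros((n_hyb, n_snps), dtype=int),
            mode=mode,
        )

    starts = matrix.snp_probe_starts
    denom = a + b
    valid = denom > 0
    counts = np.add.reduceat(valid.astype(np.int64), starts, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if summarization == "mean_of_ratios":
            ratio = np.where(valid, a / np.where(valid, denom, 1.0), 0.0)
            sums = np.add.reduceat(ratio, starts, axis=1)
            values = np.where(counts > 0, sums / counts, np.nan)
        else:
            sum_a = np.add.reduceat(np.where(valid, a, 0.0), starts, axis=1)
            sum_d = np.add.reduceat(np.where(valid, denom, 0.0), starts, axis=1)
            values = np.where(counts > 0, sum_a / np.where(counts > 0, sum_d, 1.0), np.nan)

    return RASTable(
        hybridizations=matrix.hybridizations,
        snp_ids=matrix.snp_ids,
        values=values,
        probes_used=counts,
        mode=mode,
    )
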