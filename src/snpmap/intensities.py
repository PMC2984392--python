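"""Probe-level intensity simulation for pooled hybridizations.

The signal model for pool p, SNP s with true pooled allele-A frequency f,
probe j with lognormal affinity phi_j, and quality multipliers
(m_sig, m_bg, m_noise) taken from the pool's DNA source:

    PM_A = m_sig * S * phi_j * (f + kappa * (1 - f)) + m_bg * b + eps
    PM_B = m_sig * S * phi_j * ((1 - f) + kappa * f) + m_bg * b + eps'
    MM_A = MM_B = m_bg * b + eps''        (mismatch probes see background only)

where S is the signal scale, b the shared background, kappa the
cross-hybridization fraction, and each eps is an independent zero-mean
normal with SD = noise_cv * m_noise * (channel mean), clamped at zero.
Technical replicates of a pool share the deterministic part (same pool,
same probes) and redraw only the noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .cohort import Cohort, PoolDesign, true_pool_frequencies
from .config import SimulationConfig

__all__ = ["IntensityMatrix", "simulate_intensities"]

CHANNELS = ("PM_A", "PM_B", "MM_A", "MM_B")


@dataclass
class IntensityMatrix:
    """Probe intensities for a set of hybridizations (pool x array).

    Probes are stored on a flat axis, contiguous per SNP:
    ``probe_snp_index[j]`` maps probe column j to a row of ``snp_ids``;
    ``snp_probe_starts`` gives each SNP's first probe column, so per-SNP
    reductions can run on contiguous slices.
    """

    hybridizations: pd.DataFrame  # columns: pool_id, array_id
    snp_ids: np.ndarray
    probe_snp_index: np.ndarray  # (n_probes,) int
    probe_index: np.ndarray  # (n_probes,) int, index within the SNP's probe set
    pm_a: np.ndarray  # (n_hyb, n_probes)
    pm_b: np.ndarray
    mm_a: Optional[np.ndarray] = None
    mm_b: Optional[np.ndarray] = None

    @property
    def has_mismatch(self) -> bool:
        return self.mm_a is not None and self.mm_b is not None

    @property
    def n_hybridizations(self) -> int:
        return len(self.hybridizations)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def snp_probe_starts(self) -> np.ndarray:
        counts = np.bincount(self.probe_snp_index, minlength=self.n_snps)
        starts = np.zeros(self.n_snps, dtype=np.intp)
        np.cumsum(counts[:-1], out=starts[1:])
        return starts

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (pool_id, array_id, snp_id, probe_index, channel,
        intensity) — the on-disk interchange layout."""
        n_hyb, n_probes = self.pm_a.shape
        channels = [("PM_A", self.pm_a), ("PM_B", self.pm_b)]
        if self.has_mismatch:
            channels += [("MM_A", self.mm_a), ("MM_B", self.mm_b)]
        frames = []
        snp_of_probe = self.snp_ids[self.probe_snp_index]
        for name, mat in channels:
            frames.append(
                pd.DataFrame(
                    {
                        "pool_id": np.repeat(self.hybridizations["pool_id"].to_numpy(), n_probes),
                        "array_id": np.repeat(self.hybridizations["array_id"].to_numpy(), n_probes),
                        "snp_id": np.tile(snp_of_probe, n_hyb),
                        "probe_index": np.tile(self.probe_index, n_hyb),
                        "channel": name,
                        "intensity": mat.ravel(),
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(
            ["pool_id", "array_id", "snp_id", "probe_index", "channel"], kind="stable"
        ).reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IntensityMatrix":
        """Rebuild the wide in-memory layout from the long interchange table."""
        hybs = frame[["pool_id", "array_id"]].drop_duplicates().reset_index(drop=True)
        probes = (
            frame[["snp_id", "probe_index"]]
            .drop_duplicates()
            .sort_values(["snp_id", "probe_index"])
            .reset_index(drop=True)
        )
        snp_ids = probes["snp_id"].unique()
        snp_pos = {s: i for i, s in enumerate(snp_ids)}
        probe_snp_index = probes["snp_id"].map(snp_pos).to_numpy(dtype=np.intp)
        hyb_pos = {t: i for i, t in enumerate(zip(hybs["pool_id"], hybs["array_id"]))}
        probe_pos = {t: j for j, t in enumerate(zip(probes["snp_id"], probes["probe_index"]))}

        n_hyb, n_probes = len(hybs), len(probes)
        mats: dict[str, np.ndarray] = {}
        for channel, sub in frame.groupby("channel", sort=False):
            mat = np.zeros((n_hyb, n_probes))
            rows = [hyb_pos[t] for t in zip(sub["pool_id"], sub["array_id"])]
            cols = [probe_pos[t] for t in zip(sub["snp_id"], sub["probe_index"])]
            mat[rows, cols] = sub["intensity"].to_numpy()
            mats[channel] = mat
        return cls(
            hybridizations=hybs,
            snp_ids=np.asarray(snp_ids, dtype=object),
            probe_snp_index=probe_snp_index,
            probe_index=probes["probe_index"].to_numpy(),
            pm_a=mats["PM_A"],
            pm_b=mats["PM_B"],
            mm_a=mats.get("MM_A"),
            mm_b=mats.get("MM_B"),
        )


def _noisy(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative measurement error: N(mean, cv*mean) clamped at zero."""
    if cv == 0.0:
        return mean.copy()
    return np.maximum(mean + cv * mean * rng.standard_normal(mean.shape), 0.0)


def simulate_intensities(
    design: PoolDesign, cohort: Cohort, config: SimulationConfig
) -> IntensityMatrix:
    """Simulate probe intensities for every pool (plus technical replicates).

    Probe counts per SNP are drawn uniformly on the configured range and
    probe affinities are i.i.d. lognormal with unit median. The first
    ``n_technical_replicates`` pools (in a seeded random order) are
    hybridized to a second array; replicate arrays share the pool's realized
    weights and true frequencies and redraw only the measurement noise.
    """
    probe_rng = stage_rng(config.seed, "probes")
    noise_rng = stage_rng(config.seed, "noise")
    rep_rng = stage_rng(config.seed, "replicates")

    n_snps = cohort.n_snps
    probes_per_snp = probe_rng.integers(
        config.probes_per_snp_min, config.probes_per_snp_max + 1, size=n_snps
    )
    probe_snp_index = np.repeat(np.arange(n_snps, dtype=np.intp), probes_per_snp)
    probe_index = np.concatenate([np.arange(k) for k in probes_per_snp])
    n_probes = probe_snp_index.size
    phi = np.exp(config.probe_affinity_sigma * probe_rng.standard_normal(n_probes))

    n_pools = len(design.pools)
    dup_pools = set(
        rep_rng.choice(n_pools, size=min(config.n_technical_replicates, n_pools), replace=False).tolist()
    )
    hyb_pool_idx: list[int] = []
    hyb_rows: list[tuple[str, str]] = []
    for i, pool in enumerate(design.pools):
        n_arrays = 2 if i in dup_pools else 1
        for a in range(n_arrays):
            hyb_pool_idx.append(i)
            hyb_rows.append((pool.pool_id, f"array{a + 1}"))
    hybridizations = pd.DataFrame(hyb_rows, columns=["pool_id", "array_id"])

    freqs = true_pool_frequencies(design, cohort)  # (n_pools, n_snps)
    f_probe = freqs[:, probe_snp_index]  # (n_pools, n_probes)

    S, b, kappa = config.signal_scale, config.background_level, config.cross_hyb_fraction
    m_sig = np.array([config.quality[p.dna_source].signal_multiplier for p in design.pools])
    m_bg = np.array([config.quality[p.dna_source].background_multiplier for p in design.pools])
    m_noise = np.array([config.quality[p.dna_source].noise_multiplier for p in design.pools])

    # deterministic channel means per pool (shared across technical replicates)
    sig = m_sig[:, None] * S * phi[None, :]
    bg = (m_bg * b)[:, None]
    mean_a = sig * (f_probe + kappa * (1.0 - f_probe)) + bg
    mean_b = sig * ((1.0 - f_probe) + kappa * f_probe) + bg

    n_hyb = len(hyb_rows)
    pm_a = np.empty((n_hyb, n_probes))
    pm_b = np.empty((n_hyb, n_probes))
    mm_a = np.empty((n_hyb, n_probes)) if config.has_mismatch_probes else None
    mm_b = np.empty((n_hyb, n_probes)) if config.has_mismatch_probes else None
    for h, p_idx in enumerate(hyb_pool_idx):
        cv = config.noise_cv * m_noise[p_idx]
        pm_a[h] = _noisy(noise_rng, mean_a[p_idx], cv)
        pm_b[h] = _noisy(noise_rng, mean_b[p_idx], cv)
        if config.has_mismatch_probes:
            bg_row = np.broadcast_to(bg[p_idx], (n_probes,))
            mm_a[h] = _noisy(noise_rng, bg_row, cv)
            mm_b[h] = _noisy(noise_rng, bg_row, cv)

    return IntensityMatrix(
        hybridizations=hybridizations,
        snp_ids=cohort.snp_ids,
        probe_snp_index=probe_snp_index,
        probe_index=probe_index,
        pm_a=pm_a,
        pm_b=pm_b,
        mm_a=mm_a,
        mm_b=mm_b,
    )
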