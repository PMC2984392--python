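"""Cohort simulation and DNA-pool construction.

Generates Hardy-Weinberg genotypes for a stratified case-control cohort,
optionally shifting allele frequencies at designated effect SNPs by an
allele-level odds ratio, then partitions each (phenotype, sex, stratum,
dna_source) cell into pools of roughly equal size with pipetting-noise
contribution weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .config import STRATA, SimulationConfig

__all__ = [
    "Cohort",
    "Pool",
    "PoolDesign",
    "PoolDesignError",
    "case_frequency",
    "simulate_cohort",
    "build_pools",
    "true_pool_frequency",
    "true_pool_frequencies",
]


class PoolDesignError(ValueError):
    """Raised when the cohort cannot support the requested pool design."""


def case_frequency(f: float | np.ndarray, odds_ratio: float) -> float | np.ndarray:
    """Case allele frequency after an allele-level odds-ratio shift.

    f_case = OR * f / (OR * f + (1 - f)); OR = 1 leaves f unchanged.
    """
    return odds_ratio * f / (odds_ratio * f + (1.0 - f))


@dataclass
class Cohort:
    """A simulated case-control cohort.

    individuals : one row per person (id, phenotype, sex, stratum, dna_source)
    genotypes   : (n_individuals, n_snps) int8 matrix of allele-A dose in {0,1,2}
    snp_table   : per-SNP truth (snp_id, true_maf_control, true_freq_case, is_effect)
    """

    individuals: pd.DataFrame
    genotypes: np.ndarray
    snp_table: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snp_table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_table["snp_id"].to_numpy()

    def snp_index(self, snp_id: str) -> int:
        idx = self.snp_table.index[self.snp_table["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP id: {snp_id!r}")
        return int(idx[0])

    def group_allele_frequency(self, individual_indices: np.ndarray) -> np.ndarray:
        """Allele-A frequency per SNP over the given individuals (equal weight),
        i.e. what individual genotyping of those people would report."""
        g = self.genotypes[np.asarray(individual_indices, dtype=int)]
        return g.mean(axis=0) / 2.0


@dataclass
class Pool:
    """One DNA pool: members from a single phenotypic cell plus realized
    (pipetting-noise) contribution weights that sum to 1."""

    pool_id: str
    member_indices: np.ndarray  # row indices into Cohort.individuals / genotypes
    member_ids: list[str]
    phenotype: str
    sex: str
    stratum: str
    dna_source: str
    weights: np.ndarray
    replicate_group: Optional[str] = None

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class PoolDesign:
    pools: list[Pool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pools)

    def __iter__(self) -> Iterable[Pool]:
        return iter(self.pools)

    def pool(self, pool_id: str) -> Pool:
        for p in self.pools:
            if p.pool_id == pool_id:
                return p
        raise KeyError(f"unknown pool id: {pool_id!r}")

    def phenotypes(self) -> dict[str, str]:
        return {p.pool_id: p.phenotype for p in self.pools}

    def to_frame(self) -> pd.DataFrame:
        """Long membership table (one row per pool member)."""
        rows = []
        for p in self.pools:
            for mid, w in zip(p.member_ids, p.weights):
                rows.append(
                    (p.pool_id, mid, w, p.phenotype, p.sex, p.stratum, p.dna_source,
                     p.replicate_group if p.replicate_group is not None else "")
                )
        return pd.DataFrame(
            rows,
            columns=["pool_id", "member_id", "weight", "phenotype", "sex",
                     "stratum", "dna_source", "replicate_group"],
        )


def _assign_categories(rng: np.random.Generator, n: int, levels: tuple, probs: np.ndarray) -> np.ndarray:
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a stratified case-control cohort with Hardy-Weinberg genotypes.

    Control genotypes are Binomial(2, f) at the SNP's control allele-A
    frequency f ~ Uniform(maf_low, maf_high); case genotypes use the
    odds-ratio-shifted frequency at effect SNPs and f elsewhere.
    """
    rng = stage_rng(config.seed, "cohort")
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls

    phenotype = np.array(["case"] * n_cases + ["control"] * n_controls, dtype=object)
    sex = _assign_categories(
        rng, n, ("female", "male"),
        np.array([config.female_fraction, 1.0 - config.female_fraction]),
    )
    stratum = _assign_categories(rng, n, STRATA, np.asarray(config.stratum_fractions, dtype=float))
    dna_source = np.empty(n, dtype=object)
    for pheno, frac in (("case", config.case_blood_fraction), ("control", config.control_blood_fraction)):
        mask = phenotype == pheno
        dna_source[mask] = rng.choice(
            np.array(["blood", "buccal"], dtype=object), size=mask.sum(), p=[frac, 1.0 - frac]
        )

    individuals = pd.DataFrame(
        {
            "id": [f"{p[:4]}_{i:05d}" for i, p in enumerate(phenotype)],
            "phenotype": phenotype,
            "sex": sex,
            "stratum": stratum,
            "dna_source": dna_source,
        }
    )

    f_ctrl = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
    is_effect = np.zeros(config.n_snps, dtype=bool)
    if config.n_effect_snps > 0:
        is_effect[rng.choice(config.n_snps, size=config.n_effect_snps, replace=False)] = True
    f_case = np.where(is_effect, case_frequency(f_ctrl, config.effect_odds_ratio), f_ctrl)

    genotypes = np.empty((n, config.n_snps), dtype=np.int8)
    genotypes[:n_cases] = rng.binomial(2, f_case[None, :], size=(n_cases, config.n_snps))
    genotypes[n_cases:] = rng.binomial(2, f_ctrl[None, :], size=(n_controls, config.n_snps))

    snp_table = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(config.n_snps)],
            "true_maf_control": f_ctrl,
            "true_freq_case": f_case,
            "is_effect": is_effect,
        }
    )
    return Cohort(individuals=individuals, genotypes=genotypes, snp_table=snp_table)


def _partition_sizes(n: int, target: int) -> list[int]:
    """Split n individuals into pools near the target size; pool sizes within
    a cell differ by at most one."""
    k = max(1, round(n / target))
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def _contribution_weights(rng: np.random.Generator, size: int, cv: float) -> np.ndarray:
    """Realized DNA-contribution fractions: gamma draws with the requested CV
    around equal shares, renormalized to sum to 1 (all equal when cv = 0)."""
    if cv == 0.0:
        return np.full(size, 1.0 / size)
    shape = 1.0 / cv**2
    draws = rng.gamma(shape, scale=cv**2, size=size)
    return draws / draws.sum()


def build_pools(cohort: Cohort, config: SimulationConfig) -> PoolDesign:
    """Randomly partition each phenotypic cell into pools of ~target size.

    Cells are the (phenotype, sex, stratum, dna_source) combinations; every
    expected cell (given the configured source fractions) must be nonempty.
    Pools within a cell with at least two pools share a replicate_group tag,
    making them biological replicates of one another.
    """
    rng = stage_rng(config.seed, "pools")
    ind = cohort.individuals

    expected_sources = {
        "case": [s for s, frac in (("blood", config.case_blood_fraction), ("buccal", 1 - config.case_blood_fraction)) if frac > 0],
        "control": [s for s, frac in (("blood", config.control_blood_fraction), ("buccal", 1 - config.control_blood_fraction)) if frac > 0],
    }
    expected_sexes = [s for s, frac in (("female", config.female_fraction), ("male", 1 - config.female_fraction)) if frac > 0]
    expected_strata = [s for s, frac in zip(STRATA, config.stratum_fractions) if frac > 0]
    groups = {key: idx.to_numpy() for key, idx in ind.groupby(
        ["phenotype", "sex", "stratum", "dna_source"], sort=True).groups.items()}
    missing = [
        (ph, sx, st, src)
        for ph in ("case", "control")
        for sx in expected_sexes
        for st in expected_strata
        for src in expected_sources[ph]
        if (ph, sx, st, src) not in groups
    ]
    if missing:
        raise PoolDesignError(f"empty phenotypic cell(s), cannot build pools: {missing}")

    pools: list[Pool] = []
    counter = 0
    for cell in sorted(groups):
        members = groups[cell]
        order = rng.permutation(len(members))
        sizes = _partition_sizes(len(members), config.target_pool_size)
        group_tag = "/".join(cell) if len(sizes) >= 2 else None
        start = 0
        for size in sizes:
            sel = members[order[start:start + size]]
            start += size
            weights = _contribution_weights(rng, size, config.pipetting_cv)
            pools.append(
                Pool(
                    pool_id=f"pool{counter:03d}",
                    member_indices=np.sort(sel),
                    member_ids=ind["id"].iloc[np.sort(sel)].tolist(),
                    phenotype=cell[0],
                    sex=cell[1],
                    stratum=cell[2],
                    dna_source=cell[3],
                    weights=weights,
                    replicate_group=group_tag,
                )
            )
            counter += 1
    return PoolDesign(pools=pools)


def true_pool_frequency(pool: Pool, cohort: Cohort, snp_id: str) -> float:
    """The pool's true allele-A frequency: contribution-weighted mean genotype
    dose / 2 — the quantity individual genotyping of the members estimates."""
    j = cohort.snp_index(snp_id)
    g = cohort.genotypes[pool.member_indices, j].astype(float)
    return float(np.dot(pool.weights, g) / 2.0)


def true_pool_frequencies(design: PoolDesign, cohort: Cohort) -> np.ndarray:
    """(n_pools, n_snps) matrix of weighted pooled allele-A frequencies."""
    out = np.empty((len(design.pools), cohort.n_snps))
    for i, pool in enumerate(design.pools):
        g = cohort.genotypes[pool.member_indices].astype(float)
        out[i] = pool.weights @ g / 2.0
    return out
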