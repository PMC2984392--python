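"""Tabular and VCF input/output.

The canonical interchange is tab-separated text: a genotype matrix
(individuals x SNPs, header row of SNP ids, first column of sample ids,
'.' for missing), a long pool-membership table, long-format probe
intensities and RAS scores. Genotypes can alternatively be round-tripped
through a minimal GT-only biallelic VCF (written directly, read via
cyvcf2); no genomic coordinates are modeled, so positions are synthetic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .allelotype import RASTable
from .cohort import Cohort, Pool, PoolDesign
from .intensities import IntensityMatrix

__all__ = [
    "GenotypeParseError",
    "write_genotypes",
    "read_genotypes",
    "write_cohort",
    "read_cohort",
    "write_design",
    "read_design",
    "write_intensities",
    "read_intensities",
    "write_ras",
    "read_ras",
]

log = logging.getLogger(__name__)

MISSING = -1  # sentinel dose for a missing genotype


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed; the message names the line."""


# ---------------------------------------------------------------- genotypes

def _write_genotypes_tsv(sample_ids, snp_ids, genotypes, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(map(str, snp_ids)) + "\n")
        for sid, row in zip(sample_ids, genotypes):
            tokens = [str(int(g)) if g != MISSING else "." for g in row]
            fh.write(f"{sid}\t" + "\t".join(tokens) + "\n")


def _read_genotypes_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "sample_id":
            raise GenotypeParseError(f"{path}: line 1: expected 'sample_id' header")
        snp_ids = header[1:]
        sample_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) != len(header):
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(tokens)}"
                )
            sample_ids.append(tokens[0])
            row = []
            for tok in tokens[1:]:
                if tok == ".":
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeParseError(
                        f"{path}: line {lineno}: bad genotype token {tok!r}"
                    )
            rows.append(row)
    return sample_ids, snp_ids, np.asarray(rows, dtype=np.int8)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_genotypes_vcf(sample_ids, snp_ids, genotypes, path) -> None:
    """Minimal GT-only biallelic VCF; the dose counts the ALT allele, which
    plays the role of allele A throughout the package."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, sample_ids)) + "\n")
        for j, snp in enumerate(snp_ids):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


def _read_genotypes_vcf(path) -> tuple[list[str], list[str], np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            log.warning("skipping non-biallelic record %s", variant.ID)
            continue
        doses = []
        for g in variant.genotypes:
            alleles = [a for a in g[:-1] if a >= 0]
            doses.append(sum(alleles) if len(alleles) == 2 else MISSING)
        snp_ids.append(variant.ID if variant.ID else f"{variant.CHROM}:{variant.POS}")
        columns.append(doses)
    vcf.close()
    genotypes = np.asarray(columns, dtype=np.int8).T if columns else np.empty((len(sample_ids), 0), dtype=np.int8)
    return sample_ids, snp_ids, genotypes


def write_genotypes(cohort: Cohort, path: str | Path, fmt: str = "tsv") -> None:
    sample_ids = cohort.individuals["id"].tolist()
    if fmt == "tsv":
        _write_genotypes_tsv(sample_ids, cohort.snp_ids, cohort.genotypes, path)
    elif fmt == "vcf":
        _write_genotypes_vcf(sample_ids, cohort.snp_ids, cohort.genotypes, path)
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")


def read_genotypes(path: str | Path, fmt: str = "tsv") -> tuple[list[str], list[str], np.ndarray]:
    """Read a genotype matrix; returns (sample_ids, snp_ids, doses) with
    missing genotypes encoded as -1."""
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


# ------------------------------------------------------------------- cohort

def write_cohort(cohort: Cohort, outdir: str | Path, genotype_format: str = "tsv") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "individuals": outdir / "individuals.tsv",
        "snps": outdir / "snps.tsv",
        "genotypes": outdir / ("genotypes.vcf" if genotype_format == "vcf" else "genotypes.tsv"),
    }
    cohort.individuals.to_csv(paths["individuals"], sep="\t", index=False)
    cohort.snp_table.to_csv(paths["snps"], sep="\t", index=False)
    write_genotypes(cohort, paths["genotypes"], fmt=genotype_format)
    return paths


def read_cohort(outdir: str | Path, genotype_format: str = "tsv") -> Cohort:
    outdir = Path(outdir)
    individuals = pd.read_csv(outdir / "individuals.tsv", sep="\t")
    snp_table = pd.read_csv(outdir / "snps.tsv", sep="\t")
    gpath = outdir / ("genotypes.vcf" if genotype_format == "vcf" else "genotypes.tsv")
    sample_ids, snp_ids, genotypes = read_genotypes(gpath, fmt=genotype_format)
    if sample_ids != individuals["id"].tolist():
        raise GenotypeParseError(f"{gpath}: sample ids disagree with individuals.tsv")
    if snp_ids != snp_table["snp_id"].tolist():
        raise GenotypeParseError(f"{gpath}: SNP ids disagree with snps.tsv")
    return Cohort(individuals=individuals, genotypes=genotypes, snp_table=snp_table)


# ------------------------------------------------------------------- design

def write_design(design: PoolDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, cohort: Cohort) -> PoolDesign:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    row_of = {sid: i for i, sid in enumerate(cohort.individuals["id"])}
    pools = []
    for pid, sub in frame.groupby("pool_id", sort=False):
        first = sub.iloc[0]
        pools.append(
            Pool(
                pool_id=str(pid),
                member_indices=np.array([row_of[m] for m in sub["member_id"]]),
                member_ids=sub["member_id"].tolist(),
                phenotype=first["phenotype"],
                sex=first["sex"],
                stratum=first["stratum"],
                dna_source=first["dna_source"],
                weights=sub["weight"].to_numpy(dtype=float),
                replicate_group=first["replicate_group"] or None,
            )
        )
    return PoolDesign(pools=pools)


# -------------------------------------------------------- intensities / RAS

def write_intensities(matrix: IntensityMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_intensities(path: str | Path) -> IntensityMatrix:
    return IntensityMatrix.from_frame(pd.read_csv(path, sep="\t"))


def write_ras(ras: RASTable, path: str | Path) -> None:
    ras.to_frame().to_csv(path, sep="\t", index=False)


def read_ras(path: str | Path) -> RASTable:
    return RASTable.from_frame(pd.read_csv(path, sep="\t"))
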