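"""End-to-end pipeline: simulate -> allelotype -> scan -> validate.

Each stage writes its table under the output directory and a manifest
records the seed, package versions, per-stage row counts and the SHA-256 of
every output file. The manifest contains no timestamps, so rerunning with
the same config reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import stage_rng
from .allelotype import allelotype
from .cohort import build_pools, simulate_cohort
from .config import PipelineConfig
from .gwas import run_scan
from .intensities import simulate_intensities
from .io import write_cohort, write_design, write_intensities, write_ras
from .validation import build_report, plot_ras_vs_truth, select_followup_subset

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the four stages and return the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.simulation.seed,
        "versions": {
            "snpmap": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "files": {},
        "complete": False,
    }

    def record(name: str, path: Path, n_rows: int) -> None:
        manifest["files"][name] = {"path": path.name, "sha256": _sha256(path), "n_rows": n_rows}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        cohort = simulate_cohort(config.simulation)
        design = build_pools(cohort, config.simulation)
        matrix = simulate_intensities(design, cohort, config.simulation)
        paths = write_cohort(cohort, outdir, genotype_format=config.io.genotype_format)
        for name, p in paths.items():
            record(name, p, cohort.n_individuals if name != "snps" else cohort.n_snps)
        dpath = outdir / "design.tsv"
        write_design(design, dpath)
        record("design", dpath, sum(p.size for p in design.pools))
        if config.io.write_intensities:
            ipath = outdir / "intensities.tsv"
            write_intensities(matrix, ipath)
            record("intensities", ipath, matrix.n_hybridizations * matrix.pm_a.shape[1])
        manifest["stages"][stage] = {
            "n_individuals": cohort.n_individuals,
            "n_snps": cohort.n_snps,
            "n_pools": len(design.pools),
            "n_hybridizations": matrix.n_hybridizations,
        }

        stage = "allelotype"
        log.info("stage %s", stage)
        ras = allelotype(matrix, mode=config.allelotyping.mode,
                         summarization=config.allelotyping.summarization)
        rpath = outdir / "ras.tsv"
        write_ras(ras, rpath)
        record("ras", rpath, ras.n_hybridizations * ras.n_snps)
        manifest["stages"][stage] = {"n_ras_rows": ras.n_hybridizations * ras.n_snps,
                                     "mode": config.allelotyping.mode}

        stage = "gwas"
        log.info("stage %s", stage)
        scan = run_scan(ras, design, maf_threshold=config.gwas.maf_threshold,
                        alpha_gw=config.gwas.alpha_gw, welch=config.gwas.welch)
        gpath = outdir / "gwas.tsv"
        scan.to_csv(gpath, sep="\t", index=False)
        record("gwas", gpath, len(scan))
        manifest["stages"][stage] = {
            "n_snps_tested": int((~scan["p_value"].isna()).sum()),
            "n_excluded_by_maf": int(scan["excluded_by_maf"].sum()),
            "n_genomewide_significant": int(scan["genomewide_significant"].sum()),
        }

        stage = "validate"
        log.info("stage %s", stage)
        subset_rng = stage_rng(config.simulation.seed, "followup-subset")
        subset = select_followup_subset(scan, subset_size=config.validation.subset_size,
                                        rng=subset_rng)
        report = build_report(ras, design, cohort, subset, epsilon=config.validation.epsilon)
        for name, frame in report.to_frames().items():
            vpath = outdir / f"validation_{name}.tsv"
            frame.to_csv(vpath, sep="\t", index=False)
            record(f"validation_{name}", vpath, len(frame))
        if config.validation.make_plots:
            figdir = outdir / "figures"
            figdir.mkdir(exist_ok=True)
            plot_ras_vs_truth(ras, design, cohort, str(figdir), snp_subset=subset)
        manifest["stages"][stage] = {"n_subset_snps": len(subset)}
        manifest["complete"] = True
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
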