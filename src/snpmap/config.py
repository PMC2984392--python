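"""Validated configuration for the simulator and the end-to-end pipeline.

All tunables of the probe-intensity model live in :class:`SimulationConfig`;
the pipeline stages (allelotyping mode, scan thresholds, validation subset)
are grouped in :class:`PipelineConfig`. Unknown keys are rejected so a typo
in a config file fails before any stage runs.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

Phenotype = Literal["case", "control"]
Sex = Literal["male", "female"]
DnaSource = Literal["blood", "buccal"]
STRATA = ("low", "mid", "high")  # 3-level covariate (BMI-band analogue)


class QualityPreset(BaseModel):
    """DNA-quality multipliers applied to a hybridization's signal model.

    ``signal_multiplier`` scales the allele-specific signal, while
    ``background_multiplier`` and ``noise_multiplier`` inflate nonspecific
    background and measurement noise. Degraded templates (cheek-swab DNA)
    hybridize less efficiently and noisily, which these three knobs emulate.
    """

    model_config = ConfigDict(extra="forbid")

    signal_multiplier: float = Field(gt=0.0, le=1.0)
    background_multiplier: float = Field(ge=1.0)
    noise_multiplier: float = Field(ge=1.0)


DEFAULT_QUALITY = {
    "blood": QualityPreset(signal_multiplier=1.0, background_multiplier=1.0, noise_multiplier=1.0),
    "buccal": QualityPreset(signal_multiplier=0.4, background_multiplier=2.0, noise_multiplier=2.0),
}


class SimulationConfig(BaseModel):
    """Study conditions for the synthetic pooled-hybridization experiment.

    Defaults mirror the pooled depression case-control design this package
    models: 1418 cases and 1301 controls stratified by sex and a three-level
    covariate, pools of ~48 individuals, 6-8 probes per SNP with no mismatch
    probes (SNP 6.0-style array), all case DNA from blood and roughly 10/28
    of control pools from blood. The SNP count is the simulation scale and
    defaults to 10,000.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # cohort
    n_cases: int = Field(default=1418, gt=0)
    n_controls: int = Field(default=1301, gt=0)
    n_snps: int = Field(default=10_000, gt=0)
    n_effect_snps: int = Field(default=0, ge=0)
    effect_odds_ratio: float = Field(default=1.5, gt=0.0)
    maf_low: float = Field(default=0.05, ge=0.01, le=0.5)
    maf_high: float = Field(default=0.5, ge=0.01, le=0.5)
    female_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    stratum_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    case_blood_fraction: float = Field(default=1.0, ge=0.0, le=1.0)
    control_blood_fraction: float = Field(default=10 / 28, ge=0.0, le=1.0)

    # pooling
    target_pool_size: int = Field(default=48, gt=1)
    pipetting_cv: float = Field(default=0.05, ge=0.0)

    # array / intensity model
    probes_per_snp_min: int = Field(default=6, ge=1)
    probes_per_snp_max: int = Field(default=8, ge=1)
    has_mismatch_probes: bool = False
    signal_scale: float = Field(default=1000.0, gt=0.0)
    background_level: float = Field(default=300.0, ge=0.0)
    cross_hyb_fraction: float = Field(default=0.05, ge=0.0, lt=1.0)
    noise_cv: float = Field(default=0.1, ge=0.0)
    probe_affinity_sigma: float = Field(default=0.3, ge=0.0)
    quality: dict[DnaSource, QualityPreset] = Field(
        default_factory=lambda: {k: v.model_copy() for k, v in DEFAULT_QUALITY.items()}
    )
    n_technical_replicates: int = Field(default=3, ge=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check_cross_fields(self) -> "SimulationConfig":
        if self.n_effect_snps > self.n_snps:
            raise ValueError("n_effect_snps: must not exceed n_snps")
        if self.maf_low > self.maf_high:
            raise ValueError("maf_low: must not exceed maf_high")
        if self.probes_per_snp_min > self.probes_per_snp_max:
            raise ValueError("probes_per_snp_min: must not exceed probes_per_snp_max")
        if abs(sum(self.stratum_fractions) - 1.0) > 1e-9:
            raise ValueError("stratum_fractions: must sum to 1")
        for src in ("blood", "buccal"):
            if src not in self.quality:
                raise ValueError(f"quality: missing preset for dna_source '{src}'")
        return self


class AllelotypingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["pm_only", "mm_subtracted"] = "pm_only"
    summarization: Literal["mean_of_ratios", "ratio_of_sums"] = "mean_of_ratios"


class GwasConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    maf_threshold: float = Field(default=0.05, ge=0.0, le=0.5)
    alpha_gw: float = Field(default=7.2e-8, gt=0.0, le=1.0)
    welch: bool = False


class ValidationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    subset_size: int = Field(default=110, gt=0)
    epsilon: float = Field(default=1e-6, gt=0.0)
    make_plots: bool = False


class IoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    genotype_format: Literal["tsv", "vcf"] = "tsv"
    write_intensities: bool = True


class PipelineConfig(BaseModel):
    """Top-level, schema-validated configuration for ``run_pipeline``."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    allelotyping: AllelotypingConfig = Field(default_factory=AllelotypingConfig)
    gwas: GwasConfig = Field(default_factory=GwasConfig)
    validation: ValidationConfig = Field(default_factory=ValidationConfig)
    io: IoConfig = Field(default_factory=IoConfig)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _propagate_seed(self) -> "PipelineConfig":
        # a top-level seed overrides the simulation section's seed
        if self.seed is not None:
            object.__setattr__(self.simulation, "seed", int(self.seed))
        return self


def load_pipeline_config(path: str) -> PipelineConfig:
    """Parse a YAML config file into a validated :class:`PipelineConfig`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
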