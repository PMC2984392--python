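"""Replicate QC, RAS-vs-truth correlation and the ratio-of-ratios statistic."""

import numpy as np
import pandas as pd
import pytest

from snpmap import (
    SimulationConfig,
    allelotype,
    build_report,
    ras_truth_correlation,
    ratio_of_ratios,
    replicate_correlation,
    select_followup_subset,
    simulate_cohort,
    simulate_intensities,
    build_pools,
    true_pool_frequencies,
)
from snpmap.allelotype import RASTable
from snpmap.validation import _pearson


def _ras_from_values(values, pool_ids, array_ids=None, snp_ids=None):
    values = np.asarray(values, dtype=float)
    n_hyb, n_snps = values.shape
    if array_ids is None:
        array_ids = ["array1"] * n_hyb
    if snp_ids is None:
        snp_ids = [f"s{j}" for j in range(n_snps)]
    hybs = pd.DataFrame({"pool_id": pool_ids, "array_id": array_ids})
    return RASTable(
        hybridizations=hybs,
        snp_ids=np.asarray(snp_ids, dtype=object),
        values=values,
        probes_used=np.ones((n_hyb, n_snps), dtype=int),
        mode="pm_only",
    )


def _pearson_oracle(x, y):
    """Textbook sum-formula Pearson r, coded independently of numpy.corrcoef."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def test_identical_replicate_arrays_give_r_one():
    vals = np.array([[0.1, 0.5, 0.9, 0.3]])
    ras = _ras_from_values(
        np.vstack([vals, vals]), ["p0", "p0"], ["array1", "array2"]
    )
    out = replicate_correlation(ras, "technical")
    assert out["p0"] == [pytest.approx(1.0)]


def test_noiseless_technical_replicates_are_perfectly_correlated(fixed_freq_setup):
    cohort, design = fixed_freq_setup([2, 1, 1, 0], n_snps=30)
    # distinct per-SNP frequencies so the RAS vectors are not constant
    rng = np.random.default_rng(0)
    cohort.genotypes = rng.binomial(2, rng.uniform(0.1, 0.9, 30), size=(8, 30)).astype(np.int8)
    cfg = SimulationConfig(
        n_cases=4, n_controls=4, n_snps=30, seed=6, noise_cv=0.0,
        n_technical_replicates=2, control_blood_fraction=1.0,
    )
    ras = allelotype(simulate_intensities(design, cohort, cfg))
    out = replicate_correlation(ras, "technical")
    assert len(out) == 2
    for rs in out.values():
        assert rs == [pytest.approx(1.0, abs=1e-12)]


def test_constant_vector_pairs_are_skipped():
    vals = np.full((2, 5), 0.5)
    ras = _ras_from_values(vals, ["p0", "p0"], ["array1", "array2"])
    assert replicate_correlation(ras, "technical") == {}


def test_replicate_correlation_matches_independent_oracle(fast_ras, fast_design):
    tech = replicate_correlation(fast_ras, "technical")
    pool_ids = fast_ras.hybridizations["pool_id"].to_numpy()
    for pid, rs in tech.items():
        rows = fast_ras.values[pool_ids == pid]
        assert rs[0] == pytest.approx(_pearson_oracle(rows[0], rows[1]), abs=1e-12)

    bio = replicate_correlation(fast_ras, "biological", design=fast_design)
    assert bio  # fixture cells contain >= 2 pools somewhere
    from itertools import combinations

    pool_level_ids, values = fast_ras.pool_level()
    group_of = {p.pool_id: p.replicate_group for p in fast_design.pools}
    for group, mean_r in bio.items():
        idxs = [i for i, pid in enumerate(pool_level_ids) if group_of.get(pid) == group]
        expected = np.mean([
            _pearson_oracle(values[i], values[j]) for i, j in combinations(idxs, 2)
        ])
        assert mean_r == pytest.approx(expected, abs=1e-12)


def test_noiseless_truth_correlation_is_one(fast_cohort, fast_design):
    cfg = SimulationConfig(
        n_cases=192, n_controls=192, n_snps=200, seed=7, noise_cv=0.0,
        background_level=0.0, cross_hyb_fraction=0.0, control_blood_fraction=1.0,
    )
    ras = allelotype(simulate_intensities(fast_design, fast_cohort, cfg))
    out = ras_truth_correlation(ras, fast_design, fast_cohort)
    assert out  # at least one stratum
    for r in out.values():
        assert r == pytest.approx(1.0, abs=1e-9)


def test_anti_correlated_ras_gives_minus_one(fast_cohort, fast_design, fast_ras):
    truth = true_pool_frequencies(fast_design, fast_cohort)
    pool_ids = [p.pool_id for p in fast_design.pools]
    ras = _ras_from_values(1.0 - truth, pool_ids, snp_ids=fast_cohort.snp_ids)
    out = ras_truth_correlation(ras, fast_design, fast_cohort)
    for r in out.values():
        assert r == pytest.approx(-1.0, abs=1e-12)


def test_truth_correlation_affine_invariance(fast_ras, fast_design, fast_cohort):
    """Any strictly increasing affine transform of a stratum's RAS values
    leaves its Pearson correlation with truth unchanged."""
    base = ras_truth_correlation(fast_ras, fast_design, fast_cohort)
    transformed = RASTable(
        hybridizations=fast_ras.hybridizations,
        snp_ids=fast_ras.snp_ids,
        values=0.37 * fast_ras.values + 0.11,
        probes_used=fast_ras.probes_used,
        mode=fast_ras.mode,
    )
    out = ras_truth_correlation(transformed, fast_design, fast_cohort)
    for k in base:
        assert out[k] == pytest.approx(base[k], abs=1e-12)


def test_too_few_snps_is_not_computable(fast_design, fast_cohort, fast_ras):
    out = ras_truth_correlation(
        fast_ras, fast_design, fast_cohort, snp_subset=["snp000000", "snp000001"]
    )
    assert all(np.isnan(r) for r in out.values())


def test_perfect_estimator_gives_unit_ratios(fast_cohort, fast_design):
    """RAS exactly equal to the true pooled frequencies: every R = 1, sd = 0."""
    cfg = SimulationConfig(
        n_cases=192, n_controls=192, n_snps=200, seed=7, noise_cv=0.0,
        background_level=0.0, cross_hyb_fraction=0.0,
        control_blood_fraction=1.0,
    )
    cohort = simulate_cohort(cfg)
    design = build_pools(cohort, cfg)
    ras = allelotype(simulate_intensities(design, cohort, cfg))
    subset = cohort.snp_ids[:100].tolist()
    out = ratio_of_ratios(ras, design, cohort, subset)
    assert out["mean"] == pytest.approx(1.0, abs=1e-10)
    assert out["sd"] == pytest.approx(0.0, abs=1e-10)
    assert out["n_snps"] == 100


def test_ratio_of_ratios_oracle_equivalence(fast_ras, fast_design, fast_cohort):
    """Vectorized statistic matches a pure-python loop evaluator to 1e-12."""
    subset = fast_cohort.snp_ids[:110].tolist()
    out = ratio_of_ratios(fast_ras, fast_design, fast_cohort, subset)

    pool_ids, values = fast_ras.pool_level()
    pos = {pid: i for i, pid in enumerate(pool_ids)}
    snp_pos = {s: j for j, s in enumerate(fast_ras.snp_ids)}
    case_pools = [p for p in fast_design.pools if p.phenotype == "case"]
    ctrl_pools = [p for p in fast_design.pools if p.phenotype == "control"]

    def pool_freq(pool, jc):
        return sum(
            w * g / 2.0
            for w, g in zip(pool.weights, fast_cohort.genotypes[pool.member_indices, jc])
        )

    ratios = []
    for s in subset:
        jc = fast_cohort.snp_index(s)
        f_case = np.mean([pool_freq(p, jc) for p in case_pools])
        f_ctrl = np.mean([pool_freq(p, jc) for p in ctrl_pools])
        ras_case = np.mean([values[pos[p.pool_id], snp_pos[s]] for p in case_pools])
        ras_ctrl = np.mean([values[pos[p.pool_id], snp_pos[s]] for p in ctrl_pools])
        if min(f_case, ras_case, ras_ctrl) >= 1e-6:
            ratios.append((f_ctrl / f_case) / (ras_ctrl / ras_case))
    mean = sum(ratios) / len(ratios)
    sd = (sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)) ** 0.5
    pct = 100.0 * sum(abs(r - mean) <= sd for r in ratios) / len(ratios)
    assert out["mean"] == pytest.approx(mean, abs=1e-12)
    assert out["sd"] == pytest.approx(sd, abs=1e-12)
    assert out["pct_within_1sd"] == pytest.approx(pct, abs=1e-12)
    assert out["n_snps"] == len(ratios)


def test_pct_within_1sd_invariant_under_snp_relabeling(fast_ras, fast_design, fast_cohort):
    subset = fast_cohort.snp_ids[:60].tolist()
    fwd = ratio_of_ratios(fast_ras, fast_design, fast_cohort, subset)
    rev = ratio_of_ratios(fast_ras, fast_design, fast_cohort, subset[::-1])
    assert fwd["pct_within_1sd"] == rev["pct_within_1sd"]
    assert fwd["n_snps"] == rev["n_snps"]
    assert fwd["mean"] == pytest.approx(rev["mean"], abs=1e-12)
    assert fwd["sd"] == pytest.approx(rev["sd"], abs=1e-12)


def test_denominator_guard_excludes_near_zero_snps(fast_ras, fast_design, fast_cohort):
    ras = RASTable(
        hybridizations=fast_ras.hybridizations,
        snp_ids=fast_ras.snp_ids,
        values=fast_ras.values.copy(),
        probes_used=fast_ras.probes_used,
        mode=fast_ras.mode,
    )
    ras.values[:, 0] = 0.0  # force the case-side RAS denominator to zero
    subset = fast_cohort.snp_ids[:10].tolist()
    out = ratio_of_ratios(ras, fast_design, fast_cohort, subset)
    assert out["n_excluded"] >= 1
    assert out["n_snps"] == 10 - out["n_excluded"]


def test_quality_contrast_blood_beats_buccal_paired_seeds():
    """Under the default blood and buccal presets, the RAS-vs-truth
    correlation is higher for blood DNA on the same seeds."""
    for seed in (21, 22, 23):
        rs = {}
        for source, frac in (("blood", 1.0), ("buccal", 0.0)):
            cfg = SimulationConfig(
                n_cases=96, n_controls=96, n_snps=400, seed=seed,
                case_blood_fraction=frac, control_blood_fraction=frac,
            )
            cohort = simulate_cohort(cfg)
            design = build_pools(cohort, cfg)
            ras = allelotype(simulate_intensities(design, cohort, cfg))
            out = ras_truth_correlation(ras, design, cohort)
            rs[source] = np.nanmean(list(out.values()))
        assert rs["blood"] > rs["buccal"]


def test_select_followup_subset_prefers_significant_snps():
    scan = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(20)],
            "p_value": np.linspace(1e-10, 0.9, 20),
            "excluded_by_maf": [False] * 18 + [True] * 2,
            "genomewide_significant": [True] * 3 + [False] * 17,
        }
    )
    subset = select_followup_subset(scan, subset_size=10, rng=np.random.default_rng(1))
    assert len(subset) == 10
    assert set(subset[:3]) == {"s0", "s1", "s2"}
    assert not {"s18", "s19"} & set(subset)  # MAF-excluded SNPs never chosen


def test_build_report_strata_and_shapes(fast_ras, fast_design, fast_cohort):
    subset = fast_cohort.snp_ids[:50].tolist()
    report = build_report(fast_ras, fast_design, fast_cohort, subset)
    assert "all-controls" in report.ratio_of_ratios
    frames = report.to_frames()
    assert set(frames) == {
        "technical_replicates", "biological_replicates",
        "ras_truth_correlation", "ratio_of_ratios",
    }
    for r in frames["technical_replicates"]["pearson_r"]:
        assert -1.0 <= r <= 1.0
    rr = report.ratio_of_ratios["all-controls"]
    assert 0.0 <= rr["pct_within_1sd"] <= 100.0
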