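"""Pool-level scan: MAF estimation, the t-test and the scan wrapper."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpmap import SimulationConfig, allelotype, build_pools, estimate_maf, pool_t_test, run_scan, simulate_cohort, simulate_intensities
from snpmap.allelotype import RASTable
from snpmap.gwas import P_DEGENERATE, ScanError


def _ras_from_values(values, pool_ids=None):
    values = np.asarray(values, dtype=float)
    n_hyb, n_snps = values.shape
    if pool_ids is None:
        pool_ids = [f"p{i}" for i in range(n_hyb)]
    hybs = pd.DataFrame({"pool_id": pool_ids, "array_id": ["array1"] * n_hyb})
    return RASTable(
        hybridizations=hybs,
        snp_ids=np.array([f"s{j}" for j in range(n_snps)], dtype=object),
        values=values,
        probes_used=np.ones((n_hyb, n_snps), dtype=int),
        mode="pm_only",
    )


@pytest.mark.parametrize(
    "column, expected",
    [
        ([0.5, 0.5, 0.5], 0.5),  # already at the fold point
        ([0.97, 0.97, 0.97], pytest.approx(0.03)),  # folded: rare variant
        ([0.1, 0.2, 0.3], pytest.approx(0.2)),  # mean then fold
    ],
)
def test_estimate_maf_folds_mean_ras(column, expected):
    ras = _ras_from_values(np.array(column)[:, None])
    assert estimate_maf(ras, "s0") == expected


def test_rare_variant_excluded_at_threshold():
    vals = np.column_stack([[0.97, 0.96, 0.98, 0.97], [0.5, 0.52, 0.48, 0.5]])
    ras = _ras_from_values(vals)
    from snpmap.cohort import Pool, PoolDesign

    pools = [
        Pool(f"p{i}", np.array([i]), [f"i{i}"], "case" if i < 2 else "control",
             "female", "low", "blood", np.array([1.0]))
        for i in range(4)
    ]
    scan = run_scan(ras, PoolDesign(pools), maf_threshold=0.05)
    row = scan.set_index("snp_id").loc["s0"]
    assert row["excluded_by_maf"] and not row["genomewide_significant"]
    assert not scan.set_index("snp_id").loc["s1", "excluded_by_maf"]
    # threshold 0 excludes nothing
    scan0 = run_scan(ras, PoolDesign(pools), maf_threshold=0.0)
    assert not scan0["excluded_by_maf"].any()


def test_t_test_identical_groups():
    t, df, p = pool_t_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
    assert (t, df, p) == (0.0, 4.0, 1.0)


def test_t_test_textbook_example():
    """Pooled-variance t on a hand-checkable instance, against the textbook
    formula and an exhaustive permutation of the 6 values."""
    x, y = [0.60, 0.62, 0.58], [0.50, 0.52, 0.48]
    t, df, p = pool_t_test(x, y)
    # textbook pooled-variance computation, coded independently
    mx, my = np.mean(x), np.mean(y)
    sp2 = (np.sum((x - mx) ** 2) + np.sum((y - my) ** 2)) / 4
    t_expected = (mx - my) / np.sqrt(sp2 * (2 / 3))
    assert t == pytest.approx(t_expected, abs=1e-12)
    assert df == 4
    assert p == pytest.approx(2 * stats.t.sf(abs(t_expected), 4), abs=1e-12)
    # the observed split attains the maximal |t| over all 20 label splits,
    # consistent with the minimal attainable exhaustive permutation p of 0.1
    from itertools import combinations

    vals = np.array(x + y)
    tmax = max(
        abs(pool_t_test(vals[list(idx)], np.delete(vals, list(idx)))[0])
        for idx in combinations(range(6), 3)
    )
    assert abs(t) == pytest.approx(tmax, abs=1e-12)


def test_t_test_label_swap_antisymmetry():
    x, y = [0.61, 0.55, 0.58, 0.60], [0.50, 0.52, 0.48]
    t1, df1, p1 = pool_t_test(x, y)
    t2, df2, p2 = pool_t_test(y, x)
    assert t1 == pytest.approx(-t2, abs=1e-12)
    assert (df1, p1) == (df2, pytest.approx(p2, abs=1e-15))


def test_t_test_oracle_equivalence_random_instances():
    """t and p match scipy's independent implementation to 1e-10 on 100
    random small instances (both pooled-variance and Welch)."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        n1, n2 = rng.integers(2, 12, size=2)
        x = rng.normal(0.5, 0.05, n1)
        y = rng.normal(0.5, 0.08, n2)
        for equal_var in (True, False):
            t, df, p = pool_t_test(x, y, equal_var=equal_var)
            ref = stats.ttest_ind(x, y, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            if equal_var:
                assert df == n1 + n2 - 2


def test_zero_variance_unequal_means_returns_smallest_positive_p():
    t, df, p = pool_t_test([0.6, 0.6], [0.4, 0.4])
    assert np.isinf(t) and t > 0
    assert p == P_DEGENERATE and p > 0


def test_t_test_requires_two_pools_per_group():
    with pytest.raises(ScanError, match=">= 2 pools"):
        pool_t_test([0.5], [0.4, 0.5])


def test_run_scan_requires_two_pools_per_group(fixed_freq_setup):
    cohort, design = fixed_freq_setup([2, 1, 0], n_snps=3)
    ras = _ras_from_values(np.full((2, 3), 0.5), pool_ids=["p_case", "p_ctrl"])
    with pytest.raises(ScanError, match=">= 2 pools"):
        run_scan(ras, design)


def test_run_scan_end_to_end_properties(fast_ras, fast_design):
    scan = run_scan(fast_ras, fast_design)
    assert len(scan) == fast_ras.n_snps
    assert scan["p_value"].is_monotonic_increasing
    n_case = sum(p.phenotype == "case" for p in fast_design.pools)
    n_ctrl = sum(p.phenotype == "control" for p in fast_design.pools)
    assert (scan["df"] == n_case + n_ctrl - 2).all()
    assert not scan.loc[scan["excluded_by_maf"], "genomewide_significant"].any()
    assert np.allclose(scan["estimated_maf"], np.minimum(scan["estimated_maf"], 0.5))
    # determinism: same inputs, identical result
    assert scan.equals(run_scan(fast_ras, fast_design))


def test_replicates_collapse_before_testing(fast_ras, fast_design):
    """Degrees of freedom come from pool counts, not array counts, so the
    duplicated arrays must be averaged before the t-test."""
    scan = run_scan(fast_ras, fast_design)
    n_pools = len(fast_design.pools)
    n_arrays = fast_ras.n_hybridizations
    assert n_arrays > n_pools  # fixture has technical replicates
    assert (scan["df"] == n_pools - 2).all()


def test_extreme_effect_is_flagged_significant():
    """Case and control RAS separated by ~10 pooled SDs crosses 7.2e-8."""
    rng = np.random.default_rng(7)
    n = 15
    sd = 0.01
    case = rng.normal(0.60, sd, size=(n, 1))
    ctrl = rng.normal(0.60 - 10 * sd, sd, size=(n, 1))
    ras = _ras_from_values(np.vstack([case, ctrl]))
    from snpmap.cohort import Pool, PoolDesign

    pools = [
        Pool(f"p{i}", np.array([i]), [f"i{i}"], "case" if i < n else "control",
             "female", "low", "blood", np.array([1.0]))
        for i in range(2 * n)
    ]
    scan = run_scan(ras, PoolDesign(pools), maf_threshold=0.0)
    assert bool(scan["genomewide_significant"].iloc[0])
    assert scan["p_value"].iloc[0] <= 7.2e-8


def test_external_maf_table_overrides_ras_estimate(fast_ras, fast_design):
    maf_table = pd.Series(0.01, index=fast_ras.snp_ids)
    scan = run_scan(fast_ras, fast_design, maf_table=maf_table)
    assert scan["excluded_by_maf"].all()
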