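"""Adaptive testing, correlation, ANOVA, aggregation, and clustering."""

import numpy as np
import pandas as pd
import pytest

from melvasc.stats import (
    aggregate_samples,
    anova_oneway,
    compare_groups,
    correlate,
    inflammatory_subtypes,
)


def test_normal_groups_select_t_test(rng):
    a, b = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
    res = compare_groups(a, b)
    assert res.test == "t test"
    assert res.pvalue < 0.01


def test_lognormal_groups_select_rank_test(rng):
    res = compare_groups(rng.lognormal(size=50), rng.lognormal(size=50))
    assert res.test == "mann-whitney"


def test_paired_variants(rng):
    a = rng.normal(0, 1, 30)
    res = compare_groups(a, a + rng.normal(0.5, 0.2, 30), paired=True)
    assert res.test == "paired t test"
    res2 = compare_groups(rng.lognormal(size=30), rng.lognormal(size=30),
                          paired=True)
    assert res2.test == "wilcoxon signed-rank"


def test_identical_groups_t_statistic_zero(rng):
    a = rng.normal(0, 1, 20)
    res = compare_groups(a, a.copy())
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_insufficient_data_raises():
    with pytest.raises(ValueError, match="insufficient"):
        compare_groups([1, 2], [1, 2, 3])


def test_type_i_error_calibrated():
    rng = np.random.default_rng(99)
    for sampler in (lambda: rng.standard_normal(30),
                    lambda: rng.lognormal(size=30)):
        rej = sum(compare_groups(sampler(), sampler()).pvalue < 0.05
                  for _ in range(400))
        assert 0.03 <= rej / 400 <= 0.07


def test_correlate_linear_and_monotone(rng):
    x = rng.normal(0, 1, 40)
    res = correlate(x, 2 * x)
    assert res.coefficient == pytest.approx(1.0)
    skewed = rng.lognormal(size=40)
    res2 = correlate(skewed, np.log(skewed) ** 3)
    assert res2.method == "spearman"
    assert res2.coefficient == pytest.approx(1.0)


def test_correlate_constant_flagged():
    res = correlate([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
    assert res.method == "undefined"
    assert np.isnan(res.coefficient)


def test_correlate_null_coefficients_small(rng):
    rs = [abs(correlate(rng.standard_normal(50),
                        rng.standard_normal(50)).coefficient)
          for _ in range(100)]
    assert np.mean(rs) < 0.2


def test_anova_identical_groups_f_zero():
    res = anova_oneway([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(0.0)


def test_anova_matches_hand_calculation():
    # groups (1,2,3), (3,4,5), (5,6,7): between SS = 24, within SS = 6
    # F = (24/2) / (6/6) = 12
    res = anova_oneway([[1, 2, 3], [3, 4, 5], [5, 6, 7]])
    assert res.statistic == pytest.approx(12.0)


def test_anova_two_groups_delegates():
    res = anova_oneway([np.arange(10.0), np.arange(10.0) + 5])
    assert res.test in ("t test", "mann-whitney")


def test_aggregate_samples_means_and_missing():
    roi = pd.DataFrame({
        "roi_id": ["r1", "r2", "r3", "r4"],
        "density": [2.0, 4.0, np.nan, 6.0],
    })
    manifest = pd.DataFrame({
        "roi_id": ["r1", "r2", "r3", "r4"],
        "sample_id": ["s1", "s1", "s2", "s2"],
        "sln_status": ["Neg", "Neg", "Pos", "Pos"],
    })
    agg = aggregate_samples(roi, manifest)
    s1 = agg[agg.sample_id == "s1"].iloc[0]
    s2 = agg[agg.sample_id == "s2"].iloc[0]
    assert s1.density == pytest.approx(3.0)
    assert s2.density == pytest.approx(6.0)      # missing excluded pairwise
    assert (agg.n_rois == 2).all()
    assert set(agg.sln_status) == {"Neg", "Pos"}


def test_aggregate_unmapped_roi_errors():
    roi = pd.DataFrame({"roi_id": ["r1", "rX"], "v": [1.0, 2.0]})
    manifest = pd.DataFrame({"roi_id": ["r1"], "sample_id": ["s1"]})
    with pytest.raises(ValueError, match="rX"):
        aggregate_samples(roi, manifest)


def _archetype_matrix(rng, n_per=10):
    rows, truth = [], []
    for _ in range(n_per):      # inflamed: high everything
        rows.append(np.abs([800, 400, 300, 500] + rng.normal(0, 30, 4)))
        truth.append("inflamed")
    for _ in range(n_per):      # T-cell-rich only
        rows.append(np.abs([700, 100, 30, 80] + rng.normal(0, 20, 4)))
        truth.append("t_only")
    for _ in range(n_per):      # uninflamed with moderate macrophages
        rows.append(np.abs([30, 250, 10, 40] + rng.normal(0, 10, 4)))
        truth.append("uninflamed")
    m = pd.DataFrame(rows, columns=["CD8_T", "MACROPHAGE", "B_CELL", "OTHER_CD45"])
    return m, truth


def test_inflammatory_archetypes_recovered(rng):
    from sklearn.metrics import adjusted_rand_score

    matrix, truth = _archetype_matrix(rng)
    clus = inflammatory_subtypes(matrix, k=3)
    assert adjusted_rand_score(truth, clus.labels) >= 0.9


def test_row_scaling_invariant(rng):
    matrix, _ = _archetype_matrix(rng)
    clus = inflammatory_subtypes(matrix, k=3)
    for c in clus.scaled.columns:
        col = clus.scaled[c].to_numpy()
        assert abs(col.mean()) < 1e-9
        assert abs(col.std() - 1.0) < 1e-9


def test_constant_column_scaled_to_zero_and_flagged(rng):
    matrix, _ = _archetype_matrix(rng)
    matrix["B_CELL"] = 5.0
    clus = inflammatory_subtypes(matrix, k=3)
    assert clus.constant_columns == ["B_CELL"]
    assert (clus.scaled["B_CELL"] == 0).all()


def test_k_edge_cases(rng):
    matrix, _ = _archetype_matrix(rng, n_per=2)
    assert (inflammatory_subtypes(matrix, k=1).labels == 0).all()
    with pytest.raises(ValueError):
        inflammatory_subtypes(matrix.iloc[:2], k=3)


def test_duplicated_rows_cluster_together(rng):
    matrix, _ = _archetype_matrix(rng)
    matrix = pd.concat([matrix, matrix.iloc[[0]]], ignore_index=True)
    clus = inflammatory_subtypes(matrix, k=3)
    assert clus.labels[0] == clus.labels[len(matrix) - 1]
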