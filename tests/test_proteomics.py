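import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from conftest import make_matrix
from oracles import anova_bruteforce, average_linkage_bruteforce, tukey_bruteforce
from osteomics.proteomics import (
    DapgRecord,
    IntensityMatrix,
    PairCall,
    anova_oneway,
    average_reference,
    classify_trend,
    dedupe_isoforms,
    filter_valid,
    impute_gaussian,
    log2_transform,
    pca_variance,
    permutation_fdr,
    ratio_to_reference,
    run_pipeline,
    top_regulated,
    trend_summary,
    tukey_hsd,
    zscore_and_cluster,
    zscore_rows,
)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "t0_values, expected",
    [((100.0, 100.0, 100.0), 100.0), ((100.0, 200.0, 300.0), 200.0), ((100.0, np.nan, 300.0), 200.0)],
)
def test_average_reference_is_mean_of_available_t0(t0_values, expected):
    m = make_matrix(
        {"T0_1": [t0_values[0]], "T0_2": [t0_values[1]], "T0_3": [t0_values[2]], "T8_GC_1": [5.0]}
    )
    assert average_reference(m).iloc[0] == pytest.approx(expected)


def test_average_reference_requires_t0():
    m = make_matrix({"T8_GC_1": [1.0], "T8_GC_2": [2.0]})
    with pytest.raises(ValueError, match="T0"):
        average_reference(m)


def test_ratio_drops_t0_and_propagates_missing():
    m = make_matrix(
        {"T0_1": [100.0, 100.0, 0.0], "T8_GC_1": [200.0, np.nan, 50.0], "T8_GC_2": [300.0, 4.0, 5.0]}
    )
    out = ratio_to_reference(m, average_reference(m))
    assert list(out.data.columns) == ["T8_GC_1", "T8_GC_2"]
    assert out.data.iloc[0, 0] == pytest.approx(2.0)
    assert np.isnan(out.data.iloc[1, 0])  # missing stays missing
    assert out.data.iloc[1, 1] == pytest.approx(0.04)
    assert out.data.iloc[2].isna().all()  # zero reference voids the gene


def test_ratio_rejects_mismatched_reference(toy_matrix):
    ref = average_reference(toy_matrix)
    with pytest.raises(ValueError):
        ratio_to_reference(toy_matrix, ref.iloc[:1])


def test_filter_valid_uses_exact_class_fractions():
    # gene A: 3/3 valid in T28_GC only -> kept; gene B: 2/2 in T8_GC -> kept
    # gene C: 2/3 in the size-3 classes and 1/2 in T8_GC -> dropped (max 0.667)
    nan = np.nan
    cols = {
        "T8_GC_1": [nan, 1.0, 1.0],
        "T8_GC_2": [nan, 1.0, nan],
        "T8_RPM_1": [nan, nan, 1.0],
        "T8_RPM_2": [nan, nan, 1.0],
        "T8_RPM_3": [nan, nan, nan],
        "T28_GC_1": [1.0, nan, 1.0],
        "T28_GC_2": [1.0, nan, 1.0],
        "T28_GC_3": [1.0, nan, nan],
        "T28_RPM_1": [nan, nan, 1.0],
        "T28_RPM_2": [nan, nan, nan],
        "T28_RPM_3": [nan, nan, 1.0],
    }
    m = make_matrix(cols, genes=["A", "B", "C"])
    kept = filter_valid(m, min_fraction=0.7)
    assert list(kept.genes) == ["A", "B"]


@pytest.mark.parametrize("value, expected", [(2.0, 1.0), (1.0, 0.0), (0.25, -2.0)])
def test_log2_transform_values(value, expected):
    m = make_matrix({"T8_GC_1": [value], "T8_GC_2": [4.0]})
    out = log2_transform(m)
    assert out.log2
    assert out.data.iloc[0, 0] == pytest.approx(expected)


def test_log2_transform_rejects_nonpositive():
    m = make_matrix({"T8_GC_1": [-1.0], "T8_GC_2": [4.0]})
    with pytest.raises(ValueError, match="non-positive"):
        log2_transform(m)


class TestImputeGaussian:
    def test_no_missing_is_identity(self, toy_matrix):
        m = log2_transform(toy_matrix)
        out = impute_gaussian(m, seed=0)
        pd.testing.assert_frame_equal(out.data, m.data)
        assert not out.imputed.any().any()

    def test_imputed_moments_match_downshifted_normal(self):
        rng = np.random.default_rng(11)
        observed = rng.normal(20.0, 2.0, 2000)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        m = IntensityMatrix(
            pd.DataFrame({"T8_GC_1": col, "T8_GC_2": np.ones_like(col)}), log2=True
        )
        out = impute_gaussian(m, width=0.3, downshift=1.8, seed=5)
        drawn = out.data.loc[out.imputed["T8_GC_1"], "T8_GC_1"]
        mu, sigma = observed.mean(), observed.std(ddof=1)
        se = 0.3 * sigma / np.sqrt(len(drawn))
        assert abs(drawn.mean() - (mu - 1.8 * sigma)) < 4 * se
        assert drawn.mean() == pytest.approx(16.4, abs=0.25)
        assert drawn.std(ddof=1) == pytest.approx(0.3 * sigma, rel=0.05)

    def test_same_seed_is_bit_identical(self):
        rng = np.random.default_rng(13)
        m = _complete_matrix(rng.normal(20, 2, (8, 11)))
        m.data.iloc[0, 3] = np.nan
        m.data.iloc[5, 0] = np.nan
        a = impute_gaussian(m, seed=42)
        b = impute_gaussian(m, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_column_with_single_observation_errors(self):
        m = make_matrix({"T8_GC_1": [1.0, np.nan, np.nan], "T8_GC_2": [1.0, 2.0, 3.0]}, log2=True)
        with pytest.raises(ValueError, match="fewer than 2"):
            impute_gaussian(m, seed=0)


# ---------------------------------------------------------------------------
# ANOVA / permutation FDR
# ---------------------------------------------------------------------------

class TestAnova:
    def test_equal_group_means_give_f_zero(self):
        g = [np.array([1.0, 2, 3])] * 4
        f_stat, p = anova_oneway(g)
        assert f_stat == 0.0 and p == 1.0

    def test_separated_groups_drive_p_to_zero(self):
        rng = np.random.default_rng(0)
        g = [np.zeros(3) + rng.normal(0, 1e-9, 3), np.ones(3) + rng.normal(0, 1e-9, 3)]
        _, p = anova_oneway(g)
        assert p < 1e-12

    def test_matches_bruteforce_oracle(self):
        groups = [np.array([1.0, 2]), np.array([2.0, 3, 4]), np.array([5.0, 6, 7]), np.array([8.0, 9, 10])]
        f_stat, p = anova_oneway(groups)
        f_ref, p_ref = anova_bruteforce(groups)
        assert f_stat == pytest.approx(f_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)
        # frozen values from the oracle
        assert f_stat == pytest.approx(31.27972027972028, rel=1e-6)
        assert p == pytest.approx(1.9957278930422703e-4, rel=1e-6)

    def test_random_instances_agree_with_oracle_to_6_digits(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(2, 6)) for _ in range(4)]
            f_stat, p = anova_oneway(groups)
            f_ref, p_ref = anova_bruteforce(groups)
            assert f_stat == pytest.approx(f_ref, rel=1e-7)
            assert p == pytest.approx(p_ref, rel=1e-7)

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0]), np.array([1.0, 2])])


def _complete_matrix(values: np.ndarray) -> IntensityMatrix:
    cols = (
        [f"T8_GC_{r}" for r in (1, 2)]
        + [f"T8_RPM_{r}" for r in (1, 2, 3)]
        + [f"T28_GC_{r}" for r in (1, 2, 3)]
        + [f"T28_RPM_{r}" for r in (1, 2, 3)]
    )
    df = pd.DataFrame(values, columns=cols, index=[f"G{i}" for i in range(len(values))])
    return IntensityMatrix(df, log2=True)


class TestPermutationFdr:
    def test_constant_matrix_calls_nothing(self):
        m = _complete_matrix(np.full((50, 11), 3.0))
        res = permutation_fdr(m, n_perm=50, seed=0)
        assert res.n_significant == 0

    def test_strong_spikes_are_called_and_null_genes_spared(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.25, (300, 11))
        x[:20, 2:5] += 3.0  # big shift in T8_RPM for the first 20 genes
        m = _complete_matrix(x)
        res = permutation_fdr(m, n_perm=100, seed=2)
        called = set(np.where(res.significant.to_numpy())[0])
        assert set(range(20)) <= called
        assert len(called - set(range(20))) <= 3
        # every call respects the cutoff
        assert (res.p_values[res.significant] <= res.cutoff).all()

    def test_rejects_zero_permutations(self):
        m = _complete_matrix(np.zeros((5, 11)))
        with pytest.raises(ValueError):
            permutation_fdr(m, n_perm=0)


class TestTukey:
    def test_equal_means_yield_no_significant_pairs(self):
        groups = {c: np.array([1.0, 1.0, 1.0]) for c in ("T8_GC", "T8_RPM", "T28_GC", "T28_RPM")}
        groups = {c: v + np.arange(3) * 0.1 for c, v in groups.items()}
        calls = tukey_hsd(groups)
        assert len(calls) == 6
        assert not any(c.significant for c in calls.values())

    def test_matches_studentized_range_oracle(self):
        groups = {
            "T8_GC": np.array([1.0, 1.2]),
            "T8_RPM": np.array([1.0, 1.1, 0.9]),
            "T28_GC": np.array([3.0, 3.1, 2.9]),
            "T28_RPM": np.array([3.2, 3.0, 3.1]),
        }
        calls = tukey_hsd(groups)
        oracle = tukey_bruteforce(groups)
        for pair, call in calls.items():
            assert call.p_value == pytest.approx(oracle[pair], rel=1e-6)
        sig = {pair for pair, c in calls.items() if c.significant}
        assert sig == {
            ("T8_GC", "T28_GC"),
            ("T8_GC", "T28_RPM"),
            ("T8_RPM", "T28_GC"),
            ("T8_RPM", "T28_RPM"),
        }

    def test_random_instances_agree_with_oracle_to_6_digits(self):
        rng = np.random.default_rng(8)
        names = ("T8_GC", "T8_RPM", "T28_GC", "T28_RPM")
        for _ in range(10):
            groups = {
                c: rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(2, 5))) for c in names
            }
            calls = tukey_hsd(groups)
            oracle = tukey_bruteforce(groups)
            for pair, call in calls.items():
                assert call.p_value == pytest.approx(oracle[pair], rel=1e-6, abs=1e-12)


# ---------------------------------------------------------------------------
# dedupe / trend classification / summary
# ---------------------------------------------------------------------------

def _rec(gene, p):
    return DapgRecord(gene=gene, anova_p=p, significant=True)


class TestDedupe:
    def test_no_duplicates_is_identity(self):
        recs = [_rec("A", 0.01), _rec("B", 0.02)]
        assert dedupe_isoforms(recs) == recs

    def test_isoform_suffix_collapses_to_smallest_p(self):
        recs = [_rec("GENE1", 0.02), _rec("GENE1-2", 0.01), _rec("OTHER", 0.03)]
        kept = dedupe_isoforms(recs)
        assert [r.gene for r in kept] == ["GENE1-2", "OTHER"]

    def test_reduction_count_relationship(self):
        # 486 records with 5 redundant isoform names reduce to 481
        recs = [_rec(f"G{i}", 0.001 * (i + 1)) for i in range(481)]
        recs += [_rec(f"G{i}-2", 0.5) for i in range(5)]
        assert len(dedupe_isoforms(recs)) == 481


def _pair_calls(sig8=None, sig28=None, time_pair=False):
    """Build the six pair calls; sig8/sig28 give the higher class of the SMG
    pair at that time (None = not significant)."""
    calls = {}
    for pair in [
        ("T8_GC", "T8_RPM"),
        ("T8_GC", "T28_GC"),
        ("T8_GC", "T28_RPM"),
        ("T8_RPM", "T28_GC"),
        ("T8_RPM", "T28_RPM"),
        ("T28_GC", "T28_RPM"),
    ]:
        calls[pair] = PairCall(higher=pair[0], significant=False, p_value=0.5)
    if sig8:
        calls[("T8_GC", "T8_RPM")] = PairCall(higher=sig8, significant=True, p_value=0.01)
    if sig28:
        calls[("T28_GC", "T28_RPM")] = PairCall(higher=sig28, significant=True, p_value=0.01)
    if time_pair:
        calls[("T8_GC", "T28_GC")] = PairCall(higher="T28_GC", significant=True, p_value=0.01)
    return calls


@pytest.mark.parametrize(
    "sig8, sig28, time_pair, expected",
    [
        ("T8_GC", None, False, "down_T8_only"),
        ("T8_RPM", None, False, "up_T8_only"),
        (None, "T28_GC", False, "down_T28_only"),
        (None, "T28_RPM", False, "up_T28_only"),
        ("T8_GC", "T28_GC", False, "down_both"),
        ("T8_RPM", "T28_RPM", False, "up_both"),
        ("T8_GC", "T28_RPM", False, "mixed"),
        ("T8_RPM", "T28_GC", False, "mixed"),
        (None, None, True, "time_only"),
        (None, None, False, "time_only"),
    ],
)
def test_classify_trend_mapping(sig8, sig28, time_pair, expected):
    rec = DapgRecord(gene="X", anova_p=0.001, significant=True, pair_calls=_pair_calls(sig8, sig28, time_pair))
    assert classify_trend(rec) == expected


def test_classify_trend_requires_all_pairs():
    rec = DapgRecord(gene="X", anova_p=0.001, significant=True, pair_calls={})
    with pytest.raises(KeyError):
        classify_trend(rec)


def test_trend_summary_percentages_from_counts():
    counts = {
        "down_T8_only": 73,
        "up_T8_only": 32,
        "down_T28_only": 17,
        "up_T28_only": 28,
        "down_both": 28,
        "up_both": 16,
        "time_only": 287,
    }
    summary = trend_summary(counts)
    assert summary["count"].sum() == 481
    assert summary.loc["down_T8_only", "percent"] == 15.2
    assert summary.loc["down_T28_only", "percent"] == 3.5
    assert summary.loc["down_both", "percent"] == 5.8
    assert summary.loc["up_both", "percent"] == 3.3


# ---------------------------------------------------------------------------
# top regulated / clustering / PCA
# ---------------------------------------------------------------------------

def test_top_regulated_recovers_spiked_extremes():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 0.05, (30, 11))
    x[0, 2:5] -= 2.0  # strongly down in T8_RPM
    x[0, 8:11] -= 2.0  # and in T28_RPM
    x[1, 2:5] += 2.0
    x[1, 8:11] += 2.0
    m = _complete_matrix(x)
    down, up = top_regulated(m, k=1)
    assert down == ["G0"] and up == ["G1"]


def test_top_regulated_symmetric_lists_disjoint():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.01, (40, 11))
    x[:10, 2:5] += np.linspace(1, 4, 10)[:, None]
    x[10:20, 2:5] -= np.linspace(1, 4, 10)[:, None]
    m = _complete_matrix(x)
    down, up = top_regulated(m, k=10)
    assert not set(down) & set(up)


class TestZscoreCluster:
    def test_zscore_definition(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        z = zscore_rows(df)
        np.testing.assert_allclose(z.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_zero_variance_row_names_gene(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0]], index=["FLAT"], columns=list("abc"))
        with pytest.raises(ValueError, match="FLAT"):
            zscore_rows(df)

    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame(
            [[1.0, 2, 3], [1.0, 2, 3], [9.0, 1, 2], [3.0, 8, 1]],
            index=list("abcd"),
            columns=list("xyz"),
        )
        res = zscore_and_cluster(df)
        first = res.row_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_order_matches_bruteforce_average_linkage(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (5, 4))
        link = linkage(x, method="average", metric="euclidean")
        merges = average_linkage_bruteforce(x)
        assert [m[2] for m in merges] == pytest.approx([row[2] for row in link], rel=1e-9)


class TestPca:
    def test_single_axis_explains_everything(self):
        t = np.linspace(-1, 1, 6)
        x = np.outer(np.array([1.0, 2.0, -1.0]), t)  # genes x samples, rank 1
        cols = ["T8_GC_1", "T8_GC_2", "T8_RPM_1", "T8_RPM_2", "T28_GC_1", "T28_GC_2"]
        m = IntensityMatrix(pd.DataFrame(x, index=list("abc"), columns=cols), log2=True)
        res = pca_variance(m)
        assert res.variance_percent[0] == pytest.approx(100.0, abs=1e-9)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        m = _complete_matrix(rng.normal(0, 1, (20, 11)))
        res = pca_variance(m)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.scores.shape[0] == 11

    def test_isotropic_cloud_splits_variance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, (2, 4000))  # 2 genes, many samples
        cols = [f"T8_GC_{i}" for i in range(1, 4001)]
        m = IntensityMatrix(pd.DataFrame(x, index=["a", "b"], columns=cols), log2=True)
        res = pca_variance(m)
        assert res.variance_fractions[0] == pytest.approx(0.5, abs=0.05)

    def test_constant_matrix_errors(self):
        m = _complete_matrix(np.full((5, 11), 2.0))
        with pytest.raises(ValueError):
            pca_variance(m)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def test_pipeline_is_deterministic_for_fixed_seed():
    from osteomics import simulate

    spec = simulate.ProteomicsSimSpec(n_proteins=120, frac_dapg=0.1, seed=3)
    m, _ = simulate.gen_proteomics(spec)
    a = run_pipeline(m, n_perm=40, seed=9)
    b = run_pipeline(m, n_perm=40, seed=9)
    pd.testing.assert_frame_equal(a.matrix.data, b.matrix.data)
    assert a.significant_genes == b.significant_genes
    assert [r.category for r in a.records] == [r.category for r in b.records]


def test_pipeline_categories_partition_significant_set():
    from osteomics import simulate

    spec = simulate.ProteomicsSimSpec(n_proteins=200, frac_dapg=0.15, seed=4)
    m, _ = simulate.gen_proteomics(spec)
    res = run_pipeline(m, n_perm=60, seed=4)
    assert res.summary["count"].sum() == len(res.records)
    assert all(r.category is not None for r in res.records)
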