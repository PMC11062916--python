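"""Normalization, stratification, differential expression and sample structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirreg.expression import (
    bh_adjust,
    cluster_order,
    differential_expression,
    normalize_log2,
    pca_scores,
    spearman_matrix,
    stratify_by_cutoff,
    stratify_tertiles,
)
from mirreg.simulate import SimulationConfig, gen_annotation, gen_ground_truth, gen_tumour_counts


class TestNormalize:
    def test_closed_form_cpm_log2(self):
        counts = pd.DataFrame(
            {"s1": [1023, 1_000_000 - 1023]}, index=["f1", "f2"]
        )
        norm = normalize_log2(counts)
        assert norm.loc["f1", "s1"] == pytest.approx(10.0)

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 4)) + 1,
            index=[f"f{i}" for i in range(30)],
            columns=list("abcd"),
        )
        doubled = counts.copy()
        doubled["b"] = counts["b"] * 2
        pd.testing.assert_series_equal(
            normalize_log2(counts)["b"], normalize_log2(doubled)["b"]
        )

    def test_matches_per_sample_loop_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(25, 6)) + 1,
            index=[f"f{i}" for i in range(25)],
            columns=[f"s{j}" for j in range(6)],
        )
        norm = normalize_log2(counts)
        for s in counts.columns:  # naive independent per-sample computation
            lib = counts[s].sum()
            for f in counts.index:
                expected = np.log2(counts.loc[f, s] / lib * 1e6 + 1)
                assert norm.loc[f, s] == pytest.approx(expected)

    def test_all_zero_sample_named_in_error(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["f1", "f2"])
        with pytest.raises(ValueError, match="empty"):
            normalize_log2(counts)


class TestStratify:
    def test_nine_distinct_values_exact_thirds(self):
        expr = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        strat = stratify_tertiles(expr)
        assert sorted(strat.samples_in("H")) == ["s6", "s7", "s8"]
        assert all(len(strat.samples_in(g)) == 3 for g in "HML")

    def test_156_samples_split_52_52_52(self, rng):
        expr = pd.Series(
            rng.permutation(156).astype(float), index=[f"p{i:03d}" for i in range(156)]
        )
        strat = stratify_tertiles(expr)
        assert [len(strat.samples_in(g)) for g in "HML"] == [52, 52, 52]

    def test_boundary_ties_match_stable_sort_oracle(self, rng):
        values = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        expr = pd.Series(values, index=[f"s{i:02d}" for i in range(20)])
        strat = stratify_tertiles(expr)
        order = sorted(expr.index, key=lambda s: (-expr[s], s))  # brute force
        sizes = [7, 7, 6]
        expected = {}
        pos = 0
        for g, size in zip("HML", sizes):
            for s in order[pos : pos + size]:
                expected[s] = g
            pos += size
        assert strat.assignments == expected

    def test_partition_and_size_invariants(self, rng):
        for n in (3, 7, 10, 23, 100):
            expr = pd.Series(rng.normal(size=n), index=[f"x{i}" for i in range(n)])
            strat = stratify_tertiles(expr)
            sizes = [len(strat.samples_in(g)) for g in "HML"]
            assert sum(sizes) == n and max(sizes) - min(sizes) <= 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            stratify_tertiles(pd.Series([1.0, 2.0], index=["a", "b"]))

    def test_single_cutoff_boundary_to_upper(self):
        expr = pd.Series({"a": 13.0, "b": 12.288, "c": 11.9})
        strat = stratify_by_cutoff(expr, [12.288])
        assert strat.assignments == {"a": "H", "b": "H", "c": "L"}

    def test_two_cutoffs_interval_membership(self):
        strat = stratify_by_cutoff(pd.Series({"s": 6.0}), [4, 8])
        assert strat.assignments["s"] == "M"

    def test_cutoffs_at_tertile_boundaries_agree(self, rng):
        expr = pd.Series(rng.normal(size=30), index=[f"s{i:02d}" for i in range(30)])
        assert expr.nunique() == 30
        tert = stratify_tertiles(expr)
        by_cut = stratify_by_cutoff(expr, tert.cutoffs)
        assert by_cut.assignments == tert.assignments


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_closed_form_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_definition_oracle(self, rng):
        for _ in range(120):
            p = rng.uniform(size=rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)  # from-definition oracle: sort, p*m/i, cummin, unsort
            adj_sorted = p[order] * m / np.arange(1, m + 1)
            for i in range(m - 2, -1, -1):
                adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_order_preserving_and_bounded(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        i, j = np.argsort(p)[:2]
        assert adj[i] <= adj[j]


def _planted_matrix(rng, n_features=50, n_per_group=20, shift=2.0, n_planted=5):
    base = rng.uniform(3, 8, size=n_features)
    a = rng.normal(base[:, None], 0.7, size=(n_features, n_per_group))
    b = rng.normal(base[:, None], 0.7, size=(n_features, n_per_group))
    a[:n_planted] += shift
    cols_a = [f"a{i}" for i in range(n_per_group)]
    cols_b = [f"b{i}" for i in range(n_per_group)]
    norm = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"f{i}" for i in range(n_features)],
        columns=cols_a + cols_b,
    )
    return norm, cols_a, cols_b


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        vals = np.tile(np.arange(10.0)[:, None], (1, 8))
        norm = pd.DataFrame(vals, columns=[f"s{i}" for i in range(8)])
        res = differential_expression(norm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res["log2fc"] == 0).all() and not res["significant"].any()

    def test_planted_shift_detected_up(self, rng):
        norm, a, b = _planted_matrix(rng)
        res = differential_expression(norm, a, b)
        assert res.loc["f0", "significant"] and res.loc["f0", "direction"] == "up"

    def test_expression_floor_blocks_low_features(self, rng):
        # tiny p-value but mean log2 expression 0.5 -> not significant
        norm, a, b = _planted_matrix(rng, n_features=20)
        norm.loc["f0"] = norm.loc["f0"] - norm.loc["f0"].mean() + 0.5
        res = differential_expression(norm, a, b)
        assert res.loc["f0", "mean_log2"] == pytest.approx(0.5)
        assert not res.loc["f0", "significant"]

    def test_overlapping_groups_rejected(self, rng):
        norm, a, b = _planted_matrix(rng, n_features=5)
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(norm, a, a[:2] + b[:2])

    def test_antisymmetry(self, rng):
        norm, a, b = _planted_matrix(rng, n_features=30)
        fwd = differential_expression(norm, a, b)
        rev = differential_expression(norm, b, a)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p"], rev["p"])
        np.testing.assert_allclose(fwd["fdr"], rev["fdr"])

    def test_null_calibration_no_planted_effects(self):
        frac = []
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed,
                n_planted_regulated=0,
                n_decoy_bound=0,
                n_clinical_associated=0,
                n_samples_per_subtype=(("SEM", 40), ("EC", 40)),
            )
            ann = gen_annotation(cfg)
            truth = gen_ground_truth(cfg, ann)
            counts, driver, meta = gen_tumour_counts(cfg, ann, truth)
            norm = normalize_log2(counts)
            sem = [s for s in counts.columns if s.startswith("SEM")]
            ec = [s for s in counts.columns if s.startswith("EC")]
            res = differential_expression(norm, sem, ec)
            frac.append(res["significant"].mean())
        n_tests = 200 * 20
        tol = 2 * np.sqrt(0.05 * 0.95 / n_tests)
        assert np.mean(frac) <= 0.05 + tol

    def test_planted_recovery_40_per_group(self, rng):
        hits = []
        fps = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            norm, a, b = _planted_matrix(
                r, n_features=100, n_per_group=40, shift=2.0, n_planted=10
            )
            res = differential_expression(norm, a, b)
            planted = {f"f{i}" for i in range(10)}
            called = set(res.index[res["significant"]])
            hits.append(len(called & planted) / len(planted))
            fps.append(len(called & planted) / max(len(called), 1))
        assert np.mean(hits) >= 0.9 and np.mean(fps) >= 0.8


class TestSampleStructure:
    def test_duplicated_sample_rho_one(self, rng):
        norm = pd.DataFrame(
            rng.normal(size=(20, 3)), columns=["a", "b", "c"]
        )
        norm["d"] = norm["a"]
        corr = spearman_matrix(norm)
        assert corr.loc["a", "d"] == pytest.approx(1.0)

    def test_monotone_reversal_rho_minus_one(self, rng):
        a = rng.normal(size=20)
        norm = pd.DataFrame({"a": a, "b": np.exp(-a)})
        corr = spearman_matrix(norm)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        norm = pd.DataFrame(
            rng.normal(size=(30, 5)), columns=list("abcde")
        )
        corr = spearman_matrix(norm)
        ranks = norm.rank()
        for x in norm.columns:
            for y in norm.columns:
                expected = stats.pearsonr(ranks[x], ranks[y]).statistic
                assert corr.loc[x, y] == pytest.approx(expected)

    def test_constant_sample_flagged(self, rng):
        norm = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            spearman_matrix(norm)

    def test_cluster_two_blocks_contiguous(self, rng):
        block1 = rng.normal(0, 0.1, size=(40, 4)) + rng.normal(size=(40, 1))
        block2 = rng.normal(0, 0.1, size=(40, 4)) + rng.normal(size=(40, 1))
        norm = pd.DataFrame(
            np.hstack([block1, block2]),
            columns=[f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)],
        )
        leaves, linkage = cluster_order(spearman_matrix(norm))
        labels = ["x" if s.startswith("x") else "y" for s in leaves]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)
        assert np.all(np.diff(linkage[:, 2]) >= -1e-12)  # heights non-decreasing

    def test_clear_pair_merges_first(self):
        corr = pd.DataFrame(
            [[1.0, 0.95, 0.1], [0.95, 1.0, 0.2], [0.1, 0.2, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        _, linkage = cluster_order(corr)
        assert set(linkage[0, :2].astype(int)) == {0, 1}

    def test_cluster_rejects_asymmetric(self):
        corr = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            cluster_order(corr)

    def test_pca_separates_planted_clusters(self, rng):
        a = rng.normal(0, 0.3, size=(50, 10)) + 3
        b = rng.normal(0, 0.3, size=(50, 10)) - 3
        norm = pd.DataFrame(
            np.hstack([a, b]),
            columns=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
        )
        scores = pca_scores(norm)
        pa = scores.loc[[c for c in scores.index if c.startswith("a")], "PC1"]
        pb = scores.loc[[c for c in scores.index if c.startswith("b")], "PC1"]
        assert pa.min() > pb.max() or pb.min() > pa.max()

    def test_duplicated_samples_identical_scores(self, rng):
        norm = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        norm["e"] = norm["a"]
        scores = pca_scores(norm)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["e"], atol=1e-9)

    def test_score_variance_bounded_by_data_variance(self, rng):
        norm = pd.DataFrame(rng.normal(size=(15, 6)))
        scores = pca_scores(norm, n_components=2)
        x = norm.to_numpy().T
        total_var = ((x - x.mean(axis=0)) ** 2).sum()
        assert (scores.to_numpy() ** 2).sum() <= total_var + 1e-9

    def test_pca_rank_guard(self, rng):
        norm = pd.DataFrame(rng.normal(size=(1, 3)))  # rank 1 after centring? no: 2 samples span
        with pytest.raises(ValueError):
            pca_scores(norm, n_components=3)
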