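"""Co-expression network construction, module detection and eigengenes."""

import numpy as np
import pandas as pd
import pytest

from seasonet.errors import InsufficientDataError, ValidationError
from seasonet.network import (
    NetConfig,
    adjacency,
    detect_modules,
    fit_modules,
    flag_outlier_samples,
    merge_similar_modules,
    module_eigengene,
    module_membership,
    module_trait_correlations,
    pick_soft_threshold,
    preprocess_ko,
    tom_dissimilarity,
)
from seasonet.simulate import simulate_ko_matrix


def _block_expr(sizes, n_samples=40, within=0.95, seed=0):
    """Rows in blocks sharing a latent signal at the requested correlation."""
    rng = np.random.default_rng(seed)
    rows = []
    noise_sd = np.sqrt(1.0 / within**2 - 1.0)
    for b, size in enumerate(sizes):
        latent = rng.standard_normal(n_samples)
        rows.append(latent[None, :] + noise_sd * rng.standard_normal((size, n_samples)))
    x = np.vstack(rows)
    return pd.DataFrame(
        x, index=[f"K{i:04d}" for i in range(x.shape[0])],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestPreprocess:
    def test_floor_then_aggregate_filter(self):
        ko = pd.DataFrame(
            [[0.5, 0.9, 3.0], [10.0, 0.0, 0.0], [20.0, 5.0, 0.2], [9.0, 8.0, 7.0]],
            index=["a", "b", "c", "d"], columns=["s1", "s2", "s3"],
        )
        out = preprocess_ko(ko, NetConfig(ko_min_aggregate=10))
        # row a: floored to (0,0,3), total 3 < 10 -> dropped
        assert "a" not in out.index
        assert out.loc["b"].tolist() == pytest.approx([np.log2(11), 0.0, 0.0])
        # row c: 0.2 floored away, total 25 -> kept
        assert out.loc["c", "s3"] == 0.0

    def test_clean_matrix_only_log_transformed(self):
        ko = pd.DataFrame(
            np.full((4, 3), 8.0), index=list("abcd"), columns=["s1", "s2", "s3"]
        )
        out = preprocess_ko(ko, NetConfig())
        assert np.allclose(out.to_numpy(), np.log2(9.0))

    def test_insufficient_survivors_rejected(self):
        ko = pd.DataFrame(
            [[0.5, 0.5, 0.5]] * 5, index=list("abcde"), columns=["s1", "s2", "s3"]
        )
        with pytest.raises(InsufficientDataError):
            preprocess_ko(ko, NetConfig())


class TestOutlierSamples:
    def test_identical_samples_not_flagged(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(30)
        expr = pd.DataFrame({f"s{i}": col for i in range(6)})
        out = flag_outlier_samples(expr)
        assert np.allclose(out["z"], 0.0)
        assert not out["outlier"].any()

    def test_planted_independent_sample_has_minimum_z(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal(200)
        cols = {f"s{i}": latent + 0.3 * rng.standard_normal(200) for i in range(8)}
        cols["odd"] = rng.standard_normal(200)
        out = flag_outlier_samples(pd.DataFrame(cols))
        assert out["z"].idxmin() == "odd"

    def test_flags_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.standard_normal((50, 10)))
        loose = flag_outlier_samples(expr, NetConfig(outlier_z=-1.0))
        strict = flag_outlier_samples(expr, NetConfig(outlier_z=-3.0))
        assert strict["outlier"].sum() <= loose["outlier"].sum()


class TestAdjacency:
    def test_perfect_correlation_saturates(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]],
                            index=["a", "b"])
        a = adjacency(expr, power=7)
        assert a.loc["a", "b"] == pytest.approx(1.0)

    def test_power_applied_to_absolute_correlation(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.standard_normal((5, 20)))
        a = adjacency(expr, power=3)
        r = np.corrcoef(expr.to_numpy())
        assert np.allclose(a.to_numpy(), np.where(np.eye(5), 1.0, np.abs(r) ** 3))

    def test_power_below_one_rejected(self):
        with pytest.raises(ValidationError):
            adjacency(pd.DataFrame(np.eye(3)), power=0)


class TestTom:
    def test_isolated_pair_fully_overlapping(self):
        # two nodes joined by a_ij=1 and nothing else: TOM = (0+1)/(0+1-1+1) = 1
        adj = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        d = tom_dissimilarity(adj)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_disconnected_pair_zero_overlap(self):
        adj = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        d = tom_dissimilarity(adj)
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(4)
        n = 6
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        frame = pd.DataFrame(a)
        d = tom_dissimilarity(frame).to_numpy()
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                tom = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert d[i, j] == pytest.approx(1 - tom, abs=1e-12)

    def test_structure_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        d = tom_dissimilarity(pd.DataFrame(a)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[1.0, 0.2], [0.8, 1.0]])
        with pytest.raises(ValidationError):
            tom_dissimilarity(bad)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        expr = _block_expr([80, 90], within=0.9, seed=6)
        truth = np.array([1] * 80 + [2] * 90)
        adj = adjacency(expr, 6)
        labels = detect_modules(tom_dissimilarity(adj), NetConfig(), expr=expr)
        assert labels.nunique() == 2
        for block, members in ((1, range(80)), (2, range(80, 170))):
            got = labels.iloc[list(members)]
            dominant = got.mode().iloc[0]
            assert (got == dominant).mean() >= 0.95
        # blocks map to different labels
        assert labels.iloc[:80].mode().iloc[0] != labels.iloc[80:].mode().iloc[0]

    def test_undersized_block_dissolves(self):
        expr = _block_expr([50], within=0.9, seed=7)
        adj = adjacency(expr, 6)
        labels = detect_modules(tom_dissimilarity(adj), NetConfig(min_module_size=70))
        assert (labels == 0).all()

    def test_deep_split_zero_is_static_cut(self):
        expr = _block_expr([80, 90], within=0.9, seed=8)
        diss = tom_dissimilarity(adjacency(expr, 6))
        static = detect_modules(diss, NetConfig(deep_split=0))
        # the two well-separated blocks need no recursion: labels agree
        deep = detect_modules(diss, NetConfig(deep_split=4))
        assert static.nunique() == deep.nunique() == 2

    def test_min_size_above_matrix_size_warns_unassigned(self):
        expr = _block_expr([30], seed=9)
        diss = tom_dissimilarity(adjacency(expr, 6))
        with pytest.warns(UserWarning):
            labels = detect_modules(diss, NetConfig(min_module_size=100))
        assert (labels == 0).all()


class TestEigengenes:
    def test_identical_rows_give_standardized_profile(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame([v, v, v], index=["a", "b", "c"])
        labels = pd.Series([1, 1, 1], index=expr.index)
        eig, ev = module_eigengene(expr, labels)
        expected = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(eig.loc[1], expected)
        assert ev[1] == pytest.approx(1.0)

    def test_sign_orientation_positive_mean_correlation(self):
        rng = np.random.default_rng(10)
        expr = _block_expr([20], seed=11)
        labels = pd.Series(1, index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        rs = [np.corrcoef(eig.loc[1], row)[0, 1] for _, row in expr.iterrows()]
        assert np.mean(rs) > 0
        # flipping every member flips the eigengene too
        eig_neg, _ = module_eigengene(-expr, labels)
        assert np.allclose(eig_neg.loc[1], -eig.loc[1])

    def test_unit_variance(self):
        expr = _block_expr([15, 15], seed=12)
        labels = pd.Series([1] * 15 + [2] * 15, index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        assert np.allclose(eig.std(axis=1, ddof=1), 1.0)

    def test_membership_bounded(self):
        expr = _block_expr([15, 15], seed=13)
        labels = pd.Series([1] * 15 + [2] * 15, index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        mm = module_membership(expr, eig)
        assert (mm.to_numpy() <= 1.0).all() and (mm.to_numpy() >= -1.0).all()


class TestMerging:
    def test_identical_eigengenes_merge(self):
        v = _block_expr([30], seed=14)
        expr = pd.concat([v, v + 0.01])
        expr.index = [f"K{i}" for i in range(60)]
        labels = pd.Series([1] * 30 + [2] * 30, index=expr.index)
        merged, history = merge_similar_modules(expr, labels, NetConfig())
        assert merged.nunique() == 1
        assert len(history) == 1

    def test_uncorrelated_modules_untouched(self):
        expr = _block_expr([30, 30], seed=15)
        labels = pd.Series([1] * 30 + [2] * 30, index=expr.index)
        merged, history = merge_similar_modules(expr, labels, NetConfig())
        assert merged.nunique() == 2 and history == []

    def test_merging_never_increases_module_count(self):
        expr = _block_expr([20, 20, 20], seed=16)
        labels = pd.Series([1] * 20 + [2] * 20 + [3] * 20, index=expr.index)
        merged, _ = merge_similar_modules(expr, labels, NetConfig(merge_cor=-0.9))
        assert merged.nunique() <= labels.nunique()


class TestTraitCorrelations:
    def test_trait_equal_to_eigengene(self):
        expr = _block_expr([20], seed=17)
        labels = pd.Series(1, index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        traits = pd.DataFrame({"self": eig.loc[1]}, index=eig.columns)
        r, p, q = module_trait_correlations(eig, traits)
        assert r.loc[1, "self"] == pytest.approx(1.0)
        assert p.loc[1, "self"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_trait_reported_null(self):
        expr = _block_expr([20], seed=18)
        eig, _ = module_eigengene(expr, pd.Series(1, index=expr.index))
        traits = pd.DataFrame({"flat": np.ones(len(eig.columns))}, index=eig.columns)
        r, p, q = module_trait_correlations(eig, traits)
        assert np.isnan(r.loc[1, "flat"]) and np.isnan(q.loc[1, "flat"])


class TestPipeline:
    def test_permutation_invariance(self):
        tpm, labels, _ = simulate_ko_matrix(150, 36, 2, 40, seed=19)
        cfg = NetConfig(min_module_size=30)
        with pytest.warns(UserWarning):
            base = fit_modules(tpm, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(tpm))
        with pytest.warns(UserWarning):
            shuffled = fit_modules(tpm.iloc[perm], cfg)
        # same partition up to label renaming
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(
            base.labels.reindex(tpm.index).to_numpy(),
            shuffled.labels.reindex(tpm.index).to_numpy(),
        )
        assert ari == pytest.approx(1.0)

    def test_soft_threshold_table_well_formed(self):
        tpm, _, _ = simulate_ko_matrix(100, 36, 2, 30, seed=20)
        expr = preprocess_ko(tpm, NetConfig())
        with pytest.warns(UserWarning):
            power, table = pick_soft_threshold(expr, NetConfig())
        assert power in NetConfig().candidate_powers
        assert {"power", "fit", "slope", "mean_k", "target_reached"} <= set(table.columns)
        # connectivity shrinks as the power grows
        assert table["mean_k"].is_monotonic_decreasing
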