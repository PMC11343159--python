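import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbpls.inference import (
    block_average_fc,
    bootstrap_loadings,
    bootstrap_within_sites,
    fdr_bh,
    permutation_test,
    permute_within_sites,
)
from bbpls.pls import compute_loadings, fit_pls, zscore_columns
from bbpls.synthetic import Parcellation


class TestPermuteWithinSites:
    def test_single_site_reaches_any_permutation(self, rng):
        sites = np.zeros(4)
        seen = {tuple(permute_within_sites(sites, rng)) for _ in range(2000)}
        assert len(seen) == 24

    def test_singleton_sites_force_identity(self, rng):
        sites = np.arange(6)
        for _ in range(10):
            np.testing.assert_array_equal(
                permute_within_sites(sites, rng), np.arange(6)
            )

    def test_two_sites_reach_exactly_factorial_product(self, rng):
        sites = np.array(["a", "a", "a", "b", "b"])
        # enumeration oracle: permutations fixing the site partition
        valid = {
            p
            for p in itertools.permutations(range(5))
            if all(sites[i] == sites[p[i]] for i in range(5))
        }
        assert len(valid) == 12
        seen = {tuple(permute_within_sites(sites, rng)) for _ in range(5000)}
        assert seen == valid

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30))
    def test_preserves_site_counts(self, labels):
        sites = np.array(labels)
        perm = permute_within_sites(sites, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(sites[perm]), np.sort(sites))
        np.testing.assert_array_equal(sites[perm], sites)


class TestBootstrapWithinSites:
    def test_singleton_site_always_present(self, rng):
        sites = np.array(["a", "b", "b", "b"])
        for _ in range(20):
            idx = bootstrap_within_sites(sites, rng)
            assert idx[0] == 0

    def test_site_sizes_preserved(self, rng):
        sites = np.array(["a"] * 3 + ["b"] * 5 + ["c"] * 2)
        for _ in range(20):
            idx = bootstrap_within_sites(sites, rng)
            assert (sites[idx] == sites).all()

    def test_expected_unique_fraction(self, rng):
        n = 50
        sites = np.zeros(n)
        fracs = [
            len(np.unique(bootstrap_within_sites(sites, rng))) / n for _ in range(400)
        ]
        expected = 1 - (1 - 1 / n) ** n
        assert abs(np.mean(fracs) - expected) < 0.02


class TestPermutationTest:
    def _frames(self, rng, n=30, p=4, q=3):
        X = zscore_columns(
            pd.DataFrame(rng.standard_normal((n, p)), index=range(n))
        )
        Y = zscore_columns(
            pd.DataFrame(
                rng.standard_normal((n, q)), index=range(n), columns=list("abc")[:q]
            )
        )
        return X, Y

    def test_p_value_formula_lower_bound(self, rng):
        # strong planted signal saturates at the add-one lower bound
        n = 60
        z = rng.standard_normal(n)
        X = zscore_columns(pd.DataFrame({"x": z, "x2": rng.standard_normal(n)}))
        Y = zscore_columns(pd.DataFrame({"y": z + 0.01 * rng.standard_normal(n)}))
        res = permutation_test(X, Y, np.zeros(n), n_perm=99, rng=rng)
        assert res.p_values[0] == pytest.approx(1 / 100)

    def test_p_values_in_valid_range(self, rng):
        X, Y = self._frames(rng)
        res = permutation_test(X, Y, np.zeros(30), n_perm=49, rng=rng)
        assert np.all(res.p_values >= 1 / 50) and np.all(res.p_values <= 1.0)
        assert res.null_S.shape == (49, 3)

    def test_invariant_to_site_relabeling(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        X, Y = self._frames(np.random.default_rng(1))
        sites = np.array([0, 1] * 15)
        relabeled = np.array(["x", "y"] * 15)
        r1 = permutation_test(X, Y, sites, n_perm=50, rng=rng1)
        r2 = permutation_test(X, Y, relabeled, n_perm=50, rng=rng2)
        np.testing.assert_allclose(r1.p_values, r2.p_values)

    def test_rejects_zero_permutations(self, rng):
        X, Y = self._frames(rng)
        with pytest.raises(ValueError):
            permutation_test(X, Y, np.zeros(30), n_perm=0)


class TestBlockAverage:
    def test_constant_edges_give_constant_blocks(self, toy_parcellation):
        vals = np.full(toy_parcellation.n_edges, 3.25)
        blocks = block_average_fc(vals, toy_parcellation)
        present = blocks.dropna()
        np.testing.assert_allclose(present.to_numpy(), 3.25)

    def test_block_count_for_18_networks(self):
        from bbpls.inference import block_labels

        assert len(block_labels(18)) == 171

    def test_matches_hand_enumeration(self, toy_parcellation):
        # parcels A,B in net1; C,D in net2; S in net3.  Edge order is
        # row-major lower triangle: BA, CA, CB, DA, DB, DC, SA, SB, SC, SD
        vals = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        blocks = block_average_fc(vals, toy_parcellation)
        assert blocks["net01-net01"] == pytest.approx(1.0)  # BA
        assert blocks["net01-net02"] == pytest.approx((2 + 3 + 4 + 5) / 4)
        assert blocks["net02-net02"] == pytest.approx(6.0)  # DC
        assert blocks["net01-net03"] == pytest.approx((7 + 8) / 2)
        assert blocks["net02-net03"] == pytest.approx((9 + 10) / 2)
        assert np.isnan(blocks["net03-net03"])  # single subcortical parcel

    def test_rejects_wrong_edge_count(self, toy_parcellation):
        with pytest.raises(ValueError, match="edge values"):
            block_average_fc(np.zeros(3), toy_parcellation)


class TestFdrBH:
    def test_step_up_rule_small_case(self):
        # direct step-up oracle: p=(0.01, 0.5) at q=0.05 rejects only the first
        mask = fdr_bh(np.array([0.01, 0.5]), 0.05)
        np.testing.assert_array_equal(mask, [True, False])

    def test_all_ones_rejects_none(self):
        assert not fdr_bh(np.ones(10), 0.05).any()

    def test_uniform_strong_signal_rejects_all(self):
        assert fdr_bh(np.full(10, 0.001), 0.05).all()

    def test_empty_input(self):
        assert fdr_bh(np.array([]), 0.05).shape == (0,)

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_direct_step_up_oracle(self, ps):
        p = np.array(ps)
        order = np.argsort(p)
        m = len(p)
        thresh = 0.05 * (np.arange(1, m + 1)) / m
        passed = np.flatnonzero(p[order] <= thresh)
        expected = np.zeros(m, bool)
        if len(passed):
            expected[order[: passed[-1] + 1]] = True
        np.testing.assert_array_equal(fdr_bh(p, 0.05), expected)


class TestBootstrapLoadings:
    def _fit(self, rng, n=60, sites=None):
        sites = np.zeros(n) if sites is None else sites
        z = rng.standard_normal(n)
        feats = pd.DataFrame(
            {
                "strong": z + 0.05 * rng.standard_normal(n),
                "noise": rng.standard_normal(n),
            },
            index=range(n),
        )
        Y = zscore_columns(
            pd.DataFrame(
                {"i1": z + 0.1 * rng.standard_normal(n), "i2": rng.standard_normal(n)},
                index=range(n),
            )
        )
        X = zscore_columns(feats)
        model = fit_pls(X, Y)
        compute_loadings(model, {"mod": feats}, Y)
        return X, Y, model, feats, sites

    def test_strong_feature_gets_large_z(self, rng):
        X, Y, model, feats, sites = self._fit(rng)
        res = bootstrap_loadings(
            X, Y, model, {"mod": feats}, sites, n_boot=100, n_components=1, rng=rng
        )
        z = res.z_scores["mod"]
        assert abs(z.loc["strong"].iloc[0]) > abs(z.loc["noise"].iloc[0])
        assert abs(z.loc["strong"].iloc[0]) > 5

    def test_minimal_n_boot_gives_finite_sd(self, rng):
        X, Y, model, feats, sites = self._fit(rng)
        res = bootstrap_loadings(
            X, Y, model, {"mod": feats}, sites, n_boot=2, n_components=1, rng=rng
        )
        assert np.all(np.isfinite(res.loading_sd["mod"].to_numpy()))

    def test_fc_loadings_reported_at_block_level(self, small_cohort, small_fit):
        rng = np.random.default_rng(3)
        fit = small_fit
        res = bootstrap_loadings(
            fit["X"],
            fit["Y"],
            fit["model"],
            {"rest_fc": fit["resid"]["rest_fc"], "behavior": fit["Y_resid"]},
            fit["cohort"]["site"].to_numpy(),
            parcellation=small_cohort.parcellation,
            n_boot=30,
            n_components=3,
            rng=rng,
        )
        assert res.z_scores["rest_fc"].shape == (171, 3)
        assert res.z_scores["behavior"].shape[0] == fit["Y_resid"].shape[1]

    def test_planted_top_blocks_significant(self, small_cohort, small_fit):
        """Blocks carrying the strongest planted edge loadings survive FDR."""
        rng = np.random.default_rng(4)
        fit = small_fit
        parc = small_cohort.parcellation
        res = bootstrap_loadings(
            fit["X"],
            fit["Y"],
            fit["model"],
            {"rest_fc": fit["resid"]["rest_fc"]},
            fit["cohort"]["site"].to_numpy(),
            parcellation=parc,
            n_boot=100,
            n_components=1,
            rng=rng,
        )
        truth_blocks = block_average_fc(
            small_cohort.truth.edge_loadings[:, 0], parc
        ).abs()
        top = truth_blocks.nlargest(3).index
        mask = res.fdr_mask["rest_fc"].iloc[:, 0]
        assert mask.loc[top].all()
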