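import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hypomod.qc as qc
import hypomod.synthetic as syn
import hypomod.wgcna as wg
from tests.conftest import block_expression, modular_expression, module_chain_config


class TestSignedAdjacency:
    def test_closed_forms(self):
        # perfectly correlated -> 1; anticorrelated -> 0; independent at
        # power 6 -> 0.5^6
        x = np.linspace(0, 1, 50)
        expr = np.column_stack([x, 2 * x + 1, -x])
        adj = wg.signed_adjacency(expr, power=6)
        assert adj[0, 1] == pytest.approx(1.0)
        assert adj[0, 2] == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(0)
        a = rng.normal(size=100000)
        b = rng.normal(size=100000)
        adj2 = wg.signed_adjacency(np.column_stack([a, b]), power=6)
        assert adj2[0, 1] == pytest.approx(0.5 ** 6, rel=0.05)

    def test_monotone_decreasing_in_power_below_perfect_correlation(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(60, 10))
        prev = wg.signed_adjacency(expr, 1)
        for p in (2, 4, 8):
            cur = wg.signed_adjacency(expr, p)
            off = ~np.eye(10, dtype=bool)
            assert (cur[off] <= prev[off] + 1e-12).all()
            prev = cur

    def test_zero_variance_gene_warns_and_gets_half_base(self):
        expr = np.column_stack([np.ones(30), np.random.default_rng(2).normal(size=30)])
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = wg.signed_adjacency(expr, power=2)
        assert adj[0, 1] == pytest.approx(0.25)


class TestTopologicalOverlap:
    @staticmethod
    def _brute_force_tom(A):
        n = A.shape[0]
        A0 = A.copy()
        np.fill_diagonal(A0, 0.0)
        k = A0.sum(axis=1)
        tom = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(A0[i, u] * A0[u, j] for u in range(n))
                tom[i, j] = (shared + A0[i, j]) / (min(k[i], k[j]) + 1 - A0[i, j])
        return tom

    def test_matches_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            M = rng.random((20, 20))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 1.0)
            tom, dissim = wg.topological_overlap(A)
            np.testing.assert_allclose(tom, self._brute_force_tom(A), atol=1e-12)
            assert (tom >= 0).all() and (tom <= 1).all()
            np.testing.assert_allclose(dissim, 1 - tom, atol=1e-15)

    def test_two_gene_network_formula(self):
        # no shared neighbors: numerator a_12, denominator min(k)+1-a_12 =
        # a_12+1-a_12 = 1, so TOM_12 equals the adjacency itself
        x = 0.37
        A = np.array([[1.0, x], [x, 1.0]])
        tom, _ = wg.topological_overlap(A)
        assert tom[0, 1] == pytest.approx(x, abs=1e-12)

    def test_identical_fully_connected_rows_saturate(self):
        A = np.ones((4, 4))
        tom, _ = wg.topological_overlap(A)
        np.testing.assert_allclose(tom, 1.0)

    def test_asymmetric_input_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            wg.topological_overlap(A)


class TestSoftThreshold:
    def test_modular_expression_reaches_scale_free_fit_at_low_power(self):
        rep = wg.pick_soft_threshold(modular_expression(3))
        assert rep.reached_fit
        assert rep.chosen <= 12
        assert rep.r_squared[rep.chosen - 1] >= 0.8

    def test_pure_noise_needs_a_high_power(self):
        # without planted structure no low power approximates scale-free
        # topology; the qualifying power (or fallback) is far up the range
        rng = np.random.default_rng(4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = wg.pick_soft_threshold(rng.normal(size=(200, 100)))
        assert rep.chosen > 12

    def test_mean_connectivity_nonincreasing_in_power(self):
        rep = wg.pick_soft_threshold(modular_expression(5))
        assert (np.diff(rep.mean_connectivity) <= 1e-9).all()

    def test_high_connectivity_powers_discarded(self):
        rep = wg.pick_soft_threshold(modular_expression(6))
        cutoff = np.percentile(rep.mean_connectivity, 95)
        assert (rep.mean_connectivity[rep.discarded] >= cutoff).all()
        assert not rep.discarded[rep.chosen - 1]

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            wg.pick_soft_threshold(np.random.default_rng(0).normal(size=(10, 100)))


class TestCutModules:
    def _dissim(self, expr, power=None):
        if power is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                power = wg.pick_soft_threshold(expr).chosen
        adj = wg.signed_adjacency(expr, power)
        _, dissim = wg.topological_overlap(adj)
        return dissim

    def test_two_planted_blocks_recovered_exactly(self):
        expr = block_expression(2, 150, [50, 50], 0)
        assign = wg.cut_modules(self._dissim(expr, power=6),
                                [f"g{i}" for i in range(100)])
        mods = assign.to_numpy()
        assert len(set(mods)) == 2 and wg.GREY not in set(mods)
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat([0, 1], 50)
        assert adjusted_rand_score(truth, mods) >= 0.95

    def test_minimum_size_enforced_and_small_block_greyed(self):
        expr = block_expression(1, 200, [14, 20, 50], 216)
        assign = wg.cut_modules(self._dissim(expr),
                                [f"g{i}" for i in range(300)], min_size=15)
        sizes = assign[assign != wg.GREY].value_counts()
        assert (sizes >= 15).all()
        # the 14-gene block cannot form a module
        assert (assign.iloc[:14] == wg.GREY).all()
        # the viable blocks each map to one module
        assert assign.iloc[14:34].nunique() == 1 and assign.iloc[14] != wg.GREY
        assert assign.iloc[34:84].nunique() == 1 and assign.iloc[34] != wg.GREY

    def test_deeper_split_never_yields_fewer_modules(self):
        expr = block_expression(7, 200, [50, 50, 40], 160)
        dissim = self._dissim(expr)
        gids = [f"g{i}" for i in range(300)]
        n2 = wg.cut_modules(dissim, gids, deep_split=2).nunique()
        n4 = wg.cut_modules(dissim, gids, deep_split=4).nunique()
        assert n4 >= n2

    def test_unknown_deep_split_rejected(self):
        with pytest.raises(ValueError):
            wg.cut_modules(np.zeros((4, 4)), list("abcd"), deep_split=3)


class TestEigengenes:
    def test_perfectly_correlated_module_matches_member(self):
        x = np.random.default_rng(8).normal(size=80)
        expr = np.column_stack([x, 2 * x, 3 * x + 1])
        assign = pd.Series(["M1"] * 3, index=["a", "b", "c"])
        eig = wg.module_eigengenes(expr, assign)
        assert abs(np.corrcoef(eig["M1"], x)[0, 1]) == pytest.approx(1.0)

    def test_orientation_positive_against_mean_expression(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(size=(100, 6))
        assign = pd.Series(["M1"] * 3 + ["M2"] * 3, index=list("abcdef"))
        eig = wg.module_eigengenes(expr, assign)
        for m, cols in (("M1", [0, 1, 2]), ("M2", [3, 4, 5])):
            sub = expr[:, cols]
            z = (sub - sub.mean(0)) / sub.std(0)
            assert np.corrcoef(eig[m], z.mean(axis=1))[0, 1] >= 0

    def test_unit_norm_columns(self):
        rng = np.random.default_rng(10)
        expr = rng.normal(size=(50, 4))
        assign = pd.Series(["M1"] * 4, index=list("abcd"))
        eig = wg.module_eigengenes(expr, assign)
        assert np.linalg.norm(eig["M1"]) == pytest.approx(1.0)

    def test_planted_factor_module_pc1_dominates(self):
        rng = np.random.default_rng(11)
        f = rng.normal(size=200)
        expr = 0.8 * f[:, None] + 0.6 * rng.normal(size=(200, 20))
        assign = pd.Series(["M1"] * 20, index=[f"g{i}" for i in range(20)])
        eig = wg.module_eigengenes(expr, assign)
        z = (expr - expr.mean(0)) / expr.std(0)
        total = (z ** 2).sum()
        explained = ((z.T @ eig["M1"].to_numpy()) ** 2).sum()
        assert explained / total >= 0.5

    def test_grey_only_assignment_rejected(self):
        expr = np.random.default_rng(12).normal(size=(30, 2))
        assign = pd.Series([wg.GREY, wg.GREY], index=["a", "b"])
        with pytest.raises(ValueError):
            wg.module_eigengenes(expr, assign)


class TestMergeModules:
    @staticmethod
    def _pair_with_correlation(target, n=500, seed=10):
        """Two 2-gene modules whose eigengenes have exactly the target
        correlation (via Gram-Schmidt construction)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        x = (x - x.mean())
        x /= np.linalg.norm(x)
        e = rng.normal(size=n)
        e -= e.mean()
        e -= (e @ x) * x
        e /= np.linalg.norm(e)
        y = target * x + np.sqrt(1 - target ** 2) * e
        expr = np.column_stack([x, x, y, y])
        assign = pd.Series(["A", "A", "B", "B"], index=["g0", "g1", "g2", "g3"])
        return expr, assign

    @pytest.mark.parametrize(
        "cor,merged", [(0.75, False), (0.79, False), (0.80, True),
                       (0.81, True), (0.85, True)]
    )
    def test_merge_boundary_at_correlation_point_eight(self, cor, merged):
        expr, assign = self._pair_with_correlation(cor)
        _, eig, _ = wg.merge_modules(expr, assign, cut_height=0.2)
        assert (len(eig.columns) == 1) == merged

    def test_zero_cut_height_merges_only_perfect_pairs(self):
        expr, assign = self._pair_with_correlation(0.999)
        _, eig, _ = wg.merge_modules(expr, assign, cut_height=0.0)
        assert len(eig.columns) == 2
        expr2, assign2 = self._pair_with_correlation(1.0)
        _, eig2, _ = wg.merge_modules(expr2, assign2, cut_height=0.0)
        assert len(eig2.columns) == 1

    def test_merge_history_records_pairs(self):
        expr, assign = self._pair_with_correlation(0.9)
        merged, _, history = wg.merge_modules(expr, assign, cut_height=0.2)
        assert len(history) == 1
        assert merged.nunique() == 1


class TestKME:
    def test_matches_bruteforce_on_toy(self):
        rng = np.random.default_rng(13)
        expr = rng.normal(size=(40, 5))
        assign = pd.Series(["M1", "M1", "M1", "M2", "M2"],
                           index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            wg.module_eigengenes(expr, pd.Series([wg.GREY] * 5, index=assign.index))
        eig = wg.module_eigengenes(expr, assign)
        kme = wg.compute_kme(expr, eig, assign.index)
        for g in range(5):
            for m in eig.columns:
                expected = stats.pearsonr(expr[:, g], eig[m]).statistic
                assert kme.iloc[g][m] == pytest.approx(expected, abs=1e-10)

    def test_member_genes_have_highest_own_module_kme(self):
        rng = np.random.default_rng(14)
        f1, f2 = rng.normal(size=(2, 300))
        expr = np.column_stack(
            [0.9 * f1[:, None] + 0.4 * rng.normal(size=(300, 10)),
             0.9 * f2[:, None] + 0.4 * rng.normal(size=(300, 10))]
        )
        assign = pd.Series(["M1"] * 10 + ["M2"] * 10,
                           index=[f"g{i}" for i in range(20)])
        eig = wg.module_eigengenes(expr, assign)
        kme = wg.compute_kme(expr, eig, assign.index)
        own = [kme.iloc[i][assign.iloc[i]] for i in range(20)]
        other = [kme.iloc[i][[m for m in eig.columns if m != assign.iloc[i]][0]]
                 for i in range(20)]
        assert (np.array(own) > np.array(other)).all()

    def test_zero_variance_gene_gets_zero_kme(self):
        rng = np.random.default_rng(15)
        expr = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        assign = pd.Series(["M1"] * 3, index=["a", "b", "c"])
        eig = wg.module_eigengenes(expr, assign)
        with pytest.warns(UserWarning, match="zero-variance"):
            kme = wg.compute_kme(expr, eig, assign.index)
        assert kme.iloc[0]["M1"] == 0.0


class TestModuleTraitLMM:
    @staticmethod
    def _sim(rng, n_arm=3, cells=50, beta=0.0, sample_sd=0.3):
        ys, gs, ss = [], [], []
        for i, g in enumerate(["treated"] * n_arm + ["control"] * n_arm):
            b = rng.normal(0, sample_sd)
            ys.append(b + (beta if g == "treated" else 0.0)
                      + rng.normal(0, 1.0, cells))
            gs += [g] * cells
            ss += [f"s{i}"] * cells
        return (np.concatenate(ys), np.array(gs, dtype=object),
                np.array(ss, dtype=object))

    def test_planted_treatment_shift_recovered(self):
        rng = np.random.default_rng(16)
        betas = []
        for _ in range(30):
            y, g, s = self._sim(rng, beta=0.8, sample_sd=0.1)
            b, se, p = wg.module_trait_lmm(y, g, s)
            betas.append(b)
        assert np.mean(betas) == pytest.approx(0.8, rel=0.25)

    def test_null_p_values_uniform_under_sample_permutation(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(200):
            y, g, s = self._sim(rng, beta=0.0)
            uniq = np.unique(s)
            perm = dict(zip(uniq, rng.permutation(
                ["treated"] * 3 + ["control"] * 3)))
            gp = np.array([perm[x] for x in s], dtype=object)
            b, se, p = wg.module_trait_lmm(y, gp, s)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_no_between_sample_variance_reduces_to_group_mean_difference(self):
        # balanced design, no sample effect: beta equals the raw difference
        rng = np.random.default_rng(18)
        y, g, s = self._sim(rng, beta=0.5, sample_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b, se, p = wg.module_trait_lmm(y, g, s)
        diff = y[g == "treated"].mean() - y[g == "control"].mean()
        assert b == pytest.approx(diff, abs=1e-6)

    def test_single_sample_arm_rejected(self):
        y = np.random.default_rng(19).normal(size=20)
        g = np.array(["treated"] * 10 + ["control"] * 10, dtype=object)
        s = np.array(["s1"] * 10 + ["s2"] * 5 + ["s3"] * 5, dtype=object)
        with pytest.raises(ValueError):
            wg.module_trait_lmm(y, g, s)

    def test_fdr_corrected_across_modules(self):
        rng = np.random.default_rng(20)
        y, g, s = self._sim(rng, beta=1.0, sample_sd=0.1)
        eig = pd.DataFrame({"M1": y, "M2": rng.normal(size=len(y))})
        out = wg.module_trait_table(eig, g, s)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            out["fdr"], multipletests(out["p"], method="fdr_bh")[1]
        )


class TestModuleOverlap:
    def test_identical_modules_are_vanishingly_unlikely_by_chance(self):
        genes = [f"g{i}" for i in range(1000)]
        a = pd.Series(wg.GREY, index=genes, dtype=object)
        a.iloc[:15] = "M1"
        out = wg.module_overlap_hypergeom(a, a.copy(), genes)
        assert out["p"].iloc[0] < 1e-20

    def test_disjoint_modules_give_p_one(self):
        genes = [f"g{i}" for i in range(100)]
        a = pd.Series(wg.GREY, index=genes, dtype=object)
        b = a.copy()
        a.iloc[:15] = "M1"
        b.iloc[15:30] = "M1"
        out = wg.module_overlap_hypergeom(a, b, genes)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_on_twelve_gene_universe(self):
        from itertools import combinations

        genes = [f"g{i}" for i in range(12)]
        a = pd.Series(wg.GREY, index=genes, dtype=object)
        b = a.copy()
        a.iloc[:5] = "A1"
        b.iloc[3:9] = "B1"
        out = wg.module_overlap_hypergeom(a, b, genes)
        observed_overlap = 2  # genes 3, 4
        count = 0
        total = 0
        for pick in combinations(range(12), 6):
            total += 1
            if len(set(pick) & set(range(5))) >= observed_overlap:
                count += 1
        assert out["p"].iloc[0] == pytest.approx(count / total, abs=1e-12)

    def test_empty_universe_rejected(self):
        a = pd.Series(["M1"], index=["g0"])
        with pytest.raises(ValueError):
            wg.module_overlap_hypergeom(a, a, [])


class TestEndToEndModuleChain:
    def test_responsive_module_flagged_exactly(self):
        hits = 0
        for rep in range(5):
            cfg = module_chain_config(3000 + rep)
            cm, _ = syn.simulate_dataset(cfg)
            norm = qc.normalize_log(cm)
            expr = norm.T
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                power = wg.pick_soft_threshold(expr).chosen
                adj = wg.signed_adjacency(expr, power)
                _, dissim = wg.topological_overlap(adj)
                assign = wg.cut_modules(dissim, cm.gene_ids)
                assign, eig, _ = wg.merge_modules(expr, assign,
                                                  cell_ids=cm.cell_ids)
                trait = wg.module_trait_table(
                    eig, cm.cell_meta["group"].to_numpy(),
                    cm.cell_meta["sample_id"].to_numpy())
            responsive = set(cfg.gene_ids()[30:60])
            overlap = {m: len(responsive & set(assign.index[assign == m]))
                       for m in eig.columns}
            target = max(overlap, key=overlap.get)
            sig = trait[(trait["fdr"] < 0.05) & (trait["beta"].abs() > 0.005)]
            hits += (target in sig.index) and len(sig) == 1
        assert hits == 5
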