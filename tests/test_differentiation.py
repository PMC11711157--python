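"""F_ST/Rho arithmetic, pairwise matrices, locus-wise F_ST, private
alleles, AMOVA behaviour and neighbor-joining recovery."""

import numpy as np
import pytest

import tetrahap as th
from tetrahap.madc_io import PopulationAssignment
from tests.conftest import hwe_genotypes, make_genotypes


class TestFstRhoArithmetic:
    @pytest.mark.parametrize(
        "ht,hs,expected", [(0.5, 0.5, 0.0), (0.5, 0.25, 0.5)]
    )
    def test_fst(self, ht, hs, expected):
        assert th.fst(ht, hs) == pytest.approx(expected)

    def test_fst_on_cohort_wide_heterozygosities(self):
        # total-cohort H_T/H_S pair on the scale alfalfa panels report
        assert th.fst(0.389, 0.379) == pytest.approx(0.0257, abs=2e-4)

    def test_fst_undefined_when_ht_zero(self):
        assert np.isnan(th.fst(0.0, 0.0))

    def test_rho_reduces_to_fst_when_ho_zero(self):
        assert th.rho(0.4, 0.3, 0.0) == pytest.approx(th.fst(0.4, 0.3))

    def test_rho_arithmetic(self):
        assert th.rho(0.4, 0.3, 0.4, k=4) == pytest.approx(1.0)

    def test_rho_zero_when_no_differentiation(self):
        for ho in (0.0, 0.2, 0.35):
            assert th.rho(0.4, 0.4, ho) == pytest.approx(0.0)

    def test_rho_at_least_fst_on_random_h_triples(self):
        rng = np.random.default_rng(30)
        checked = 0
        for _ in range(1000):
            ht = rng.uniform(0.05, 1)
            hs = rng.uniform(0, ht)
            ho = rng.uniform(0, 1)
            r, f = th.rho(ht, hs, ho), th.fst(ht, hs)
            if np.isnan(r) or ho <= 0 or hs >= ht:
                continue
            assert r >= f - 1e-12
            checked += 1
        assert checked > 500


class TestPairwiseDifferentiation:
    def test_duplicated_population_gives_zero(self):
        rng = np.random.default_rng(31)
        geno = hwe_genotypes(rng, 20, [np.array([0.6, 0.4])] * 30)
        half = {s: ("A" if i < 10 else "B") for i, s in enumerate(geno.sample_ids)}
        # make B an exact copy of A
        for i in range(10):
            geno.calls[10 + i] = geno.calls[i]
        m = th.pairwise_differentiation(geno, PopulationAssignment(half), "fst")
        assert m.values[0, 1] == 0.0

    def test_complete_fixation_gives_one(self):
        dosages_a = [[(4, 0)] * 5] * 4
        dosages_b = [[(0, 4)] * 5] * 4
        geno = make_genotypes(dosages_a + dosages_b)
        pops = PopulationAssignment(
            {s: ("A" if i < 4 else "B") for i, s in enumerate(geno.sample_ids)}
        )
        m = th.pairwise_differentiation(geno, pops, "fst")
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_matrix_symmetric_zero_diagonal_in_range(self, small_cohort, small_calls):
        _cfg, _table, pops, _truth = small_cohort
        m = th.pairwise_differentiation(small_calls, pops, "fst")
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        off = m.values[np.triu_indices(4, 1)]
        assert np.all((off >= 0) & (off <= 1))

    def test_recovers_truth_frequency_oracle(self, small_cohort, small_calls):
        _cfg, _table, pops, truth = small_cohort
        m = th.pairwise_differentiation(small_calls, pops, "fst")
        oracle = th.oracle_fst(truth)
        iu = np.triu_indices(4, 1)
        assert abs(m.values[iu].mean() - oracle[iu].mean()) <= 0.02

    def test_microhap_and_snp_matrices_rank_concordant(self):
        # heterogeneous drift so pairs genuinely differ in differentiation
        from scipy.stats import spearmanr

        cfg = th.synthetic_data.small_config(
            seed=2, n_loci=200, differentiation=(0.02, 0.05, 0.12, 0.25)
        )
        table, pops, _truth = th.simulate_cohort(cfg)
        mh_g = th.iterate_frequency_prior(table, th.DosageModel(), pops)
        sn_g = th.collapse_to_target_snp(table, th.DosageModel(), pops)
        iu = np.triu_indices(4, 1)
        mh = th.pairwise_differentiation(mh_g, pops, "fst").values[iu]
        sn = th.pairwise_differentiation(sn_g, pops, "fst").values[iu]
        rho_s, _ = spearmanr(mh, sn)
        assert rho_s > 0.9

    def test_rho_exceeds_fst_on_cohort(self, small_cohort, small_calls):
        _cfg, _table, pops, _truth = small_cohort
        iu = np.triu_indices(4, 1)
        f = th.pairwise_differentiation(small_calls, pops, "fst").values[iu]
        r = th.pairwise_differentiation(small_calls, pops, "rho").values[iu]
        assert np.all(r >= f - 1e-9)


class TestLocusFst:
    def test_monomorphic_locus_zero(self):
        geno = make_genotypes([[(4, 0)], [(4, 0)], [(4, 0)], [(4, 0)]])
        pops = PopulationAssignment(
            {s: ("A" if i < 2 else "B") for i, s in enumerate(geno.sample_ids)}
        )
        df = th.locus_fst(geno, pops)
        assert df.iloc[0]["fst"] == 0.0

    def test_alternate_fixation_gives_one(self):
        geno = make_genotypes([[(4, 0)], [(4, 0)], [(0, 4)], [(0, 4)]])
        pops = PopulationAssignment(
            {s: ("A" if i < 2 else "B") for i, s in enumerate(geno.sample_ids)}
        )
        df = th.locus_fst(geno, pops)
        assert df.iloc[0]["fst"] == pytest.approx(1.0)
        assert bool(df.iloc[0]["large_effect"])

    def test_matches_hand_computation_with_divergent_population(self):
        # pops A,B,C at p(ref)=1; D at p(ref)=0.5 (all dosages (2,2))
        dosages = [[(4, 0)]] * 6 + [[(2, 2)]] * 2
        geno = make_genotypes(dosages)
        assign = {}
        for i, s in enumerate(geno.sample_ids):
            assign[s] = "ABCD"[i // 2]
        df = th.locus_fst(geno, PopulationAssignment(assign))
        # hand computation: H_S = mean(0,0,0,(8/7)*0.5) = 1/7
        # pbar = (1+1+1+0.5)/4 = 0.875 -> H_T = 1 - (0.875^2 + 0.125^2)
        hs = (8 / 7 * 0.5) / 4
        ht = 1 - (0.875**2 + 0.125**2)
        assert df.iloc[0]["fst"] == pytest.approx((ht - hs) / ht)


class TestPrivateAlleles:
    def _freqs(self, f_b=0.38):
        return {
            "A": {"L1": (np.array([1.0, 0.0]), 80)},
            "B": {"L1": (np.array([1 - f_b, f_b]), 80)},
        }

    def test_exclusive_high_frequency_allele_is_private(self):
        df = th.private_alleles(self._freqs())
        assert len(df) == 1
        row = df.iloc[0]
        assert row["population"] == "B"
        assert row["frequency"] == pytest.approx(0.38)

    def test_below_threshold_not_private(self):
        assert th.private_alleles(self._freqs(0.04)).empty

    def test_shared_allele_not_private(self):
        freqs = {
            "A": {"L1": (np.array([0.6, 0.4]), 80)},
            "B": {"L1": (np.array([0.6, 0.4]), 80)},
        }
        assert th.private_alleles(freqs).empty


class TestAmova:
    def test_identical_populations_no_structure(self):
        rng = np.random.default_rng(32)
        geno = hwe_genotypes(rng, 20, [np.array([0.5, 0.5])] * 30)
        for i in range(10):
            geno.calls[10 + i] = geno.calls[i]
        pops = PopulationAssignment(
            {s: ("A" if i < 10 else "B") for i, s in enumerate(geno.sample_ids)}
        )
        res = th.amova(geno, pops, n_permutations=99, seed=0)
        assert res.iloc[0]["pct_var"] == 0.0
        assert res.attrs["p_value"] > 0.5

    def test_fixed_differences_give_all_variance_among(self):
        geno = make_genotypes([[(4, 0)] * 10] * 4 + [[(0, 4)] * 10] * 4)
        pops = PopulationAssignment(
            {s: ("A" if i < 4 else "B") for i, s in enumerate(geno.sample_ids)}
        )
        res = th.amova(geno, pops, n_permutations=99, seed=0)
        assert res.iloc[0]["pct_var"] == pytest.approx(100.0)

    def test_pct_var_sums_to_100_and_df_partition(self, small_cohort, small_calls):
        _cfg, _table, pops, _truth = small_cohort
        res = th.amova(small_calls, pops, n_permutations=49, seed=0)
        assert res["pct_var"].sum() == pytest.approx(100.0)
        n_units = 4 * len(small_calls.sample_ids)
        assert res["df"].sum() == n_units - 1

    def test_recovers_nominal_differentiation(self, small_cohort, small_calls):
        _cfg, _table, pops, _truth = small_cohort
        res = th.amova(small_calls, pops, n_permutations=199, seed=0)
        assert res.iloc[0]["pct_var"] == pytest.approx(10.0, abs=3.0)
        assert res.attrs["p_value"] <= 1 / 100

    def test_individual_units_land_on_rho_scale(self, small_cohort, small_calls):
        _cfg, _table, pops, _truth = small_cohort
        res = th.amova(small_calls, pops, n_permutations=9, seed=0, units="individuals")
        iu = np.triu_indices(4, 1)
        rho_all = th.pairwise_differentiation(small_calls, pops, "rho")
        # ploidy-inflated: well above the nominal F, in the Rho ballpark
        assert res.iloc[0]["pct_var"] > 100 * rho_all.values[iu].mean() * 0.5


class TestNjTree:
    def test_three_taxon_closed_form(self):
        import skbio

        m = th.differentiation.PairwiseMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float),
            "rho",
        )
        nwk = th.nj_tree(m)
        tree = skbio.TreeNode.read([nwk])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_additive_four_taxon_metric_recovered(self):
        import skbio

        # tree: ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0 + 7, 0],
            ],
            float,
        )
        d[3, 2] = 7
        m = th.differentiation.PairwiseMatrix(list("ABCD"), d, "rho")
        tree = skbio.TreeNode.read([th.nj_tree(m)])
        # neighbor pairs: (A,B) and (C,D)
        tip_dist = {
            frozenset([a, b]): tree.find(a).distance(tree.find(b))
            for a in "ABCD"
            for b in "ABCD"
            if a < b
        }
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    i, j = "ABCD".index(a), "ABCD".index(b)
                    assert tip_dist[frozenset([a, b])] == pytest.approx(d[i, j])

    def test_ultrametric_pairs_are_neighbors(self):
        import skbio

        d = np.array(
            [
                [0, 0.1, 1, 1],
                [0.1, 0, 1, 1],
                [1, 1, 0, 0.1],
                [1, 1, 0.1, 0],
            ]
        )
        m = th.differentiation.PairwiseMatrix(list("ABCD"), d, "rho")
        tree = skbio.TreeNode.read([th.nj_tree(m)])
        # in the unrooted 4-taxon tree the single internal edge must
        # separate {A,B} from {C,D}
        cherries = {
            frozenset(t.name for t in node.children)
            for node in tree.non_tips(include_self=True)
            if all(c.is_tip() for c in node.children) and len(node.children) == 2
        }
        assert cherries <= {frozenset("AB"), frozenset("CD")}
        assert cherries

    def test_fewer_than_three_taxa_rejected(self):
        m = th.differentiation.PairwiseMatrix(
            ["A", "B"], np.array([[0, 1], [1, 0]], float), "fst"
        )
        with pytest.raises(ValueError):
            th.nj_tree(m)
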