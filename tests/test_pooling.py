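"""Pool construction (merge rule, replicates) and the BAF measurement model."""

import numpy as np
import pytest

import poolgwas as pg
from poolgwas.exceptions import ConfigError, InputError
from poolgwas.pooling import REFERENCE_COMBINATION_COUNTS, combination_table


class TestCombinations:
    def test_reference_counts_tabulated_exactly(self, reference_cohort):
        combos = pg.tabulate_combinations(reference_cohort)
        assert tuple(combos["n"]) == REFERENCE_COMBINATION_COUNTS
        assert combos["n"].sum() == 1402

    def test_shares_match_printed_percentages(self):
        shares = pg.combination_shares(combination_table(REFERENCE_COMBINATION_COUNTS))["share"]
        assert round(100 * shares.iloc[0], 2) == 13.55   # 190/1402
        assert round(100 * shares.iloc[14], 2) == 12.77  # 179/1402

    def test_lexicographic_row_order(self):
        combos = combination_table(range(16))
        codes = combos[["T2D", "CO", "HTN", "DL"]].to_numpy() @ [8, 4, 2, 1]
        assert list(codes) == list(range(16))

    def test_empty_cohort_share_errors(self):
        combos = combination_table([0] * 16)
        assert (combos["n"] == 0).all()
        with pytest.raises(InputError):
            pg.combination_shares(combos)


class TestMergeRule:
    def test_reference_merge_gives_14_pools(self):
        plan = pg.merge_rare_combinations(combination_table(REFERENCE_COMBINATION_COUNTS))
        assert plan.n_pools == 14
        # rare combos 9 (Yes,No,No,Yes; n=7) and 11 (Yes,No,Yes,Yes; n=11)
        # are absorbed by the preceding same-outcome pools
        merged = {tuple(m) for m in plan.pools["merged_from"]}
        assert (8, 9) in merged   # pool 9 absorbs row 9
        assert (10, 11) in merged  # pool 10 absorbs row 11
        assert (plan.pools["n"] / 1402 >= 0.01).all()

    def test_outcome_constant_after_merge(self):
        plan = pg.merge_rare_combinations(combination_table(REFERENCE_COMBINATION_COUNTS))
        combos = combination_table(REFERENCE_COMBINATION_COUNTS)
        for _, pool in plan.pools.iterrows():
            t2d = {combos["T2D"].iloc[i] for i in pool["merged_from"]}
            assert len(t2d) == 1

    def test_no_rare_combinations_identity(self):
        plan = pg.merge_rare_combinations(combination_table([100] * 16))
        assert plan.n_pools == 16

    def test_zero_threshold_drops_only_empty(self):
        counts = list(REFERENCE_COMBINATION_COUNTS)
        counts[3] = 0
        plan = pg.merge_rare_combinations(combination_table(counts), threshold=0.0)
        assert plan.n_pools == 15

    def test_merge_idempotent(self):
        plan = pg.merge_rare_combinations(combination_table(REFERENCE_COMBINATION_COUNTS))
        counts = np.zeros(16, dtype=int)
        for _, pool in plan.pools.iterrows():
            counts[pool["merged_from"][0]] = pool["n"]
        again = pg.merge_rare_combinations(combination_table(counts))
        assert again.n_pools == plan.n_pools
        assert list(again.pools["n"]) == list(plan.pools["n"])

    def test_forward_merge_when_no_preceding_same_outcome(self):
        # make the FIRST T2D=Yes row rare: must merge forward with a warning
        counts = [300] * 8 + [5, 0, 300, 300, 300, 300, 300, 300]
        with pytest.warns(UserWarning):
            plan = pg.merge_rare_combinations(combination_table(counts))
        assert plan.n_pools == 14  # 8 control + 6 case pools (5 absorbed, 1 empty)

    def test_partition_conservation(self, reference_cohort):
        plan = pg.build_pool_plan(reference_cohort)
        assert plan.pools["n"].sum() == reference_cohort.n
        all_members = np.concatenate(list(plan.members.values()))
        assert len(all_members) == len(set(all_members)) == reference_cohort.n

    def test_fractional_covariates_of_merged_pools(self):
        plan = pg.merge_rare_combinations(combination_table(REFERENCE_COMBINATION_COUNTS))
        pool9 = plan.pools[plan.pools["merged_from"].apply(lambda m: m == (8, 9))].iloc[0]
        assert pool9["DL_prop"] == pytest.approx(7 / 29)
        assert pool9["HT_prop"] == 0.0


class TestReplicatesAndChips:
    def test_28_units_from_14_pools(self, reference_cohort):
        plan = pg.build_pool_plan(reference_cohort)
        plan = pg.replicate_and_batch(plan, n_replicates=2, n_chips=2)
        assert plan.n_pools == 14 and plan.n_units == 28

    def test_chip_not_aliased_with_replicate(self, reference_cohort):
        plan = pg.replicate_and_batch(pg.build_pool_plan(reference_cohort))
        cross = plan.units.groupby(["replicate", "chip"]).size()
        assert len(cross) == 4  # both chips appear within each replicate

    def test_single_replicate_breaks_error_estimation(self, reference_cohort, small_cohort):
        cohort, panel, geno = small_cohort
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort), n_replicates=1)
        baf = pg.measure_baf(plan, cohort, geno, seed=0)
        with pytest.raises(ConfigError, match="2 replicates"):
            pg.estimate_pooling_error(baf)

    def test_invalid_chip_count(self, reference_cohort):
        with pytest.raises(ConfigError):
            pg.replicate_and_batch(pg.build_pool_plan(reference_cohort), n_chips=0)

    def test_deterministic_layout(self, reference_cohort):
        a = pg.replicate_and_batch(pg.build_pool_plan(reference_cohort), seed=3).units
        b = pg.replicate_and_batch(pg.build_pool_plan(reference_cohort), seed=3).units
        assert a.equals(b)


class TestMeasurement:
    def test_exact_mean_with_no_noise(self, small_cohort):
        cohort, panel, geno = small_cohort
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort))
        baf = pg.measure_baf(plan, cohort, geno, dirichlet_concentration=np.inf,
                             array_sd=0.0, seed=0)
        for u, (_, unit) in enumerate(plan.units.iterrows()):
            members = plan.members[int(unit["pool_id"])]
            g = geno[cohort.index_of(members)]
            assert baf.baf[u] == pytest.approx(g.mean(axis=0) / 2.0)

    def test_three_member_pool_mean(self):
        """Genotypes {0,1,2} pooled with equal weights give BAF 0.5."""
        assert (0 + 1 + 2) / (2 * 3) == 0.5  # the arithmetic the model must hit
        cohort = pg.simulate_pedigrees(1, {"shape": "trio"}, seed=0)
        panel = pg.default_panel(1, seed=0)
        geno = np.array([[0], [1], [2]], dtype=np.int8)
        pg.assign_traits(cohort, seed=0)
        cohort.individuals[["T2D", "CO", "HTN", "DL"]] = 0  # one pool
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort, threshold=0.0))
        baf = pg.measure_baf(plan, cohort, geno, dirichlet_concentration=np.inf,
                             array_sd=0.0, seed=0)
        assert np.allclose(baf.baf, 0.5)

    def test_monomorphic_variant_clipped_at_zero(self, small_cohort):
        cohort, panel, geno = small_cohort
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort))
        zero = np.zeros_like(geno)
        baf = pg.measure_baf(plan, cohort, zero, array_sd=0.02, seed=5)
        assert (baf.baf >= 0).all()
        assert baf.baf.mean() <= 0.02

    def test_unbiased_at_interior_frequencies(self, small_cohort):
        """E[observed BAF] equals the member-mean pooled AF (Monte-Carlo)."""
        cohort, panel, geno = small_cohort
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort))
        truth = pg.measure_baf(plan, cohort, geno, dirichlet_concentration=np.inf,
                               array_sd=0.0, seed=0).baf
        reps = [pg.measure_baf(plan, cohort, geno, dirichlet_concentration=50,
                               array_sd=0.01, seed=s).baf for s in range(30)]
        interior = (truth > 0.1) & (truth < 0.9)
        bias = (np.mean(reps, axis=0) - truth)[interior]
        assert abs(bias.mean()) < 2e-3

    def test_replicate_difference_magnitude_matches_noise(self, small_cohort):
        """mean |rep1-rep2| ~ 2*sigma/sqrt(pi) when array noise dominates.

        Restricted to interior frequencies: near the [0,1] boundary the
        truncation of the additive noise shrinks replicate differences."""
        cohort, panel, geno = small_cohort
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort))
        sigma = 0.01
        truth = pg.measure_baf(plan, cohort, geno, dirichlet_concentration=np.inf,
                               array_sd=0.0, seed=2).baf
        baf = pg.measure_baf(plan, cohort, geno, dirichlet_concentration=1e9,
                             array_sd=sigma, seed=2)
        interior = ((truth > 0.1) & (truth < 0.9)).all(axis=0)
        r1 = baf.baf[baf.units["replicate"].to_numpy() == 1][:, interior]
        r2 = baf.baf[baf.units["replicate"].to_numpy() == 2][:, interior]
        expected = 2 * sigma / np.sqrt(np.pi)  # E|N(0, 2 sigma^2)|
        assert np.mean(np.abs(r1 - r2)) == pytest.approx(expected, rel=0.10)

    def test_empty_pool_errors(self, small_cohort):
        cohort, panel, geno = small_cohort
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort))
        plan.members[int(plan.pools["pool_id"].iloc[0])] = np.array([], dtype=object)
        with pytest.raises(InputError):
            pg.measure_baf(plan, cohort, geno, seed=0)


class TestPoolingError:
    def _baf(self, small_cohort, sigma, seed=0, n=None):
        """Equal-weight pools; interior allele frequencies so noise is unclipped."""
        cohort, panel, geno = small_cohort
        plan = pg.replicate_and_batch(pg.build_pool_plan(cohort))
        freq = geno.mean(axis=0) / 2.0
        geno = geno[:, (freq > 0.15) & (freq < 0.85)]
        if n is not None:
            geno = np.tile(geno, (1, int(np.ceil(n / geno.shape[1]))))[:, :n]
        return pg.measure_baf(plan, cohort, geno, dirichlet_concentration=np.inf,
                              array_sd=sigma, seed=seed)

    def test_identical_replicates_give_zero(self, small_cohort):
        baf = self._baf(small_cohort, 0.0)
        est = pg.estimate_pooling_error(baf)
        assert est["mean_signed_diff"] == 0.0
        assert est["variance_component"] == 0.0

    def test_constant_shift_sign_convention(self, small_cohort):
        baf = self._baf(small_cohort, 0.0)
        keep = (baf.baf <= 0.98).all(axis=0)  # headroom so the shift is unclipped
        baf = pg.PoolBAFMatrix(baf=baf.baf[:, keep], true_af=baf.true_af[:, keep],
                               units=baf.units, variant_ids=baf.variant_ids[keep])
        shifted = baf.baf.copy()
        rep2 = baf.units["replicate"].to_numpy() == 2
        shifted[rep2] = shifted[rep2] + 0.01
        b2 = pg.PoolBAFMatrix(baf=shifted, true_af=baf.true_af, units=baf.units,
                              variant_ids=baf.variant_ids)
        est = pg.estimate_pooling_error(b2)
        assert est["mean_signed_diff"] == pytest.approx(-0.01)  # rep1 - rep2
        assert est["variance_component"] == pytest.approx(0.0, abs=1e-12)

    def test_variance_component_recovers_sigma2(self, small_cohort):
        sigma = 0.02
        baf = self._baf(small_cohort, sigma, seed=11, n=10_000)
        est = pg.estimate_pooling_error(baf)
        assert est["variance_component"] == pytest.approx(sigma**2, rel=0.10)
        lo, hi = est["ci95"]
        assert lo < est["mean_signed_diff"] < hi


def test_baf_matrix_validates_range(small_cohort, reference_cohort):
    cohort, panel, geno = small_cohort
    plan = pg.replicate_and_batch(pg.build_pool_plan(cohort))
    baf = pg.measure_baf(plan, cohort, geno, seed=0)
    with pytest.raises(InputError):
        pg.PoolBAFMatrix(baf=baf.baf + 2.0, true_af=baf.true_af,
                         units=baf.units, variant_ids=baf.variant_ids)
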