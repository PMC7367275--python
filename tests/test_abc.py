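import numpy as np
import pandas as pd
import pytest

from geckoabc import abc, coalsim
from geckoabc.abc import STAT_NAMES, PriorSet, ReferenceTable, Retained
from geckoabc.coalsim import DemographicScenario, SimDesign, SimulatedDataset


def _dataset(seqs, seq_cl, geno=None, gen_cl=None):
    if geno is None:
        geno = np.zeros((0, 1, 2), int)
        gen_cl = np.zeros(0, int)
    return SimulatedDataset(np.asarray(geno), np.asarray(gen_cl),
                            np.asarray(seqs, dtype=np.uint8), np.asarray(seq_cl))


class TestComputeSumstats:
    def test_fixed_cluster_haplotypes(self):
        """Two clusters fixed for haplotypes at Hamming distance 3: sequence
        F_ST = 1, no private segregating sites (monomorphic within clusters),
        between-cluster differences equal the distance."""
        a = [0, 0, 0, 0]
        b = [2, 2, 2, 0]
        seqs = [a, a, a, b, b, b]
        v, mask = abc.compute_sumstats(_dataset(seqs, [0, 0, 0, 1, 1, 1]))
        idx = {n: i for i, n in enumerate(STAT_NAMES)}
        assert v[idx["mt_fst"]] == pytest.approx(1.0)
        assert v[idx["mt_between_mean"]] == pytest.approx(3.0)
        assert v[idx["mt_within_mean"]] == pytest.approx(0.0)
        assert v[idx["mt_private_S_c0"]] == 0
        assert v[idx["mt_private_S_c1"]] == 0
        assert v[idx["mt_S_pooled"]] == 3
        assert v[idx["mt_nhap_pooled"]] == 2

    def test_identical_clusters_give_zero_fst(self):
        a, b = [0, 1, 2, 3], [0, 1, 2, 0]
        seqs = [a] * 8 + [b] * 8 + [a] * 8 + [b] * 8
        clusters = [0] * 16 + [1] * 16
        v, _ = abc.compute_sumstats(_dataset(seqs, clusters))
        idx = {n: i for i, n in enumerate(STAT_NAMES)}
        assert v[idx["mt_between_mean"]] == pytest.approx(v[idx["mt_within_mean"]], abs=0.05)
        assert abs(v[idx["mt_fst"]]) < 0.1

    def test_monomorphic_everything_flags_degenerate(self):
        seqs = [[1, 1, 1]] * 4
        geno = np.full((4, 2, 2), 100)
        v, mask = abc.compute_sumstats(_dataset(seqs, [0, 0, 1, 1], geno, [0, 0, 1, 1]))
        idx = {n: i for i, n in enumerate(STAT_NAMES)}
        assert v[idx["mt_S_pooled"]] == 0
        assert mask[idx["mt_rarest_mean_c0"]]
        assert v[idx["ms_het_pooled"]] == 0.0

    def test_private_segregating_sites_counted_per_direction(self):
        # site 0 segregates only in cluster 0; site 1 segregates in both
        seqs = [[0, 0], [1, 2], [0, 0], [0, 2]]
        v, _ = abc.compute_sumstats(_dataset(seqs, [0, 0, 1, 1]))
        idx = {n: i for i, n in enumerate(STAT_NAMES)}
        assert v[idx["mt_private_S_c0"]] == 1
        assert v[idx["mt_private_S_c1"]] == 0


class TestPriors:
    @pytest.mark.parametrize("label", ["I", "II", "III", "IV"])
    def test_draws_respect_bounds_and_ordering(self, label, rng):
        priors = PriorSet()
        for _ in range(50):
            p = priors.draw(label, rng)
            p.validate(DemographicScenario(label))
            for name in priors.param_names(label):
                lo, hi = priors.bounds(label, name)
                assert lo <= getattr(p, name) <= hi
            if label != "IV":
                assert p.t_admix < p.t_div


class TestReferenceTable:
    def test_equal_allocation(self, rng):
        design = SimDesign((3, 3), (3, 3), 2, 60)
        table = abc.build_reference_table(PriorSet(), 8, design, rng)
        counts = pd.Series(table.scenarios).value_counts()
        assert (counts == 2).all()

    def test_fixed_seed_identical(self):
        design = SimDesign((3, 3), (3, 3), 2, 60)
        t1 = abc.build_reference_table(PriorSet(), 8, design, np.random.default_rng(5))
        t2 = abc.build_reference_table(PriorSet(), 8, design, np.random.default_rng(5))
        assert np.array_equal(t1.stats, t2.stats)
        assert t1.params.equals(t2.params)

    def test_indivisible_allocation_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            abc.build_reference_table(PriorSet(), 10, SimDesign((2, 2), (2, 2), 1, 30), rng)


def _toy_table(rng, n=400):
    stats = rng.normal(size=(n, len(STAT_NAMES)))
    scen = np.array(["I", "II", "III", "IV"] * (n // 4))
    params = pd.DataFrame({"t_div": rng.uniform(10, 60000, n)})
    return ReferenceTable(scen, params, stats, abc.robust_scale(stats))


class TestRejection:
    def test_tolerance_one_retains_all(self, rng):
        table = _toy_table(rng)
        ret = abc.abc_reject(table.stats[0], table, 1.0)
        assert len(ret.indices) == table.n

    def test_exact_row_has_rank_one_distance_zero(self, rng):
        table = _toy_table(rng)
        ret = abc.abc_reject(table.stats[17], table, 0.01)
        assert ret.indices[0] == 17
        assert ret.distances[0] == 0.0

    def test_scaling_invariance_of_ranks(self, rng):
        table = _toy_table(rng)
        obs = rng.normal(size=len(STAT_NAMES))
        ret1 = abc.abc_reject(obs, table, 0.05)
        scaled = ReferenceTable(table.scenarios, table.params, table.stats * 7.0,
                                abc.robust_scale(table.stats * 7.0))
        ret2 = abc.abc_reject(obs * 7.0, scaled, 0.05)
        assert np.array_equal(ret1.indices, ret2.indices)

    def test_masked_dimensions_dropped(self, rng):
        table = _toy_table(rng)
        obs = table.stats[3].copy()
        mask = np.zeros(len(STAT_NAMES), bool)
        mask[0] = True
        obs[0] = 1e9  # garbage in a masked dimension must not matter
        ret = abc.abc_reject(obs, table, 0.01, mask=mask)
        assert ret.indices[0] == 3

    def test_invalid_tolerance(self, rng):
        table = _toy_table(rng)
        with pytest.raises(ValueError):
            abc.abc_reject(table.stats[0], table, 0.0)


class TestModelChoice:
    def _retained(self, scenarios, rng):
        n = len(scenarios)
        return Retained(
            np.arange(n), np.sort(rng.random(n)), np.asarray(scenarios),
            pd.DataFrame({"t_div": rng.uniform(0, 1, n)}),
            rng.normal(size=(n, 4)),
        )

    def test_single_scenario_direct_posterior(self, rng):
        ret = self._retained(["IV"] * 30, rng)
        post = abc.model_choice(ret, "direct")
        assert post.probabilities == {"I": 0.0, "II": 0.0, "III": 0.0, "IV": 1.0}

    def test_equal_counts_give_quarter_each(self, rng):
        ret = self._retained(["I", "II", "III", "IV"] * 10, rng)
        post = abc.model_choice(ret, "direct")
        assert all(p == pytest.approx(0.25) for p in post.probabilities.values())

    def test_probabilities_sum_to_one(self, rng):
        ret = self._retained(list(rng.choice(["I", "II", "III", "IV"], 200)), rng)
        for method in ("direct", "logistic"):
            post = abc.model_choice(ret, method)
            assert sum(post.probabilities.values()) == pytest.approx(1.0, abs=1e-6)

    def test_logistic_falls_back_when_one_scenario(self, rng):
        ret = self._retained(["II"] * 40, rng)
        with pytest.warns(UserWarning):
            post = abc.model_choice(ret, "logistic")
        assert post.method == "direct"

    def test_logistic_recovers_separable_labels(self, rng):
        # scenario label determined by the sign of the first stat difference;
        # observed (at 0) sits on the decision boundary
        n = 300
        x = rng.normal(size=(n, 3))
        labels = np.where(x[:, 0] > 0, "I", "IV")
        ret = Retained(np.arange(n), np.sort(rng.random(n)), labels,
                       pd.DataFrame({"t_div": np.ones(n)}), x)
        post = abc.model_choice(ret, "logistic")
        assert post.method == "logistic"
        assert post.probabilities["I"] == pytest.approx(0.5, abs=0.15)


class TestEstimateParameters:
    def test_uninformative_limit_recovers_prior(self, rng):
        """Zero regression signal and tolerance 1: the adjusted posterior is
        the prior sample itself."""
        priors = PriorSet()
        n = 600
        t = rng.uniform(10, 60000, n)
        ret = Retained(
            np.arange(n), np.sort(rng.random(n)), np.array(["IV"] * n),
            pd.DataFrame({
                "N1": rng.uniform(10, 4e6, n), "N2": rng.uniform(10, 4e6, n),
                "NA": rng.uniform(10, 4e6, n), "t_div": t,
                "useq": rng.uniform(1e-9, 1e-4, n), "kappa": rng.uniform(1, 30, n),
                "mu_mic_mean": rng.uniform(1e-6, 1e-2, n),
                "P_gsm": rng.uniform(0.1, 0.3, n), "sni": rng.uniform(1e-8, 1e-5, n),
            }),
            rng.normal(size=(n, 4)) * 1e-9,
        )
        est = abc.estimate_parameters(ret, priors, "IV")
        row = est.estimates.loc["t_div"]
        assert row.q025 == pytest.approx(np.quantile(t, 0.025), rel=0.25)
        assert row.q975 == pytest.approx(np.quantile(t, 0.975), rel=0.25)

    def test_linear_toy_mode_near_truth(self, rng):
        """One stat equals the parameter plus noise: the adjusted mode lands
        within a couple of noise SDs of the observed stat."""
        priors = PriorSet()
        n = 500
        t = rng.uniform(10, 60000, n)
        noise_sd = 1000.0
        stat = t + rng.normal(0, noise_sd, n)
        observed_t = 30000.0
        diffs = np.zeros((n, 2))
        diffs[:, 0] = (stat - observed_t) / 10000.0
        dist = np.abs(diffs[:, 0])
        order = np.argsort(dist)[:200]
        ret = Retained(order, dist[order], np.array(["IV"] * 200),
                       pd.DataFrame({
                           "N1": np.full(200, 1e5), "N2": np.full(200, 1e5),
                           "NA": np.full(200, 1e5), "t_div": t[order],
                           "useq": np.full(200, 1e-6), "kappa": np.full(200, 2.0),
                           "mu_mic_mean": np.full(200, 1e-4),
                           "P_gsm": np.full(200, 0.2), "sni": np.full(200, 1e-7),
                       }), diffs[order])
        est = abc.estimate_parameters(ret, priors, "IV")
        assert abs(est.estimates.loc["t_div", "mode"] - observed_t) < 2 * noise_sd

    def test_quantiles_inside_prior_bounds(self, rng):
        priors = PriorSet()
        n = 200
        ret = Retained(np.arange(n), np.sort(rng.random(n)), np.array(["IV"] * n),
                       pd.DataFrame({k: rng.uniform(*priors.bounds("IV", k), n)
                                     for k in priors.param_names("IV")}),
                       rng.normal(size=(n, 5)))
        est = abc.estimate_parameters(ret, priors, "IV")
        for name, row in est.estimates.iterrows():
            lo, hi = priors.bounds("IV", name)
            assert lo <= row.q025 <= row.q975 <= hi

    def test_too_few_rows_rejected(self, rng):
        priors = PriorSet()
        ret = Retained(np.arange(10), np.ones(10), np.array(["IV"] * 10),
                       pd.DataFrame({k: np.ones(10) for k in priors.param_names("IV")}),
                       np.ones((10, 3)))
        with pytest.raises(ValueError, match="50"):
            abc.estimate_parameters(ret, priors, "IV")


class TestPriorCheck:
    def test_simulated_row_inside_cloud(self, rng):
        table = _toy_table(rng)
        check = abc.pca_prior_check(table, table.stats[5])
        assert check.percentile < 99
        assert not check.flagged

    def test_far_outlier_flagged(self, rng):
        table = _toy_table(rng)
        obs = table.stats[0].copy()
        obs[2] += 100 * table.stats[:, 2].std()
        check = abc.pca_prior_check(table, obs)
        assert check.flagged

    def test_row_order_invariance(self, rng):
        table = _toy_table(rng)
        perm = rng.permutation(table.n)
        shuffled = ReferenceTable(table.scenarios[perm], table.params.iloc[perm],
                                  table.stats[perm], table.mad)
        obs = rng.normal(size=len(STAT_NAMES))
        c1 = abc.pca_prior_check(table, obs)
        c2 = abc.pca_prior_check(shuffled, obs)
        assert c1.percentile == pytest.approx(c2.percentile, abs=1e-6)

    def test_constant_column_dropped(self, rng):
        table = _toy_table(rng)
        table.stats[:, 7] = 3.14
        check = abc.pca_prior_check(table, table.stats[1])
        assert STAT_NAMES[7] in check.dropped_stats
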