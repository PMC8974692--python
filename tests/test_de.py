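"""Normality gating, omnibus tests, two-stage FDR and the DE pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection_twostage

from gwas2genes.de import (
    DegenerateVarianceError,
    ExpressionDataset,
    InsufficientDataError,
    KRUSKAL_WALLIS,
    WELCH_ANOVA,
    bky_two_stage,
    kruskal_wallis,
    normality_gate,
    run_de,
    welch_anova,
)
from gwas2genes.io import ValidationError
from gwas2genes.simulate import SimulationConfig, gen_expression


class TestNormalityGate:
    def test_all_normal_groups_take_the_welch_path(self, rng):
        groups = {g: rng.normal(0, 1, 50) for g in "abc"}
        assert normality_gate(groups) == WELCH_ANOVA

    def test_one_skewed_group_forces_kruskal(self, rng):
        groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50), "c": rng.exponential(1, 50)}
        assert normality_gate(groups) == KRUSKAL_WALLIS

    def test_constant_group_is_degenerate_hence_kruskal(self, rng):
        groups = {"a": rng.normal(0, 1, 20), "b": np.full(20, 5.0)}
        assert normality_gate(groups) == KRUSKAL_WALLIS

    def test_tiny_group_is_an_error(self, rng):
        with pytest.raises(InsufficientDataError):
            normality_gate({"a": [1.0, 2.0], "b": rng.normal(0, 1, 10)})


class TestKruskalWallis:
    def test_hand_computed_two_group_instance(self):
        # 12/(n(n+1)) * sum R_i^2/n_i - 3(n+1) with rank sums 6 and 15
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7)
        assert p == pytest.approx(stats.chi2.sf(27 / 7, 1))

    def test_identical_values_yield_zero_statistic_unit_p(self):
        assert kruskal_wallis([[5, 5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_chi_square_p_tracks_permutation_oracle_on_small_groups(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(0, 1, 5), rng.normal(0.8, 1, 5), rng.normal(0.3, 1, 5)]
        h, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = pooled.size
        n_perm = 100_000
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        permuted = ranks[perm]
        rank_sq = (
            permuted[:, :5].sum(axis=1) ** 2
            + permuted[:, 5:10].sum(axis=1) ** 2
            + permuted[:, 10:].sum(axis=1) ** 2
        ) / 5
        h_perm = 12.0 / (n * (n + 1)) * rank_sq - 3 * (n + 1)
        p_perm = float((h_perm >= h - 1e-9).mean())
        # chi-square reference carries its own approximation error at n=5/group
        assert p_chi2 == pytest.approx(p_perm, abs=0.02)

    def test_invariant_under_strictly_monotone_transform(self, rng):
        groups = [rng.normal(0, 1, 8), rng.normal(1, 2, 12), rng.normal(-1, 1, 6)]
        h, p = kruskal_wallis(groups)
        transformed = [np.exp(g) for g in groups]  # strictly increasing map
        h_t, p_t = kruskal_wallis(transformed)
        assert (h_t, p_t) == pytest.approx((h, p))

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])


class TestWelchAnova:
    def test_two_groups_equal_squared_welch_t(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, int(rng.integers(4, 25)))
            b = rng.normal(0.5, 2, int(rng.integers(4, 25)))
            f, df1, df2, p = welch_anova([a, b])
            t = stats.ttest_ind(a, b, equal_var=False)
            assert f == pytest.approx(t.statistic**2)
            assert df2 == pytest.approx(t.df)
            assert p == pytest.approx(t.pvalue)

    def test_matches_reference_implementation(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 5))
            groups = [
                rng.normal(rng.normal(0, 1), rng.uniform(0.5, 2), int(rng.integers(5, 30)))
                for _ in range(k)
            ]
            f, df1, df2, p = welch_anova(groups)
            import pingouin as pg

            frame = pd.DataFrame(
                {
                    "y": np.concatenate(groups),
                    "g": np.repeat(np.arange(k), [len(g) for g in groups]),
                }
            )
            ref = pg.welch_anova(frame, dv="y", between="g")
            assert f == pytest.approx(float(ref["F"][0]))
            assert df2 == pytest.approx(float(ref["ddof2"][0]))
            assert p == pytest.approx(float(ref["p_unc"][0]))

    def test_approaches_classic_anova_for_balanced_equal_variance(self):
        # the two statistics agree at O(n^-1/2); large balanced groups
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, 5000) for m in (0.0, 0.3, 0.6)]
        f_star, *_ = welch_anova(groups)
        f_classic = stats.f_oneway(*groups).statistic
        assert abs(f_star - f_classic) / f_classic < 0.02

    def test_shifted_to_common_mean_gives_near_zero_statistic(self, rng):
        groups = [rng.normal(m, 1, 30) for m in (0.0, 1.0, 2.0)]
        centred = [g - g.mean() for g in groups]
        f, _, _, p = welch_anova(centred)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(11)
        pvals = np.empty(5000)
        for i in range(5000):
            groups = [rng.normal(0, s, 12) for s in (1.0, 1.5, 2.0)]
            *_, pvals[i] = welch_anova(groups)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_group_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])


class TestBkyTwoStage:
    def test_all_unit_p_values_reject_nothing(self):
        rejected, q_adj = bky_two_stage([1.0] * 20)
        assert not rejected.any()
        assert np.all(q_adj == 1.0)

    def test_single_small_p_rejected_at_stage_one_level(self):
        # q' = 0.05/1.05 ~ 0.0476 > 0.001
        rejected, _ = bky_two_stage([0.001])
        assert rejected.all()

    def test_matches_reference_two_stage_procedure(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 80))
            p = rng.uniform(0, 1, m) ** float(rng.uniform(0.3, 3))
            rejected, q_adj = bky_two_stage(p, 0.05)
            ref_rej, ref_q, _, _ = fdrcorrection_twostage(
                p, alpha=0.05, method="bky", maxiter=1
            )
            assert np.array_equal(rejected, ref_rej)
            assert q_adj == pytest.approx(ref_q)

    def test_rejects_superset_of_stage_one_and_monotone_in_q(self, rng):
        p = np.concatenate([rng.uniform(0, 1, 60), rng.beta(0.1, 1, 40)])
        q = 0.05
        rejected, _ = bky_two_stage(p, q)
        # stage 1 alone: plain BH at the shrunk level q/(1+q)
        from statsmodels.stats.multitest import multipletests

        stage1 = multipletests(p, alpha=q / (1 + q), method="fdr_bh")[0]
        assert np.all(rejected[stage1])
        counts = [bky_two_stage(p, qq)[0].sum() for qq in (0.01, 0.02, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_q_adjusted_values_decide_rejection_at_nominal_level(self, rng):
        p = rng.uniform(0, 1, 50) ** 2
        rejected, q_adj = bky_two_stage(p, 0.05)
        assert np.array_equal(rejected, q_adj <= 0.05)
        assert np.all((q_adj >= 0) & (q_adj <= 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            bky_two_stage([0.5, 1.5])
        with pytest.raises(ValidationError):
            bky_two_stage([], 0.05)
        with pytest.raises(ValidationError):
            bky_two_stage([0.5], q=1.0)


def _toy_dataset(rng, shift=0.0):
    samples = [f"s{i}" for i in range(30)]
    group = {s: ("control", "mild_moderate", "severe")[i // 10] for i, s in enumerate(samples)}
    values = rng.normal(0, 1, (1, 30))
    values[0, 10:] += shift
    return ExpressionDataset(genes=["gene1"], samples=samples, values=values, group=group)


class TestRunDe:
    def test_planted_genes_recovered_at_study_group_sizes(self):
        """100 genes, 10 planted 2-SD shifts, groups 20/50/38: all recovered."""
        dataset, planted = gen_expression(SimulationConfig(seed=0))
        results = run_de(dataset)
        significant = {r.gene for r in results if r.significant}
        assert set(planted) <= significant
        for r in results:
            if r.significant:
                assert r.pairwise  # post-hoc p-values attached to discoveries

    def test_false_discovery_proportion_controlled_over_replicates(self):
        fdps = []
        for seed in range(15):
            dataset, planted = gen_expression(SimulationConfig(seed=seed))
            results = run_de(dataset)
            significant = {r.gene for r in results if r.significant}
            fdps.append(len(significant - set(planted)) / max(len(significant), 1))
        fdps = np.asarray(fdps)
        mc_se = fdps.std(ddof=1) / np.sqrt(len(fdps))
        assert fdps.mean() <= 0.05 + 3 * mc_se

    def test_null_dataset_yields_few_discoveries(self):
        dataset, _ = gen_expression(SimulationConfig(seed=2, effect_sd_units=0.0))
        results = run_de(dataset)
        # expectation under the procedure is <= q*m = 5; allow Monte-Carlo room
        assert sum(r.significant for r in results) <= 10

    def test_single_gene_strong_effect_significant(self, rng):
        results = run_de(_toy_dataset(rng, shift=3.0))
        assert results[0].significant

    def test_force_kruskal_bypasses_gate(self, rng):
        results = run_de(_toy_dataset(rng, shift=3.0), force_kruskal=True)
        assert results[0].test_used == KRUSKAL_WALLIS


class TestExpressionDataset:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ExpressionDataset(
                genes=["g1"], samples=["s1", "s2"], values=np.zeros((1, 3)),
                group={"s1": "control", "s2": "severe"},
            )

    def test_from_frames_round_trip(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(2, 4)),
            index=["g1", "g2"],
            columns=["s1", "s2", "s3", "s4"],
        )
        sheet = pd.DataFrame(
            {"sample": ["s1", "s2", "s3", "s4"],
             "group": ["control", "control", "severe", "severe"]}
        )
        ds = ExpressionDataset.from_frames(matrix, sheet)
        assert ds.group_levels == ["control", "severe"]
        by_group = ds.values_by_group("g2")
        assert by_group["severe"] == pytest.approx(matrix.loc["g2", ["s3", "s4"]].to_numpy())
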