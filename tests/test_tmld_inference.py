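"""Double-layer EM for the tmLD mixture model and its likelihood-ratio test."""

import numpy as np
import pytest
from scipy.stats import chi2, norm

from tmld import (
    QuantParams,
    SimulationConfig,
    ThreeLocusParams,
    conditional_qtl_probs,
    e_step,
    fit_alternative,
    fit_null,
    haplotype_frequencies,
    joint_loglikelihood,
    joint_zygote_table,
    lrt_test,
    m_step_pop,
    m_step_quant,
    simulate_cohort,
)
from tmld.genotype_model import MarkerGenotype
from tmld.tmld_inference import _Workspace

from conftest import STUDY_PARAMS, random_valid_params


def brute_force_loglik(g1, g3, y, omega_p, omega_q):
    """Straight-line re-implementation of the joint likelihood."""
    table = joint_zygote_table(haplotype_frequencies(omega_p)).prob
    total = 0.0
    for gi1, gi3, yi in zip(g1, g3, y):
        row = table[3 * gi1 + gi3]
        m = row.sum()
        mix = sum((row[j] / m) * norm.pdf(yi, omega_q.mu[j], omega_q.sigma)
                  for j in range(3))
        total += np.log(m) + np.log(mix)
    return total


def toy_cohort(n=60, seed=0, h2=0.3, mu=(0, 5, 10)):
    return simulate_cohort(SimulationConfig(n=n, params=STUDY_PARAMS,
                                            mu=mu, h2=h2, seed=seed))


class TestJointLoglikelihood:
    def test_matches_brute_force_on_toy(self):
        g1 = np.array([0, 1, 2, 2, 1] * 4)
        g3 = np.array([0, 1, 2, 1, 0] * 4)
        y = np.linspace(-2, 12, 20)
        oq = QuantParams(mu=(0.0, 5.0, 10.0), sigma=2.0)
        got = joint_loglikelihood(y, (g1, g3), STUDY_PARAMS, oq)
        want = brute_force_loglik(g1, g3, y, STUDY_PARAMS, oq)
        assert got == pytest.approx(want, abs=1e-9)

    def test_equal_means_collapse_to_single_normal(self):
        c = toy_cohort(n=200, seed=2)
        oq = QuantParams(mu=(1.5, 1.5, 1.5), sigma=2.0)
        ll = joint_loglikelihood(c.y, (c.g1, c.g3), STUDY_PARAMS, oq)
        table = joint_zygote_table(haplotype_frequencies(STUDY_PARAMS)).prob
        marker = np.log(table.sum(axis=1))[3 * c.g1 + c.g3].sum()
        trait = norm.logpdf(c.y, 1.5, 2.0).sum()
        assert ll == pytest.approx(marker + trait, abs=1e-8)

    def test_no_ld_trait_part_is_hwe_mixture(self):
        c = toy_cohort(n=200, seed=3)
        p0 = ThreeLocusParams(p1=0.5, p2=0.4, p3=0.5)
        oq = QuantParams(mu=(0.0, 5.0, 10.0), sigma=3.0)
        ll = joint_loglikelihood(c.y, (c.g1, c.g3), p0, oq)
        w = np.array([0.36, 0.48, 0.16])
        mix = np.log((w * np.array([norm.pdf(c.y, m, 3.0)
                                    for m in (0, 5, 10)]).T).sum(axis=1)).sum()
        marker = (np.log(0.25) * 2 + 0)  # placeholder, computed below
        table = joint_zygote_table(haplotype_frequencies(p0)).prob
        marker = np.log(table.sum(axis=1))[3 * c.g1 + c.g3].sum()
        assert ll == pytest.approx(marker + mix, abs=1e-8)

    def test_label_swap_invariance(self):
        # relabeling the QTL allele (p2 -> 1-p2, mu reversed, coupling D's
        # sign-flipped) leaves the likelihood unchanged
        c = toy_cohort(n=150, seed=4)
        oq = QuantParams(mu=(0.0, 5.0, 10.0), sigma=2.5)
        f = haplotype_frequencies(STUDY_PARAMS).freq
        from tmld import params_from_frequencies
        from tmld.ld_model import HaplotypeDistribution
        mirrored = params_from_frequencies(
            HaplotypeDistribution(f[:, ::-1, :].copy()))
        oq_m = QuantParams(mu=(10.0, 5.0, 0.0), sigma=2.5)
        a = joint_loglikelihood(c.y, (c.g1, c.g3), STUDY_PARAMS, oq)
        b = joint_loglikelihood(c.y, (c.g1, c.g3), mirrored, oq_m)
        assert a == pytest.approx(b, abs=1e-9)


class TestESte:
    def test_equal_means_posterior_equals_prior(self):
        c = toy_cohort(n=100, seed=5)
        oq = QuantParams(mu=(2.0, 2.0, 2.0), sigma=1.0)
        post = e_step(c.y, (c.g1, c.g3), STUDY_PARAMS, oq)
        table = joint_zygote_table(haplotype_frequencies(STUDY_PARAMS))
        for i in range(len(c)):
            prior = conditional_qtl_probs(
                table, MarkerGenotype(int(c.g1[i]), int(c.g3[i])))
            assert np.allclose(post[i], prior, atol=1e-12)

    def test_extreme_trait_dominates(self):
        g1 = np.array([1, 1, 0, 1, 1, 2, 1, 1, 0, 1, 1, 2])
        g3 = np.array([2, 1, 0] * 4)
        y = np.full(12, 1e3)
        oq = QuantParams(mu=(0.0, 5.0, 10.0), sigma=1.0)
        post = e_step(y, (g1, g3), STUDY_PARAMS, oq)
        assert np.allclose(post[:, 2], 1.0)

    def test_hand_computed_bayes_ratio(self):
        # subject with g=(2,2): prior (0.225625, 0.49875, 0.275625)
        g1 = np.array([2] * 11 + [0])
        g3 = np.array([2] * 11 + [0])
        y = np.array([9.0] * 12)
        oq = QuantParams(mu=(0.0, 5.0, 10.0), sigma=2.0)
        post = e_step(y, (g1, g3), STUDY_PARAMS, oq)
        prior = np.array([0.225625, 0.49875, 0.275625])
        dens = norm.pdf(9.0, np.array([0.0, 5.0, 10.0]), 2.0)
        want = prior * dens / (prior * dens).sum()
        assert np.allclose(post[0], want, atol=1e-12)

    def test_rows_sum_to_one(self):
        c = toy_cohort(n=80, seed=6)
        post = e_step(c.y, (c.g1, c.g3), STUDY_PARAMS,
                      QuantParams(mu=(0, 4, 9), sigma=3.0))
        assert np.allclose(post.sum(axis=1), 1.0)


class TestMStepQuant:
    def test_one_hot_gives_group_means(self):
        c = toy_cohort(n=300, seed=7, h2=0.4)
        post = np.zeros((len(c), 3))
        post[np.arange(len(c)), c.qtl] = 1.0
        oq = m_step_quant(c.y, post)
        for j in (0, 1, 2):
            assert oq.mu[j] == pytest.approx(np.mean(c.y[c.qtl == j]))

    def test_uniform_posterior_gives_grand_mean(self):
        c = toy_cohort(n=100, seed=8)
        post = np.full((len(c), 3), 1 / 3)
        oq = m_step_quant(c.y, post)
        assert np.allclose(oq.mu, np.mean(c.y))
        assert oq.sigma == pytest.approx(np.std(c.y))

    def test_empty_component_frozen_with_warning(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        post = np.column_stack([np.full(4, 0.5), np.full(4, 0.5), np.zeros(4)])
        prev = QuantParams(mu=(0.0, 1.0, 42.0), sigma=1.0)
        with pytest.warns(RuntimeWarning, match="empty"):
            oq = m_step_quant(y, post, prev=prev)
        assert oq.mu[2] == 42.0

    def test_quant_update_never_decreases_loglik(self):
        for seed in range(5):
            c = toy_cohort(n=120, seed=40 + seed)
            oq = QuantParams(mu=(-1.0, 3.0, 8.0), sigma=4.0)
            post = e_step(c.y, (c.g1, c.g3), STUDY_PARAMS, oq)
            before = joint_loglikelihood(c.y, (c.g1, c.g3), STUDY_PARAMS, oq)
            after = joint_loglikelihood(c.y, (c.g1, c.g3), STUDY_PARAMS,
                                        m_step_quant(c.y, post, prev=oq))
            assert after >= before - 1e-9


class TestMStepPop:
    def test_complete_data_limit_equals_counting(self):
        # homozygous-marker subjects with known QTL genotype: the inner EM
        # must reduce to direct haplotype counting
        g1 = np.array([0, 0, 2, 2, 0, 2] * 10)
        g3 = np.array([0, 2, 0, 2, 2, 0] * 10)
        qtl = np.array([0, 2, 0, 2, 0, 2] * 10)
        post = np.zeros((60, 3))
        post[np.arange(60), qtl] = 1.0
        start = ThreeLocusParams(p1=0.5, p2=0.5, p3=0.5)
        est = m_step_pop((g1, g3), post, start)
        f = haplotype_frequencies(est).freq
        # haplotypes are unambiguous: e.g. subject (0,0,qtl=0) carries two
        # copies of 000
        counts = np.zeros((2, 2, 2))
        for a, q, b in zip(g1, qtl, g3):
            counts[a // 2, q // 2, b // 2] += 2
        assert np.allclose(f, counts / counts.sum(), atol=1e-9)

    def test_full_outer_iteration_is_ascent(self):
        # generalized-EM property: E-step + both M-steps never decrease
        # the joint log-likelihood
        rng = np.random.default_rng(0)
        for trial in range(20):
            p = random_valid_params(rng)
            c = simulate_cohort(SimulationConfig(
                n=50, params=p, mu=(0, 3, 6), h2=0.3,
                seed=int(rng.integers(2 ** 31))))
            op = random_valid_params(rng)
            oq = QuantParams(mu=tuple(np.sort(rng.normal(3, 2, 3))),
                             sigma=float(rng.uniform(1, 4)))
            try:
                ll0 = joint_loglikelihood(c.y, (c.g1, c.g3), op, oq)
            except ValueError:
                continue  # start assigns zero mass to an observed class
            post = e_step(c.y, (c.g1, c.g3), op, oq)
            oq1 = m_step_quant(c.y, post, prev=oq)
            op1 = m_step_pop((c.g1, c.g3), post, op)
            ll1 = joint_loglikelihood(c.y, (c.g1, c.g3), op1, oq1)
            assert ll1 >= ll0 - 1e-8


class TestFits:
    def test_alternative_monotone_and_consistent_loglik(self):
        c = toy_cohort(n=400, seed=9, h2=0.4)
        fit = fit_alternative(c.y, (c.g1, c.g3))
        # reported loglik must equal the likelihood at the reported params
        ll = joint_loglikelihood(c.y, (c.g1, c.g3), fit.omega_p, fit.omega_q)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)
        assert np.allclose(fit.posterior.sum(axis=1), 1.0)

    def test_null_nested_in_alternative(self):
        for seed in (10, 11, 12):
            c = toy_cohort(n=300, seed=seed, h2=0.2)
            null = fit_null(c.y, (c.g1, c.g3))
            alt = fit_alternative(c.y, (c.g1, c.g3))
            assert null.loglik <= alt.loglik + 1e-6
            assert (null.omega_p.d12, null.omega_p.d23,
                    null.omega_p.d123) == (0.0, 0.0, 0.0)

    def test_null_marker_fit_matches_standalone_two_locus_em(self):
        from tmld.tmld_inference import (_marker_pair_em, _table2_from_f)
        c = toy_cohort(n=500, seed=13)
        ws = _Workspace(c.y, (c.g1, c.g3))
        f2 = _marker_pair_em(ws)
        # allele-frequency margins of the EM solution equal sample values
        assert f2[2] + f2[3] == pytest.approx(np.mean(c.g1) / 2, abs=1e-8)
        assert f2[1] + f2[3] == pytest.approx(np.mean(c.g3) / 2, abs=1e-8)
        # EM likelihood is not beaten by a 1-D grid over admissible D13
        counts = ws.n_r
        q1, q3 = np.mean(c.g1) / 2, np.mean(c.g3) / 2

        def marker_ll(d):
            f = np.array([(1 - q1) * (1 - q3) + d, (1 - q1) * q3 - d,
                          q1 * (1 - q3) - d, q1 * q3 + d])
            if np.any(f <= 0):
                return -np.inf
            tab = _table2_from_f(f).ravel()
            obs = counts > 0
            return float(counts[obs] @ np.log(tab[obs]))

        grid = np.linspace(-min(q1 * q3, (1 - q1) * (1 - q3)) + 1e-6,
                           min(q1 * (1 - q3), (1 - q1) * q3) - 1e-6, 4001)
        best_grid = max(marker_ll(d) for d in grid)
        assert marker_ll(f2[3] - q1 * q3) >= best_grid - 1e-6

    def test_monomorphic_marker_refused(self):
        y = np.random.default_rng(0).normal(size=50)
        g_mono = np.zeros(50, dtype=int)
        g_poly = np.tile([0, 1, 2, 1, 0], 10)
        with pytest.raises(ValueError, match="monomorphic"):
            fit_alternative(y, (g_mono, g_poly))
        with pytest.raises(ValueError, match="monomorphic"):
            fit_null(y, (g_poly, g_mono))

    def test_too_few_subjects_refused(self):
        with pytest.raises(ValueError):
            fit_alternative(np.zeros(5), (np.array([0, 1, 2, 1, 0]),
                                          np.array([0, 1, 2, 1, 0])))


class TestLrtTest:
    def test_df_and_pvalue_reference(self):
        c = toy_cohort(n=300, seed=14, h2=0.2)
        res = lrt_test(c.y, (c.g1, c.g3))
        assert res.df == 3
        assert res.pvalue == pytest.approx(chi2.sf(res.lrt, 3))
        assert res.lrt >= 0.0

    def test_detects_strong_association(self):
        c = toy_cohort(n=1000, seed=15, h2=0.3)
        res = lrt_test(c.y, (c.g1, c.g3))
        assert res.pvalue < 1e-4

    def test_scale_invariance_of_statistic(self):
        c = toy_cohort(n=400, seed=16, h2=0.0, mu=(0, 0, 0))
        a = lrt_test(c.y, (c.g1, c.g3))
        b = lrt_test(3.7 * c.y + 11.0, (c.g1, c.g3))
        assert a.lrt == pytest.approx(b.lrt, abs=1e-4)

    def test_null_generated_data_modest_statistic(self):
        # no-LD data: estimated couplings stay small and the statistic is
        # far from the strong-signal regime
        p0 = ThreeLocusParams(p1=0.5, p2=0.5, p3=0.5, d13=0.15)
        c = simulate_cohort(SimulationConfig(n=2000, params=p0,
                                             mu=(0, 5, 10), h2=0.3, seed=17))
        res = lrt_test(c.y, (c.g1, c.g3))
        assert res.lrt < 30.0
        assert abs(res.fit_alt.omega_p.d12) < 0.2
        assert abs(res.fit_alt.omega_p.d23) < 0.2

    def test_permutation_pvalue_reasonable(self):
        c = toy_cohort(n=200, seed=18, h2=0.0, mu=(0, 0, 0))
        res = lrt_test(c.y, (c.g1, c.g3), permutations=19)
        assert res.perm_pvalue is not None
        assert 0.05 <= res.perm_pvalue <= 1.0

    def test_serialization_record(self):
        c = toy_cohort(n=200, seed=19)
        rec = lrt_test(c.y, (c.g1, c.g3)).to_record()
        for key in ("lrt", "df", "pvalue", "alt_loglik", "null_loglik",
                    "alt_D123", "null_sigma"):
            assert key in rec
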