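"""ML rate estimation, small-sample estimators and exact tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from karyodyn.inference import (
    CountTable,
    binomial_two_sided,
    class_probabilities,
    estimate_xyy_selection,
    fisher_exact_2x2,
    fit_mle,
    likelihood_ratio_test,
    secondary_ndj_upper_bound,
    selection_coefficient,
    selection_to_frequency,
)
from karyodyn.io import load_ndj_counts
from karyodyn.karyotype import RateSet, ViabilityScheme
from karyodyn.synth import GeneratorSpec, gen_cross_counts


class TestClassProbabilities:
    def test_no_exceptional_mass_without_errors(self, designs):
        pc = class_probabilities(designs["spontaneous_sexed"], RateSet())
        assert pc["maternal_xxy_female"] == 0.0
        assert pc["paternal_null_male"] == 0.0
        assert sum(pc.values()) == pytest.approx(1.0)

    def test_de_novo_xxy_rate_among_females(self, designs, paper_rates):
        # combined maternal + paternal nondisjunction gives roughly one
        # XXY per 750-800 females at the published rates
        pc = class_probabilities(designs["spontaneous_pooled_females"],
                                 paper_rates)
        rate = pc["xxy_female"]
        assert 1 / 800 < rate < 1 / 700


class TestFitMLE:
    def test_packaged_fixture_reproduces_published_rates(self):
        table, assay_designs = load_ndj_counts()
        res = fit_mle(table, assay_designs)
        assert res.converged
        # point estimates agree with the published values at 2 s.f.
        assert round(res.estimates["mu_f"], 4) == pytest.approx(1.5e-3)
        assert round(res.estimates["mu_m"], 5) == pytest.approx(5.8e-4)
        assert round(res.estimates["lambda_f"], 4) == pytest.approx(6.3e-3)
        # lambda_m is tiny with a large SE; agree within one SE of 5.5e-5
        assert abs(res.estimates["lambda_m"] - 5.5e-5) < 3.1e-4

    def test_lrt_statistics_on_fixture(self):
        table, assay_designs = load_ndj_counts()
        full = fit_mle(table, assay_designs)
        mu_eq = fit_mle(table, assay_designs, constraints={"mu_m": "mu_f"})
        la_eq = fit_mle(table, assay_designs,
                        constraints={"lambda_m": "lambda_f"})
        chi_mu, df_mu, p_mu = likelihood_ratio_test(full, mu_eq)
        chi_la, df_la, p_la = likelihood_ratio_test(full, la_eq)
        # female-biased nondisjunction is significant, loss strongly so
        assert df_mu == df_la == 1
        assert p_mu < 0.05
        assert chi_la == pytest.approx(29.50, rel=0.05)
        assert p_la < 1e-6

    def test_parameter_recovery_on_synthetic_counts(self, designs,
                                                    paper_rates):
        spec = GeneratorSpec(seed=99, rates=paper_rates, n_offspring=2_000_000)
        t1 = gen_cross_counts(designs["spontaneous_pooled"], spec, "a1",
                              rng=101)
        t2 = gen_cross_counts(designs["spontaneous_sexed"], spec, "a2",
                              rng=102)
        res = fit_mle([t1, t2], {"a1": designs["spontaneous_pooled"],
                                 "a2": designs["spontaneous_sexed"]})
        for name in ("mu_f", "mu_m", "lambda_f", "lambda_m"):
            truth = getattr(paper_rates, name)
            se = res.se[name]
            assert np.isfinite(se)
            assert abs(res.estimates[name] - truth) < 3 * se

    def test_optimum_beats_truth_on_synthetic_data(self, designs,
                                                   paper_rates):
        spec = GeneratorSpec(seed=7, rates=paper_rates, n_offspring=100_000)
        t = gen_cross_counts(designs["spontaneous_sexed"], spec, "a", rng=7)
        res = fit_mle(t, {"a": designs["spontaneous_sexed"]})
        # log-likelihood at the MLE >= log-likelihood at the true rates
        from karyodyn.inference import _neg_loglik, _resolve_constraints
        rep, free = _resolve_constraints(None)
        counts = t.class_counts("a", designs["spontaneous_sexed"].scored_classes)
        truth = np.array([getattr(paper_rates, n) for n in free])
        ll_truth = -_neg_loglik(truth, rep, free,
                                [(designs["spontaneous_sexed"], counts)],
                                ViabilityScheme())
        assert res.loglik >= ll_truth - 1e-6

    def test_zero_exceptional_counts_hit_boundary(self, designs):
        df = pd.DataFrame([
            dict(assay_id="a", block="b", phenotype_class="regular_female",
                 count=5000),
            dict(assay_id="a", block="b", phenotype_class="regular_male",
                 count=5000),
        ])
        res = fit_mle(CountTable(df), {"a": designs["spontaneous_sexed"]})
        for name in ("mu_f", "mu_m", "lambda_f", "lambda_m"):
            assert res.estimates[name] == 0.0
            assert res.boundary[name]

    def test_wald_p_matches_z(self):
        table, assay_designs = load_ndj_counts()
        res = fit_mle(table, assay_designs)
        for name in ("mu_f", "mu_m", "lambda_f"):
            z = res.z[name]
            assert res.p[name] == pytest.approx(2 * stats.norm.sf(abs(z)),
                                                abs=1e-10)

    def test_lrt_of_model_against_itself_is_zero(self):
        table, assay_designs = load_ndj_counts()
        res = fit_mle(table, assay_designs)
        chi2, df, p = likelihood_ratio_test(res, res)
        assert chi2 == 0.0 and df == 0 and p == 1.0


class TestSecondaryNdjBound:
    def test_closed_form_at_zero_events(self):
        n = 500
        raw = secondary_ndj_upper_bound(0, n, 0.95, recovery_factor=1.0)
        assert raw == pytest.approx(1 - 0.05 ** (1 / n), rel=1e-9)

    def test_published_upper_limit_at_aggregate_sample(self):
        # zero events among ~2772 scoreable offspring, half-recovery
        # correction: upper 95% limit 2.16e-3
        assert secondary_ndj_upper_bound(0, 2772, 0.95) == pytest.approx(
            2.16e-3, abs=5e-6)

    @pytest.mark.parametrize("k,n", [(1, 200), (3, 500), (10, 1000)])
    def test_matches_beta_quantile_oracle(self, k, n):
        got = secondary_ndj_upper_bound(k, n, 0.95, recovery_factor=1.0)
        # independent oracle: numeric inversion of the binomial tail
        from scipy.optimize import brentq
        p_up = brentq(lambda p: stats.binom.cdf(k, n, p) - 0.05, 1e-9, 1 - 1e-9)
        assert got == pytest.approx(p_up, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            secondary_ndj_upper_bound(0, 0)
        with pytest.raises(ValueError):
            secondary_ndj_upper_bound(5, 4)


class TestSelectionCoefficient:
    @pytest.mark.parametrize("f,s", [(0.5, 0.0), (1 / 3, 0.5),
                                     (0.4413, 0.21)])
    def test_known_values(self, f, s):
        assert selection_coefficient(f) == pytest.approx(s, abs=5e-4)

    def test_roundtrip_identity(self):
        for f in np.linspace(0.0, 0.95, 40):
            assert selection_to_frequency(
                selection_coefficient(f)) == pytest.approx(f, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            selection_coefficient(1.0)


class TestEstimateXyySelection:
    @staticmethod
    def _vial_table(rng, n_vials=200, males_per_vial=50, s=0.2):
        w = 1.0 - s
        p = w / (1.0 + w)
        rows = []
        for v in range(n_vials):
            xyy = rng.binomial(males_per_vial, p)
            rows.append(dict(assay_id="v", block=f"v{v}",
                             phenotype_class="xyy_male", count=xyy))
            rows.append(dict(assay_id="v", block=f"v{v}",
                             phenotype_class="xy_male",
                             count=males_per_vial - xyy))
        return CountTable(pd.DataFrame(rows))

    def test_recovers_truth(self, rng):
        table = self._vial_table(rng, s=0.2)
        res = estimate_xyy_selection(table, seed=1)
        assert res["s"] == pytest.approx(0.2, abs=0.05)
        assert res["ci_s"][0] < 0.2 < res["ci_s"][1]

    def test_equal_counts_give_zero_selection(self):
        df = pd.DataFrame([
            dict(assay_id="v", block="v1", phenotype_class="xy_male",
                 count=100),
            dict(assay_id="v", block="v1", phenotype_class="xyy_male",
                 count=100),
            dict(assay_id="v", block="v2", phenotype_class="xy_male",
                 count=80),
            dict(assay_id="v", block="v2", phenotype_class="xyy_male",
                 count=80),
        ])
        res = estimate_xyy_selection(CountTable(df), seed=0)
        assert res["s"] == 0.0

    def test_single_block_has_no_interval(self):
        df = pd.DataFrame([
            dict(assay_id="v", block="v1", phenotype_class="xy_male",
                 count=90),
            dict(assay_id="v", block="v1", phenotype_class="xyy_male",
                 count=70),
        ])
        res = estimate_xyy_selection(CountTable(df), seed=0)
        assert np.isnan(res["ci_s"][0]) and np.isnan(res["ci_s"][1])

    def test_bootstrap_interval_coverage(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            table = self._vial_table(rng, n_vials=60, males_per_vial=30,
                                     s=0.2)
            res = estimate_xyy_selection(table, n_boot=400,
                                         seed=rng.integers(2**31))
            if res["ci_s"][0] <= 0.2 <= res["ci_s"][1]:
                hits += 1
        assert 0.88 * reps <= hits <= 0.995 * reps


class TestExactTests:
    def test_standing_frequency_comparison(self):
        # one detection in 158 test-cross females vs one in 75 PCR females
        assert fisher_exact_2x2([[1, 157], [1, 74]]) == pytest.approx(
            0.54, abs=5e-3)

    def test_empty_margin_convention(self):
        assert fisher_exact_2x2([[0, 10], [0, 7]]) == 1.0

    def test_fisher_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            t = rng.integers(0, 13, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            got = fisher_exact_2x2(t)
            # brute force over all tables with the same margins
            r0, r1 = t.sum(axis=1)
            c0 = t[:, 0].sum()
            n = t.sum()
            p_obs = stats.hypergeom.pmf(t[0, 0], n, r0, c0)
            total = 0.0
            for a in range(max(0, c0 - r1), min(r0, c0) + 1):
                p = stats.hypergeom.pmf(a, n, r0, c0)
                if p <= p_obs * (1 + 1e-9):
                    total += p
            assert got == pytest.approx(min(total, 1.0), rel=1e-6)

    def test_development_time_sex_ratio(self):
        # 571 XXY of 1159 females is compatible with 1:1
        assert binomial_two_sided(571, 1159, 0.5) == pytest.approx(
            0.638, abs=5e-4)

    def test_binomial_exact_center_is_one(self):
        assert binomial_two_sided(10, 20, 0.5) == pytest.approx(1.0)

    def test_binomial_matches_enumeration(self):
        for n in (5, 11, 17):
            for k in range(n + 1):
                got = binomial_two_sided(k, n, 0.3)
                pk = stats.binom.pmf(k, n, 0.3)
                expect = sum(stats.binom.pmf(j, n, 0.3)
                             for j in range(n + 1)
                             if stats.binom.pmf(j, n, 0.3) <= pk * (1 + 1e-9))
                assert got == pytest.approx(expect, rel=1e-8)
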