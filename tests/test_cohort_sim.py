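"""Simulator correctness: Mendelian bookkeeping, ascertainment, error injection."""

import math

import numpy as np
import pytest
from scipy import stats

from ibdfootprint import cohort_sim
from ibdfootprint.cohort_sim import ErrorModel, SnpSpec
from ibdfootprint.liability import LiabilityModel, sibling_recurrence_ratio


@pytest.fixture(scope="module")
def null_cohort():
    """Unlinked 2-SNP null cohort (no SNP effect)."""
    model = LiabilityModel(alpha=0.055, sib_corr=0.193)
    snps = [SnpSpec(0.5, 0.0, chrom="1"), SnpSpec(0.3, 0.0, chrom="2")]
    return cohort_sim.simulate_cohort(model, snps, 100_000, seed=101)


class TestSimulateCohort:
    def test_participation_rate_calibrated(self, null_cohort):
        part = null_cohort.participates[:, 2:]
        n = part.size
        se = math.sqrt(0.055 * 0.945 / n)
        assert abs(part.mean() - 0.055) < 3 * se

    def test_ibd_proportions_quarter_half_quarter(self, null_cohort):
        counts = np.bincount(null_cohort.ibd_state.ravel(), minlength=3)
        total = counts.sum()
        for state, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = math.sqrt(expected * (1 - expected) / total)
            assert abs(counts[state] / total - expected) < 4 * se

    def test_unlinked_snps_have_independent_ibd(self, null_cohort):
        s = null_cohort.ibd_state
        r = np.corrcoef(s[:, 0], s[:, 1])[0, 1]
        assert abs(r) < 4 / math.sqrt(s.shape[0])

    def test_founder_frequencies(self, null_cohort):
        for l, f in ((0, 0.5), (1, 0.3)):
            realized = null_cohort.haplotypes[:, :2, :, l].mean()
            se = math.sqrt(f * (1 - f) / (4 * null_cohort.n_pairs))
            assert abs(realized - f) < 4 * se

    def test_null_snp_has_no_ibd2_ibd0_difference(self, null_cohort):
        s = cohort_sim.frequency_summaries(null_cohort, 0)
        # w1 = 0: expect F_IBD2 - F_IBD0 ~ 0 within binomial error
        se = math.sqrt(0.25 / (2 * s.n_ibd2) + 0.25 / (4 * s.n_ibd0))
        assert abs(s.f_ibd2 - s.f_ibd0) < 4 * se

    def test_linkage_preserves_ibd_runs(self):
        model = LiabilityModel(alpha=0.5, sib_corr=0.2)
        snps = [SnpSpec(0.5, 0.0, map_position=i * 1.0) for i in range(50)]
        cohort = cohort_sim.simulate_cohort(model, snps, 2000, seed=5)
        # 1 cM spacing: adjacent IBD states agree far more often than unlinked (5/8)
        agree = (cohort.ibd_state[:, :-1] == cohort.ibd_state[:, 1:]).mean()
        assert agree > 0.9

    def test_excess_var_share_rejected(self):
        model = LiabilityModel(alpha=0.5, sib_corr=0.4)
        with pytest.raises(ValueError):
            cohort_sim.simulate_cohort(model, [SnpSpec(0.5, 0.6), SnpSpec(0.5, 0.5)], 10, seed=0)

    def test_transmission_symmetry_shared_parent(self, null_cohort):
        # at IBD1 loci the shared allele is paternal half the time
        sp = null_cohort.shared_parent()
        ibd1 = sp[sp > 0]
        k, n = int((ibd1 == 1).sum()), int(ibd1.size)
        p = stats.binomtest(k, n, 0.5).pvalue
        assert p > 1e-4


class TestFrequencySummaries:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_population_identity_exact(self, seed):
        model = LiabilityModel(alpha=0.3, sib_corr=0.3)
        cohort = cohort_sim.simulate_cohort(model, [SnpSpec(0.4, 0.01)], 5000, seed=seed)
        s = cohort_sim.frequency_summaries(cohort, 0)
        # (F_samp - f_pop) = (1 - alpha)(F_samp - F_nonparticipants) on realized counts
        assert s.eq_identity_residual == pytest.approx(0.0, abs=1e-14)

    def test_parent_offspring_identity_and_tnt(self):
        model = LiabilityModel(alpha=0.3, sib_corr=0.3)
        cohort = cohort_sim.simulate_cohort(
            model, [SnpSpec(0.4, 0.01)], 20000, pair_type="parent_offspring", seed=9
        )
        s = cohort_sim.frequency_summaries(cohort, 0)
        assert s.eq_identity_residual == pytest.approx(0.0, abs=1e-14)
        assert s.n_po_pairs > 0
        # positive participation effect: transmitted allele enriched
        assert s.f_t > s.f_nt

    def test_empty_stratum_is_nan_not_crash(self):
        model = LiabilityModel(alpha=0.055, sib_corr=0.0)
        cohort = cohort_sim.simulate_cohort(model, [SnpSpec(0.5)], 50, seed=2)
        s = cohort_sim.frequency_summaries(cohort, 0)
        assert s.n_both == 0 or math.isfinite(s.f_sibs)


class TestLambdaEstimate:
    def test_matches_quadrature_oracle(self):
        model = LiabilityModel(alpha=0.055, sib_corr=0.35)
        cohort = cohort_sim.simulate_cohort(model, [SnpSpec(0.5, 0.001)], 400_000, seed=17)
        lam_hat = cohort_sim.estimate_lambda_s(cohort)
        expected = sibling_recurrence_ratio(0.055, 0.35)
        n_both = int((cohort.participates[:, 2] & cohort.participates[:, 3]).sum())
        se_rel = 1 / math.sqrt(n_both)  # leading-order MC error of the ratio
        assert abs(lam_hat - expected) < 3 * expected * (se_rel + 2 / math.sqrt(0.055 * 800_000))

    def test_zero_corr_gives_one(self):
        model = LiabilityModel(alpha=0.3, sib_corr=0.0)
        cohort = cohort_sim.simulate_cohort(model, [SnpSpec(0.5)], 200_000, seed=4)
        assert cohort_sim.estimate_lambda_s(cohort) == pytest.approx(1.0, abs=0.05)


class TestFastPathConsistency:
    def test_fast_path_matches_full_simulator(self):
        """Category-sampling replicate path agrees with explicit liability draws."""
        model = LiabilityModel(alpha=0.2, sib_corr=0.3)
        snp = SnpSpec(0.4, 0.02)
        n = 150_000
        full = cohort_sim.simulate_cohort(model, [snp], n, seed=8)
        s_full = cohort_sim.frequency_summaries(full, 0)
        s_fast = cohort_sim.single_snp_summary(model, snp, n, np.random.default_rng(8))
        # same model: stratum counts and frequencies agree within MC error
        for attr, scale in [("alpha_realized", 1), ("f_samp", 1), ("f_ibd2", 1), ("f_ibd1s", 1)]:
            a, b = getattr(s_full, attr), getattr(s_fast, attr)
            assert abs(a - b) < 5 * math.sqrt(0.25 / min(s_full.n_both, s_fast.n_both) * 2), attr
        for attr in ("n_both", "n_ibd2", "n_ibd0", "n_ibd1"):
            a, b = getattr(s_full, attr), getattr(s_fast, attr)
            assert abs(a - b) < 5 * math.sqrt(max(a, b) * 2) + 10, attr

    def test_category_probs_sum_to_marginals(self):
        from ibdfootprint.cohort_sim import _participation_category_probs
        from scipy.stats import norm

        model = LiabilityModel(alpha=0.1, sib_corr=0.25)
        snp = SnpSpec(0.3, 0.01)
        pb, p1, p2 = _participation_category_probs(model, snp)
        wa, _ = model.component_weights(snp.var_share)
        w1 = math.sqrt(snp.var_share)
        gs = cohort_sim.standardized_genotype(np.arange(3.0), snp.f_pop, snp.mode)
        s = math.sqrt(1 - w1**2)
        for g1 in range(3):
            for g2 in range(3):
                k = 3 * g1 + g2
                # P(sib1 participates | g1) independent of g2
                assert pb[k] + p1[k] == pytest.approx(norm.sf((model.tau - w1 * gs[g1]) / s), abs=1e-9)
                assert pb[k] + p2[k] == pytest.approx(norm.sf((model.tau - w1 * gs[g2]) / s), abs=1e-9)


@pytest.fixture(scope="module")
def base_cohort():
    model = LiabilityModel(alpha=0.5, sib_corr=0.25)
    snps = [SnpSpec(f, 0.0, map_position=i * 2.0) for i, f in enumerate([0.3, 0.5, 0.7] * 10)]
    return cohort_sim.simulate_cohort(model, snps, 3000, seed=55)


class TestErrorInjection:
    def test_zero_rates_identity(self, base_cohort):
        out = cohort_sim.inject_errors(base_cohort, ErrorModel(), seed=1)
        assert np.array_equal(out.called_haplotypes, base_cohort.haplotypes)
        assert out.haplotypes is base_cohort.haplotypes  # truth untouched, shared

    def test_truth_layer_untouched(self, base_cohort):
        before = base_cohort.haplotypes.copy()
        cohort_sim.inject_errors(base_cohort, ErrorModel(genotype_error_rate=0.05), seed=1)
        assert np.array_equal(base_cohort.haplotypes, before)

    def test_genotype_replacement_rate(self, base_cohort):
        rate = 0.02
        out = cohort_sim.inject_errors(base_cohort, ErrorModel(genotype_error_rate=rate), seed=3)
        geno_t = base_cohort.genotypes("truth")
        geno_c = out.genotypes("called")
        changed = (geno_t != geno_c).mean()
        # a replacement draws the same genotype sometimes, so changed < rate
        assert 0.2 * rate < changed < rate

    def test_genotype_replacement_preserves_marginal_distribution(self, base_cohort):
        """Replacement by population draws leaves called-genotype sampling distribution unchanged."""
        out = cohort_sim.inject_errors(base_cohort, ErrorModel(genotype_error_rate=0.05), seed=7)
        geno = out.genotypes("called")
        for l, f in [(0, 0.3), (1, 0.5), (2, 0.7)]:
            counts = np.bincount(geno[:, :, l].ravel(), minlength=3)
            hwe = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * counts.sum()
            p = stats.chisquare(counts, hwe).pvalue
            assert p > 1e-4, f"marginal genotype distribution shifted at f={f}"

    def test_phasing_switch_preserves_genotypes(self, base_cohort):
        out = cohort_sim.inject_errors(base_cohort, ErrorModel(phasing_switch_rate=0.1), seed=9)
        assert np.array_equal(out.genotypes("called"), base_cohort.genotypes("truth"))
        assert not np.array_equal(out.called_haplotypes, base_cohort.haplotypes)

    def test_double_het_miscall_rate_reproduces_eps(self):
        """Injected double-het errors occur at the configured frequency-dependent rate."""
        model = LiabilityModel(alpha=0.5, sib_corr=0.25)
        freqs = [0.2, 0.4, 0.6, 0.8]
        snps = [SnpSpec(f, 0.0, map_position=i * 2.0) for i, f in enumerate(freqs)]
        cohort = cohort_sim.simulate_cohort(model, snps, 60_000, seed=77)

        def eps(f):
            return 0.05 + 0.2 * f

        out = cohort_sim.inject_errors(cohort, ErrorModel(double_het_error_fn=eps), seed=78)
        geno = cohort.genotypes("truth")
        truth_shared = cohort.truth_shared_allele()
        # called shared allele at a flipped double-het site = 1 - truth
        called_sib1 = out.called_haplotypes[:, 2]
        truth_sib1 = cohort.haplotypes[:, 2]
        for l, f in enumerate(freqs):
            dh = (geno[:, 2, l] == 1) & (geno[:, 3, l] == 1) & (cohort.ibd_state[:, l] == 1)
            for allele, rate in ((1, eps(f)), (0, eps(1 - f))):
                mask = dh & (truth_shared[:, l] == allele)
                flipped = (called_sib1[mask, 0, l] != truth_sib1[mask, 0, l]).mean()
                n = int(mask.sum())
                se = math.sqrt(rate * (1 - rate) / n)
                assert abs(flipped - rate) < 4 * se, (f, allele)

    def test_reproducible_with_seed(self, base_cohort):
        em = ErrorModel(genotype_error_rate=0.01, phasing_switch_rate=0.02)
        a = cohort_sim.inject_errors(base_cohort, em, seed=42)
        b = cohort_sim.inject_errors(base_cohort, em, seed=42)
        assert np.array_equal(a.called_haplotypes, b.called_haplotypes)
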