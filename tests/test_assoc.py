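"""Association machinery: LRT, permutation threshold, pseudo-haploid calls."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from balpoly import assoc, synthgen


def make_counts(seed=0, n=200, L=500, causal=True, coverage=0.35):
    pop = synthgen.simulate_population(n, L, f_pheno=0.39, causal=causal, seed=seed)
    reads = synthgen.simulate_reads(pop, coverage=coverage, seed=seed + 10_000)
    return assoc.AlleleCountMatrix.from_read_sim(reads), pop


class TestSiteLrt:
    def test_identical_frequencies_give_zero(self):
        stat, p = assoc.site_lrt(10, 10, 10, 10)
        assert stat == 0.0
        assert p == 1.0

    def test_opposite_fixation_closed_form(self):
        stat, p = assoc.site_lrt(0, 20, 20, 0)
        expected = 2.0 * (0.0 - 40.0 * math.log(0.5))
        assert stat == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(9.6e-14, rel=0.05)

    def test_label_swap_symmetry(self):
        s1, p1 = assoc.site_lrt(3, 14, 11, 2)
        s2, p2 = assoc.site_lrt(11, 2, 3, 14)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_statistic_nonnegative_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, 4)
            if a + b == 0 or c + d == 0:
                continue
            stat, _ = assoc.site_lrt(int(a), int(b), int(c), int(d))
            assert stat >= 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            assoc.site_lrt(0, 0, 5, 5)


class TestRunGwas:
    def test_null_pvalues_uniform_ks(self):
        acm, pop = make_counts(seed=1, n=200, L=5000, causal=False)
        res = assoc.run_gwas(acm, pop.phenotypes)
        p = res.p_values[~np.isnan(res.p_values)]
        assert p.size > 4000
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_causal_site_is_top_hit(self):
        hits = 0
        for s in range(10):
            acm, pop = make_counts(seed=50 + s, n=300, L=2000, causal=True)
            res = assoc.run_gwas(acm, pop.phenotypes)
            pv = np.where(np.isnan(res.p_values), 2.0, res.p_values)
            hits += int(np.argmin(pv) == pop.causal_index)
        assert hits >= 9

    def test_monomorphic_sites_flagged(self):
        ref = np.full((10, 4), 3)
        alt = np.zeros((10, 4), dtype=int)
        acm = assoc.AlleleCountMatrix(ref_counts=ref, alt_counts=alt)
        phen = np.array([1] * 5 + [0] * 5)
        res = assoc.run_gwas(acm, phen)
        assert np.isnan(res.p_values).all()
        assert res.n_tested == 0

    def test_single_class_phenotype_rejected(self):
        acm, _ = make_counts(seed=2, n=20, L=10)
        with pytest.raises(ValueError):
            assoc.run_gwas(acm, np.ones(20, dtype=int))


class TestPermutationThreshold:
    def test_threshold_is_order_statistic(self):
        # with n_perm permutations at fwer, the threshold equals the
        # ceil(n_perm * fwer)-th smallest recorded minimum
        acm, pop = make_counts(seed=3, n=100, L=200, causal=False)
        thr, minima = assoc.permutation_threshold(
            acm, pop.phenotypes, n_perm=40, fwer=0.05, seed=4, return_minima=True
        )
        assert thr == np.sort(minima)[math.ceil(40 * 0.05) - 1]

    def test_degenerate_minima_give_one(self):
        # monomorphic data: every permutation min defaults to 1
        ref = np.full((10, 4), 2)
        alt = np.zeros((10, 4), dtype=int)
        acm = assoc.AlleleCountMatrix(ref_counts=ref, alt_counts=alt)
        phen = np.array([1] * 5 + [0] * 5)
        thr = assoc.permutation_threshold(acm, phen, n_perm=20, seed=5)
        assert thr == 1.0

    def test_causal_data_exceeds_threshold(self):
        acm, pop = make_counts(seed=6, n=300, L=2000, causal=True)
        res = assoc.gwas_with_threshold(acm, pop.phenotypes, n_perm=50, seed=7)
        assert pop.causal_index in res.significant()


class TestPseudoHaploid:
    def test_call_fraction_matches_read_fraction(self):
        ref = np.full((4000, 1), 3)
        alt = np.full((4000, 1), 1)
        acm = assoc.AlleleCountMatrix(ref_counts=ref, alt_counts=alt)
        calls = assoc.pseudo_haploid(acm, seed=8)
        assert calls.calls.mean() == pytest.approx(0.25, abs=0.025)

    def test_zero_reads_missing_and_pure_cells_deterministic(self):
        ref = np.array([[0, 5, 0]])
        alt = np.array([[0, 0, 4]])
        acm = assoc.AlleleCountMatrix(ref_counts=ref, alt_counts=alt)
        calls = assoc.pseudo_haploid(acm, seed=9)
        assert calls.calls[0, 0] == assoc.CALL_MISSING
        assert calls.calls[0, 1] == 0
        assert calls.calls[0, 2] == 1

    def test_preserves_expected_allele_frequency(self):
        acm, _ = make_counts(seed=10, n=500, L=200, coverage=1.0)
        calls = assoc.pseudo_haploid(acm, seed=11)
        tot = acm.ref_counts + acm.alt_counts
        read_freq = acm.alt_counts.sum() / tot.sum()
        obs = calls.calls[calls.calls != assoc.CALL_MISSING]
        assert obs.mean() == pytest.approx(read_freq, abs=0.01)


class TestFilterCalls:
    def make_calls(self, cols):
        return assoc.PseudoHaploidCalls(calls=np.array(cols, dtype=np.int8).T, seed=0)

    def test_rare_site_removed(self):
        col = [1] + [0] * 99
        calls = self.make_calls([col])
        assert assoc.filter_calls(calls).n_sites == 0

    def test_mostly_missing_site_removed(self):
        col = [assoc.CALL_MISSING] * 80 + [0, 1] * 10
        calls = self.make_calls([col])
        assert assoc.filter_calls(calls).n_sites == 0

    def test_boundary_site_retained(self):
        # MAF exactly 0.02 and missing fraction just under 0.75 stays
        col = [assoc.CALL_MISSING] * 74 + [1] * 1 + [0] * 25
        # 26 non-missing, 1 alt -> maf 1/26 > 0.02; adjust to exactly 0.02:
        col = [assoc.CALL_MISSING] * 50 + [1] * 1 + [0] * 49  # maf = 0.02
        calls = self.make_calls([col])
        assert assoc.filter_calls(calls).n_sites == 1

    def test_site_index_tracks_kept_columns(self):
        good = [0] * 50 + [1] * 50
        bad = [0] * 99 + [1]
        calls = self.make_calls([bad, good, bad])
        out = assoc.filter_calls(calls)
        assert list(out.site_index) == [1]


class TestCovariateAssociation:
    def test_causal_site_top_hit_without_structure(self):
        # a little base error keeps the causal site from complete
        # separation (alt call would otherwise imply case exactly)
        pop = synthgen.simulate_population(400, 60, f_pheno=0.39, seed=12)
        reads = synthgen.simulate_reads(pop, coverage=4.0, error_rate=0.02, seed=13)
        acm = assoc.AlleleCountMatrix.from_read_sim(reads)
        calls = assoc.pseudo_haploid(acm, seed=14)
        p = assoc.covariate_association(calls, pop.phenotypes, n_pcs=4)
        assert np.nanargmin(p) == pop.causal_index

    def test_zero_pcs_matches_plain_logistic(self):
        import statsmodels.api as sm

        pop = synthgen.simulate_population(200, 10, f_pheno=0.39, seed=15)
        reads = synthgen.simulate_reads(pop, coverage=4.0, seed=16)
        calls = assoc.pseudo_haploid(assoc.AlleleCountMatrix.from_read_sim(reads), seed=17)
        p = assoc.covariate_association(calls, pop.phenotypes, n_pcs=0)
        j = 0
        col = calls.calls[:, j]
        ok = col != assoc.CALL_MISSING
        fit = sm.Logit(
            pop.phenotypes[ok].astype(float),
            sm.add_constant(col[ok].astype(float)),
        ).fit(disp=0)
        assert p[j] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_stratification_controlled_by_pcs(self):
        # two subpopulations with different allele freqs and phenotype rates:
        # without PCs the null sites are confounded; with PCs they are not
        rng = np.random.default_rng(18)
        n_half, L = 150, 300
        freqs_a = rng.uniform(0.1, 0.4, L)
        freqs_b = np.clip(freqs_a + rng.normal(0, 0.2, L), 0.02, 0.98)
        geno = np.vstack(
            [
                rng.binomial(2, freqs_a[None, :], (n_half, L)),
                rng.binomial(2, freqs_b[None, :], (n_half, L)),
            ]
        )
        phen = np.concatenate(
            [rng.random(n_half) < 0.2, rng.random(n_half) < 0.6]
        ).astype(int)
        calls = assoc.PseudoHaploidCalls(
            calls=rng.binomial(1, geno / 2).astype(np.int8), seed=0
        )
        p_corr = assoc.covariate_association(calls, phen, n_pcs=2)
        p_raw = assoc.covariate_association(calls, phen, n_pcs=0)
        frac_corr = np.nanmean(p_corr < 0.05)
        frac_raw = np.nanmean(p_raw < 0.05)
        assert frac_raw > 0.15  # confounding inflates the naive test
        assert frac_corr < 0.10  # PCs absorb the structure


class TestPairwiseR2:
    def test_identical_columns_r2_one(self):
        m = np.tile(np.array([0, 0, 1, 1, 2, 2]), (2, 1)).T
        r2 = assoc.pairwise_r2(m, 0)
        assert r2[1] == pytest.approx(1.0)

    def test_hand_zero_correlation(self):
        m = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        r2 = assoc.pairwise_r2(m, 0)
        assert r2[1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_sites_near_zero(self):
        rng = np.random.default_rng(19)
        m = rng.binomial(2, 0.4, (4000, 2))
        r2 = assoc.pairwise_r2(m, 0)
        assert r2[1] < 0.005

    def test_monomorphic_partner_flagged(self):
        m = np.array([[0, 1], [1, 1], [0, 1], [1, 1]])
        r2 = assoc.pairwise_r2(m, 0)
        assert np.isnan(r2[1])

    def test_window_restriction(self):
        m = np.tile(np.array([0, 1, 0, 1]), (3, 1)).T
        pos = np.array([100, 200, 5_000_000])
        r2 = assoc.pairwise_r2(m, 0, positions=pos, window_bp=1000)
        assert np.isnan(r2[2]) and r2[1] == pytest.approx(1.0)
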