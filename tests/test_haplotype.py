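"""EM haplotype inference, score tests, and the haplotype GLM."""

import numpy as np
import pytest

import genecase as gc

from _oracles import grid_mle_2locus
from conftest import make_cohort


class TestEM:
    def test_single_locus_reduces_to_allele_counting(self, expanded_cohort):
        em = gc.em_haplotypes(expanded_cohort, ["rs1800625"], group="cases")
        counts = gc.count_genotypes(expanded_cohort, "rs1800625").case_counts
        maf = gc.allele_frequency(counts)
        assert em.freq_of("C") == pytest.approx(maf, abs=1e-9)
        assert em.freq_of("T") == pytest.approx(1 - maf, abs=1e-9)

    def test_unambiguous_cohort_converges_immediately(self):
        # nobody is heterozygous at more than one locus -> exact counting
        cohort = make_cohort(
            {"rs1800625": [0, 0, 2, 1, 0, 2], "rs1800624": [0, 1, 0, 0, 2, 2]},
            [1, 1, 1, 0, 0, 0])
        em = gc.em_haplotypes(cohort, ["rs1800625", "rs1800624"])
        # direct haplotype counting: 12 chromosomes
        # subj doses (625,624): (0,0)->TT,TT (0,1)->TT,TA (2,0)->CT,CT
        # (1,0)->TT,CT (0,2)->TA,TA (2,2)->CA,CA
        expected = {"T-T": 4 / 12, "T-A": 3 / 12, "C-T": 3 / 12, "C-A": 2 / 12}
        for hap, f in expected.items():
            assert em.freq_of(hap) == pytest.approx(f, abs=1e-9)
        assert em.n_iter <= 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_grid_likelihood_oracle(self, seed):
        """EM frequencies equal a brute-force likelihood-grid maximizer
        on 50-subject two-locus instances."""
        cohort = gc.simulate_cohort(gc.SimConfig(n_cases=25, n_controls=25, seed=seed))
        loci = ["rs1800625", "rs1800624"]
        em = gc.em_haplotypes(cohort, loci)
        oracle = grid_mle_2locus(cohort.doses(loci))
        # both use the binary (major=0, minor=1) enumeration order
        assert np.abs(em.freqs - oracle).max() < 1e-3

    def test_loglik_monotone_and_posteriors_normalised(self):
        cohort = gc.simulate_cohort(gc.SimConfig(n_cases=200, n_controls=200, seed=17))
        em = gc.em_haplotypes(cohort, gc.RAGE_LOCI)
        assert np.all(np.diff(em.loglik_history) >= -1e-9)
        assert em.freqs.sum() == pytest.approx(1.0, abs=1e-9)
        for w in em.posterior:
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovers_true_phase_frequencies(self):
        """At n=1600 the EM frequencies should track the true (side-channel)
        haplotype frequencies to better than 0.01 mean absolute error."""
        cohort = gc.simulate_null(gc.SimConfig(n_cases=800, n_controls=800, seed=23))
        em = gc.em_haplotypes(cohort, gc.RAGE_LOCI)
        ph = cohort.phase
        true = {h: ((ph["rage_hap_a"] == h).sum() + (ph["rage_hap_b"] == h).sum())
                / (2 * len(cohort)) for h in em.haplotypes}
        err = np.mean([abs(em.freq_of(h) - true[h]) for h in em.haplotypes])
        assert err < 0.01

    def test_no_complete_subjects_errors(self):
        cohort = make_cohort({"rs1800625": [-1, -1], "rs1800624": [0, 1]}, [1, 0])
        with pytest.raises(ValueError, match="complete"):
            gc.em_haplotypes(cohort, ["rs1800625", "rs1800624"])


class TestScoreTest:
    def test_deterministic_association_reaches_minimum_p(self):
        """When status is a function of carrying a haplotype, the carrier
        haplotype's permutation p must hit the attainable minimum."""
        rng = np.random.default_rng(3)
        dose = rng.choice([0, 1, 2], size=300, p=[0.49, 0.42, 0.09])
        cohort = make_cohort({"rs1130409": list(dose)}, list((dose >= 1).astype(int)))
        res = gc.haplotype_score_test(cohort, ["rs1130409"], n_perm=199, seed=4)
        i = res.haplotypes.index("T")
        assert res.p_sim[i] == pytest.approx(1 / 200)
        assert res.global_p_sim == pytest.approx(1 / 200)

    def test_planted_effect_has_positive_score(self):
        cfg = gc.SimConfig(hap_log_or={"C-A-A": np.log(2.1)}, seed=19)
        cohort = gc.simulate_cohort(cfg)
        res = gc.haplotype_score_test(cohort, gc.RAGE_LOCI, n_perm=199, seed=1)
        i = res.haplotypes.index("C-A-A")
        assert res.z[i] > 0
        assert res.p_sim[i] <= 0.05

    def test_covariate_adjustment_runs(self):
        cohort = gc.simulate_null(gc.SimConfig(n_cases=150, n_controls=150, seed=21))
        res = gc.haplotype_score_test(cohort, gc.APE1_LOCI,
                                      covariates=["age", "sex"], n_perm=199, seed=2)
        assert len(res.p_sim) == len(res.haplotypes)
        assert np.all((res.p_sim > 0) & (res.p_sim <= 1))

    def test_too_few_permutations_rejected(self):
        cohort = gc.simulate_null(gc.SimConfig(n_cases=30, n_controls=30, seed=1))
        with pytest.raises(ValueError):
            gc.haplotype_score_test(cohort, gc.APE1_LOCI, n_perm=50)


class TestHaplotypeGLM:
    def test_single_snp_reduces_to_dose_logistic(self):
        cohort = gc.simulate_null(gc.SimConfig(n_cases=400, n_controls=400, seed=3))
        glm = gc.haplotype_glm(cohort, ["rs1130409"])
        dose = cohort.table["rs1130409"].to_numpy(float)
        X = np.column_stack([np.ones(len(dose)), dose])
        fit = gc.logistic_fit(X, cohort.status.astype(float))
        assert glm.reference == "G"
        or_, (lo, hi), _ = glm.or_of("T")
        assert or_ == pytest.approx(np.exp(fit.coef[1]), abs=1e-6)
        assert lo < or_ < hi

    def test_reference_is_most_frequent(self):
        cohort = gc.simulate_null(gc.SimConfig(seed=4))
        glm = gc.haplotype_glm(cohort, gc.RAGE_LOCI)
        assert glm.reference == "T-T-G"
        assert "T-T-G" not in glm.haplotypes

    def test_rare_haplotypes_pooled(self):
        freqs = dict(gc.control_hap_freqs("RAGE"))
        # push one haplotype below the pooling threshold
        moved = freqs["T-A-A"] - 0.005
        freqs["T-A-A"] = 0.005
        freqs["T-T-G"] += moved
        cohort = gc.simulate_null(gc.SimConfig(n_cases=600, n_controls=600,
                                               rage_hap_freqs=freqs, seed=6))
        glm = gc.haplotype_glm(cohort, gc.RAGE_LOCI, min_freq=0.01)
        assert "T-A-A" in glm.pooled_rare
        assert "T-A-A" not in glm.haplotypes

    def test_bad_reference_rejected(self):
        cohort = gc.simulate_null(gc.SimConfig(n_cases=100, n_controls=100, seed=7))
        with pytest.raises(ValueError, match="reference"):
            gc.haplotype_glm(cohort, gc.RAGE_LOCI, reference="T-A-A", min_freq=0.2)

    def test_recovers_planted_or_in_one_cohort(self):
        cfg = gc.SimConfig(hap_log_or={"C-A-A": np.log(2.1)}, seed=1003)
        cohort = gc.simulate_cohort(cfg)
        or_, (lo, hi), _ = gc.haplotype_glm(cohort, gc.RAGE_LOCI).or_of("C-A-A")
        assert lo < 2.1 < hi
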