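import numpy as np
import pytest
from scipy.stats import multivariate_normal

import snpblup as sb


@pytest.fixture(scope="module")
def reml_data():
    """355 animals x ~150 markers at h2 = 0.30: large enough to identify
    (sigma2_g, sigma2_e) well, small enough for dense REML in seconds."""
    design = sb.BreedingDesign(n_sires_per_gen=5, dams_per_sire=10,
                               progeny_per_mating=2, n_generations=4,
                               n_chromosomes=3, markers_per_chromosome=50)
    ped = sb.simulate_pedigree(design, 11)
    geno = sb.maf_filter(sb.simulate_genotypes(ped, design, 12), 0.01)
    study = sb.simulate_phenotypes(
        geno, sb.TraitArchitecture(mu_true=1.0, sigma2_g=1e-2, target_h2=0.30),
        13, pedigree=ped)
    designs = {s: sb.apply_coding(geno, s)
               for s in ("012", "210", "101", "centered")}
    return {"geno": geno, "y": study.phenotypes, "designs": designs,
            "start": sb.VarianceComponents.from_marker(5e-3, 1.0, geno)}


@pytest.fixture(scope="module")
def reml_fits(reml_data):
    """AI-REML fits of the marker model under every coding (shared, expensive)."""
    return {s: sb.ai_reml(reml_data["y"], d, reml_data["start"])
            for s, d in reml_data["designs"].items()}


@pytest.fixture(scope="module")
def em_fit(reml_data):
    return sb.em_reml(reml_data["y"], reml_data["designs"]["012"],
                      reml_data["start"], tol=1e-8, max_iter=500)


class TestRemlLoglik:
    def test_coding_invariance(self, reml_data):
        vc = sb.VarianceComponents.from_marker(0.01, 2.0, reml_data["geno"])
        vals = [sb.reml_loglik(vc, reml_data["y"], d)
                for d in reml_data["designs"].values()]
        assert np.ptp(vals) < 1e-8

    def test_contrast_matrix_oracle(self, small_study):
        """Matches the density of orthonormal error contrasts K y, K 1 = 0."""
        y, d = small_study["y"], small_study["designs"]["012"]
        n = y.size
        vc = sb.VarianceComponents.from_marker(0.01, 2.0, small_study["geno"])
        w, V = np.linalg.eigh(np.eye(n) - np.ones((n, n)) / n)
        K = V[:, w > 0.5].T
        Vm = 0.01 * (d.Z @ d.Z.T) + 2.0 * np.eye(n)
        oracle = multivariate_normal(mean=np.zeros(n - 1),
                                     cov=K @ Vm @ K.T).logpdf(K @ y)
        assert sb.reml_loglik(vc, y, d) == pytest.approx(oracle, abs=1e-6)

    def test_zero_genetic_variance_closed_form(self, small_study):
        """sigma2_g = 0 reduces to the intercept-only restricted likelihood."""
        y, d = small_study["y"], small_study["designs"]["012"]
        n = y.size
        se2 = 1.7
        vc = sb.VarianceComponents(0.0, se2, 1.0)
        sse = np.sum((y - y.mean()) ** 2)
        closed = -0.5 * ((n - 1) * np.log(2 * np.pi * se2) + sse / se2)
        assert sb.reml_loglik(vc, y, d) == pytest.approx(closed, abs=1e-10)

    def test_marker_and_gblup_forms_agree(self, small_study):
        """Identical when Z Z' sigma2_g = G sigma2_a."""
        y, d = small_study["y"], small_study["designs"]["012"]
        geno = small_study["geno"]
        vc = sb.VarianceComponents.from_marker(0.01, 2.0, geno)
        grm = sb.build_grm(d)
        vc_a = sb.VarianceComponents(vc.sigma2_a, vc.sigma2_e, 1.0)
        assert sb.reml_loglik(vc, y, d) == pytest.approx(
            sb.reml_loglik(vc_a, y, grm), abs=1e-8)


class TestEmReml:
    def test_converges_and_loglik_monotone(self, em_fit):
        assert em_fit.converged
        path = np.asarray(em_fit.loglik_path)
        assert (np.diff(path) > -1e-8).all()

    def test_agrees_with_ai(self, em_fit, reml_fits):
        ai = reml_fits["012"]
        assert em_fit.estimates.sigma2_g == pytest.approx(
            ai.estimates.sigma2_g, rel=1e-4)
        assert em_fit.estimates.sigma2_e == pytest.approx(
            ai.estimates.sigma2_e, rel=1e-5)
        assert ai.n_iterations < em_fit.n_iterations

    def test_max_iter_flag(self, reml_data):
        res = sb.em_reml(reml_data["y"], reml_data["designs"]["012"],
                         reml_data["start"], tol=1e-12, max_iter=3)
        assert not res.converged and res.n_iterations == 3

    def test_coding_invariance(self, reml_data):
        ests = []
        for s in ("012", "210", "101", "centered"):
            r = sb.em_reml(reml_data["y"], reml_data["designs"][s],
                           reml_data["start"], tol=1e-8, max_iter=500)
            ests.append((r.estimates.sigma2_g, r.estimates.sigma2_e))
        sg = [e[0] for e in ests]
        se = [e[1] for e in ests]
        assert np.ptp(sg) / np.mean(sg) < 1e-6
        assert np.ptp(se) / np.mean(se) < 1e-6

    def test_grid_oracle_no_point_beats_optimum(self, reml_data, reml_fits):
        y, d = reml_data["y"], reml_data["designs"]["012"]
        est = reml_fits["012"].estimates
        best = sb.reml_loglik(est, y, d)
        for fg in np.linspace(0.6, 1.6, 20):
            for fe in np.linspace(0.6, 1.6, 20):
                vc = sb.VarianceComponents(est.sigma2_g * fg, est.sigma2_e * fe,
                                           est.scale_denominator)
                assert sb.reml_loglik(vc, y, d) <= best + 1e-6


class TestAiReml:
    def test_coding_invariance(self, reml_fits):
        sg = [r.estimates.sigma2_g for r in reml_fits.values()]
        se = [r.estimates.sigma2_e for r in reml_fits.values()]
        assert np.ptp(sg) / np.mean(sg) < 1e-6
        assert np.ptp(se) / np.mean(se) < 1e-6

    def test_fewer_iterations_than_em(self, reml_fits, em_fit):
        assert all(r.n_iterations < em_fit.n_iterations
                   for r in reml_fits.values())

    def test_start_at_optimum_converges_immediately(self, reml_data, reml_fits):
        res = sb.ai_reml(reml_data["y"], reml_data["designs"]["012"],
                         reml_fits["012"].estimates)
        assert res.converged and res.n_iterations <= 3

    def test_gblup_with_inflated_centered_g_near_marker(self, reml_data, reml_fits):
        grm = sb.build_grm(reml_data["designs"]["centered"], inflation=1.001)
        start = sb.VarianceComponents(reml_fits["012"].estimates.sigma2_a, 1.0, 1.0)
        res = sb.ai_reml(reml_data["y"], grm, start)
        assert res.estimates.sigma2_a == pytest.approx(
            reml_fits["012"].estimates.sigma2_a, rel=0.01)
        assert res.estimates.sigma2_e == pytest.approx(
            reml_fits["012"].estimates.sigma2_e, rel=0.01)

    def test_gblup_em_matches_gblup_ai(self, small_study):
        # m > n here, so the 012 relationship matrix is invertible as
        # required; h2 = 0.6 keeps the optimum well in the interior, where
        # EM's linear convergence is fast enough to compare against AI
        geno = small_study["geno"]
        study = sb.simulate_phenotypes(
            geno, sb.TraitArchitecture(mu_true=1.0, sigma2_g=1e-2, target_h2=0.6),
            14)
        grm = sb.build_grm(small_study["designs"]["012"])
        start = sb.VarianceComponents(small_study["vc"].sigma2_a, 1.0, 1.0)
        ai = sb.ai_reml(study.phenotypes, grm, start)
        em = sb.em_reml(study.phenotypes, grm, start, tol=1e-8, max_iter=1000)
        assert em.converged
        assert em.estimates.sigma2_a == pytest.approx(ai.estimates.sigma2_a,
                                                      rel=1e-4)

    def test_parameter_recovery_monte_carlo(self):
        """Replicate-mean AI-REML estimates are unbiased at the MC resolution.

        Ten replicate populations at (sigma2_g, sigma2_e) = (0.001, 3.0),
        ~500 animals x ~600 markers; the weak per-marker signal makes
        sigma2_g_hat noisy, so the check is against the larger of a 15%
        relative band and 3 Monte-Carlo standard errors of the mean.
        """
        design = sb.desk_scale_design()
        sg_hat, se_hat = [], []
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            ped = sb.simulate_pedigree(design, int(rng.integers(2 ** 31)))
            geno = sb.maf_filter(
                sb.simulate_genotypes(ped, design, int(rng.integers(2 ** 31))), 0.01)
            study = sb.simulate_phenotypes(
                geno, sb.TraitArchitecture(sigma2_g=1e-3, sigma2_e=3.0),
                int(rng.integers(2 ** 31)), pedigree=ped)
            start = sb.VarianceComponents.from_marker(
                1e-3, np.var(study.phenotypes) * 0.7, geno)
            res = sb.ai_reml(study.phenotypes, sb.apply_coding(geno, "012"),
                             start, max_iter=100)
            sg_hat.append(res.estimates.sigma2_g)
            se_hat.append(res.estimates.sigma2_e)
        mc_band = 3 * np.std(sg_hat, ddof=1) / np.sqrt(len(sg_hat))
        assert abs(np.mean(sg_hat) - 1e-3) < max(0.15e-3, mc_band)
        assert np.mean(se_hat) == pytest.approx(3.0, rel=0.15)

    def test_positive_start_required(self, reml_data):
        with pytest.raises(ValueError):
            sb.ai_reml(reml_data["y"], reml_data["designs"]["012"],
                       sb.VarianceComponents(0.0, 1.0, 1.0))
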