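import numpy as np
import pytest

import snpblup as sb

SHIFT_SCHEMES = ("012", "101", "centered")


def dense_oracle(y, Z, sg2, se2):
    """Independent dense solve of the (1+m) marker system."""
    n, m = Z.shape
    X = np.column_stack([np.ones(n), Z])
    Q = X.T @ X / se2
    Q[1:, 1:] += np.eye(m) / sg2
    C = np.linalg.inv(Q)
    sol = C @ (X.T @ y / se2)
    return sol, C


class TestMarkerMme:
    def test_toy_matches_dense_solve(self, toy):
        d = sb.apply_coding(toy["geno"], "012")
        fit = sb.solve_marker_mme(toy["y"], d, toy["vc"])
        sol, C = dense_oracle(toy["y"], d.Z, 1.0, 1.0)
        assert fit.mu_hat == pytest.approx(sol[0])
        np.testing.assert_allclose(fit.g_hat, sol[1:], rtol=1e-10)
        np.testing.assert_allclose(fit.C_g, C[1:, 1:], rtol=1e-10, atol=1e-14)
        assert fit.c_mumu == pytest.approx(C[0, 0])

    def test_infinite_shrinkage_leaves_intercept(self, toy):
        d = sb.apply_coding(toy["geno"], "012")
        vc = sb.VarianceComponents(1e-12, 1.0, toy["geno"].heterozygosity_sum())
        fit = sb.solve_marker_mme(toy["y"], d, vc)
        np.testing.assert_allclose(fit.g_hat, 0.0, atol=1e-9)
        assert fit.mu_hat == pytest.approx(np.mean(toy["y"]), abs=1e-9)

    def test_coding_invariance_of_g_hat_and_C_g(self, small_study, small_fits):
        ref = small_fits["012"]
        for s in ("101", "centered"):
            np.testing.assert_allclose(small_fits[s].g_hat, ref.g_hat, atol=1e-8)
            np.testing.assert_allclose(small_fits[s].C_g, ref.C_g, atol=1e-8)
        np.testing.assert_allclose(small_fits["210"].g_hat, -ref.g_hat, atol=1e-8)

    def test_input_validation(self, toy):
        d = sb.apply_coding(toy["geno"], "012")
        with pytest.raises(ValueError):
            sb.solve_marker_mme(np.ones(5), d, toy["vc"])
        with pytest.raises(ValueError):
            sb.solve_marker_mme(toy["y"], d,
                                sb.VarianceComponents(0.0, 1.0, 1.0))


class TestCompleteGebv:
    def test_invariant_across_codings(self, small_study, small_fits):
        gebvs = {s: sb.complete_gebv(small_fits[s], small_study["designs"][s])
                 for s in small_fits}
        ref = gebvs["012"]
        for s, v in gebvs.items():
            np.testing.assert_allclose(v, ref, atol=1e-8)

    def test_gebv_without_mean_shifted_by_constant(self, small_study, small_fits):
        a0 = small_study["designs"]["012"].Z @ small_fits["012"].g_hat
        a1 = small_study["designs"]["101"].Z @ small_fits["101"].g_hat
        diff = a0 - a1
        np.testing.assert_allclose(diff, diff[0], atol=1e-8)

    def test_mean_shift_law(self, small_study):
        """mu_hat(v) - mu_hat(012) = v' g_hat for any shift coding."""
        geno, y, vc = small_study["geno"], small_study["y"], small_study["vc"]
        rng = np.random.default_rng(3)
        v = rng.uniform(-1, 2, size=geno.m)
        fit0 = sb.solve_marker_mme(y, sb.apply_coding(geno, "012"), vc)
        fitv = sb.solve_marker_mme(y, sb.apply_coding(geno, "custom", v=v), vc)
        assert fitv.mu_hat - fit0.mu_hat == pytest.approx(v @ fit0.g_hat, abs=1e-8)

    def test_scheme_mismatch_rejected(self, small_study, small_fits):
        with pytest.raises(ValueError):
            sb.complete_gebv(small_fits["012"], small_study["designs"]["210"])


class TestGrm:
    def test_centered_grm_is_singular_with_zero_row_sums(self, small_study):
        grm = sb.build_grm(small_study["designs"]["centered"])
        np.testing.assert_allclose(grm.G @ np.ones(grm.n), 0.0, atol=1e-8)
        assert np.linalg.eigvalsh(grm.G).min() < 1e-10

    def test_identical_genotypes_give_identical_rows(self, toy):
        Z0 = np.array([[0, 1], [0, 1], [2, 0], [1, 2]])
        g = sb.orient_to_minor(Z0)
        grm = sb.build_grm(sb.apply_coding(g, "012"))
        np.testing.assert_allclose(grm.G[0], grm.G[1])
        assert abs(np.linalg.det(grm.G)) < 1e-10

    def test_inflation_restores_positive_definiteness(self, small_study):
        grm = sb.build_grm(small_study["designs"]["centered"], inflation=1.001)
        assert np.linalg.eigvalsh(grm.G).min() > 0

    def test_monomorphic_panel_rejected(self):
        g = sb.orient_to_minor(np.zeros((4, 3), dtype=int))
        with pytest.raises(ValueError):
            sb.build_grm(sb.apply_coding(g, "012"))


class TestGblupDuality:
    @pytest.mark.parametrize("scheme", ["012", "101"])
    def test_a_hat_equals_Z_g_hat(self, small_study, small_fits, scheme):
        d = small_study["designs"][scheme]
        grm = sb.build_grm(d)
        gf = sb.solve_gblup_mme(small_study["y"], grm, small_study["vc"])
        np.testing.assert_allclose(gf.a_hat, d.Z @ small_fits[scheme].g_hat,
                                   atol=1e-6)

    @pytest.mark.parametrize("scheme", ["012", "101"])
    def test_pev_duality(self, small_study, small_fits, scheme):
        d = small_study["designs"][scheme]
        gf = sb.solve_gblup_mme(small_study["y"], sb.build_grm(d), small_study["vc"])
        np.testing.assert_allclose(gf.pev, sb.pev_marker(small_fits[scheme], d),
                                   atol=1e-6)

    def test_singular_G_rejected_with_guidance(self, small_study):
        grm = sb.build_grm(small_study["designs"]["centered"])
        with pytest.raises(Exception, match="regularize"):
            sb.solve_gblup_mme(small_study["y"], grm, small_study["vc"])

    def test_reliability_endpoints_and_bounds(self, small_study):
        d = small_study["designs"]["012"]
        grm = sb.build_grm(d)
        gf = sb.solve_gblup_mme(small_study["y"], grm, small_study["vc"])
        assert ((gf.reliability >= 0) & (gf.reliability <= 1)).all()
        assert (gf.pev >= 0).all()
        # endpoints of the reliability formula
        sa2 = small_study["vc"].sigma2_a
        gd = grm.raw_diagonal
        np.testing.assert_allclose(1 - 0.0 / (gd * sa2), 1.0)
        np.testing.assert_allclose(1 - (gd * sa2) / (gd * sa2), 0.0)


class TestPevMarker:
    def test_pev_differs_between_codings(self, small_study, small_fits):
        p012 = sb.pev_marker(small_fits["012"], small_study["designs"]["012"])
        p210 = sb.pev_marker(small_fits["210"], small_study["designs"]["210"])
        assert np.max(np.abs(p012 - p210)) > 0

    def test_all_major_homozygote_has_zero_pev_under_012(self, small_study):
        geno = small_study["geno"]
        Z0 = np.vstack([geno.Z0, np.zeros((1, geno.m), dtype=np.int8)])
        g2 = sb.orient_to_minor(Z0)
        d = sb.apply_coding(g2, "012")
        y = np.append(small_study["y"], np.mean(small_study["y"]))
        fit = sb.solve_marker_mme(y, d, small_study["vc"])
        assert sb.pev_marker(fit, d)[-1] == pytest.approx(0.0, abs=1e-12)

    def test_toy_pev_matches_dense_inverse(self, toy):
        d = sb.apply_coding(toy["geno"], "012")
        fit = sb.solve_marker_mme(toy["y"], d, toy["vc"])
        _, C = dense_oracle(toy["y"], d.Z, 1.0, 1.0)
        expected = np.diag(d.Z @ C[1:, 1:] @ d.Z.T)
        np.testing.assert_allclose(sb.pev_marker(fit, d), expected, rtol=1e-10)


class TestVarComplete:
    def test_invariant_across_codings(self, small_study, small_fits):
        V0 = sb.var_complete(small_fits["012"], small_study["designs"]["012"])
        Vc = sb.var_complete(small_fits["centered"], small_study["designs"]["centered"])
        np.testing.assert_allclose(V0, Vc, atol=1e-8)

    def test_centered_cross_covariance_vanishes(self, small_fits):
        np.testing.assert_allclose(small_fits["centered"].c_mug, 0.0, atol=1e-10)

    def test_centered_closed_form(self, small_study, small_fits):
        d = small_study["designs"]["centered"]
        fit = small_fits["centered"]
        V = sb.var_complete(fit, d)
        closed = (small_study["vc"].sigma2_e / d.n
                  + d.Z @ fit.C_g @ d.Z.T)
        np.testing.assert_allclose(V, closed, atol=1e-10)

    def test_diagonal_dominates_pev_under_centered(self, small_study, small_fits):
        d = small_study["designs"]["centered"]
        V = sb.var_complete(small_fits["centered"], d)
        pev = sb.pev_marker(small_fits["centered"], d)
        assert (np.diag(V) - pev >= -1e-12).all()


@pytest.fixture(scope="module")
def gblup_fits(small_study):
    fits = {}
    for s, d in small_study["designs"].items():
        inflation = 1.001 if s == "centered" else 1.0
        grm = sb.build_grm(d, inflation=inflation)
        fits[s] = sb.solve_gblup_mme(small_study["y"], grm, small_study["vc"])
    return fits


class TestReliabilityReport:

    def test_summary_and_correlations(self, gblup_fits):
        rep = sb.reliability_report(gblup_fits)
        assert set(rep["summary"].index) == set(gblup_fits)
        assert list(rep["summary"].columns) == ["min", "mean", "max", "sd"]
        assert rep["correlations"].shape == (4, 4)
        assert not rep["correlations"].isna().any().any()

    def test_centered_beats_210_on_mean_reliability(self, gblup_fits):
        rep = sb.reliability_report(gblup_fits)
        assert (rep["summary"].loc["centered", "mean"]
                > rep["summary"].loc["210", "mean"])

    def test_constant_vector_reported_not_nan(self, gblup_fits):
        import copy
        fits = dict(gblup_fits)
        broken = copy.deepcopy(fits["012"])
        broken.reliability = np.full_like(broken.reliability, 0.5)
        fits["012"] = broken
        rep = sb.reliability_report(fits)
        assert rep["degenerate"] == ["012"]
        assert "012" not in rep["correlations"].index
        assert not rep["correlations"].isna().any().any()

    def test_single_scheme_identity(self, gblup_fits):
        rep = sb.reliability_report({"012": gblup_fits["012"]})
        np.testing.assert_allclose(rep["correlations"].to_numpy(), [[1.0]])
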