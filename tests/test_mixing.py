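"""Mixing model: posterior density, MCMC sampler, grid oracle, mass balance."""

import numpy as np
import pytest
from scipy import stats

from ventmix import (
    CapabilityError,
    DegenerateModelError,
    MixingProblem,
    ValidationError,
    analytic_two_source_point,
    fit_mixing,
    grid_posterior_mean,
    kst_preset,
    log_unnormalized_posterior,
    tdf_for_guild,
)
from ventmix.mixing import ilr, ilr_inv

from conftest import make_consumer, make_pool, make_tdf


# ---------------------------------------------------------------------------
# log posterior density
# ---------------------------------------------------------------------------

class TestLogPosterior:
    def test_matches_scipy_oracle_on_fixed_problem(self, two_source_problem):
        """Hand-assembled density: Dirichlet prior + one Gaussian per isotope."""
        problem = two_source_problem
        p = np.array([0.35, 0.65])
        mu = np.array([[-15.0, -22.0], [4.0, -1.0]])      # (J, K)
        var = np.array(
            [[0.8**2 + 0.5**2, 0.6**2 + 0.5**2], [0.9**2 + 0.5**2, 0.7**2 + 0.5**2]]
        )
        dlt = np.array([[0.5, 0.5], [2.0, 2.0]])
        x = np.array([-18.0, 2.5])
        expected = stats.dirichlet.logpdf(p, [1.0, 1.0])
        for j in range(2):
            m = float(p @ (mu[j] + dlt[j]))
            s = float(np.sqrt(p**2 @ var[j]))
            expected += stats.norm.logpdf(x[j], m, s)
        got = log_unnormalized_posterior(p, problem)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_identical_sources_cannot_be_distinguished(self):
        """Two identical sources: the density is exactly symmetric under the
        source swap (the likelihood carries no information about labels), so
        the posterior mean sits at 1/K.  Note the density is not constant in
        p — the mixture variance Σ p_k²(ω²+τ²) still depends on p."""
        s1 = make_pool("a", -20.0, 0.5, 3.0, 0.5)
        s2 = make_pool("b", -20.0, 0.5, 3.0, 0.5)
        prob = MixingProblem([s1, s2], make_tdf(c_sd=0.1, n_sd=0.1),
                             [make_consumer(-19.0, 4.0)])
        for f in (0.1, 0.3, 0.45):
            assert log_unnormalized_posterior([f, 1 - f], prob) == pytest.approx(
                log_unnormalized_posterior([1 - f, f], prob), rel=1e-12
            )
        assert np.allclose(grid_posterior_mean(prob, 0.005), 0.5, atol=1e-9)

    def test_symmetric_problem_is_swap_invariant(self):
        s1 = make_pool("a", -15.0, 0.5, 5.0, 0.5)
        s2 = make_pool("b", -25.0, 0.5, -5.0, 0.5)
        prob = MixingProblem([s1, s2], make_tdf(c_sd=0.2, n_sd=0.2),
                             [make_consumer(-20.0, 0.0)])
        a = log_unnormalized_posterior([0.3, 0.7], prob)
        b = log_unnormalized_posterior([0.7, 0.3], prob)
        assert a == pytest.approx(b, rel=1e-12)

    def test_off_simplex_rejected(self, two_source_problem):
        with pytest.raises(ValidationError):
            log_unnormalized_posterior([0.4, 0.4], two_source_problem)
        with pytest.raises(ValidationError):
            log_unnormalized_posterior([-0.1, 1.1], two_source_problem)

    def test_zero_total_variance_is_degenerate(self):
        s1 = make_pool("a", -15.0, 0.0, 5.0, 0.0)
        s2 = make_pool("b", -25.0, 0.0, -5.0, 0.0)
        with pytest.raises(DegenerateModelError):
            log_unnormalized_posterior(
                [0.5, 0.5],
                MixingProblem([s1, s2], make_tdf(), [make_consumer(-20.0, 0.0)]),
            )


class TestProblemValidation:
    def test_needs_two_sources(self):
        with pytest.raises(ValidationError):
            MixingProblem([make_pool("a", -20, 1, 3, 1)], make_tdf(),
                          [make_consumer(-19, 4)])

    def test_undefined_source_sd_rejected(self):
        from ventmix import IsotopeSummary, SourcePool

        bad = SourcePool("a", {
            "C13": IsotopeSummary("C13", -20.0, None, 1),
            "N15": IsotopeSummary("N15", 3.0, 0.5, 2),
        })
        with pytest.raises(ValidationError, match="undefined SD"):
            MixingProblem([bad, make_pool("b", -15, 1, 5, 1)], make_tdf(),
                          [make_consumer(-19, 4)])

    def test_alpha_must_be_positive(self, two_source_problem):
        with pytest.raises(ValidationError):
            MixingProblem(
                two_source_problem.sources,
                two_source_problem.tdf,
                two_source_problem.consumers,
                alpha=[1.0, 0.0],
            )


# ---------------------------------------------------------------------------
# ILR transform
# ---------------------------------------------------------------------------

class TestILR:
    @pytest.mark.parametrize("K", [2, 3, 4, 5])
    def test_roundtrip(self, K):
        rng = np.random.default_rng(7)
        P = rng.dirichlet(np.ones(K), size=20)
        assert np.allclose(ilr_inv(ilr(P)), P, atol=1e-12)

    @pytest.mark.parametrize("K", [3, 4])
    def test_agrees_with_skbio_composition_roundtrip(self, K):
        """Independent route: scikit-bio's ILR pair on the same compositions."""
        from skbio.stats.composition import ilr as sk_ilr
        from skbio.stats.composition import ilr_inv as sk_ilr_inv

        rng = np.random.default_rng(8)
        P = rng.dirichlet(np.ones(K), size=10)
        ours = ilr_inv(ilr(P))
        theirs = np.asarray(sk_ilr_inv(sk_ilr(P)))
        assert np.allclose(ours, theirs, atol=1e-10)
        # both coordinate systems are isometries: distances are preserved
        d_ours = np.linalg.norm(ilr(P[0]) - ilr(P[1]))
        d_theirs = np.linalg.norm(np.asarray(sk_ilr(P[:2]))[0]
                                  - np.asarray(sk_ilr(P[:2]))[1])
        assert d_ours == pytest.approx(d_theirs, rel=1e-10)


# ---------------------------------------------------------------------------
# Grid oracle
# ---------------------------------------------------------------------------

class TestGridOracle:
    def test_flat_posterior_returns_prior_mean(self):
        srcs = [make_pool(n, -20.0, 0.5, 3.0, 0.5) for n in "abc"]
        prob = MixingProblem(srcs, make_tdf(c_sd=0.2, n_sd=0.2),
                             [make_consumer(-19.5, 4.0)])
        mean = grid_posterior_mean(prob, resolution=0.02)
        assert np.allclose(mean, 1.0 / 3.0, atol=0.02)

    def test_self_convergence_under_refinement(self, two_source_problem):
        coarse = grid_posterior_mean(two_source_problem, resolution=0.005)
        fine = grid_posterior_mean(two_source_problem, resolution=0.0005)
        assert np.allclose(coarse, fine, atol=0.002)

    def test_too_many_sources_rejected(self):
        srcs = [make_pool(f"s{i}", -20.0 + i, 0.5, 3.0 + i, 0.5) for i in range(5)]
        prob = MixingProblem(srcs, make_tdf(c_sd=0.2, n_sd=0.2),
                             [make_consumer(-18.0, 5.0)])
        with pytest.raises(CapabilityError):
            grid_posterior_mean(prob)

    def test_coarse_resolution_rejected(self, two_source_problem):
        with pytest.raises(ValidationError):
            grid_posterior_mean(two_source_problem, resolution=0.1)

    def test_relabeling_sources_permutes_expectations(self, three_source_problem):
        p = three_source_problem
        mean = grid_posterior_mean(p, resolution=0.01)
        perm = [2, 0, 1]
        swapped = MixingProblem(
            sources=[p.sources[i] for i in perm],
            tdf=p.tdf,
            consumers=p.consumers,
        )
        mean_sw = grid_posterior_mean(swapped, resolution=0.01)
        assert np.allclose(mean_sw, mean[perm], atol=1e-10)


# ---------------------------------------------------------------------------
# MCMC sampler
# ---------------------------------------------------------------------------

class TestFitMixing:
    def test_draws_live_on_simplex_and_means_sum_to_one(self, two_source_problem):
        res = fit_mixing(two_source_problem, iterations=20_000, seed=1)
        assert np.all(res.draws >= 0)
        assert np.allclose(res.draws.sum(axis=1), 1.0, atol=1e-12)
        assert res.mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_reproduces_draws_exactly(self, two_source_problem):
        a = fit_mixing(two_source_problem, iterations=20_000, seed=42)
        b = fit_mixing(two_source_problem, iterations=20_000, seed=42)
        assert np.array_equal(a.draws, b.draws)
        c = fit_mixing(two_source_problem, iterations=20_000, seed=43)
        assert not np.array_equal(a.draws, c.draws)

    def test_agrees_with_grid_oracle_k2(self, two_source_problem):
        res = fit_mixing(two_source_problem, iterations=200_000, seed=5)
        grid = grid_posterior_mean(two_source_problem, resolution=0.005)
        assert np.allclose(res.mean, grid, atol=0.01)

    def test_agrees_with_grid_oracle_k3(self, three_source_problem):
        res = fit_mixing(three_source_problem, iterations=300_000, seed=6)
        grid = grid_posterior_mean(three_source_problem, resolution=0.01)
        assert np.allclose(res.mean, grid, atol=0.01)

    def test_identical_sources_recover_uniform_prior_mean(self):
        srcs = [make_pool(n, -20.0, 0.5, 3.0, 0.5) for n in "ab"]
        prob = MixingProblem(srcs, make_tdf(c_sd=0.2, n_sd=0.2),
                             [make_consumer(-19.5, 4.0)])
        res = fit_mixing(prob, iterations=100_000, seed=7)
        assert np.allclose(res.mean, 0.5, atol=0.01)

    def test_vent_fraction_monotone_in_consumer_d13c(self):
        """Pushing a consumer's δ13C toward the vent end member must raise the
        inferred vent-POM share (KST two-source configuration, grid oracle)."""
        base = kst_preset()["zoop_venting_gt2000"]
        herb = tdf_for_guild("herbivore")
        fractions = []
        for d13c in (-22.5, -21.5, -20.5, -19.5, -18.5):
            prob = MixingProblem(
                sources=base.sources, tdf=herb,
                consumers=[make_consumer(d13c, 6.9, guild="herbivore")],
            )
            fractions.append(grid_posterior_mean(prob, resolution=0.005)[1])
        assert np.all(np.diff(fractions) > 0)

    def test_small_variance_limit_recovers_analytic_point(self):
        """As source and TDF SDs shrink, the posterior collapses onto the
        deterministic two-source mass-balance fraction."""
        tdf = make_tdf(c_sd=1e-3, n_sd=1e-3)
        s1 = make_pool("a", -15.0, 1e-3, 2.0, 1e-3)
        s2 = make_pool("b", -25.0, 1e-3, -4.0, 1e-3)
        f = 0.3
        cons = make_consumer(f * -15.0 + (1 - f) * -25.0, f * 2.0 + (1 - f) * -4.0)
        prob = MixingProblem([s1, s2], tdf, [cons])
        res = fit_mixing(prob, iterations=200_000, seed=3)
        analytic = analytic_two_source_point(cons, s1, s2, tdf, "C13")
        assert analytic == pytest.approx(f, abs=1e-9)
        assert res.mean[0] == pytest.approx(f, abs=0.005)

    def test_out_of_polygon_consumer_is_flagged_not_fatal(self):
        base = kst_preset()["ep_crustacean_venting"]
        far = MixingProblem(
            sources=base.sources, tdf=tdf_for_guild("herbivore"),
            consumers=[make_consumer(-10.0, 6.5, guild="herbivore")],
        )
        res = fit_mixing(far, iterations=20_000, seed=9)
        assert res.out_of_polygon
        assert np.allclose(res.draws.sum(axis=1), 1.0, atol=1e-12)

    def test_equal_concentrations_match_concentration_free_model(self):
        s1 = make_pool("a", -15.0, 0.8, 4.0, 0.9)
        s2 = make_pool("b", -22.0, 0.6, -1.0, 0.7)
        from dataclasses import replace

        s1c = replace(s1, concentration={"C13": 0.4, "N15": 0.4})
        s2c = replace(s2, concentration={"C13": 0.4, "N15": 0.4})
        tdf = make_tdf(c=0.5, n=2.0, c_sd=0.5, n_sd=0.5)
        cons = make_consumer(-18.0, 2.5)
        plain = MixingProblem([s1, s2], tdf, [cons])
        conc = MixingProblem([s1c, s2c], tdf, [cons],
                             concentration_dependent=True)
        g1 = grid_posterior_mean(plain, resolution=0.005)
        g2 = grid_posterior_mean(conc, resolution=0.005)
        assert np.allclose(g1, g2, atol=1e-10)

    def test_unequal_concentrations_shift_the_posterior(self):
        from dataclasses import replace

        s1 = make_pool("a", -15.0, 0.8, 4.0, 0.9)
        s2 = make_pool("b", -22.0, 0.6, -1.0, 0.7)
        s1c = replace(s1, concentration={"C13": 0.9, "N15": 0.9})
        s2c = replace(s2, concentration={"C13": 0.1, "N15": 0.1})
        tdf = make_tdf(c=0.5, n=2.0, c_sd=0.5, n_sd=0.5)
        cons = make_consumer(-18.0, 2.5)
        plain = MixingProblem([s1, s2], tdf, [cons])
        conc = MixingProblem([s1c, s2c], tdf, [cons],
                             concentration_dependent=True)
        g1 = grid_posterior_mean(plain, resolution=0.005)
        g2 = grid_posterior_mean(conc, resolution=0.005)
        assert not np.allclose(g1, g2, atol=0.02)


# ---------------------------------------------------------------------------
# Analytic two-source mass balance
# ---------------------------------------------------------------------------

class TestAnalyticTwoSource:
    def test_seawater_vs_vent_pom_hand_value(self):
        """f_vent for a −21.0‰ consumer under the herbivore TDF:
        (−21.0 + 0.41 + 23.4) / (−18.2 + 23.4) = 2.81 / 5.2 ≈ 0.540."""
        from ventmix import kst_sources

        src = kst_sources()
        cons = make_consumer(-21.0, 6.0, guild="herbivore")
        f = analytic_two_source_point(
            cons, src["vent POM"], src["seawater POM"],
            tdf_for_guild("herbivore"), "C13",
        )
        assert f == pytest.approx(2.81 / 5.2, abs=1e-12)

    def test_consumer_at_either_end_member(self):
        s1 = make_pool("a", -15.0, 0.5, 5.0, 0.5)
        s2 = make_pool("b", -25.0, 0.5, -5.0, 0.5)
        tdf = make_tdf(c=1.0)
        at_s1 = make_consumer(-15.0 + 1.0, 0.0)
        at_s2 = make_consumer(-25.0 + 1.0, 0.0)
        assert analytic_two_source_point(at_s1, s1, s2, tdf, "C13") == pytest.approx(1.0)
        assert analytic_two_source_point(at_s2, s1, s2, tdf, "C13") == pytest.approx(0.0)

    def test_equal_means_rejected_with_message(self):
        s1 = make_pool("a", -20.0, 0.5, 5.0, 0.5)
        s2 = make_pool("b", -20.0, 0.5, -5.0, 0.5)
        with pytest.raises(ValidationError, match="equal"):
            analytic_two_source_point(
                make_consumer(-19.0, 1.0), s1, s2, make_tdf(), "C13"
            )

    def test_unclipped_outside_interval(self):
        s1 = make_pool("a", -15.0, 0.5, 5.0, 0.5)
        s2 = make_pool("b", -25.0, 0.5, -5.0, 0.5)
        f = analytic_two_source_point(
            make_consumer(-10.0, 0.0), s1, s2, make_tdf(), "C13"
        )
        assert f > 1.0
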