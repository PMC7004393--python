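"""EFM approximation of growth states, the O(mu) law, mu_ub and the
explicit growth-rate dependence of an allocation vector."""

import numpy as np
import pytest

from egmodes import (RateLaw, WholeCellModel, allocation_at_growth_rate,
                     approximating_efm, concentrations_from_allocation,
                     enumerate_efms, enumerate_egs, evaluate_rate_laws,
                     growth_scaling, growth_upper_bound,
                     precursor_consumption, proportional_composition_check,
                     two_enzyme_model)


class TestPrecursorConsumption:
    def test_equals_direct_matrix_multiply(self, fig_two_enzyme, probe_x):
        egs = enumerate_egs(fig_two_enzyme, probe_x, 0.4)[0]
        st = concentrations_from_allocation(fig_two_enzyme, egs.alpha,
                                            probe_x, 0.4)
        phi = precursor_consumption(fig_two_enzyme, st)
        assert phi == pytest.approx(fig_two_enzyme.M @ st.w)
        assert phi.shape == (1,)
        assert phi[0] > 0

    def test_zero_fluxes_zero_phi(self, fig_two_enzyme, probe_x):
        st = concentrations_from_allocation(
            fig_two_enzyme, np.array([0.1, 0.0, 0.2]), probe_x, 0.4)
        st.w = np.zeros(3)
        assert precursor_consumption(fig_two_enzyme, st) == \
            pytest.approx([0.0])


class TestApproximatingEFM:
    def test_nullspace_and_steady_state_identities(self, fig_two_enzyme,
                                                   probe_x):
        mu = 0.3
        for egs in enumerate_egs(fig_two_enzyme, probe_x, mu):
            approx = approximating_efm(fig_two_enzyme, egs)
            assert np.abs(approx.P_phi @ approx.V).max() < 1e-10
            assert approx.V[-1] == pytest.approx(1.0)
            # restricted steady state: P_phi [v; 1] = mu x
            st = concentrations_from_allocation(fig_two_enzyme, egs.alpha,
                                                probe_x, mu)
            v_D = st.v[list(approx.metabolic_columns)]
            lhs = approx.P_phi @ np.concatenate([v_D, [1.0]])
            assert lhs == pytest.approx(mu * probe_x, abs=1e-8)

    def test_error_linear_in_mu(self, fig_two_enzyme, probe_x):
        """The flux-vs-EFM deviation shrinks linearly with mu: halving
        mu roughly halves the error over a decade."""
        errors = {}
        for mu in (0.2, 0.1, 0.05, 0.025, 0.0125):
            egs = enumerate_egs(fig_two_enzyme, probe_x, mu)[0]
            errors[mu] = approximating_efm(fig_two_enzyme, egs).error
        mus = sorted(errors)
        for m1, m2 in zip(mus, mus[1:]):
            ratio = errors[m2] / errors[m1]
            assert 1.5 < ratio < 2.5

    def test_loglog_slope_near_one(self, fig_two_enzyme, probe_x):
        mus = np.geomspace(0.002, 0.2, 7)
        errs = [approximating_efm(
            fig_two_enzyme, enumerate_egs(fig_two_enzyme, probe_x, mu)[0]
        ).error for mu in mus]
        slope = np.polyfit(np.log(mus), np.log(errs), 1)[0]
        assert 0.8 < slope < 1.2

    def test_rank_deficient_case_reported(self, probe_x):
        """A network whose restricted stoichiometry loses rank is
        reported, not silently approximated."""
        # two metabolites, one reaction: P_D is 2x1, [P_D -phi] is 2x2
        # but phi parallel to P column makes it rank 1
        model = WholeCellModel(
            metabolites=["a", "b"], reactions=["r"],
            P=np.array([[1.0], [1.0]]),
            M=np.array([[0.5, 2.0], [0.5, 2.0]]),
            f=[RateLaw("constant", 6.0)],
            g=[RateLaw("constant", 4.0), RateLaw("constant", 2.0)],
            rho=np.array([0.2, 0.2]), sigma=np.array([0.4, 1.6]))
        egs_list = enumerate_egs(model, np.array([0.1, 0.1]), 0.2)
        for egs in egs_list:
            with pytest.raises(ValueError, match="rank"):
                approximating_efm(model, egs)
        if not egs_list:
            pytest.skip("no vertex at probe context")


class TestGrowthUpperBound:
    def test_direct_ratio_toy(self):
        """Single reaction with unit translation rates: the bound is
        supply/demand = P f / M."""
        model = WholeCellModel(
            metabolites=["s"], reactions=["imp"],
            P=np.array([[2.0]]), M=np.array([[2.0, 4.0]]),
            f=[RateLaw("constant", 2.0)],  # P f = 4
            g=[RateLaw("constant", 1.0), RateLaw("constant", 1.0)],
            rho=np.array([0.1]), sigma=np.array([0.3, 0.5]))
        alpha0 = np.array([1.0, 0.5])
        assert growth_upper_bound(model, alpha0, np.array([0.1])) == \
            pytest.approx(2.0)

    def test_invariant_to_allocation_rescaling(self, fig_two_enzyme,
                                               probe_x):
        egs = enumerate_egs(fig_two_enzyme, probe_x, 0.4)[0]
        mu1 = growth_upper_bound(fig_two_enzyme, egs.alpha, probe_x)
        mu2 = growth_upper_bound(fig_two_enzyme, 2 * egs.alpha, probe_x)
        assert mu1 == pytest.approx(mu2)

    def test_invalid_metabolite_rejected(self, fig_toxin_free):
        x = np.array([0.2, 0.2, 0.2, 0.2, 0.0])
        egs = enumerate_egs(fig_toxin_free, x, 0.3)[0]
        with pytest.raises(ValueError, match="no information"):
            growth_upper_bound(fig_toxin_free, egs.alpha, x, k=0)

    def test_brackets_dilution_free_feasibility(self, probe_x):
        """The bound is the supremum of the dilution-free system: just
        below it the mode exists, just above it does not."""
        model = two_enzyme_model(negligible_dilution=True)
        egs = enumerate_egs(model, probe_x, 0.5)[0]
        mu_ub = growth_upper_bound(model, egs.alpha, probe_x)

        def alive(mu):
            return any(s.support == egs.support
                       for s in enumerate_egs(model, probe_x, mu))

        assert alive(0.99 * mu_ub)
        assert not alive(1.01 * mu_ub)
        # bisect the true boundary and compare within 1e-4
        lo, hi = 0.99 * mu_ub, 1.01 * mu_ub
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if alive(mid) else (lo, mid)
        assert abs(lo - mu_ub) < 1e-4 * mu_ub


class TestGrowthScaling:
    @pytest.fixture()
    def dilution_free(self, probe_x):
        model = two_enzyme_model(negligible_dilution=True)
        egs = enumerate_egs(model, probe_x, 0.5)[0]
        return model, egs

    def test_h_monotone_and_shape(self, dilution_free):
        """H increases on (0, mu_ub) and H (mu_ub - mu)/mu^2 is the
        constant prefactor."""
        model, egs = dilution_free
        scal = growth_scaling(model, egs)
        grid = np.linspace(0.05, 0.95, 10) * scal.mu_ub
        H = np.array([scal.H(mu) for mu in grid])
        assert np.all(np.diff(H) > 0)
        shape = H * (scal.mu_ub - grid) / grid ** 2
        assert np.abs(shape - shape[0]).max() < 1e-12 * abs(shape[0])

    def test_common_ratio_across_metabolic_fractions(self, dilution_free,
                                                     probe_x):
        model, egs = dilution_free
        a1 = allocation_at_growth_rate(model, egs.alpha, probe_x, 0.3)
        a2 = allocation_at_growth_rate(model, egs.alpha, probe_x, 1.7)
        j = sorted(j for j in egs.support if j < model.n)
        ratios = a2[j] / a1[j]
        assert np.abs(ratios - ratios[0]).max() < 1e-10 * abs(ratios[0])

    def test_ribosome_row_exact(self, dilution_free, probe_x):
        model, egs = dilution_free
        _, gv = evaluate_rate_laws(model, probe_x)
        for mu in (0.2, 1.0, 4.0):
            alpha = allocation_at_growth_rate(model, egs.alpha, probe_x,
                                              mu)
            assert alpha[-1] * gv[-1] == pytest.approx(mu, abs=1e-10)

    def test_matches_fresh_dilution_free_solve(self, dilution_free,
                                               probe_x):
        """The closed form agrees with a fresh vertex enumeration of the
        dilution-free system at the new growth rate."""
        model, egs = dilution_free
        for mu in (0.1, 0.9, 3.0):
            pred = allocation_at_growth_rate(model, egs.alpha, probe_x, mu)
            fresh = [s for s in enumerate_egs(model, probe_x, mu)
                     if s.support == egs.support]
            assert fresh, f"mode lost at mu={mu}"
            assert np.abs(pred - fresh[0].alpha).max() < 1e-6

    def test_vanishes_quadratically_at_zero(self, dilution_free, probe_x):
        model, egs = dilution_free
        a1 = allocation_at_growth_rate(model, egs.alpha, probe_x, 1e-3)
        a2 = allocation_at_growth_rate(model, egs.alpha, probe_x, 2e-3)
        j = sorted(j for j in egs.support if j < model.n)
        assert a2[j] / a1[j] == pytest.approx(4.0, rel=1e-2)

    def test_mu_outside_range_rejected(self, dilution_free, probe_x):
        model, egs = dilution_free
        scal = growth_scaling(model, egs)
        with pytest.raises(ValueError, match="mu"):
            allocation_at_growth_rate(model, egs.alpha, probe_x,
                                      1.1 * scal.mu_ub)


class TestProportionalComposition:
    def test_single_state(self, fig_two_enzyme, probe_x):
        egs = enumerate_egs(fig_two_enzyme, probe_x, 0.4)[0]
        st = concentrations_from_allocation(fig_two_enzyme, egs.alpha,
                                            probe_x, 0.4)
        hs, dev = proportional_composition_check(fig_two_enzyme, [st])
        assert hs == pytest.approx([1.0])
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_proportional_columns_exact(self, fig_toxin_free):
        """All synthesis columns share one composition, so precursor
        consumption stays on a ray across growth rates."""
        model = fig_toxin_free
        x = np.array([0.2, 0.2, 0.2, 0.2, 0.0])
        states = []
        for mu in (0.1, 0.25, 0.4):
            egs = enumerate_egs(model, x, mu)[0]
            states.append(concentrations_from_allocation(model, egs.alpha,
                                                         x, mu))
        hs, dev = proportional_composition_check(model, states)
        assert dev < 1e-8
        assert np.all(np.diff(hs) > 0)  # consumption grows with mu

    def test_perturbed_composition_grows_residual(self, probe_x):
        """Breaking the common composition raises the reported
        deviation monotonically on average."""
        devs = []
        for eps in (0.0, 0.2, 0.4):
            model = WholeCellModel(
                metabolites=["a", "b"], reactions=["ra", "rb"],
                P=np.array([[1.0, 0.0], [0.0, 1.0]]),
                M=np.array([[1.0, 1.0, 4.0],
                            [1.0 + eps, 1.0, 4.0 - eps]]),
                f=[RateLaw("constant", 8.0), RateLaw("constant", 8.0)],
                g=[RateLaw("constant", 4.0), RateLaw("constant", 4.0),
                   RateLaw("constant", 1.5)],
                rho=np.array([0.1, 0.1]),
                sigma=np.array([0.25, 0.25, 1.0]))
            x = np.array([0.1, 0.1])
            states = []
            for mu in (0.1, 0.5):
                egs_list = enumerate_egs(model, x, mu)
                assert egs_list
                states.append(concentrations_from_allocation(
                    model, egs_list[0].alpha, x, mu))
            devs.append(proportional_composition_check(model, states)[1])
        assert devs[0] < 1e-10
        assert devs[0] <= devs[1] <= devs[2]


class TestEFMEnumeration:
    def test_parallel_routes_two_modes(self):
        """One metabolite fed by two reactions and drained by a biomass
        flux: exactly two elementary modes at unit biomass."""
        S = np.array([[1.0, 1.0, -1.0]])
        efms = enumerate_efms(S, fixed_flux_index=2)
        assert len(efms) == 2
        supports = sorted(tuple(np.nonzero(v > 1e-9)[0]) for v in efms)
        assert supports == [(0, 2), (1, 2)]

    def test_chain_single_mode(self):
        S = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        efms = enumerate_efms(S, fixed_flux_index=2)
        assert len(efms) == 1
        assert efms[0] == pytest.approx([1.0, 1.0, 1.0])
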