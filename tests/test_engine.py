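"""Interaction energies, the self-consistent sigma-potential, and
infinite-dilution activity coefficients."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from cosmoscreen import (
    ConvergenceError,
    EnergyParameters,
    SigmaGrid,
    SigmaProfile,
    capacity,
    capacity_from_gamma,
    hb_energy,
    ln_gamma_infinite_dilution,
    misfit_energy,
    pseudo_chemical_potential,
    solve_sigma_potential,
)
from cosmoscreen.engine import ActivityResult, interaction_energy_matrix
from cosmoscreen.synthetic import ProfileSpec, generate_profile


class TestMisfitEnergy:
    def test_complementary_charges_cost_nothing(self, params):
        assert misfit_energy(0.01, -0.01, params) == 0.0
        assert misfit_energy(0.0, 0.0, params) == 0.0

    def test_closed_form_value(self, params):
        # (alpha'/2)(0.01+0.01)^2 = 8419/2 * 4e-4
        assert misfit_energy(0.01, 0.01, params) == pytest.approx(
            8419.0 / 2 * (0.02) ** 2
        )

    def test_symmetric_and_nonnegative(self, params, rng):
        s = rng.uniform(-0.025, 0.025, 100)
        sp = rng.uniform(-0.025, 0.025, 100)
        np.testing.assert_allclose(
            misfit_energy(s, sp, params), misfit_energy(sp, s, params)
        )
        assert np.all(misfit_energy(s, sp, params) >= 0)


class TestHBEnergy:
    def test_zero_without_donor_acceptor_pair(self, params):
        assert hb_energy(0.0, 0.0, params) == 0.0
        assert hb_energy(0.005, -0.005, params) == 0.0  # below threshold
        assert hb_energy(0.02, 0.02, params) == 0.0  # two acceptors

    def test_closed_form_value(self, params):
        expected = 85580.0 * (0.02 - 0.0084) * (-0.02 + 0.0084)
        assert hb_energy(0.02, -0.02, params) == pytest.approx(expected)
        assert expected < 0

    def test_symmetric_and_nonpositive(self, params, rng):
        s = rng.uniform(-0.025, 0.025, 100)
        sp = rng.uniform(-0.025, 0.025, 100)
        np.testing.assert_allclose(
            hb_energy(s, sp, params), hb_energy(sp, s, params)
        )
        assert np.all(hb_energy(s, sp, params) <= 0)


def toy_profile(grid, weights, compound_id="toy"):
    p = np.asarray(weights, dtype=float)
    return SigmaProfile(grid, p, compound_id)


class TestSigmaPotentialSolver:
    def test_zero_interaction_gives_zero_potential(self, library):
        null = EnergyParameters(alpha_prime=0.0, c_hb=0.0)
        pot = solve_sigma_potential(library["EPA"], null)
        np.testing.assert_allclose(pot.mu, 0.0, atol=1e-10)

    def test_symmetric_profile_gives_symmetric_potential(self, grid, params):
        prof = generate_profile(
            ProfileSpec(100.0, 0, peaks=((0.0, 0.006, 1.0),), seed=0), grid
        )
        p_sym = 0.5 * (prof.p + prof.p[::-1])
        pot = solve_sigma_potential(SigmaProfile(grid, p_sym, "sym"), params)
        np.testing.assert_allclose(pot.mu, pot.mu[::-1], atol=1e-8)

    def test_residual_below_tolerance(self, library, params):
        for cid in ("EPA", "[EMIM]", "[SO4]"):
            pot = solve_sigma_potential(library[cid], params, tol=1e-8)
            assert pot.residual < 1e-8

    def test_matches_brute_force_on_small_grid(self, params):
        # independent route: generic root-finder on the dense equations.
        # The toy grid stays inside ±0.012 so hydrogen bonding is active
        # but the root is unique and well conditioned; at much larger
        # |sigma| the saturated donor/acceptor wings leave a numerically
        # flat valley of machine-precision roots.
        grid = SigmaGrid(-0.012, 0.012, 5)
        prof = toy_profile(grid, [0.5, 1.0, 4.0, 2.0, 1.5])
        pot = solve_sigma_potential(prof, params, tol=1e-10)

        p = prof.normalize().p
        beta = params.a_eff / params.RT
        E = interaction_energy_matrix(grid.centers, params)

        def residual(mu):
            rhs = np.array([
                -np.log(np.sum(p * np.exp(beta * (mu - E[i])))) / beta
                for i in range(5)
            ])
            return mu - rhs

        mu_bf = fsolve(residual, np.zeros(5), xtol=1e-13)
        np.testing.assert_allclose(pot.mu, mu_bf, atol=1e-8)

    def test_nonconvergence_carries_diagnostics(self, library, params):
        with pytest.raises(ConvergenceError) as exc:
            solve_sigma_potential(library["EPA"], params, tol=1e-30, max_iter=3)
        assert exc.value.iterations >= 1
        assert np.isfinite(exc.value.residual)


class TestPseudoChemicalPotential:
    def test_zero_area_solute(self, grid, params, library):
        pot = solve_sigma_potential(library["[Cl]"], params)
        empty = SigmaProfile(grid, np.zeros(grid.n_bins), "none")
        assert pseudo_chemical_potential(empty, pot) == 0.0

    def test_delta_solute_linearity(self, grid, params, library):
        pot = solve_sigma_potential(library["[Cl]"], params)
        k, area = 17, 42.0
        p = np.zeros(grid.n_bins)
        p[k] = area
        delta = SigmaProfile(grid, p, "delta")
        assert pseudo_chemical_potential(delta, pot) == pytest.approx(
            area * pot.mu[k]
        )

    def test_equals_direct_summation(self, params, library):
        pot = solve_sigma_potential(library["[EMIM]"], params)
        epa = library["EPA"]
        direct = sum(a * m for a, m in zip(epa.p, pot.mu))
        assert pseudo_chemical_potential(epa, pot) == pytest.approx(direct)

    def test_grid_mismatch_rejected(self, params, library):
        pot = solve_sigma_potential(library["[Cl]"], params)
        other = generate_profile(ProfileSpec(10.0, 0, seed=0),
                                 SigmaGrid(-0.03, 0.03, 31))
        with pytest.raises(ValueError, match="grid"):
            pseudo_chemical_potential(other, pot)


class TestActivityCoefficient:
    def test_self_solvation_identity(self, library, params):
        res = ln_gamma_infinite_dilution(library["EPA"], library["EPA"], params)
        assert res.gamma_inf == pytest.approx(1.0, abs=1e-6)

    def test_zero_interaction_limit(self, library):
        null = EnergyParameters(alpha_prime=0.0, c_hb=0.0)
        res = ln_gamma_infinite_dilution(library["EPA"], library["[Cl]"], null)
        assert res.gamma_inf == pytest.approx(1.0, abs=1e-8)

    def test_matches_end_to_end_brute_force(self, params):
        grid = SigmaGrid(-0.012, 0.012, 5)
        solute = toy_profile(grid, [0.5, 1.0, 3.0, 1.0, 0.5], "X")
        solvent = toy_profile(grid, [2.0, 1.0, 1.0, 1.0, 2.0], "S")
        res = ln_gamma_infinite_dilution(solute, solvent, params, tol=1e-12)

        beta = params.a_eff / params.RT
        E = interaction_energy_matrix(grid.centers, params)

        def solve_bf(profile):
            p = profile.p / profile.p.sum()

            def residual(mu):
                rhs = np.array([
                    -np.log(np.sum(p * np.exp(beta * (mu - E[i])))) / beta
                    for i in range(5)
                ])
                return mu - rhs

            return fsolve(residual, np.zeros(5), xtol=1e-13)

        mu_s = solve_bf(solvent)
        mu_x = solve_bf(solute)
        ln_g = (solute.p @ mu_s - solute.p @ mu_x) / params.RT
        assert res.ln_gamma_inf == pytest.approx(ln_g, abs=1e-8)

    def test_combinatorial_self_term_vanishes(self, library, params):
        res = ln_gamma_infinite_dilution(
            library["EPA"], library["EPA"], params,
            combinatorial=True, solute_volume=500.0, solvent_volume=500.0,
        )
        assert res.gamma_inf == pytest.approx(1.0, abs=1e-6)

    def test_combinatorial_requires_volumes(self, library, params):
        with pytest.raises(ValueError, match="volume"):
            ln_gamma_infinite_dilution(
                library["EPA"], library["[Cl]"], params, combinatorial=True
            )

    def test_grid_refinement_stability(self, params):
        # doubling resolution changes ln gamma by < 1% for smooth profiles
        def gaussian_profile(grid, area, centers_widths_weights, cid):
            p = np.zeros(grid.n_bins)
            for c, w, wt in centers_widths_weights:
                p += wt * np.exp(-0.5 * ((grid.centers - c) / w) ** 2)
            return SigmaProfile(grid, p * area / p.sum(), cid)

        results = []
        for n_bins in (51, 101):
            grid = SigmaGrid(-0.025, 0.025, n_bins)
            solute = gaussian_profile(grid, 300.0, [(0.0, 0.005, 1.0)], "X")
            solvent = gaussian_profile(
                grid, 150.0, [(0.004, 0.005, 0.5), (-0.004, 0.005, 0.5)], "S"
            )
            res = ln_gamma_infinite_dilution(solute, solvent, params)
            results.append(res.ln_gamma_inf)
        assert results[1] == pytest.approx(results[0], rel=0.01)


class TestCapacity:
    @pytest.mark.parametrize(
        "gamma, expected",
        [
            (9.52e-10, 1.05e9),   # reported shortlist arithmetic
            (6.61e-4, 1.513e3),
            (1.0, 1.0),
        ],
    )
    def test_reciprocal_relation(self, gamma, expected):
        assert capacity_from_gamma(gamma) == pytest.approx(expected, rel=5e-3)

    def test_capacity_times_gamma_is_one(self, library, params):
        res = ln_gamma_infinite_dilution(library["EPA"], library["[EMIM]"], params)
        assert res.capacity_inf * res.gamma_inf == pytest.approx(1.0, rel=1e-15)

    def test_monotone_decreasing_in_gamma(self):
        gammas = [1e-6, 1e-3, 1.0, 10.0]
        caps = [capacity_from_gamma(g) for g in gammas]
        assert caps == sorted(caps, reverse=True)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            capacity_from_gamma(0.0)
        bad = ActivityResult("x", "s", 298.15, 0.0, -1.0, 0.0)
        with pytest.raises(ValueError):
            capacity(bad)


class TestPhysicalTrends:
    @staticmethod
    def _wing_solvent(grid, wing_weight):
        # a small non-polar weight is always kept: with zero central mass
        # the purely bipartite ensemble has no finite sigma-potential
        return generate_profile(
            ProfileSpec(
                150.0, 0,
                peaks=((0.018, 0.002, wing_weight),
                       (-0.018, 0.002, wing_weight),
                       (0.0, 0.003, 1.0 - 2 * wing_weight)),
                seed=6,
            ),
            grid,
        )

    def test_self_associating_solvent_expels_nonpolar_solute(self, params):
        """As the solvent's donor/acceptor wings grow it hydrogen-bonds
        with itself, and a mostly non-polar solute loses capacity — the
        solvophobic analogue of the hydrophobic effect."""
        grid = SigmaGrid()
        solute = generate_profile(
            ProfileSpec(200.0, 0,
                        peaks=((0.0, 0.0035, 0.9), (-0.015, 0.002, 0.1)),
                        seed=5),
            grid,
        )
        caps = []
        for wing_weight in (0.05, 0.15, 0.3, 0.45):
            res = ln_gamma_infinite_dilution(
                solute, self._wing_solvent(grid, wing_weight), params
            )
            caps.append(res.capacity_inf)
        assert all(b < a for a, b in zip(caps, caps[1:]))

    def test_donor_solute_preferred_over_nonpolar_in_accepting_solvent(
        self, params
    ):
        """Complementarity: relative to an all-non-polar solute of the
        same area, a solute carrying a donor shoulder is increasingly
        favored as the solvent's hydrogen-bonding wings grow."""
        grid = SigmaGrid()
        nonpolar = generate_profile(
            ProfileSpec(200.0, 0, peaks=((0.0, 0.0035, 1.0),), seed=5), grid
        )
        donor = generate_profile(
            ProfileSpec(200.0, 0,
                        peaks=((0.0, 0.0035, 0.9), (-0.015, 0.002, 0.1)),
                        seed=5),
            grid,
        )
        gaps = []
        for wing_weight in (0.05, 0.15, 0.3, 0.45):
            solvent = self._wing_solvent(grid, wing_weight)
            g_d = ln_gamma_infinite_dilution(donor, solvent, params)
            g_n = ln_gamma_infinite_dilution(nonpolar, solvent, params)
            gaps.append(g_d.ln_gamma_inf - g_n.ln_gamma_inf)
        assert all(b < a for a, b in zip(gaps, gaps[1:]))
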