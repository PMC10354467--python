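import numpy as np
import pytest

from tissuefit.grids import DensityField, Grid, MultiSpeciesState
from tissuefit.params import ModelParams
from tissuefit.solver import (
    front_position,
    radial_profile,
    sample_field,
    solve,
    stable_dt,
    step,
    wave_speed_estimate,
)


def _random_radial_state(nr=5, ns=2, seed=0, h=0.1):
    rng = np.random.default_rng(seed)
    return MultiSpeciesState(Grid.radial(nr * h, h), rng.uniform(0, 1000, (ns, nr)))


def _dense_oracle_radial(rho, h, dt, Dint, r, K, m):
    """Independent straight-from-the-equations porous update on a tiny grid."""
    ns, nr = rho.shape
    tot = rho.sum(axis=0)
    P = Dint * tot ** (m - 1)
    new = rho.copy()
    for i in range(ns):
        F = np.zeros(nr + 1)
        for k in range(1, nr):
            v = -(P[k] - P[k - 1]) / h
            F[k] = (rho[i, k - 1] if v > 0 else rho[i, k]) * v
        for k in range(nr):
            rc = (k + 0.5) * h
            new[i, k] -= dt * ((k + 1) * h * F[k + 1] - k * h * F[k]) / (rc * h)
            new[i, k] += dt * r * rho[i, k] * (1 - tot[k] / K)
    return new


class TestStep:
    def test_matches_dense_oracle(self):
        state = _random_radial_state()
        p = ModelParams("porous", 1.18, 0.2, 5319.0)
        dt = 0.5 * stable_dt(state, p)
        expected = _dense_oracle_radial(
            state.densities, state.grid.h, dt, p.D_internal, p.r, p.K, p.m
        )
        out = step(state, p, dt)
        np.testing.assert_allclose(out.densities, expected, rtol=0, atol=1e-13)

    def test_uniform_carrying_capacity_is_steady(self):
        g = Grid.cartesian((0, 1), (0, 1), 0.1)
        p = ModelParams("porous", 1.18, 0.2, 5319.0)
        state = MultiSpeciesState(g, np.full((1, *g.shape), p.K))
        out = step(state, p, 0.5 * stable_dt(state, p))
        np.testing.assert_allclose(out.densities, state.densities, atol=1e-9)

    def test_rejects_unstable_dt_with_bound(self):
        state = _random_radial_state()
        p = ModelParams("porous", 1.18, 0.2, 5319.0)
        bound = stable_dt(state, p)
        with pytest.raises(ValueError, match="admissible"):
            step(state, p, 2 * bound)

    def test_mass_conserved_without_growth(self):
        p = ModelParams("porous", 1.18, 0.0, 5319.0)
        state = _random_radial_state(nr=40, ns=2, seed=1, h=0.05)
        m0 = state.masses()
        dt = stable_dt(state, p)
        for _ in range(200):
            state = step(state, p, dt)
        np.testing.assert_allclose(state.masses(), m0, rtol=1e-11)


class TestSolve:
    def test_heat_kernel_limit_under_refinement(self):
        # linear family, r = 0: Gaussian variance grows by 2 D t
        p = ModelParams("linear", 1e6, 0.0, 1000.0)  # D_int = 1 mm^2/h
        s0sq, T = 0.5, 1.0
        errs = []
        for h in (0.1, 0.05):
            g = Grid.cartesian((-8, 8), (0, h), h)
            x = g.cell_centers()[0][0]
            rho0 = np.exp(-(x**2) / (2 * s0sq)) / np.sqrt(2 * np.pi * s0sq)
            out = solve(MultiSpeciesState(g, rho0[None, None, :]), p, [T])[0]
            ssq = s0sq + 2 * p.D_internal * T
            exact = np.exp(-(x**2) / (2 * ssq)) / np.sqrt(2 * np.pi * ssq)
            errs.append(np.sum(np.abs(out.densities[0, 0] - exact)) * h)
        assert errs[1] < errs[0]
        assert errs[1] < 5e-3

    def test_barenblatt_profile_under_refinement(self):
        # porous m=2, r=0 is d_t rho = (D/2) Lap(rho^2); self-similar source
        # solution u(x,s) = s^(-1/3) (C - x^2/(12 s^(2/3)))_+ with s = D t / 2
        p = ModelParams("porous", 1e6, 0.0, 1000.0)  # D_int = 1
        C, s0, s1 = 1.0, 1.0, 3.0
        t1 = 2 * (s1 - s0) / p.D_internal

        def barenblatt(x, s):
            return np.maximum(C - x**2 / (12 * s ** (2 / 3)), 0.0) / s ** (1 / 3)

        errs = []
        for h in (0.08, 0.04):
            g = Grid.cartesian((-6, 6), (0, h), h)
            x = g.cell_centers()[0][0]
            st0 = MultiSpeciesState(g, barenblatt(x, s0)[None, None, :])
            out = solve(st0, p, [t1])[0]
            errs.append(np.sum(np.abs(out.densities[0, 0] - barenblatt(x, s1))) * h)
        assert errs[1] < errs[0]
        assert errs[1] < 2e-2

    def test_vanishing_second_species_reduces_to_single(self, porous_modes):
        g = Grid.radial(2.0, 0.02)
        r = g.cell_centers()
        rho = np.clip((1.0 - (r - g.h / 2)) / g.h, 0, 1) * 2000.0
        two = MultiSpeciesState(g, np.stack([rho, np.zeros_like(rho)]))
        one = MultiSpeciesState(g, rho[None, :])
        out2 = solve(two, porous_modes, [5.0, 10.0])
        out1 = solve(one, porous_modes, [5.0, 10.0])
        for a, b in zip(out2, out1):
            np.testing.assert_allclose(a.densities[0], b.densities[0], atol=1e-12)
            assert np.all(a.densities[1] == 0)

    def test_comparison_principle_linear(self):
        rng = np.random.default_rng(7)
        g = Grid.cartesian((0, 1), (0, 1), 0.05)
        lo = rng.uniform(0, 500, (1, *g.shape))
        hi = lo + rng.uniform(0, 300, (1, *g.shape))
        p = ModelParams("linear", 1000.0, 0.0, 1000.0)
        a = solve(MultiSpeciesState(g, lo), p, [5.0])[0]
        b = solve(MultiSpeciesState(g, hi), p, [5.0])[0]
        assert np.all(a.densities <= b.densities + 1e-12)

    def test_positivity_random_states(self, porous_modes):
        rng = np.random.default_rng(11)
        for _ in range(5):
            g = Grid.cartesian((0, 1), (0, 1), 0.05)
            rho = rng.uniform(0, 6000, (2, *g.shape))
            rho[:, :, 10:] = 0.0  # include a vacuum region
            out = solve(MultiSpeciesState(g, rho), porous_modes, [0.5, 2.0])
            for stt in out:
                assert stt.densities.min() >= 0.0

    def test_rejects_non_monotone_times(self, porous_modes):
        st0 = _random_radial_state()
        with pytest.raises(ValueError):
            solve(st0, porous_modes, [2.0, 1.0])

    def test_radial_and_cartesian_agree_for_circular_expansion(self, porous_modes):
        from tissuefit.observations import disc_state

        T = 16.0
        rad = solve(disc_state(Grid.radial(2.8, 0.01), 2600.0, 1.7), porous_modes, [T])[0]
        car = solve(
            disc_state(Grid.cartesian((-2.8, 2.8), (-2.8, 2.8), 0.025), 2600.0, 1.7),
            porous_modes,
            [T],
        )[0]
        bins, prof2d = radial_profile(car.field(0), center=(0.0, 0.0))
        prof1d = sample_field(rad.field(0), bins)
        # mass-weighted L1 difference small relative to the total mass
        diff = np.sum(np.abs(prof2d - prof1d) * 2 * np.pi * bins * 0.025)
        assert diff / rad.field(0).mass() < 0.03


class TestDiagnostics:
    def test_front_undefined_for_empty_field(self):
        g = Grid.radial(2.0, 0.02)
        f = DensityField(g, np.zeros(g.shape))
        assert front_position(f, 10.0) is None

    def test_front_of_indicator_disc(self):
        g = Grid.radial(3.0, 0.01)
        r = g.cell_centers()
        f = DensityField(g, np.where(r <= 1.7, 2600.0, 0.0))
        pos = front_position(f, 10.0)
        assert abs(pos - 1.7) <= g.h

    def test_radial_profile_matches_brute_force(self):
        rng = np.random.default_rng(3)
        g = Grid.cartesian((-1, 1), (-1, 1), 0.05)
        f = DensityField(g, rng.uniform(0, 100, g.shape))
        bins, prof = radial_profile(f, center=(0.0, 0.0))
        X, Y = g.cell_centers()
        dist = np.hypot(X, Y)
        for b, value in zip(bins, prof):
            mask = (dist >= b - g.h / 2) & (dist < b + g.h / 2)
            if mask.sum():
                assert value == pytest.approx(f.values[mask].mean(), abs=1e-12)

    def test_radial_profile_mass_within_one_percent(self):
        g = Grid.cartesian((-2, 2), (-2, 2), 0.02)
        X, Y = g.cell_centers()
        vals = np.where(np.hypot(X, Y) <= 1.5, 1000.0, 0.0)
        f = DensityField(g, vals)
        bins, prof = radial_profile(f, center=(0.0, 0.0))
        binned_mass = np.sum(prof * 2 * np.pi * bins * g.h)
        assert binned_mass == pytest.approx(f.mass(), rel=0.01)

    def test_profile_of_radially_symmetric_field(self):
        g = Grid.cartesian((-2, 2), (-2, 2), 0.04)
        X, Y = g.cell_centers()
        vals = np.exp(-np.hypot(X, Y) ** 2)
        bins, prof = radial_profile(DensityField(g, vals), center=(0.0, 0.0))
        inner = bins < 1.5
        assert np.max(np.abs(prof[inner] - np.exp(-bins[inner] ** 2))) < 0.02

    def test_wave_speed_of_exact_line(self):
        g = Grid.radial(5.0, 0.01)
        states = []
        speed = 0.03
        for t in (10.0, 20.0, 30.0):
            r = g.cell_centers()
            edge = 1.0 + speed * t
            states.append(
                MultiSpeciesState(g, np.where(r <= edge, 100.0, 0.0)[None, :], t)
            )
        est = wave_speed_estimate(states, 10.0)
        assert est == pytest.approx(speed, abs=2 * 0.01 / 20.0)

    def test_rejects_center_outside_domain(self):
        g = Grid.cartesian((0, 1), (0, 1), 0.1)
        with pytest.raises(ValueError):
            radial_profile(DensityField(g, np.zeros(g.shape)), center=(5.0, 5.0))
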