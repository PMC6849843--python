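"""Mean-field and lattice grazing-model tests."""

import dataclasses

import numpy as np
import pytest

from sewscape import (
    ModelParams,
    NoFoldError,
    drift,
    equilibria,
    fold_points,
    gradient_snapshots,
    hysteresis_sweep,
    integrate_meanfield,
    pulse_recovery,
    simulate_lattice,
)

P = ModelParams()  # r=1, K=100, B0=10


def poly_roots_oracle(c, p):
    """Positive equilibria via an independently assembled cubic."""
    # r(1 - B/K)(B^2 + B0^2) = c B
    B = np.polynomial.Polynomial([0, 1])
    poly = p.r * (1 - B / p.K) * (B**2 + p.B0**2) - c * B
    roots = poly.roots()
    return sorted(
        float(r.real) for r in roots if abs(r.imag) < 1e-9 and 0 < r.real <= p.K
    )


class TestDrift:
    def test_extinction_is_equilibrium(self):
        for c in (0.0, 5.0, 50.0):
            assert drift(0.0, c, P) == 0.0

    def test_logistic_equilibrium_without_grazing(self):
        assert drift(100.0, 0.0, P) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # r B (1-B/K) - c B^2/(B0^2+B^2) at B=80, c=20:
        # 1*80*0.2 - 20*6400/6500 = 16 - 19.6923... = -3.6923...
        assert drift(80.0, 20.0, P) == pytest.approx(16 - 20 * 6400 / 6500)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            drift(-1.0, 10.0, P)


class TestEquilibria:
    def test_no_grazing(self):
        eq = equilibria(0.0, P)
        assert [(round(b, 9), s) for b, s in eq] == [(0.0, False), (100.0, True)]

    def test_bistable_point_matches_polynomial_oracle(self):
        eq = equilibria(22.0, P)
        pos = [b for b, _ in eq if b > 0]
        assert len(pos) == 3
        assert pos == pytest.approx(poly_roots_oracle(22.0, P), rel=1e-8)
        # stability alternates stable/unstable/stable along positive roots
        flags = [s for b, s in eq if b > 0]
        assert flags == [True, False, True]

    def test_collapsed_regime_single_stable_root(self):
        eq = equilibria(30.0, P)
        stable_pos = [b for b, s in eq if s and b > 0]
        assert len(stable_pos) == 1
        assert stable_pos[0] == pytest.approx(poly_roots_oracle(30.0, P)[0])

    def test_bistability_window_matches_fold_points(self):
        c_lo, c_up = fold_points(P)
        for c in np.linspace(c_lo + 0.2, c_up - 0.2, 7):
            stable = [b for b, s in equilibria(c, P) if s and b > 0]
            assert len(stable) == 2, f"expected bistability at c={c}"
        for c in (c_lo - 0.5, c_up + 0.5):
            stable = [b for b, s in equilibria(c, P) if s and b > 0]
            assert len(stable) == 1


class TestFoldPoints:
    def test_printed_bistable_window(self):
        c_lo, c_up = fold_points(P)
        assert round(c_lo) == 18
        assert round(c_up) == 26
        # exact decimals from the 1-D extremum characterization
        assert c_lo == pytest.approx(17.872, abs=1e-3)
        assert c_up == pytest.approx(26.044, abs=1e-3)

    def test_extrema_oracle(self):
        # independent oracle: dense scan of c(B) for its interior extrema
        B = np.linspace(1e-3, P.K - 1e-3, 200_001)
        c_of_b = P.r * (1 - B / P.K) * (B**2 + P.B0**2) / B
        interior = c_of_b[1:-1]
        is_min = (interior < c_of_b[:-2]) & (interior < c_of_b[2:])
        is_max = (interior > c_of_b[:-2]) & (interior > c_of_b[2:])
        c_lo, c_up = fold_points(P)
        assert c_lo == pytest.approx(interior[is_min].min(), abs=1e-5)
        assert c_up == pytest.approx(interior[is_max].max(), abs=1e-5)

    def test_scaling_symmetry(self):
        lam = 0.1
        scaled = ModelParams(K=P.K * lam, B0=P.B0 * lam)
        ref = fold_points(P)
        got = fold_points(scaled)
        assert got[0] == pytest.approx(ref[0] * lam, rel=1e-9)
        assert got[1] == pytest.approx(ref[1] * lam, rel=1e-9)

    def test_monotone_response_reports_no_fold(self):
        # large B0 relative to K: c(B) monotone, no tipping point
        with pytest.raises(NoFoldError):
            fold_points(ModelParams(B0=90.0))


class TestMeanField:
    def test_stays_at_stable_equilibrium(self):
        b_star = max(b for b, s in equilibria(20.0, P) if s)
        traj = integrate_meanfield(
            dataclasses.replace(P, c=20.0), b_star, 50.0
        )
        assert np.allclose(traj.states, b_star, rtol=1e-5)

    def test_converges_to_high_branch(self):
        b_star = max(b for b, s in equilibria(20.0, P) if s)
        traj = integrate_meanfield(dataclasses.replace(P, c=20.0), 90.0, 100.0)
        assert traj.final == pytest.approx(b_star, rel=1e-5)

    def test_collapse_beyond_upper_fold(self):
        low = min(b for b, s in equilibria(28.0, P) if s and b > 0)
        traj = integrate_meanfield(dataclasses.replace(P, c=28.0), 90.0, 300.0)
        assert traj.final == pytest.approx(low, rel=1e-4)

    def test_nonnegativity(self):
        traj = integrate_meanfield(dataclasses.replace(P, c=50.0), 5.0, 50.0)
        assert np.all(np.asarray(traj.states) >= 0)


class TestHysteresis:
    def test_branch_switch_points_match_folds(self):
        table = hysteresis_sweep(P, list(range(10, 31)))
        up = table[table.direction == "up"].set_index("c")["biomass"]
        down = table[table.direction == "down"].set_index("c")["biomass"]
        # up branch stays high through c=26, collapses at 27
        assert up.loc[26] > 50
        assert up.loc[27] < 20
        # down branch stays low through c=18, recovers at 17
        assert down.loc[18] < 20
        assert down.loc[17] > 50

    def test_no_hysteresis_below_lower_fold(self):
        table = hysteresis_sweep(P, [5, 8, 11, 14])
        up = table[table.direction == "up"].set_index("c")["biomass"]
        down = table[table.direction == "down"].set_index("c")["biomass"]
        assert np.allclose(up.values, down.loc[up.index].values, rtol=1e-6)


class TestLattice:
    def test_deterministic_equilibrium_is_fixed_point(self):
        p = ModelParams(L=16, sigma=0.0, D=0.0, c=10.0, seed=1)
        b_star = max(b for b, s in equilibria(10.0, p) if s)
        traj = simulate_lattice(p, b_star, 5.0)
        assert np.allclose(traj.final.values, b_star, atol=1e-8)

    def test_uniform_field_stays_uniform_with_dispersal(self):
        p = ModelParams(L=16, sigma=0.0, D=0.5, c=15.0, seed=1)
        traj = simulate_lattice(p, 80.0, 5.0)
        assert np.ptp(traj.final.values) == 0.0

    def test_seed_determinism(self):
        p = ModelParams(L=16, sigma=1.0, c=10.0, seed=7)
        a = simulate_lattice(p, 90.0, 2.0)
        b = simulate_lattice(p, 90.0, 2.0)
        assert np.array_equal(a.final.values, b.final.values)

    def test_meanfield_consistency_without_noise(self):
        p = ModelParams(L=16, sigma=0.0, D=0.3, c=18.0, dt=0.005, seed=0)
        traj = simulate_lattice(p, 60.0, 10.0)
        mf = integrate_meanfield(dataclasses.replace(p, c=18.0), 60.0, 10.0)
        # lattice stays uniform; its mean must track the mean-field ODE
        lattice_final = float(traj.final.values.mean())
        assert lattice_final == pytest.approx(float(mf.final), rel=5e-3)

    def test_stochastic_mean_matches_equilibrium(self):
        b_star = max(b for b, s in equilibria(10.0, P) if s)
        means = []
        for seed in range(10):
            p = ModelParams(L=32, sigma=1.0, D=0.1, c=10.0, seed=seed)
            traj = simulate_lattice(p, b_star, 20.0)
            means.append(traj.final.values.mean())
        assert np.mean(means) == pytest.approx(b_star, rel=0.02)

    def test_nonnegative_biomass_under_strong_noise(self):
        p = ModelParams(L=16, sigma=20.0, c=20.0, seed=3)
        traj = simulate_lattice(p, 5.0, 5.0)
        for g in traj.states:
            assert np.all(g.values >= 0)

    def test_stability_guard(self):
        with pytest.raises(ValueError, match="unstable"):
            ModelParams(dt=0.5, D=1.0)


class TestGradientSnapshots:
    def test_deterministic_high_equilibrium_snapshot(self):
        p = ModelParams(L=16, sigma=0.0, D=0.1, seed=0)
        series = gradient_snapshots(p, [5.0], burn_in=5.0)
        b_star = max(b for b, s in equilibria(5.0, p) if s)
        assert np.allclose(series.grids[0].values, b_star, atol=1e-6)

    def test_series_reproducible(self):
        p = ModelParams(L=16, sigma=1.0, seed=11)
        a = gradient_snapshots(p, [5.0, 15.0], burn_in=2.0)
        b = gradient_snapshots(p, [5.0, 15.0], burn_in=2.0)
        for ga, gb in zip(a.grids, b.grids):
            assert np.array_equal(ga.values, gb.values)

    def test_beyond_fold_warns_and_collapses(self):
        p = ModelParams(L=16, sigma=0.0, seed=0)
        with pytest.warns(UserWarning, match="beyond the upper fold"):
            series = gradient_snapshots(p, [28.0], burn_in=50.0)
        assert series.grids[0].values.mean() < 20


class TestPulse:
    def test_zero_pulse_is_flat(self):
        res = pulse_recovery(P, 10.0, delta_c=0.0)
        states = np.asarray(res.trajectory.states)
        assert np.allclose(states, res.equilibrium, atol=1e-4 * P.K)
        assert not res.collapsed

    def test_recovery_duration_grows_with_grazing(self):
        # critical slowing down, read directly off the trajectories
        def recovery_span(c):
            res = pulse_recovery(P, c)
            return res.trajectory.times[-1]

        assert recovery_span(20.0) > recovery_span(10.0)

    def test_collapse_flagged_near_fold(self):
        res = pulse_recovery(P, 25.9, delta_c=10.0, pulse_duration=2.0)
        assert res.collapsed
        assert float(res.trajectory.final) < 30.0
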