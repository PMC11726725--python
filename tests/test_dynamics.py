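"""Forward-Euler scenario integration, forcing terms and Lyapunov diagnostics."""

import numpy as np
import pytest

from ribostat import (
    Forcing,
    MixtureState,
    RateConstants,
    Totals,
    design_concentrations,
    full_equilibrium,
    integrate,
    jump_noise_step,
    lyapunov_derivative,
    lyapunov_value,
    state_from_free,
)
from ribostat.errors import InvalidParameterError
from conftest import random_parameter_set


def uncomplexed(totals: Totals) -> MixtureState:
    return state_from_free(totals.cA, totals.cY, totals)


def random_feasible_state(totals: Totals, rng: np.random.Generator) -> MixtureState:
    """A random state with the same conserved totals."""
    for _ in range(100):
        A = totals.cA * rng.uniform(0.0, 1.0)
        Y = totals.cY * rng.uniform(0.0, 1.0)
        try:
            return state_from_free(A, Y, totals)
        except Exception:
            continue
    return uncomplexed(totals)


class TestIntegrate:
    def test_relaxation_to_spreadsheet_equilibrium(
        self, unit_rates, spreadsheet_totals, spreadsheet_equilibrium
    ):
        """From the uncomplexed start the mixture settles at the designed
        free-agent level within a few hundred Euler steps."""
        traj = integrate(
            uncomplexed(spreadsheet_totals), unit_rates,
            dt=0.001, n_steps=5000,
        )
        eq = spreadsheet_equilibrium
        # early approach: essentially equilibrated after ~200 steps
        assert abs(traj.A[300] - eq.x) < 0.01
        # long-run agreement with the static solver
        final = traj.final_state()
        assert max(
            abs(a - b) for a, b in zip(final.as_tuple(), eq.state.as_tuple())
        ) < 1e-3

    def test_equilibrium_is_stationary(self, unit_rates, spreadsheet_equilibrium):
        traj = integrate(
            spreadsheet_equilibrium.state, unit_rates, dt=0.001, n_steps=500
        )
        assert np.max(np.abs(traj.A - traj.A[0])) < 1e-10

    def test_conservation_along_unforced_trajectories(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            rates, totals = random_parameter_set(rng)
            traj = integrate(
                random_feasible_state(totals, rng), rates, dt=0.001, n_steps=2000
            )
            # drift <= 1e-9 per unit time over 2 time units
            for series, ref in ((traj.cA, totals.cA), (traj.cX, totals.cX),
                                (traj.cY, totals.cY)):
                assert np.max(np.abs(series - ref)) <= 2e-9 * max(1.0, ref)

    def test_convergence_to_static_equilibrium(self):
        """Long-time Euler limit equals the root-finding equilibrium."""
        rng = np.random.default_rng(43)
        for _ in range(20):
            rates, totals = random_parameter_set(rng)
            eq = full_equilibrium(rates, totals)
            state = random_feasible_state(totals, rng)
            for _chunk in range(10):
                traj = integrate(state, rates, dt=0.001, n_steps=20_000,
                                 record_every=20_000)
                state = traj.final_state()
                err = max(abs(a - b) for a, b in
                          zip(state.as_tuple(), eq.state.as_tuple()))
                if err <= 1e-6:
                    break
            assert err <= 1e-6

    def test_identical_seed_identical_trajectory(self, unit_rates, spreadsheet_totals):
        forcing = Forcing.jump_noise(0.05, -0.075, 0.075)
        t1 = integrate(uncomplexed(spreadsheet_totals), unit_rates, forcing,
                       dt=0.001, n_steps=2000, seed=123)
        t2 = integrate(uncomplexed(spreadsheet_totals), unit_rates, forcing,
                       dt=0.001, n_steps=2000, seed=123)
        assert np.array_equal(t1.A, t2.A)
        assert t1.n_jumps == t2.n_jumps > 0

    def test_rejects_bad_step(self, unit_rates, spreadsheet_totals):
        with pytest.raises(InvalidParameterError):
            integrate(uncomplexed(spreadsheet_totals), unit_rates, dt=0.0, n_steps=10)


class TestJumpNoise:
    def test_zero_probability_is_identity(self, spreadsheet_equilibrium):
        rng = np.random.default_rng(0)
        s = spreadsheet_equilibrium.state
        assert jump_noise_step(s, rng, 0.0, -1.0, 1.0) is s

    def test_degenerate_interval_exact_jump(self, spreadsheet_equilibrium):
        rng = np.random.default_rng(0)
        s = spreadsheet_equilibrium.state
        s2 = jump_noise_step(s, rng, 1.0, 0.05, 0.05)
        assert s2.A == pytest.approx(s.A + 0.05)
        assert s2.A + s2.AX == pytest.approx(s.A + s.AX + 0.05)

    def test_clip_at_zero(self):
        rng = np.random.default_rng(0)
        s = MixtureState(A=0.01, X=1.0, Y=0.0, AX=1.0, XY=0.0)
        s2 = jump_noise_step(s, rng, 1.0, -0.5, -0.5)
        assert s2.A == 0.0

    def test_relaxed_shift_is_jump_over_capacity(
        self, unit_rates, spreadsheet_totals, spreadsheet_equilibrium
    ):
        """A sudden addition of delta relaxes to a new equilibrium shifted
        by ~delta/beta — the operational meaning of the system capacity."""
        eq = spreadsheet_equilibrium
        delta = 0.075
        s = eq.state
        bumped = MixtureState(A=s.A + delta, X=s.X, Y=s.Y, AX=s.AX, XY=s.XY)
        traj = integrate(bumped, unit_rates, dt=0.001, n_steps=30_000,
                         record_every=30_000)
        observed = traj.final_state().A - eq.x
        predicted = delta / eq.beta
        assert observed == pytest.approx(predicted, rel=0.2)


class TestRampNoise:
    def test_more_inhibitor_means_better_rejection(self):
        """Against a steady drift on [A], systems designed for the same
        set point but with more inhibitor (larger capacity) deviate less."""
        rates = RateConstants.all_equal(1.0)
        forcing = Forcing.ramp_noise(s=-1.0)  # falling drift
        deviations = []
        for cX in (99.0, 200.0, 500.0):
            totals = design_concentrations(rates, cA=100.0, target_x=10.0, cX=cX)
            eq = full_equilibrium(rates, totals)
            traj = integrate(eq.state, rates, forcing, dt=0.001, n_steps=3000,
                             record_every=10)
            deviations.append(np.max(np.abs(traj.A - eq.x)))
        assert deviations[0] > deviations[1] > deviations[2]

class TestReplicationForcing:
    def test_uncontrolled_growth_exceeds_tenfold(self):
        """Without inhibitors, autocatalysis blows [A] past 10x its start."""
        rates = RateConstants.all_equal(1.0)
        initial = MixtureState(A=0.1, X=0.0, Y=0.0, AX=0.0, XY=0.0)
        traj = integrate(initial, rates, Forcing.replication(kRR=1.0, dR=0.01),
                         dt=0.001, n_steps=15_000, record_every=10)
        assert np.max(traj.A) > 1.0
        assert traj.exploded  # reported as divergence, not a crash

    def test_inhibitors_hold_the_line_longer(self, unit_rates, spreadsheet_totals):
        """With the control pair present the free agent stays near its
        designed level far beyond the uncontrolled blow-up time."""
        forcing = Forcing.replication(kRR=1.0, dR=0.01)
        bare = integrate(
            MixtureState(A=0.1, X=0.0, Y=0.0, AX=0.0, XY=0.0),
            unit_rates, forcing, dt=0.001, n_steps=15_000, record_every=10)
        t_bare = bare.t[np.argmax(bare.A > 1.0)]
        assert 0 < t_bare < 15.0

        horizon = int(round(12 * t_bare / 0.001))
        inhibited = integrate(
            uncomplexed(spreadsheet_totals), unit_rates, forcing,
            dt=0.001, n_steps=horizon, record_every=100)
        in_band = (inhibited.A >= 0.05) & (inhibited.A <= 0.2)
        t_enter = inhibited.t[np.argmax(in_band)]
        after = inhibited.t[~in_band & (inhibited.t > t_enter)]
        t_leave = after[0] if len(after) else inhibited.t[-1]
        assert (t_leave - t_enter) >= 10.0 * t_bare


class TestLyapunov:
    def test_zero_at_equilibrium(self, unit_rates, spreadsheet_equilibrium):
        assert lyapunov_value(
            spreadsheet_equilibrium.state, spreadsheet_equilibrium, unit_rates
        ) == 0.0
        assert lyapunov_derivative(
            spreadsheet_equilibrium.state, spreadsheet_equilibrium, unit_rates
        ) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_value(self):
        # x=1, y=0, k3=1, y0=2 -> V = k3 y0 x^2 = 2
        rates = RateConstants.all_equal(1.0)
        totals = Totals(cA=4.0, cX=3.0, cY=3.0)
        eq = full_equilibrium(rates, totals)
        state = state_from_free(eq.x + 1.0, eq.state.Y, totals)
        v = lyapunov_value(state, eq, rates)
        assert v == pytest.approx(rates.k3 * eq.state.Y * 1.0 ** 2)

    def test_strictly_decreasing_along_trajectories(self):
        rng = np.random.default_rng(47)
        for _ in range(10):
            rates, totals = random_parameter_set(rng)
            if totals.cY == 0.0:
                continue
            eq = full_equilibrium(rates, totals)
            traj = integrate(random_feasible_state(totals, rng), rates,
                             dt=0.001, n_steps=3000, equilibrium_ref=eq)
            dV = np.diff(traj.V)
            assert np.all(dV <= 1e-12)

    def test_derivative_negative_off_equilibrium(self):
        rng = np.random.default_rng(53)
        checked = 0
        while checked < 100:
            rates, totals = random_parameter_set(rng)
            eq = full_equilibrium(rates, totals)
            state = random_feasible_state(totals, rng)
            if (abs(state.A - eq.x) < 1e-6 and abs(state.Y - eq.state.Y) < 1e-6):
                continue
            assert lyapunov_derivative(state, eq, rates) < 0.0
            checked += 1

    def test_derivative_matches_finite_difference(self):
        """dV/dt from the closed form equals (V(t+dt)-V(t))/dt at small dt."""
        rng = np.random.default_rng(59)
        for _ in range(10):
            rates, totals = random_parameter_set(rng)
            eq = full_equilibrium(rates, totals)
            state = random_feasible_state(totals, rng)
            v0 = lyapunov_value(state, eq, rates)
            if v0 < 1e-8:
                continue
            dt = 1e-5
            traj = integrate(state, rates, dt=dt, n_steps=1, equilibrium_ref=eq)
            fd = (traj.V[1] - traj.V[0]) / dt
            assert lyapunov_derivative(state, eq, rates) == pytest.approx(fd, rel=1e-3)

    def test_mismatched_totals_rejected(self, unit_rates, spreadsheet_equilibrium):
        other = state_from_free(1.0, 1.0, Totals(cA=2.0, cX=5.0, cY=4.0))
        with pytest.raises(InvalidParameterError):
            lyapunov_value(other, spreadsheet_equilibrium, unit_rates)
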