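"""Closed-form solutions: oracle equivalence, regimes, extinction machinery."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecascade.analytic import (
    ConfluentRatesWarning,
    DecayRateTieWarning,
    ThresholdNeverReachedError,
    extinction_time,
    long_run_decay_rate,
    mutant_solution,
    stationary_clone_solution,
    stem_driven_solution,
)
from clonecascade.fixtures import random_valid_model
from clonecascade.model import CloneInit, CompartmentModel, derived_rates, equilibrium
from clonecascade.ode import OdeProblem, integrate

from conftest import rel_err


class TestStemDrivenSolution:
    def test_starts_empty(self, hema8):
        for k in (1, 4, 8):
            assert stem_driven_solution(hema8, k).value(0.0) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_single_compartment_closed_form(self):
        """K=1: N_1(t) = (phi/b)(1 - exp(-b t)) with phi=1, b=0.7."""
        m = CompartmentModel.constant(1, eps=0.85, d=0.0, r1=1.0, stem_count=1.0)
        sol = stem_driven_solution(m, 1)
        t = np.array([0.5, 1.0, 3.0])
        np.testing.assert_allclose(
            sol.value(t), (1 / 0.7) * (1 - np.exp(-0.7 * t)), rtol=1e-12
        )
        assert sol.value(1.0) == pytest.approx(0.719163, abs=1e-6)

    def test_long_time_limit_is_equilibrium(self, hema8):
        nstar = equilibrium(hema8)
        for k in (1, 5, 8):
            sol = stem_driven_solution(hema8, k)
            assert sol.constant_term == pytest.approx(nstar[k - 1], rel=1e-10)
            assert sol.value(200.0) == pytest.approx(nstar[k - 1], rel=1e-9)

    def test_gamma_zero_upstream_rejected(self):
        m = CompartmentModel.constant(2, eps=0.5, d=0.0)
        with pytest.raises(ValueError, match="gamma=0"):
            stem_driven_solution(m, 2)


class TestMutantSolution:
    def test_initial_condition(self, hema8):
        clone = CloneInit(3, initial_count=2.5)
        assert mutant_solution(hema8, clone, 3).value(0.0) == pytest.approx(2.5, rel=1e-12)
        for k in (4, 6, 8):
            assert mutant_solution(hema8, clone, k).value(0.0) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_origin_compartment_pure_decay(self):
        m = CompartmentModel.constant(2, eps=0.85, d=0.0, r1=1.0)
        sol = mutant_solution(m, CloneInit(1), 1)
        assert sol.value(1.0) == pytest.approx(np.exp(-0.7), rel=1e-12)
        assert sol.value(1.0) == pytest.approx(0.496585, abs=5e-7)

    def test_two_compartment_bateman_form(self):
        """c=1, k=2: N_2 = a_2 (e^{-b_1 t} - e^{-b_2 t})/(b_2 - b_1)."""
        m = CompartmentModel.constant(2, eps=0.85, d=0.0, r1=1.0, rate_ratio=1.26)
        sol = mutant_solution(m, CloneInit(1), 2)
        b1, b2, a2 = 0.7, 0.7 * 1.26, 1.7
        for t in (0.5, 1.0, 2.0):
            expected = a2 * (np.exp(-b1 * t) - np.exp(-b2 * t)) / (b2 - b1)
            assert sol.value(t) == pytest.approx(expected, rel=1e-10)
        # and against the ODE oracle
        grid = np.array([0.0, 0.5, 1.0, 2.0])
        traj = integrate(OdeProblem(m, [1.0, 0.0], False, grid))
        assert np.max(rel_err(sol.value(grid), traj.compartment(2))) < 1e-8

    def test_upstream_compartment_is_zero_function(self, hema8):
        sol = mutant_solution(hema8, CloneInit(4), 2)
        assert np.all(sol.value(np.linspace(0, 5, 7)) == 0.0)

    def test_washout_when_all_gamma_positive(self, hema8):
        sol = mutant_solution(hema8, CloneInit(1), 5)
        assert sol.value(400.0) == pytest.approx(0.0, abs=1e-12)

    def test_divergence_with_one_negative_gamma_downstream(self):
        """gamma < 0 in a single compartment makes every downstream count
        diverge exponentially: the count keeps growing between t and 2t."""
        eps = np.array([0.85, 0.4, 0.85, 0.85])  # gamma_2 = -0.2
        m = CompartmentModel.constant(4, eps=0.85, d=0.0, r1=1.0, rate_ratio=1.26)
        m = m.with_(diff_prob=eps)
        for k in (2, 3, 4):
            sol = mutant_solution(m, CloneInit(1), k)
            big_t = 60.0
            assert sol.value(2 * big_t) > 10 * sol.value(big_t) > 0


class TestOracleEquivalence:
    """Analytic solutions agree with direct integration on random models."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_models_match_ode(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(4):
            m = random_valid_model(rng)
            K = m.n_compartments
            horizon = 3.0 / np.min(derived_rates(m).decay)
            times = np.sort(rng.uniform(0.0, horizon, size=12))
            grid = np.concatenate([[0.0], times])
            c = int(rng.integers(1, K + 1))
            k = int(rng.integers(c, K + 1))
            init = np.zeros(K)
            init[c - 1] = 1.0
            traj = integrate(OdeProblem(m, init, False, grid), rtol=1e-12, atol=1e-14)
            sol = mutant_solution(m, CloneInit(c), k)
            assert np.max(rel_err(sol.value(grid), traj.compartment(k))) < 1e-8
            fill = integrate(OdeProblem(m, np.zeros(K), True, grid), rtol=1e-12, atol=1e-14)
            sol2 = stem_driven_solution(m, k)
            assert np.max(rel_err(sol2.value(grid), fill.compartment(k))) < 1e-8

    def test_confluent_rates_fall_back_to_oracle(self):
        """Exactly equal decay coefficients cannot be expanded in pure
        exponentials; the solution is flagged and still evaluates correctly."""
        m = CompartmentModel(
            rates=[1.0, 1.0, 1.5], diff_prob=[0.85, 0.85, 0.85],
            death_prob=[0.0, 0.0, 0.0], stem_count=1.0, stem_rate=1.0,
        )
        with pytest.warns(ConfluentRatesWarning):
            sol = mutant_solution(m, CloneInit(1), 3)
        assert sol.confluent
        grid = np.linspace(0.0, 4.0, 9)
        traj = integrate(OdeProblem(m, [1.0, 0, 0], False, grid))
        assert np.max(rel_err(sol.value(grid), traj.compartment(3))) < 1e-7


class TestSuperpositionProperty:
    def test_two_simultaneous_clones_add(self, hema8):
        """Independent clones evolve independently: the sum of the single-clone
        closed forms equals integrating both founders jointly."""
        grid = np.linspace(0.0, 6.0, 13)
        init = np.zeros(8)
        init[0] = 1.0
        init[2] = 3.0
        joint = integrate(OdeProblem(hema8, init, False, grid))
        for k in (3, 5, 8):
            summed = (
                mutant_solution(hema8, CloneInit(1), k).value(grid)
                + mutant_solution(hema8, CloneInit(3, 3.0), k).value(grid)
            )
            assert np.max(rel_err(summed, joint.compartment(k))) < 1e-8

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(n0=st.floats(min_value=0.5, max_value=20.0))
    def test_solution_is_homogeneous_in_founder_count(self, n0):
        m = CompartmentModel.constant(4, eps=0.8, d=0.1, r1=1.0, rate_ratio=1.5)
        grid = np.linspace(0.0, 4.0, 9)
        one = mutant_solution(m, CloneInit(1, 1.0), 4).value(grid)
        many = mutant_solution(m, CloneInit(1, n0), 4).value(grid)
        np.testing.assert_allclose(many, n0 * one, rtol=1e-9, atol=1e-12)


class TestStationaryClone:
    @staticmethod
    def _model():
        # gamma_1 = 0 exactly, downstream gamma = 0.7
        m = CompartmentModel.constant(4, eps=0.85, d=0.0, r1=1.0, rate_ratio=1.26)
        return m.with_(diff_prob=np.array([0.5, 0.85, 0.85, 0.85]))

    def test_origin_count_is_constant(self):
        sol = stationary_clone_solution(self._model(), CloneInit(1), 1)
        assert np.all(sol.value(np.linspace(0, 50, 11)) == 1.0)

    def test_downstream_fixed_point_value(self):
        """a_2 = 2*0.5*1 = 1, b_2 = 0.7*1.26 = 0.882: N*_2 = 1/0.882."""
        sol = stationary_clone_solution(self._model(), CloneInit(1), 2)
        assert sol.constant_term == pytest.approx(1.133787, abs=5e-7)
        assert sol.value(100.0) == pytest.approx(1 / 0.882, rel=1e-10)
        # long-time integration agrees
        grid = np.array([0.0, 100.0])
        traj = integrate(OdeProblem(self._model(), [1.0, 0, 0, 0], False, grid))
        assert traj.compartment(2)[-1] == pytest.approx(sol.constant_term, rel=1e-8)

    def test_index_shift_equivalence_with_stem_driven(self):
        """The gamma_c = 0 clone's downstream time course is the stem-driven
        solution with compartment c playing the stem role (index shift)."""
        m = self._model()
        rr = derived_rates(m)
        # shifted model: compartments 2..4 of m, fed by flux a_2 * n0
        shifted = CompartmentModel(
            rates=m.rates[1:], diff_prob=m.diff_prob[1:], death_prob=m.death_prob[1:],
            stem_count=rr.inflow[1] * 1.0, stem_rate=1.0,
        )
        grid = np.linspace(0.0, 12.0, 25)
        for k in (2, 3, 4):
            a = stationary_clone_solution(m, CloneInit(1), k).value(grid)
            b = stem_driven_solution(shifted, k - 1).value(grid)
            assert np.max(rel_err(a, b)) < 1e-8

    def test_nonzero_gamma_rejected(self, hema8):
        with pytest.raises(ValueError, match="gamma_c must be 0"):
            stationary_clone_solution(hema8, CloneInit(1), 2)

    def test_fixed_point_is_stable_to_state_perturbation(self):
        """Perturbing the downstream state decays back to the fixed point."""
        m = self._model()
        fix = [stationary_clone_solution(m, CloneInit(1), k).constant_term
               for k in range(1, 5)]
        bumped = np.array(fix) + np.array([0.0, 0.5, -0.2, 0.3])
        traj = integrate(OdeProblem(m, bumped, False, np.array([0.0, 120.0])))
        np.testing.assert_allclose(traj.counts[-1], fix, rtol=1e-6)

    def test_gamma_perturbation_switches_regime(self):
        """Nudging gamma_c away from 0 flips the long run to extinction or
        divergence: the balanced compartment is structurally unstable."""
        m = self._model()
        delta = 0.02
        up = m.with_(diff_prob=m.diff_prob + np.array([delta, 0, 0, 0]))
        down = m.with_(diff_prob=m.diff_prob - np.array([delta, 0, 0, 0]))
        grid = np.array([0.0, 400.0])
        washed = integrate(OdeProblem(up, [1.0, 0, 0, 0], False, grid))
        assert washed.compartment(4)[-1] < 1e-3
        growing = mutant_solution(down, CloneInit(1), 4)
        assert growing.value(400.0) > 10 * growing.value(200.0)


class TestLongRunDecayRate:
    def test_minimum_at_origin_for_increasing_rates(self):
        m = CompartmentModel.constant(6, eps=0.85, d=0.0, r1=1.26, rate_ratio=1.26)
        res = long_run_decay_rate(m, CloneInit(3))
        assert res.compartment == 3
        assert res.rate == pytest.approx(0.7 * 1.26**3, rel=1e-12)
        assert not res.tied

    def test_minimum_not_at_origin(self):
        # eps=1, d=0 gives gamma=1 so b_k = r_k: b = [0.5, 0.3, 0.9]
        m = CompartmentModel(
            rates=[0.5, 0.3, 0.9], diff_prob=[1.0, 1.0, 1.0],
            death_prob=[0.0, 0.0, 0.0], stem_count=1.0, stem_rate=1.0,
        )
        res = long_run_decay_rate(m, CloneInit(1))
        assert res.rate == pytest.approx(0.3)
        assert res.compartment == 2

    def test_tie_is_flagged(self):
        m = CompartmentModel(
            rates=[0.5, 0.5, 0.9], diff_prob=[1.0, 1.0, 1.0],
            death_prob=[0.0, 0.0, 0.0], stem_count=1.0, stem_rate=1.0,
        )
        with pytest.warns(DecayRateTieWarning):
            res = long_run_decay_rate(m, CloneInit(1))
        assert res.tied

    def test_growth_regime_rejected(self):
        m = CompartmentModel.constant(3, eps=0.4, d=0.0)
        with pytest.raises(ValueError, match="not washed out"):
            long_run_decay_rate(m, CloneInit(1))


class TestExtinctionTime:
    def test_asymptotic_solves_amplitude_equation_exactly(self, hema8):
        clone = CloneInit(1)
        est = extinction_time(hema8, clone, 5, "asymptotic")
        sol = mutant_solution(hema8, clone, 5)
        j = sol.slowest_rate_index
        residual = sol.log_amplitudes[j] - sol.rates[j] * est.tau
        assert residual == pytest.approx(np.log(1.0), abs=1e-9)

    def test_asymptotic_needs_downstream_compartment(self, hema8):
        with pytest.raises(ValueError, match="k > c"):
            extinction_time(hema8, CloneInit(3), 3, "asymptotic")

    def test_small_clone_never_reaches_threshold(self, hema8):
        # compartment 2 of a single origin-1 mutant peaks below one cell
        with pytest.raises(ThresholdNeverReachedError):
            extinction_time(hema8, CloneInit(1), 2, "root_finding")

    def test_tau_increases_with_compartment(self, hema8):
        taus = [extinction_time(hema8, CloneInit(1), k, "asymptotic").tau
                for k in range(3, 8)]
        assert np.all(np.diff(taus) > 0)

    def test_agreement_with_root_finding_improves_downstream(self, hema8):
        """For a single founder the asymptotic formula overestimates the exact
        crossing, with the relative gap shrinking as k - c grows."""
        gaps = []
        for k in range(3, 8):
            a = extinction_time(hema8, CloneInit(1), k, "asymptotic").tau
            r = extinction_time(hema8, CloneInit(1), k, "root_finding").tau
            assert a > r
            gaps.append((a - r) / r)
        assert np.all(np.diff(gaps) < 0)

    def test_threshold_parameter_shifts_tau(self, hema8):
        lo = extinction_time(hema8, CloneInit(1), 5, "asymptotic", threshold=0.5)
        hi = extinction_time(hema8, CloneInit(1), 5, "asymptotic", threshold=2.0)
        assert lo.tau > hi.tau


class TestClonePeakShape:
    """Qualitative dependence of the downstream maximum on the parameters."""

    @staticmethod
    def _peak(model, c=1, k=4):
        sol = mutant_solution(model, CloneInit(c), k)
        tmax = sol.time_of_maximum()
        return tmax, sol.value(tmax)

    def test_slower_proliferation_raises_and_delays_the_maximum(self):
        """In the r_k = r**k family a lower proliferation ratio r lets cells
        linger downstream: the maximum grows and arrives later.  (A uniform
        rescaling of all rates only stretches time and leaves the peak height
        unchanged, by the t -> s*t scaling symmetry.)"""
        fast = CompartmentModel.constant(4, eps=0.85, d=0.0, r1=1.5, rate_ratio=1.5)
        slow = CompartmentModel.constant(4, eps=0.85, d=0.0, r1=1.1, rate_ratio=1.1)
        t_fast, n_fast = self._peak(fast)
        t_slow, n_slow = self._peak(slow)
        assert n_slow > n_fast
        assert t_slow > t_fast

    def test_higher_net_loss_lowers_the_maximum(self):
        base = CompartmentModel.constant(4, eps=0.80, d=0.0, r1=1.0, rate_ratio=1.26)
        lossy = CompartmentModel.constant(4, eps=0.90, d=0.0, r1=1.0, rate_ratio=1.26)
        assert self._peak(lossy)[1] < self._peak(base)[1]
        deadly = CompartmentModel.constant(4, eps=0.80, d=0.10, r1=1.0, rate_ratio=1.26)
        assert self._peak(deadly)[1] < self._peak(base)[1]

    def test_later_origin_gives_smaller_earlier_maximum(self, hema8):
        t2, n2 = self._peak(hema8, c=2, k=6)
        t4, n4 = self._peak(hema8, c=4, k=6)
        assert n4 < n2
        assert t4 < t2
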