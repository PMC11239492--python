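"""Unit and property tests for the clonal-organism Gillespie simulator."""

import dataclasses

import numpy as np
import pytest

from genetclock import sim
from genetclock.sim import (
    AbsorbedStateError,
    Module,
    SeasonalQuiescence,
    SimulationParams,
    StochasticQuiescence,
    count_fixed,
    form_module,
    initialize,
    run,
    sample_mean_fixed,
    step,
    transition_rates,
)


def small_params(**kw):
    base = dict(
        b=20.0, lambda_sym=0.0, gamma_asym=20.0, r=3.0, N=5, N0=2, Z=10,
        mu=0.05, t_max=5.0, seed=7,
    )
    base.update(kw)
    return SimulationParams(**base)


class TestInitialize:
    def test_single_founder_cell(self):
        state = initialize(small_params())
        assert state.n_modules() == 1
        (mod,) = state.modules
        assert mod.size() == 1
        assert mod.cells[0] == set()
        assert state.t == 0.0

    def test_deterministic_under_seed(self):
        p = small_params(seed=42)
        t1 = run(p, [1.0, 3.0, 5.0]).to_frame()
        t2 = run(p, [1.0, 3.0, 5.0]).to_frame()
        assert t1.equals(t2)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(N0=6),  # N0 > N
            dict(N0=5, formation_mode="splitting"),  # splitting needs N0 <= N-1
            dict(b=-1.0),
            dict(mu=-0.1),
            dict(Z=0),
            dict(t_max=0.0),
            dict(N0=0),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            initialize(small_params(**kw))


class TestTransitionRates:
    def test_all_homeostatic(self):
        p = small_params(thin_asymmetric=False)
        state = initialize(p)
        # grow the founder module to homeostasis
        while state.growing:
            step(state, p)
        r_a, r_b, r_c, r_d = transition_rates(state, p)
        zh = state.z_homeostatic
        assert r_a == 0.0
        assert r_b == p.lambda_sym * p.N * zh
        assert r_c == p.gamma_asym * p.N * zh
        assert r_d == p.r * zh

    def test_growing_module_rate(self):
        p = small_params()
        state = initialize(p)
        r_a, _, _, r_d = transition_rates(state, p)
        assert r_a == p.b * 1  # one growing cell
        assert r_d == 0.0  # no homeostatic module yet

    def test_pure_asymmetric_regime(self):
        p = small_params(lambda_sym=0.0, gamma_asym=20.0)
        state = initialize(p)
        assert transition_rates(state, p)[1] == 0.0

    def test_quiescent_modules_contribute_nothing(self):
        p = small_params(quiescence=StochasticQuiescence(1.0, 1.0))
        state = initialize(p)
        while state.growing:
            step(state, p)
        mod = state.homeostatic.pop()
        mod.phase = "quiescent"
        state.quiescent.append(mod)
        assert transition_rates(state, p) == (0.0, 0.0, 0.0, 0.0)


class TestStep:
    def test_no_mutations_when_mu_zero(self):
        p = small_params(mu=0.0)
        state = initialize(p)
        for _ in range(500):
            step(state, p)
        assert all(c == set() for m in state.modules for c in m.cells)

    def test_moran_preserves_module_size(self):
        p = small_params(lambda_sym=20.0, gamma_asym=0.0, r=0.0, thin_asymmetric=False)
        state = initialize(p)
        while state.growing:
            step(state, p)
        for _ in range(200):
            step(state, p)
        assert [m.size() for m in state.modules] == [p.N]

    def test_growth_enters_homeostasis_at_N(self):
        p = small_params(r=0.0)
        state = initialize(p)
        while state.growing:
            assert all(m.size() < p.N for m in state.growing)
            step(state, p)
        assert state.modules[0].phase == "homeostatic"
        assert state.modules[0].size() == p.N

    def test_absorbed_state_signalled(self):
        p = small_params(lambda_sym=0.0, gamma_asym=0.0, r=0.0)
        state = initialize(p)
        while state.growing:
            step(state, p)
        with pytest.raises(AbsorbedStateError):
            step(state, p)

    def test_conservation_invariant(self):
        """Cached n_growth / Z_homeostatic always match recomputed values."""
        p = small_params(
            formation_mode="splitting", N0=2,
            quiescence=StochasticQuiescence(rate_in=2.0, rate_out=4.0),
        )
        state = initialize(p)
        for _ in range(800):
            step(state, p)
            assert (state.n_growth, state.z_homeostatic) == state.recompute_tallies()
            assert state.n_modules() <= p.Z


class TestFormModule:
    def _homeostatic_state(self, p):
        state = initialize(p)
        while state.growing:
            step(state, p)
        return state

    def test_branching_leaves_parent_unchanged(self):
        p = small_params(mu=0.5)
        state = self._homeostatic_state(p)
        parent = state.homeostatic[0]
        before = sorted(sorted(c) for c in parent.cells)
        form_module(state, parent, p)
        assert sorted(sorted(c) for c in parent.cells) == before
        assert parent.phase == "homeostatic"
        child = state.growing[-1]
        assert child.size() == p.N0
        assert child.parent_id == parent.module_id

    def test_splitting_shrinks_parent(self):
        p = small_params(formation_mode="splitting", N=10, N0=3, mu=0.5)
        state = self._homeostatic_state(p)
        parent = state.homeostatic[0]
        form_module(state, parent, p)
        assert parent.size() == 7
        assert parent.phase == "growing"
        assert state.growing[-1].size() == 3

    def test_cap_keeps_module_count_constant(self):
        p = small_params(Z=4, mu=0.0)
        state = self._homeostatic_state(p)
        for _ in range(3000):
            step(state, p)
            assert state.n_modules() <= 4
        assert state.n_modules() == 4
        parent = state.homeostatic[0]
        form_module(state, parent, p)
        assert state.n_modules() == 4

    def test_growing_parent_rejected(self):
        p = small_params()
        state = initialize(p)
        with pytest.raises(ValueError):
            form_module(state, state.growing[0], p)


class TestCountFixed:
    def test_shared_mutation(self):
        m = Module(cells=[{7}, {7, 3}, {7, 9}], birth_times=[0] * 3,
                   phase="homeostatic", founding_time=0.0, module_id=0)
        assert count_fixed(m) == 1

    def test_fresh_module_zero(self):
        state = initialize(small_params())
        assert count_fixed(state.modules[0]) == 0

    def test_matches_bruteforce_intersection(self, rng):
        cells = [set(rng.choice(30, size=rng.integers(1, 15), replace=False))
                 for _ in range(6)]
        m = Module(cells=cells, birth_times=[0] * 6, phase="homeostatic",
                   founding_time=0.0, module_id=0)
        brute = sum(1 for mut in range(30) if all(mut in c for c in cells))
        assert count_fixed(m) == brute

    def test_empty_module_rejected(self):
        m = Module(cells=[], birth_times=[], phase="growing",
                   founding_time=0.0, module_id=0)
        with pytest.raises(ValueError):
            count_fixed(m)


class TestRun:
    def test_asymmetric_without_formation_never_fixes(self):
        """lambda = 0 and r = 0: drift has no mechanism, zero new fixations."""
        p = small_params(lambda_sym=0.0, gamma_asym=30.0, r=0.0, mu=0.3,
                         t_max=20.0, seed=3)
        traj = run(p, [5.0, 10.0, 20.0])
        for counts in traj.fixed_counts:
            assert counts.tolist() == [0]

    def test_mu_zero_all_counts_zero(self):
        p = small_params(mu=0.0, t_max=6.0)
        traj = run(p, [2.0, 6.0])
        assert all((c == 0).all() for c in traj.fixed_counts)

    def test_record_times_validated(self):
        p = small_params()
        with pytest.raises(ValueError):
            run(p, [3.0, 1.0])
        with pytest.raises(ValueError):
            run(p, [p.t_max + 1.0])

    def test_branching_fixed_counts_monotone_along_module(self):
        """A surviving module's fixed count never decreases under branching."""
        p = small_params(mu=0.4, t_max=8.0, seed=11)
        traj = run(p, np.arange(0.5, 8.5, 0.5))
        seen = {}
        for ids, counts in zip(traj.module_ids, traj.fixed_counts):
            for mid, c in zip(ids, counts):
                if mid in seen:
                    assert c >= seen[mid]
                seen[mid] = c

    def test_symmetric_single_module_matches_direct_moran(self):
        """Single-module symmetric turnover is a neutral Moran process: the
        conditional fixation time of a seeded mutant matches an independent
        direct Moran simulation."""
        from genetclock.analytics import moran_fixation_oracle

        N, b = 6, 30.0
        p = small_params(lambda_sym=b, gamma_asym=0.0, b=b, r=0.0, N=N, N0=1,
                         mu=0.0, t_max=1e9, thin_asymmetric=False)
        rng_seeds = range(4000)
        times = []
        for s in rng_seeds:
            pp = dataclasses.replace(p, seed=s)
            state = initialize(pp)
            while state.growing:
                step(state, pp)
            state.homeostatic[0].cells[0].add(999)
            t0 = state.t
            while True:
                k = sum(999 in c for c in state.homeostatic[0].cells)
                if k == 0 or k == N:
                    break
                step(state, pp)
            if k == N:
                times.append(state.t - t0)
        sim_mean = np.mean(times)
        oracle_mean, n_fix = moran_fixation_oracle(N, b, replicates=6000, seed=5)
        assert len(times) > 300 and n_fix > 300
        assert sim_mean == pytest.approx(oracle_mean, rel=0.15)
        # diffusion scale N/b is the right order
        assert sim_mean == pytest.approx(N / b, rel=0.35)


class TestSampleMeanFixed:
    def _traj(self):
        p = small_params(mu=0.4, t_max=6.0, seed=2)
        return run(p, [3.0, 6.0])

    def test_k_equals_all_is_plain_mean(self):
        traj = self._traj()
        k = traj.fixed_counts[0].size
        assert np.allclose(
            sample_mean_fixed(traj, k, seed=0),
            [c.mean() for c in traj.fixed_counts],
        )

    def test_k_one_returns_single_module_count(self):
        traj = self._traj()
        vals = sample_mean_fixed(traj, 1, seed=3)
        for v, counts in zip(vals, traj.fixed_counts):
            assert v in counts

    def test_same_seed_same_sample(self):
        traj = self._traj()
        assert np.array_equal(
            sample_mean_fixed(traj, 2, seed=9), sample_mean_fixed(traj, 2, seed=9)
        )

    def test_oversampling_rejected(self):
        traj = self._traj()
        with pytest.raises(ValueError, match="survive"):
            sample_mean_fixed(traj, 10_000, seed=0)


class TestQuiescence:
    def test_seasonal_time_warp_roundtrip(self):
        q = SeasonalQuiescence(active_fraction=0.4, period=1.0)
        for t in [0.0, 0.1, 0.39, 0.4, 1.0, 2.75, 10.2]:
            act = sim._wall_to_active(t, q)
            assert 0 <= act <= t + 1e-12
            # active time never exceeds active_fraction per period
            assert act == pytest.approx(min(t, act), abs=1e-9)
        # inverse maps active time back into an active window
        for a in [0.0, 0.2, 0.4, 1.3, 5.17]:
            wall = sim._active_to_wall(a, q)
            assert sim._wall_to_active(wall, q) == pytest.approx(a, abs=1e-9)

    def test_seasonal_run_slows_accumulation(self):
        """Half-year activity should roughly halve mutation accumulation."""
        t_max, reps = 6.0, 6
        tot_active, tot_seasonal = 0, 0
        for s in range(reps):
            pa = small_params(mu=0.3, t_max=t_max, seed=100 + s)
            ps = small_params(
                mu=0.3, t_max=t_max, seed=100 + s,
                quiescence=SeasonalQuiescence(active_fraction=0.5, period=1.0),
            )
            tot_active += run(pa, [t_max]).fixed_counts[-1].mean()
            tot_seasonal += run(ps, [t_max]).fixed_counts[-1].mean()
        assert tot_seasonal < tot_active

    def test_stochastic_quiescence_runs_and_conserves(self):
        p = small_params(
            quiescence=StochasticQuiescence(rate_in=5.0, rate_out=5.0),
            t_max=4.0,
        )
        traj = run(p, [2.0, 4.0])
        assert len(traj.fixed_counts) == 2
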