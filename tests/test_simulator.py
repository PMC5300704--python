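"""Entry rule, single-file diffusion, crystallization and trace invariants."""

import numpy as np
import pytest

import flagrow as fg
from flagrow.simulator import ChannelState, attempt_load, channel_occupancy, diffuse_step


def params(LS=0, D=5000.0, **kw):
    return fg.SimParams(D=D, LS=LS, **kw)


class ForcedRng:
    """Deterministic stand-in for the RNG: fixed Z draws, identity permutation."""

    def __init__(self, z_values):
        self.z = list(z_values)

    def permutation(self, n):
        return np.arange(n)

    def standard_normal(self):
        return self.z.pop(0)


class TestAttemptLoad:
    def test_empty_channel_accepts_at_base(self):
        ok, new = attempt_load(ChannelState(L=100.0), params(LS=0))
        assert ok and new.positions.tolist() == [0.0]

    def test_ls0_requires_first_ell_empty(self):
        ok, new = attempt_load(ChannelState(L=500.0, positions=[30.0]), params(LS=0))
        assert not ok and new.positions.tolist() == [30.0]

    def test_ls1_pushes_single_resident(self):
        ok, new = attempt_load(ChannelState(L=500.0, positions=[30.0]), params(LS=1))
        assert ok and new.positions.tolist() == [0.0, 56.0]

    def test_ls1_cannot_push_two(self):
        ok, new = attempt_load(ChannelState(L=500.0, positions=[10.0, 70.0]), params(LS=1))
        assert not ok and new.positions.tolist() == [10.0, 70.0]

    def test_push_past_tip_fails(self):
        # resident would be pushed to 56 with front edge 112 > L = 100
        ok, _ = attempt_load(ChannelState(L=100.0, positions=[30.0]), params(LS=5))
        assert not ok

    def test_untouched_residents_do_not_count_against_ls(self):
        # resident at 200 already beyond 1*ell: no displacement needed
        ok, new = attempt_load(ChannelState(L=500.0, positions=[200.0]), params(LS=0))
        assert ok and new.positions.tolist() == [0.0, 200.0]

    @pytest.mark.parametrize("ls", [0, 1, 3, 12])
    def test_equivalent_to_direct_counting_rule(self, ls, rng):
        """The entry rule counts exactly the residents below their packed slot.

        For LS = 0 this reduces to 'the first ell nm are empty'; in general
        success requires <= LS residents with x_k < k*ell and no push past
        the tip.
        """
        p = params(LS=ls)
        ell = p.ell
        for _ in range(300):
            m = rng.integers(0, 8)
            # random valid configuration in a 1000 nm channel
            gaps = rng.uniform(0, 80, size=m)
            x = np.cumsum(gaps) + np.arange(m) * ell
            state = ChannelState(L=1000.0, positions=x)
            state.check_invariants(ell)
            k = np.arange(1, m + 1)
            direct = (np.sum(x < k * ell - 1e-12) <= ls) and np.all(
                np.maximum(x, k * ell) + ell <= 1000.0 + 1e-12
            )
            ok, _ = attempt_load(state, p)
            assert ok == direct

    def test_ls0_direct_sentence(self):
        """LS=0: entry iff the first 56 nm of the channel are empty."""
        p = params(LS=0)
        for x0 in (0.0, 10.0, 55.9, 56.0, 300.0):
            ok, _ = attempt_load(ChannelState(L=1000.0, positions=[x0]), p)
            assert ok == (x0 >= p.ell)


class TestDiffuseStep:
    def test_base_is_reflecting(self):
        p = params(D=5000.0)
        state = ChannelState(L=500.0, positions=[5.0])
        new = diffuse_step(state, p, ForcedRng([-1e6]))
        assert new.positions.tolist() == [0.0]

    def test_hard_core_exclusion_clips_at_contact(self):
        p = params(D=5000.0, dt=1.0)  # huge step so the draw matters
        state = ChannelState(L=5000.0, positions=[0.0, 56.0])
        # monomer 1 proposed far forward: clipped at x2 - ell = 0
        new = diffuse_step(state, p, ForcedRng([30.0 / np.sqrt(2 * 5000.0), 0.0]))
        assert new.positions[0] == pytest.approx(0.0)
        assert new.positions[1] - new.positions[0] >= p.ell - 1e-9

    def test_tip_crystallization_elongates(self):
        p = params(D=5000.0, dt=1.0)
        state = ChannelState(L=200.0, positions=[100.0])
        new = diffuse_step(state, p, ForcedRng([1e3]))
        assert new.n_monomers == 0
        assert new.L == pytest.approx(200.0 + p.dL)
        assert new.n_crystallized == 1

    def test_single_step_variance_is_2Ddt(self, rng):
        """A lone monomer far from boundaries diffuses with Var = 2*D*dt."""
        p = params(D=5000.0, dt=1e-3, L_stop=1e7)
        n = 40_000
        state = ChannelState(L=1e6, positions=[5e5])
        increments = np.empty(n)
        for i in range(n):
            new = diffuse_step(state, p, rng)
            increments[i] = new.positions[0] - state.positions[0]
            state = new
        var = increments.var()
        expected = 2 * p.D * p.dt
        se = expected * np.sqrt(2.0 / (n - 1))  # SE of a normal sample variance
        assert abs(var - expected) < 3 * se

    def test_invariants_preserved_under_random_evolution(self, rng):
        p = params(LS=3, D=5000.0, dt=0.05, S_load=5.0)
        state = ChannelState(L=400.0, positions=[0.0, 60.0, 130.0])
        for i in range(400):
            state = diffuse_step(state, p, rng)
            if i % 3 == 0:
                _, state = attempt_load(state, p)
            state.check_invariants(p.ell)


class TestOccupancy:
    def test_empty_channel(self):
        assert channel_occupancy(ChannelState(L=560.0), params()) == 0.0

    def test_printed_definition(self):
        state = ChannelState(L=560.0, positions=[0.0, 100.0])
        assert channel_occupancy(state, params()) == pytest.approx(0.2)

    def test_close_packed_bound(self):
        m = int(560.0 // 56.0)
        state = ChannelState(L=560.0, positions=np.arange(m) * 56.0)
        assert channel_occupancy(state, params()) <= 1.0 + 1e-12

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            channel_occupancy(ChannelState(L=0.0), params())


class TestSimulate:
    def test_length_conservation_is_exact(self, fast_params):
        trace = fg.simulate(fast_params)
        n = (trace.lengths_nm[-1] - fast_params.resolved_L0) / fast_params.dL
        assert n == pytest.approx(round(n), abs=1e-6)

    def test_lengths_non_decreasing_occupancy_bounded(self, fast_params):
        trace = fg.simulate(fast_params)
        assert np.all(np.diff(trace.lengths_nm) >= 0)
        assert np.all((trace.occupancy >= 0) & (trace.occupancy <= 1 + 1e-12))

    def test_loading_limits_growth_rate(self, fast_params):
        """Long-run growth never exceeds S_load * dL nm/s for any D, LS."""
        trace = fg.simulate(fast_params)
        rate = (trace.lengths_nm[-1] - trace.lengths_nm[0]) / trace.times_s[-1]
        assert rate <= fast_params.S_load * fast_params.dL * (1 + 1e-9)

    def test_loading_limited_regime_hits_ceiling(self, fast_params):
        """At high D the rate equals S_load*dL*60 = 47.9 nm/min on the plateau."""
        curve = fg.instantaneous_rates(fg.simulate(fast_params), interval_min=1.0)
        mask = curve.lengths_nm > 150.0  # skip the initial channel-filling transient
        mean = curve.rates_nm_per_min[mask].mean()
        assert mean == pytest.approx(47.94, rel=0.08)

    def test_seeded_determinism(self, fast_params):
        t1 = fg.simulate(fast_params)
        t2 = fg.simulate(fast_params)
        assert np.array_equal(t1.lengths_nm, t2.lengths_nm)
        assert np.array_equal(t1.times_s, t2.times_s)

    def test_truncation_flagged(self):
        p = params(LS=0, D=2000.0, L_stop=4000.0, t_max=30.0)
        trace = fg.simulate(p)
        assert trace.truncated

    def test_python_and_numba_engines_agree_statistically(self):
        """Mean growth rates of the two engines agree within replicate scatter."""
        def mean_rate(engine, seeds):
            rates = []
            for s in seeds:
                p = fg.SimParams(D=5000.0, LS=2, ell=56.0, dL=5.0, S_load=1.7,
                                 L_stop=200.0, seed=s)
                tr = fg.simulate(p, engine=engine)
                rates.append((tr.lengths_nm[-1] - tr.lengths_nm[0]) / tr.times_s[-1])
            return np.mean(rates), np.std(rates, ddof=1) / np.sqrt(len(rates))

        m_py, se_py = mean_rate("python", (1, 2, 3, 4, 5))
        m_nb, se_nb = mean_rate("numba", (6, 7, 8, 9, 10))
        assert abs(m_py - m_nb) < 4 * np.hypot(se_py, se_nb)

    def test_waiting_slot_outgrows_discarded_arrivals(self):
        """A blocked flagellin that waits and retries yields faster growth
        than dropping blocked arrivals until the next clock tick."""
        def mean_time(mode, seeds):
            ts = []
            for s in seeds:
                p = fg.SimParams(D=5000.0, LS=1, ell=56.0, dL=5.0, L_stop=300.0,
                                 seed=s, blocked_monomer=mode)
                ts.append(fg.simulate(p).times_s[-1])
            return np.mean(ts)

        assert mean_time("wait", (21, 22, 23)) < mean_time("discard", (24, 25, 26))

    def test_poisson_loading_option_runs(self):
        p = fg.SimParams(D=2.0e4, LS=25, L_stop=200.0, seed=3, poisson_loading=True)
        trace = fg.simulate(p)
        assert trace.lengths_nm[-1] >= 200.0


class TestSimParamsValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"D": -1.0, "LS": 0},
            {"D": 5000.0, "LS": -2},
            {"D": 5000.0, "LS": 0, "S_load": 0.0},
            {"D": 5000.0, "LS": 0, "dL": 60.0},          # dL >= ell
            {"D": 5000.0, "LS": 0, "L_stop": 10.0},       # below L0
            {"D": 5000.0, "LS": 0, "seed": 2**31},
            {"D": 5000.0, "LS": 0, "blocked_monomer": "teleport"},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            fg.SimParams(**kw)

    def test_default_dt_is_dL_squared_over_D(self):
        p = fg.SimParams(D=5000.0, LS=12)
        assert p.resolved_dt == pytest.approx(0.47**2 / 5000.0)
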