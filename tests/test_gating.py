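"""Stochastic three-state gating against deterministic oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from quantalca.gating import (
    AdditionProtocol, GatingRates, ReceptorEnsemble, dwell_time_sample,
    inject_tetraliganded, meanfield_occupancies, rate_matrix,
    simulate_protocol, stationary_distribution, step, step_per_receptor,
)
from quantalca.occupancy import LigandParams, OccupancyModel, tetra_count


class TestGatingRates:
    def test_defaults_and_reverse_rates(self, rates):
        assert rates.k_rev1 == pytest.approx(0.004)
        assert rates.k_rev2 == pytest.approx(0.002)

    def test_closed_to_inactivated_forbidden(self, rates):
        # the irreversible step: no C4 -> I4 edge in the generator
        q = rate_matrix(rates)
        assert q[2, 0] == 0.0

    def test_rejects_coarse_step(self):
        with pytest.raises(ValueError):
            GatingRates(k1=0.4, dt=0.5)   # k1*dt = 0.2 >= 0.1

    def test_infinite_reverse_factor_disables_reverse(self):
        r = GatingRates(reverse_factor=np.inf)
        assert r.k_rev1 == 0.0 and r.k_rev2 == 0.0


class TestStep:
    def test_null_dynamics(self, rng):
        r = GatingRates(k1=0.0, k2=0.0, k3=0.0, reverse_factor=np.inf)
        ens = ReceptorEnsemble(C4=10, O4=5, I4=3)
        out = step(ens, r, rng)
        assert (out.C4, out.O4, out.I4) == (10, 5, 3)

    def test_counts_conserved_over_many_steps(self, rates, rng):
        ens = ReceptorEnsemble(C4=500, O4=300, I4=200)
        for _ in range(200):
            ens = step(ens, rates, rng)
            assert ens.total == 1000

    def test_single_exit_probability_matches_rate_times_dt(self, rates):
        # C4 -> O4 per-step probability is k1*dt = 0.005; freeze O4 by
        # zeroing its exits so one step counts transitions exactly
        r = GatingRates(k1=0.4, k2=0.0, k3=0.0, reverse_factor=np.inf)
        n = 2_000_000
        out = step(ReceptorEnsemble(C4=n), r, np.random.default_rng(7))
        p_hat = out.O4 / n
        se = np.sqrt(0.005 * 0.995 / n)
        assert abs(p_hat - 0.005) < 4 * se

    def test_per_receptor_mode_agrees_with_multinomial(self, rates):
        # same one-step transition law in both engines
        n = 20000
        a = step(ReceptorEnsemble(O4=n), rates, np.random.default_rng(1))
        b = step_per_receptor(ReceptorEnsemble(O4=n), rates,
                              np.random.default_rng(2))
        for s in ("C4", "I4"):
            pa, pb = getattr(a, s) / n, getattr(b, s) / n
            se = np.sqrt(2 * max(pa, pb) / n)
            assert abs(pa - pb) < 4 * se + 1e-9


class TestInjection:
    def test_increment_goes_to_closed_state(self):
        ens = ReceptorEnsemble(C4=3, O4=2, I4=1)
        out = inject_tetraliganded(ens, 10)
        assert (out.C4, out.O4, out.I4) == (7, 2, 1)

    def test_zero_increment_is_identity(self):
        ens = ReceptorEnsemble(C4=3, O4=2, I4=1)
        assert inject_tetraliganded(ens, 6) == ens

    def test_decrease_rejected(self):
        with pytest.raises(ValueError):
            inject_tetraliganded(ReceptorEnsemble(C4=10), 5)

    def test_protocol_targets_match_occupancy_oracle(self):
        proto = AdditionProtocol(
            events=((0.0, 60.0), (10.0, 90.0), (20.0, 120.0)),
            K_D=794.0, receptors_total=2e10, duration=30.0)
        model = OccupancyModel(LigandParams("IP3", 794.0), int(2e10))
        expected = [round(tetra_count(c, model)) for c in (60.0, 90.0, 120.0)]
        assert proto.target_counts() == expected

    def test_sequential_injection_fold_change(self):
        # 60 -> 90 nM multiplies the tetra-liganded total by 4.41
        proto = AdditionProtocol(events=((0.0, 60.0), (10.0, 90.0)),
                                 K_D=794.0, receptors_total=2e10,
                                 duration=20.0)
        t60, t90 = proto.target_counts()
        assert t90 / t60 == pytest.approx(4.41, abs=0.01)


class TestProtocolValidation:
    def test_decreasing_concentration_rejected(self):
        with pytest.raises(ValueError):
            AdditionProtocol(events=((0.0, 90.0), (10.0, 60.0)),
                             K_D=794.0, receptors_total=1e4, duration=20.0)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            AdditionProtocol(events=((10.0, 60.0), (10.0, 90.0)),
                             K_D=794.0, receptors_total=1e4, duration=20.0)


class TestSimulateProtocol:
    def test_zero_concentration_trajectory_is_empty(self, rates):
        proto = AdditionProtocol(events=((0.0, 0.0),), K_D=794.0,
                                 receptors_total=1e6, duration=5.0)
        df = simulate_protocol(proto, rates, seed=1)
        assert (df[["C4", "O4", "I4"]].to_numpy() == 0).all()

    def test_bitwise_reproducible(self, rates):
        proto = AdditionProtocol(events=((0.0, 200.0),), K_D=794.0,
                                 receptors_total=1e6, duration=20.0)
        a = simulate_protocol(proto, rates, seed=42)
        b = simulate_protocol(proto, rates, seed=42)
        assert a.equals(b)
        c = simulate_protocol(proto, rates, seed=43)
        assert not a.equals(c)

    def test_counts_conserved_between_injections(self, rates):
        proto = AdditionProtocol(events=((0.0, 100.0), (10.0, 300.0)),
                                 K_D=794.0, receptors_total=1e6,
                                 duration=20.0)
        df = simulate_protocol(proto, rates, seed=3)
        totals = df[["C4", "O4", "I4"]].sum(axis=1).to_numpy()
        t1, t2 = proto.target_counts()
        assert (totals[df.time_s < 10.0] == t1).all()
        assert (totals[df.time_s >= 10.0] == t2).all()

    def test_transient_surge_matches_master_equation(self, rates):
        # injection into C4 -> O4 surges then decays; the ensemble mean
        # tracks the matrix-exponential solution within 3 binomial SE
        n = 20000
        proto = AdditionProtocol(events=((0.0, 794.0 * 1e6),), K_D=794.0,
                                 receptors_total=n, duration=60.0)
        df = simulate_protocol(proto, rates, seed=11, record_every=160)
        assert df[["C4", "O4", "I4"]].sum(axis=1).iloc[0] == pytest.approx(
            n, rel=1e-3)
        n_inj = int(df[["C4", "O4", "I4"]].sum(axis=1).iloc[0])
        for _, row in df.iloc[1:].iterrows():
            p = meanfield_occupancies([1, 0, 0], rates, row.time_s)
            for k, s in enumerate(("C4", "O4", "I4")):
                se = np.sqrt(max(n_inj * p[k] * (1 - p[k]), 1e-9))
                assert abs(row[s] - n_inj * p[k]) < 3.5 * se, (row.time_s, s)
        # surge shape: O4 peaks early then decays well below the peak
        o4 = df["O4"].to_numpy()
        assert o4.max() == o4[: len(o4) // 3].max()
        assert o4[-1] < 0.5 * o4.max()

    def test_stationary_law_is_invariant(self, rates):
        # an ensemble started at the stationary distribution stays there
        pi = stationary_distribution(rates)
        n = 30000
        counts = np.round(pi * n).astype(int)
        proto_free = ReceptorEnsemble(C4=int(counts[0]), O4=int(counts[1]),
                                      I4=int(counts[2]))
        rng = np.random.default_rng(5)
        ens = proto_free
        for _ in range(int(200 / rates.dt)):
            ens = step(ens, rates, rng)
        for k, s in enumerate(("C4", "O4", "I4")):
            se = np.sqrt(max(n * pi[k] * (1 - pi[k]), 1e-9))
            assert abs(getattr(ens, s) - n * pi[k]) < 4 * se

    def test_halving_dt_leaves_mean_trajectory_unchanged(self, rates):
        # exact mean of the discrete chain via matrix powers: halving dt
        # moves it by less than one binomial SE at 1e5 receptors
        n, t = 1e5, 60.0
        q = rate_matrix(rates)

        def discrete_mean(dt):
            p_step = np.eye(3) + q * dt
            p = np.array([1.0, 0.0, 0.0])
            for _ in range(int(round(t / dt))):
                p = p_step @ p
            return p
        diff = np.abs(discrete_mean(rates.dt) - discrete_mean(rates.dt / 2))
        se = np.sqrt(0.25 / n)
        assert diff.max() < se


class TestMeanfield:
    def test_identity_cases(self, rates):
        p0 = [0.2, 0.3, 0.5]
        assert meanfield_occupancies(p0, rates, 0.0) == pytest.approx(p0)
        null = GatingRates(k1=0, k2=0, k3=0, reverse_factor=np.inf)
        assert meanfield_occupancies(p0, null, 500.0) == pytest.approx(p0)

    def test_expm_agrees_with_ode_integrator(self, rates):
        # two independent oracles for P(t) from pure C4
        q = rate_matrix(rates)
        sol = solve_ivp(lambda t, p: q @ p, (0, 2.0), [1.0, 0.0, 0.0],
                        rtol=1e-10, atol=1e-12, dense_output=True)
        p_ode = sol.y[:, -1]
        p_expm = meanfield_occupancies([1, 0, 0], rates, 2.0)
        assert p_expm == pytest.approx(p_ode, abs=1e-6)

    def test_probabilities_stay_normalized(self, rates):
        for t in (0.1, 1.0, 10.0, 1000.0):
            p = meanfield_occupancies([1, 0, 0], rates, t)
            assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_long_time_limit_is_stationary(self, rates):
        p = meanfield_occupancies([1, 0, 0], rates, 1e5)
        assert p == pytest.approx(stationary_distribution(rates), abs=1e-8)

    def test_rejects_bad_probabilities(self, rates):
        with pytest.raises(ValueError):
            meanfield_occupancies([-0.1, 0.6, 0.5], rates, 1.0)
        with pytest.raises(ValueError):
            meanfield_occupancies([0.5, 0.4, 0.0], rates, 1.0)


class TestDwellTimes:
    @pytest.mark.parametrize("state, expected", [
        ("C4", 2.5),                  # 1/k1: rapid opening
        ("O4", 1 / 0.204),            # 1/(k2 + k1/100): ~5 s before inactivating
        ("I4", 1 / 0.006),            # 1/(k3 + k2/100): slow recovery
    ])
    def test_mean_dwell_matches_exit_rates(self, rates, state, expected):
        d = dwell_time_sample(state, rates, n=20000, seed=9)
        assert d.mean() == pytest.approx(expected, rel=0.03)

    def test_absorbing_state_reports_infinite_dwell(self):
        r = GatingRates(k1=0.4, k2=0.2, k3=0.0, reverse_factor=np.inf)
        assert np.all(np.isinf(dwell_time_sample("I4", r, n=5, seed=0)))

    def test_recovery_dwell_without_reverse_path(self):
        r = GatingRates(reverse_factor=np.inf)
        d = dwell_time_sample("I4", r, n=20000, seed=2)
        assert d.mean() == pytest.approx(250.0, rel=0.03)
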