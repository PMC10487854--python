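import numpy as np
import pytest
from scipy.integrate import solve_ivp

from g4kit.exchange_kinetics import (
    build_rate_table,
    crosspeak_maximum_time,
    fit_autocorrelation,
    fit_crosspeak,
    fit_exchange_network,
    normalize_volumes,
    parse_pathway_label,
)
from g4kit.synthetic import (
    DEFAULT_MIXING_TIMES,
    ExchangeNetworkSpec,
    VolumeSeries,
    simulate_exchange,
)

TAUS = np.array(DEFAULT_MIXING_TIMES)


def _series(label, volumes, taus=TAUS):
    return VolumeSeries(label, tuple(taus), tuple(np.asarray(volumes, float)))


def _two_site(k, t1, taus=TAUS, noise=0.0, seed=None):
    return ExchangeNetworkSpec(
        sites=("S", "D"), rates={("S", "D"): k},
        t1={"S": t1, "D": t1}, m0={"S": 1.0, "D": 0.0},
        mixing_times=tuple(taus), noise_sigma=noise, seed=seed,
    )


class TestNormalize:
    def test_reference_scaled_to_100(self):
        raw = {
            "O5": _series("O5", 250.0 * np.exp(-TAUS / 0.5)),
            "I": _series("I", 100.0 * np.exp(-TAUS / 0.4)),
        }
        # reference volume is taken at the grid point nearest 13 ms
        ref0 = 250.0 * np.exp(-TAUS[0] / 0.5)
        out = normalize_volumes(raw, "O5", 0.013)
        assert out["O5"].v[0] == pytest.approx(100.0)
        assert np.allclose(out["I"].v, raw["I"].v * 100.0 / ref0)

    def test_already_normalized_unchanged(self):
        v = 100.0 * np.exp(-TAUS / 0.5) / np.exp(-TAUS[0] / 0.5)
        out = normalize_volumes({"O5": _series("O5", v)}, "O5", 0.013)
        assert np.allclose(out["O5"].v, v)

    def test_missing_or_invalid_reference(self):
        with pytest.raises(KeyError):
            normalize_volumes({"I": _series("I", np.ones_like(TAUS))}, "O5")
        with pytest.raises(ValueError):
            normalize_volumes({"O5": _series("O5", np.zeros_like(TAUS))}, "O5")


class TestAutocorrelationFit:
    def test_noise_free_parameters_recovered(self):
        v = 60 * np.exp(-1.5 * TAUS) + 40 * np.exp(-TAUS / 0.5)
        f = fit_autocorrelation(_series("O5", v))
        assert f.A1 == pytest.approx(60.0, rel=1e-3)
        assert f.A2 == pytest.approx(40.0, rel=1e-3)
        assert f.r1 == pytest.approx(1.5, rel=1e-3)
        assert f.T1 == pytest.approx(0.5, rel=1e-3)
        assert f.identifiable

    def test_pure_t1_decay_flagged_unidentifiable(self):
        v = 80 * np.exp(-TAUS / 0.6)
        f = fit_autocorrelation(_series("B", v))
        assert not f.identifiable
        assert f.t1_slow == pytest.approx(0.6, rel=1e-3)

    def test_zero_time_limit_is_amplitude_sum(self):
        v = 55 * np.exp(-2.2 * TAUS) + 25 * np.exp(-TAUS / 0.35)
        f = fit_autocorrelation(_series("I", v))
        assert f.A1 + f.A2 == pytest.approx(80.0, rel=1e-3)

    def test_rescaling_only_scales_amplitudes(self):
        v = 60 * np.exp(-1.5 * TAUS) + 40 * np.exp(-TAUS / 0.5)
        f1 = fit_autocorrelation(_series("O5", v))
        f2 = fit_autocorrelation(_series("O5", 3.5 * v))
        assert f2.A1 / f1.A1 == pytest.approx(3.5, rel=1e-6)
        assert f2.r1 == pytest.approx(f1.r1, rel=1e-6)
        assert f2.T1 == pytest.approx(f1.T1, rel=1e-6)

    def test_multistart_best_of_n_monotone(self):
        v = 60 * np.exp(-4.0 * TAUS) + 40 * np.exp(-TAUS / 0.8)
        sses = [fit_autocorrelation(_series("O5", v), n_starts=n).residual_sse
                for n in range(1, 6)]
        assert all(b <= a + 1e-12 for a, b in zip(sses, sses[1:]))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_autocorrelation(_series("O5", np.zeros_like(TAUS)))
        with pytest.raises(ValueError):
            fit_autocorrelation(VolumeSeries("O5", (0.1, 0.2, 0.3), (1.0, 0.5, 0.2)))


class TestCrosspeakFit:
    def test_noise_free_rate_recovered(self):
        v = 50 * np.exp(-TAUS / 0.4) * (1 - np.exp(-2.0 * TAUS))
        f = fit_crosspeak(_series("O3B", v), T1=0.4)
        assert f.A == pytest.approx(50.0, rel=1e-3)
        assert f.k == pytest.approx(2.0, rel=1e-3)

    def test_all_zero_flags_no_exchange(self):
        f = fit_crosspeak(_series("O3B", np.zeros_like(TAUS)), T1=0.4)
        assert f.no_exchange and f.k == 0.0

    def test_fitted_maximum_at_analytic_time(self):
        """dV/dtau = 0 at tau* = ln(1 + k T1)/k."""
        v = 50 * np.exp(-TAUS / 0.4) * (1 - np.exp(-2.0 * TAUS))
        f = fit_crosspeak(_series("O3B", v), T1=0.4)
        tstar = crosspeak_maximum_time(f.k, f.T1_used)
        grid = np.linspace(0.001, 3.0, 20000)
        numeric_max = grid[int(np.argmax(f(grid)))]
        assert tstar == pytest.approx(np.log1p(2.0 * 0.4) / 2.0, rel=1e-3)
        assert numeric_max == pytest.approx(tstar, abs=2e-3)

    def test_invalid_t1_rejected(self):
        with pytest.raises(ValueError):
            fit_crosspeak(_series("O3B", np.ones_like(TAUS)), T1=0.0)


class TestNetworkOracle:
    def test_two_site_transfer_matches_ode_integration(self):
        """Matrix-exponential simulator vs an independent ODE solve, and
        both equal the closed-form build-up for one-way exchange."""
        k, t1 = 2.0, 0.4
        series = simulate_exchange(_two_site(k, t1))
        A = np.array([[-k - 1 / t1, 0.0], [k, -1 / t1]])

        def rhs(_, y):
            return A @ y

        sol = solve_ivp(rhs, (0, TAUS[-1]), [1.0, 0.0], t_eval=TAUS,
                        rtol=1e-10, atol=1e-12)
        assert np.allclose(series["S"].v, sol.y[0], atol=1e-7)
        assert np.allclose(series["SD"].v, sol.y[1], atol=1e-7)
        closed = np.exp(-TAUS / t1) * (1 - np.exp(-k * TAUS))
        assert np.allclose(series["SD"].v, closed, atol=1e-10)

    def test_two_site_rate_recovered_within_15_percent(self):
        series = simulate_exchange(_two_site(2.0, 0.4))
        f = fit_crosspeak(series["SD"], T1=0.4)
        assert f.k == pytest.approx(2.0, rel=0.15)

    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("t1", [0.2, 0.5, 1.0])
    def test_slow_exchange_recovery_grid(self, k, t1):
        series = simulate_exchange(_two_site(k, t1))
        f = fit_crosspeak(series["SD"], T1=t1)
        assert f.k == pytest.approx(k, rel=0.15)

    def test_four_site_dominant_pathway_recovered(self):
        spec = ExchangeNetworkSpec(
            rates={("O5", "I"): 0.1, ("I", "O5"): 0.15, ("I", "O3"): 0.1,
                   ("O3", "I"): 0.3, ("O3", "B"): 2.0}
        )
        _, _, table = fit_exchange_network(simulate_exchange(spec))
        assert table[("O3", "B")] == pytest.approx(2.0, rel=0.15)
        # apparent rates are bounded by the fastest total site escape rate
        max_escape = 2.3
        assert all(v <= max_escape * 1.05 for v in table.rates.values())

    def test_noisy_replicates_recover_within_30_percent(self):
        """5% multiplicative noise: k within 30% in >= 90% of 100 seeded
        replicates."""
        ok = 0
        for seed in range(100):
            series = simulate_exchange(_two_site(2.0, 0.4, noise=0.05, seed=seed))
            f = fit_crosspeak(series["SD"], T1=0.4)
            if abs(f.k - 2.0) / 2.0 <= 0.30:
                ok += 1
        assert ok >= 90


class TestRateTable:
    def test_label_parsing(self):
        assert parse_pathway_label("O5I") == ("O5", "I")
        assert parse_pathway_label("IO5") == ("I", "O5")
        assert parse_pathway_label("O3B") == ("O3", "B")
        with pytest.raises(ValueError):
            parse_pathway_label("XY")

    def test_empty_and_duplicate_handling(self):
        from g4kit.exchange_kinetics import CrossFit
        assert len(build_rate_table({}, {})) == 0
        fits = {"O3B": CrossFit(1.0, 2.0, 0.4, 0.0)}
        dup = {"O3B": CrossFit(1.0, 2.0, 0.4, 0.0), "x": CrossFit(1.0, 1.0, 0.4, 0.0)}
        with pytest.raises(ValueError):
            build_rate_table({}, dup, pathway_map={"O3B": ("O3", "B"), "x": ("O3", "B")})
        table = build_rate_table({}, fits)
        assert table[("O3", "B")] == 2.0

    def test_unobserved_pathway_absent_not_zero(self):
        from g4kit.exchange_kinetics import CrossFit
        fits = {"O3B": CrossFit(0.0, 0.0, 0.4, 0.0, no_exchange=True)}
        table = build_rate_table({}, fits)
        assert ("O3", "B") not in table
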