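"""Curve fitting: parameter recovery, feature extraction, invariances."""

import numpy as np
import pytest

from navkit import (
    FIT_MODELS,
    FitError,
    activation_features,
    availability_features,
    deactivation_features,
    fit_curve,
    load_channel,
    make_protocol,
    repriming_features,
    run_protocol,
    slow_onset_features,
)
from navkit.channels import (
    MarkovSchemeSpec,
    MarkovTransition,
    build_generator,
)
from navkit.ratelaws import RateLaw

V_GRID = np.arange(-120.0, 1.0, 5.0)
T_LOG = np.logspace(-1, 3, 33)


# exact generator parameters and the grids they are sampled on
_RECOVERY_CASES = {
    "boltzmann": (V_GRID, {"V_half": -34.1, "k": -6.9}),
    "boltzmann_offset": (V_GRID, {"A": 0.05, "V_half": -89.1, "k": 5.5}),
    "mono_exp": (np.arange(0.025, 5.0, 0.025), {"A": 1.3, "tau": 0.8}),
    "hh_m3h": (np.arange(0.025, 14.0, 0.025), {"A": 2.0, "tau_m": 0.4, "tau_h": 1.5}),
    "recovery_single": (T_LOG, {"A1": 0.95, "tau1": 5.2}),
    "slow_onset_exp": (np.logspace(1, 4, 25), {"A1": 0.53, "A2": 0.47, "tau": 1780.0}),
    "recovery_double": (np.logspace(-1, 4, 41),
                        {"A1": 0.8, "tau1": 5.0, "A2": 0.2, "tau2": 600.0}),
}


@pytest.mark.parametrize("model", sorted(FIT_MODELS))
def test_zero_noise_parameter_recovery(model):
    """Each fit model recovers its own zero-noise generator within 0.1%."""
    x, params = _RECOVERY_CASES[model]
    y = FIT_MODELS[model].func(x, *[params[p] for p in FIT_MODELS[model].param_names])
    res = fit_curve(model, x, y)
    assert res.converged
    for name, true in params.items():
        assert res.params[name] == pytest.approx(true, rel=1e-3), (model, name)
    assert res.ssr < 1e-12


def test_fitted_ssr_not_worse_than_generator_ssr():
    """Optimality sanity: returned parameters never lose to the truth."""
    rng = np.random.default_rng(7)
    x = T_LOG
    true = (0.9, 8.0)
    y = FIT_MODELS["recovery_single"].func(x, *true) + rng.normal(0, 0.01, x.size)
    res = fit_curve("recovery_single", x, y)
    ssr_true = float(np.sum((FIT_MODELS["recovery_single"].func(x, *true) - y) ** 2))
    assert res.ssr <= ssr_true + 1e-12


def test_recovery_double_matches_grid_search_oracle():
    """Multi-start NLS vs an independent coarse grid search on tau1/tau2."""
    x = np.logspace(-1, 4, 41)
    y = FIT_MODELS["recovery_double"].func(x, 0.8, 5.0, 0.2, 600.0)
    # oracle: exhaustive tau grid, amplitudes by linear least squares
    best = None
    for t1 in np.logspace(-0.5, 1.5, 81):
        for t2 in np.logspace(1.5, 3.5, 81):
            B = np.column_stack([1 - np.exp(-x / t1), 1 - np.exp(-x / t2)])
            amps, *_ = np.linalg.lstsq(B, y, rcond=None)
            ssr = float(np.sum((B @ amps - y) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, t1, t2)
    res = fit_curve("recovery_double", x, y)
    assert res.params["tau1"] == pytest.approx(best[1], rel=0.1)
    assert res.params["tau2"] == pytest.approx(best[2], rel=0.1)
    assert res.ssr <= best[0] + 1e-12


def test_fit_rejects_underdetermined_input():
    with pytest.raises(FitError):
        fit_curve("recovery_double", [1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
    with pytest.raises(FitError):
        fit_curve("nonsense", [1, 2, 3], [1, 2, 3])


def test_fit_deterministic():
    x, params = _RECOVERY_CASES["slow_onset_exp"]
    y = FIT_MODELS["slow_onset_exp"].func(x, 0.5, 0.5, 1500.0) + 0.01 * np.sin(x)
    a = fit_curve("slow_onset_exp", x, y)
    b = fit_curve("slow_onset_exp", x, y)
    assert a.params == b.params and a.ssr == b.ssr


class TestActivationFeatures:
    def test_synthetic_boltzmann_conductance_recovered(self, markov):
        """A sweep family manufactured from a pure Boltzmann open-fraction
        profile recovers the generating V1/2 and k within 0.1 mV."""
        from navkit.protocols import EpochTrace, Sweep, SweepSet

        prot = make_protocol("activation")
        V = np.asarray(prot.sweep_values)
        v_half, k = -34.0, -7.0
        po = 1.0 / (1.0 + np.exp((V - v_half) / k))
        t = np.arange(0, 14.0, 0.025)
        sweeps = []
        for Vt, p in zip(V, po):
            I = markov.gbar * p * (Vt - markov.E_rev) * np.exp(-t / 3.0)
            sweeps.append(Sweep(float(Vt), [
                EpochTrace(V=-120.0, t=np.array([0.0, 2.0]),
                           states=np.zeros((2, 5)), I=np.zeros(2)),
                EpochTrace(V=float(Vt), t=2.0 + t, states=np.zeros((t.size, 5)), I=I),
            ]))
        ss = SweepSet(protocol=prot, channel=markov, dt=0.025, sweeps=sweeps)
        fs = activation_features(ss)
        assert fs.features["activation_v_half"] == pytest.approx(v_half, abs=0.1)
        assert fs.features["activation_k"] == pytest.approx(k, abs=0.1)

    def test_near_reversal_sweeps_excluded(self, markov):
        prot = make_protocol("activation",
                             sweep_values=[-40, -30, -20, -10, 0, 64.5])
        fs = activation_features(run_protocol(markov, prot))
        assert np.isfinite(fs.features["activation_v_half"])

    def test_time_constant_table_shapes(self, markov):
        fs = activation_features(run_protocol(markov, make_protocol("activation")))
        tbl = fs.tables["time_constants"]
        assert {"V_mV", "tau_m_ms", "tau_h_ms"} <= set(tbl.columns)
        assert (tbl["tau_m_ms"] > 0).all() and (tbl["tau_h_ms"] > 0).all()


class TestAvailabilityFeatures:
    def test_markov_flat_when_inactivation_removed(self, markov):
        """Deleting the closed->inactivated and open->inactivated entries
        leaves a flat availability curve, which is flagged."""
        keep = tuple(
            tr for tr in markov.transitions
            if (tr.source, tr.target) not in {("C1", "I1"), ("O1", "I1"), ("I1", "I2")}
        )
        no_inact = MarkovSchemeSpec(
            states=markov.states, open_state="O1", transitions=keep,
            gbar=markov.gbar, E_rev=markov.E_rev,
            temperature=markov.temperature, name="no_inactivation",
        )
        fs = availability_features(
            run_protocol(no_inact, make_protocol("availability"))
        )
        assert fs.fits["availability_boltzmann"].flagged

    def test_steady_state_features_q10_invariant(self, markov):
        cold = markov.with_temperature(T=20.0)
        hot = markov.with_temperature(T=30.0)
        f_c = availability_features(run_protocol(cold, make_protocol("availability")))
        f_h = availability_features(run_protocol(hot, make_protocol("availability")))
        # hotter kinetics equilibrate at least as fully within 500 ms
        assert abs(f_c.features["availability_v_half"]
                   - f_h.features["availability_v_half"]) < 0.05
        assert abs(f_c.features["availability_k"]
                   - f_h.features["availability_k"]) < 0.05


class TestDeactivationFeatures:
    def test_constant_closing_rate_pair_exact_tau(self):
        """An open/closed pair whose closing rate is a constant r and whose
        opening rate vanishes at hyperpolarized voltages has tail time
        constant 1/(r q10) exactly (q10 = 1 here)."""
        r = 0.5
        pair = MarkovSchemeSpec(
            states=("C", "O"), open_state="O",
            transitions=(
                MarkovTransition(
                    "C", "O",
                    RateLaw("sigmoid", {"A": 4.0, "V_half": -30.0, "k": -5.0})),
                MarkovTransition("O", "C", RateLaw("constant", {"A": r})),
            ),
            gbar=0.1, E_rev=65.0, name="pair",
        )
        fs = deactivation_features(
            run_protocol(pair, make_protocol("deactivation"))
        )
        tbl = fs.tables["tail_tau"].set_index("V_mV")
        # opening rate at -100 mV is ~3e-6 ms^-1: tail decays at r
        assert tbl.loc[-100.0, "tau_ms"] == pytest.approx(1.0 / r, rel=1e-4)

    def test_markov_tails_faster_when_hyperpolarized(self, markov):
        fs = deactivation_features(
            run_protocol(markov, make_protocol("deactivation"))
        )
        tbl = fs.tables["tail_tau"].sort_values("V_mV")
        assert tbl["tau_ms"].iloc[0] < tbl["tau_ms"].iloc[-1]

    def test_hh_tail_rate_matches_m3_kinetics(self, hh_row_h):
        """At strongly hyperpolarized tails the m^3 conductance decays at
        3 (alpha_m + beta_m) q10."""
        from navkit.ratelaws import eval_rate_law

        fs = deactivation_features(
            run_protocol(hh_row_h, make_protocol("deactivation"))
        )
        row = fs.tables["tail_tau"].set_index("V_mV").loc[-100.0]
        g = {g.name: g for g in hh_row_h.gates}
        q10 = hh_row_h.temperature.factor()
        rate_m = (eval_rate_law(g["m"].alpha, -100.0)
                  + eval_rate_law(g["m"].beta, -100.0)) * q10
        assert 1.0 / row["tau_ms"] == pytest.approx(3 * rate_m, rel=0.05)


class TestReprimingAndOnset:
    def test_sequential_scheme_tau_matches_slow_eigenvalue(self):
        """For a linear three-state chain the fitted slow recovery time
        constant approaches the generator's slowest relaxation time."""
        f1 = RateLaw("constant", {"A": 2.0})
        scheme = MarkovSchemeSpec(
            states=("C", "O", "I"),
            open_state="O",
            transitions=(
                MarkovTransition("C", "O", RateLaw("sigmoid", {"A": 4.0, "V_half": -40, "k": -8})),
                MarkovTransition("O", "C", RateLaw("sigmoid", {"A": 4.0, "V_half": -80, "k": 8})),
                MarkovTransition("O", "I", f1),
                MarkovTransition("I", "C", RateLaw("sigmoid", {"A": 0.2, "V_half": -110, "k": 10})),
            ),
            gbar=0.1, E_rev=65.0, name="three_state",
        )
        Q = build_generator(scheme, -120.0, q10=1.0)
        evals = np.sort(np.abs(np.linalg.eigvals(Q).real))
        slow = 1.0 / evals[1]  # slowest non-zero mode
        prot = make_protocol("fast_repriming",
                             sweep_values=np.logspace(-1, 2.5, 40))
        fs = repriming_features(run_protocol(scheme, prot), kind="fast")
        assert fs.features["recovery_tau"] == pytest.approx(slow, rel=0.15)

    def test_slow_onset_plateau_matches_null_space(self, markov):
        """The onset plateau approximates the equilibrium non-slow-
        inactivated availability at the conditioning voltage."""
        from navkit.channels import steady_state

        fs = slow_onset_features(run_protocol(markov, make_protocol("slow_onset")))
        eq = steady_state(markov, -20.0)
        available = 1.0 - eq["I2"]
        assert fs.features["slow_onset_plateau"] == pytest.approx(available, abs=0.05)

    def test_onset_flat_without_deep_state_flagged(self, markov):
        keep = tuple(tr for tr in markov.transitions
                     if (tr.source, tr.target) != ("I1", "I2"))
        # I2 unreachable -> drop it entirely
        no_i2 = MarkovSchemeSpec(
            states=("C1", "C2", "O1", "I1"), open_state="O1",
            transitions=tuple(tr for tr in keep if "I2" not in (tr.source, tr.target)),
            gbar=markov.gbar, E_rev=markov.E_rev,
            temperature=markov.temperature, name="no_i2",
        )
        fs = slow_onset_features(run_protocol(no_i2, make_protocol("slow_onset")))
        assert fs.fits["onset"].flagged
        assert fs.features["slow_onset_plateau"] == pytest.approx(1.0, abs=1e-3)

    def test_feature_extraction_pure(self, markov):
        ss = run_protocol(markov, make_protocol("fast_repriming"))
        a = repriming_features(ss, kind="fast")
        b = repriming_features(ss, kind="fast")
        assert a.features == b.features
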