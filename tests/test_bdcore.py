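"""Birth-death likelihoods, information criteria, and ML fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsetree import bdcore as bd
from pulsetree import simdata, treeio
from pulsetree.envmodels import make_pulse
from pulsetree.errors import DomainError, ValidationError
from pulsetree.treeio import BranchingTimes

BT3 = BranchingTimes(ages=np.array([2.0, 1.0]), n_tips=3)


def oracle_loglik(model, bt, max_step=0.02):
    """Independent route: LSODA integration of the log-survival ODE at
    rtol 1e-10 (scipy), assembled into the same conditioned likelihood."""
    from scipy.integrate import solve_ivp

    lam = lambda t: float(model.speciation.values(np.atleast_1d(t))[0])
    mu = lambda t: float(model.extinction.values(np.atleast_1d(t))[0])
    rho = model.sampling_fraction

    def rhs(t, y):
        l, m = lam(t), mu(t)
        return [(l - m) - l * math.exp(min(y[0], 0.0)), l - m]

    ts = np.unique(np.concatenate([bt.ages, [0.0, bt.crown_age]]))
    sol = solve_ivp(rhs, (0.0, bt.crown_age), [math.log(rho), 0.0], t_eval=ts,
                    rtol=1e-10, atol=1e-12, max_step=max_step, method="LSODA")
    Y = dict(zip(sol.t, sol.y[0]))
    R = dict(zip(sol.t, sol.y[1]))
    logq = {t: 2 * Y[t] - R[t] - math.log(rho) for t in sol.t}
    ll = 2 * (logq[bt.crown_age] - Y[bt.crown_age])
    for x in bt.ages[1:]:
        ll += math.log(lam(x)) + logq[x]
    return ll


class TestConstantBD:
    def test_yule_three_tip_closed_form(self):
        # pure birth, rho=1, crown-conditioned: L = e^{-2 lam x1} * lam e^{-lam x2}
        lam = 0.3
        hand = -2 * lam * 2.0 + math.log(lam) - lam * 1.0
        assert bd.loglik_constant_bd(BT3, lam, 0.0, 1.0) == pytest.approx(hand, abs=1e-12)

    def test_equal_rates_limit_continuous(self):
        at = bd.loglik_constant_bd(BT3, 0.3, 0.3, 0.9)
        near = bd.loglik_constant_bd(BT3, 0.3, 0.3 * (1 - 1e-8), 0.9)
        assert at == pytest.approx(near, abs=1e-5)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bd.loglik_constant_bd(BT3, 0.0, 0.1, 1.0)
        with pytest.raises(DomainError):
            bd.loglik_constant_bd(BT3, 0.3, -0.1, 1.0)
        with pytest.raises(DomainError):
            bd.loglik_constant_bd(BT3, 0.3, 0.1, 0.0)

    def test_rho_one_continuity(self):
        # continuity of the likelihood in rho near 1
        lls = [bd.loglik_constant_bd(BT3, 0.4, 0.2, r) for r in (0.999999, 1.0)]
        assert lls[0] == pytest.approx(lls[1], abs=1e-4)

    def test_parameter_array_broadcasting(self):
        lams = np.array([0.2, 0.3, 0.4])
        out = bd.loglik_constant_bd(BT3, lams, 0.1, 0.9)
        assert out.shape == (3,)
        for i, l in enumerate(lams):
            assert out[i] == pytest.approx(bd.loglik_constant_bd(BT3, l, 0.1, 0.9))


class TestCrossRouteAgreement:
    def test_three_routes_agree_on_simulated_trees(self, small_trees):
        for bt in small_trees:
            llc = bd.loglik_constant_bd(bt, 0.25, 0.19, 0.74)
            llt = bd.loglik_timevarying_bd(
                bt, bd.BDModel(bd.RateSpec(0.25), bd.RateSpec(0.19), 0.74)
            )
            lle = bd.loglik_episodic_bd(
                bt, bd.EpisodicBDModel([0.25], [0.19], [], [], 0.74)
            )
            assert abs(llc - llt) < 1e-4
            assert abs(llc - lle) < 1e-10

    def test_grid_self_convergence(self, small_trees):
        model = bd.BDModel(
            bd.RateSpec(0.2, time_sensitivity=0.02),
            bd.RateSpec(0.1, time_sensitivity=-0.01),
            0.74,
        )
        for bt in small_trees[:10]:
            coarse = bd.loglik_timevarying_bd(bt, model, grid_step=0.1)
            fine = bd.loglik_timevarying_bd(bt, model, grid_step=0.05)
            assert abs(coarse - fine) < 1e-4

    def test_pulse_model_matches_independent_ode_solver(self, small_trees):
        bt = small_trees[0]
        pulse = make_pulse(15.0, 0.5, (0.0, bt.crown_age))
        for alpha in (2.0, 6.0):
            model = bd.BDModel(
                bd.RateSpec(0.3),
                bd.RateSpec(0.05, env_sensitivity=alpha, covariate=pulse),
                0.74,
            )
            assert bd.loglik_timevarying_bd(bt, model) == pytest.approx(
                oracle_loglik(model, bt), abs=1e-5
            )


class TestEpisodic:
    def test_identity_event(self, small_trees):
        bt = small_trees[1]
        base = bd.loglik_episodic_bd(bt, bd.EpisodicBDModel([0.25], [0.1], [], [], 0.74))
        with_s1 = bd.loglik_episodic_bd(
            bt, bd.EpisodicBDModel([0.25], [0.1], [], [(bt.crown_age / 2, 1.0)], 0.74)
        )
        assert with_s1 == pytest.approx(base, abs=1e-12)

    def test_interval_structure(self, small_trees):
        bt = small_trees[2]
        uniform = bd.loglik_episodic_bd(bt, bd.EpisodicBDModel([0.25], [0.1], [], [], 0.74))
        split = bd.loglik_episodic_bd(
            bt, bd.EpisodicBDModel([0.25, 0.25], [0.1, 0.1], [bt.crown_age / 3], [], 0.74)
        )
        assert split == pytest.approx(uniform, abs=1e-10)

    def test_event_domain_checks(self):
        with pytest.raises(DomainError):
            bd.EpisodicBDModel([0.2], [0.1], [], [(1.0, 1.5)], 1.0)
        with pytest.raises(DomainError):
            bd.loglik_episodic_bd(
                BT3, bd.EpisodicBDModel([0.2], [0.1], [], [(2.5, 0.5)], 1.0)
            )

    def test_true_event_model_beats_no_event_on_event_trees(self, event_trees):
        # evaluated at the generating parameters: the model with the 95%
        # kill at 34 Ma should dominate the rate-matched no-event model
        wins = 0
        for bt, truth in event_trees:
            with_event = bd.loglik_episodic_bd(
                bt, bd.EpisodicBDModel([0.25], [0.11], [], [(34.0, 0.05)], 0.74)
            )
            without = bd.loglik_episodic_bd(
                bt, bd.EpisodicBDModel([0.25], [0.11], [], [], 0.74)
            )
            wins += with_event > without
        assert wins >= 0.9 * len(event_trees)


class TestAICc:
    def test_closed_formula(self):
        assert bd.aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98)
        assert bd.aicc(0.0, 0, 10) == 0.0

    def test_domain(self):
        with pytest.raises(DomainError):
            bd.aicc(0.0, 9, 10)

    @given(st.integers(1, 20), st.integers(25, 500), st.floats(-1e3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_correction_positive(self, k, n, logL):
        assert bd.aicc(logL, k, n) > -2 * logL + 2 * k


class TestAkaikeWeights:
    def test_two_equal(self):
        assert np.allclose(bd.akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_single(self):
        assert np.allclose(bd.akaike_weights([123.4]), [1.0])

    def test_evidence_ratio_inversion(self):
        # delta chosen so that w1/w2 = 35.3
        delta = 2 * math.log(35.3)
        w = bd.akaike_weights([100.0, 100.0 + delta])
        assert w[0] / w[1] == pytest.approx(35.3, rel=1e-9)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=8),
           st.floats(-1e6, 1e6))
    @settings(max_examples=60, deadline=None)
    def test_shift_invariance_and_normalization(self, vals, shift):
        w1 = bd.akaike_weights(vals)
        w2 = bd.akaike_weights([v + shift for v in vals])
        assert abs(w1.sum() - 1) < 1e-12
        assert np.allclose(w1, w2, atol=1e-12)

    def test_all_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            bd.akaike_weights([math.inf, math.nan])


class TestSamplingFraction:
    def test_empirical_value(self):
        assert round(bd.sampling_fraction(89, 120), 2) == 0.74


class TestFitML:
    def test_zero_restarts_rejected(self, small_trees):
        with pytest.raises(DomainError):
            bd.fit_ml(small_trees[0], bd.BDModel(bd.RateSpec(0.1), bd.RateSpec(0.05), 1.0),
                      ["lambda0"], n_restarts=0)

    def test_tiny_tree_rejected(self):
        bt2 = BranchingTimes(ages=np.array([2.0]), n_tips=2)
        with pytest.raises(ValidationError):
            bd.fit_ml(bt2, bd.BDModel(bd.RateSpec(0.1), bd.RateSpec(0.05), 1.0), ["lambda0"])

    def test_no_free_parameters_is_plain_evaluation(self, small_trees):
        bt = small_trees[3]
        model = bd.BDModel(bd.RateSpec(0.25), bd.RateSpec(0.19), 0.74)
        res = bd.fit_ml(bt, model, [])
        assert res.k == 0
        assert res.log_likelihood == pytest.approx(
            bd.loglik_timevarying_bd(bt, model), abs=1e-8
        )

    def test_deterministic_given_seed(self, small_trees):
        bt = small_trees[4]
        model = bd.BDModel(bd.RateSpec(0.1), bd.RateSpec(0.05), 1.0)
        r1 = bd.fit_ml(bt, model, ["lambda0", "mu0"], n_restarts=3, seed=11)
        r2 = bd.fit_ml(bt, model, ["lambda0", "mu0"], n_restarts=3, seed=11)
        assert r1.parameters == r2.parameters
        assert r1.log_likelihood == r2.log_likelihood

    def test_fit_agrees_between_grid_and_episodic_routes(self, small_trees):
        bt = small_trees[5]
        f_grid = bd.fit_ml(bt, bd.BDModel(bd.RateSpec(0.1), bd.RateSpec(0.05), 1.0),
                           ["lambda0", "mu0"], n_restarts=3, seed=2)
        f_epi = bd.fit_ml(bt, bd.EpisodicBDModel([0.1], [0.05], [], [], 1.0),
                          ["lambda0", "mu0"], n_restarts=3, seed=2)
        assert f_grid.parameters["lambda0"] == pytest.approx(
            f_epi.parameters["lambda0"], rel=1e-3
        )
        assert f_grid.aicc == pytest.approx(f_epi.aicc, abs=1e-2)

    def test_recovery_improves_with_tree_size(self):
        # asymptotic consistency: median relative error of lambda-hat
        # shrinks from 50-tip to 400-tip trees
        errs = {}
        for n_lo, n_hi, label, seed0 in ((40, 60, "small", 7000), (250, 450, "large", 8000)):
            rel = []
            for i in range(10):
                cfg = simdata.TreeSimConfig(
                    crown_age=math.log((n_lo + n_hi) / 4) / 0.06,
                    lambda0=0.25, mu0=0.19, rho=1.0,
                    min_tips=n_lo, max_tips=n_hi, seed=seed0 + i,
                )
                tree, _ = simdata.simulate_tree(cfg)
                bt = treeio.branching_times(tree)
                f = bd.fit_ml(bt, bd.EpisodicBDModel([0.1], [0.05], [], [], 1.0),
                              ["lambda0", "mu0"], n_restarts=3, seed=i)
                rel.append(abs(f.parameters["lambda0"] - 0.25) / 0.25)
            errs[label] = float(np.median(rel))
        assert errs["large"] < errs["small"]
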