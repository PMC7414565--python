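"""Pulse scans, support classes, survival priors, Bayes-factor profiles."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from pulsetree import bdcore as bd
from pulsetree import scan, simdata, treeio
from pulsetree.errors import DomainError, ValidationError


@pytest.fixture(scope="module")
def demo_bt():
    cfg = simdata.TreeSimConfig(
        crown_age=40.0, lambda0=0.18, mu0=0.05, rho=1.0,
        min_tips=25, max_tips=60, seed=77,
    )
    tree, _ = simdata.simulate_tree(cfg)
    return treeio.branching_times(tree)


class TestSupportClasses:
    @pytest.mark.parametrize(
        "delta, cls",
        [(0.0, "indistinguishable"), (3.9, "indistinguishable"),
         (4.0, "indistinguishable"), (7.0, "moderate"), (10.0, "moderate"),
         (12.0, "strong")],
    )
    def test_aicc_classes(self, delta, cls):
        assert scan.classify_support(delta) == cls

    @pytest.mark.parametrize(
        "bf, cls",
        [(1.9, "none"), (2.0, "none"), (3.56, "moderate"), (6.0, "moderate"),
         (6.5, "strong")],
    )
    def test_bf_classes(self, bf, cls):
        assert scan.classify_bf(bf) == cls


class TestCandidateGrids:
    def test_default_pulse_grid_integer_ages(self):
        g = scan.default_pulse_grid(50.0)
        assert g.ages.min() == 1.0 and g.ages.max() == 49.0
        assert np.all(np.diff(g.ages) == -1)

    def test_default_bf_grid(self):
        g = scan.default_bf_grid(50.0)
        assert g.ages.max() == 48.75 and g.ages.min() == 1.25

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            scan.CandidateGrid(ages=np.array([3.0, 3.0]))


class TestSurvivalPrior:
    @pytest.mark.parametrize(
        "mean, ci",
        [(0.05, (0.01, 0.10)), (0.25, (0.07, 0.50)), (0.75, (0.48, 0.94))],
    )
    def test_stated_priors_fit(self, mean, ci):
        p = scan.fit_survival_prior(mean, ci)
        d = p.distribution()
        assert abs(d.mean() - mean) < 0.01
        assert abs(d.ppf(0.025) - ci[0]) < 0.03
        assert abs(d.ppf(0.975) - ci[1]) < 0.03

    def test_symmetric_interval_gives_symmetric_beta(self):
        p = scan.fit_survival_prior(0.5, (0.2, 0.8))
        assert p.a == pytest.approx(p.b, rel=1e-2)

    def test_quantiles_recovered_by_quadrature(self):
        # independent quantile check: integrate the fitted Beta density
        p = scan.fit_survival_prior(0.05, (0.01, 0.10))
        pdf = p.distribution().pdf
        q025 = p.distribution().ppf(0.025)
        mass = quad(pdf, 0, q025, epsabs=1e-12)[0]
        assert mass == pytest.approx(0.025, abs=1e-8)

    def test_infeasible_interval_rejected(self):
        with pytest.raises(DomainError):
            scan.fit_survival_prior(0.5, (0.6, 0.9))


class TestEvidenceRatio:
    def test_identity_e_and_transitivity(self, demo_bt):
        prof = scan.run_pulse_scan(
            demo_bt,
            grid=scan.CandidateGrid(ages=np.array([10.0, 20.0, 30.0])),
            rho=1.0, seed=3, include_time_varying=False,
        )
        tab = prof.table
        assert abs(tab["weight"].sum() - 1) < 1e-12
        assert (tab["delta_aicc"] == 0).sum() == 1
        m = list(tab["model"])
        assert scan.evidence_ratio(prof, m[0], m[0]) == pytest.approx(1.0)
        r_ab = scan.evidence_ratio(prof, m[0], m[1])
        r_bc = scan.evidence_ratio(prof, m[1], m[2])
        r_ac = scan.evidence_ratio(prof, m[0], m[2])
        assert r_ab * r_bc == pytest.approx(r_ac, rel=1e-9)
        # ratio equals the closed form from the AICc difference
        d = float(tab.set_index("model").loc[m[1], "aicc"] - tab.set_index("model").loc[m[0], "aicc"])
        assert r_ab == pytest.approx(math.exp(d / 2), rel=1e-9)

    def test_null_reduction(self, demo_bt):
        # with the sensitivity fixed at zero the pulse model is the null
        engine = bd.TimeVaryingGrid(demo_bt)
        null = bd.fit_ml(
            demo_bt, bd.BDModel(bd.RateSpec(0.1), bd.RateSpec(0.05), 1.0),
            ["lambda0", "mu0"], n_restarts=4, seed=0, engine=engine,
        )
        from pulsetree.envmodels import make_pulse

        pulse = make_pulse(20.0, 0.5, (0.0, demo_bt.crown_age))
        fixed = bd.BDModel(
            bd.RateSpec(null.parameters["lambda0"]),
            bd.RateSpec(null.parameters["mu0"], env_sensitivity=0.0, covariate=pulse),
            1.0,
        )
        assert bd.loglik_timevarying_bd(demo_bt, fixed) == pytest.approx(
            null.log_likelihood, abs=1e-3
        )


class TestPulseScanStructure:
    def test_profile_contents_and_determinism(self, demo_bt):
        g = scan.CandidateGrid(ages=np.array([12.0, 22.0, 32.0]))
        p1 = scan.run_pulse_scan(demo_bt, grid=g, rho=1.0, seed=5)
        p2 = scan.run_pulse_scan(demo_bt, grid=g, rho=1.0, seed=5)
        assert p1.table["logL"].tolist() == p2.table["logL"].tolist()
        models = set(p1.table["model"])
        assert {"null", "pulse_12", "pulse_22", "pulse_32",
                "tv_lambda", "tv_mu", "tv_both"} <= models
        pulses = p1.table[p1.table["age_ma"].notna()]
        assert p1.weight_mode_age() in set(pulses["age_ma"])
        # null is k=2, pulse models k=3
        tab = p1.table.set_index("model")
        assert tab.loc["null", "k"] == 2
        assert tab.loc["pulse_22", "k"] == 3

    def test_speciation_target_runs(self, demo_bt):
        g = scan.CandidateGrid(ages=np.array([15.0]))
        p = scan.run_pulse_scan(
            demo_bt, grid=g, rho=1.0, target="speciation", seed=1,
            include_time_varying=False,
        )
        assert "pulse_15" in set(p.table["model"])
        alpha = p.table.set_index("model").loc["pulse_15", "parameters"]["lambda_env"]
        assert alpha <= 0  # speciation drop, not boost

    def test_temperature_models_included(self, demo_bt):
        raw = simdata.simulate_temperature(
            simdata.TempSimConfig(seed=4, support=(0.0, demo_bt.crown_age + 1))
        )
        p = scan.run_pulse_scan(
            demo_bt, grid=scan.CandidateGrid(ages=np.array([20.0])),
            rho=1.0, temperature=raw.curve, seed=2, include_time_varying=False,
        )
        assert {"temperature", "temperature_roc"} <= set(p.table["model"])


class TestBFProfile:
    def test_near_one_survival_prior_gives_null_bf(self, demo_bt):
        # a prior concentrated at s ~ 1 makes the event a no-op
        prior = scan.SurvivalPrior(mean_survival=0.999, ci95=(0.995, 0.9999),
                                   a=5000.0, b=5.0)
        prof = scan.run_bf_profile(
            demo_bt, grid=scan.CandidateGrid(ages=np.array([10.0, 25.0])),
            prior=prior, rho=1.0, n_nodes=16, seed=0,
        )
        assert np.all(np.abs(prof.table["two_ln_bf"]) < 0.1)

    def test_grid_order_invariance(self, demo_bt):
        prior = scan.fit_survival_prior(0.05, (0.01, 0.10))
        rp = scan.default_rate_priors(demo_bt, 1.0)
        a = scan.run_bf_profile(
            demo_bt, grid=scan.CandidateGrid(ages=np.array([10.0, 20.0, 30.0])),
            prior=prior, rate_priors=rp, rho=1.0, n_nodes=12,
        )
        b = scan.run_bf_profile(
            demo_bt, grid=scan.CandidateGrid(ages=np.array([30.0, 10.0, 20.0])),
            prior=prior, rate_priors=rp, rho=1.0, n_nodes=12,
        )
        assert np.allclose(
            a.table.sort_values("age_ma")["two_ln_bf"].to_numpy(),
            b.table.sort_values("age_ma")["two_ln_bf"].to_numpy(),
        )

    def test_convergence_flag(self, demo_bt):
        prior = scan.fit_survival_prior(0.05, (0.01, 0.10))
        prof = scan.run_bf_profile(
            demo_bt, grid=scan.CandidateGrid(ages=np.array([15.0])),
            prior=prior, rho=1.0, n_nodes=24, check_convergence=True,
        )
        assert prof.table["converged"].all()
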