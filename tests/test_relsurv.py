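"""Excess-hazard model: predictions, likelihood, fitting, invariances."""

import numpy as np
import pandas as pd
import pytest

import relmediate as rm
from relmediate.design import LinearTerm
from relmediate.relsurv import RelSurvSpec, design_matrices, _negll_grad
from relmediate.splines import RcsSpec

from conftest import flat_lifetable, weibull_fit


def _frame(n=2, **over):
    base = {
        "time": 1.0,
        "event": 1,
        "exposure": [0, 1][:n] if n <= 2 else 0,
        "mediator": "a",
        "age": 70.0,
        "sex": "male",
        "year": 2012.0,
    }
    base.update(over)
    return pd.DataFrame({k: (v if np.ndim(v) else [v] * n) for k, v in base.items()})


class TestPredictions:
    def test_zero_coefficients_give_unit_cumhaz(self):
        fit = weibull_fit(0.0, 0.0)
        df = _frame(1)
        assert np.allclose(rm.cumulative_excess_hazard(fit, df, 2.3), 1.0)
        assert np.allclose(rm.relative_survival(fit, df, 2.3), np.exp(-1.0))

    def test_weibull_closed_form(self):
        lam0, kappa, bx = 0.3, 1.4, 0.5
        fit = weibull_fit(np.log(lam0), kappa, (LinearTerm("exposure"),), (bx,))
        df = _frame(2)
        for t in (0.2, 1.0, 3.7):
            lp = bx * df["exposure"].to_numpy()
            R = np.exp(-lam0 * t**kappa * np.exp(lp))
            lam = lam0 * kappa * t ** (kappa - 1) * np.exp(lp)
            assert np.max(np.abs(rm.relative_survival(fit, df, t) - R)) < 1e-10
            assert np.max(np.abs(rm.excess_hazard(fit, df, t) - lam)) < 1e-10

    def test_hazard_matches_cumhaz_derivative(self):
        fit = weibull_fit(np.log(0.2), 0.8, (LinearTerm("exposure"),), (0.4,))
        df = _frame(2)
        for t in (0.5, 2.0, 4.0):
            h = 1e-6 * t
            fd = (
                rm.cumulative_excess_hazard(fit, df, t + h)
                - rm.cumulative_excess_hazard(fit, df, t - h)
            ) / (2 * h)
            lam = rm.excess_hazard(fit, df, t)
            assert np.max(np.abs(fd - lam)) < 1e-6 * np.max(np.abs(lam))

    def test_exponential_hazard_constant_in_time(self):
        fit = weibull_fit(np.log(0.25), 1.0)
        df = _frame(1)
        assert np.allclose(rm.excess_hazard(fit, df, 1.3), rm.excess_hazard(fit, df, 2.6))

    def test_nonpositive_time_rejected(self):
        fit = weibull_fit(0.0, 1.0)
        with pytest.raises(rm.DomainError):
            rm.eta(fit, _frame(1), 0.0)

    def test_zero_coefficient_td_term_leaves_eta_unchanged(self):
        base = weibull_fit(np.log(0.3), 1.2, (LinearTerm("exposure"),), (0.5,))
        td_spec = RelSurvSpec(
            baseline=base.spec.baseline,
            terms=base.spec.terms,
            td=((LinearTerm("exposure"), RcsSpec(knots=(np.log(0.05), np.log(2.0), np.log(6.0)))),),
        )
        nested = rm.RelSurvFit(
            spec=td_spec,
            beta=np.concatenate([base.beta, np.zeros(2)]),
            cov=np.eye(5),
            colnames=[],
            loglik=0.0,
            grad_norm=0.0,
            n_iter=0,
            converged=True,
        )
        df = _frame(2)
        for t in (0.3, 1.0, 4.0):
            assert np.allclose(rm.eta(base, df, t), rm.eta(nested, df, t), atol=1e-14)


class TestLikelihood:
    def test_censored_contribution_is_minus_cumhaz(self):
        lt = flat_lifetable(0.02)
        fit = weibull_fit(np.log(0.1), 0.8)
        df = _frame(1, event=0, time=2.0)
        ll = rm.log_likelihood(fit.beta, df, lt, fit.spec)
        assert np.isclose(ll, -0.1 * 2.0**0.8, atol=1e-12)

    def test_single_event_direct_evaluation(self):
        # h* = 0.02, Lambda_E(1) = 0.1 and lambda(1) = 0.08 via Weibull kappa = 0.8
        lt = flat_lifetable(0.02)
        fit = weibull_fit(np.log(0.1), 0.8)
        df = _frame(1, event=1, time=1.0)
        ll = rm.log_likelihood(fit.beta, df, lt, fit.spec)
        assert np.isclose(ll, np.log(0.10) - 0.1, atol=1e-12)

    def test_matches_per_record_loop(self, toy_frame, toy_models):
        lt = flat_lifetable(0.03)
        fit = toy_models.rs
        ll = rm.log_likelihood(fit.beta, toy_frame, lt, fit.spec)
        total = 0.0
        for _, row in toy_frame.iterrows():
            one = row.to_frame().T
            t = float(row["time"])
            lam = rm.excess_hazard(fit, one, t)[0]
            Lam = rm.cumulative_excess_hazard(fit, one, t)[0]
            if row["event"] == 1:
                total += np.log(0.03 + lam)
            total -= Lam
        assert np.isclose(ll, total, atol=1e-10)

    def test_gradient_matches_finite_differences(self, toy_frame, toy_models):
        lt = flat_lifetable(0.03)
        fit = toy_models.rs
        t = toy_frame["time"].to_numpy(float)
        d = toy_frame["event"].to_numpy(float)
        X, Xp, _ = design_matrices(fit.spec, toy_frame, t)
        hstar = np.full(len(toy_frame), 0.03)
        beta = fit.beta * 0.9
        f0, g0 = _negll_grad(beta, X, Xp, t, d, hstar)
        for j in range(beta.size):
            h = 1e-6
            bp = beta.copy()
            bp[j] += h
            bm = beta.copy()
            bm[j] -= h
            fd = (_negll_grad(bp, X, Xp, t, d, hstar)[0] - _negll_grad(bm, X, Xp, t, d, hstar)[0]) / (2 * h)
            assert abs(fd - g0[j]) < 1e-5 * max(1.0, abs(g0[j]))


class TestFitting:
    def test_all_censored_rejected(self, zero_lifetable):
        df = _frame(4, event=0, time=[1.0, 2.0, 1.5, 0.7], exposure=[0, 1, 0, 1])
        df["stratum"] = "0"
        spec = RelSurvSpec(baseline=RcsSpec(knots=(np.log(0.1), np.log(3.0))))
        with pytest.raises(rm.ValidationError, match="event"):
            rm.fit_relsurv(df, zero_lifetable, spec, stratum_col="stratum")

    def test_duplicated_column_is_rank_deficiency(self, sim):
        spec = RelSurvSpec(
            baseline=sim.rs.spec.baseline,
            terms=(LinearTerm("exposure"), LinearTerm("exposure")),
        )
        with pytest.raises(rm.RankDeficiencyError, match="exposure"):
            rm.fit_relsurv(sim.frame, sim.lt, spec, stratum_col="stratum")

    def test_weibull_simulation_recovery(self):
        """A df-1 baseline fit on Weibull data recovers (ln lam0, kappa, b_x)
        within 3 standard errors at n = 5,000."""
        rng = np.random.default_rng(10)
        n = 5000
        lam0, kappa, bx = 0.15, 0.8, 0.4
        x = rng.integers(0, 2, n)
        e = rng.exponential(size=n)
        t_cancer = (e / (lam0 * np.exp(bx * x))) ** (1 / kappa)
        t_other = rng.exponential(1 / 0.02, size=n)
        time = np.minimum(np.minimum(t_cancer, t_other), 5.0)
        event = (np.minimum(t_cancer, t_other) <= 5.0).astype(int)
        df = pd.DataFrame(
            {
                "time": np.maximum(time, 1e-8),
                "event": event,
                "exposure": x,
                "mediator": "a",
                "age": 70.0,
                "sex": "male",
                "year": 2012.0,
            }
        )
        lt = flat_lifetable(0.02)
        spec = RelSurvSpec(
            baseline=RcsSpec(knots=(np.log(0.01), np.log(5.0))),
            terms=(LinearTerm("exposure"),),
        )
        fit = rm.fit_relsurv(df, lt, spec)
        truth = np.array([np.log(lam0), kappa, bx])
        se = np.sqrt(np.diag(fit.cov))
        assert np.all(np.abs(fit.beta - truth) < 3 * se)
        assert fit.grad_norm < 1e-6

    def test_zero_expected_hazard_reduces_to_allcause_weibull(self):
        """With h* = 0 the fit equals an ordinary censored-Weibull MLE
        (independent brute-force optimization of the closed-form likelihood)."""
        import scipy.optimize

        rng = np.random.default_rng(11)
        n = 2000
        lam0, kappa = 0.25, 1.3
        t_event = (rng.exponential(size=n) / lam0) ** (1 / kappa)
        time = np.minimum(t_event, 4.0)
        event = (t_event <= 4.0).astype(int)
        df = pd.DataFrame(
            {
                "time": time,
                "event": event,
                "exposure": 0,
                "mediator": "a",
                "age": 70.0,
                "sex": "male",
                "year": 2012.0,
            }
        )
        lt = flat_lifetable(0.0)
        spec = RelSurvSpec(baseline=RcsSpec(knots=(np.log(0.01), np.log(5.0))))
        fit = rm.fit_relsurv(df, lt, spec)

        def negll(par):
            ll0, kk = par
            lam = np.exp(ll0)
            return -np.sum(
                event * (np.log(lam * kk) + (kk - 1) * np.log(time)) - lam * time**kk
            )

        res = scipy.optimize.minimize(negll, [0.0, 1.0], method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12})
        assert np.allclose(fit.beta, res.x, atol=1e-5)

    def test_orthogonalization_leaves_predictions_invariant(self, sim):
        spec_o = rm.default_relsurv_spec(
            sim.frame,
            sim.cfg.mediator_levels,
            baseline_df=4,
            td_df=0,
            td_vars=(),
            mediator_exposure_interaction=False,
            orthogonalize=True,
        )
        fit_o = rm.fit_relsurv(sim.frame, sim.lt, spec_o, stratum_col="stratum")
        sub = sim.frame.head(25)
        for t in (0.5, 2.0, 4.5):
            assert np.max(np.abs(rm.eta(sim.rs, sub, t) - rm.eta(fit_o, sub, t))) < 1e-10

    def test_covariance_symmetric_psd(self, sim):
        cov = sim.rs.cov
        assert np.allclose(cov, cov.T)
        w = np.linalg.eigvalsh(cov)
        assert w.min() > -1e-10 * max(1.0, w.max())

    def test_serialization_round_trip(self, sim, tmp_path):
        path = tmp_path / "fit.json"
        sim.rs.save(path)
        back = rm.RelSurvFit.load(path)
        sub = sim.frame.head(10)
        assert np.array_equal(rm.eta(sim.rs, sub, 2.0), rm.eta(back, sub, 2.0))
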