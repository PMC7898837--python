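"""Standardization and mediation estimands: loop oracles on small fixtures,
algebraic identities, collapse properties."""

import numpy as np
import pandas as pd
import pytest

import relmediate as rm
from relmediate.design import CategoricalTerm, LinearTerm
from relmediate.mediation import StandardizationEngine, ac_sstar_matrices

from conftest import flat_lifetable, toy_mediator_fit, weibull_fit

T_GRID = np.array([0.5, 1.0, 3.0, 5.0])


def loop_xi(rs, mf, frame, y, x, t_grid, sstar=None):
    """Independent oracle: explicit nested loops over individuals, mediator
    levels and times."""
    levels = mf.spec.ordered_levels
    out = np.zeros(len(t_grid))
    for ti, t in enumerate(t_grid):
        total = 0.0
        for i in range(len(frame)):
            one = frame.iloc[[i]].copy()
            probs = rm.mediator_probs(mf, one, x)[0]
            acc = 0.0
            for j, lev in enumerate(levels):
                rec = one.copy()
                rec["exposure"] = y
                rec["mediator"] = lev
                acc += probs[j] * rm.relative_survival(rs, rec, t)[0]
            if sstar is not None:
                acc *= sstar[i, ti]
            total += acc
        out[ti] = total / len(frame)
    return out


class TestLoopOracles:
    def test_standardized_relsurv_matches_double_loop(self, toy_frame, toy_models):
        rs = toy_models.rs
        est = rm.standardized_relsurv(rs, toy_frame, 1, T_GRID)
        brute = np.zeros(len(T_GRID))
        for ti, t in enumerate(T_GRID):
            for i in range(len(toy_frame)):
                one = toy_frame.iloc[[i]].copy()
                one["exposure"] = 1
                brute[ti] += rm.relative_survival(rs, one, t)[0]
            brute[ti] /= len(toy_frame)
        assert np.max(np.abs(est - brute)) < 1e-12

    def test_single_record_equals_individual_prediction(self, toy_frame, toy_models):
        one = toy_frame.iloc[[3]]
        est = rm.standardized_relsurv(toy_models.rs, one, 0, T_GRID)
        work = one.copy()
        work["exposure"] = 0
        direct = np.array([rm.relative_survival(toy_models.rs, work, t)[0] for t in T_GRID])
        assert np.max(np.abs(est - direct)) < 1e-14

    @pytest.mark.parametrize("y,x", [(1, 1), (1, 0), (0, 0)])
    def test_xi_matches_triple_loop(self, toy_frame, toy_models, y, x):
        est = rm.xi(toy_models.rs, toy_models.mf, toy_frame, y, x, T_GRID)
        brute = loop_xi(toy_models.rs, toy_models.mf, toy_frame, y, x, T_GRID)
        assert np.max(np.abs(est - brute)) < 1e-12

    @pytest.mark.parametrize("mode", ["AC1", "AC2"])
    def test_allcause_matches_loops(self, toy_frame, toy_models, mode):
        lt = flat_lifetable(0.04, strata=("0", "1"))
        ms = rm.mediation_effects_allcause(
            toy_models.rs, toy_models.mf, lt, toy_frame, T_GRID, mode=mode, scale="survival"
        )
        s = ac_sstar_matrices(lt, toy_frame, T_GRID, mode)
        xi11 = loop_xi(toy_models.rs, toy_models.mf, toy_frame, 1, 1, T_GRID, sstar=s["11"])
        xi10 = loop_xi(toy_models.rs, toy_models.mf, toy_frame, 1, 0, T_GRID, sstar=s["10"])
        xi00 = loop_xi(toy_models.rs, toy_models.mf, toy_frame, 0, 0, T_GRID, sstar=s["00"])
        assert np.max(np.abs(ms.estimates["NDE"] - (xi10 - xi00))) < 1e-12
        assert np.max(np.abs(ms.estimates["NIE"] - (xi11 - xi10))) < 1e-12


class TestIdentities:
    @pytest.mark.parametrize("scale", ["death", "survival"])
    def test_additivity(self, toy_frame, toy_models, scale):
        ms = rm.mediation_effects_net(toy_models.rs, toy_models.mf, toy_frame, T_GRID, scale=scale)
        gap = ms.estimates["NDE"] + ms.estimates["NIE"] - ms.estimates["TCE"]
        assert np.max(np.abs(gap)) < 1e-12

    def test_zero_expected_hazard_collapses_allcause_to_net(self, toy_frame, toy_models, zero_lifetable):
        net = rm.mediation_effects_net(toy_models.rs, toy_models.mf, toy_frame, T_GRID)
        for mode in ("AC1", "AC2"):
            ac = rm.mediation_effects_allcause(
                toy_models.rs, toy_models.mf, zero_lifetable, toy_frame, T_GRID, mode=mode
            )
            for k in ("TCE", "NDE", "NIE"):
                assert np.array_equal(ac.estimates[k], net.estimates[k])

    def test_point_mass_mediator_forces_null_nie(self, toy_frame, toy_models):
        # intercepts drive all mass to level "c" regardless of exposure
        mf = toy_mediator_fit(("a", "b", "c"), [[-40.0, 0.0], [40.0, 0.0]])
        ms = rm.mediation_effects_net(toy_models.rs, mf, toy_frame, T_GRID)
        assert np.max(np.abs(ms.estimates["NIE"])) < 1e-12
        # and xi equals the standardization with M fixed at the point mass
        fixed = toy_frame.copy()
        fixed["mediator"] = "b"
        mf_b = toy_mediator_fit(("a", "b", "c"), [[40.0, 0.0], [-40.0, 0.0]])
        est = rm.xi(toy_models.rs, mf_b, toy_frame, 1, 1, T_GRID)
        ref = rm.standardized_relsurv(toy_models.rs, fixed, 1, T_GRID)
        assert np.max(np.abs(est - ref)) < 1e-12

    def test_exposure_independent_mediator_forces_null_nie(self, toy_frame, toy_models):
        mf = toy_mediator_fit(("a", "b", "c"), [[0.2, 0.0], [-0.1, 0.0]])
        a = rm.xi(toy_models.rs, mf, toy_frame, 1, 1, T_GRID)
        b = rm.xi(toy_models.rs, mf, toy_frame, 1, 0, T_GRID)
        assert np.array_equal(a, b)

    def test_null_exposure_in_both_models_zeroes_all_effects(self, toy_frame):
        rs = weibull_fit(
            np.log(0.1),
            0.9,
            extra_terms=(LinearTerm("exposure"), CategoricalTerm("mediator", ("a", "b", "c"))),
            extra_beta=(0.0, 0.5, 1.1),
        )
        mf = toy_mediator_fit(("a", "b", "c"), [[0.2, 0.0], [-0.1, 0.0]])
        net = rm.mediation_effects_net(rs, mf, toy_frame, T_GRID)
        for k in ("TCE", "NDE", "NIE"):
            assert np.max(np.abs(net.estimates[k])) == 0.0
        # AC2 cancels the shared S* factor even with a stratified lifetable
        lt = flat_lifetable(0.05, strata=("0", "1"))
        ac2 = rm.mediation_effects_allcause(rs, mf, lt, toy_frame, T_GRID, mode="AC2")
        for k in ("TCE", "NDE", "NIE"):
            assert np.max(np.abs(ac2.estimates[k])) == 0.0

    def test_model_without_exposure_term_gives_equal_thetas(self, toy_frame):
        rs = weibull_fit(
            np.log(0.2), 1.1,
            extra_terms=(CategoricalTerm("mediator", ("a", "b", "c")),),
            extra_beta=(0.5, 1.1),
        )
        t1 = rm.standardized_relsurv(rs, toy_frame, 1, T_GRID)
        t0 = rm.standardized_relsurv(rs, toy_frame, 0, T_GRID)
        assert np.array_equal(t1, t0)

    def test_xi_surfaces_monotone_nonincreasing(self, toy_frame, toy_models):
        grid = np.linspace(0.05, 5, 60)
        ms = rm.mediation_effects_net(toy_models.rs, toy_models.mf, toy_frame, grid, scale="survival")
        for comp in ms.components.values():
            assert np.all(np.diff(comp) <= 1e-14)
            assert comp.min() >= 0 and comp.max() <= 1


class TestAc1Guards:
    def test_ac1_without_stratified_lifetable_refused(self, toy_frame, toy_models):
        lt = flat_lifetable(0.02)  # unstratified
        with pytest.raises(rm.ConfigurationError, match="stratified"):
            rm.mediation_effects_allcause(
                toy_models.rs, toy_models.mf, lt, toy_frame, T_GRID, mode="AC1"
            )

    def test_ac1_override_flag_accepts_degeneracy(self, toy_frame, toy_models):
        lt = flat_lifetable(0.02)
        ms = rm.mediation_effects_allcause(
            toy_models.rs, toy_models.mf, lt, toy_frame, T_GRID,
            mode="AC1", allow_unstratified=True,
        )
        assert np.all(np.isfinite(ms.estimates["TCE"]))


class TestPmAndRestrict:
    def test_pm_flagged_where_tce_negligible(self):
        pm, defined = rm.proportion_mediated([0.5, 1e-6], [1.0, 1e-6], tol=1e-4)
        assert pm[0] == 0.5 and defined[0]
        assert np.isnan(pm[1]) and not defined[1]

    def test_restrict_identity_and_empty(self, toy_frame):
        same = rm.restrict(toy_frame, lambda d: np.ones(len(d), dtype=bool))
        assert same.equals(toy_frame)
        with pytest.raises(rm.ValidationError):
            rm.restrict(toy_frame, lambda d: np.zeros(len(d), dtype=bool))

    def test_restrict_exposed_fraction_matches_generator(self, sim):
        exposed = rm.restrict(sim.frame, lambda d: d["exposure"] == 1)
        frac = len(exposed) / len(sim.frame)
        assert abs(frac - sim.cfg.exposure_prevalence) < 0.03


def test_engine_matches_plain_path_at_drawn_parameters(toy_frame, toy_models):
    """The precomputed engine and the direct path agree at arbitrary params."""
    rng = np.random.default_rng(4)
    rs_p = toy_models.rs.beta + 0.1 * rng.standard_normal(toy_models.rs.beta.size)
    mf_p = toy_models.mf.packed + 0.1 * rng.standard_normal(toy_models.mf.packed.size)
    eng = StandardizationEngine(toy_models.rs, toy_models.mf, toy_frame, T_GRID)
    fast = eng.xi(1, 0, rs_params=rs_p, mf_params=mf_p)
    # rebuild both fits with the drawn parameters for the loop oracle
    rs2 = rm.RelSurvFit(
        spec=toy_models.rs.spec, beta=rs_p, cov=toy_models.rs.cov,
        colnames=toy_models.rs.colnames, loglik=0.0, grad_norm=0.0, n_iter=0, converged=True,
    )
    slow2 = loop_xi(rs2, rm.MediatorFit(
        spec=toy_models.mf.spec, coef=toy_models.mf.unpack(mf_p), cov=toy_models.mf.cov,
        colnames=toy_models.mf.colnames, loglik=0.0, converged=True,
    ), toy_frame, 1, 0, T_GRID)
    assert np.max(np.abs(fast - slow2)) < 1e-12
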