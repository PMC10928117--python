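import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from hwle.exceptions import MissingDataError, ValidationError
from hwle.model import (
    MultiStateModel,
    ParameterVector,
    TransitionModelSpec,
    build_generator,
    format_hrr_table,
    hazard_ratio_table,
    interval_probability,
    subject_log_likelihood,
)
from hwle.model import _PanelDesign
from hwle.panel import SubjectHistory, from_dataframe
from hwle.states import StateSpace, three_state_space


def _history(ages, states, covs=None):
    ages = np.asarray(ages, dtype=float)
    states = np.asarray(states, dtype=float)
    death = states == 3.0
    covs = covs if covs is not None else pd.DataFrame(index=range(len(ages)))
    return SubjectHistory("s", ages, states, death, covs)


def _random_3state_params(rng, covariates=()):
    spec = TransitionModelSpec(state_space=three_state_space(), covariates=covariates)
    T, K = spec.n_transitions, len(covariates)
    return ParameterVector(
        spec,
        rng.uniform(-4.0, -1.0, T),
        rng.uniform(-0.1, 0.1, T),
        rng.uniform(-0.5, 0.5, (T, K)),
    )


class TestGenerator:
    def test_log_linear_predictor_hand_values(self, two_state_space):
        spec = TransitionModelSpec(state_space=two_state_space)
        pv = ParameterVector(spec, [-2.0], [np.log(1.07)], np.zeros((1, 0)))
        q50 = build_generator(pv, 50.0)
        assert q50[0, 1] == pytest.approx(0.13534, abs=1e-5)
        assert q50[0, 0] == pytest.approx(-0.13534, abs=1e-5)
        q60 = build_generator(pv, 60.0)
        assert q60[0, 1] == pytest.approx(np.exp(-2) * 1.07**10, rel=1e-12)

    def test_constrained_covariate_leaves_generator_unchanged(self):
        space = three_state_space()
        spec = TransitionModelSpec(
            state_space=space,
            covariates=("work_support",),
            constraints=tuple((lab, "work_support") for lab in space.transition_labels),
        )
        pv = ParameterVector(spec, [-2, -3, -2, -3], np.zeros(4), np.ones((4, 1)))
        q0 = build_generator(pv, 60.0, {"work_support": 0})
        q1 = build_generator(pv, 60.0, {"work_support": 1})
        assert np.array_equal(q0, q1)

    def test_missing_covariate_value_directs_to_imputation(self):
        spec = TransitionModelSpec(
            state_space=three_state_space(), covariates=("oa",)
        )
        pv = ParameterVector.zeros(spec)
        with pytest.raises(MissingDataError, match="impute"):
            build_generator(pv, 55.0, {"oa": np.nan})

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_generator_rows_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        pv = _random_3state_params(rng)
        q = build_generator(pv, float(rng.uniform(50, 100)))
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        off = q[~np.eye(3, dtype=bool)]
        assert (off >= 0).all()
        assert np.array_equal(q[2], np.zeros(3))  # death row


class TestIntervalProbability:
    def test_two_state_closed_form(self, const_mortality_params):
        p = interval_probability(const_mortality_params, 50.0, 51.0)
        assert p[0, 1] == pytest.approx(1 - np.exp(-0.1), rel=1e-10)

    def test_zero_length_interval_is_identity(self, age_only_params):
        assert np.array_equal(
            interval_probability(age_only_params, 60.0, 60.0), np.eye(3)
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rows_are_probability_distributions(self, seed):
        rng = np.random.default_rng(seed)
        pv = _random_3state_params(rng)
        a0 = float(rng.uniform(50, 90))
        p = interval_probability(pv, a0, a0 + float(rng.uniform(0.1, 10)))
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-10
        assert (p >= -1e-12).all() and (p <= 1 + 1e-12).all()

    def test_matches_kolmogorov_forward_solution(self):
        """Chaining must agree with an ODE solve of dP/dt = P Q(t) for the
        piecewise-constant age-varying generator (small version of the
        randomized oracle in the acceptance suite)."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            pv = _random_3state_params(rng)
            a0, a1, step = 55.0, 58.3, 0.5
            p_chain = interval_probability(pv, a0, a1, step_years=step)

            k = int(np.ceil((a1 - a0) / step - 1e-12))
            dt = (a1 - a0) / k

            def q_of(t):
                j = min(int(np.floor((t - a0) / dt - 1e-12)), k - 1)
                return build_generator(pv, a0 + (max(j, 0) + 0.5) * dt)

            def rhs(t, y):
                return (y.reshape(3, 3) @ q_of(t)).ravel()

            sol = solve_ivp(
                rhs, (a0, a1), np.eye(3).ravel(), rtol=1e-11, atol=1e-12,
                max_step=dt,
            )
            assert np.abs(sol.y[:, -1].reshape(3, 3) - p_chain).max() < 1e-6

    def test_step_halving_stability(self, age_only_params):
        p1 = interval_probability(age_only_params, 60.0, 62.0, step_years=0.5)
        p2 = interval_probability(age_only_params, 60.0, 62.0, step_years=0.25)
        assert np.abs(p1 - p2).max() < 5e-3
        p3 = interval_probability(age_only_params, 60.0, 62.0, step_years=0.125)
        # first-order convergence: quartering the step shrinks the change ~4x
        assert np.abs(p2 - p3).max() < 0.6 * np.abs(p1 - p2).max()


class TestSubjectLogLikelihood:
    def test_exact_death_closed_form(self, const_mortality_params, two_state_space):
        hist = SubjectHistory(
            "s",
            np.array([50.0, 52.0]),
            np.array([1.0, 2.0]),
            np.array([False, True]),
            pd.DataFrame(index=[0, 1]),
        )
        ll = subject_log_likelihood(const_mortality_params, hist)
        assert ll == pytest.approx(-0.2 + np.log(0.1), abs=1e-9)

    def test_zero_exit_intensity_gives_probability_one(self):
        spec = TransitionModelSpec(state_space=three_state_space())
        pv = ParameterVector(spec, np.full(4, -60.0), np.zeros(4), np.zeros((4, 0)))
        ll = subject_log_likelihood(pv, _history([50, 60], [1, 1]))
        assert ll == pytest.approx(0.0, abs=1e-15)

    def test_impossible_path_is_minus_inf_not_an_exception(self):
        # remove the nHW -> HW return arrow: an observed 2 -> 1 move is impossible
        allowed = np.zeros((3, 3), dtype=bool)
        allowed[0, 1] = allowed[0, 2] = allowed[1, 2] = True
        space = StateSpace(labels=("HW", "nHW", "dead"), death=2, allowed=allowed)
        spec = TransitionModelSpec(state_space=space)
        pv = ParameterVector(spec, np.full(3, -2.0), np.zeros(3), np.zeros((3, 0)))
        ll = subject_log_likelihood(pv, _history([50, 52], [2, 1]))
        assert ll == -np.inf


class TestFitting:
    def test_constant_hazard_mle_equals_deaths_over_person_time(self, two_state_space):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(500):
            t = rng.exponential(10.0)
            if t > 8.0:
                rows += [
                    {"id": i, "age": 50.0, "state": 1},
                    {"id": i, "age": 58.0, "state": 1},
                ]
            else:
                rows += [
                    {"id": i, "age": 50.0, "state": 1},
                    {"id": i, "age": 50.0 + t, "state": 2},
                ]
        panel = from_dataframe(pd.DataFrame(rows), two_state_space)
        fit = MultiStateModel(
            state_space=two_state_space, constraints=(("alive-dead", "age"),)
        ).fit(panel)
        design = fit._design_
        crude = design.transition_counts[0, 1] / (design.t1 - design.t0).sum()
        assert np.exp(fit.params_.log_q0[0]) == pytest.approx(crude, rel=1e-6)

    def test_loglik_at_mle_dominates_truth(self, small_cohort, small_fit):
        panel, truth = small_cohort
        pv_true = ParameterVector(
            small_fit.spec_, truth["log_q0"], truth["beta_age"], np.array(truth["beta"])
        )
        assert small_fit.loglik_ >= small_fit._design_.loglik(pv_true)

    def test_analytic_gradient_matches_finite_differences(self, small_cohort):
        panel, _ = small_cohort
        spec = TransitionModelSpec(state_space=three_state_space(), covariates=("pain",))
        design = _PanelDesign.build(spec, panel.iter_histories())
        rng = np.random.default_rng(0)
        pv = _random_3state_params(rng, covariates=("pain",))
        _, grad = design.loglik_grad(pv)
        x = pv.pack()
        for i in rng.choice(len(x), size=4, replace=False):
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (
                design.loglik(ParameterVector.unpack(spec, xp))
                - design.loglik(ParameterVector.unpack(spec, xm))
            ) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=5e-5, abs=1e-6)

    def test_fully_constrained_covariate_is_ignorable(self, small_cohort):
        """Fixing a covariate's effect on every transition (HRR = 1) makes
        the fit invariant to arbitrarily permuting that covariate's values."""
        panel, _ = small_cohort
        space = three_state_space()
        cons = tuple((lab, "pain") for lab in space.transition_labels)
        fit1 = MultiStateModel(covariates=("pain",), constraints=cons,
                               compute_covariance=False).fit(panel)
        shuffled = panel.copy()
        rng = np.random.default_rng(1)
        alive = ~shuffled.data["exact_death"]
        vals = shuffled.data.loc[alive, "pain"].to_numpy()
        shuffled.data.loc[alive, "pain"] = rng.permutation(vals)
        fit2 = MultiStateModel(covariates=("pain",), constraints=cons,
                               compute_covariance=False).fit(shuffled)
        assert fit1.loglik_ == pytest.approx(fit2.loglik_, abs=1e-8)
        assert np.allclose(fit1.free_params_, fit2.free_params_, atol=1e-6)

    def test_missing_cells_raise_unless_dropped(self, small_cohort):
        panel, _ = small_cohort
        holed = panel.copy()
        idx = holed.data.index[~holed.data["exact_death"]][10]
        holed.data.loc[idx, "pain"] = np.nan
        with pytest.raises(MissingDataError, match="impute"):
            MultiStateModel(covariates=("pain",)).fit(holed)
        fit = MultiStateModel(covariates=("pain",), on_missing="drop",
                              compute_covariance=False).fit(holed)
        assert fit.converged_

    def test_impossible_observed_transition_is_reported(self):
        allowed = np.zeros((3, 3), dtype=bool)
        allowed[0, 1] = allowed[0, 2] = allowed[1, 2] = True
        space = StateSpace(labels=("HW", "nHW", "dead"), death=2, allowed=allowed)
        df = pd.DataFrame(
            {"id": [1, 1, 1], "age": [52.0, 54.0, 56.0], "state": [2, 1, 1]}
        )
        panel = from_dataframe(df, space)
        with pytest.raises(ValidationError, match="impossible"):
            MultiStateModel(state_space=space).fit(panel)


class TestFiveStateVariant:
    def test_end_to_end_fit_on_full_health_work_space(self):
        """The same machinery handles the 5-state space (all four
        health x work combinations plus death), here with constant
        intensities per transition."""
        from hwle.simulate import SimulationConfig, TrueModel, simulate_cohort
        from hwle.states import five_state_space

        space = five_state_space()
        spec = TransitionModelSpec(state_space=space)
        T = spec.n_transitions
        log_q0 = np.full(T, np.log(0.05))
        for t, (r, s) in enumerate(spec.transitions):
            if s == space.death:
                log_q0[t] = np.log(0.004)
        tm = TrueModel(
            params=ParameterVector(spec, log_q0, np.full(T, 0.05), np.zeros((T, 0))),
            alive_remainder=np.array([0.45, 0.07, 0.41]),  # HnW, nHW, nHnW mix
        )
        panel, _ = simulate_cohort(tm, SimulationConfig(n_subjects=500, n_waves=4),
                                   seed=55)
        fit = MultiStateModel(
            state_space=space,
            constraints=tuple((lab, "age") for lab in space.transition_labels),
            compute_covariance=False,
        ).fit(panel)
        assert fit.converged_
        p = fit.transition_probability(60.0, 64.0)
        assert p.shape == (5, 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.array_equal(p[space.death], np.eye(5)[space.death])


class TestHazardRatioTable:
    def test_wald_interval_hand_value(self, small_fit):
        spec = small_fit.spec_
        table = hazard_ratio_table(small_fit)
        idx = spec.free_index("HW-nHW", "pain")
        se = np.sqrt(small_fit.covariance_[idx, idx])
        row = table[(table.transition == "HW-nHW") & (table.effect == "pain")].iloc[0]
        beta = row["log_hrr"]
        assert row["ci_low"] == pytest.approx(np.exp(beta - 1.96 * se), rel=1e-3)
        assert row["ci_high"] == pytest.approx(np.exp(beta + 1.96 * se), rel=1e-3)

    def test_beta_zero_se_point_one_formats_as_expected(self):
        # exp(±1.96 × 0.1) -> (0.82, 1.22)
        lo, hi = np.exp(-1.959964 * 0.1), np.exp(1.959964 * 0.1)
        assert f"{1.0:.2f} ({lo:.2f},{hi:.2f})" == "1.00 (0.82,1.22)"

    def test_constrained_effects_render_as_fixed(self, small_fit):
        table = format_hrr_table(hazard_ratio_table(small_fit))
        assert table.loc["nHW-HW", "pain"] == "1.00 (fixed)"
        assert table.loc["nHW-dead", "pain"] == "1.00 (fixed)"
        assert "(" in table.loc["HW-nHW", "age"]

    def test_sparse_transition_warns(self, two_state_space):
        rows = []
        for i in range(30):
            rows += [
                {"id": i, "age": 50.0, "state": 1},
                {"id": i, "age": 52.0, "state": 1},
            ]
        rows[-1]["state"] = 2  # a single death for two free parameters
        panel = from_dataframe(pd.DataFrame(rows), two_state_space)
        with pytest.warns(UserWarning, match="observed transitions"):
            MultiStateModel(state_space=two_state_space,
                            compute_covariance=False).fit(panel)
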