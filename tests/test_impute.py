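import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hwle.exceptions import ConvergenceError, ValidationError
from hwle.impute import (
    ImputationRun,
    PMMImputer,
    barnard_rubin_df,
    pmm_impute,
    pool_hazard_ratios,
    rubin_pool,
    run_per_imputation,
)
from hwle.model import MultiStateModel
from hwle.simulate import (
    config_from_scenario,
    inject_missingness,
    load_scenario,
    simulate_cohort,
    true_model_from_scenario,
)


@pytest.fixture(scope="module")
def holed_cohort():
    scn = load_scenario("recovery")
    tm = true_model_from_scenario(scn)
    cfg = config_from_scenario(scn, n_subjects=600)
    panel, _ = simulate_cohort(tm, cfg, seed=314)
    complete_prev = float(panel.data.loc[~panel.data["exact_death"], "pain"].mean())
    holed, mask = inject_missingness(
        panel, "MAR", 0.30, columns=["pain"],
        mar={"age_coef": 0.7, "aux": "aux_pain", "aux_coef": 0.7}, seed=315,
    )
    return panel, holed, mask, complete_prev


class TestPMM:
    def test_imputed_values_are_donor_values(self, holed_cohort):
        _, holed, mask, _ = holed_cohort
        imps = pmm_impute(holed, m=3, cycles=3, seed=1)
        for completed in imps.panels:
            vals = completed.data["pain"].dropna().unique()
            assert set(vals) <= {0.0, 1.0}
            # everything originally missing is now filled (death rows aside)
            alive = ~completed.data["exact_death"]
            assert completed.data.loc[alive, "pain"].notna().all()

    def test_non_missing_cells_are_untouched(self, holed_cohort):
        _, holed, _, _ = holed_cohort
        imps = pmm_impute(holed, m=2, cycles=2, seed=2)
        observed = holed.data["pain"].notna()
        for completed in imps.panels:
            assert completed.data.loc[observed, "pain"].equals(
                holed.data.loc[observed, "pain"]
            )

    def test_no_missing_cells_gives_identical_copies(self, holed_cohort):
        panel, _, _, _ = holed_cohort
        imps = pmm_impute(panel, m=3, seed=3)
        assert all(p.equals(panel) for p in imps.panels)

    def test_mar_prevalence_is_recovered(self, holed_cohort):
        """With 30% MAR missingness, the average imputed prevalence should
        sit within 3 percentage points of the complete-data prevalence."""
        _, holed, _, complete_prev = holed_cohort
        imps = pmm_impute(holed, m=10, seed=4)
        prevs = [
            float(p.data.loc[~p.data["exact_death"], "pain"].mean())
            for p in imps.panels
        ]
        assert np.mean(prevs) == pytest.approx(complete_prev, abs=0.03)

    def test_deterministic_given_seed(self, holed_cohort):
        _, holed, _, _ = holed_cohort
        a = pmm_impute(holed, m=2, cycles=2, seed=5)
        b = pmm_impute(holed, m=2, cycles=2, seed=5)
        for pa, pb in zip(a.panels, b.panels):
            assert pa.equals(pb)
        assert not a.panels[0].equals(pmm_impute(holed, m=1, cycles=2, seed=6).panels[0])

    def test_variable_without_complete_cases_is_named(self, holed_cohort):
        panel, _, _, _ = holed_cohort
        broken = panel.copy()
        broken.data.loc[~broken.data["exact_death"], "pain"] = np.nan
        with pytest.raises(ValidationError, match="pain"):
            pmm_impute(broken, m=2, seed=7)

    def test_diagnostics_summarise_imputed_cells(self, holed_cohort):
        from hwle.impute import imputation_diagnostics

        _, holed, mask, _ = holed_cohort
        imps = pmm_impute(holed, m=3, cycles=2, seed=12)
        diag = imputation_diagnostics(imps)
        pain = diag[diag["variable"] == "pain"]
        assert len(pain) == 3
        n_missing = (mask["column"] == "pain").sum()
        assert (pain["n_missing"] == n_missing).all()
        assert pain["imputed_mean"].between(0, 1).all()

    def test_transformer_interface_matches_function(self, holed_cohort):
        _, holed, _, _ = holed_cohort
        a = PMMImputer(m=2, cycles=2, seed=8).fit_transform(holed)
        b = pmm_impute(holed, m=2, cycles=2, seed=8)
        assert all(pa.equals(pb) for pa, pb in zip(a.panels, b.panels))


class TestRubinRules:
    def test_worked_example(self):
        pooled = rubin_pool([1.0, 1.2, 0.8], [0.04, 0.04, 0.04])
        assert pooled.point == pytest.approx(1.0)
        assert pooled.between_var == pytest.approx(0.04)
        assert pooled.within_var == pytest.approx(0.04)
        assert pooled.total_var == pytest.approx(0.09333, abs=1e-5)
        assert pooled.total_var == pytest.approx(
            pooled.within_var + (1 + 1 / 3) * pooled.between_var
        )
        assert pooled.m_used == 3

    def test_identical_points_reduce_to_single_imputation_wald(self):
        pooled = rubin_pool([2.0, 2.0, 2.0, 2.0], [0.25, 0.25, 0.25, 0.25])
        assert pooled.between_var == 0.0
        assert pooled.total_var == pytest.approx(0.25)
        assert np.isinf(pooled.df)
        half = stats.norm.ppf(0.975) * 0.5
        assert pooled.ci95 == pytest.approx((2.0 - half, 2.0 + half))

    def test_log_scale_pooling_is_geometric_mean(self):
        hrrs = np.array([1.2, 1.5, 1.1, 1.4])
        pooled = rubin_pool(np.log(hrrs), np.full(4, 0.01))
        assert np.exp(pooled.point) == pytest.approx(stats.gmean(hrrs))

    def test_permutation_invariance_and_variance_ordering(self):
        points = [0.3, -0.1, 0.8, 0.2, 0.5]
        variances = [0.1, 0.2, 0.05, 0.15, 0.1]
        a = rubin_pool(points, variances)
        b = rubin_pool(points[::-1], variances[::-1])
        assert a.point == pytest.approx(b.point, rel=1e-14)
        assert a.total_var == pytest.approx(b.total_var, rel=1e-14)
        assert a.df == pytest.approx(b.df, rel=1e-12)
        assert a.total_var >= a.within_var

    def test_fewer_than_two_imputations_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            rubin_pool([1.0], [0.1])

    def test_barnard_rubin_df(self):
        df_inf = barnard_rubin_df(5, between=0.1, total=0.5)
        assert df_inf > 0
        df_small = barnard_rubin_df(5, between=0.1, total=0.5, dfcom=30)
        assert 0 < df_small < df_inf
        assert np.isinf(barnard_rubin_df(5, between=0.0, total=0.5))


class _FailSomeModel(MultiStateModel):
    """Test double: refuses to converge on chosen imputation indices."""

    _counter = {"i": 0}

    def fit(self, panel, y=None):
        i = _FailSomeModel._counter["i"]
        _FailSomeModel._counter["i"] += 1
        super().fit(panel, y)
        if i in (1, 3):
            self.converged_ = False
        return self


class TestPerImputationRuns:
    def test_failed_fits_are_excluded_not_fatal(self, holed_cohort):
        _, holed, _, _ = holed_cohort
        imps = pmm_impute(holed, m=5, cycles=2, seed=9)
        _FailSomeModel._counter["i"] = 0
        model = _FailSomeModel(
            covariates=("pain",),
            constraints=(("HW-dead", "pain"), ("nHW-HW", "pain"), ("nHW-dead", "pain")),
        )
        run = run_per_imputation(imps, model)
        assert run.converged == [True, False, True, False, True]
        assert run.m_used == 3
        pooled = pool_hazard_ratios(run)
        assert (pooled.loc[~pooled["fixed"], "m_used"] == 3).all()

    def test_all_failures_raise(self, holed_cohort):
        _, holed, _, _ = holed_cohort
        imps = pmm_impute(holed, m=2, cycles=2, seed=10)
        model = MultiStateModel(covariates=("not_a_column",))
        with pytest.raises(ConvergenceError):
            run_per_imputation(imps, model)

    def test_identical_panels_give_identical_fits(self, holed_cohort):
        panel, _, _, _ = holed_cohort
        imps = pmm_impute(panel, m=2, seed=11)  # no missing cells: copies
        run = run_per_imputation(
            imps, MultiStateModel(covariates=("pain",),
                                  constraints=(("HW-dead", "pain"),
                                               ("nHW-HW", "pain"),
                                               ("nHW-dead", "pain")))
        )
        assert np.allclose(run.fits[0].free_params_, run.fits[1].free_params_,
                           atol=1e-8)
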