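"""Multiple imputation by predictive mean matching and Rubin's-rules pooling.

Missing interview cells (state or covariate values; never death records)
are imputed with chained equations across all waves simultaneously: the
panel is pivoted to one row per subject with one column per (variable,
wave), each incomplete column is regressed on every other column plus the
auxiliary predictors among its observed cases with a Bayesian draw of the
coefficients, and each missing cell receives the observed value of a donor
drawn uniformly from the ``donors`` nearest complete cases by predicted
value (type-1 matching).  Donor values only — imputed binaries stay binary.

Per-imputation model fits that fail to converge are flagged and excluded
from pooling.  Scalars are pooled with Rubin's rules; the reference t
distribution uses the Barnard–Rubin degrees of freedom (complete-data df
taken as large by default).  Hazard rate ratios are pooled on the log
scale; expectancies on the raw scale with their per-imputation Monte-Carlo
variance as the within-imputation variance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone

from .exceptions import ConvergenceError, ValidationError
from .expectancy import (
    ExpectancyEstimate,
    expectancy_uncertainty,
    initial_state_distribution,
)
from .model import MultiStateModel, hazard_ratio_table
from .panel import CohortPanel

__all__ = [
    "ImputationSet",
    "PMMImputer",
    "pmm_impute",
    "ImputationRun",
    "run_per_imputation",
    "PooledScalar",
    "rubin_pool",
    "barnard_rubin_df",
    "pool_hazard_ratios",
    "pool_expectancy",
]


@dataclass
class ImputationSet:
    """M completed panels differing only in originally-missing cells."""

    panels: list[CohortPanel]
    m: int
    aux_vars: tuple[str, ...]
    seed: int | None
    source: CohortPanel | None = None

    def __iter__(self):
        return iter(self.panels)


def _bayesian_ols_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior draw of OLS coefficients (ridge-stabilised normal model)."""
    n, p = X.shape
    S = X.T @ X
    ridge = 1e-5 * (np.trace(S) / p + 1.0)
    S = S + ridge * np.eye(p)
    beta_hat = np.linalg.solve(S, X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    V = np.linalg.inv(S)
    L = np.linalg.cholesky(0.5 * (V + V.T) + 1e-12 * np.eye(p))
    beta_dot = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return beta_hat, beta_dot


def _pmm_fill(
    wide: np.ndarray, rng: np.random.Generator, donors: int, cycles: int,
    colnames: Sequence[str],
) -> np.ndarray:
    """Chained PMM over the columns of ``wide`` (NaN = to fill)."""
    n, p = wide.shape
    filled = wide.copy()
    miss = np.isnan(wide)
    targets = [j for j in range(p) if miss[:, j].any()]
    for j in targets:
        obs_vals = wide[~miss[:, j], j]
        if len(obs_vals) == 0:
            raise ValidationError(
                f"variable {colnames[j]!r} has no complete cases to impute from"
            )
        filled[miss[:, j], j] = rng.choice(obs_vals, size=int(miss[:, j].sum()))
    # monotone-ish visit order: least missing first
    targets.sort(key=lambda j: int(miss[:, j].sum()))
    for _ in range(cycles):
        for j in targets:
            obs = ~miss[:, j]
            mis = miss[:, j]
            others = [k for k in range(p) if k != j]
            X = np.column_stack([np.ones(n), filled[:, others]])
            y = wide[obs, j]
            beta_hat, beta_dot = _bayesian_ols_draw(X[obs], y, rng)
            yhat_obs = X[obs] @ beta_hat
            yhat_mis = X[mis] @ beta_dot
            k = min(donors, len(y))
            d = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
            near = np.argpartition(d, k - 1, axis=1)[:, :k]
            pick = near[np.arange(len(yhat_mis)), rng.integers(0, k, len(yhat_mis))]
            filled[mis, j] = y[pick]
    return filled


def _wide_layout(panel: CohortPanel, aux_vars: Sequence[str]):
    """Pivot the panel to one row per subject, one column per (variable, wave).

    Returns (matrix, colnames, cell_index) where cell_index maps writable
    (originally missing) matrix cells back to panel row/column positions.
    Structurally absent cells (waves a subject never reached) are treated as
    latent during chaining but never written back.
    """
    df = panel.data
    alive = ~df["exact_death"]
    wave = df[alive].groupby("id", sort=False).cumcount()
    n_waves = int(wave.max()) + 1 if alive.any() else 0
    ids = df["id"].unique()
    id_pos = {s: i for i, s in enumerate(ids)}
    variables = ["state"] + list(panel.covariate_names)

    ncol = 1 + len(variables) * n_waves + len(aux_vars)
    wide = np.full((len(ids), ncol), np.nan)
    colnames = ["baseline_age"]
    col_of: dict[tuple[str, int], int] = {}
    for v in variables:
        for w in range(n_waves):
            col_of[(v, w)] = len(colnames)
            colnames.append(f"{v}@w{w + 1}")
    for a in aux_vars:
        colnames.append(a)

    cell_index: list[tuple[int, int, int]] = []  # (row, col, panel_row)
    alive_rows = df.index[alive]
    wave_arr = wave.to_numpy()
    for pos, ridx in enumerate(alive_rows):
        i = id_pos[df.at[ridx, "id"]]
        w = int(wave_arr[pos])
        if w == 0:
            wide[i, 0] = df.at[ridx, "age"]
        for v in variables:
            c = col_of[(v, w)]
            val = df.at[ridx, v]
            if pd.isna(val):
                cell_index.append((i, c, int(ridx)))
            else:
                wide[i, c] = float(val)
    for k, a in enumerate(aux_vars):
        first = df.groupby("id", sort=False)[a].first()
        wide[:, 1 + len(variables) * n_waves + k] = first.loc[ids].to_numpy(dtype=float)
    # subjects whose first record is a death have no baseline age; use the death age
    base_missing = np.isnan(wide[:, 0])
    if base_missing.any():
        first_age = df.groupby("id", sort=False)["age"].first()
        wide[base_missing, 0] = first_age.loc[ids[base_missing]].to_numpy(dtype=float)
    return wide, colnames, cell_index, variables


def pmm_impute(
    panel: CohortPanel,
    aux_vars: Sequence[str] | None = None,
    m: int = 20,
    donors: int = 5,
    cycles: int = 10,
    seed: int | None = None,
) -> ImputationSet:
    """Produce ``m`` completed copies of ``panel`` by chained PMM.

    ``aux_vars`` default to every auxiliary column carried by the panel.
    Deterministic given ``seed``.
    """
    if aux_vars is None:
        aux_vars = panel.aux_names
    aux_vars = tuple(aux_vars)
    for a in aux_vars:
        if panel.data[a].isna().any():
            raise ValidationError(f"auxiliary variable {a!r} has missing values")
    wide, colnames, cell_index, variables = _wide_layout(panel, aux_vars)

    panels = []
    streams = np.random.SeedSequence(seed).spawn(m)
    for imp in range(m):
        if cell_index:
            rng = np.random.default_rng(streams[imp])
            filled = _pmm_fill(wide, rng, donors, cycles, colnames)
            completed = panel.copy()
            for i, c, ridx in cell_index:
                var = colnames[c].split("@")[0]
                completed.data.at[ridx, var] = filled[i, c]
        else:
            completed = panel.copy()
        panels.append(completed)
    return ImputationSet(panels=panels, m=m, aux_vars=aux_vars, seed=seed, source=panel)


def imputation_diagnostics(imps: ImputationSet) -> pd.DataFrame:
    """Per-variable missing counts and imputed-value summaries.

    One row per (variable, imputation): how many cells were originally
    missing and the mean of the values imputed for them — a quick check
    that the chained equations produced stable, plausible fills.
    """
    if imps.source is None:
        raise ValueError("imputation set carries no source panel")
    src = imps.source.data
    alive = ~src["exact_death"]
    rows = []
    for var in ["state"] + list(imps.source.covariate_names):
        miss = alive & src[var].isna()
        for m, completed in enumerate(imps.panels, start=1):
            filled = completed.data.loc[miss, var]
            rows.append(
                {
                    "variable": var,
                    "imputation": m,
                    "n_missing": int(miss.sum()),
                    "imputed_mean": float(filled.mean()) if miss.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


class PMMImputer(BaseEstimator):
    """Transform-shaped wrapper around :func:`pmm_impute`."""

    def __init__(self, m: int = 20, donors: int = 5, cycles: int = 10,
                 aux_vars: Sequence[str] | None = None, seed: int | None = None):
        self.m = m
        self.donors = donors
        self.cycles = cycles
        self.aux_vars = aux_vars
        self.seed = seed

    def fit(self, panel: CohortPanel, y=None) -> "PMMImputer":
        return self

    def transform(self, panel: CohortPanel) -> ImputationSet:
        return pmm_impute(panel, aux_vars=self.aux_vars, m=self.m,
                          donors=self.donors, cycles=self.cycles, seed=self.seed)

    def fit_transform(self, panel: CohortPanel, y=None) -> ImputationSet:
        return self.transform(panel)


# ---------------------------------------------------------------------------
# per-imputation runs and pooling
# ---------------------------------------------------------------------------


@dataclass
class ImputationRun:
    """Fits and expectancy estimates per completed panel, with flags."""

    fits: list[MultiStateModel]
    estimates: list[ExpectancyEstimate | None]
    converged: list[bool]

    @property
    def m_used(self) -> int:
        return int(sum(self.converged))

    def converged_fits(self) -> list[MultiStateModel]:
        return [f for f, ok in zip(self.fits, self.converged) if ok]


def run_per_imputation(
    imps: ImputationSet,
    model: MultiStateModel,
    expectancy_settings: Mapping | None = None,
) -> ImputationRun:
    """Fit ``model`` (cloned) on every completed panel; flag failures.

    When ``expectancy_settings`` is given (keys: ``n_draws``, ``seed``,
    optional ``covariates``/``start_age``/``max_age``/``h``), marginal
    expectancies with Monte-Carlo intervals are computed for each converged
    fit, with the initial-state distribution re-estimated per panel.
    """
    fits, ests, flags = [], [], []
    warm = None  # completed panels differ in few cells: warm-start later fits
    first: tuple | None = None  # (panel, fit) of the first converged fit
    for i, completed in enumerate(imps.panels):
        if first is not None and completed.equals(first[0]):
            # identical completed data: identical fit, by construction
            fits.append(copy.deepcopy(first[1]))
            flags.append(True)
            ests.append(_maybe_expectancy(fits[-1], completed,
                                          expectancy_settings, i))
            continue
        fit = clone(model)
        if warm is not None:
            fit.set_params(init=warm)
        try:
            fit.fit(completed)
            ok = bool(fit.converged_)
            if ok and warm is None:
                warm = fit.params_
                first = (completed, fit)
        except Exception:
            ok = False
        fits.append(fit)
        flags.append(ok)
        ests.append(
            _maybe_expectancy(fit, completed, expectancy_settings, i) if ok else None
        )
    if not any(flags):
        raise ConvergenceError("no imputed-data fit converged")
    return ImputationRun(fits=fits, estimates=ests, converged=flags)


def _maybe_expectancy(fit, completed, expectancy_settings, i):
    if expectancy_settings is None:
        return None
    cfg = dict(expectancy_settings)
    seed = cfg.pop("seed", 0)
    init = initial_state_distribution(completed, cfg.pop("start_age", 50.0))
    return expectancy_uncertainty(
        fit, init, covariates=cfg.pop("covariates", None),
        n_draws=cfg.pop("n_draws", 500),
        seed=int(seed) + i, start_age=50.0, **cfg,
    )


@dataclass
class PooledScalar:
    """A Rubin's-rules pooled scalar with Barnard–Rubin reference df."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci95: tuple[float, float]
    m_used: int


def barnard_rubin_df(m: int, between: float, total: float,
                     dfcom: float = np.inf) -> float:
    """Barnard–Rubin adjusted degrees of freedom for the pooled t reference."""
    if total <= 0 or between <= 0:
        return np.inf
    lam = (1 + 1 / m) * between / total
    nu_old = (m - 1) / lam**2
    if not np.isfinite(dfcom):
        return float(nu_old)
    nu_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
    return float(nu_old * nu_obs / (nu_old + nu_obs))


def rubin_pool(points: Sequence[float], variances: Sequence[float],
               dfcom: float = np.inf) -> PooledScalar:
    """Pool a scalar across imputations: mean point, within + between variance.

    ``total = within + (1 + 1/m) * between``; the 95% CI uses a t reference
    with Barnard–Rubin degrees of freedom.
    """
    points = np.asarray(points, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if points.shape != variances.shape or points.ndim != 1:
        raise ValueError("points and variances must be equal-length 1-d sequences")
    m = len(points)
    if m < 2:
        raise ValueError("need at least 2 imputations to estimate between-variance")
    point = float(points.mean())
    between = float(points.var(ddof=1))
    within = float(variances.mean())
    total = within + (1 + 1 / m) * between
    df = barnard_rubin_df(m, between, total, dfcom)
    half = (stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975))
    half *= np.sqrt(total)
    return PooledScalar(
        point=point, within_var=within, between_var=between, total_var=total,
        df=df, ci95=(point - half, point + half), m_used=m,
    )


def pool_hazard_ratios(run: ImputationRun, dfcom: float = np.inf) -> pd.DataFrame:
    """Pool per-imputation HRR tables on the log scale.

    Returns the hazard-ratio table layout with pooled HRRs, 95% CIs and the
    number of imputations pooled (non-converged fits excluded).
    """
    tables = [hazard_ratio_table(f) for f in run.converged_fits()]
    if len(tables) < 2:
        raise ValueError("need at least two converged fits to pool")
    base = tables[0][["transition", "effect", "fixed"]]
    rows = []
    for idx in range(len(base)):
        fixed = bool(base.at[idx, "fixed"])
        if fixed:
            rows.append({**base.loc[idx].to_dict(), "hrr": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "m_used": len(tables)})
            continue
        points = [t.at[idx, "log_hrr"] for t in tables]
        variances = [t.at[idx, "se"] ** 2 for t in tables]
        pooled = rubin_pool(points, variances, dfcom)
        rows.append({
            **base.loc[idx].to_dict(),
            "hrr": float(np.exp(pooled.point)),
            "ci_low": float(np.exp(pooled.ci95[0])),
            "ci_high": float(np.exp(pooled.ci95[1])),
            "m_used": pooled.m_used,
        })
    return pd.DataFrame(rows)


def pool_expectancy(run: ImputationRun, quantity: str = "hwle",
                    dfcom: float = np.inf) -> PooledScalar:
    """Pool an expectancy (``hwle``, ``years_not_hw`` or ``le``) across
    imputations, using each imputation's Monte-Carlo variance as the
    within-imputation variance."""
    points, variances = [], []
    for est, ok in zip(run.estimates, run.converged):
        if not ok or est is None:
            continue
        if quantity == "hwle":
            points.append(float(est.marginal[0]))
        elif quantity == "years_not_hw":
            points.append(float(est.marginal[1:].sum()))
        elif quantity == "le":
            points.append(est.total_le)
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        variances.append(est.mc_var[
            {"hwle": "hwle", "years_not_hw": "years_not_hw", "le": "le"}[quantity]
        ])
    return rubin_pool(points, variances, dfcom)
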