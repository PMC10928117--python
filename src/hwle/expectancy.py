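"""State expectancies from a fitted multi-state model.

Occupancy probabilities are propagated from the start age (50) to a hard
truncation age (120) on a fine grid by chaining interval transition
probabilities, with covariates held fixed over age.  A state expectancy is
the trapezoidal integral of that state's occupancy over age; healthy
working life expectancy (HWLE) is the expectancy of the healthy-and-working
state, and life expectancy is the sum of the alive-state expectancies.

Marginal ("population overall") expectancies weight the conditional
expectancies by a model of the initial state distribution at the start
age — a logistic (or multinomial) regression of baseline state on baseline
age, evaluated at the start age.

Uncertainty is parametric-bootstrap style: parameter vectors are drawn from
the asymptotic normal distribution of the MLE, expectancies are recomputed
per draw, and 2.5/97.5 percentiles reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._linalg import expm_batch, nearest_psd
from .exceptions import ValidationError
from .model import (
    MultiStateModel,
    ParameterVector,
    _covariate_row,
    _generator_batch,
)
from .panel import CohortPanel
from .states import StateSpace

__all__ = [
    "OccupancyGrid",
    "ExpectancyEstimate",
    "occupancy_curve",
    "state_expectancy",
    "initial_state_distribution",
    "fit_initial_state_model",
    "marginal_expectancies",
    "expectancy_uncertainty",
    "expectancy_table",
]


def _params_of(fit) -> ParameterVector:
    if isinstance(fit, ParameterVector):
        return fit
    return fit.params_


@dataclass
class OccupancyGrid:
    """State-occupancy probabilities over an age grid.

    ``occupancy[i, g, s]`` is the probability of being in state ``s`` at
    grid age ``g`` having started in the i-th alive state at the first grid
    age.
    """

    state_space: StateSpace
    ages: np.ndarray
    occupancy: np.ndarray  # (n_alive_start, n_ages, n_states)

    @property
    def start_age(self) -> float:
        return float(self.ages[0])


def _grid(start_age: float, max_age: float, h: float) -> np.ndarray:
    if max_age <= start_age:
        raise ValueError("max_age must exceed start_age")
    if h <= 0:
        raise ValueError("grid step h must be positive")
    n = int(np.ceil((max_age - start_age) / h - 1e-12))
    return np.linspace(start_age, max_age, n + 1)


def _occupancy_batch(
    pv_stack: Sequence[ParameterVector],
    x: np.ndarray,
    ages: np.ndarray,
) -> np.ndarray:
    """Occupancy for a stack of parameter vectors.

    Returns an array of shape (n_draws, n_alive_start, n_ages, n_states).
    The generator is frozen at each grid cell's midpoint: a second-order
    accurate rule, so halving the grid step changes expectancies at the
    O(h^2) level.
    """
    spec = pv_stack[0].spec
    space = spec.state_space
    S = space.n_states
    alive = space.alive
    D, G = len(pv_stack), len(ages)
    h_steps = np.diff(ages)

    M = np.empty((D, G - 1, S, S))
    X = np.broadcast_to(x, (G - 1, len(x)))
    mid = 0.5 * (ages[:-1] + ages[1:])
    cap = 1e8  # intensities above this are numerically "instantaneous"
    for d, pv in enumerate(pv_stack):
        _, Q = _generator_batch(pv, mid, X)
        if not np.isfinite(Q).all() or np.abs(Q).max() > cap:
            Q = np.clip(np.nan_to_num(Q, posinf=cap, neginf=-cap), -cap, cap)
            Q[..., range(S), range(S)] = 0.0
            Q[..., range(S), range(S)] = -Q.sum(axis=-1)
        M[d] = expm_batch(Q * h_steps[:, None, None])

    occ = np.zeros((D, len(alive), G, S))
    for i, a in enumerate(alive):
        occ[:, i, 0, a] = 1.0
    for g in range(1, G):
        occ[:, :, g, :] = occ[:, :, g - 1, :] @ M[:, g - 1]
    return occ


def occupancy_curve(
    fit,
    covariates: Mapping[str, float] | None = None,
    start_age: float = 50.0,
    max_age: float = 120.0,
    h: float = 0.25,
) -> OccupancyGrid:
    """Propagate occupancy probabilities from ``start_age`` to ``max_age``.

    ``fit`` may be a fitted :class:`~hwle.model.MultiStateModel` or a bare
    :class:`~hwle.model.ParameterVector` (e.g. the generating truth of a
    simulation).  Covariates are held fixed over age.
    """
    pv = _params_of(fit)
    ages = _grid(start_age, max_age, h)
    x = _covariate_row(pv.spec, covariates)
    occ = _occupancy_batch([pv], x, ages)[0]
    return OccupancyGrid(pv.spec.state_space, ages, occ)


def state_expectancy(grid: OccupancyGrid, state) -> np.ndarray:
    """Expected years spent in ``state``, conditional on each starting state.

    Trapezoidal integration of the state's occupancy over the age grid;
    returns one value per starting alive state.
    """
    idx = grid.state_space.index_of(state) if not isinstance(state, (int, np.integer)) else int(state)
    return np.trapezoid(grid.occupancy[:, :, idx], grid.ages, axis=1)


@dataclass
class InitialStateModel:
    """Baseline-state-given-age model used for marginal weighting."""

    state_space: StateSpace
    params: np.ndarray | None  # regression coefficients, or None if degenerate
    empirical: np.ndarray  # fallback distribution over alive states
    kind: str = "logit"

    def probabilities(self, age: float) -> np.ndarray:
        alive = self.state_space.alive
        if self.params is None:
            return self.empirical
        x = np.array([1.0, float(age)])
        if self.kind == "logit":
            p1 = 1.0 / (1.0 + np.exp(-(x @ self.params)))
            rest = self.empirical[1:] / max(self.empirical[1:].sum(), 1e-12)
            return np.concatenate([[p1], (1 - p1) * rest])
        # multinomial: params has one column per non-reference alive state
        eta = x @ self.params
        expeta = np.concatenate([[1.0], np.exp(eta)])
        return expeta / expeta.sum()


def fit_initial_state_model(panel: CohortPanel) -> InitialStateModel:
    """Regress baseline state on baseline age (logistic for 3-state,
    multinomial for larger spaces)."""
    import statsmodels.api as sm

    space = panel.state_space
    base = panel.baseline()
    base = base[~base["exact_death"] & base["state"].notna()]
    if len(base) == 0:
        raise ValidationError("no baseline observations with a known alive state")
    states = base["state"].to_numpy(dtype=int) - 1
    ages = base["age"].to_numpy(dtype=float)
    alive = space.alive
    counts = np.array([(states == a).sum() for a in alive], dtype=float)
    empirical = counts / counts.sum()
    if (counts > 0).sum() < 2:
        warnings.warn("fewer than two alive states observed at baseline; "
                      "using a degenerate initial distribution", stacklevel=2)
        return InitialStateModel(space, None, empirical)
    X = np.column_stack([np.ones_like(ages), ages])
    try:
        if len(alive) == 2:
            y = (states == alive[0]).astype(float)
            res = sm.Logit(y, X).fit(disp=0)
            return InitialStateModel(space, np.asarray(res.params), empirical, "logit")
        res = sm.MNLogit(states, X).fit(disp=0, maxiter=200)
        return InitialStateModel(space, np.asarray(res.params), empirical, "mnlogit")
    except Exception:  # perfect separation etc.
        warnings.warn("baseline state regression failed; using empirical shares",
                      stacklevel=2)
        return InitialStateModel(space, None, empirical)


def initial_state_distribution(panel: CohortPanel, at_age: float = 50.0) -> np.ndarray:
    """Probability of each alive state at ``at_age`` from the baseline model."""
    return fit_initial_state_model(panel).probabilities(at_age)


@dataclass
class ExpectancyEstimate:
    """Expected years per alive state from the start age.

    ``conditional[i, j]`` is years in alive state j starting from alive
    state i; ``marginal`` weights the starting states by ``init_dist``;
    ``total_le`` is the sum of the marginal alive-state expectancies.
    ``ci`` maps quantity names ('state:<label>' and 'le') to (low, high).
    """

    state_space: StateSpace
    start_age: float
    init_dist: np.ndarray
    conditional: np.ndarray
    marginal: np.ndarray
    total_le: float
    ci: dict = field(default_factory=dict)
    mc_var: dict = field(default_factory=dict)
    n_draws: int = 0

    def years(self, state) -> float:
        idx = self.state_space.index_of(state)
        return float(self.marginal[list(self.state_space.alive).index(idx)])

    @property
    def hwle(self) -> float:
        """Years healthy-and-working (first alive state)."""
        return float(self.marginal[0])


def _expectancies_from_occ(occ: np.ndarray, ages: np.ndarray, alive) -> np.ndarray:
    """(n_draws, n_alive_start, n_alive_state) expected years."""
    return np.trapezoid(occ[:, :, :, list(alive)], ages, axis=2)


def marginal_expectancies(
    fit,
    init_dist: np.ndarray,
    covariates: Mapping[str, float] | None = None,
    start_age: float = 50.0,
    max_age: float = 120.0,
    h: float = 0.25,
) -> ExpectancyEstimate:
    """Point estimates of the per-state expectancies and total LE."""
    pv = _params_of(fit)
    space = pv.spec.state_space
    init_dist = np.asarray(init_dist, dtype=float)
    if init_dist.shape != (len(space.alive),) or abs(init_dist.sum() - 1) > 1e-8:
        raise ValueError("init_dist must be a probability vector over alive states")
    ages = _grid(start_age, max_age, h)
    x = _covariate_row(pv.spec, covariates)
    occ = _occupancy_batch([pv], x, ages)
    cond = _expectancies_from_occ(occ, ages, space.alive)[0]
    marginal = init_dist @ cond
    return ExpectancyEstimate(
        state_space=space,
        start_age=start_age,
        init_dist=init_dist,
        conditional=cond,
        marginal=marginal,
        total_le=float(marginal.sum()),
    )


def expectancy_uncertainty(
    fit: MultiStateModel,
    init_dist: np.ndarray,
    covariates: Mapping[str, float] | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
    start_age: float = 50.0,
    max_age: float = 120.0,
    h: float = 0.25,
) -> ExpectancyEstimate:
    """Point estimates plus percentile intervals from MLE-normal draws.

    Deterministic given ``seed``.  A non-PSD covariance is repaired by
    eigenvalue clipping with a warning.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible intervals")
    if fit.covariance_ is None:
        raise ValueError("fit has no covariance; refit with compute_covariance=True")
    est = marginal_expectancies(fit, init_dist, covariates, start_age, max_age, h)
    cov = 0.5 * (fit.covariance_ + fit.covariance_.T)
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-10:
        warnings.warn("covariance is not PSD; repaired by eigenvalue clipping",
                      stacklevel=2)
        cov = nearest_psd(cov)
    elif eigmin < 0:
        cov = nearest_psd(cov)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.free_params_, cov, size=n_draws,
                                    method="eigh")
    spec = fit.spec_
    pvs = [ParameterVector.unpack(spec, d) for d in draws]
    ages = _grid(start_age, max_age, h)
    x = _covariate_row(spec, covariates)
    occ = _occupancy_batch(pvs, x, ages)
    cond = _expectancies_from_occ(occ, ages, spec.state_space.alive)
    marg = np.einsum("i,dij->dj", np.asarray(init_dist, dtype=float), cond)
    le = marg.sum(axis=1)

    ci = {}
    for j, a in enumerate(spec.state_space.alive):
        lo, hi = np.percentile(marg[:, j], [2.5, 97.5])
        ci[f"state:{spec.state_space.labels[a]}"] = (float(lo), float(hi))
    lo, hi = np.percentile(le, [2.5, 97.5])
    ci["le"] = (float(lo), float(hi))
    lo, hi = np.percentile(marg[:, 1:].sum(axis=1), [2.5, 97.5])
    ci["years_not_hw"] = (float(lo), float(hi))
    est.ci = ci
    est.mc_var = {
        "hwle": float(marg[:, 0].var(ddof=1)) if n_draws > 1 else 0.0,
        "years_not_hw": float(marg[:, 1:].sum(axis=1).var(ddof=1)) if n_draws > 1 else 0.0,
        "le": float(le.var(ddof=1)) if n_draws > 1 else 0.0,
    }
    est.n_draws = n_draws
    return est


def expectancy_table(
    fit: MultiStateModel,
    profiles: Sequence[Mapping[str, float]],
    init_dist: np.ndarray,
    n_draws: int = 1000,
    seed: int | None = None,
    start_age: float = 50.0,
    max_age: float = 120.0,
    h: float = 0.25,
) -> pd.DataFrame:
    """One row per covariate profile: HWLE, non-HW years, LE, with 95% CIs."""
    space = fit.spec_.state_space
    hw_label = space.labels[space.alive[0]]
    rows = []
    for i, prof in enumerate(profiles):
        if n_draws > 0:
            est = expectancy_uncertainty(
                fit, init_dist, prof, n_draws=n_draws,
                seed=None if seed is None else seed + i,
                start_age=start_age, max_age=max_age, h=h,
            )
        else:
            est = marginal_expectancies(fit, init_dist, prof, start_age, max_age, h)
        hwle = est.marginal[0]
        other = float(est.marginal[1:].sum())
        row = {
            "profile": ", ".join(f"{k}={v:g}" for k, v in prof.items()) or "(age only)",
            "hwle": float(hwle),
            "years_not_hw": other,
            "le": est.total_le,
            "decomposition_residual": est.total_le - (float(hwle) + other),
        }
        if est.ci:
            row["hwle_lo"], row["hwle_hi"] = est.ci[f"state:{hw_label}"]
            row["le_lo"], row["le_hi"] = est.ci["le"]
            row["years_not_hw_lo"], row["years_not_hw_hi"] = est.ci["years_not_hw"]
        rows.append(row)
    return pd.DataFrame(rows)
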