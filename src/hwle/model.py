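"""Continuous-time multi-state survival models for panel data.

The model class: each permitted transition r → s has intensity

    q_rs(age, x) = exp( log_q0_rs + beta_age_rs * (age - 50) + sum_k beta_rsk * x_k )

i.e. a Gompertz-type log-linear age effect anchored at age 50 plus
proportional effects of binary covariates (hazard rate ratios).  Individual
effects may be constrained to zero on the log scale ("HRR fixed at 1"),
e.g. workplace factors on transitions out of the not-working state.

States are panel-observed at interviews; death ages are exact.  The
likelihood for an alive → alive interval is the interval transition
probability P_rs(t0, t1), computed by piecewise-constant evaluation of the
generator over sub-intervals (default 0.5 years, generator frozen at each
sub-interval's midpoint) and matrix-exponential chaining.  An exact
death at td contributes  sum_{s alive} P_rs(t0, td) * q_{s,dead}(td) — the
state immediately before death is unknown.  Covariates enter at their value
at the start of each observation interval.

Fitting is quasi-Newton (L-BFGS-B) on the exact analytic gradient
(Fréchet-derivative adjoints of the matrix exponentials), with the
covariance of the MLE taken as the inverse of a finite-difference Hessian
of the negative log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from ._linalg import expm_batch, expm_frechet_rank1
from .exceptions import MissingDataError, ValidationError
from .panel import CohortPanel, SubjectHistory
from .states import StateSpace, three_state_space

__all__ = [
    "TransitionModelSpec",
    "ParameterVector",
    "MultiStateModel",
    "fit_multistate",
    "build_generator",
    "interval_probability",
    "subject_log_likelihood",
    "panel_log_likelihood",
    "hazard_ratio_table",
    "format_hrr_table",
]

_AGE = "age"
_PROB_FLOOR = 1e-300


def _resolve_transition(space: StateSpace, key) -> tuple[int, int]:
    """Accept 'HW-nHW', '1-2', (1, 2) or ('HW', 'nHW') transition keys."""
    if isinstance(key, str):
        left, _, right = key.partition("-")
        key = (left, right)
    r, s = key
    try:
        r = int(r)
    except (TypeError, ValueError):
        pass
    try:
        s = int(s)
    except (TypeError, ValueError):
        pass
    return space.index_of(r), space.index_of(s)


@dataclass(frozen=True)
class TransitionModelSpec:
    """Which effects act on which transitions, and which are fixed.

    ``constraints`` is an iterable of (transition, effect-name) pairs whose
    coefficient is fixed at zero on the log scale; effect-name may be a
    covariate or ``"age"``.  Age is included on every transition unless
    explicitly constrained.
    """

    state_space: StateSpace = field(default_factory=three_state_space)
    covariates: tuple[str, ...] = ()
    constraints: tuple = ()
    age_origin: float = 50.0

    @cached_property
    def transitions(self) -> tuple[tuple[int, int], ...]:
        return self.state_space.transitions

    @cached_property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @cached_property
    def _constraint_masks(self) -> tuple[np.ndarray, np.ndarray]:
        t_index = {rs: t for t, rs in enumerate(self.transitions)}
        free_age = np.ones(self.n_transitions, dtype=bool)
        free_beta = np.ones((self.n_transitions, len(self.covariates)), dtype=bool)
        for trans_key, name in self.constraints:
            rs = _resolve_transition(self.state_space, trans_key)
            if rs not in t_index:
                raise ValidationError(
                    f"constraint on {trans_key!r}: transition not permitted by the state space"
                )
            t = t_index[rs]
            if name == _AGE:
                free_age[t] = False
            elif name in self.covariates:
                free_beta[t, self.covariates.index(name)] = False
            else:
                raise ValidationError(f"constraint names unknown covariate {name!r}")
        return free_age, free_beta

    @property
    def free_age(self) -> np.ndarray:
        return self._constraint_masks[0]

    @property
    def free_beta(self) -> np.ndarray:
        return self._constraint_masks[1]

    @property
    def n_free(self) -> int:
        return self.n_transitions + int(self.free_age.sum()) + int(self.free_beta.sum())

    @cached_property
    def param_names(self) -> tuple[str, ...]:
        labels = [self.state_space.transition_label(r, s) for r, s in self.transitions]
        names = [f"logq0[{lab}]" for lab in labels]
        names += [f"age[{lab}]" for lab, f in zip(labels, self.free_age) if f]
        for k, cov in enumerate(self.covariates):
            names += [
                f"{cov}[{lab}]" for lab, f in zip(labels, self.free_beta[:, k]) if f
            ]
        return tuple(names)

    def free_index(self, transition, name: str) -> int | None:
        """Position of an effect in the free-parameter vector; None if fixed."""
        t = list(self.transitions).index(_resolve_transition(self.state_space, transition))
        T = self.n_transitions
        if name == "logq0":
            return t
        if name == _AGE:
            if not self.free_age[t]:
                return None
            return T + int(self.free_age[:t].sum())
        k = self.covariates.index(name)
        if not self.free_beta[t, k]:
            return None
        off = T + int(self.free_age.sum())
        # beta block is laid out covariate-major
        for kk in range(k):
            off += int(self.free_beta[:, kk].sum())
        return off + int(self.free_beta[:t, k].sum())


@dataclass
class ParameterVector:
    """Full per-transition parameter arrays; constrained entries are zero."""

    spec: TransitionModelSpec
    log_q0: np.ndarray
    beta_age: np.ndarray
    beta: np.ndarray  # (n_transitions, n_covariates)

    def __post_init__(self) -> None:
        T, K = self.spec.n_transitions, len(self.spec.covariates)
        self.log_q0 = np.asarray(self.log_q0, dtype=float).reshape(T).copy()
        self.beta_age = np.asarray(self.beta_age, dtype=float).reshape(T).copy()
        self.beta = np.asarray(self.beta, dtype=float).reshape(T, K).copy()
        self.beta_age[~self.spec.free_age] = 0.0
        self.beta[~self.spec.free_beta] = 0.0
        if not (
            np.isfinite(self.log_q0).all()
            and np.isfinite(self.beta_age).all()
            and np.isfinite(self.beta).all()
        ):
            raise ValueError("parameters must be finite")

    @classmethod
    def zeros(cls, spec: TransitionModelSpec, log_q0: float = -3.0) -> "ParameterVector":
        T, K = spec.n_transitions, len(spec.covariates)
        return cls(spec, np.full(T, log_q0), np.zeros(T), np.zeros((T, K)))

    def pack(self) -> np.ndarray:
        s = self.spec
        return np.concatenate(
            [self.log_q0, self.beta_age[s.free_age], self.beta.T[s.free_beta.T]]
        )

    @classmethod
    def unpack(cls, spec: TransitionModelSpec, vec: np.ndarray) -> "ParameterVector":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (spec.n_free,):
            raise ValueError(f"expected {spec.n_free} free parameters, got {vec.shape}")
        T, K = spec.n_transitions, len(spec.covariates)
        log_q0 = vec[:T]
        beta_age = np.zeros(T)
        n_age = int(spec.free_age.sum())
        beta_age[spec.free_age] = vec[T : T + n_age]
        beta = np.zeros((T, K))
        beta.T[spec.free_beta.T] = vec[T + n_age :]
        return cls(spec, log_q0, beta_age, beta)


# ---------------------------------------------------------------------------
# generator construction
# ---------------------------------------------------------------------------


def _covariate_row(spec: TransitionModelSpec, covariates: Mapping[str, float] | None) -> np.ndarray:
    x = np.zeros(len(spec.covariates))
    if covariates:
        unknown = set(covariates) - set(spec.covariates)
        if unknown:
            raise ValidationError(f"unknown covariates {sorted(unknown)}")
        for k, name in enumerate(spec.covariates):
            if name in covariates:
                val = covariates[name]
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    raise MissingDataError(
                        f"covariate {name!r} is missing; impute it (hwle.impute) first"
                    )
                x[k] = float(val)
    return x


def _intensities(pv: ParameterVector, ages: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-transition intensities, shape (n, T)."""
    spec = pv.spec
    lin = (
        pv.log_q0[None, :]
        + np.outer(ages - spec.age_origin, pv.beta_age)
        + X @ pv.beta.T
    )
    with np.errstate(over="ignore"):  # callers guard non-finite intensities
        return np.exp(lin)


def _generator_batch(pv: ParameterVector, ages: np.ndarray, X: np.ndarray):
    """(q, Q) with q of shape (n, T) and Q of shape (n, S, S)."""
    spec = pv.spec
    q = _intensities(pv, ages, X)
    S = spec.state_space.n_states
    Q = np.zeros((len(ages), S, S))
    for t, (r, s) in enumerate(spec.transitions):
        Q[:, r, s] = q[:, t]
    Q[:, range(S), range(S)] = -Q.sum(axis=2)
    return q, Q


def build_generator(
    params: ParameterVector, age: float, covariates: Mapping[str, float] | None = None
) -> np.ndarray:
    """Generator (intensity) matrix Q at a given age and covariate profile.

    Rows sum to zero; disallowed transitions are exactly zero; the death row
    is all zeros.
    """
    x = _covariate_row(params.spec, covariates)
    _, Q = _generator_batch(params, np.array([float(age)]), x[None, :])
    return Q[0]


def _piece_grid(t0: float, t1: float, step: float) -> tuple[np.ndarray, float]:
    length = t1 - t0
    k = max(1, int(np.ceil(length / step - 1e-12)))
    dt = length / k
    return t0 + dt * (np.arange(k) + 0.5), dt


def interval_probability(
    params: ParameterVector,
    age0: float,
    age1: float,
    covariates: Mapping[str, float] | None = None,
    step_years: float = 0.5,
) -> np.ndarray:
    """Transition probability matrix P(age0, age1) for a fixed covariate profile.

    The age-inhomogeneous generator is approximated as piecewise constant on
    sub-intervals of length <= ``step_years`` (evaluated at each
    sub-interval midpoint, a second-order rule); P is the ordered product
    of the piece exponentials.
    """
    if age1 < age0:
        raise ValueError("age1 must be >= age0")
    S = params.spec.state_space.n_states
    if age1 == age0:
        return np.eye(S)
    if step_years <= 0:
        raise ValueError("step_years must be positive")
    x = _covariate_row(params.spec, covariates)
    ages, dt = _piece_grid(age0, age1, step_years)
    _, Q = _generator_batch(params, ages, np.broadcast_to(x, (len(ages), len(x))))
    if not np.isfinite(Q).all():
        raise FloatingPointError("non-finite generator entries")
    M = expm_batch(Q * dt)
    P = M[0]
    for j in range(1, len(M)):
        P = P @ M[j]
    return P


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


class _PanelDesign:
    """Flattened interval/piece arrays for fast vectorised likelihood."""

    def __init__(self, spec: TransitionModelSpec, step_years: float):
        self.spec = spec
        self.step = step_years
        space = spec.state_space
        self.death_transitions = [
            t for t, (r, s) in enumerate(spec.transitions) if s == space.death
        ]
        # reachability (any number of jumps) for impossible-path detection
        reach = np.eye(space.n_states, dtype=bool) | space.allowed
        for _ in range(space.n_states):
            reach = reach | (reach @ reach)
        self.reachable = reach

    @classmethod
    def build(
        cls,
        spec: TransitionModelSpec,
        histories: Iterable[SubjectHistory],
        step_years: float = 0.5,
        on_missing: str = "raise",
    ) -> "_PanelDesign":
        if on_missing not in ("raise", "drop"):
            raise ValueError("on_missing must be 'raise' or 'drop'")
        self = cls(spec, step_years)
        space = spec.state_space
        cov_names = list(spec.covariates)
        death_code = float(space.death_code)

        r_list, s_list, t0_list, t1_list, X_list, death_list = [], [], [], [], [], []
        n_subjects = 0
        impossible: list[tuple] = []
        counts = np.zeros((space.n_states, space.n_states), dtype=int)

        for hist in histories:
            ages = hist.ages
            states = hist.states
            covs = (
                hist.covariates[cov_names].to_numpy(dtype=float)
                if cov_names
                else np.zeros((len(ages), 0))
            )
            is_death = hist.exact_death
            complete = ~np.isnan(states)
            if cov_names:
                cov_ok = ~np.isnan(covs).any(axis=1)
                complete = complete & (cov_ok | is_death)
            if on_missing == "raise":
                if not complete.all():
                    raise MissingDataError(
                        f"subject {hist.subject_id!r} has missing state/covariate cells; "
                        "impute them (hwle.impute) or fit with on_missing='drop'"
                    )
            else:
                ages, states, covs, is_death = (
                    ages[complete],
                    states[complete],
                    covs[complete],
                    is_death[complete],
                )
            n_alive = int((~is_death).sum())
            if not (n_alive >= 2 or (n_alive >= 1 and is_death.any())):
                continue
            n_subjects += 1
            for j in range(len(ages) - 1):
                r = int(states[j]) - 1
                t0, t1 = float(ages[j]), float(ages[j + 1])
                if is_death[j + 1]:
                    s = space.death
                else:
                    s = int(states[j + 1]) - 1
                    if not self.reachable[r, s]:
                        impossible.append((hist.subject_id, t0, space.labels[r], space.labels[s]))
                counts[r, s] += 1
                r_list.append(r)
                s_list.append(s)
                t0_list.append(t0)
                t1_list.append(t1)
                X_list.append(covs[j])
                death_list.append(bool(is_death[j + 1]))

        self.n_subjects = n_subjects
        self.impossible_pairs = impossible
        self.transition_counts = counts
        self.r = np.array(r_list, dtype=int)
        self.s = np.array(s_list, dtype=int)
        self.t0 = np.array(t0_list, dtype=float)
        self.t1 = np.array(t1_list, dtype=float)
        self.X = np.array(X_list, dtype=float).reshape(len(r_list), len(cov_names))
        self.is_death = np.array(death_list, dtype=bool)
        self._build_pieces()
        return self

    def _build_pieces(self) -> None:
        n_i = len(self.r)
        k = np.maximum(1, np.ceil((self.t1 - self.t0) / self.step - 1e-12).astype(int))
        self.kmax = int(k.max()) if n_i else 0
        dt = np.where(k > 0, (self.t1 - self.t0) / np.maximum(k, 1), 0.0)
        p_age, p_dt, p_int, p_pos = [], [], [], []
        for i in range(n_i):
            ki = k[i]
            # generator frozen at each sub-interval midpoint (second order)
            p_age.append(self.t0[i] + dt[i] * (np.arange(ki) + 0.5))
            p_dt.append(np.full(ki, dt[i]))
            p_int.append(np.full(ki, i, dtype=int))
            p_pos.append(np.arange(ki))
        self.p_age = np.concatenate(p_age) if n_i else np.empty(0)
        self.p_dt = np.concatenate(p_dt) if n_i else np.empty(0)
        self.p_int = np.concatenate(p_int) if n_i else np.empty(0, dtype=int)
        p_pos = np.concatenate(p_pos) if n_i else np.empty(0, dtype=int)
        self.pos_groups = []
        for pos in range(self.kmax):
            sel = np.nonzero(p_pos == pos)[0]
            self.pos_groups.append((sel, self.p_int[sel]))
        self.p_X = self.X[self.p_int]
        self.d_rows = np.nonzero(self.is_death)[0]
        self.d_age = self.t1[self.d_rows]
        self.d_X = self.X[self.d_rows]

    @property
    def n_intervals(self) -> int:
        return len(self.r)

    @property
    def n_transitions_observed(self) -> int:
        off_diag = self.transition_counts.copy()
        np.fill_diagonal(off_diag, 0)
        return int(off_diag.sum())

    # -- core evaluation --------------------------------------------------
    _Q_CAP = 1e4  # intensities beyond this are optimizer excursions, not models

    def _forward(self, pv: ParameterVector, need_grad: bool):
        S = self.spec.state_space.n_states
        n_i = self.n_intervals
        q_p, Q = _generator_batch(pv, self.p_age, self.p_X)
        if not np.isfinite(q_p).all() or (q_p.size and q_p.max() > self._Q_CAP):
            return None
        M = expm_batch(Q * self.p_dt[:, None, None])
        eye = np.eye(S)
        P = np.tile(eye, (n_i, 1, 1))
        A = np.empty_like(M) if need_grad else None
        for pidx, iidx in self.pos_groups:
            if need_grad:
                A[pidx] = P[iidx]
            P[iidx] = P[iidx] @ M[pidx]
        B = None
        if need_grad:
            B = np.empty_like(M)
            suf = np.tile(eye, (n_i, 1, 1))
            for pidx, iidx in reversed(self.pos_groups):
                B[pidx] = suf[iidx]
                suf[iidx] = M[pidx] @ suf[iidx]
        return q_p, Q, M, P, A, B

    def _death_weights(self, pv: ParameterVector):
        """Intensities into death evaluated at each exact death age."""
        S = self.spec.state_space.n_states
        q_d = _intensities(pv, self.d_age, self.d_X)
        w = np.zeros((len(self.d_rows), S))
        for t in self.death_transitions:
            r_t = self.spec.transitions[t][0]
            w[:, r_t] = q_d[:, t]
        return q_d, w

    def loglik(self, pv: ParameterVector) -> float:
        if self.impossible_pairs:
            return -np.inf
        if self.n_intervals == 0:
            return 0.0
        fwd = self._forward(pv, need_grad=False)
        if fwd is None:
            return -np.inf
        return self._contributions(pv, fwd[3])[0]

    def _contributions(self, pv: ParameterVector, P: np.ndarray):
        alive = ~self.is_death
        p_obs = np.clip(P[alive, self.r[alive], self.s[alive]], _PROB_FLOOR, None)
        q_d, w = self._death_weights(pv)
        v = np.clip(
            np.einsum("ij,ij->i", P[self.d_rows, self.r[self.d_rows], :], w),
            _PROB_FLOOR,
            None,
        )
        ll = float(np.log(p_obs).sum() + np.log(v).sum())
        return ll, p_obs, q_d, w, v

    def loglik_grad(self, pv: ParameterVector) -> tuple[float, np.ndarray]:
        """Log-likelihood and its gradient w.r.t. the free parameter vector."""
        if self.impossible_pairs:
            return -np.inf, np.zeros(self.spec.n_free)
        spec = self.spec
        if self.n_intervals == 0:
            return 0.0, np.zeros(spec.n_free)
        S = spec.state_space.n_states
        fwd = self._forward(pv, need_grad=True)
        if fwd is None:
            return -np.inf, np.zeros(spec.n_free)
        q_p, Q, M, P, A, B = fwd
        ll, p_obs, q_d, w, v = self._contributions(pv, P)

        # rank-one dL/dP = e_r c^T per interval
        with np.errstate(over="ignore", invalid="ignore"):
            c = np.zeros((self.n_intervals, S))
            alive = ~self.is_death
            c[alive, self.s[alive]] = 1.0 / p_obs
            c[self.d_rows] = w / v[:, None]

        # per piece: dL/dM_j = outer(A_j[r,:], B_j @ c)
        r_int = self.r[self.p_int]
        u = A[np.arange(len(A)), r_int, :]
        with np.errstate(over="ignore", invalid="ignore"):
            b = (B @ c[self.p_int][..., None])[..., 0]
        X_mat = (Q * self.p_dt[:, None, None]).swapaxes(-1, -2)
        if not (np.isfinite(u).all() and np.isfinite(b).all()):
            return -np.inf, np.zeros(spec.n_free)
        G = expm_frechet_rank1(X_mat, u, b) * self.p_dt[:, None, None]

        g = np.empty((len(G), spec.n_transitions))
        for t, (r, s) in enumerate(spec.transitions):
            g[:, t] = q_p[:, t] * (G[:, r, s] - G[:, r, r])

        grad_q0 = g.sum(axis=0)
        grad_age = ((self.p_age - spec.age_origin)[:, None] * g).sum(axis=0)
        grad_beta = g.T @ self.p_X

        # direct dependence of the death factor on q_{s,dead}(td)
        if len(self.d_rows):
            gd = np.zeros((len(self.d_rows), spec.n_transitions))
            Pd = P[self.d_rows, self.r[self.d_rows], :]
            with np.errstate(over="ignore", invalid="ignore"):
                for t in self.death_transitions:
                    r_t = spec.transitions[t][0]
                    gd[:, t] = Pd[:, r_t] * q_d[:, t] / v
            grad_q0 += gd.sum(axis=0)
            grad_age += ((self.d_age - spec.age_origin)[:, None] * gd).sum(axis=0)
            grad_beta += gd.T @ self.d_X

        grad = np.concatenate(
            [grad_q0, grad_age[spec.free_age], grad_beta.T[spec.free_beta.T]]
        )
        return ll, grad


def _histories(panel: CohortPanel) -> Iterable[SubjectHistory]:
    return panel.iter_histories()


def subject_log_likelihood(
    params: ParameterVector,
    history: SubjectHistory,
    step_years: float = 0.5,
) -> float:
    """Panel log-likelihood contribution of a single subject.

    Returns ``-inf`` (not an exception) when the observed path is impossible
    under the allowed-transition mask.
    """
    design = _PanelDesign.build(params.spec, [history], step_years=step_years)
    return design.loglik(params)


def panel_log_likelihood(
    params: ParameterVector,
    panel: CohortPanel,
    step_years: float = 0.5,
    on_missing: str = "raise",
) -> float:
    design = _PanelDesign.build(
        params.spec, _histories(panel), step_years=step_years, on_missing=on_missing
    )
    return design.loglik(params)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


def _crude_init(design: _PanelDesign) -> ParameterVector:
    """Crude transition rates (counts / person-time) as starting values."""
    spec = design.spec
    person_time = np.zeros(spec.state_space.n_states)
    for r, t0, t1 in zip(design.r, design.t0, design.t1):
        person_time[r] += t1 - t0
    log_q0 = np.empty(spec.n_transitions)
    for t, (r, s) in enumerate(spec.transitions):
        n_rs = max(design.transition_counts[r, s], 0.5)
        pt = max(person_time[r], 1e-8)
        log_q0[t] = np.log(n_rs / pt)
    T, K = spec.n_transitions, len(spec.covariates)
    return ParameterVector(spec, log_q0, np.zeros(T), np.zeros((T, K)))


def _fd_hessian(design: _PanelDesign, spec: TransitionModelSpec, x: np.ndarray) -> np.ndarray:
    """Central finite differences of the analytic gradient of -loglik."""
    p = len(x)
    H = np.empty((p, p))
    for i in range(p):
        h = 1e-5 * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += h
        _, gp = design.loglik_grad(ParameterVector.unpack(spec, xp))
        xp[i] -= 2 * h
        _, gm = design.loglik_grad(ParameterVector.unpack(spec, xp))
        H[:, i] = -(gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


class MultiStateModel(BaseEstimator):
    """Panel-data multi-state model with Gompertz-type age effects.

    Parameters
    ----------
    state_space : StateSpace, default three-state HWLE topology
    covariates : sequence of str
        Binary covariate columns to include on every transition (unless
        constrained).
    constraints : sequence of (transition, name) pairs
        Effects fixed at zero on the log scale (HRR = 1).  ``name`` may be a
        covariate or ``"age"``.
    age_origin : float
        Age at which baseline intensities are anchored (50).
    step_years : float
        Piecewise-constant approximation step for interval probabilities.
    init : "crude" or ParameterVector
        Starting values; "crude" uses observed counts / person-time.
    gtol : float
        Projected-gradient tolerance for L-BFGS-B.
    compute_covariance : bool
        Whether to compute the inverse-Hessian covariance after fitting.
    on_missing : "raise" or "drop"
        How to treat missing state/covariate cells: refuse (directing the
        caller to the imputation module) or drop record-wise
        (complete-case analysis).

    Attributes (after ``fit``)
    --------------------------
    params_ : ParameterVector            MLE on the natural scale
    free_params_ : ndarray               packed free-parameter MLE
    covariance_ : ndarray or None        inverse observed information
    loglik_ : float
    converged_ : bool
    n_subjects_, n_intervals_, n_transitions_observed_ : int
    """

    def __init__(
        self,
        state_space: StateSpace | None = None,
        covariates: Sequence[str] = (),
        constraints: Sequence = (),
        age_origin: float = 50.0,
        step_years: float = 0.5,
        init="crude",
        gtol: float = 1e-5,
        max_iter: int = 500,
        compute_covariance: bool = True,
        on_missing: str = "raise",
    ):
        self.state_space = state_space
        self.covariates = covariates
        self.constraints = constraints
        self.age_origin = age_origin
        self.step_years = step_years
        self.init = init
        self.gtol = gtol
        self.max_iter = max_iter
        self.compute_covariance = compute_covariance
        self.on_missing = on_missing

    # -- fitting ----------------------------------------------------------
    def fit(self, panel: CohortPanel, y=None) -> "MultiStateModel":
        space = self.state_space or panel.state_space
        spec = TransitionModelSpec(
            state_space=space,
            covariates=tuple(self.covariates),
            constraints=tuple(self.constraints),
            age_origin=self.age_origin,
        )
        design = _PanelDesign.build(
            spec, panel.iter_histories(), step_years=self.step_years,
            on_missing=self.on_missing,
        )
        if design.n_intervals == 0:
            raise ValidationError("no usable observation intervals in the panel")
        if design.impossible_pairs:
            k = len(design.impossible_pairs)
            raise ValidationError(
                f"{k} observed transition(s) are impossible under the allowed mask, "
                f"e.g. {design.impossible_pairs[0]}"
            )
        self._warn_sparse(design, spec)

        if isinstance(self.init, ParameterVector):
            x0 = self.init.pack()
        elif self.init == "crude":
            x0 = _crude_init(design).pack()
        else:
            raise ValueError("init must be 'crude' or a ParameterVector")

        # Internal reparameterization: anchor each baseline log-intensity at
        # the person-time-weighted mean of the slope covariates (mean
        # observation age instead of age 50, mean-centred binary
        # covariates).  Baselines and slopes are nearly orthogonal there,
        # which conditions the quasi-Newton search far better; results are
        # mapped back to the age-50 anchoring.
        T = spec.n_transitions
        wgt = design.p_dt if len(design.p_dt) else None
        delta = (
            float(np.average(design.p_age, weights=wgt)) - spec.age_origin
            if wgt is not None
            else 0.0
        )
        xbar = (
            np.average(design.p_X, axis=0, weights=wgt)
            if wgt is not None and design.p_X.shape[1]
            else np.zeros(len(spec.covariates))
        )
        t_of, c_of = [], []
        for t in np.nonzero(spec.free_age)[0]:
            t_of.append(t)
            c_of.append(delta)
        for k in range(len(spec.covariates)):
            for t in np.nonzero(spec.free_beta[:, k])[0]:
                t_of.append(t)
                c_of.append(float(xbar[k]))
        C = np.zeros((T, len(t_of)))
        C[t_of, np.arange(len(t_of))] = c_of

        def from_internal(y):
            x = y.copy()
            x[:T] -= C @ y[T:]
            return x

        def negloglik(y: np.ndarray):
            x = from_internal(y)
            ll, grad = design.loglik_grad(ParameterVector.unpack(spec, x))
            if not np.isfinite(ll) or not np.isfinite(grad).all():
                return 1e12, np.zeros_like(y)
            g = grad.copy()
            g[T:] -= C.T @ grad[:T]
            return -ll, -g

        y0 = x0.copy()
        y0[:T] += C @ x0[T:]
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*precision loss.*")
            res = minimize(
                negloglik,
                y0,
                jac=True,
                method="BFGS",
                options={"maxiter": self.max_iter, "gtol": self.gtol},
            )
        grad_ok = np.isfinite(res.jac).all() and np.abs(res.jac).max() <= 1e2 * self.gtol
        if not (res.success or grad_ok):
            # boundary MLEs (e.g. zero observed events on a transition) have
            # no stationary point; finish with a box-bounded search where the
            # projected gradient criterion is meaningful
            n_beta = spec.n_free - T - int(spec.free_age.sum())
            bounds = (
                [(-25.0, 5.0)] * T
                + [(-2.0, 2.0)] * int(spec.free_age.sum())
                + [(-8.0, 8.0)] * n_beta
            )
            res2 = minimize(
                negloglik,
                np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds]),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": 1e-12},
            )
            if res2.fun <= res.fun:
                res = res2
        res.x = from_internal(res.x)
        self.spec_ = spec
        self._design_ = design
        self.free_params_ = res.x
        self.params_ = ParameterVector.unpack(spec, res.x)
        self.loglik_ = float(-res.fun)
        # BFGS may stop on line-search precision loss after the gradient is
        # already far below any statistically meaningful level, so judge
        # convergence from the final (projected) gradient as well
        self.grad_norm_ = float(np.abs(res.jac).max()) if np.size(res.jac) else 0.0
        self.converged_ = bool(res.success or self.grad_norm_ <= 1e2 * self.gtol)
        self.n_subjects_ = design.n_subjects
        self.n_intervals_ = design.n_intervals
        self.n_transitions_observed_ = design.n_transitions_observed
        self.n_free_ = spec.n_free
        self.covariance_ = None
        self.covariance_ok_ = False
        if self.compute_covariance and self.converged_:
            H = _fd_hessian(design, spec, res.x)
            w, q = np.linalg.eigh(0.5 * (H + H.T))
            if np.isfinite(w).all() and w.min() > 1e-10 * max(w.max(), 1.0):
                cov = (q / w) @ q.T
                self.covariance_ = 0.5 * (cov + cov.T)
                self.covariance_ok_ = True
            else:
                # flat directions (boundary MLEs) get a large-but-finite
                # variance: clip the information spectrum from below
                warnings.warn(
                    "observed information is singular (boundary estimate?); "
                    "flat directions reported with very large variance",
                    stacklevel=2,
                )
                floor = 1e-6 * max(w.max(), 1e-6)
                cov = (q / np.clip(w, floor, None)) @ q.T
                self.covariance_ = 0.5 * (cov + cov.T)
        return self

    def _warn_sparse(self, design: _PanelDesign, spec: TransitionModelSpec) -> None:
        per_trans = 1 + spec.free_age.astype(int) + spec.free_beta.sum(axis=1)
        for t, (r, s) in enumerate(spec.transitions):
            n_obs = design.transition_counts[r, s]
            if n_obs < per_trans[t]:
                warnings.warn(
                    f"transition {spec.state_space.transition_label(r, s)}: "
                    f"{n_obs} observed transitions for {per_trans[t]} free parameters",
                    stacklevel=3,
                )

    # -- fitted queries ----------------------------------------------------
    def intensity_matrix(self, age: float, covariates=None) -> np.ndarray:
        return build_generator(self.params_, age, covariates)

    def transition_probability(self, age0, age1, covariates=None, step_years=None):
        return interval_probability(
            self.params_, age0, age1, covariates, step_years or self.step_years
        )

    def log_likelihood(self, panel: CohortPanel) -> float:
        return panel_log_likelihood(
            self.params_, panel, self.step_years, on_missing=self.on_missing
        )

    def score(self, panel: CohortPanel, y=None) -> float:
        """Mean per-subject log-likelihood (higher is better)."""
        return self.log_likelihood(panel) / max(panel.n_subjects, 1)

    def hazard_ratio_table(self, z: float = 1.959963984540054) -> pd.DataFrame:
        return hazard_ratio_table(self, z=z)


def hazard_ratio_table(fit: MultiStateModel, z: float = 1.959963984540054) -> pd.DataFrame:
    """Per-transition hazard rate ratios with Wald 95% CIs.

    One row per (transition, effect); constrained effects appear with
    ``fixed=True`` and HRR exactly 1.  CIs are ``exp(beta ± z·se)`` and are
    missing (NaN) when no valid covariance is available.
    """
    spec = fit.spec_
    have_cov = fit.covariance_ is not None
    if not have_cov:
        warnings.warn("no covariance available; HRR CIs reported as missing",
                      stacklevel=2)
    elif not fit.covariance_ok_:
        warnings.warn("covariance is from a singular information matrix; "
                      "CIs on flat directions are nominal", stacklevel=2)
    rows = []
    for t, (r, s) in enumerate(spec.transitions):
        label = spec.state_space.transition_label(r, s)
        for name, value, free in [
            (_AGE, fit.params_.beta_age[t], spec.free_age[t]),
            *[
                (cov, fit.params_.beta[t, k], spec.free_beta[t, k])
                for k, cov in enumerate(spec.covariates)
            ],
        ]:
            se = lo = hi = np.nan
            if free and have_cov:
                idx = spec.free_index((r + 1, s + 1), name)
                se = float(np.sqrt(fit.covariance_[idx, idx]))
                lo, hi = np.exp(value - z * se), np.exp(value + z * se)
            rows.append(
                {
                    "transition": label,
                    "effect": name,
                    "log_hrr": float(value),
                    "se": se,
                    "hrr": float(np.exp(value)),
                    "ci_low": lo,
                    "ci_high": hi,
                    "fixed": not bool(free),
                }
            )
    return pd.DataFrame(rows)


def format_hrr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render an HRR table with '1.07 (1.06,1.08)' / '1.00 (fixed)' cells."""
    def cell(row):
        if row["fixed"]:
            return "1.00 (fixed)"
        if np.isnan(row["se"]):
            return f"{row['hrr']:.2f} (-,-)"
        return f"{row['hrr']:.2f} ({row['ci_low']:.2f},{row['ci_high']:.2f})"

    out = table.copy()
    out["formatted"] = out.apply(cell, axis=1)
    return out.pivot(index="transition", columns="effect", values="formatted")


def fit_multistate(panel: CohortPanel, **kwargs) -> MultiStateModel:
    """Convenience wrapper: construct and fit a :class:`MultiStateModel`."""
    return MultiStateModel(**kwargs).fit(panel)
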