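"""Synthetic ageing-cohort panels with known ground truth.

Emulates the observation design of English Longitudinal Study of Ageing
(ELSA)-style panels with mortality register linkage: continuous-time
trajectories are drawn from a known multi-state model (the *true model*)
and observed at roughly 2-yearly interview waves; death ages are recorded
exactly within the observation window; binary covariates evolve
wave-to-wave by flip probabilities; MCAR/MAR missingness can be injected
into interview cells.  Baseline conditions
emulate the English ageing-cohort structure: ages 50+, an age-band mix,
~27% of the baseline cross-section healthy-and-working, and covariate
prevalences near the study population (osteoarthritis 24%, mental health
problems 25%, obesity 24%, pain interference 28%, physical inactivity
37%).

Event times are sampled exactly for a piecewise-constant approximation of
the age-inhomogeneous intensities on a monthly grid (cumulative-hazard
inversion), with covariates stepping at interview ages.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import ParameterVector, TransitionModelSpec, _resolve_transition
from .panel import CohortPanel, SubjectHistory, from_dataframe
from .states import StateSpace, three_state_space

__all__ = [
    "TrueModel",
    "SimulationConfig",
    "Trajectory",
    "simulate_trajectory",
    "sample_waves",
    "simulate_cohort",
    "inject_missingness",
    "load_scenario",
    "true_model_from_scenario",
    "config_from_scenario",
    "DEFAULT_COVARIATES",
]

_MONTH = 1.0 / 12.0

# Default covariate battery: prevalence at baseline and hazard rate ratios
# by transition (HRR 1 on every transition not listed).
DEFAULT_COVARIATES: dict[str, dict] = {
    "osteoarthritis": {
        "prevalence": 0.24,
        "hrr": {"HW-nHW": 1.32, "nHW-HW": 0.66, "nHW-dead": 0.89},
        "flip_up": 0.05, "flip_down": 0.0,
    },
    "mental_health": {
        "prevalence": 0.25,
        "hrr": {"HW-nHW": 1.36, "nHW-HW": 0.51, "nHW-dead": 1.63},
        "flip_up": 0.05, "flip_down": 0.05,
    },
    "obese": {
        "prevalence": 0.24,
        "hrr": {"HW-nHW": 1.12, "nHW-HW": 0.91},
        "flip_up": 0.03, "flip_down": 0.03,
    },
    "pain": {
        "prevalence": 0.28,
        "hrr": {"HW-nHW": 1.50, "nHW-HW": 0.57, "nHW-dead": 1.25},
        "flip_up": 0.05, "flip_down": 0.05,
    },
    "inactive": {
        "prevalence": 0.37,
        "hrr": {"HW-nHW": 1.12, "nHW-HW": 0.55, "nHW-dead": 2.27},
        "flip_up": 0.05, "flip_down": 0.05,
    },
}


@dataclass
class TrueModel:
    """Generating process: parameters, covariate dynamics, initial-state law.

    The initial-state law is logistic in (age − 50) for the probability of
    the healthy-and-working state; the remainder is split over the other
    alive states in proportion to ``alive_remainder``.
    """

    params: ParameterVector
    prevalence: dict[str, float] = field(default_factory=dict)
    flip_up: dict[str, float] = field(default_factory=dict)
    flip_down: dict[str, float] = field(default_factory=dict)
    init_intercept: float = -0.42
    init_age_slope: float = -0.035
    alive_remainder: np.ndarray | None = None
    aux_agreement: float = 0.9

    def __post_init__(self) -> None:
        for name, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name} outside [0,1]")
        space = self.params.spec.state_space
        n_other = len(space.alive) - 1
        if self.alive_remainder is None:
            self.alive_remainder = np.full(n_other, 1.0 / max(n_other, 1))
        else:
            self.alive_remainder = np.asarray(self.alive_remainder, dtype=float)
            self.alive_remainder = self.alive_remainder / self.alive_remainder.sum()

    @property
    def spec(self) -> TransitionModelSpec:
        return self.params.spec

    def initial_state_probs(self, age: float) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-(self.init_intercept + self.init_age_slope * (age - 50.0))))
        return np.concatenate([[p1], (1 - p1) * self.alive_remainder])


@dataclass
class SimulationConfig:
    """Observation design: cohort size, waves, baseline age mix, missingness."""

    n_subjects: int = 2000
    n_waves: int = 5
    wave_interval: float = 2.0
    wave_jitter: float = 0.2
    max_age: float = 120.0
    # (low, high) -> weight; defaults follow the baseline age mix of the cohort
    age_bands: dict[tuple[float, float], float] = field(
        default_factory=lambda: {
            (50, 60): 0.30, (60, 70): 0.32, (70, 80): 0.25, (80, 90): 0.12, (90, 100): 0.01,
        }
    )
    missingness: dict = field(default_factory=lambda: {"mechanism": "none"})

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if not 0 <= self.wave_jitter < self.wave_interval / 2:
            raise ValueError("wave_jitter must be in [0, wave_interval/2)")


@dataclass
class Trajectory:
    """A continuous-time path: jump chain plus death/censoring age."""

    jumps: list[tuple[float, int]]  # (age, state code), first entry is baseline
    death_age: float | None
    end_age: float

    def state_at(self, age: float) -> int:
        code = self.jumps[0][1]
        for t, c in self.jumps:
            if t <= age + 1e-12:
                code = c
            else:
                break
        return code


def simulate_trajectory(
    true_model: TrueModel,
    baseline_age: float,
    baseline_state: int,
    covariate_path: tuple[np.ndarray, np.ndarray] | None,
    rng: np.random.Generator,
    max_age: float = 120.0,
) -> Trajectory:
    """Sample one path by competing-risks inversion on a monthly grid.

    ``covariate_path`` is (change_ages, values) with one value row per
    change age; covariates are piecewise constant.  The path ends at death
    or at ``max_age`` (censored).
    """
    pv = true_model.params
    spec = pv.spec
    space = spec.state_space
    K = len(spec.covariates)
    if covariate_path is None:
        change_ages = np.array([baseline_age])
        cov_values = np.zeros((1, K))
    else:
        change_ages, cov_values = covariate_path
        cov_values = np.asarray(cov_values, dtype=float).reshape(len(change_ages), K)

    trans_from: dict[int, list[int]] = {}
    for t, (r, s) in enumerate(spec.transitions):
        trans_from.setdefault(r, []).append(t)

    jumps = [(float(baseline_age), int(baseline_state))]
    a = float(baseline_age)
    r = int(baseline_state) - 1
    death_age = None
    while r != space.death and a < max_age - 1e-12:
        k0 = int(np.ceil((a - baseline_age) / _MONTH - 1e-9))
        kend = int(np.ceil((max_age - baseline_age) / _MONTH - 1e-9))
        edges = baseline_age + _MONTH * np.arange(k0, kend + 1)
        edges = np.concatenate([[a], edges[edges > a + 1e-12]])
        edges[-1] = min(edges[-1], max_age)
        left, dt = edges[:-1], np.diff(edges)
        ci = np.clip(np.searchsorted(change_ages, left, side="right") - 1, 0, None)
        X = cov_values[ci]
        tidx = trans_from[r]
        lin = (
            pv.log_q0[tidx][None, :]
            + np.outer(left - spec.age_origin, pv.beta_age[tidx])
            + X @ pv.beta[tidx].T
        )
        q = np.exp(lin)
        lam = q.sum(axis=1)
        cum = np.cumsum(lam * dt)
        target = rng.exponential()
        pos = int(np.searchsorted(cum, target))
        if pos >= len(cum):
            break  # censored at max_age
        prev = cum[pos - 1] if pos else 0.0
        t_event = left[pos] + (target - prev) / lam[pos]
        dest_t = tidx[rng.choice(len(tidx), p=q[pos] / lam[pos])]
        dest = spec.transitions[dest_t][1]
        jumps.append((float(t_event), dest + 1))
        if dest == space.death:
            death_age = float(t_event)
        a, r = float(t_event), dest
    return Trajectory(jumps=jumps, death_age=death_age, end_age=max_age)


def sample_waves(
    traj: Trajectory,
    wave_ages: np.ndarray,
    wave_covariates: np.ndarray,
    space: StateSpace,
    covariate_names: Sequence[str] = (),
) -> SubjectHistory:
    """Observe a trajectory at interview waves, plus an exact death record.

    Deaths are recorded only when they fall inside the observation window
    (at or before the last scheduled wave), mirroring registry linkage that
    ends with the final wave.  Subjects failing the multiple-observation
    rule are emitted anyway; validation drops them.
    """
    rows = _wave_rows(traj, wave_ages, wave_covariates, space, covariate_names)
    ages = np.array([r["age"] for r in rows])
    states = np.array([float(r["state"]) for r in rows])
    exact = np.array([bool(r["exact_death"]) for r in rows])
    covs = pd.DataFrame(
        [[r.get(c, np.nan) for c in covariate_names] for r in rows],
        columns=list(covariate_names),
        dtype=float,
    )
    return SubjectHistory("sim", ages, states, exact, covs)


def _wave_rows(traj, wave_ages, wave_covariates, space, covariate_names):
    rows = []
    death_code = space.death_code
    for w, age in enumerate(np.asarray(wave_ages, dtype=float)):
        if traj.death_age is not None and traj.death_age <= age:
            rows.append(
                {"age": traj.death_age, "state": death_code, "exact_death": True,
                 **{c: np.nan for c in covariate_names}}
            )
            break
        row = {"age": float(age), "state": traj.state_at(age), "exact_death": False}
        for k, c in enumerate(covariate_names):
            row[c] = float(wave_covariates[w, k])
        rows.append(row)
    return rows


def simulate_cohort(
    true_model: TrueModel,
    config: SimulationConfig,
    seed: int,
) -> tuple[CohortPanel, dict]:
    """Generate a validated cohort panel plus a ground-truth record.

    Deterministic given ``seed`` (per-subject child streams of a single
    seed sequence).  Returns ``(panel, truth)`` where ``truth`` carries the
    generating parameters and, when missingness is injected, the mask of
    blanked cells.
    """
    spec = true_model.spec
    space = spec.state_space
    cov_names = list(spec.covariates)
    prev = np.array([true_model.prevalence.get(c, 0.0) for c in cov_names])
    p_up = np.array([true_model.flip_up.get(c, 0.0) for c in cov_names])
    p_down = np.array([true_model.flip_down.get(c, 0.0) for c in cov_names])

    bands = list(config.age_bands.items())
    band_w = np.array([w for _, w in bands], dtype=float)
    band_w = band_w / band_w.sum()

    ss = np.random.SeedSequence(seed)
    rng_root = np.random.default_rng(ss)
    child_seeds = ss.spawn(config.n_subjects)

    all_rows: list[dict] = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(child_seeds[i])
        lo, hi = bands[rng.choice(len(bands), p=band_w)][0]
        age0 = float(rng.uniform(lo, hi))
        probs = true_model.initial_state_probs(age0)
        state0 = int(space.alive[rng.choice(len(probs), p=probs)]) + 1
        x = (rng.random(len(cov_names)) < prev).astype(float)

        offsets = config.wave_interval * np.arange(1, config.n_waves)
        if config.wave_jitter > 0:
            offsets = offsets + rng.uniform(
                -config.wave_jitter, config.wave_jitter, size=len(offsets)
            )
        wave_ages = np.concatenate([[age0], age0 + np.sort(offsets)])

        wave_covs = np.empty((config.n_waves, len(cov_names)))
        wave_covs[0] = x
        for w in range(1, config.n_waves):
            cur = wave_covs[w - 1]
            u = rng.random(len(cov_names))
            wave_covs[w] = np.where(cur == 1.0, (u >= p_down).astype(float),
                                    (u < p_up).astype(float))

        path = (wave_ages, wave_covs)
        traj = simulate_trajectory(
            true_model, age0, state0, path, rng,
            max_age=min(config.max_age, float(wave_ages[-1]) + 1e-9),
        )
        rows = _wave_rows(traj, wave_ages, wave_covs, space, cov_names)
        # auxiliary candidates: noisy copies of the baseline covariates
        aux = {
            f"aux_{c}": (x[k] if rng.random() < true_model.aux_agreement else 1.0 - x[k])
            for k, c in enumerate(cov_names)
        }
        sid = f"S{i:06d}"
        for row in rows:
            row["id"] = sid
            row.update(aux)
            all_rows.append(row)

    df = pd.DataFrame(all_rows)
    truth: dict = {
        "seed": seed,
        "log_q0": true_model.params.log_q0.tolist(),
        "beta_age": true_model.params.beta_age.tolist(),
        "beta": true_model.params.beta.tolist(),
        "transitions": list(space.transition_labels),
        "covariates": cov_names,
        "init_intercept": true_model.init_intercept,
        "init_age_slope": true_model.init_age_slope,
    }
    panel = from_dataframe(df, space, covariates=cov_names,
                           aux=[f"aux_{c}" for c in cov_names])
    mech = config.missingness.get("mechanism", "none")
    if mech and mech != "none":
        miss_seed = int(np.random.SeedSequence(seed).generate_state(2)[1] % (2**31))
        panel, mask = inject_missingness(
            panel,
            mechanism=mech,
            rate=config.missingness.get("rate", 0.0),
            columns=config.missingness.get("columns"),
            mar=config.missingness.get("mar"),
            seed=miss_seed,
        )
        truth["missing_mask"] = mask.to_dict(orient="list")
    return panel, truth


def inject_missingness(
    panel: CohortPanel,
    mechanism: str,
    rate: float,
    columns: Sequence[str] | None = None,
    mar: Mapping | None = None,
    seed: int | None = None,
) -> tuple[CohortPanel, pd.DataFrame]:
    """Blank interview cells MCAR or MAR; death records are never touched.

    MAR missingness depends only on fully observed quantities: the record's
    age band (70+), an auxiliary column, and (for covariate cells) the
    co-observed state, through a logistic model whose intercept is
    calibrated so the average rate matches ``rate``.  Returns
    the modified panel and a truth mask (row index, column, true value).
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be 'MCAR' or 'MAR'")
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    df = out.data
    eligible = ~df["exact_death"]
    cols = list(columns) if columns is not None else ["state"] + list(panel.covariate_names)

    mask_rows = []
    for col in cols:
        idx = df.index[eligible & df[col].notna()]
        if len(idx) == 0 or rate == 0:
            continue
        if mechanism == "MCAR":
            p = np.full(len(idx), rate)
        else:
            mar = mar or {}
            age_coef = float(mar.get("age_coef", 1.0))
            aux_coef = float(mar.get("aux_coef", 1.0))
            state_coef = float(mar.get("state_coef", 0.0))
            aux_col = mar.get("aux")
            z = age_coef * (df.loc[idx, "age"].to_numpy() >= 70.0)
            if aux_col is not None:
                z = z + aux_coef * df.loc[idx, aux_col].to_numpy(dtype=float)
            if state_coef and col != "state":
                # covariate missingness may depend on the co-observed state
                not_hw = df.loc[idx, "state"].to_numpy(dtype=float) != 1.0
                z = z + state_coef * not_hw
            # calibrate the intercept so mean probability == rate
            lo, hi = -20.0, 20.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.mean(1 / (1 + np.exp(-(mid + z)))) < rate:
                    lo = mid
                else:
                    hi = mid
            p = 1 / (1 + np.exp(-(0.5 * (lo + hi) + z)))
        hit = idx[rng.random(len(idx)) < p]
        for i in hit:
            mask_rows.append({"row": int(i), "column": col,
                              "true_value": float(df.at[i, col])})
        df.loc[hit, col] = np.nan

    mask = pd.DataFrame(mask_rows, columns=["row", "column", "true_value"])
    return out, mask


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def load_scenario(name_or_path: str | Path) -> dict:
    """Load a scenario mapping from a packaged name or a YAML file path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        res = importlib.resources.files("hwle") / "scenarios" / f"{name_or_path}.yaml"
        text = res.read_text()
    return yaml.safe_load(text)


def true_model_from_scenario(scn: Mapping) -> TrueModel:
    space = three_state_space() if scn.get("states", 3) == 3 else None
    if space is None:
        from .states import five_state_space

        space = five_state_space()
    cov_spec = scn.get("covariates", {}) or {}
    cov_names = tuple(cov_spec)
    spec = TransitionModelSpec(state_space=space, covariates=cov_names)
    T = spec.n_transitions
    log_q0 = np.empty(T)
    beta_age = np.zeros(T)
    t_of = {rs: t for t, rs in enumerate(spec.transitions)}
    for key, val in scn["baseline_hazards"].items():
        log_q0[t_of[_resolve_transition(space, key)]] = np.log(float(val))
    for key, val in scn.get("age_hrr", {}).items():
        beta_age[t_of[_resolve_transition(space, key)]] = np.log(float(val))
    beta = np.zeros((T, len(cov_names)))
    prevalence, flip_up, flip_down = {}, {}, {}
    for k, (name, cfg) in enumerate(cov_spec.items()):
        prevalence[name] = float(cfg.get("prevalence", 0.0))
        flip_up[name] = float(cfg.get("flip_up", 0.0))
        flip_down[name] = float(cfg.get("flip_down", 0.0))
        for key, hrr in (cfg.get("hrr") or {}).items():
            beta[t_of[_resolve_transition(space, key)], k] = np.log(float(hrr))
    init = scn.get("init_logit", {})
    return TrueModel(
        params=ParameterVector(spec, log_q0, beta_age, beta),
        prevalence=prevalence,
        flip_up=flip_up,
        flip_down=flip_down,
        init_intercept=float(init.get("intercept", -0.42)),
        init_age_slope=float(init.get("age_slope", -0.035)),
        aux_agreement=float(scn.get("aux_agreement", 0.9)),
    )


def config_from_scenario(scn: Mapping, **overrides) -> SimulationConfig:
    bands = scn.get("age_bands")
    kwargs: dict = {}
    if bands:
        parsed = {}
        for key, w in bands.items():
            lo, _, hi = str(key).partition("-")
            parsed[(float(lo), float(hi))] = float(w)
        kwargs["age_bands"] = parsed
    for fld in ("n_subjects", "n_waves", "wave_interval", "wave_jitter", "max_age",
                "missingness"):
        if fld in scn:
            kwargs[fld] = scn[fld]
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
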