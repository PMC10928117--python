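"""Long-format panel cohorts: reading, validation, and exclusion rules.

A cohort is one row per subject per observation: subject id, decimal age at
observation, state code (1-based, per the :class:`~hwle.states.StateSpace`),
an exact-death flag, binary covariate columns (0/1, empty cell = missing)
and optional auxiliary columns used only as imputation predictors.

Validation applies the study inclusion rules:

* records observed before age 50 are dropped record-wise (the age scale
  starts at 50);
* subjects must contribute either at least two interviews, or at least one
  interview plus an exact death record; others are excluded with a tally;
* duplicate (subject, age) rows and records after death are errors;
* missing states/covariates at interviews are *retained* for the
  imputation stage, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .states import StateSpace, encode_state, three_state_space

__all__ = [
    "SubjectHistory",
    "CohortPanel",
    "ValidationReport",
    "read_panel",
    "write_panel",
    "from_dataframe",
    "validate_cohort",
]

_CANONICAL = ("id", "age", "state", "exact_death")


@dataclass
class SubjectHistory:
    """Time-ordered observations for one subject.

    ``states`` holds 1-based codes as floats with NaN marking an interview
    whose state is missing; ``covariates`` is aligned row-wise.
    """

    subject_id: object
    ages: np.ndarray
    states: np.ndarray
    exact_death: np.ndarray
    covariates: pd.DataFrame

    def __len__(self) -> int:
        return len(self.ages)


class CohortPanel:
    """A validated cohort: the unit of likelihood evaluation.

    Wraps a canonical long-format DataFrame (sorted by subject then age)
    plus the state space and the ordered covariate/auxiliary column names.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        state_space: StateSpace,
        covariate_names: Sequence[str] = (),
        aux_names: Sequence[str] = (),
        exclusions: Mapping[str, int] | None = None,
    ):
        self.state_space = state_space
        self.covariate_names = tuple(covariate_names)
        self.aux_names = tuple(aux_names)
        self.data = data.reset_index(drop=True)
        self.exclusions_ = dict(exclusions or {})

    # -- basic queries ----------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.data["id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.data)

    def baseline(self) -> pd.DataFrame:
        """First observed record per subject."""
        return self.data.groupby("id", sort=False).head(1)

    def iter_histories(self) -> Iterator[SubjectHistory]:
        cov_cols = list(self.covariate_names)
        for sid, grp in self.data.groupby("id", sort=False):
            yield SubjectHistory(
                subject_id=sid,
                ages=grp["age"].to_numpy(dtype=float),
                states=grp["state"].to_numpy(dtype=float),
                exact_death=grp["exact_death"].to_numpy(dtype=bool),
                covariates=grp[cov_cols].reset_index(drop=True),
            )

    def copy(self) -> "CohortPanel":
        return CohortPanel(
            self.data.copy(),
            self.state_space,
            self.covariate_names,
            self.aux_names,
            self.exclusions_,
        )

    def equals(self, other: "CohortPanel") -> bool:
        return (
            self.covariate_names == other.covariate_names
            and self.aux_names == other.aux_names
            and self.data.shape == other.data.shape
            and bool(
                self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortPanel(n_subjects={self.n_subjects}, n_records={self.n_records}, "
            f"states={self.state_space.labels}, covariates={list(self.covariate_names)})"
        )


def _fail(msg: str, subjects: Iterable) -> None:
    ids = sorted(map(str, set(subjects)))
    shown = ", ".join(ids[:10]) + (" ..." if len(ids) > 10 else "")
    raise ValidationError(f"{msg} (subjects: {shown})")


def from_dataframe(
    df: pd.DataFrame,
    state_space: StateSpace | None = None,
    covariates: Sequence[str] | None = None,
    aux: Sequence[str] = (),
    min_age: float = 50.0,
) -> CohortPanel:
    """Build a validated :class:`CohortPanel` from a long-format DataFrame.

    Exclusion tallies are stored on the returned panel's ``exclusions_``.
    """
    space = state_space or three_state_space()
    df = df.copy()
    for col in ("id", "age", "state"):
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} not found")
    if covariates is None:
        covariates = [
            c
            for c in df.columns
            if c not in _CANONICAL and c not in tuple(aux) and not c.startswith("aux_")
        ]
        aux = tuple(aux) + tuple(c for c in df.columns if c.startswith("aux_"))
    covariates = list(covariates)
    aux = list(aux)

    df["age"] = df["age"].astype(float)
    df["state"] = pd.to_numeric(df["state"], errors="raise").astype(float)
    for c in covariates + aux:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)

    observed = df["state"].notna()
    bad = observed & ~df["state"].isin([float(c) for c in space.codes])
    if bad.any():
        _fail(
            f"unknown state codes {sorted(df.loc[bad, 'state'].unique())}",
            df.loc[bad, "id"],
        )

    is_death = df["state"] == float(space.death_code)
    if "exact_death" in df.columns:
        df["exact_death"] = (
            pd.to_numeric(df["exact_death"], errors="coerce").fillna(0).astype(bool)
        )
        mismatch = df["exact_death"] != is_death
        if mismatch.any():
            _fail(
                "exact_death flag must be set exactly on death records",
                df.loc[mismatch, "id"],
            )
    else:
        df["exact_death"] = is_death

    n_subjects_in = df["id"].nunique()
    under_50 = df["age"] < min_age
    n_under_50 = int(under_50.sum())
    df = df[~under_50]

    dup = df.duplicated(subset=["id", "age"], keep=False)
    if dup.any():
        _fail("duplicate (subject, age) observations", df.loc[dup, "id"])

    df = df.sort_values(["id", "age"], kind="stable").reset_index(drop=True)

    # a death record must be unique per subject and must come last
    grp = df.groupby("id", sort=False)
    death_counts = grp["exact_death"].sum()
    if (death_counts > 1).any():
        _fail("more than one death record", death_counts.index[death_counts > 1])
    has_tail = grp["exact_death"].apply(lambda s: bool(s.any()) and not bool(s.iloc[-1]))
    if has_tail.any():
        _fail("records observed after death", has_tail.index[has_tail])

    # multiple-observation inclusion rule
    n_alive = grp.size() - death_counts
    keep = (n_alive >= 2) | ((n_alive >= 1) & (death_counts >= 1))
    n_dropped_subjects = int((~keep).sum())
    df = df[df["id"].isin(keep.index[keep])].reset_index(drop=True)

    exclusions = {
        "subjects_in": n_subjects_in,
        "under_50_records": n_under_50,
        "insufficient_observation_subjects": n_dropped_subjects,
        "subjects_kept": df["id"].nunique(),
    }
    cols = ["id", "age", "state", "exact_death"] + covariates + aux
    return CohortPanel(df[cols], space, covariates, aux, exclusions)


def read_panel(
    path: str | Path,
    state_space: StateSpace | None = None,
    covariates: Sequence[str] | None = None,
    aux: Sequence[str] = (),
    schema: Mapping[str, str] | None = None,
) -> CohortPanel:
    """Read a delimited panel file and validate it.

    ``schema`` maps canonical column names (``id``, ``age``, ``state``,
    ``exact_death`` — or ``healthy``/``working``/``dead`` flag columns in
    place of ``state``) to the file's column names.
    """
    space = state_space or three_state_space()
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if "state" not in df.columns and {"healthy", "working", "dead"} <= set(df.columns):
        df["state"] = [
            encode_state(bool(h), bool(w), bool(d), space)
            for h, w, d in zip(df["healthy"], df["working"], df["dead"])
        ]
        df = df.drop(columns=["healthy", "working", "dead"])
    return from_dataframe(df, space, covariates=covariates, aux=aux)


def write_panel(panel: CohortPanel, path: str | Path) -> None:
    """Write a panel back to CSV in the canonical schema (round-trip safe)."""
    out = panel.data.copy()
    out["state"] = out["state"].astype("Int64")
    out["exact_death"] = out["exact_death"].astype(int)
    out.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Cohort summary mirroring a baseline-characteristics table."""

    n_subjects: int
    n_records: int
    n_deaths: int
    exclusions: dict = field(default_factory=dict)
    baseline_state_share: dict = field(default_factory=dict)
    state_counts_by_wave: dict = field(default_factory=dict)
    missing_cells: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)

    def to_text(self) -> str:
        lines = [
            f"subjects: {self.n_subjects}   records: {self.n_records}   deaths: {self.n_deaths}",
            "exclusions: "
            + ", ".join(f"{k}={v}" for k, v in self.exclusions.items()),
            "baseline state share: "
            + ", ".join(f"{k}={v:.1%}" for k, v in self.baseline_state_share.items()),
        ]
        if self.missing_cells:
            lines.append(
                "missing cells: "
                + ", ".join(f"{k}={v}" for k, v in self.missing_cells.items())
            )
        return "\n".join(lines)


def validate_cohort(panel: CohortPanel) -> ValidationReport:
    """Summarise a validated cohort; raises on an empty cohort."""
    if panel.n_subjects == 0:
        raise ValidationError("cohort is empty after exclusions")
    space = panel.state_space
    df = panel.data
    base = panel.baseline()
    base_alive = base[~base["exact_death"]]
    shares = {}
    for idx in space.alive:
        code = float(idx + 1)
        shares[space.labels[idx]] = float((base_alive["state"] == code).mean())

    wave = df.groupby("id", sort=False).cumcount() + 1
    counts: dict[int, dict[str, int]] = {}
    for w, grp in df.groupby(wave):
        counts[int(w)] = {
            space.labels[i]: int((grp["state"] == float(i + 1)).sum())
            for i in range(space.n_states)
        }
    missing = {"state": int(df["state"].isna().sum())}
    for c in panel.covariate_names:
        alive_rows = ~df["exact_death"]
        missing[c] = int(df.loc[alive_rows, c].isna().sum())

    return ValidationReport(
        n_subjects=panel.n_subjects,
        n_records=panel.n_records,
        n_deaths=int(df["exact_death"].sum()),
        exclusions=dict(panel.exclusions_),
        baseline_state_share=shares,
        state_counts_by_wave=counts,
        missing_cells=missing,
    )
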