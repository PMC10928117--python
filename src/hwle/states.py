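"""State spaces for healthy-working-life multi-state models.

A :class:`StateSpace` is a labelled set of alive states plus a single
absorbing death state, together with a boolean mask of permitted
instantaneous transitions.  Two presets are provided:

* ``three_state_space`` — the reduced HWLE topology: healthy-and-working
  (``HW``), not-healthy-and/or-not-working (``nHW``) and ``dead``; the two
  alive states communicate in both directions and each may die.
* ``five_state_space`` — all four combinations of the binary health and
  work statuses plus death, with free movement among the alive states.

State *codes* as they appear in data files are 1-based integers in label
order (so ``dead`` is code 3 in the three-state preset); matrix rows and
columns use the corresponding 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpace",
    "three_state_space",
    "five_state_space",
    "encode_state",
]


@dataclass(frozen=True)
class StateSpace:
    """Alive states plus one absorbing death state with a transition mask.

    Parameters
    ----------
    labels : tuple of str
        Short names for every state, death included, in code order.
    death : int
        0-based index of the absorbing death state.
    allowed : ndarray of bool, shape (S, S)
        ``allowed[r, s]`` is True when the instantaneous transition r → s is
        permitted.  The death row must be all False (absorbing) and the
        diagonal is ignored/forbidden.
    """

    labels: tuple[str, ...]
    death: int
    allowed: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        allowed = np.asarray(self.allowed, dtype=bool).copy()
        allowed.setflags(write=False)
        object.__setattr__(self, "allowed", allowed)
        object.__setattr__(self, "labels", tuple(self.labels))
        s = len(self.labels)
        if allowed.shape != (s, s):
            raise ValueError(f"allowed mask must be {s}x{s}, got {allowed.shape}")
        if not (0 <= self.death < s):
            raise ValueError("death index out of range")
        if np.any(np.diag(allowed)):
            raise ValueError("self-transitions are not permitted")
        # exactly one absorbing state, and it is the declared death state
        absorbing = [i for i in range(s) if not allowed[i].any()]
        if absorbing != [self.death]:
            raise ValueError(
                "the state space must have exactly one absorbing state "
                f"(the death state); found absorbing rows {absorbing}"
            )

    # -- basic structure -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def alive(self) -> tuple[int, ...]:
        """0-based indices of the alive states."""
        return tuple(i for i in range(self.n_states) if i != self.death)

    @property
    def transitions(self) -> tuple[tuple[int, int], ...]:
        """Permitted (from, to) index pairs in row-major order."""
        rows, cols = np.nonzero(self.allowed)
        return tuple(zip(rows.tolist(), cols.tolist()))

    def transition_label(self, r: int, s: int) -> str:
        return f"{self.labels[r]}-{self.labels[s]}"

    @property
    def transition_labels(self) -> tuple[str, ...]:
        return tuple(self.transition_label(r, s) for r, s in self.transitions)

    # -- code helpers -----------------------------------------------------
    @property
    def codes(self) -> tuple[int, ...]:
        """1-based state codes as used in panel files."""
        return tuple(range(1, self.n_states + 1))

    @property
    def death_code(self) -> int:
        return self.death + 1

    def index_of(self, label_or_code: str | int) -> int:
        """Resolve a label or 1-based code to a 0-based index."""
        if isinstance(label_or_code, str):
            try:
                return self.labels.index(label_or_code)
            except ValueError:
                raise KeyError(f"unknown state label {label_or_code!r}") from None
        code = int(label_or_code)
        if code not in self.codes:
            raise KeyError(f"unknown state code {code}")
        return code - 1


def three_state_space() -> StateSpace:
    """The 3-state HWLE topology: HW ↔ nHW, HW → dead, nHW → dead."""
    allowed = np.zeros((3, 3), dtype=bool)
    allowed[0, 1] = allowed[1, 0] = True
    allowed[0, 2] = allowed[1, 2] = True
    return StateSpace(labels=("HW", "nHW", "dead"), death=2, allowed=allowed)


def five_state_space() -> StateSpace:
    """All four health × work combinations plus death.

    Labels: ``HW`` healthy & working, ``HnW`` healthy & not working,
    ``nHW`` not healthy & working, ``nHnW`` not healthy & not working.
    Every ordered pair of distinct alive states is permitted, and every
    alive state may transition to death.
    """
    allowed = np.ones((5, 5), dtype=bool)
    np.fill_diagonal(allowed, False)
    allowed[4, :] = False
    return StateSpace(labels=("HW", "HnW", "nHW", "nHnW", "dead"), death=4, allowed=allowed)


_FIVE_STATE_COMBO = {(True, True): 1, (True, False): 2, (False, True): 3, (False, False): 4}


def encode_state(healthy: bool, working: bool, dead: bool, space: StateSpace) -> int:
    """Map binary health/work/death flags to a 1-based state code.

    In the 3-state preset only the simultaneously healthy-and-working
    combination maps to state 1; every other alive combination collapses to
    state 2.  In the 5-state preset the four alive combinations map
    bijectively to codes 1–4.
    """
    if dead:
        return space.death_code
    n_alive = space.n_states - 1
    if n_alive == 2:
        return 1 if (healthy and working) else 2
    if n_alive == 4:
        return _FIVE_STATE_COMBO[(bool(healthy), bool(working))]
    raise ValueError(f"no health/work encoding for a state space with {n_alive} alive states")
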