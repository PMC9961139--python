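"""Absorbing discrete-time Markov chains: representation, validation and absorption analytics.

An absorbing chain over states ``0..s-1`` is a row-stochastic matrix ``P`` in
which some states are absorbing (self-transition probability 1) and every
transient state reaches an absorbing state with positive probability.  After
permuting transient states first, ``P`` takes the canonical block form
``[[Q, R], [0, I]]``.  The fundamental matrix ``N = (I - Q)^-1`` gives expected
visit counts among transient states before absorption, and ``B = N R`` gives
the probability of ending in each absorbing state from each transient start.

Both ``N`` and ``B`` are computed from a single LU factorization of ``I - Q``;
no explicit matrix inverse is ever formed.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "AbsorbingChain",
    "CanonicalForm",
    "AbsorptionResult",
    "ChainStructureError",
    "ChainValidationError",
    "NoAbsorptionError",
    "validate_chain",
    "canonical_decompose",
    "solve_absorption",
]

#: Tolerance for row-stochasticity checks.
ROW_SUM_TOL = 1e-9


class ChainStructureError(ValueError):
    """Malformed chain container: non-square matrix or mismatched sizes.

    Distinct from a validation failure — a structurally broken chain cannot
    even be inspected for the probabilistic invariants.
    """


class ChainValidationError(ValueError):
    """A structurally sound chain violates the absorbing-chain invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid absorbing chain:\n  - " + "\n  - ".join(self.violations)
        )


class NoAbsorptionError(ValueError):
    """A transient class can never reach absorption, so (I - Q) is singular."""

    def __init__(self, trapped_states: list[str]):
        self.trapped_states = list(trapped_states)
        super().__init__(
            "no path to absorption from state(s): " + ", ".join(trapped_states)
        )


@dataclass(frozen=True)
class AbsorbingChain:
    """Named-state absorbing Markov chain.

    Parameters
    ----------
    state_names :
        Ordered state labels; must be unique.
    transition :
        Square row-stochastic matrix, ``transition[i, j]`` the probability of
        moving from state ``i`` to state ``j`` in one step.
    absorbing_flags :
        Boolean per state; flagged states must have self-probability exactly 1.
        The flag is explicit (not inferred from the matrix) so that a
        near-absorbing rounding artifact is caught rather than silently
        reclassified.
    """

    state_names: tuple[str, ...]
    transition: np.ndarray
    absorbing_flags: np.ndarray

    def __init__(self, state_names, transition, absorbing_flags):
        names = tuple(str(s) for s in state_names)
        P = np.asarray(transition, dtype=float)
        flags = np.asarray(absorbing_flags, dtype=bool)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ChainStructureError(f"transition matrix must be square, got shape {P.shape}")
        if P.shape[0] != len(names):
            raise ChainStructureError(
                f"{len(names)} state names but transition matrix is {P.shape[0]}x{P.shape[1]}"
            )
        if flags.shape != (len(names),):
            raise ChainStructureError(
                f"absorbing_flags has shape {flags.shape}, expected ({len(names)},)"
            )
        if len(set(names)) != len(names):
            raise ChainStructureError("duplicate state names")
        P = P.copy()
        P.flags.writeable = False
        flags = flags.copy()
        flags.flags.writeable = False
        object.__setattr__(self, "state_names", names)
        object.__setattr__(self, "transition", P)
        object.__setattr__(self, "absorbing_flags", flags)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def transient_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.absorbing_flags)

    @property
    def absorbing_indices(self) -> np.ndarray:
        return np.flatnonzero(self.absorbing_flags)

    def index_of(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r}; states are {list(self.state_names)}") from None

    def validate(self) -> list[str]:
        return validate_chain(self)

    def require_valid(self) -> "AbsorbingChain":
        violations = self.validate()
        if violations:
            raise ChainValidationError(violations)
        return self

    def renormalized(self) -> "AbsorbingChain":
        """Return a copy with each row rescaled to sum to exactly 1.

        Opt-in repair for matrices transcribed from rounded published tables;
        rows summing to zero are left untouched (they will fail validation).
        """
        P = self.transition.copy()
        sums = P.sum(axis=1)
        ok = sums > 0
        P[ok] = P[ok] / sums[ok, None]
        return AbsorbingChain(self.state_names, P, self.absorbing_flags)


def validate_chain(chain: AbsorbingChain) -> list[str]:
    """Check the absorbing-chain invariants; return human-readable violations.

    An empty list means the chain is valid: entries in [0, 1], rows summing to
    1 within ``ROW_SUM_TOL``, flagged states truly absorbing, at least one
    absorbing state, and every transient state able to reach absorption.
    """
    P = chain.transition
    names = chain.state_names
    violations: list[str] = []

    bad = np.argwhere((P < 0) | (P > 1))
    for i, j in bad:
        violations.append(
            f"entry ({names[i]!r} -> {names[j]!r}) = {P[i, j]:g} outside [0, 1]"
        )

    row_sums = P.sum(axis=1)
    for i in np.flatnonzero(np.abs(row_sums - 1.0) > ROW_SUM_TOL):
        violations.append(f"row {names[i]!r} sums to {row_sums[i]:.12g}, not 1")

    for i in chain.absorbing_indices:
        if P[i, i] != 1.0 or np.any(P[i, np.arange(chain.n_states) != i] != 0.0):
            violations.append(
                f"state {names[i]!r} flagged absorbing but its row is not the unit self-loop"
            )

    if not chain.absorbing_flags.any():
        violations.append("chain has no absorbing state")
    else:
        trapped = _states_never_absorbed(chain)
        for i in trapped:
            violations.append(f"transient state {names[i]!r} cannot reach any absorbing state")

    return violations


def _states_never_absorbed(chain: AbsorbingChain) -> list[int]:
    """Transient states from which no absorbing state is reachable.

    Breadth-first search backwards from the absorbing states along positive
    transition probabilities.
    """
    P = chain.transition
    n = chain.n_states
    reaches = chain.absorbing_flags.copy()
    queue = deque(chain.absorbing_indices.tolist())
    # predecessors[j] = states with positive probability into j
    positive = P > 0
    while queue:
        j = queue.popleft()
        for i in np.flatnonzero(positive[:, j]):
            if not reaches[i]:
                reaches[i] = True
                queue.append(i)
    return [i for i in range(n) if not reaches[i]]


@dataclass(frozen=True)
class CanonicalForm:
    """The ``[[Q, R], [0, I]]`` partition of an absorbing chain.

    ``Q`` holds transient-to-transient and ``R`` transient-to-absorbing
    probabilities, both in the original relative state order;
    ``transient_index`` / ``absorbing_index`` map block rows/columns back to
    positions in the source chain, and ``transient_names`` /
    ``absorbing_names`` carry the labels.
    """

    Q: np.ndarray
    R: np.ndarray
    transient_index: tuple[int, ...]
    absorbing_index: tuple[int, ...]
    transient_names: tuple[str, ...] = field(default=())
    absorbing_names: tuple[str, ...] = field(default=())

    @property
    def n_transient(self) -> int:
        return self.Q.shape[0]

    @property
    def n_absorbing(self) -> int:
        return len(self.absorbing_index)

    def reassemble(self) -> np.ndarray:
        """Rebuild the full permuted matrix ``[[Q, R], [0, I]]``."""
        t, a = self.n_transient, self.n_absorbing
        out = np.zeros((t + a, t + a))
        out[:t, :t] = self.Q
        out[:t, t:] = self.R
        out[t:, t:] = np.eye(a)
        return out


def canonical_decompose(chain: AbsorbingChain) -> CanonicalForm:
    """Partition a valid chain into its canonical Q/R blocks.

    Transient and absorbing states each keep their original relative order, so
    the permutation is fully determined by the index tuples reported on the
    result.  A chain with zero transient states yields empty blocks.
    """
    chain.require_valid()
    t_idx = chain.transient_indices
    a_idx = chain.absorbing_indices
    P = chain.transition
    Q = P[np.ix_(t_idx, t_idx)]
    R = P[np.ix_(t_idx, a_idx)]
    return CanonicalForm(
        Q=Q,
        R=R,
        transient_index=tuple(int(i) for i in t_idx),
        absorbing_index=tuple(int(i) for i in a_idx),
        transient_names=tuple(chain.state_names[i] for i in t_idx),
        absorbing_names=tuple(chain.state_names[i] for i in a_idx),
    )


@dataclass(frozen=True)
class AbsorptionResult:
    """Fundamental and absorption matrices of an absorbing chain.

    ``fundamental[i, j]`` is the expected number of visits to transient state
    ``j`` starting from transient state ``i`` before absorption (the start
    state counts as one visit, so the diagonal is >= 1).  ``absorption[i, k]``
    is the probability of eventually being absorbed in absorbing state ``k``;
    each row sums to 1.  ``expected_steps`` are the row sums of the
    fundamental matrix.
    """

    fundamental: np.ndarray
    absorption: np.ndarray
    expected_steps: np.ndarray
    transient_names: tuple[str, ...]
    absorbing_names: tuple[str, ...]

    def absorption_probability(self, start: str, end: str) -> float:
        return float(
            self.absorption[self.transient_names.index(start), self.absorbing_names.index(end)]
        )

    def expected_visits(self, start: str, visited: str) -> float:
        return float(
            self.fundamental[self.transient_names.index(start), self.transient_names.index(visited)]
        )


def solve_absorption(canon: CanonicalForm) -> AbsorptionResult:
    """Solve ``(I - Q) N = I`` and ``(I - Q) B = R`` by LU factorization.

    Raises
    ------
    NoAbsorptionError
        If ``I - Q`` is singular, i.e. some transient class never reaches an
        absorbing state; the offending states are named.
    """
    t = canon.n_transient
    if t == 0:
        empty = np.zeros((0, 0))
        return AbsorptionResult(
            fundamental=empty,
            absorption=np.zeros((0, canon.n_absorbing)),
            expected_steps=np.zeros(0),
            transient_names=canon.transient_names,
            absorbing_names=canon.absorbing_names,
        )
    A = np.eye(t) - canon.Q
    try:
        with warnings.catch_warnings():
            # singularity is handled explicitly below; silence scipy's advisory
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            lu, piv = scipy.linalg.lu_factor(A)
    except scipy.linalg.LinAlgError:
        raise NoAbsorptionError(_trapped_names(canon)) from None
    # lu_factor does not signal exact singularity for all inputs; a zero on
    # the U diagonal does.
    if np.any(np.abs(np.diag(lu)) < 1e-300):
        raise NoAbsorptionError(_trapped_names(canon))
    N = scipy.linalg.lu_solve((lu, piv), np.eye(t))
    B = scipy.linalg.lu_solve((lu, piv), canon.R)
    return AbsorptionResult(
        fundamental=N,
        absorption=B,
        expected_steps=N.sum(axis=1),
        transient_names=canon.transient_names,
        absorbing_names=canon.absorbing_names,
    )


def _trapped_names(canon: CanonicalForm) -> list[str]:
    """Name transient states with no path to absorption within the blocks."""
    t, a = canon.n_transient, canon.n_absorbing
    positive_Q = canon.Q > 0
    reaches = canon.R.sum(axis=1) > 0
    queue = deque(np.flatnonzero(reaches).tolist())
    while queue:
        j = queue.popleft()
        for i in np.flatnonzero(positive_Q[:, j]):
            if not reaches[i]:
                reaches[i] = True
                queue.append(i)
    names = canon.transient_names or tuple(str(i) for i in range(t))
    trapped = [names[i] for i in range(t) if not reaches[i]]
    return trapped or list(names)


def analyze_chain(chain: AbsorbingChain) -> AbsorptionResult:
    """Convenience composition: validate, decompose and solve in one call."""
    return solve_absorption(canonical_decompose(chain))
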