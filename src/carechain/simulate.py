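"""Monte Carlo cohort simulation and random-chain generation.

The cohort walker is the package's independent empirical counterpart of the
analytic absorption quantities: ``n`` individuals start in the same state and
take categorical steps under the transition matrix until absorbed, and the
empirical absorption fractions, mean visit counts and mean steps estimate the
rows of B and N.  The walker is fully vectorized over individuals and driven
by an explicitly seeded ``numpy.random.Generator`` (PCG64), so identical
inputs reproduce identical output on any platform.

``random_absorbing_chain`` draws row-stochastic matrices from the flat
Dirichlet distribution over the simplex and mixes in a guaranteed floor of
direct absorption mass, which bounds the spectral radius of Q away from 1;
it is the fixture generator for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain_core import AbsorbingChain

__all__ = ["CohortRun", "simulate_cohort", "random_absorbing_chain"]


@dataclass(frozen=True)
class CohortRun:
    """Outcome of a seeded cohort walk over an absorbing chain.

    ``absorption_counts`` maps each absorbing state to the number of walkers
    it absorbed (summing to ``n_walkers`` minus any capped walkers);
    ``mean_visits`` maps each transient state to the average number of visits
    before absorption (the start state counts its initial visit);
    ``capped_walkers`` counts those still unabsorbed at ``max_steps`` — they
    are reported, never silently attributed to an outcome.
    """

    n_walkers: int
    seed: int
    start_state: str
    absorption_counts: dict[str, int]
    mean_visits: dict[str, float]
    mean_steps: float
    capped_walkers: int

    @property
    def absorption_fractions(self) -> dict[str, float]:
        return {k: v / self.n_walkers for k, v in self.absorption_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-state summary (deterministic ordering)."""
        rows = [
            {"state": k, "kind": "absorbing", "absorbed_fraction": v, "mean_visits": np.nan}
            for k, v in self.absorption_fractions.items()
        ] + [
            {"state": k, "kind": "transient", "absorbed_fraction": np.nan, "mean_visits": v}
            for k, v in self.mean_visits.items()
        ]
        return pd.DataFrame(rows, columns=["state", "kind", "absorbed_fraction", "mean_visits"])


def simulate_cohort(
    chain: AbsorbingChain,
    start: str,
    n: int,
    seed: int,
    max_steps: int = 10**6,
) -> CohortRun:
    """Walk ``n`` individuals from ``start`` until absorption.

    Each step is one categorical draw per active walker from the walker's
    current row of the transition matrix (inverse-CDF sampling against the
    row's cumulative probabilities).  Identical ``(chain, start, n, seed)``
    reproduce identical output.  An absorbing start returns a degenerate run
    of zero steps.
    """
    if n < 1:
        raise ValueError(f"need at least one walker, got n={n}")
    chain.require_valid()
    start_idx = chain.index_of(start)

    t_idx = chain.transient_indices
    a_idx = chain.absorbing_indices
    names = chain.state_names
    visit_counts = np.zeros(chain.n_states, dtype=np.int64)
    absorbed_counts = np.zeros(chain.n_states, dtype=np.int64)

    if chain.absorbing_flags[start_idx]:
        return CohortRun(
            n_walkers=n,
            seed=seed,
            start_state=start,
            absorption_counts={names[i]: (n if i == start_idx else 0) for i in a_idx},
            mean_visits={names[i]: 0.0 for i in t_idx},
            mean_steps=0.0,
            capped_walkers=0,
        )

    rng = np.random.default_rng(seed)
    cum = np.cumsum(chain.transition, axis=1)
    # guard against round-off: the last positive column must catch u -> 1
    cum[:, -1] = 1.0

    state = np.full(n, start_idx, dtype=np.int64)
    total_steps = 0
    for step in range(max_steps):
        if state.size == 0:
            break
        np.add.at(visit_counts, state, 1)
        u = rng.random(state.size)
        state = (u[:, None] > cum[state]).sum(axis=1)
        total_steps += state.size
        newly_absorbed = chain.absorbing_flags[state]
        if newly_absorbed.any():
            np.add.at(absorbed_counts, state[newly_absorbed], 1)
            state = state[~newly_absorbed]
    capped = int(state.size)

    return CohortRun(
        n_walkers=n,
        seed=seed,
        start_state=start,
        absorption_counts={names[i]: int(absorbed_counts[i]) for i in a_idx},
        mean_visits={names[i]: float(visit_counts[i]) / n for i in t_idx},
        mean_steps=total_steps / n,
        capped_walkers=capped,
    )


def random_absorbing_chain(
    n_transient: int,
    n_absorbing: int,
    seed: int,
    min_exit: float = 0.01,
) -> AbsorbingChain:
    """Draw a random valid absorbing chain for property testing.

    Transient rows are flat-Dirichlet draws over all states mixed with a
    ``min_exit`` floor of probability spread uniformly over the absorbing
    states, so every transient state has at least ``min_exit`` direct
    absorption probability; the spectral radius of Q is then at most
    ``1 - min_exit < 1`` and absorption is certain.  Identical arguments
    reproduce identical chains.
    """
    if n_transient < 1 or n_absorbing < 1:
        raise ValueError("need at least one transient and one absorbing state")
    if not 0.0 < min_exit <= 1.0:
        raise ValueError(f"min_exit must be in (0, 1], got {min_exit}")

    rng = np.random.default_rng(seed)
    s = n_transient + n_absorbing
    names = tuple(f"T{i}" for i in range(n_transient)) + tuple(
        f"A{i}" for i in range(n_absorbing)
    )
    flags = np.array([False] * n_transient + [True] * n_absorbing)

    P = np.zeros((s, s))
    raw = rng.dirichlet(np.ones(s), size=n_transient)
    floor = np.zeros(s)
    floor[n_transient:] = min_exit / n_absorbing
    P[:n_transient] = (1.0 - min_exit) * raw + floor
    P[n_transient:, n_transient:] = np.eye(n_absorbing)
    return AbsorbingChain(names, P, flags).require_valid()
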