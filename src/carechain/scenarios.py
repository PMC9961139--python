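"""Intervention scenarios on the AMI care-continuum chain.

Two levers are modelled, each as an absolute percentage-point shift of
transition probability:

* **awareness** — shrinking the non-seeking share, which moves mass in the
  recognize row from inaction/self-management into help-seeking (raises p12);
* **access** — moving mass in the seek-help row from bouncing back to the
  start (p21) into receiving professional care (p23).

The **combined** scenario applies both shifts; they touch disjoint rows, so
the composition commutes.  For each delta the scenario chain is solved for
the suicide absorption probability from the recognize state, reported in
percent alongside the reduction versus the baseline and versus the previous
scenario on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ami_model import (
    AmiChainConfig,
    LiteratureEvidence,
    RECOGNIZE,
    SUICIDE,
    ami_suicide_probability,
    build_current_state,
    derive_row1,
)
from .chain_core import AbsorbingChain

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "InfeasibleScenarioError",
    "apply_awareness",
    "apply_access",
    "apply_combined",
    "run_experiment",
    "extrapolate_population",
    "diminishing_returns",
    "PUBLISHED_AWARENESS_ROWS",
]

MODES = ("awareness", "access", "combined")

#: Awareness rows exactly as printed in the published scenario table
#: (delta -> (p11, p12, p14)), for audit only: the 12% row is internally
#: inconsistent with the redistribution rule and with its own row sum logic
#: (0.676 where the rule gives 0.656); see ``apply_awareness(verbatim=True)``.
PUBLISHED_AWARENESS_ROWS: dict[float, tuple[float, float, float]] = {
    0.00: (0.3200, 0.5360, 0.1300),
    0.04: (0.2911, 0.5760, 0.1189),
    0.08: (0.2627, 0.6160, 0.1073),
    0.12: (0.2201, 0.6760, 0.0899),
}


class InfeasibleScenarioError(ValueError):
    """An intervention delta exceeds the probability mass available to shift."""


@dataclass(frozen=True)
class ScenarioSpec:
    """An intervention mode plus a grid of deltas (absolute probability units).

    For ``combined``, each listed delta is applied in full to *both* factors
    (a grid entry of 0.02 means awareness and access each rise by 2 points).
    """

    mode: str
    deltas: tuple[float, ...]

    def __init__(self, mode: str, deltas):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        deltas = tuple(float(d) for d in deltas)
        if any(d <= 0 for d in deltas):
            raise ValueError("deltas must be strictly positive")
        if list(deltas) != sorted(deltas):
            raise ValueError("deltas must be sorted ascending")
        object.__setattr__(self, "mode", mode)
        object.__setattr__(self, "deltas", deltas)


def apply_awareness(
    evidence: LiteratureEvidence | None = None,
    delta: float = 0.0,
    config: AmiChainConfig | None = None,
    verbatim: bool = False,
) -> AbsorbingChain:
    """Raise help-seeking by ``delta`` via the non-seeking redistribution rule.

    The non-seeking share drops to ``nonseek_share - delta`` and the recognize
    row is re-derived: ``p14' = selfmanage_share * nonseek'``,
    ``p11' = nonseek' - p14'``, ``p12' = 1 - nonseek' - p15``; other rows are
    untouched.  ``delta = 0`` returns the current-state chain unchanged
    (including its published rounding).

    With ``verbatim=True`` the row is instead copied from the published
    scenario table (only defined on the 0/4/8/12-point grid with default
    evidence); note the published 12-point row disagrees with the rule and is
    reproduced here for audit only.
    """
    evidence = evidence or LiteratureEvidence()
    config = config or AmiChainConfig()
    if delta >= evidence.nonseek_share:
        raise InfeasibleScenarioError(
            f"awareness delta {delta} >= non-seeking share {evidence.nonseek_share}"
        )
    if delta < 0:
        raise InfeasibleScenarioError(f"awareness delta {delta} is negative")

    base = build_current_state(evidence, config)
    if verbatim:
        key = round(delta, 6)
        row = {round(k, 6): v for k, v in PUBLISHED_AWARENESS_ROWS.items()}.get(key)
        if row is None:
            raise ValueError(
                f"verbatim awareness rows are only published for deltas "
                f"{sorted(PUBLISHED_AWARENESS_ROWS)}, got {delta}"
            )
        p11, p12, p14 = row
    elif delta == 0:
        return base
    else:
        nonseek = evidence.nonseek_share - delta
        p14 = evidence.selfmanage_share * nonseek
        p11 = nonseek - p14
        p12 = 1.0 - nonseek - evidence.baseline_suicide

    P = base.transition.copy()
    P[0] = [p11, p12, 0.0, p14, evidence.baseline_suicide, 0.0]
    return AbsorbingChain(base.state_names, P, base.absorbing_flags).require_valid()


def apply_access(
    evidence: LiteratureEvidence | None = None,
    delta: float = 0.0,
    config: AmiChainConfig | None = None,
) -> AbsorbingChain:
    """Shift ``delta`` of seek-row mass from bouncing back (p21) into care (p23)."""
    evidence = evidence or LiteratureEvidence()
    config = config or AmiChainConfig()
    base = build_current_state(evidence, config)
    p21 = base.transition[1, 0]
    if delta > p21 + 1e-12:
        raise InfeasibleScenarioError(
            f"access delta {delta} exceeds the baseline bounce-back probability p21 = {p21:.6g}"
        )
    if delta < 0:
        raise InfeasibleScenarioError(f"access delta {delta} is negative")
    P = base.transition.copy()
    P[1, 0] = max(p21 - delta, 0.0)
    P[1, 2] = P[1, 2] + delta
    return AbsorbingChain(base.state_names, P, base.absorbing_flags).require_valid()


def apply_combined(
    evidence: LiteratureEvidence | None = None,
    delta_each: float = 0.0,
    config: AmiChainConfig | None = None,
) -> AbsorbingChain:
    """Apply awareness and access shifts of ``delta_each`` simultaneously.

    The two shifts edit disjoint rows, so composition order is immaterial;
    commutativity is asserted rather than assumed.
    """
    evidence = evidence or LiteratureEvidence()
    config = config or AmiChainConfig()
    aware_first = _overlay_access(apply_awareness(evidence, delta_each, config), evidence, delta_each)
    access_first = _overlay_awareness(apply_access(evidence, delta_each, config), evidence, delta_each)
    assert np.allclose(aware_first.transition, access_first.transition, atol=1e-15), (
        "awareness and access edits unexpectedly interact"
    )
    return aware_first.require_valid()


def _overlay_access(chain: AbsorbingChain, evidence: LiteratureEvidence, delta: float) -> AbsorbingChain:
    P = chain.transition.copy()
    if delta > P[1, 0] + 1e-12:
        raise InfeasibleScenarioError(
            f"access delta {delta} exceeds the bounce-back probability p21 = {P[1, 0]:.6g}"
        )
    P[1, 0] = max(P[1, 0] - delta, 0.0)
    P[1, 2] += delta
    return AbsorbingChain(chain.state_names, P, chain.absorbing_flags)


def _overlay_awareness(chain: AbsorbingChain, evidence: LiteratureEvidence, delta: float) -> AbsorbingChain:
    if delta == 0:
        return chain
    P = chain.transition.copy()
    nonseek = evidence.nonseek_share - delta
    p14 = evidence.selfmanage_share * nonseek
    P[0] = [nonseek - p14, 1.0 - nonseek - evidence.baseline_suicide, 0.0, p14,
            evidence.baseline_suicide, 0.0]
    return AbsorbingChain(chain.state_names, P, chain.absorbing_flags)


@dataclass(frozen=True)
class ScenarioResult:
    """Suicide absorption probabilities over a delta grid, with reductions.

    ``table`` has one row per grid point (the baseline delta-0 row first) and
    columns ``delta_pct``, ``suicide_probability_pct``,
    ``reduction_vs_baseline_pct`` and ``reduction_vs_previous_pct``, all in
    percent at full precision (rounding to the published 4 decimals happens
    only when writing files).
    """

    mode: str
    baseline_pct: float
    table: pd.DataFrame = field(repr=False)

    @property
    def suicide_pct(self) -> np.ndarray:
        """Per-delta suicide probabilities (%), excluding the baseline row."""
        return self.table["suicide_probability_pct"].to_numpy()[1:]

    @property
    def reductions_pct(self) -> np.ndarray:
        """Per-delta reduction vs baseline (percentage points)."""
        return self.table["reduction_vs_baseline_pct"].to_numpy()[1:]

    @property
    def increments_pct(self) -> np.ndarray:
        """Per-delta reduction vs the previous grid point (percentage points)."""
        return self.table["reduction_vs_previous_pct"].to_numpy()[1:]


def scenario_chain(
    mode: str,
    delta: float,
    evidence: LiteratureEvidence | None = None,
    config: AmiChainConfig | None = None,
) -> AbsorbingChain:
    """Build the chain for one intervention mode at one delta."""
    if mode == "awareness":
        return apply_awareness(evidence, delta, config)
    if mode == "access":
        return apply_access(evidence, delta, config)
    if mode == "combined":
        return apply_combined(evidence, delta, config)
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def run_experiment(
    spec: ScenarioSpec,
    evidence: LiteratureEvidence | None = None,
    config: AmiChainConfig | None = None,
) -> ScenarioResult:
    """Solve the suicide absorption probability across a scenario grid.

    The baseline (delta 0) row is always included; reductions are recomputed
    from the probability column, so the increments telescope exactly to the
    total reduction.
    """
    evidence = evidence or LiteratureEvidence()
    config = config or AmiChainConfig()

    baseline_pct = 100.0 * ami_suicide_probability(build_current_state(evidence, config))
    deltas = [0.0, *spec.deltas]
    probs = [baseline_pct]
    for d in spec.deltas:
        try:
            chain = scenario_chain(spec.mode, d, evidence, config)
        except InfeasibleScenarioError as err:
            raise InfeasibleScenarioError(f"delta {d:g} ({spec.mode}): {err}") from err
        probs.append(100.0 * ami_suicide_probability(chain))

    probs_arr = np.asarray(probs)
    table = pd.DataFrame(
        {
            "delta_pct": [100.0 * d for d in deltas],
            "suicide_probability_pct": probs_arr,
            "reduction_vs_baseline_pct": baseline_pct - probs_arr,
            "reduction_vs_previous_pct": np.concatenate([[0.0], -np.diff(probs_arr)]),
        }
    )
    return ScenarioResult(mode=spec.mode, baseline_pct=baseline_pct, table=table)


def extrapolate_population(reduction_pct_points: float, population: float) -> float:
    """Convert a suicide-rate reduction (percentage points) into persons spared.

    ``population * reduction / 100`` — e.g. a 0.4728-point reduction over the
    one billion people living with AMI worldwide is about 4.73 million
    prevented suicides.
    """
    if reduction_pct_points < 0:
        raise ValueError(f"reduction must be non-negative, got {reduction_pct_points}")
    if population < 0:
        raise ValueError(f"population must be non-negative, got {population}")
    return population * reduction_pct_points / 100.0


def diminishing_returns(result: ScenarioResult, rel_tol: float = 1e-9) -> tuple[bool, np.ndarray]:
    """Is each successive equal-sized increment buying less reduction?

    Returns the incremental-reduction series and whether it is strictly
    decreasing.  Requires at least two deltas on an equally spaced grid —
    comparing increments of unequal width is not meaningful.
    """
    deltas = result.table["delta_pct"].to_numpy()[1:]
    if len(deltas) < 2:
        raise ValueError("need at least two deltas to assess diminishing returns")
    spacing = np.diff(np.concatenate([[0.0], deltas]))
    if not np.allclose(spacing, spacing[0], rtol=rel_tol, atol=1e-12):
        raise ValueError(f"delta grid is not equally spaced: spacings {spacing}")
    increments = result.increments_pct
    return bool(np.all(np.diff(increments) < 0)), increments
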