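"""Six-state care-continuum chain for any mental illness (AMI).

The chain follows an individual from recognizing a mental-health problem
through the decision to seek professional help, receiving (or failing to
receive) care, or self-managing, to one of two absorbing outcomes: recovery
("get better") or death by suicide.  States, in order:

1. Recognize AMI          (transient)
2. Seek professional help (transient)
3. Professional help      (transient)
4. Do something beneficial(transient)
5. Commit suicide         (absorbing)
6. Get better             (absorbing)

Transition probabilities are derived from a handful of published scalar
statistics (help-seeking gap, self-management preference, access barriers,
access success, treatment effectiveness, per-state suicide probability); the
rows with no direct literature support (ineffective treatment and
self-management outcomes) are completed by equal splits, with the
return-to-start probability after ineffective treatment exposed as a
one-dimensional calibration knob against the overall AMI suicide rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .chain_core import AbsorbingChain, analyze_chain

__all__ = [
    "STATE_NAMES",
    "RECOGNIZE",
    "SEEK",
    "PROFESSIONAL",
    "BENEFICIAL",
    "SUICIDE",
    "BETTER",
    "LiteratureEvidence",
    "AmiChainConfig",
    "DerivationError",
    "LayoutError",
    "CalibrationResult",
    "CalibrationWarning",
    "build_current_state",
    "seek_and_receive_rate",
    "calibrate_row3_return",
    "ami_suicide_probability",
]

RECOGNIZE = "Recognize AMI"
SEEK = "Seek professional help"
PROFESSIONAL = "Professional help"
BENEFICIAL = "Do something beneficial"
SUICIDE = "Commit suicide"
BETTER = "Get better"

STATE_NAMES: tuple[str, ...] = (RECOGNIZE, SEEK, PROFESSIONAL, BENEFICIAL, SUICIDE, BETTER)
ABSORBING_FLAGS = (False, False, False, False, True, True)


class DerivationError(ValueError):
    """A derived transition probability is out of range or a row fails its sum check."""


class LayoutError(ValueError):
    """A chain does not have the 6-state AMI layout an operation requires."""


class CalibrationWarning(UserWarning):
    """Calibration target unattainable; nearest feasible endpoint returned."""


@dataclass(frozen=True)
class LiteratureEvidence:
    """Published scalar statistics the current-state matrix is derived from.

    All fields are probabilities in [0, 1].

    nonseek_share : fraction of persons with AMI who do not seek professional
        help (default 0.45).
    selfmanage_share : fraction of the non-seekers who prefer to manage on
        their own (default 0.29).
    access_barrier_share : fraction of those not receiving help who cite
        affordability or access (default 0.275).
    access_success : probability that a help-seeker actually receives
        professional care (default 0.862).
    treatment_effectiveness : probability professional help leads to recovery
        (default 0.80).
    baseline_suicide : per-state, per-step suicide probability (default 0.014,
        the general-population rate).
    target_ami_suicide : overall suicide probability among persons with AMI,
        used as the calibration target (default 0.065).
    """

    nonseek_share: float = 0.45
    selfmanage_share: float = 0.29
    access_barrier_share: float = 0.275
    access_success: float = 0.862
    treatment_effectiveness: float = 0.80
    baseline_suicide: float = 0.014
    target_ami_suicide: float = 0.065

    def __post_init__(self):
        for name, value in vars(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} outside [0, 1]")
        if self.nonseek_share * self.selfmanage_share + self.baseline_suicide >= 1.0:
            raise ValueError(
                "self-management share of non-seekers plus suicide probability "
                "leaves no mass for help-seeking"
            )


@dataclass(frozen=True)
class AmiChainConfig:
    """Choices for the rows the literature leaves under-determined.

    row3_return : probability of returning to the recognize state after
        ineffective professional treatment (default 0.100); must leave room
        for treatment effectiveness and the suicide probability.
    row4_split_mode : how the self-management row's non-suicide mass 0.986 is
        divided among return/stay/recover — ``"exact-thirds"`` (default,
        0.986/3 each) or ``"published-rounded"`` (0.329, 0.329, 0.328 with the
        0.328 residual on recovery, as sometimes printed in rounded tables).
    rounding : ``"published"`` (default) reproduces the published rounded
        derivation (p14 at 2 decimals, p21 at 3 decimals — the published row
        sums only close under this rounding); ``"exact"`` keeps the raw
        products for sensitivity checks.
    """

    row3_return: float = 0.100
    row4_split_mode: str = "exact-thirds"
    rounding: str = "published"

    def __post_init__(self):
        if self.row4_split_mode not in ("exact-thirds", "published-rounded"):
            raise ValueError(f"unknown row4_split_mode {self.row4_split_mode!r}")
        if self.rounding not in ("published", "exact"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        if not 0.0 <= self.row3_return <= 1.0:
            raise ValueError(f"row3_return = {self.row3_return} outside [0, 1]")


def row3_return_bounds(evidence: LiteratureEvidence) -> tuple[float, float]:
    """Feasible interval for the return-to-start probability after ineffective care."""
    return 0.0, 1.0 - evidence.treatment_effectiveness - evidence.baseline_suicide


def derive_row1(evidence: LiteratureEvidence, rounding: str = "published") -> dict[str, float]:
    """Recognize-AMI row: split the non-seeking share, remainder seeks help."""
    p14 = evidence.selfmanage_share * evidence.nonseek_share
    if rounding == "published":
        p14 = round(p14, 2)
    p11 = evidence.nonseek_share - p14
    p15 = evidence.baseline_suicide
    p12 = 1.0 - p11 - p14 - p15
    return {"p11": p11, "p12": p12, "p14": p14, "p15": p15}


def derive_row2(evidence: LiteratureEvidence, rounding: str = "published") -> dict[str, float]:
    """Seek-help row: access barrier bounces back to the start, success proceeds."""
    p21 = evidence.access_barrier_share * evidence.nonseek_share
    if rounding == "published":
        p21 = round(p21, 3)
    return {"p21": p21, "p23": evidence.access_success, "p25": evidence.baseline_suicide}


def build_current_state(
    evidence: LiteratureEvidence | None = None,
    config: AmiChainConfig | None = None,
) -> AbsorbingChain:
    """Assemble the 6-state current-state chain from the literature evidence.

    Row derivation (states indexed 1..6 as in :data:`STATE_NAMES`):

    * Row 1: ``p14 = selfmanage_share * nonseek_share`` (rounded per config),
      ``p11 = nonseek_share - p14``, ``p15 = baseline_suicide``, and the
      remainder ``p12 = 1 - p11 - p14 - p15`` seeks help.
    * Row 2: ``p21 = access_barrier_share * nonseek_share`` (rounded per
      config), ``p23 = access_success``, ``p25 = baseline_suicide``.  The
      row-sum identity ``p21 + p23 + p25 = 1`` is asserted, not repaired:
      evidence combinations that break it fail loudly.
    * Row 3: ``p31 = row3_return``, ``p36 = treatment_effectiveness``,
      ``p35 = baseline_suicide``, remainder split equally between staying in
      care and switching to self-management.
    * Row 4: ``p45 = baseline_suicide``; the remaining 0.986 split equally
      among return/stay/recover (or the rounded 0.329/0.329/0.328 variant).

    Raises
    ------
    DerivationError
        If any derived entry falls outside [0, 1] or a row fails its sum
        check; the offending row is named.
    """
    evidence = evidence or LiteratureEvidence()
    config = config or AmiChainConfig()

    r1 = derive_row1(evidence, config.rounding)
    row1 = [r1["p11"], r1["p12"], 0.0, r1["p14"], r1["p15"], 0.0]

    r2 = derive_row2(evidence, config.rounding)
    row2 = [r2["p21"], 0.0, r2["p23"], 0.0, r2["p25"], 0.0]
    if abs(sum(row2) - 1.0) > 1e-9:
        raise DerivationError(
            f"row 2 ({SEEK!r}) sums to {sum(row2):.12g}, not 1: the access statistics "
            "(p21 + p23 + p25) are mutually inconsistent"
        )

    p31 = config.row3_return
    p35 = evidence.baseline_suicide
    p36 = evidence.treatment_effectiveness
    residual3 = 1.0 - p31 - p35 - p36
    if residual3 < -1e-12:
        raise DerivationError(
            f"row 3 ({PROFESSIONAL!r}): row3_return={p31} exceeds the mass left by "
            f"treatment effectiveness and suicide probability ({1 - p35 - p36:.6g})"
        )
    p33 = p34 = max(residual3, 0.0) / 2.0
    row3 = [p31, 0.0, p33, p34, p35, p36]

    p45 = evidence.baseline_suicide
    if config.row4_split_mode == "exact-thirds":
        q = (1.0 - p45) / 3.0
        row4 = [q, 0.0, 0.0, q, p45, q]
    else:  # published-rounded: two at 0.329, residual on recovery
        hi = round((1.0 - p45) / 3.0, 3)
        lo = 1.0 - p45 - 2 * hi
        row4 = [hi, 0.0, 0.0, hi, p45, lo]

    rows = {1: row1, 2: row2, 3: row3, 4: row4}
    for idx, row in rows.items():
        for j, p in enumerate(row):
            if not -1e-12 <= p <= 1 + 1e-12:
                raise DerivationError(
                    f"row {idx} ({STATE_NAMES[idx - 1]!r}): derived p{idx}{j + 1} = {p:.6g} "
                    "outside [0, 1]"
                )
        if abs(sum(row) - 1.0) > 1e-9:
            raise DerivationError(
                f"row {idx} ({STATE_NAMES[idx - 1]!r}) sums to {sum(row):.12g}, not 1"
            )

    P = [
        row1,
        row2,
        row3,
        row4,
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    ]
    return AbsorbingChain(STATE_NAMES, P, ABSORBING_FLAGS).require_valid()


def require_ami_layout(chain: AbsorbingChain) -> AbsorbingChain:
    """Check the 6-state layout with the two terminal outcomes absorbing."""
    if chain.state_names != STATE_NAMES or tuple(chain.absorbing_flags) != ABSORBING_FLAGS:
        raise LayoutError(
            "chain does not have the 6-state AMI care-continuum layout "
            f"(expected states {STATE_NAMES})"
        )
    return chain


def seek_and_receive_rate(chain: AbsorbingChain) -> float:
    """One-pass probability of seeking and then receiving professional care.

    ``p12 * p23``: the product published as the share of adults with AMI who
    received mental health services (46.2% at the default evidence).
    """
    require_ami_layout(chain)
    P = chain.transition
    return float(P[0, 1] * P[1, 2])


def ami_suicide_probability(chain: AbsorbingChain) -> float:
    """Probability that a person recognizing AMI is eventually absorbed in suicide."""
    require_ami_layout(chain)
    return analyze_chain(chain).absorption_probability(RECOGNIZE, SUICIDE)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of calibrating the ineffective-treatment return probability."""

    row3_return: float
    achieved_rate: float
    gap: float
    config: AmiChainConfig
    chain: AbsorbingChain
    at_boundary: bool


def calibrate_row3_return(
    evidence: LiteratureEvidence | None = None,
    config: AmiChainConfig | None = None,
    target: float | None = None,
    tol: float = 1e-10,
) -> CalibrationResult:
    """Tune the return-to-start probability to hit the overall AMI suicide rate.

    All other derivation rules are held fixed; the suicide absorption
    probability from the recognize state is monotone increasing in
    ``row3_return`` (every return re-exposes the individual to per-state
    suicide risk), which is verified by bracketing before bisection
    (:func:`scipy.optimize.brentq`).

    If the target lies outside the attainable range, the nearest endpoint is
    returned with ``at_boundary=True`` and a :class:`CalibrationWarning` —
    never a silent success.
    """
    import scipy.optimize

    evidence = evidence or LiteratureEvidence()
    config = config or AmiChainConfig()
    if target is None:
        target = evidence.target_ami_suicide

    lo, hi = row3_return_bounds(evidence)

    def rate_at(r: float) -> float:
        return ami_suicide_probability(build_current_state(evidence, replace(config, row3_return=r)))

    f_lo, f_hi = rate_at(lo), rate_at(hi)
    if not f_lo <= f_hi:
        raise RuntimeError(
            f"suicide rate not increasing over row3_return in [{lo}, {hi}]: "
            f"f({lo})={f_lo}, f({hi})={f_hi}"
        )

    if target <= f_lo or target >= f_hi:
        r_star = lo if abs(target - f_lo) <= abs(target - f_hi) else hi
        achieved = f_lo if r_star == lo else f_hi
        warnings.warn(
            f"target suicide rate {target:.4g} outside attainable range "
            f"[{f_lo:.4g}, {f_hi:.4g}]; returning endpoint row3_return={r_star:.4g}",
            CalibrationWarning,
            stacklevel=2,
        )
    else:
        r_star = float(scipy.optimize.brentq(lambda r: rate_at(r) - target, lo, hi, xtol=tol))
        achieved = rate_at(r_star)

    best_config = replace(config, row3_return=r_star)
    return CalibrationResult(
        row3_return=r_star,
        achieved_rate=achieved,
        gap=abs(achieved - target),
        config=best_config,
        chain=build_current_state(evidence, best_config),
        at_boundary=not (f_lo < target < f_hi),
    )
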