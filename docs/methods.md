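# Methods

## Model

`carechain` models the care continuum for any mental illness (AMI) as a
discrete-time absorbing Markov chain over six states:

| # | State | Kind |
|---|-------|------|
| 1 | Recognize AMI | transient |
| 2 | Seek professional help | transient |
| 3 | Professional help | transient |
| 4 | Do something beneficial (self-management) | transient |
| 5 | Commit suicide | absorbing |
| 6 | Get better | absorbing |

Assumptions inherited from the model's framing: each care episode is
memoryless (the next move depends only on the current state); professional
help and independent beneficial action are mutually exclusive per step;
unsuccessful self-management attempts are not modelled separately — the only
negative exit is the absorbing suicide state; both terminal outcomes are
truly absorbing (no relapse across episodes is modelled).

With the matrix permuted to canonical form `[[Q, R], [0, I]]`, the
fundamental matrix `N = (I − Q)⁻¹` holds expected visit counts among
transient states and `B = N R` the absorption probabilities. The package
computes both from one LU factorization of `I − Q` (`scipy.linalg.lu_factor`
/ `lu_solve`); the inverse notation is mathematical shorthand, not an
implementation. Expected steps to absorption are the row sums of `N`.

## Parameters

All parameters are probabilities (dimensionless, in [0, 1]).

| Parameter | Default | Meaning |
|-----------|---------|---------|
| `nonseek_share` | 0.45 | persons with AMI not seeking professional help |
| `selfmanage_share` | 0.29 | non-seekers preferring self-management |
| `access_barrier_share` | 0.275 | share citing affordability/access barriers |
| `access_success` | 0.862 | a help-seeker actually receives care |
| `treatment_effectiveness` | 0.80 | professional help leads to recovery |
| `baseline_suicide` | 0.014 | per-state, per-step suicide probability |
| `target_ami_suicide` | 0.065 | overall AMI suicide rate (calibration target) |
| `row3_return` | 0.100 | return to start after ineffective treatment |

Row derivation: `p14 = selfmanage_share · nonseek_share` (0.13 after
rounding), `p11 = nonseek_share − p14` (0.32), `p12 = 1 − p11 − p14 − p15`
(0.536); `p21 = access_barrier_share · nonseek_share` (0.124 after
rounding), `p23 = access_success`; row 3 splits its residual equally between
staying in care and switching to self-management (0.043 each at the
defaults); row 4 splits its non-suicide mass 0.986 equally among
return/stay/recover.

### Rounding

The published derivation only closes under specific rounding: `p14` at two
decimals (0.1305 → 0.13) and `p21` at three (0.12375 → 0.124) — the seek row
`0.124 + 0.862 + 0.014 = 1` sums to one *only* with the rounded value. The
default `rounding="published"` reproduces this; `rounding="exact"` keeps raw
products for sensitivity work (and then requires evidence whose seek row
closes exactly, since the builder asserts the row sum rather than silently
renormalizing).

### Self-management row split

Row 4 admits two published readings: exact thirds (0.986/3 ≈ 0.328667 each)
or the rounded triple 0.329/0.329/0.328. The default is **exact thirds**,
because every headline result (baseline 6.3901%, fundamental entry 2.035,
and all scenario columns) reproduces to ≤ 0.001 percentage points under it,
while the rounded variant drifts by ~0.002 pp and its residual assignment is
ambiguous. `row4_split_mode="published-rounded"` (residual on the recovery
column) is kept for sensitivity checks.

### Calibration

Six probabilities (rows 3 and 4) lack direct literature support. Rather than
an unreproducible multi-parameter adjustment, the package fixes the
equal-split structure and exposes a single knob, `row3_return`, searched by
bisection (`scipy.optimize.brentq`) over its feasible interval
`[0, 1 − treatment_effectiveness − baseline_suicide]` against the overall
AMI suicide target. The suicide absorption probability is strictly
increasing in `row3_return` (every return re-exposes the individual to
per-state suicide risk); the bracketing is verified before the search. An
unattainable target returns the nearest endpoint with an explicit warning.
At the defaults, `row3_return = 0.100` yields 6.3907% and calibrating to the
6.5% target gives `row3_return ≈ 0.142`.

## Intervention scenarios

Deltas are absolute percentage-point shifts, not relative multipliers.

* **Awareness** (delta d): the non-seeking share drops to
  `nonseek_share − d` and row 1 is re-derived with exact products
  (`p14' = selfmanage_share · nonseek'`, `p12' = 1 − nonseek' − p15`). At
  d = 0 the current-state chain (with its published rounding) is returned
  unchanged.
* **Access** (delta d): `p23' = p23 + d`, `p21' = p21 − d`; feasible up to
  d = p21 = 0.124.
* **Combined**: both shifts at the same per-factor delta; they edit disjoint
  rows, so the composition commutes (asserted at run time).

The published awareness table's 12-point row (`p12 = 0.676`) contradicts the
redistribution rule (0.656) and its own companion results table, which
matches the rule; the rule is therefore authoritative here, and the printed
rows remain available verbatim through `apply_awareness(..., verbatim=True)`
for audit. Likewise the combined experiment's printed reduction columns
duplicate the access table's and contradict its own probability column, so
all reduction columns are recomputed from the probability column; increments
then telescope to the total reduction by construction.

Reported probabilities are ×100 at four decimals in written tables; internal
computation is full double precision.

## Monte Carlo cohort walker

`simulate_cohort` is the package's independent empirical counterpart of `N`
and `B`: `n` walkers start in one state and take categorical steps
(inverse-CDF draws against each row's cumulative probabilities, vectorized
over walkers) until absorbed or until `max_steps` (default 10⁶; capped
walkers are reported separately, never silently assigned an outcome).
Randomness comes exclusively from a `numpy.random.Generator` (PCG64) seeded
explicitly, so identical inputs give byte-identical outputs across
platforms.

What it emulates: independent individuals walking a homogeneous chain —
exactly the model's own assumptions. What it does not emulate: covariate
heterogeneity, time-varying rates, interacting individuals, or measurement
error in the evidence parameters; agreement between the walker and the
analytic solution therefore validates the *solver*, not the realism of the
transition probabilities themselves.

`random_absorbing_chain` draws transient rows from the flat Dirichlet
distribution and mixes in a `min_exit` floor of direct absorption mass,
bounding the spectral radius of `Q` by `1 − min_exit`; it generates the
fixtures for property tests.

## Numerical choices and problem sizes

* Row-stochasticity tolerance 1e-9; an opt-in `renormalized()` repairs
  matrices transcribed from rounded published tables.
* Absorbing states are declared by flag and cross-checked against the unit
  self-loop, never inferred from near-1 entries.
* Singular `I − Q` (a transient class that can never absorb) raises an error
  naming the trapped states, found by reverse reachability from the
  absorbing set.
* Canonical form preserves the original relative order of transient and of
  absorbing states; index maps are reported with the result.
* Monte Carlo checks use 10⁶ walkers (3σ band ≈ 0.07 pp at b ≈ 6.4%) across
  20 seeds with an 18/20 pass requirement — the 3σ criterion itself has a
  nonzero false-alarm rate. Unit tests use 2×10⁵-walker cohorts, enough for
  their wider bands while keeping the default suite fast.
* Fixed-point oracles (iterating `B ← QB + R` and `N ← I + QN` to 1e-14)
  cross-check the linear solves on small chains.

## Limitations

* The evidence parameters are point estimates; no uncertainty propagation is
  attempted (a delta grid is the only sensitivity device).
* The two under-determined rows rest on equal-split assumptions; the
  one-knob calibration makes them reproducible but not validated.
* Absolute-point interventions ignore implementation cost and
  time-to-effect; no discounting, stratification, or attitude modelling.
* Absorbing "get better" means within-episode recovery; lifetime relapse is
  out of scope.
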