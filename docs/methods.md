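# Methods

## The model

A population of `N = k·n` agents is partitioned into `k` groups of equal
size `n`. Each generation has two stages.

**Stage 1 (contribution).** Every agent receives an endowment `e` and
chooses one of three actions: invest in the *public good* (each invested
unit is multiplied by `b_PG` and shared equally over all `N` agents), invest
in the own group's *club good* (multiplied by `b_CG`, shared over the `n`
group members), or keep the endowment. Investing costs `c_c`. The parameter
ranges `b_CG/n < c_c < b_CG` and `b_PG/N < c_c < b_PG` make both options
social dilemmas: individually unprofitable, collectively beneficial. These
inequalities are enforced by `ModelParams` at construction and config load.

**Stage 2 (dyadic helping).** Every agent receives a second endowment and
is assigned a receiver: an in-group member with probability `p` (uniform
among the `n−1` others), otherwise an out-group member (uniform among the
`N−n` outsiders). A donor may pay `c_h` to confer `b_h` on its receiver.
Helping is the enforcement mechanism: strategies couple a stage-1 action
with a helping rule.

The canonical three types are **universalists** U (invest public, help
universal cooperators wherever met), **parochialists** P (invest club, help
in-group parochialists) and **free-riders** F (keep, never help). Expected
per-generation payoffs, writing `n_U` for the population-wide universalist
count and `n_U^i, n_P^i` for counts in group `i`:

    π_F^i = 2e + n_U b_PG/N + n_P^i b_CG/n_i
    π_P^i = π_F-term − c_c + p (n_P^i − 1)/(n_i − 1) · (b_h − c_h)
    π_U^i = π_F-term − c_c + [p (n_U^i − 1)/(n_i − 1)
                              + (1−p)(n_U − n_U^i)/(N − n_i)] · (b_h − c_h)

The bracketed factors are the probabilities of being matched with another
member of the focal helping class; because every agent is a donor once and
is a receiver with the mirror-image probability, cost and benefit combine
into the single net factor `(b_h − c_h)`. The public-good return accrues to
everyone (it is non-excludable), which is why it appears in all three
payoffs. Conventions for degenerate denominators: a vanishing denominator
(`n_i = 1`, or `k = 1` so `N − n_i = 0`) means no partner of that kind
exists and the term is 0. These formulas are validated against an
independent oracle that enumerates every donor's possible receivers
exhaustively (absolute tolerance 1e−9, systems up to `N = 8`).

**Evolution.** Selection is a frequency-dependent Moran process. After each
generation one agent "dies": group `i`, type `j` with probability
`(1/k)(n_ij/n)` (equivalently, uniform over agents when group sizes are
equal). With probability `μ` the replacement type is drawn uniformly at
random from the type space (including the current type, so the effective
mutation rate is `μ(T−1)/T`; a flag switches to excluding it); with
probability `1 − μ` it is drawn by global imitation, type `y` with
probability `Σ_s n_sy e^{π_sy} / Σ_t Σ_s n_st e^{π_st}` evaluated in the
pre-death state (self-imitation is possible). Fitness is exponential,
`e^π`; payoffs are normalized by subtracting the state maximum before
exponentiation, which preserves all ratios and cannot overflow.

## Exact engine

For small systems the full Markov chain is solved exactly. States are the
per-group type counts; for `k` equal groups of `n` with `T` types there are
`C(n+T−1, T−1)^k` states (225 for `n=4, k=2, T=3`; 1,758,276 already for
`N = 100, k = 2`, far above the default enumeration cap of 1e6). The
enumeration order is lexicographic on the flattened `(group, type)` count
vector and is recorded in output manifests.

One Moran event changes at most one agent's type, so each row of the
transition matrix `M` has at most `k·T·(T−1)` off-diagonal entries plus the
diagonal. Rows sum to 1 to within 1e−12 (property-tested over 1000 random
parameter draws). For `μ > 0` the chain is irreducible and aperiodic, so the
stationary law `w` (`wM = w`, the left Perron eigenvector) is unique and
strictly positive. Three backends compute it and must agree to 1e−8:

- `solve` (default): replace one equation of `(Mᵀ − I)w = 0` by the
  normalization `Σw = 1` and solve the linear system;
- `eig`: dense left eigendecomposition, eigenvalue nearest 1 (refuses
  reducible chains, which have a multiple unit eigenvalue);
- `power`: repeated squaring of `M` until all rows coincide.

`μ = 0` is refused with a pointer to absorption analysis: homogeneous states
are then absorbing and the long-run law depends on the initial state.

Summaries are stationary expectations: type proportions `E_w[counts]/N` and
welfare as the mean expected payoff per agent and generation (both stage
endowments included). The canonical sweep crosses
`p ∈ {0.50, 0.51, …, 1.00}` with `b_h ∈ {0, 0.1, …, 9}` — 4641 cells — and
runs in about a minute on one core; construction is vectorized over the
whole state space and the per-cell solve is a single 225×225 LU.

## Closed-form thresholds

- *Cooperation share*: a cooperator type proliferates once the share of its
  helping class among potential partners exceeds `c_c/(b_h − c_h)`. For
  `c_c = c_h = 1` the threshold reaches 1 exactly at `b_h = 2`, so
  cooperation needs `b_h > 2`. When `b_h ≤ c_h` the function returns the
  sentinel `UNATTAINABLE` (`inf`).
- *Parochial invasion*: against a fully universalist other group,
  parochialists win once their share of their own group exceeds
  `(b_h − c_h)/(b_h − c_h + b_CG)` — 50% at `b_h = 3, c_h = 1, b_CG = 2`.
  The condition is stated for a fully universalist opposing group and is not
  extrapolated to mixed ones.
- *Simple majority* (fluid boundaries, `p = 0.5` only): universalists beat
  parochialists when their total number exceeds the parochialist count
  within every group. Exact ties predict no advantage; other `p` values
  return an explicit out-of-scope marker.

Strict inequalities are used throughout ("exceeds").

## Agent-based simulator

The ABM replicates the Moran rules with *realized* interactions: actual
stage-1 earnings from the chosen contributions, one concrete receiver per
donor (receivers may be chosen by several donors independently; no
matching constraint and no "your receiver is not your decider" exclusion,
which is an experimental control, not part of the evolutionary model), and
one Moran event per iteration with imitation weights `e^{payoff}`.

Two engines realize the same stochastic model. The NumPy path supports the
full extended strategy space; the numba-compiled kernel covers the
canonical (U, P, F) space and makes 1e8-iteration time averages and large
sweeps cheap. They are cross-validated statistically (seeded run batteries
must produce the same winning type and mean compositions within 0.15).

**Realized vs. expected fitness.** Whether imitation weights should use
realized or expected payoffs is a genuine modeling fork, and the two are
*not* equivalent: a helped agent's realized payoff jumps by `b_h`, so with
exponential fitness the lucky-receiver effect strengthens selection for
cooperators. At `(b_h = 2.5, p = 1)` the realized-fitness chain spends ~98%
of its time parochialist while the exact (expected-payoff) stationary law
gives P only ~44%. Both modes are implemented; `run_simulation` defaults to
realized payoffs (pairing is explicitly realized per iteration), and
equivalence checks against the exact engine use `expected_fitness=True`,
the mode that shares the exact engine's selection gradient.

**Equivalence with the exact engine.** With mutation on, the three-type ABM
is ergodic and its time-averaged type shares converge to the exact
stationary proportions. The chain is metastable at `μ = 1e−4` — it sits in
near-homogeneous states and switches on the scale of 1e5–1e9 iterations
depending on the cell (measured by the second eigenvalue of `M`) — so the
test battery uses four cells spanning the free-riding, parochial and
universalist regimes whose relaxation times are ≤ ~1e6 iterations
(`(b_h, p)` = (1.5, 1.0), (2.0, 0.5), (3.0, 1.0), (4.0, 0.5)), runs 1.2e8
iterations each, discards the first 25% and compares against the exact
proportions within 3 Monte-Carlo standard errors estimated from 16 batch
means (batch means absorb the heavy autocorrelation). The four marked
corners of the canonical sweep themselves include a cell with a ~6.5e8
iteration relaxation time, which no desk-scale run can average over; regime
coverage, not those exact coordinates, is what the battery checks.

**Runs and sweeps.** A run starts from an i.i.d.-uniform random composition
and stops at homogeneity or at 2000 iterations, in which case the reported
composition is the mean over the last 1000 iterations. The canonical sweep
design crosses two manipulations — group size (`k = 8`,
`n ∈ {4, 8, 16, 32, 64}`) and fragmentation (`N = 128`,
`k ∈ {2, 4, 8, 16, 32}`) — with `p ∈ {0.5, 0.55, …, 1.0}` and
`b_h ∈ {1, 1.2, …, 4}` at 200 runs per cell: 352,000 runs, which is not a
desk-scale computation. The scaled replication in the test suite uses
`p ∈ {0.6, 0.8, 1.0}`, `b_h ∈ {2, 3, 4}` and 20 runs per cell (1800 runs,
~30 s) and checks the trends as rank properties: the mean universalist
share increases strictly with group size and decreases strictly with
fragmentation. Run seeds derive deterministically from
`(base seed, cell index, run index)` via `SeedSequence` spawn keys, so any
cell can be re-run independently.

## Extended strategy space and second-order free-riding

`ExtendedStrategy` couples a contribution action with a helping rule
(`never`, help public contributors, help in-group club contributors, help
any cooperator) and an optional second-order condition on the receiver's
reputation. Named members: nondiscriminating helper (public contributor
who helps any stage-1 cooperator), second-order free-riders of both
contribution kinds (cooperate in stage 1, never help), and "detecting"
variants of both helpers.

Two reputation semantics are implemented:

- `detection="history"`: the factual previous-round helping flag, as a
  participant would observe it. Round-1 reputation is unknown and governed
  by a benefit-of-the-doubt flag (default: treat as having helped). This
  signal is noisy in a specific, consequential way: a helper whose own rule
  did not fire last round (its receiver was not covered) is
  indistinguishable from a second-order free-rider, so strict
  history-conditioning makes conditional helpers sanction *each other* and
  cooperation collapses in the detectable condition too — at these
  population sizes the noise defeats the mechanism.
- `detection="disposition"`: perfect detection of nonhelping *types*
  (receivers whose strategy never helps). This is the clean operationalization
  of helpers detecting second-order free-riders and is what the detectable
  control of the packaged experiment uses.

`second_order_experiment` runs paired conditions sharing seeds. Both spaces
contain {two helper types, pure free-rider, both second-order free-riders};
the undetectable condition uses unconditional helpers, the detectable
control uses detecting helpers with disposition detection. Conditions
chosen once, on power grounds: two groups of eight (`N = 16`; with five
strategies over eight agents, initialization noise dominates selection and
both conditions collapse sporadically), `b_h = 7, p = 0.5`, `μ = 1e−3` so
the invasion sequence — second-order free-riders displacing helpers, then
defectors invading — completes within the 12,000-iteration no-stop horizon,
with the pure free-rider share time-averaged over the second half. Fifty
pairs give a decisive one-sided paired effect (higher free-rider share when
undetectable). With nondiscriminating helpers added to the core space,
cooperative steady states remain dominated by the discriminating helper
types under the same kind of battery.

## What the synthetic conditions do and do not show

All inputs are parameter sets; there is no external data. The generator
conventions (uniform random initial compositions, equal group sizes,
independent receiver draws) match the model definition, so passing tests
validate the implementation against the model's own mathematics and its
printed worked examples — they do not validate the model against behavior
of real groups. Human data aspects (repeated 20-round play, reputation
feedback screens, direct-reciprocity exclusion) are deliberately outside
the evolutionary model.

## Numerical conventions and limitations

- Monetary quantities are float64; equality tests use 1e−9 absolute
  tolerance; row-stochasticity 1e−12; stationary residual 1e−8.
- Payoff of a type with zero count is evaluated with counts as given (it
  enters the dynamics weighted by the count, hence never contributes); an
  `as_resident` flag substitutes a hypothetical resident for invasion
  analyses.
- The exact engine requires equal group sizes; unequal groups are refused
  rather than guessing a convention for `N` not divisible by `k`.
- The printed payoff equations assume `k = 2`; for `k > 2` (ABM only) the
  out-group meeting term generalizes to a uniform choice among all
  out-group members.
- CSV output preserves full float64 precision (`%.17g`); exact-engine
  results are byte-reproducible given the manifest.
- No spatial or network structure, no migration, no group fission/fusion,
  no weak-selection approximations, no symbolic stationary solutions.
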