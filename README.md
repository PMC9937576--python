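# coopevo

Evolutionary dynamics of **parochial vs. universal cooperation** in
group-structured populations.

`coopevo` models a nested social dilemma: a population of `N = k·n` agents is
split into `k` groups of `n`. In stage 1 each agent may invest an endowment
`e` into its group's **club good** (benefit `b_CG`, shared by the `n` group
members only), into a population-wide **public good** (benefit `b_PG`, shared
by all `N` agents), or keep it. Both options are costly (`b_CG/n < c_c < b_CG`
and `b_PG/N < c_c < b_PG`), so free-riding dominates stage 1 on its own. In
stage 2 each agent meets a partner — an in-group member with probability `p`
(the *fluidity* of group boundaries) — and may pay `c_h` to confer a helping
benefit `b_h`. Conditional helping is the reciprocity mechanism that can
enforce cooperation, and `p` decides *which kind* of cooperation it enforces:
group-bound (parochial) or population-wide (universal).

The package is for researchers in evolutionary game theory and social
evolution who want to reproduce, probe, or extend this model. It provides:

- **`coopevo.exact`** — an exact Moran-process engine: the full state space of
  group compositions is enumerated (225 states for `n=4, k=2`, 3 types), the
  one-event transition matrix `M` is built from the death probability
  `(1/k)(n_ij/n)` and the global fitness-proportional adoption probability
  `Σ_s n_sy e^{π_sy} / Σ_t Σ_s n_st e^{π_st}`, and the stationary distribution
  `w` (with `wM = w`) is solved by three interchangeable backends.
- **`coopevo.model_core`** — stage-1 earnings and the closed-form expected
  payoffs `π_U, π_P, π_F` of universalists, parochialists and free-riders,
  with fitness `e^π`.
- **`coopevo.thresholds`** — closed-form conditions: the cooperation share
  threshold `c_c/(b_h − c_h)`, the parochial invasion threshold
  `(b_h − c_h)/(b_h − c_h + b_CG)`, and the universalist simple-majority rule.
- **`coopevo.abm`** — an agent-based simulator with *realized* pairing and
  helping for large and fragmented populations (`k > 2`), including a
  compiled fast path for the canonical three-type space and an extended
  strategy space (nondiscriminating helpers, second-order free-riders,
  history- or disposition-conditioned helping).
- **`coopevo` CLI** — `exact`, `sweep-exact`, `abm`, `sweep-abm`,
  `thresholds`, `validate-config`; results are written as CSV with a JSON
  manifest recording parameters, grids, seeds and software version.

## Worked example

The canonical configuration is two groups of four with
`e = c_c = c_h = 1, b_CG = 2, b_PG = 3, μ = 1e-4`. With a high helping
benefit and fluid boundaries:

```bash
$ coopevo exact --bh 7 --p 0.5
{
  "prop_U": 0.9944162476773031,
  "prop_P": 0.005504212434362059,
  "prop_F": 7.95398883348415e-05,
  "welfare": 9.976841552329738,
  "state_count": 225,
  ...
}
```

Universal cooperators carry ~99.4% of the stationary mass: when helping is
valuable (`b_h = 7`) and half of all dyadic encounters cross group lines
(`p = 0.5`), reciprocity rewards public-good provision and universalism wins.
Rerun with `--p 1.0` (solid boundaries) and parochialists take over instead
(`prop_P ≈ 0.97`) at lower welfare — club goods create less value than the
public good since `b_CG < b_PG`.

The closed-form thresholds for the same regime:

```bash
$ coopevo thresholds --bh 3
cooperation_share_threshold      0.5
parochial_invasion_threshold     0.5
universalist_majority_rule       total U > P within each group (p=0.5)
```

At `b_h = 3` a cooperator type spreads once its share among potential helping
partners exceeds `c_c/(b_h − c_h) = 0.5`, and parochialists outcompete a fully
universalist group once they make up 50% of the opposing group.

For the full fluidity × helping-benefit landscape (51 × 91 = 4641 exact
steady states) and the group-size/fragmentation sweeps of the agent-based
model:

```bash
coopevo sweep-exact --out sweep_exact.csv          # ~1 minute
coopevo sweep-abm --scale 0.2 --runs 20 --seed 1 --out sweep_abm.csv
```

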