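# Methods

## The stage game

One round of the modified trust game: the donor entrusts or not; an
entrusted recipient honors the trust or defects; nature then draws
success with probability `a` (competence), independent of intention.
Payoffs: honored + success → `(R, R)`; defection + success → `(0, T)`;
any failure → `(0, 0)`; no trust → `(P, P)`. Parameter constraints
`T > R > P > 0` and `2R > T` make mutual cooperation jointly efficient
(total `2R > T`) while leaving a per-round temptation `T − R` for the
recipient. Benchmark values `P=1, R=4, T=6`.

The round's public history is `C` only on honored-and-successful
rounds; defection and honest failure both read `D`. This information
asymmetry is the crux: any rule that punishes `D` punishes unlucky
cooperators at rate `1 − a`.

## Exact repeated-game payoffs

A relationship lasts `n = 100` rounds unless broken; after any break,
voluntary or exogenous (probability `d = 0.1` per round), both parties
collect `P` per remaining round and never re-match. No discounting.

Donor exit rules: `H` never exits; `M` exits after two consecutive `D`
outcomes (a success clears the pending failure); `L` exits after one.
Recipient intents are pure `C` or `D`. Each (rule, intent) pair induces
a three-state absorbing Markov chain — intact with no pending failure,
intact with one pending failure (reachable only under `M`), broken.
Round order: play the sub-game, apply the exit rule to the observed
outcome, then draw exogenous dissolution. Round 1 is always played.

Expected totals are accumulated by forward propagation of the state
distribution (start intact; per round add the intact probability times
the expected stage reward, `aR` per player under `C` or `(0, aT)` under
`D`, plus the broken probability times `P`). Forward propagation makes
the finite-horizon truncation exact; no matrix inversion or geometric
approximation is involved. A vectorized Monte-Carlo simulator of the
identical process (explicit Bernoulli draws per round and replicate)
serves as an independent oracle; the tests require agreement within
three standard errors at 10^5 replicates.

## Equilibrium structure

The six payoff pairs form a 3×2 bimatrix (rows `H/M/L`, columns `C/D`,
entries `a1..f2`). The mixed equilibrium with donor support `{H, M}`
and recipient support `{C, D}` exists when three conditions hold:

* C1: `q_C = (d1−b1)/(a1−c1+d1−b1) ∈ (0, 1)` — the cooperation
  probability equalizing the donor's `H` and `M` payoffs;
* C2: `[(d1−b1)(a1−e1) + (a1−c1)(b1−f1)]/(a1−c1+d1−b1) > 0` — at that
  `q_C` the `{H, M}` payoff strictly exceeds the deviation to `L`;
* C3: `p_H = (c2−d2)/((c2−d2)+(b2−a2)) ∈ (0, 1)` — the `H` probability
  equalizing the recipient's `C` and `D` payoffs.

Pure equilibria are found by exhaustive best-response checks with ties
admitted (a strictness flag is available); with these payoffs the only
candidate is `(L, D)`, which is an equilibrium exactly while
`f2 ≥ e2`. Pareto efficiency of `(H, C)` is checked by cell dominance
(no other cell weakly improves both totals with one strict
improvement).

Three competence thresholds are located by bisection (tolerance 1e−6,
preceded by a 40-point grid scan that verifies a single sign change;
absence of a sign change is an explicit error): the C2/Pareto boundary
at `a = P/R = 0.25` (every relevant payoff difference carries the
factor `aR − P`, so the root is exact), the cooperation boundary
`c2 = d2` at `a ≈ 0.4695`, and the uniqueness boundary `e2 = f2` at
`a ≈ 0.5370`. Thresholds are reported to two decimals; full precision
is kept internally. Regime labels (four phases) are always derived
from the computed equilibria, never from hard-coded cut-offs.

Two knife-edge facts worth recording. At `a = P/R` exactly, every
cooperate-column cell pays the isolation stream to both players, so the
dominance check reports `(H, C)` as (trivially) efficient; efficiency
in the strict sense holds only for `a > P/R`. And while the donor's
equilibrium weight on `H` rises strictly with `a` throughout the
mixed-only range, the recipient's `q_C` first dips by about 0.01 just
above the uniqueness boundary (minimum near `a ≈ 0.64`) before rising;
at `a = 1` exactly the `H` and `M` rows coincide (nothing to forgive)
and the mixture is no longer identified.

## The evolutionary matching market

Population: `N = 250` donors and `250` recipients (fixed roles). Donor
policies cross a matching attitude and an exit attitude — ST (strict in
both), MG (generous matching, strict exit), EG (strict matching,
generous exit), SG (generous in both). Recipients hold an intention
`x ∈ {0, 0.5, 1}` (probability of honoring trust) and the common
competence `a`, which never evolves.

Round procedure (within a generation of `L = 100` rounds):

1. **Matching.** Unpaired donors, visited in a fresh random order, each
   draw one recipient uniformly at random from the currently unpaired
   recipients whose last-round history they accept (strict: `C` only;
   generous: any); chosen recipients leave the pool immediately; donors
   finding no acceptable recipient stay alone this round.
2. **Play.** Each pair plays the stage game (`cooperate ~ Bernoulli(x)`,
   `success ~ Bernoulli(a)`); the recipient's history is set to the
   outcome. Every unpaired agent of either role collects `P`.
3. **Commitment.** An exit-strict donor leaves after a `D` outcome;
   surviving pairs break exogenously with probability `d = 0.1`. Both
   members of a dissolved pair re-enter the pool with a **one-round
   re-entry latency**: dissolved in round `t`, they sit out round
   `t + 1` (collecting `P`) and are matchable again from `t + 2`.

The re-entry latency is the one design choice here that the round
diagram leaves open, and it is load-bearing. With instantaneous
re-entry, ostracism is costless: a dumped defector is recycled by some
matching-generous donor within about a round, a half-hearted cooperator
(`x = 0.5`) weakly dominates a full cooperator at every competence
level, and mean intention plateaus near 0.45 for all `a ≥ 0.6` — no
cooperation threshold exists. Charging one isolated round per
dissolution, on both sides, makes every punishment and every churn
costly, and the documented phase structure (strictness below the
threshold, generous trust above it) emerges robustly. We verified the
alternative readings — latency on the recipient side only, random
single-encounter matching, strategy-mean imitation, history persistence
across generations, isolation payoff 0, forgive-once exit rules — and
none reproduces the cooperative regime.

Generation boundary: each agent compares its cumulative payoff with one
uniformly random same-role peer and adopts the peer's entire strategy
iff the peer's payoff is strictly higher (ties keep one's own), all
updates synchronous; then with probability `M = 0.025` the strategy is
replaced by a uniformly random one from the role's space. Payoffs,
pairings, wait flags and histories (back to `C`) reset, so each
generation starts from a full matching pool.

RNG discipline: one master seed spawns an independent `SeedSequence`
substream per (grid value, trial); a trial is bit-reproducible from its
substream, and identical configuration plus seed reproduces identical
generation records.

## What the simulation measures

Per generation we record donor policy shares, mean intention, and two
pool statistics averaged over the generation's post-matching rounds:
the number of unpaired recipients and the number of unpaired
recipients with a good intention but a bad (`D`) history — cooperators
ostracized for an accident. "Good intention" defaults to `x = 1`; a
cutoff option (`x ≥ 0.5`) is exposed.

A sweep runs 10 independent trials per competence value on a 0.05 grid
and summarizes final states as means over the last 10 generations
(damping mutation-driven fluctuations). A grid value *sustains
cooperation* when the tail-mean intention exceeds 0.5 in a strict
majority of trials; the simulated cooperation threshold is the smallest
sustaining value, reported with its bracketing grid interval, and a
criterion that never (or always) holds is reported as such rather than
interpolated.

Default sweep scale is 10 trials × 40 generations. The dynamics
stabilize well before generation 40 (the three transient phases —
strict selection, rise of matching generosity, generous-trust balance —
complete within roughly 16 generations), and the threshold estimate is
unchanged across master seeds at this scale; larger runs are available
through the `--trials`/`--generations` flags.

## Numerical and degenerate-input conventions

* Parameters are validated at construction (payoff ordering, probability
  ranges, positive counts); operations assume valid inputs.
* Degenerate condition denominators (`a1−c1+d1−b1 = 0` or
  `(c2−d2)+(b2−a2) = 0`) are flagged in the condition report, never
  divided through; the mixed equilibrium is then reported absent.
* `d = 1` collapses every pair after one round; `M = 0` with a uniform
  strategy freezes the distribution — both covered by tests.
* Imitation peers are sampled with replacement and may be the agent
  itself (a self-comparison never copies, so this is equivalent to
  excluding it under strict improvement).

## Limitations

* Both models inherit the one-round history: reputations have no
  memory, so the only information channels are the current record and
  the pairing structure itself.
* The dyadic model covers pure recipient intents only; the mixed intent
  `x = 0.5` exists only in the simulation.
* Fixed roles, fixed competence, no spatial or network structure, no
  time discounting; populations are finite and equal-sized, which pins
  the number of unpaired donors to the number of unpaired recipients.
* The simulated threshold is a grid statement (smallest sustaining grid
  value under a majority criterion), not a root of a smooth function;
  different sustainment criteria shift it by at most one grid step in
  our checks.
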