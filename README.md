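# gentrust

Tools for studying **generous trust**: when is it rational to forgive a
partner whose promised task failed, given that you cannot tell an honest
failure from a betrayal?

The setting is a *modified trust game*. A donor decides whether to
entrust a resource to a recipient; the recipient decides whether to
honor the trust (intention) and then nature decides whether the
undertaking succeeds, with probability `a` — the recipient's
*competence*. Honored, successful trust pays both parties `R`;
successful betrayal pays the recipient `T` and the donor nothing; any
failure pays nothing; a donor who withholds trust leaves both with the
isolation payoff `P` (defaults `P=1, R=4, T=6`, with `T > R > P > 0` and
`2R > T`). Crucially the public record of a round is `C` only on
cooperation-and-success: malice and bad luck are observationally
identical, so punishing every `D` also punishes honest but fallible
cooperators.

The package answers the resulting design question — how much
forgiveness is optimal, and where should it live — at two levels:

1. **Dyadic repeated game** (exact). A 100-round relationship with
   exogenous dissolution probability `d` per round, donor exit rules of
   high, middle and low generosity (`H` never exits, `M` exits after two
   consecutive `D` outcomes, `L` exits after one) against pure recipient
   intents `C`/`D`. Expected totals are computed exactly with small
   absorbing Markov chains, and the 3×2 game is analyzed for pure and
   mixed Nash equilibria, Pareto efficiency of `(H, C)`, and the three
   competence thresholds that organize the phase diagram.
2. **Matching market** (agent-based). 250 donors and 250 recipients
   meet through a matching pool; donor generosity splits into *matching
   generosity* (accept a partner with a bad record) and *exit
   generosity* (keep one), giving four policies ST/MG/EG/SG; recipients
   carry intentions `x ∈ {0, 0.5, 1}`. Strategies evolve by imitation
   of more successful same-role peers with mutation.

## Worked example

Exact analysis at competence `a = 0.6` (benchmark payoffs, `d = 0.1`):

```sh
gentrust analyze --a 0.6 --out results/analysis
```

prints (abridged from `results/analysis/analysis.json`):

```text
regime at a=0.6: mixed-only
thresholds: pareto=0.2500 cooperation=0.4695 uniqueness=0.5370
mixed equilibrium: p_H=0.1566 q_C=0.5425
```

and the entire-game payoff matrix (donor total, recipient total):

|       | C                | D               |
|-------|------------------|-----------------|
| **H** | (114.00, 114.00) | ( 90.00, 126.00)|
| **M** | (107.17, 107.17) | ( 98.10, 104.94)|
| **L** | (103.04, 103.04) | ( 99.00, 102.60)|

Reading: below `a = 0.25` even sustained cooperation is worth less than
staying alone (`aR < P`) and the strict pair `(L, D)` is the only
equilibrium; from `0.25` the cooperative outcome `(H, C)` is Pareto
efficient but never a pure equilibrium (given `H`, defection always pays
the recipient more — the dilemma of the game); from `0.47` the
recipient facing a middle-generosity donor prefers to cooperate, and a
mixed equilibrium appears in which the donor mixes `H`/`M` and the
recipient `C`/`D`; from `0.54` that mixed equilibrium is the only one.
At `a = 0.6` the donor plays `H` with probability 0.157 and the
recipient cooperates with probability 0.542.

The evolutionary sweep:

```sh
gentrust sweep --a-min 0.50 --a-max 0.65 --a-step 0.05 \
    --trials 10 --generations 40 --seed 1 --out results/sweep
```

reports `simulated cooperation threshold: threshold at 0.6, bracketed by
(0.55, 0.6]`: at `a ≤ 0.55` the strict-trust policy dominates and
intention collapses, while from `a = 0.60` the population sustains
cooperation with the exit-generous and super-generous policies holding
the largest joint share — generosity becomes viable once failures are
sufficiently likely to be accidents, but only together with the
ostracism of the matching process.

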