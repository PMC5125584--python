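"""Evolutionary agent-based simulation of socially embedded trust.

A population of donors and recipients interacts through a matching
pool.  Each round every unpaired donor, visited in a fresh random
order, picks one recipient uniformly at random from the pooled
recipients whose last-round history it accepts (strict matchers accept
``C`` only, matching-generous donors accept anyone); paired couples
play the modified trust game; the donor then applies its exit rule
(strict: leave after a ``D`` outcome; exit-generous: stay), and
surviving pairs break exogenously with probability ``d``.  Unpaired
agents of either role collect the isolation payoff ``P``.

Crossing a donor's matching and exit attitudes yields the four
policies: strict trust (ST), matching generous (MG), exit generous
(EG) and super generous (SG).  Recipients carry an intention
``x in {0, 0.5, 1}``, the probability of honoring trust, and a common
competence ``a`` fixed for the whole run (a natural endowment, not
subject to evolution).

Dissolution is not free for either side: a pair dissolved at round
``t`` spends round ``t + 1`` in the pool unmatched (collecting the
isolation payoff) and re-enters the matching process at round
``t + 2``.  This one-round re-entry latency is what gives ostracism
its bite — without it a dumped defector is recycled by some
matching-generous donor within a round and punishment carries no
cost.

After ``L`` rounds a generation ends: within each role every agent
compares its cumulative payoff with one uniformly random same-role
peer and copies the peer's full strategy if the peer did strictly
better, then mutates to a uniformly random strategy with probability
``M``.  Payoffs, pairings and histories reset between generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .game import PayoffParams

__all__ = [
    "DONOR_POLICIES",
    "INTENT_LEVELS",
    "SimConfig",
    "Population",
    "GenerationRecord",
    "init_population",
    "matching_step",
    "play_round",
    "commitment_step",
    "evolve_population",
    "run_trial",
]

DONOR_POLICIES = ("ST", "MG", "EG", "SG")
INTENT_LEVELS = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Benchmark simulation parameters.

    Defaults are the benchmark conditions: 250 donors and 250
    recipients, payoffs P=1, R=4, T=6, exogenous dissolution d=0.1,
    L=100 rounds per generation and mutation rate M=0.025.
    """

    a: float
    n_donors: int = 250
    n_recipients: int = 250
    d: float = 0.1
    rounds_per_generation: int = 100
    mutation_rate: float = 0.025
    generations: int = 100
    params: PayoffParams = field(default_factory=PayoffParams)

    def __post_init__(self) -> None:
        for name in ("a", "d", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("n_donors", "n_recipients", "rounds_per_generation", "generations"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")


class Population:
    """Array-backed state of all donors and recipients.

    Partner links are stored as indices (``-1`` when unpaired) and are
    kept mutual: ``rec_partner[donor_partner[i]] == i`` for every paired
    donor ``i``.  Histories live on recipients (a single symbol, ``C``
    encoded as ``True``), since only recipient behavior is observable.
    """

    __slots__ = (
        "donor_match_gen",
        "donor_exit_gen",
        "donor_partner",
        "donor_payoff",
        "donor_wait",
        "rec_intent",
        "rec_history_c",
        "rec_partner",
        "rec_payoff",
        "rec_wait",
    )

    def __init__(self, n_donors: int, n_recipients: int) -> None:
        self.donor_match_gen = np.zeros(n_donors, dtype=bool)
        self.donor_exit_gen = np.zeros(n_donors, dtype=bool)
        self.donor_partner = np.full(n_donors, -1, dtype=np.int64)
        self.donor_payoff = np.zeros(n_donors)
        self.donor_wait = np.zeros(n_donors, dtype=bool)  # re-entry latency
        self.rec_intent = np.zeros(n_recipients)
        self.rec_history_c = np.ones(n_recipients, dtype=bool)
        self.rec_partner = np.full(n_recipients, -1, dtype=np.int64)
        self.rec_payoff = np.zeros(n_recipients)
        self.rec_wait = np.zeros(n_recipients, dtype=bool)

    @property
    def n_donors(self) -> int:
        return self.donor_match_gen.size

    @property
    def n_recipients(self) -> int:
        return self.rec_intent.size

    def donor_policy_codes(self) -> np.ndarray:
        """Policy index per donor: 0=ST, 1=MG, 2=EG, 3=SG."""
        return self.donor_match_gen.astype(np.int64) + 2 * self.donor_exit_gen.astype(np.int64)

    def policy_shares(self) -> dict[str, float]:
        counts = np.bincount(self.donor_policy_codes(), minlength=4)
        return {name: counts[i] / self.n_donors for i, name in enumerate(DONOR_POLICIES)}

    def mean_intent(self) -> float:
        return float(self.rec_intent.mean())


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation summary taken just before the evolution update.

    Isolation counts are averages over the generation's rounds of the
    post-matching pool: ``n_isolated_recipients`` counts all unpaired
    recipients, ``n_isolated_good_intent_bad_history`` the unpaired
    recipients whose intention qualifies as good but whose last-round
    history is ``D`` — cooperators ostracized for an accidental failure.
    """

    trial: int
    generation: int
    share_ST: float
    share_MG: float
    share_EG: float
    share_SG: float
    mean_intent: float
    n_isolated_recipients: float
    n_isolated_good_intent_bad_history: float


@njit(cache=False)
def _match_kernel(match_gen, pool_c, pool_d, u):  # pragma: no cover - jitted
    """Sequentially assign pooled recipients to donors in visit order.

    ``match_gen[i]`` is the i-th visited donor's matching generosity;
    ``pool_c``/``pool_d`` hold indices of unpaired recipients by
    history; ``u`` one uniform draw per donor.  Picks are uniform over
    the donor's acceptable remainder with immediate removal
    (swap-delete), mirroring donors drawing one at a time.
    """
    n_c = pool_c.size
    n_d = pool_d.size
    out = np.empty(match_gen.size, dtype=np.int64)
    for i in range(match_gen.size):
        if match_gen[i]:
            total = n_c + n_d
            if total == 0:
                out[i] = -1
                continue
            k = int(u[i] * total)
            if k >= total:  # guard u == 1.0 edge
                k = total - 1
            if k < n_c:
                out[i] = pool_c[k]
                n_c -= 1
                pool_c[k] = pool_c[n_c]
            else:
                k -= n_c
                out[i] = pool_d[k]
                n_d -= 1
                pool_d[k] = pool_d[n_d]
        else:
            if n_c == 0:
                out[i] = -1
                continue
            k = int(u[i] * n_c)
            if k >= n_c:
                k = n_c - 1
            out[i] = pool_c[k]
            n_c -= 1
            pool_c[k] = pool_c[n_c]
    return out


def init_population(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Fresh population with uniformly random strategies, all unpaired.

    Donor matching and exit flags are independent fair coin flips (so
    each of ST/MG/EG/SG has probability 1/4); recipient intents are
    uniform over {0, 0.5, 1}.  Histories start at ``C`` so strict
    matchers can pair in the first round.
    """
    pop = Population(cfg.n_donors, cfg.n_recipients)
    pop.donor_match_gen[:] = rng.integers(0, 2, cfg.n_donors).astype(bool)
    pop.donor_exit_gen[:] = rng.integers(0, 2, cfg.n_donors).astype(bool)
    pop.rec_intent[:] = np.asarray(INTENT_LEVELS)[rng.integers(0, 3, cfg.n_recipients)]
    return pop


def matching_step(pop: Population, rng: np.random.Generator) -> None:
    """Pair unpaired donors with acceptable pooled recipients (in place).

    Agents whose relationship dissolved in the previous round carry a
    wait flag and sit this matching out; the flags are cleared here so
    they become selectable next round.
    """
    unpaired = np.flatnonzero((pop.donor_partner < 0) & ~pop.donor_wait)
    if unpaired.size:
        order = rng.permutation(unpaired)
        selectable = (pop.rec_partner < 0) & ~pop.rec_wait
        pool_c = np.flatnonzero(selectable & pop.rec_history_c)
        pool_d = np.flatnonzero(selectable & ~pop.rec_history_c)
        u = rng.random(order.size)
        chosen = _match_kernel(pop.donor_match_gen[order], pool_c, pool_d, u)
        got = chosen >= 0
        pop.donor_partner[order[got]] = chosen[got]
        pop.rec_partner[chosen[got]] = order[got]
    pop.donor_wait[:] = False
    pop.rec_wait[:] = False


def play_round(pop: Population, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Play the sub-game in every pair; pay isolation to everyone else."""
    p = cfg.params
    d_idx = np.flatnonzero(pop.donor_partner >= 0)
    if d_idx.size:
        r_idx = pop.donor_partner[d_idx]
        coop = rng.random(d_idx.size) < pop.rec_intent[r_idx]
        succ = rng.random(d_idx.size) < cfg.a
        hist_c = coop & succ
        pop.donor_payoff[d_idx] += np.where(hist_c, p.R, 0.0)
        # on failure both sides get nothing; on success a defector keeps T
        pop.rec_payoff[r_idx] += np.where(hist_c, p.R, np.where(succ, p.T, 0.0))
        pop.rec_history_c[r_idx] = hist_c
    pop.donor_payoff[pop.donor_partner < 0] += p.P
    pop.rec_payoff[pop.rec_partner < 0] += p.P


def commitment_step(pop: Population, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Apply exit rules, then exogenous dissolution, to every pair.

    An exit-strict donor leaves after a ``D`` outcome; any surviving
    pair breaks exogenously with probability ``d``.  Both members of a
    dissolved pair return to the pool with a one-round wait before they
    can match again.
    """
    d_idx = np.flatnonzero(pop.donor_partner >= 0)
    if d_idx.size == 0:
        return
    r_idx = pop.donor_partner[d_idx]
    voluntary = ~pop.rec_history_c[r_idx] & ~pop.donor_exit_gen[d_idx]
    exogenous = rng.random(d_idx.size) < cfg.d
    dissolve = voluntary | exogenous
    pop.donor_partner[d_idx[dissolve]] = -1
    pop.rec_partner[r_idx[dissolve]] = -1
    pop.donor_wait[d_idx[dissolve]] = True
    pop.rec_wait[r_idx[dissolve]] = True


def evolve_population(pop: Population, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Role-wise imitation with mutation; reset the generation state.

    Every agent samples one uniformly random same-role peer and adopts
    the peer's full strategy iff the peer's cumulative payoff is
    strictly higher (ties keep one's own).  With probability ``M`` the
    result is replaced by a uniformly random strategy from the role's
    space.  Competence never changes.  Payoffs reset to zero, all pairs
    dissolve and histories reset to ``C``.
    """
    n_d, n_r = pop.n_donors, pop.n_recipients

    peers = rng.integers(0, n_d, n_d)
    better = pop.donor_payoff[peers] > pop.donor_payoff
    match_gen = np.where(better, pop.donor_match_gen[peers], pop.donor_match_gen)
    exit_gen = np.where(better, pop.donor_exit_gen[peers], pop.donor_exit_gen)
    mutate = rng.random(n_d) < cfg.mutation_rate
    random_policy = rng.integers(0, 4, n_d)
    pop.donor_match_gen[:] = np.where(mutate, random_policy % 2 == 1, match_gen)
    pop.donor_exit_gen[:] = np.where(mutate, random_policy // 2 == 1, exit_gen)

    peers = rng.integers(0, n_r, n_r)
    better = pop.rec_payoff[peers] > pop.rec_payoff
    intent = np.where(better, pop.rec_intent[peers], pop.rec_intent)
    mutate = rng.random(n_r) < cfg.mutation_rate
    random_intent = np.asarray(INTENT_LEVELS)[rng.integers(0, 3, n_r)]
    pop.rec_intent[:] = np.where(mutate, random_intent, intent)

    pop.donor_payoff[:] = 0.0
    pop.rec_payoff[:] = 0.0
    pop.donor_partner[:] = -1
    pop.rec_partner[:] = -1
    pop.rec_history_c[:] = True
    pop.donor_wait[:] = False
    pop.rec_wait[:] = False


def run_trial(
    cfg: SimConfig,
    seed: int | np.random.Generator,
    trial_id: int = 0,
    good_intent_min: float = 1.0,
) -> list[GenerationRecord]:
    """One full trial: initialize, then iterate generations of L rounds.

    Per round the sequence is matching → play → commitment; isolation
    metrics are counted on the post-matching pool.  ``good_intent_min``
    sets the intention level counted as a good intention in the
    isolated-with-bad-history metric (1.0 by default; 0.5 to include
    half-hearted cooperators).  Fully reproducible given a seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = init_population(cfg, rng)
    records: list[GenerationRecord] = []
    rounds = cfg.rounds_per_generation
    for generation in range(1, cfg.generations + 1):
        isolated_sum = 0.0
        good_bad_sum = 0.0
        for _ in range(rounds):
            matching_step(pop, rng)
            pooled = pop.rec_partner < 0
            isolated_sum += pooled.sum()
            good_bad_sum += (
                pooled & ~pop.rec_history_c & (pop.rec_intent >= good_intent_min)
            ).sum()
            play_round(pop, cfg, rng)
            commitment_step(pop, cfg, rng)
        shares = pop.policy_shares()
        records.append(
            GenerationRecord(
                trial=trial_id,
                generation=generation,
                share_ST=shares["ST"],
                share_MG=shares["MG"],
                share_EG=shares["EG"],
                share_SG=shares["SG"],
                mean_intent=pop.mean_intent(),
                n_isolated_recipients=isolated_sum / rounds,
                n_isolated_good_intent_bad_history=good_bad_sum / rounds,
            )
        )
        evolve_population(pop, cfg, rng)
    return records
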