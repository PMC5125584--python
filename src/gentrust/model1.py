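"""Exact expected payoffs of the finite repeated trust game.

The dyadic model restricts the donor to three exit rules — high (``H``,
never exits), middle (``M``, exits after two consecutive ``D`` outcomes)
and low (``L``, exits after a single ``D``) generosity — and the
recipient to the pure intents ``C`` / ``D``.  While a pair is intact
every round plays the sub-game; afterwards the donor applies its exit
rule to the observed history and the relationship additionally dissolves
exogenously with probability ``d``.  A broken relationship is never
re-established: both parties collect the isolation payoff ``P`` for each
remaining round.

Expected totals are computed exactly by forward propagation of the state
distribution of a small absorbing Markov chain (states: intact with no
pending failure, intact with one pending failure, broken), accumulating
per-round expected rewards over the finite horizon.  A vectorized
Monte-Carlo simulator of the same process serves as an independent
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game import GameConfig, PayoffParams

__all__ = [
    "DONOR_STRATEGIES",
    "RECIPIENT_STRATEGIES",
    "PayoffMatrix",
    "expected_total_payoffs",
    "payoff_matrix",
    "simulate_repeated_game",
    "SimulationResult",
]

DONOR_STRATEGIES = ("H", "M", "L")
RECIPIENT_STRATEGIES = ("C", "D")

# chain states: 0 = intact, no pending failure; 1 = intact, one pending
# failure (only reachable under M); 2 = broken (absorbing)
_S_OK, _S_PENDING, _S_BROKEN = 0, 1, 2


def _validate_strategies(donor: str, recipient: str) -> None:
    if donor not in DONOR_STRATEGIES:
        raise ValueError(f"unknown donor strategy {donor!r}; expected one of {DONOR_STRATEGIES}")
    if recipient not in RECIPIENT_STRATEGIES:
        raise ValueError(
            f"unknown recipient strategy {recipient!r}; expected one of {RECIPIENT_STRATEGIES}"
        )


def _transition_matrix(donor: str, recipient: str, cfg: GameConfig) -> np.ndarray:
    """One-round 3x3 transition matrix applied *after* the round is played.

    The round outcome is ``C`` with probability ``a`` when the recipient
    cooperates and never otherwise.  The donor's exit rule acts on the
    outcome first; a surviving pair then breaks exogenously with
    probability ``d``.
    """
    p_c = cfg.a if recipient == "C" else 0.0
    p_d = 1.0 - p_c
    keep = 1.0 - cfg.d
    t = np.zeros((3, 3))
    t[_S_BROKEN, _S_BROKEN] = 1.0
    if donor == "H":
        # never exits voluntarily; outcome is irrelevant to survival
        t[_S_OK, _S_OK] = keep
        t[_S_OK, _S_BROKEN] = cfg.d
        t[_S_PENDING] = t[_S_OK]  # unreachable, kept consistent
    elif donor == "L":
        # any D outcome ends the relationship immediately
        t[_S_OK, _S_OK] = p_c * keep
        t[_S_OK, _S_BROKEN] = p_d + p_c * cfg.d
        t[_S_PENDING] = t[_S_OK]  # unreachable
    elif donor == "M":
        # one failure is forgiven (pending); a success clears the slate;
        # a second consecutive failure triggers exit
        t[_S_OK, _S_OK] = p_c * keep
        t[_S_OK, _S_PENDING] = p_d * keep
        t[_S_OK, _S_BROKEN] = cfg.d
        t[_S_PENDING, _S_OK] = p_c * keep
        t[_S_PENDING, _S_BROKEN] = p_d + p_c * cfg.d
    return t


def expected_total_payoffs(
    donor: str,
    recipient: str,
    cfg: GameConfig,
    params: PayoffParams = PayoffParams(),
) -> tuple[float, float]:
    """Exact expected (donor, recipient) totals over the full horizon.

    Round 1 is always played (every donor strategy trusts an unknown
    partner), so the chain starts intact.  Per round an intact pair earns
    the expected sub-game payoffs ``(aR, aR)`` or ``(0, aT)``; a broken
    pair earns ``(P, P)``.
    """
    _validate_strategies(donor, recipient)
    a, d, n = cfg.a, cfg.d, cfg.n_rounds
    p = params
    if recipient == "C":
        reward_donor, reward_recipient = a * p.R, a * p.R
    else:
        reward_donor, reward_recipient = 0.0, a * p.T

    t = _transition_matrix(donor, recipient, cfg)
    v = np.array([1.0, 0.0, 0.0])
    donor_total = 0.0
    recipient_total = 0.0
    for _ in range(n):
        intact = v[_S_OK] + v[_S_PENDING]
        broken = v[_S_BROKEN]
        donor_total += intact * reward_donor + broken * p.P
        recipient_total += intact * reward_recipient + broken * p.P
        v = v @ t
    return donor_total, recipient_total


@dataclass(frozen=True)
class PayoffMatrix:
    """Entire-game expected payoffs for the six strategy pairs.

    Rows are the donor strategies ``H``/``M``/``L``, columns the
    recipient intents ``C``/``D``.  Entry names follow the standard
    bimatrix layout: ``(a1, a2)`` for (H, C), ``(b1, b2)`` for (H, D),
    ``(c1, c2)`` for (M, C), ``(d1, d2)`` for (M, D), ``(e1, e2)`` for
    (L, C) and ``(f1, f2)`` for (L, D), with index 1 the donor and 2 the
    recipient.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    d1: float
    d2: float
    e1: float
    e2: float
    f1: float
    f2: float

    _CELLS = {
        ("H", "C"): ("a1", "a2"),
        ("H", "D"): ("b1", "b2"),
        ("M", "C"): ("c1", "c2"),
        ("M", "D"): ("d1", "d2"),
        ("L", "C"): ("e1", "e2"),
        ("L", "D"): ("f1", "f2"),
    }

    def cell(self, donor: str, recipient: str) -> tuple[float, float]:
        """(donor, recipient) expected totals for one strategy pair."""
        names = self._CELLS[(donor, recipient)]
        return getattr(self, names[0]), getattr(self, names[1])

    def donor_payoffs(self) -> np.ndarray:
        """3x2 array of donor totals, rows H/M/L, columns C/D."""
        return np.array([[self.a1, self.b1], [self.c1, self.d1], [self.e1, self.f1]])

    def recipient_payoffs(self) -> np.ndarray:
        """3x2 array of recipient totals, rows H/M/L, columns C/D."""
        return np.array([[self.a2, self.b2], [self.c2, self.d2], [self.e2, self.f2]])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per strategy pair."""
        rows = []
        for (donor, recipient), (n1, n2) in self._CELLS.items():
            rows.append(
                {
                    "donor": donor,
                    "recipient": recipient,
                    "donor_payoff": getattr(self, n1),
                    "recipient_payoff": getattr(self, n2),
                }
            )
        return pd.DataFrame(rows)


def payoff_matrix(cfg: GameConfig, params: PayoffParams = PayoffParams()) -> PayoffMatrix:
    """Assemble all six expected-total-payoff pairs for one (a, d, n)."""
    values: dict[str, float] = {}
    for (donor, recipient), (n1, n2) in PayoffMatrix._CELLS.items():
        v1, v2 = expected_total_payoffs(donor, recipient, cfg, params)
        values[n1] = v1
        values[n2] = v2
    return PayoffMatrix(**values)


@dataclass(frozen=True)
class SimulationResult:
    """Monte-Carlo sample means and standard errors of both totals."""

    donor_mean: float
    donor_se: float
    recipient_mean: float
    recipient_se: float
    n_reps: int


def simulate_repeated_game(
    donor: str,
    recipient: str,
    cfg: GameConfig,
    params: PayoffParams = PayoffParams(),
    n_reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> SimulationResult:
    """Monte-Carlo estimate of the repeated-game totals.

    Draws explicit Bernoulli success and dissolution variables per round
    for ``n_reps`` independent replicates, vectorized across replicates.
    Serves as an independent oracle for :func:`expected_total_payoffs`.
    """
    _validate_strategies(donor, recipient)
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params
    coop = recipient == "C"

    state = np.zeros(n_reps, dtype=np.int8)
    donor_tot = np.zeros(n_reps)
    rec_tot = np.zeros(n_reps)
    for _ in range(cfg.n_rounds):
        intact = state != _S_BROKEN
        success = rng.random(n_reps) < cfg.a
        exo_break = rng.random(n_reps) < cfg.d

        outcome_c = intact & success if coop else np.zeros(n_reps, dtype=bool)
        if coop:
            donor_tot += np.where(outcome_c, p.R, 0.0)
            rec_tot += np.where(outcome_c, p.R, 0.0)
        else:
            rec_tot += np.where(intact & success, p.T, 0.0)
        donor_tot += np.where(~intact, p.P, 0.0)
        rec_tot += np.where(~intact, p.P, 0.0)

        outcome_d = intact & ~outcome_c
        if donor == "H":
            exits = np.zeros(n_reps, dtype=bool)
        elif donor == "L":
            exits = outcome_d
        else:  # M
            exits = outcome_d & (state == _S_PENDING)
            state = np.where(intact & outcome_c, _S_OK, state)
            state = np.where(outcome_d & (state == _S_OK), _S_PENDING, state)
        state = np.where(intact & (exits | exo_break), _S_BROKEN, state)

    def _mean_se(x: np.ndarray) -> tuple[float, float]:
        se = float(x.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
        return float(x.mean()), se

    dm, dse = _mean_se(donor_tot)
    rm, rse = _mean_se(rec_tot)
    return SimulationResult(dm, dse, rm, rse, n_reps)
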