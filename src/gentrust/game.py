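"""Single-round mechanics of the modified trust game.

A donor decides whether to entrust a resource to a recipient.  The
recipient decides whether to honor the trust (cooperate) and then
"nature" decides whether the undertaking succeeds, with success
probability ``a`` (the recipient's competence).  The donor observes only
the realized return, so a recipient who meant to cooperate but failed is
indistinguishable from one who defected: the round's public *history* is
``C`` only on cooperation-and-success and ``D`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PayoffParams",
    "GameConfig",
    "SubgameOutcome",
    "play_subgame",
    "expected_subgame_payoffs",
    "update_history",
]


@dataclass(frozen=True)
class PayoffParams:
    """Stage-game payoffs.

    Parameters
    ----------
    P : float
        Isolation payoff collected by a player with no active relationship.
    R : float
        Per-player payoff when trust is honored and the task succeeds
        (the augmented resource is split equally).
    T : float
        Temptation payoff a defecting recipient keeps for itself on success.

    The payoffs must satisfy ``T > R > P > 0`` and ``2R > T``, so that
    mutual cooperation is jointly efficient but defection tempts the
    recipient in any single round.
    """

    P: float = 1.0
    R: float = 4.0
    T: float = 6.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > 0):
            raise ValueError(
                f"payoffs must satisfy T > R > P > 0, got "
                f"T={self.T}, R={self.R}, P={self.P}"
            )
        if not (2 * self.R > self.T):
            raise ValueError(f"payoffs must satisfy 2R > T, got R={self.R}, T={self.T}")


@dataclass(frozen=True)
class GameConfig:
    """Repeated-game parameters.

    Parameters
    ----------
    a : float
        Competence: probability in [0, 1] that the recipient's undertaking
        succeeds, independent of its intention.
    d : float
        Exogenous dissolution probability per round: an intact relationship
        breaks for outside reasons with this probability after each round.
    n_rounds : int
        Finite horizon of the repeated game (no discounting).
    """

    a: float
    d: float = 0.1
    n_rounds: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"competence a must be in [0, 1], got {self.a}")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"dissolution probability d must be in [0, 1], got {self.d}")
        if self.n_rounds < 1:
            raise ValueError(f"n_rounds must be >= 1, got {self.n_rounds}")


@dataclass(frozen=True)
class SubgameOutcome:
    """Realized result of one sub-game round."""

    donor_payoff: float
    recipient_payoff: float
    history: str  # "C" or "D"; the round's publicly observable record


def update_history(cooperated: bool, succeeded: bool) -> str:
    """Public history symbol of a played round.

    ``C`` only when the recipient both intended to cooperate and
    succeeded; everything else — deliberate defection or an honest
    failure — is recorded ``D``.  The donor cannot tell the two apart.
    """
    return "C" if (cooperated and succeeded) else "D"


def play_subgame(
    trusted: bool,
    cooperated: bool,
    succeeded: bool,
    params: PayoffParams = PayoffParams(),
) -> SubgameOutcome:
    """Resolve one sub-game round with realized (not expected) payoffs.

    If the donor withholds trust both parties take the isolation payoff
    ``P`` and the round leaves no history mark (recorded ``D`` by the
    caller's convention never applies; history here reflects the played
    branch only when trust was given — an untrusted round keeps the
    recipient's standing unchanged, so callers should ignore ``history``
    in that case; we return ``"D"`` for definiteness).
    """
    if not trusted:
        return SubgameOutcome(params.P, params.P, "D")
    if not succeeded:
        return SubgameOutcome(0.0, 0.0, "D")
    if cooperated:
        return SubgameOutcome(params.R, params.R, "C")
    return SubgameOutcome(0.0, params.T, "D")


def expected_subgame_payoffs(
    donor_trusts: bool,
    recipient_cooperates: bool,
    a: float,
    params: PayoffParams = PayoffParams(),
) -> tuple[float, float]:
    """Expected (donor, recipient) payoffs of one round over the success draw.

    Trust plus cooperation yields ``(aR, aR)``; trust met with defection
    yields ``(0, aT)``; no trust yields ``(P, P)`` independent of ``a``.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"competence a must be in [0, 1], got {a}")
    if not donor_trusts:
        return (params.P, params.P)
    if recipient_cooperates:
        return (a * params.R, a * params.R)
    return (0.0, a * params.T)
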