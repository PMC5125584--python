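"""Nash-equilibrium and efficiency analysis of the entire repeated game.

The 3x2 bimatrix (donor rows H/M/L, recipient columns C/D) admits a
mixed equilibrium in which the donor randomizes over {H, M} and the
recipient over {C, D} whenever three conditions hold:

* ``C1``: the cooperation probability ``q_C = (d1-b1)/(a1-c1+d1-b1)``
  that makes the donor indifferent between H and M lies in (0, 1);
* ``C2``: at that ``q_C`` the donor's {H, M} payoff strictly exceeds the
  deviation payoff of L, i.e.
  ``[(d1-b1)(a1-e1) + (a1-c1)(b1-f1)] / (a1-c1+d1-b1) > 0``;
* ``C3``: the H-probability ``p_H = (c2-d2)/((c2-d2)+(b2-a2))`` that
  makes the recipient indifferent between C and D lies in (0, 1).

Three competence thresholds organize the phase structure: the Pareto /
C2 boundary (below it even mutual cooperation under H is dominated), the
cooperation threshold (where the recipient facing M starts preferring C)
and the uniqueness boundary (where (L, D) stops being a pure
equilibrium, leaving the mixed one alone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .game import GameConfig, PayoffParams
from .model1 import PayoffMatrix, payoff_matrix

__all__ = [
    "ConditionReport",
    "MixedEquilibrium",
    "EquilibriumReport",
    "REGIME_LABELS",
    "evaluate_conditions",
    "mixed_equilibrium",
    "pure_equilibria",
    "pareto_HC",
    "find_threshold",
    "classify_regime",
    "analyze_game",
]

REGIME_LABELS = (
    "only-LD-not-pareto",
    "only-LD-pareto",
    "LD-and-mixed",
    "mixed-only",
)

_DEGENERATE_EPS = 1e-12


@dataclass(frozen=True)
class ConditionReport:
    """Raw values and truth flags of the mixed-equilibrium conditions."""

    c1_value: float | None
    c1_holds: bool
    c2_value: float | None
    c2_holds: bool
    c3_value: float | None
    c3_holds: bool
    degenerate: list[str] = field(default_factory=list)

    @property
    def all_hold(self) -> bool:
        return self.c1_holds and self.c2_holds and self.c3_holds


@dataclass(frozen=True)
class MixedEquilibrium:
    """Mixing probabilities of the donor (over {H, M}) and recipient."""

    p_H: float  # probability the donor plays H (1 - p_H on M)
    q_C: float  # probability the recipient plays C


def evaluate_conditions(m: PayoffMatrix) -> ConditionReport:
    """Evaluate C1-C3 on a payoff matrix, flagging degenerate denominators."""
    degenerate: list[str] = []

    den1 = m.a1 - m.c1 + m.d1 - m.b1
    if abs(den1) < _DEGENERATE_EPS:
        degenerate.append("C1/C2 denominator a1-c1+d1-b1 is zero")
        c1_value = c2_value = None
        c1_holds = c2_holds = False
    else:
        c1_value = (m.d1 - m.b1) / den1
        c1_holds = 0.0 < c1_value < 1.0
        c2_value = ((m.d1 - m.b1) * (m.a1 - m.e1) + (m.a1 - m.c1) * (m.b1 - m.f1)) / den1
        c2_holds = c2_value > 0.0

    den3 = (m.c2 - m.d2) + (m.b2 - m.a2)
    if abs(den3) < _DEGENERATE_EPS:
        degenerate.append("C3 denominator (c2-d2)+(b2-a2) is zero")
        c3_value = None
        c3_holds = False
    else:
        c3_value = (m.c2 - m.d2) / den3
        c3_holds = 0.0 < c3_value < 1.0

    return ConditionReport(c1_value, c1_holds, c2_value, c2_holds, c3_value, c3_holds, degenerate)


def mixed_equilibrium(m: PayoffMatrix) -> MixedEquilibrium | None:
    """The {H, M} x {C, D} mixed equilibrium, or ``None`` if C1-C3 fail.

    ``q_C`` equalizes the donor's H and M payoffs; ``p_H`` equalizes the
    recipient's C and D payoffs.
    """
    report = evaluate_conditions(m)
    if not report.all_hold:
        return None
    assert report.c1_value is not None and report.c3_value is not None
    return MixedEquilibrium(p_H=report.c3_value, q_C=report.c1_value)


def pure_equilibria(m: PayoffMatrix, strict: bool = False) -> list[tuple[str, str]]:
    """All pure-strategy Nash cells of the 3x2 game by exhaustive check.

    With ``strict=False`` (default) ties count as best responses; with
    ``strict=True`` a cell qualifies only if each strategy is the unique
    best response.
    """
    donor = m.donor_payoffs()
    recipient = m.recipient_payoffs()
    rows, cols = ("H", "M", "L"), ("C", "D")
    result: list[tuple[str, str]] = []
    for i in range(3):
        for j in range(2):
            if strict:
                donor_br = all(donor[i, j] > donor[k, j] for k in range(3) if k != i)
                rec_br = all(recipient[i, j] > recipient[i, k] for k in range(2) if k != j)
            else:
                donor_br = donor[i, j] >= donor[:, j].max()
                rec_br = recipient[i, j] >= recipient[i, :].max()
            if donor_br and rec_br:
                result.append((rows[i], cols[j]))
    return result


def pareto_HC(m: PayoffMatrix) -> bool:
    """Whether the (H, C) outcome is Pareto efficient among the six cells.

    True iff no other cell weakly improves both totals with a strict
    improvement for at least one player.  With the default payoffs this
    reduces to ``aR > P``: below that, breaking up early (the L row)
    dominates sustained but unprofitable cooperation.
    """
    donor = m.donor_payoffs().ravel()
    recipient = m.recipient_payoffs().ravel()
    hc_d, hc_r = m.a1, m.a2
    for u1, u2 in zip(donor, recipient):
        if u1 >= hc_d and u2 >= hc_r and (u1 > hc_d or u2 > hc_r):
            return False
    return True


_CRITERIA = ("pareto", "cooperation", "uniqueness")


def _criterion_value(criterion: str, a: float, cfg: GameConfig, params: PayoffParams) -> float:
    m = payoff_matrix(GameConfig(a=a, d=cfg.d, n_rounds=cfg.n_rounds), params)
    if criterion == "pareto":
        value = evaluate_conditions(m).c2_value
        if value is None:
            raise ArithmeticError(f"degenerate C2 denominator at a={a}")
        return value
    if criterion == "cooperation":
        return m.c2 - m.d2
    if criterion == "uniqueness":
        return m.e2 - m.f2
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {_CRITERIA}")


def find_threshold(
    criterion: str,
    cfg: GameConfig = GameConfig(a=0.5),
    params: PayoffParams = PayoffParams(),
    tolerance: float = 1e-6,
    grid_points: int = 40,
) -> float:
    """Competence value where a regime indicator changes sign, by bisection.

    ``pareto`` locates the sign change of the C2 expression (the Pareto
    boundary of (H, C)); ``cooperation`` the root of ``c2 - d2`` (the
    recipient facing M switching to C); ``uniqueness`` the root of
    ``e2 - f2`` ((L, D) ceasing to be a pure equilibrium).  A grid
    pre-scan on (0, 1] locates the bracket; a missing sign change is an
    explicit error, never a guess.
    """
    grid = np.linspace(1e-6, 1.0, grid_points)
    values = [_criterion_value(criterion, a, cfg, params) for a in grid]
    bracket = None
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
        if flo == 0.0:
            return float(lo)
        if flo * fhi < 0:
            if bracket is not None:
                raise ArithmeticError(
                    f"criterion {criterion!r} changes sign more than once on (0, 1]"
                )
            bracket = (lo, hi)
    if bracket is None:
        raise ArithmeticError(f"criterion {criterion!r} has no sign change on (0, 1]")
    root = brentq(
        lambda a: _criterion_value(criterion, a, cfg, params),
        bracket[0],
        bracket[1],
        xtol=tolerance,
    )
    return float(root)


def classify_regime(
    a: float,
    cfg: GameConfig = GameConfig(a=0.5),
    params: PayoffParams = PayoffParams(),
) -> str:
    """Regime label at competence ``a``, derived from the equilibria themselves.

    The four phases are: (L, D) the only equilibrium with (H, C) Pareto
    dominated; (L, D) only but (H, C) efficient; (L, D) coexisting with
    the mixed equilibrium; and the mixed equilibrium alone.  Labels are
    computed from :func:`pure_equilibria`, :func:`mixed_equilibrium` and
    :func:`pareto_HC`, never from hard-coded competence cut-offs.
    """
    m = payoff_matrix(GameConfig(a=a, d=cfg.d, n_rounds=cfg.n_rounds), params)
    pure = pure_equilibria(m)
    mixed = mixed_equilibrium(m)
    ld_pure = ("L", "D") in pure
    if mixed is None:
        if not ld_pure:
            raise ArithmeticError(f"no equilibrium found at a={a}; unexpected payoff structure")
        return "only-LD-pareto" if pareto_HC(m) else "only-LD-not-pareto"
    return "LD-and-mixed" if ld_pure else "mixed-only"


@dataclass(frozen=True)
class EquilibriumReport:
    """Full analysis of the entire game at one competence level."""

    a: float
    matrix: PayoffMatrix
    conditions: ConditionReport
    pure: list[tuple[str, str]]
    mixed: MixedEquilibrium | None
    pareto_HC: bool
    regime: str
    thresholds: dict[str, float]

    def to_dict(self) -> dict:
        """JSON-serializable summary."""
        return {
            "a": self.a,
            "payoff_matrix": {
                f"{d}{r}": self.matrix.cell(d, r)
                for d in ("H", "M", "L")
                for r in ("C", "D")
            },
            "conditions": {
                "C1": {"value": self.conditions.c1_value, "holds": self.conditions.c1_holds},
                "C2": {"value": self.conditions.c2_value, "holds": self.conditions.c2_holds},
                "C3": {"value": self.conditions.c3_value, "holds": self.conditions.c3_holds},
                "degenerate": self.conditions.degenerate,
            },
            "pure_equilibria": [list(cell) for cell in self.pure],
            "mixed_equilibrium": (
                None if self.mixed is None else {"p_H": self.mixed.p_H, "q_C": self.mixed.q_C}
            ),
            "pareto_HC": self.pareto_HC,
            "regime": self.regime,
            "thresholds": self.thresholds,
        }


def analyze_game(
    a: float,
    cfg: GameConfig | None = None,
    params: PayoffParams = PayoffParams(),
    threshold_tolerance: float = 1e-6,
) -> EquilibriumReport:
    """One-stop analysis: matrix, conditions, equilibria, thresholds, regime."""
    base = cfg if cfg is not None else GameConfig(a=a)
    game_cfg = GameConfig(a=a, d=base.d, n_rounds=base.n_rounds)
    m = payoff_matrix(game_cfg, params)
    thresholds = {
        name: find_threshold(name, game_cfg, params, tolerance=threshold_tolerance)
        for name in _CRITERIA
    }
    return EquilibriumReport(
        a=a,
        matrix=m,
        conditions=evaluate_conditions(m),
        pure=pure_equilibria(m),
        mixed=mixed_equilibrium(m),
        pareto_HC=pareto_HC(m),
        regime=classify_regime(a, game_cfg, params),
        thresholds=thresholds,
    )
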