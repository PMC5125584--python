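"""Competence sweeps, trial aggregation and the simulated cooperation threshold.

A sweep runs independent trials of the evolutionary simulation on a grid
of competence values and aggregates final-state statistics.  "Final
state" is the mean over the last ``last_k`` generations (10 by default)
rather than the single last generation, which damps the mutation-driven
fluctuations of the imitation dynamics.  A grid value *sustains
cooperation* when the tail-mean recipient intention exceeds a cutoff
(0.5 by default) in a strict majority of trials; the simulated
cooperation threshold is the smallest such grid value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .abm import GenerationRecord, Population, SimConfig, run_trial

__all__ = [
    "SweepSummary",
    "ThresholdEstimate",
    "records_to_frame",
    "generation_metrics",
    "competence_sweep",
    "estimate_sim_threshold",
]


def records_to_frame(records: list[GenerationRecord]) -> pd.DataFrame:
    """Tidy per-generation table (one row per GenerationRecord)."""
    fields = list(GenerationRecord.__dataclass_fields__)
    return pd.DataFrame([{f: getattr(r, f) for f in fields} for r in records], columns=fields)


def generation_metrics(
    pop: Population,
    trial: int = 0,
    generation: int = 0,
    good_intent_min: float = 1.0,
) -> GenerationRecord:
    """Instantaneous metrics from one post-matching population snapshot.

    Isolation counts refer to the current pool: every unpaired recipient,
    and the subset with a good intention (``x >= good_intent_min``) but a
    bad (``D``) last-round history — would-be cooperators ostracized for
    an accidental failure.
    """
    shares = pop.policy_shares()
    pooled = pop.rec_partner < 0
    good_bad = pooled & ~pop.rec_history_c & (pop.rec_intent >= good_intent_min)
    return GenerationRecord(
        trial=trial,
        generation=generation,
        share_ST=shares["ST"],
        share_MG=shares["MG"],
        share_EG=shares["EG"],
        share_SG=shares["SG"],
        mean_intent=pop.mean_intent(),
        n_isolated_recipients=float(pooled.sum()),
        n_isolated_good_intent_bad_history=float(good_bad.sum()),
    )


@dataclass(frozen=True)
class SweepSummary:
    """Aggregated sweep results.

    ``per_trial`` has one row per (a, trial) with tail-mean final
    statistics; ``per_a`` aggregates mean and standard deviation across
    trials per competence value.
    """

    per_trial: pd.DataFrame
    per_a: pd.DataFrame
    last_k: int
    intent_cutoff: float

    @property
    def grid(self) -> list[float]:
        return sorted(self.per_a["a"].tolist())


_FINAL_COLS = ("final_intent", "final_ST", "final_MG", "final_EG", "final_SG")


def _aggregate(per_trial: pd.DataFrame, intent_cutoff: float) -> pd.DataFrame:
    rows = []
    for a, grp in per_trial.groupby("a"):
        row: dict[str, float] = {"a": float(a), "n_trials": len(grp)}
        for col in _FINAL_COLS:
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_sd"] = float(grp[col].std(ddof=0))
        row["frac_sustained"] = float((grp["final_intent"] > intent_cutoff).mean())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("a").reset_index(drop=True)


def competence_sweep(
    grid: list[float],
    cfg_template: SimConfig,
    trials: int,
    seed: int,
    last_k: int = 10,
    intent_cutoff: float = 0.5,
    good_intent_min: float = 1.0,
) -> SweepSummary:
    """Run ``trials`` independent trials of the simulation per grid value.

    One master seed spawns an independent RNG substream per (grid value,
    trial), so any sub-sweep is reproducible in isolation.  Per-trial
    final statistics are means over the last ``last_k`` generations.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if any(not 0.0 <= a <= 1.0 for a in grid):
        raise ValueError("grid values must lie in [0, 1]")
    streams = np.random.SeedSequence(seed).spawn(len(grid) * trials)
    rows = []
    for i, a in enumerate(grid):
        cfg = replace(cfg_template, a=a)
        for t in range(trials):
            rng = np.random.default_rng(streams[i * trials + t])
            records = run_trial(cfg, rng, trial_id=t, good_intent_min=good_intent_min)
            tail = records[-last_k:]
            rows.append(
                {
                    "a": a,
                    "trial": t,
                    "substream": i * trials + t,
                    "final_intent": float(np.mean([r.mean_intent for r in tail])),
                    "final_ST": float(np.mean([r.share_ST for r in tail])),
                    "final_MG": float(np.mean([r.share_MG for r in tail])),
                    "final_EG": float(np.mean([r.share_EG for r in tail])),
                    "final_SG": float(np.mean([r.share_SG for r in tail])),
                    "last_intent": records[-1].mean_intent,
                    "mean_isolated": float(np.mean([r.n_isolated_recipients for r in tail])),
                }
            )
    per_trial = pd.DataFrame(rows)
    return SweepSummary(
        per_trial=per_trial,
        per_a=_aggregate(per_trial, intent_cutoff),
        last_k=last_k,
        intent_cutoff=intent_cutoff,
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    """Smallest sustaining grid value with its bracketing interval."""

    value: float | None  # None when no grid value sustains cooperation
    bracket: tuple[float | None, float | None]
    all_sustain: bool
    none_sustain: bool

    def __str__(self) -> str:
        if self.none_sustain:
            return "no grid value sustains cooperation"
        lo = "grid start" if self.bracket[0] is None else f"{self.bracket[0]:g}"
        note = " (criterion holds on the whole grid)" if self.all_sustain else ""
        return f"threshold at {self.value:g}, bracketed by ({lo}, {self.value:g}]{note}"


def estimate_sim_threshold(
    summary: SweepSummary,
    intent_cutoff: float | None = None,
) -> ThresholdEstimate:
    """Smallest grid value sustaining cooperation in a majority of trials.

    The criterion is re-evaluated from the stored per-trial tail means,
    so raising ``intent_cutoff`` can only raise (never lower) the
    estimate.  When the criterion never holds, or holds on the whole
    grid, the boundary is reported explicitly rather than guessed.
    """
    cutoff = summary.intent_cutoff if intent_cutoff is None else intent_cutoff
    grid = summary.grid
    sustained = []
    for a in grid:
        grp = summary.per_trial[summary.per_trial["a"] == a]
        sustained.append(float((grp["final_intent"] > cutoff).mean()) > 0.5)
    if not any(sustained):
        return ThresholdEstimate(None, (grid[-1], None), False, True)
    idx = sustained.index(True)
    below = grid[idx - 1] if idx > 0 else None
    return ThresholdEstimate(grid[idx], (below, grid[idx]), all(sustained), False)
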