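"""Reference-label derivation and cohort descriptive statistics.

Binarization rules: a swallow is *unsafe* when its Penetration-Aspiration
Scale (PAS) score is 3-8 (1-2 = safe) and *inefficient* when post-swallow
residue fills at least 50% of the valleculae and/or the pyriform sinuses.
A participant is impaired on a consistency when at least one bolus of that
series is impaired ("at least one positive" roll-up).  PAS 8 (material
below the folds, no ejection response) additionally marks silent
aspiration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import BolusTrial, CohortDataset, Consistency, DataError, PROTOCOL_BOLUSES

__all__ = [
    "map_pas_to_safety",
    "map_residue_to_efficiency",
    "rollup_participant",
    "apply_stopping_rules",
    "participant_statuses",
    "prevalence_summary",
    "cumulative_detection_curve",
    "silent_aspiration_summary",
    "ParticipantStatus",
    "pct1",
    "PAS_EVENT_THRESHOLD",
    "SILENT_ASPIRATION_PAS",
    "RESIDUE_THRESHOLD_PCT",
    "OUTCOMES",
]

PAS_EVENT_THRESHOLD = 3
SILENT_ASPIRATION_PAS = 8
RESIDUE_THRESHOLD_PCT = 50.0
OUTCOMES = ("safety", "efficiency")


def pct1(n: int, total: int) -> float:
    """Percentage ``100*n/total`` rounded half-up to one decimal place."""
    if total == 0:
        return math.nan
    return math.floor(1000.0 * n / total + 0.5) / 10.0


def map_pas_to_safety(pas: Optional[int]) -> Optional[int]:
    """PAS 1-2 -> 0 (safe), PAS 3-8 -> 1 (unsafe), not-rateable -> None."""
    if pas is None:
        return None
    if pas not in range(1, 9):
        raise DataError(f"PAS must be in 1..8, got {pas}")
    return int(pas >= PAS_EVENT_THRESHOLD)


def map_residue_to_efficiency(
    vallecular_fill: Optional[float], pyriform_fill: Optional[float]
) -> Optional[int]:
    """Inefficient (1) iff either residue fill is >= 50%.

    When one space is not rateable, impairment can still be confirmed by the
    other space (>= 50% fill) but cannot be excluded; a sub-threshold single
    rating therefore yields a missing label.
    """
    fills = []
    for name, v in (("vallecular_fill", vallecular_fill), ("pyriform_fill", pyriform_fill)):
        if v is not None:
            if not (0.0 <= v <= 100.0):
                raise DataError(f"{name} must be in [0, 100], got {v}")
            fills.append(v)
    if any(v >= RESIDUE_THRESHOLD_PCT for v in fills):
        return 1
    if len(fills) == 2:
        return 0
    return None


def rollup_participant(labels: Sequence[Optional[int]]) -> Optional[int]:
    """'At least one positive' roll-up over a participant's bolus labels.

    Missing (not-rateable) labels are ignored; with no rateable label the
    participant status itself is missing.
    """
    rateable = [x for x in labels if x is not None]
    if not rateable:
        return None
    return int(any(x == 1 for x in rateable))


def apply_stopping_rules(trials: Sequence[BolusTrial]) -> list[BolusTrial]:
    """Truncate a protocol-ordered trial sequence per the safety rules.

    A penetration-aspiration event is a rateable PAS >= 3.  Testing of one
    consistency stops after its second event (the triggering bolus is kept);
    the whole protocol stops after the fifth event overall.
    """
    administered: list[BolusTrial] = []
    per_consistency: dict[Consistency, int] = {}
    total = 0
    for t in trials:
        if total >= 5:
            break
        if per_consistency.get(t.consistency, 0) >= 2:
            continue
        administered.append(t)
        if t.rating.pas is not None and t.rating.pas >= PAS_EVENT_THRESHOLD:
            per_consistency[t.consistency] = per_consistency.get(t.consistency, 0) + 1
            total += 1
    return administered


@dataclass(frozen=True)
class ParticipantStatus:
    participant_id: str
    consistency: Consistency
    safety_impaired: Optional[int]
    efficiency_impaired: Optional[int]
    silent_aspirator: Optional[int]
    n_rateable_safety: int
    n_rateable_efficiency: int

    def __post_init__(self):
        if self.silent_aspirator == 1 and self.safety_impaired != 1:
            raise DataError(
                f"{self.participant_id}: silent aspiration implies impaired safety"
            )


def participant_statuses(
    cohort: CohortDataset, consistency: Consistency
) -> dict[str, ParticipantStatus]:
    """Roll bolus labels up to one status record per participant."""
    out: dict[str, ParticipantStatus] = {}
    for pid, trials in cohort.by_participant(consistency).items():
        saf = [t.safety_label for t in trials]
        eff = [t.efficiency_label for t in trials]
        pas = [t.rating.pas for t in trials if t.rating.pas is not None]
        silent: Optional[int]
        if pas:
            silent = int(any(p == SILENT_ASPIRATION_PAS for p in pas))
        else:
            silent = None
        out[pid] = ParticipantStatus(
            participant_id=pid,
            consistency=consistency,
            safety_impaired=rollup_participant(saf),
            efficiency_impaired=rollup_participant(eff),
            silent_aspirator=silent,
            n_rateable_safety=sum(x is not None for x in saf),
            n_rateable_efficiency=sum(x is not None for x in eff),
        )
    return out


def _bolus_label(trial: BolusTrial, outcome: str) -> Optional[int]:
    return trial.safety_label if outcome == "safety" else trial.efficiency_label


def prevalence_summary(cohort: CohortDataset) -> pd.DataFrame:
    """Bolus- and participant-level impairment prevalence table.

    One row per consistency x outcome.  Denominators count rateable boluses
    and participants with at least one rateable bolus for that outcome;
    percentages are rounded half-up to one decimal.
    """
    rows = []
    for consistency in Consistency:
        trials = cohort.select(consistency)
        if not trials:
            continue
        statuses = participant_statuses(cohort, consistency)
        for outcome in OUTCOMES:
            labels = [_bolus_label(t, outcome) for t in trials]
            bolus_n = sum(x is not None for x in labels)
            bolus_impaired = sum(x == 1 for x in labels)
            st = [
                s.safety_impaired if outcome == "safety" else s.efficiency_impaired
                for s in statuses.values()
            ]
            part_n = sum(x is not None for x in st)
            part_impaired = sum(x == 1 for x in st)
            rows.append(
                {
                    "consistency": consistency.name,
                    "outcome": outcome,
                    "bolus_n": bolus_n,
                    "bolus_impaired_n": bolus_impaired,
                    "bolus_pct": pct1(bolus_impaired, bolus_n),
                    "participant_n": part_n,
                    "participant_impaired_n": part_impaired,
                    "participant_pct": pct1(part_impaired, part_n),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "consistency",
            "outcome",
            "bolus_n",
            "bolus_impaired_n",
            "bolus_pct",
            "participant_n",
            "participant_impaired_n",
            "participant_pct",
        ],
    )


def cumulative_detection_curve(
    cohort: CohortDataset,
    consistency: Consistency,
    outcome: str = "safety",
    series_length: Optional[int] = None,
) -> pd.DataFrame:
    """Cumulative fraction of participants first detected by bolus k.

    The denominator is the participants administered the complete bolus
    series for the consistency (``series_length``, defaulting to the
    protocol count): participants truncated by stopping rules or missing
    data have no defined status at later bolus numbers, so including them
    would bias the tail of the curve.  The numerator at k counts complete
    participants whose earliest impaired rateable bolus has index <= k.
    Returned percentages are rounded half-up to one decimal and are
    non-decreasing in k.
    """
    if series_length is None:
        series_length = PROTOCOL_BOLUSES[consistency]
    complete_first_pos: list[Optional[int]] = []
    for pid, trials in cohort.by_participant(consistency).items():
        if len(trials) != series_length:
            continue
        first = None
        for t in trials:
            if _bolus_label(t, outcome) == 1:
                first = t.bolus_index
                break
        complete_first_pos.append(first)
    denom = len(complete_first_pos)
    rows = []
    for k in range(1, series_length + 1):
        c = sum(1 for f in complete_first_pos if f is not None and f <= k)
        rows.append(
            {"bolus_index": k, "n_detected": c, "n_participants": denom,
             "cumulative_pct": pct1(c, denom)}
        )
    return pd.DataFrame(rows)


def silent_aspiration_summary(
    cohort: CohortDataset, consistency: Consistency
) -> tuple[int, float]:
    """(count, %) of participants with PAS 8 on >= 1 bolus of a consistency.

    The denominator is participants with at least one rateable PAS score.
    """
    statuses = participant_statuses(cohort, consistency)
    silent = [s.silent_aspirator for s in statuses.values()]
    denom = sum(x is not None for x in silent)
    count = sum(x == 1 for x in silent)
    return count, pct1(count, denom)
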