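"""Participant-level inclusion rules and the exclusion ledger.

A participant is kept only if they produced enough valid (non-omitted)
trials and judged the extreme morphs consistently.  Boundary semantics
are strict: exactly ``min_trials`` valid trials is included, exactly
``happy_floor`` at the positive extreme is included, and exactly
``angry_ceiling`` at the negative extreme is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from emobias.io import VALID_RESPONSES

REASON_TOO_FEW = "too_few_trials"
REASON_BIASED = "biased_extreme_responses"
REASON_NO_EXTREME = "no_extreme_trials"


@dataclass(frozen=True)
class QCDecision:
    """Inclusion decision for one participant; included iff no reasons."""

    participant_id: str
    n_valid_trials: int
    p_happy_at_plus80: float | None
    p_happy_at_minus80: float | None
    included: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "n_valid_trials": self.n_valid_trials,
            "p_happy_at_plus80": self.p_happy_at_plus80,
            "p_happy_at_minus80": self.p_happy_at_minus80,
            "included": self.included,
            "reasons": ";".join(self.reasons),
        }


def count_valid_trials(trials: pd.DataFrame) -> int:
    """Number of trials with a happy/angry judgment (omitted excluded)."""
    if len(trials) == 0:
        return 0
    _require_single_participant(trials)
    return int(trials["response"].isin(VALID_RESPONSES).sum())


def extreme_level_consistency(trials: pd.DataFrame,
                              extreme_level: int = 80,
                              ) -> tuple[float | None, float | None]:
    """Happy proportions at the +/- extreme morphs over valid trials.

    Returns ``(p_happy_at_plus, p_happy_at_minus)``; a level with no
    valid trials yields ``None`` — undefined is a value, not an error.
    """
    if len(trials) == 0:
        return None, None
    _require_single_participant(trials)
    valid = trials[trials["response"].isin(VALID_RESPONSES)]

    def proportion(level: int) -> float | None:
        at_level = valid[valid["morph_level"] == level]
        if len(at_level) == 0:
            return None
        return float((at_level["response"] == "happy").mean())

    return proportion(extreme_level), proportion(-extreme_level)


def apply_exclusions(trials: pd.DataFrame,
                     min_trials: int = 30,
                     happy_floor: float = 0.75,
                     angry_ceiling: float = 0.25,
                     extreme_level: int = 80) -> list[QCDecision]:
    """Apply the inclusion rules to every participant in a trial table.

    Exclusion triggers: fewer than ``min_trials`` valid trials; happy
    proportion at +extreme below ``happy_floor``; happy proportion at
    -extreme above ``angry_ceiling``; or an extreme level with no valid
    trials at all (the consistency check cannot be evaluated).  The
    returned ledger covers every participant exactly once.
    """
    decisions: list[QCDecision] = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        n_valid = count_valid_trials(sub)
        p_plus, p_minus = extreme_level_consistency(sub, extreme_level)
        reasons: list[str] = []
        if n_valid < min_trials:
            reasons.append(REASON_TOO_FEW)
        if p_plus is None or p_minus is None:
            reasons.append(REASON_NO_EXTREME)
        if (p_plus is not None and p_plus < happy_floor) or \
           (p_minus is not None and p_minus > angry_ceiling):
            reasons.append(REASON_BIASED)
        decisions.append(QCDecision(
            participant_id=str(pid), n_valid_trials=n_valid,
            p_happy_at_plus80=p_plus, p_happy_at_minus80=p_minus,
            included=not reasons, reasons=tuple(reasons)))
    return decisions


def decisions_frame(decisions: list[QCDecision]) -> pd.DataFrame:
    """Ledger as a flat table (CSV-ready)."""
    return pd.DataFrame([d.to_dict() for d in decisions],
                        columns=["participant_id", "n_valid_trials",
                                 "p_happy_at_plus80", "p_happy_at_minus80",
                                 "included", "reasons"])


def _require_single_participant(trials: pd.DataFrame) -> None:
    ids = trials["participant_id"].unique()
    if len(ids) > 1:
        raise ValueError(
            f"expected trials from one participant, got {len(ids)} ids")
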