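"""Health states of the decision tree.

The model distinguishes three mutually exclusive health states a child can
occupy at a medical visit: an acute exacerbation severe enough to require
hospitalization, an acute exacerbation managed in outpatient care, and a
symptom-free (controlled) state.  Every per-state vector in the package —
costs, probabilities, utilities — is ordered by :data:`STATE_ORDER`.
"""

from __future__ import annotations

import enum


class HealthState(str, enum.Enum):
    """One of the three health states of the decision tree."""

    HOSPITALIZATION = "hospitalization"
    OUTPATIENT_EXACERBATION = "outpatient_exacerbation"
    SYMPTOM_FREE = "symptom_free"

    @property
    def index(self) -> int:
        return STATE_ORDER.index(self)


#: Canonical ordering of states for all per-state vectors.
STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.HOSPITALIZATION,
    HealthState.OUTPATIENT_EXACERBATION,
    HealthState.SYMPTOM_FREE,
)

#: Number of health states.
N_STATES: int = len(STATE_ORDER)

STATE_LABELS: tuple[str, ...] = tuple(s.value for s in STATE_ORDER)
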