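"""Status vocabulary shared across the cohort pipeline.

A cohort net is observed at each survey round with one of three field
codes (present / not found / discarded); cleaning introduces two more
(unsurveyed rounds and genuinely ambiguous cells left for the Bayesian
sampler).  Attrition causes fall into two families: "not found" losses
(given away, stolen, exchanged) whose ultimate fate is unknown, and
"discard" losses (damaged and discarded, repurposed) which are terminal
wear-and-tear outcomes.
"""

from __future__ import annotations

import enum


class NetStatus(str, enum.Enum):
    """Per-net per-round status in the cohort matrix."""

    PRESENT = "PRESENT"
    DISCARDED = "DISCARDED"
    NOT_FOUND = "NOT_FOUND"
    UNKNOWN = "UNKNOWN"
    UNSURVEYED = "UNSURVEYED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Integer codes used internally for vectorised matrix operations.
STATUS_CODE = {
    NetStatus.PRESENT: 0,
    NetStatus.DISCARDED: 1,
    NetStatus.NOT_FOUND: 2,
    NetStatus.UNKNOWN: 3,
    NetStatus.UNSURVEYED: 4,
}
CODE_STATUS = {v: k for k, v in STATUS_CODE.items()}

# Attrition cause labels (the five categories recorded in the field).
GIVEN_AWAY = "given_away"
STOLEN = "stolen"
EXCHANGED = "exchanged"
DAMAGED_DISCARDED = "damaged_discarded"
REPURPOSED = "repurposed"

#: Fixed cause ordering used for weight vectors and report tables.
CAUSES = (GIVEN_AWAY, STOLEN, EXCHANGED, DAMAGED_DISCARDED, REPURPOSED)

#: Causes whose observed status is NOT_FOUND (net left the household,
#: fate unknown — excluded from the survival-rate denominator).
NOT_FOUND_CAUSES = frozenset({GIVEN_AWAY, STOLEN, EXCHANGED})

#: Causes whose observed status is DISCARDED (wear-and-tear loss —
#: excluded from the retention-rate denominator).
DISCARD_CAUSES = frozenset({DAMAGED_DISCARDED, REPURPOSED})

#: Default survey rounds, in months after distribution.
DEFAULT_ROUNDS = (6, 12, 24, 36)
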