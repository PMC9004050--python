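"""Proportionate hole index (pHI) and physical-condition classification.

The pHI approximates the damaged surface area of a net from counts of
holes in four WHO diameter classes (size 1: 0.5-2 cm, size 2: 2-10 cm,
size 3: 10-25 cm, size 4: > 25 cm):

    pHI = n1 + 23 * n2 + 196 * n3 + 576 * n4

Nets are classified Good (pHI <= 64), Damaged (65 <= pHI <= 642) or
Torn (pHI > 642); a net is *serviceable* unless it is Torn.  The weights
and thresholds are the WHO scheme and are deliberately hard-coded, not
configurable: they define the metric.

Holes measured at exactly 2, 10 or 25 cm sit on class boundaries; field
protocols assign them to a class before counting, so this module only
ever sees per-class counts and never resolves the boundary itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: WHO weights for hole size classes 1-4 (approximate cm^2 per hole).
PHI_WEIGHTS = (1, 23, 196, 576)

#: Upper pHI bound for the "Good" category.
GOOD_MAX = 64

#: Upper pHI bound for serviceability ("Damaged" but usable).
SERVICEABLE_MAX = 642

#: Observation-file columns holding per-class hole counts.
HOLE_COLUMNS = ("holes_size1", "holes_size2", "holes_size3", "holes_size4")


class ConditionCategory(str, enum.Enum):
    GOOD = "GOOD"
    DAMAGED = "DAMAGED"
    TORN = "TORN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class HoleCounts:
    """Hole counts per WHO size class for one net at one round."""

    size1: int
    size2: int
    size3: int
    size4: int

    def __post_init__(self) -> None:
        for name in ("size1", "size2", "size3", "size4"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"hole count {name}={v!r} must be a nonnegative integer")


def compute_phi(holes: HoleCounts) -> int:
    """Weighted hole count approximating damaged surface area (cm^2)."""
    return int(
        holes.size1 * PHI_WEIGHTS[0]
        + holes.size2 * PHI_WEIGHTS[1]
        + holes.size3 * PHI_WEIGHTS[2]
        + holes.size4 * PHI_WEIGHTS[3]
    )


def classify_condition(phi: int) -> ConditionCategory:
    """Good / Damaged / Torn category for a pHI value."""
    if phi < 0:
        raise ValueError(f"pHI must be nonnegative, got {phi}")
    if phi <= GOOD_MAX:
        return ConditionCategory.GOOD
    if phi <= SERVICEABLE_MAX:
        return ConditionCategory.DAMAGED
    return ConditionCategory.TORN


def is_serviceable(phi: int) -> bool:
    """True when the net is still usable, i.e. not Torn (pHI <= 642)."""
    if phi < 0:
        raise ValueError(f"pHI must be nonnegative, got {phi}")
    return phi <= SERVICEABLE_MAX


def phi_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Compute pHI, condition and serviceability for observation rows.

    Rows without hole counts (absent nets, unvisited rounds) are dropped.
    Returns a frame with net_id, round, phi, condition, serviceable.
    """
    obs = observations.dropna(subset=list(HOLE_COLUMNS))
    counts = obs[list(HOLE_COLUMNS)].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        bad = obs.index[(counts < 0).any(axis=1)].tolist()
        raise ValueError(f"negative hole counts at rows {bad}")
    phi = counts @ np.asarray(PHI_WEIGHTS, dtype=np.int64)
    condition = np.where(
        phi <= GOOD_MAX,
        ConditionCategory.GOOD.value,
        np.where(phi <= SERVICEABLE_MAX, ConditionCategory.DAMAGED.value, ConditionCategory.TORN.value),
    )
    return pd.DataFrame(
        {
            "net_id": obs["net_id"].to_numpy(),
            "round": obs["round"].to_numpy(),
            "phi": phi,
            "condition": condition,
            "serviceable": phi <= SERVICEABLE_MAX,
        }
    )
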