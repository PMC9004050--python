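import numpy as np
import pandas as pd
import pytest

from llinsurv.matrix import CohortMatrix
from llinsurv.statuses import STATUS_CODE, NetStatus

#: Compact trajectory notation used throughout the tests.
CHAR_STATUS = {
    "P": NetStatus.PRESENT,
    "D": NetStatus.DISCARDED,
    "N": NetStatus.NOT_FOUND,
    "U": NetStatus.UNKNOWN,
    "-": NetStatus.UNSURVEYED,
}


def traj_matrix(trajectories, reasons=None, rounds=(6, 12, 24, 36), households=None):
    """Build a CohortMatrix from strings like 'PPDN' (one char per round).

    '-' marks an unvisited round; every other cell counts as observed.
    ``reasons`` maps (net_index, round_index) -> cause label.
    """
    n = len(trajectories)
    k = len(rounds)
    status = np.empty((n, k), dtype=np.int8)
    for i, t in enumerate(trajectories):
        assert len(t) == k, f"trajectory {t!r} needs {k} characters"
        status[i] = [STATUS_CODE[CHAR_STATUS[c]] for c in t]
    reason = np.full((n, k), "", dtype=object)
    for (i, j), cause in (reasons or {}).items():
        reason[i, j] = cause
    observed = status != STATUS_CODE[NetStatus.UNSURVEYED]
    if households is None:
        households = [f"H{i:03d}" for i in range(n)]
    return CohortMatrix(
        net_ids=np.array([f"N{i:03d}" for i in range(n)], dtype=object),
        household_ids=np.array(households, dtype=object),
        rounds=tuple(rounds),
        status=status,
        reason=reason,
        observed=observed,
    )


def roster_for(matrix, brand="A", zone="urban"):
    """Minimal roster matching a trajectory matrix."""
    n = matrix.n_nets
    brands = [brand] * n if isinstance(brand, str) else list(brand)
    zones = [zone] * n if isinstance(zone, str) else list(zone)
    return pd.DataFrame(
        {
            "net_id": matrix.net_ids,
            "household_id": matrix.household_ids,
            "brand": brands,
            "zone": zones,
            "dist_date": "2014-11-15",
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A ~450-net two-brand cohort with ambiguity and missingness."""
    from llinsurv.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        seed=42,
        n_households=300,
        nets_per_household_mean=1.5,
        brands={"A": (0.97, 0.9, 0.85, 0.9), "B": (0.95, 0.8, 0.7, 0.8)},
        household_sd=0.4,
        zone_log_odds=0.5,
        missingness=(0.0, 0.1, 0.2, 0.4),
    )
    roster, obs, params = simulate_cohort(cfg)
    return cfg, roster, obs, params
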