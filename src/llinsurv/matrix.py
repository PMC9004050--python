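"""Nets x rounds status matrix and monotone cleaning rules.

Raw round observations are reorganised into a matrix with one row per
cohort net (keyed by household ID and net ID) and one column per survey
round.  Three deterministic cleaning rules are then applied, in a fixed
order:

1. **backfill_presence** — a net registered present at some round must
   have been present at all earlier rounds, even if it was not seen
   then; earlier UNSURVEYED / NOT_FOUND / UNKNOWN cells become PRESENT.
2. **forward_discard** — a net recorded as discarded (destroyed or
   repurposed) stays discarded: discard is an absorbing state, and all
   later cells become DISCARDED.
3. **mark_unknown** — a NOT_FOUND report that precedes a later
   DISCARDED report is genuinely ambiguous (the net may already have
   been destroyed, or still present); such cells become UNKNOWN and are
   left for the Bayesian sampler to impute.

Raw data in which a net is PRESENT after a DISCARDED record violates
the absorbing state and is surfaced as an error, never silently
repaired.  The pipeline is idempotent.

Rounds at which a household was not visited are UNSURVEYED; they are
excluded from survey denominators downstream.  (An alternative reading
would lump them with NOT_FOUND; we keep them distinct so that
missingness never inflates attrition.)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .statuses import CODE_STATUS, STATUS_CODE, NetStatus

_PRESENT = STATUS_CODE[NetStatus.PRESENT]
_DISCARDED = STATUS_CODE[NetStatus.DISCARDED]
_NOT_FOUND = STATUS_CODE[NetStatus.NOT_FOUND]
_UNKNOWN = STATUS_CODE[NetStatus.UNKNOWN]
_UNSURVEYED = STATUS_CODE[NetStatus.UNSURVEYED]

#: Statuses that may appear in raw field observations.
RAW_STATUSES = {NetStatus.PRESENT.value, NetStatus.DISCARDED.value, NetStatus.NOT_FOUND.value}

_ABSENT_CODES = (_DISCARDED, _NOT_FOUND, _UNKNOWN)


class ReferentialIntegrityError(ValueError):
    """Observation refers to a net absent from the roster."""


class DuplicateObservationError(ValueError):
    """More than one observation for the same (net, round) cell."""


class InconsistentTrajectoryError(ValueError):
    """A net is PRESENT after a DISCARDED record (absorbing-state violation)."""


@dataclass
class CohortMatrix:
    """Status lattice for a net cohort.

    Attributes
    ----------
    net_ids, household_ids : per-row identifiers (aligned arrays).
    rounds : ordered round labels (months).
    status : (n_nets, n_rounds) integer status codes (see STATUS_CODE).
    reason : (n_nets, n_rounds) attrition cause labels ('' when none).
    observed : True where the household was actually visited and the
        net's status recorded; survey denominators count these cells.
    filled : True where a cleaning rule changed the cell.
    """

    net_ids: np.ndarray
    household_ids: np.ndarray
    rounds: tuple
    status: np.ndarray
    reason: np.ndarray
    observed: np.ndarray
    filled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.filled is None:
            self.filled = np.zeros_like(self.observed, dtype=bool)

    @property
    def n_nets(self) -> int:
        return len(self.net_ids)

    def copy(self) -> "CohortMatrix":
        return replace(
            self,
            status=self.status.copy(),
            reason=self.reason.copy(),
            observed=self.observed.copy(),
            filled=self.filled.copy(),
        )

    def round_index(self, round_label) -> int:
        try:
            return self.rounds.index(round_label)
        except ValueError:
            raise KeyError(f"round {round_label!r} not in matrix rounds {self.rounds}") from None

    def statuses_of(self, net_id) -> list[NetStatus]:
        i = int(np.flatnonzero(self.net_ids == net_id)[0])
        return [CODE_STATUS[c] for c in self.status[i]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: net_id, household_id, round, status, reason, flags."""
        n, k = self.status.shape
        return pd.DataFrame(
            {
                "household_id": np.repeat(self.household_ids, k),
                "net_id": np.repeat(self.net_ids, k),
                "round": np.tile(np.asarray(self.rounds), n),
                "status": [CODE_STATUS[c].value for c in self.status.ravel()],
                "reason": self.reason.ravel(),
                "observed": self.observed.ravel(),
                "imputed_flag": self.filled.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortMatrix":
        """Rebuild a matrix from its long-format file representation."""
        rounds = tuple(sorted(frame["round"].unique()))
        pivot = frame.pivot(index=["household_id", "net_id"], columns="round")
        status_str = pivot["status"][list(rounds)].to_numpy()
        status = np.vectorize(lambda s: STATUS_CODE[NetStatus(s)])(status_str)
        reason = pivot["reason"][list(rounds)].fillna("").to_numpy(dtype=object)
        observed = pivot["observed"][list(rounds)].to_numpy(dtype=bool)
        filled = (
            pivot["imputed_flag"][list(rounds)].to_numpy(dtype=bool)
            if "imputed_flag" in frame.columns
            else None
        )
        hh, nets = zip(*pivot.index)
        return cls(
            net_ids=np.asarray(nets, dtype=object),
            household_ids=np.asarray(hh, dtype=object),
            rounds=rounds,
            status=status.astype(np.int8),
            reason=reason,
            observed=observed,
            filled=filled,
        )


def build_matrix(
    roster: pd.DataFrame, observations: pd.DataFrame, rounds=None
) -> CohortMatrix:
    """Reorganise raw observations into a nets x rounds matrix.

    Every roster net gets a row; (net, round) pairs with no observation
    are UNSURVEYED.  Observations for nets not in the roster, duplicate
    cells, and status codes outside the raw vocabulary are errors.
    """
    if roster["net_id"].duplicated().any():
        dups = roster.loc[roster["net_id"].duplicated(), "net_id"].tolist()
        raise DuplicateObservationError(f"duplicate net IDs in roster: {dups}")

    if rounds is None:
        rounds = tuple(sorted(observations["round"].unique()))
    else:
        rounds = tuple(rounds)
        extra = set(observations["round"].unique()) - set(rounds)
        if extra:
            raise ValueError(f"observations contain unconfigured rounds: {sorted(extra)}")

    bad_status = set(observations["status"].unique()) - RAW_STATUSES
    if bad_status:
        raise ValueError(f"raw status codes outside vocabulary: {sorted(bad_status)}")

    net_ids = roster["net_id"].to_numpy(dtype=object)
    orphans = set(observations["net_id"]) - set(net_ids)
    if orphans:
        raise ReferentialIntegrityError(
            f"observations for nets not in roster: {sorted(orphans)}"
        )
    dup = observations.duplicated(subset=["net_id", "round"], keep=False)
    if dup.any():
        keys = observations.loc[dup, ["net_id", "round"]].drop_duplicates()
        raise DuplicateObservationError(
            "duplicate (net, round) observations: "
            + ", ".join(f"({r.net_id}, {r.round})" for r in keys.itertuples())
        )

    n, k = len(net_ids), len(rounds)
    row_of = {nid: i for i, nid in enumerate(net_ids)}
    col_of = {r: j for j, r in enumerate(rounds)}

    status = np.full((n, k), _UNSURVEYED, dtype=np.int8)
    reason = np.full((n, k), "", dtype=object)
    observed = np.zeros((n, k), dtype=bool)

    rows = observations["net_id"].map(row_of).to_numpy()
    cols = observations["round"].map(col_of).to_numpy()
    status[rows, cols] = [
        STATUS_CODE[NetStatus(s)] for s in observations["status"]
    ]
    reason[rows, cols] = observations["reason"].fillna("").to_numpy(dtype=object)
    observed[rows, cols] = True

    return CohortMatrix(
        net_ids=net_ids,
        household_ids=roster["household_id"].to_numpy(dtype=object),
        rounds=rounds,
        status=status,
        reason=reason,
        observed=observed,
    )


def _check_absorbing(status: np.ndarray, net_ids: np.ndarray) -> None:
    """Raise if any net is PRESENT at a later round than a DISCARDED record."""
    has_disc = (status == _DISCARDED).any(axis=1)
    first_disc = np.argmax(status == _DISCARDED, axis=1)
    last_pres = np.where(
        (status == _PRESENT).any(axis=1),
        status.shape[1] - 1 - np.argmax(status[:, ::-1] == _PRESENT, axis=1),
        -1,
    )
    bad = has_disc & (last_pres > first_disc)
    if bad.any():
        raise InconsistentTrajectoryError(
            "net(s) PRESENT after a DISCARDED record: "
            + ", ".join(map(str, net_ids[bad]))
        )


def backfill_presence(matrix: CohortMatrix) -> CohortMatrix:
    """Make every cell before a PRESENT cell PRESENT."""
    m = matrix.copy()
    _check_absorbing(m.status, m.net_ids)
    has_pres = (m.status == _PRESENT).any(axis=1)
    last_pres = np.where(
        has_pres,
        m.status.shape[1] - 1 - np.argmax(m.status[:, ::-1] == _PRESENT, axis=1),
        -1,
    )
    cols = np.arange(m.status.shape[1])
    target = (cols[None, :] < last_pres[:, None]) & (m.status != _PRESENT)
    m.filled |= target
    m.reason[target] = ""
    m.status[target] = _PRESENT
    return m


def forward_discard(matrix: CohortMatrix) -> CohortMatrix:
    """Propagate the absorbing DISCARDED state to all later rounds."""
    m = matrix.copy()
    _check_absorbing(m.status, m.net_ids)
    has_disc = (m.status == _DISCARDED).any(axis=1)
    first_disc = np.where(has_disc, np.argmax(m.status == _DISCARDED, axis=1), m.status.shape[1])
    cols = np.arange(m.status.shape[1])
    target = (cols[None, :] > first_disc[:, None]) & (m.status != _DISCARDED)
    m.filled |= target
    m.status[target] = _DISCARDED
    # reason stays with the first terminal cell only
    later = cols[None, :] > first_disc[:, None]
    m.reason[later & (m.status == _DISCARDED)] = ""
    return m


def mark_unknown(matrix: CohortMatrix) -> CohortMatrix:
    """Turn NOT_FOUND cells that precede a DISCARDED cell into UNKNOWN.

    Whether such a net was already destroyed at the NOT_FOUND round, or
    still present, cannot be decided from the data; the survival model
    imputes these cells.
    """
    m = matrix.copy()
    has_disc = (m.status == _DISCARDED).any(axis=1)
    first_disc = np.where(has_disc, np.argmax(m.status == _DISCARDED, axis=1), -1)
    cols = np.arange(m.status.shape[1])
    target = (m.status == _NOT_FOUND) & has_disc[:, None] & (cols[None, :] < first_disc[:, None])
    m.status[target] = _UNKNOWN
    return m


def clean(matrix: CohortMatrix) -> CohortMatrix:
    """Full cleaning pipeline: backfill -> forward discard -> mark unknown."""
    return mark_unknown(forward_discard(backfill_presence(matrix)))


def net_causes(matrix: CohortMatrix) -> np.ndarray:
    """First recorded attrition cause per net ('' if none recorded).

    The cause is read from the earliest absent cell that carries a
    reason label; later repeated reports never override it.
    """
    n, k = matrix.status.shape
    causes = np.full(n, "", dtype=object)
    absent = np.isin(matrix.status, _ABSENT_CODES)
    has_reason = absent & (matrix.reason != "")
    rows_any = has_reason.any(axis=1)
    first = np.argmax(has_reason, axis=1)
    causes[rows_any] = matrix.reason[np.flatnonzero(rows_any), first[rows_any]]
    return causes
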