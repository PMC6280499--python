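"""Dual-reviewer consensus workflow.

Each event is rated independently by a pharmacist and a physician under
each assessment method. Concordant pairs are final. Discordant pairs are
resolved by the raters' recorded discussion outcome; if no discussion
outcome exists, a third reviewer's adjudication is used. Discussion and
adjudication outcomes are *inputs* (a resolutions table) — they record
human judgments and are never synthesised here.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import pandas as pd

from .algorithm import Rating
from .errors import RecordValidationError, UnresolvedCaseError

__all__ = [
    "Method",
    "RaterRole",
    "ConsensusPath",
    "AssessmentRecord",
    "ConsensusRecord",
    "resolve",
    "consensus_dataset",
]

log = logging.getLogger(__name__)


class Method(str, enum.Enum):
    BEST_PRACTICE = "BEST_PRACTICE"
    ERROR_BASED = "ERROR_BASED"
    ALGORITHM = "ALGORITHM"


class RaterRole(str, enum.Enum):
    PHARMACIST = "PHARMACIST"
    PHYSICIAN = "PHYSICIAN"
    ADJUDICATOR = "ADJUDICATOR"


class ConsensusPath(str, enum.Enum):
    CONCORDANT = "CONCORDANT"
    DISCUSSED = "DISCUSSED"
    ADJUDICATED = "ADJUDICATED"


@dataclass(frozen=True)
class AssessmentRecord:
    """One rater's rating of one event under one method."""

    event_id: str
    rater_id: str
    rater_role: RaterRole
    method: Method
    rating: Rating


@dataclass(frozen=True)
class ConsensusRecord:
    """Final per-event, per-method rating and how it was reached."""

    event_id: str
    method: Method
    final_rating: Rating
    path: ConsensusPath


def resolve(
    r1: AssessmentRecord,
    r2: AssessmentRecord,
    discussion_rating: Rating | None = None,
    adjudication_rating: Rating | None = None,
) -> ConsensusRecord:
    """Reconcile one rater pair into a consensus record.

    A concordant pair is final as-is (any supplied resolution values are
    ignored). A discordant pair takes the discussion outcome when present,
    else the adjudication outcome; with neither, the case is unresolved.
    The result is symmetric in (r1, r2).
    """
    if r1.event_id != r2.event_id or r1.method != r2.method:
        raise RecordValidationError(
            f"records do not share event/method: ({r1.event_id!r}, {r1.method}) "
            f"vs ({r2.event_id!r}, {r2.method})"
        )
    if r1.rater_id == r2.rater_id:
        raise RecordValidationError(
            f"event {r1.event_id!r}: both records are from rater {r1.rater_id!r}"
        )
    if r1.rating == r2.rating:
        return ConsensusRecord(r1.event_id, r1.method, r1.rating, ConsensusPath.CONCORDANT)
    if discussion_rating is not None:
        return ConsensusRecord(r1.event_id, r1.method, discussion_rating, ConsensusPath.DISCUSSED)
    if adjudication_rating is not None:
        return ConsensusRecord(r1.event_id, r1.method, adjudication_rating, ConsensusPath.ADJUDICATED)
    raise UnresolvedCaseError([(r1.event_id, r1.method.value)])


def consensus_dataset(
    assessments: pd.DataFrame, resolutions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Build the consensus table for a whole assessment dataset.

    ``assessments`` columns: event_id, rater_id, rater_role, method, rating.
    ``resolutions`` columns: event_id, method, discussion_rating,
    adjudication_rating (blank/NA allowed). Adjudicator rows in
    ``assessments`` are ignored; every (event, method) must carry exactly
    two primary ratings.

    Returns one row per (event_id, method) with final_rating and path;
    path counts are logged.
    """
    prim = assessments[assessments["rater_role"] != RaterRole.ADJUDICATOR.value]
    sizes = prim.groupby(["event_id", "method"], sort=False).size()
    bad = sizes[sizes != 2]
    if len(bad):
        raise RecordValidationError(
            "each (event, method) needs exactly two primary ratings; violations: "
            + ", ".join(f"{e}/{m}×{n}" for (e, m), n in bad.head(10).items())
        )
    pairs = (
        prim.sort_values(["event_id", "method", "rater_id"], kind="stable")
        .groupby(["event_id", "method"], sort=False)["rating"]
        .agg(rating_a="first", rating_b="last")
        .reset_index()
    )
    if resolutions is not None and len(resolutions):
        pairs = pairs.merge(resolutions, on=["event_id", "method"], how="left")
    else:
        pairs["discussion_rating"] = pd.NA
        pairs["adjudication_rating"] = pd.NA

    concordant = pairs["rating_a"] == pairs["rating_b"]
    has_disc = pairs["discussion_rating"].notna() & (pairs["discussion_rating"] != "")
    has_adj = pairs["adjudication_rating"].notna() & (pairs["adjudication_rating"] != "")
    unresolved = ~concordant & ~has_disc & ~has_adj
    if unresolved.any():
        raise UnresolvedCaseError(
            list(pairs.loc[unresolved, ["event_id", "method"]].itertuples(index=False, name=None))
        )

    final = pairs["rating_a"].where(
        concordant,
        pairs["discussion_rating"].where(has_disc, pairs["adjudication_rating"]),
    )
    path = pd.Series(ConsensusPath.DISCUSSED.value, index=pairs.index)
    path[concordant] = ConsensusPath.CONCORDANT.value
    path[~concordant & ~has_disc] = ConsensusPath.ADJUDICATED.value

    out = pd.DataFrame(
        {
            "event_id": pairs["event_id"],
            "method": pairs["method"],
            "final_rating": final,
            "path": path,
        }
    )
    log.info("consensus paths: %s", out["path"].value_counts().to_dict())
    return out
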