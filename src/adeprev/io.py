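"""Readers and writers for the pipeline's delimited-text formats.

All tabular files are comma-separated UTF-8 with a header row:

- ratings:      event_id, rater_id, rater_role, method, rating
- forms:        event_id, rater_id, then one column per criterion id
                (1, 1a, 2, ..., 9, 9a, ..., 18; a leading "Q"/"q" on the
                header is accepted), values YES/NO/UNCERTAIN
- resolutions:  event_id, method, discussion_rating, adjudication_rating
                (blank where not applicable)

Forms also round-trip through a nested JSON representation in which each
gate question carries its follow-up inline.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .algorithm import ALL_IDS, GATES, Rating, Response, ResponseForm
from .consensus import Method, RaterRole
from .errors import RecordValidationError
from .errors import FormValidationError

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_forms",
    "write_forms",
    "read_resolutions",
    "write_resolutions",
    "forms_to_records",
    "records_to_frame",
    "write_forms_json",
    "read_forms_json",
]

log = logging.getLogger(__name__)

_RATING_NAMES = {r.name for r in Rating}
_RESPONSE_NAMES = {r.value for r in Response}

RATINGS_COLUMNS = ["event_id", "rater_id", "rater_role", "method", "rating"]
RESOLUTIONS_COLUMNS = ["event_id", "method", "discussion_rating", "adjudication_rating"]


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise RecordValidationError(f"{path}: missing columns {missing}")


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Load an assessment-ratings file; ratings/roles/methods are validated
    and upper-cased."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(frame, RATINGS_COLUMNS, path)
    frame = frame[RATINGS_COLUMNS].copy()
    for col in ("rater_role", "method", "rating"):
        frame[col] = frame[col].str.strip().str.upper()
    bad = ~frame["rating"].isin(_RATING_NAMES)
    if bad.any():
        row = int(frame.index[bad][0]) + 2  # header line is 1
        raise RecordValidationError(
            f"{path}: line {row}: rating {frame['rating'][bad].iloc[0]!r} is not "
            f"one of {sorted(_RATING_NAMES)}"
        )
    for col, allowed in (("rater_role", RaterRole), ("method", Method)):
        names = {m.value for m in allowed}
        bad = ~frame[col].isin(names)
        if bad.any():
            row = int(frame.index[bad][0]) + 2
            raise RecordValidationError(
                f"{path}: line {row}: {col} {frame[col][bad].iloc[0]!r} is not "
                f"one of {sorted(names)}"
            )
    return frame


def write_ratings(frame: pd.DataFrame, path: str | Path) -> None:
    frame[RATINGS_COLUMNS].to_csv(path, index=False)


def _canonical_criterion(col: str) -> str | None:
    cid = col.strip().lower().removeprefix("q")
    return cid if cid in ALL_IDS else None


def read_forms(path: str | Path, invert: tuple[str, ...] = ()) -> pd.DataFrame:
    """Load a criterion-response file.

    ``invert`` names criterion ids recorded in the opposite polarity (e.g.
    a form asking whether a re-exposure was *appropriate* rather than
    inappropriate): their YES/NO answers are swapped on read, with the
    normalisation logged. Unknown criterion columns are a hard error.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(frame, ["event_id", "rater_id"], path)
    rename, unknown = {}, []
    for col in frame.columns:
        if col in ("event_id", "rater_id"):
            continue
        cid = _canonical_criterion(col)
        if cid is None:
            unknown.append(col)
        else:
            rename[col] = cid
    if unknown:
        raise FormValidationError(f"{path}: unknown criterion columns {unknown}")
    frame = frame.rename(columns=rename)
    missing = [cid for cid in ALL_IDS if cid not in frame.columns]
    if missing:
        raise FormValidationError(f"{path}: missing criterion columns {missing}")
    for cid in ALL_IDS:
        frame[cid] = frame[cid].str.strip().str.upper()
        bad = ~frame[cid].isin(_RESPONSE_NAMES)
        if bad.any():
            row = int(frame.index[bad][0]) + 2
            raise FormValidationError(
                f"{path}: line {row}: criterion {cid}: response "
                f"{frame[cid][bad].iloc[0]!r} is not one of YES/NO/UNCERTAIN"
            )
    for cid in invert:
        if cid not in ALL_IDS:
            raise FormValidationError(f"cannot invert unknown criterion {cid!r}")
        frame[cid] = frame[cid].map(
            {"YES": "NO", "NO": "YES", "UNCERTAIN": "UNCERTAIN"}
        )
        log.info("%s: inverted polarity of criterion %s on read", path, cid)
    return frame[["event_id", "rater_id", *ALL_IDS]]


def write_forms(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["event_id", "rater_id", *ALL_IDS]].to_csv(path, index=False)


def read_resolutions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(frame, RESOLUTIONS_COLUMNS, path)
    frame = frame[RESOLUTIONS_COLUMNS].copy()
    frame["method"] = frame["method"].str.strip().str.upper()
    for col in ("discussion_rating", "adjudication_rating"):
        frame[col] = frame[col].str.strip().str.upper()
        bad = ~frame[col].isin(_RATING_NAMES | {""})
        if bad.any():
            row = int(frame.index[bad][0]) + 2
            raise RecordValidationError(
                f"{path}: line {row}: {col} {frame[col][bad].iloc[0]!r} is invalid"
            )
    return frame


def write_resolutions(frame: pd.DataFrame, path: str | Path) -> None:
    frame[RESOLUTIONS_COLUMNS].to_csv(path, index=False)


def forms_to_records(frame: pd.DataFrame) -> list[ResponseForm]:
    """Materialise each row of a forms table as a validated ResponseForm."""
    return [
        ResponseForm(
            event_id=row["event_id"],
            rater_id=row["rater_id"],
            responses={cid: row[cid] for cid in ALL_IDS},
        )
        for _, row in frame.iterrows()
    ]


def records_to_frame(forms: list[ResponseForm]) -> pd.DataFrame:
    rows = [
        {
            "event_id": f.event_id,
            "rater_id": f.rater_id,
            **{cid: f.responses.get(cid, Response.NO).value for cid in ALL_IDS},
        }
        for f in forms
    ]
    return pd.DataFrame(rows, columns=["event_id", "rater_id", *ALL_IDS])


def write_forms_json(frame: pd.DataFrame, path: str | Path) -> None:
    """Nested-JSON form representation: follow-ups sit inside their gate."""
    nested_children = {gate: cid for cid, gate in GATES.items()}
    docs = []
    for _, row in frame.iterrows():
        criteria: dict[str, dict] = {}
        for cid in ALL_IDS:
            if cid in GATES:  # follow-up handled under its gate
                continue
            entry = {"response": row[cid]}
            child = nested_children.get(cid)
            if child is not None:
                entry["follow_up"] = {"id": child, "response": row[child]}
            criteria[cid] = entry
        docs.append(
            {"event_id": row["event_id"], "rater_id": row["rater_id"], "criteria": criteria}
        )
    Path(path).write_text(json.dumps(docs, indent=2, sort_keys=True))


def read_forms_json(path: str | Path) -> pd.DataFrame:
    docs = json.loads(Path(path).read_text())
    rows = []
    for doc in docs:
        row = {"event_id": doc["event_id"], "rater_id": doc["rater_id"]}
        for cid, entry in doc["criteria"].items():
            if cid not in ALL_IDS or cid in GATES:
                raise FormValidationError(f"{path}: unknown top-level criterion {cid!r}")
            row[cid] = entry["response"]
            fu = entry.get("follow_up")
            if fu is not None:
                row[fu["id"]] = fu["response"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    missing = [cid for cid in ALL_IDS if cid not in frame.columns]
    if missing:
        raise FormValidationError(f"{path}: missing criteria {missing}")
    return frame[["event_id", "rater_id", *ALL_IDS]]
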