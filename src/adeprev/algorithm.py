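"""Rule engine for the modified Schumock–Thornton preventability algorithm.

The instrument poses 18 yes/no/uncertain questions about an adverse drug
event (ADE), two of which (Q1, Q9) are gate questions with a nested
follow-up (Q1a, Q9a). Every non-gate question is a *trigger*: answering YES
forces the event's rating. Definite triggers force "definitely preventable",
probable triggers force "probably preventable", and definite triggers
dominate probable ones regardless of how many of each fired. An event with
no fired trigger is "not preventable". UNCERTAIN answers never fire a
trigger — classification treats them exactly like NO.

The nested follow-ups are only consulted when their gate is YES: Q1a
("was the re-exposure inappropriate?") requires Q1 = YES (history of
allergy or previous reaction), and Q9a ("were preventative measures not
contraindicated?") requires Q9 = YES (preventative measures not given).
Whatever a form carries in a follow-up field while its gate is not YES is
ignored.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._formatting import round_percent
from .errors import FormValidationError

__all__ = [
    "Response",
    "Rating",
    "Severity",
    "ResponseForm",
    "Attribution",
    "TOP_LEVEL_IDS",
    "NESTED_IDS",
    "ALL_IDS",
    "GATES",
    "DEFINITE_TRIGGERS",
    "PROBABLE_TRIGGERS",
    "SEVERITY",
    "CRITERION_LABELS",
    "classify",
    "classify_table",
    "attribute",
    "criterion_frequency",
    "severity_table",
]


class Response(str, enum.Enum):
    """One answer on the three-state response scale."""

    YES = "YES"
    NO = "NO"
    UNCERTAIN = "UNCERTAIN"


class Rating(enum.IntEnum):
    """Ordered preventability outcome; higher means more preventable."""

    NOT_PREVENTABLE = 0
    PROBABLY = 1
    DEFINITELY = 2


class Severity(enum.IntEnum):
    """What a fired trigger forces the rating to."""

    PROBABLE_TRIGGER = 1
    DEFINITE_TRIGGER = 2

    @property
    def rating(self) -> Rating:
        return Rating(int(self))


#: Top-level question ids, in instrument order.
TOP_LEVEL_IDS: tuple[str, ...] = tuple(str(i) for i in range(1, 19))
#: Nested follow-up ids and the gate each one requires.
GATES: dict[str, str] = {"1a": "1", "9a": "9"}
NESTED_IDS: tuple[str, ...] = tuple(GATES)
ALL_IDS: tuple[str, ...] = ("1", "1a") + TOP_LEVEL_IDS[1:9] + ("9a",) + TOP_LEVEL_IDS[9:]

DEFINITE_TRIGGERS: tuple[str, ...] = (
    "1a", "2", "3", "4", "5", "10", "12", "13", "14", "15", "17", "18",
)
PROBABLE_TRIGGERS: tuple[str, ...] = ("6", "7", "8", "9a", "11", "16")

#: Trigger id -> severity. Gate questions 1 and 9 carry no severity.
SEVERITY: dict[str, Severity] = {
    **{cid: Severity.DEFINITE_TRIGGER for cid in DEFINITE_TRIGGERS},
    **{cid: Severity.PROBABLE_TRIGGER for cid in PROBABLE_TRIGGERS},
}

#: Short human-readable labels, instrument order.
CRITERION_LABELS: dict[str, str] = {
    "1": "history of allergy or previous reaction to the drug or drug class (gate)",
    "1a": "re-exposure to the drug was inappropriate",
    "2": "drug inappropriate for the patient's clinical condition",
    "3": "dose, route or frequency inappropriate for age, weight or disease state",
    "4": "toxic serum drug concentration or laboratory monitoring test documented",
    "5": "a known treatment for the ADE existed",
    "6": "required therapeutic drug monitoring or other necessary tests not performed",
    "7": "a drug interaction was involved in the ADE",
    "8": "poor compliance was involved in the ADE",
    "9": "preventative measures not prescribed or administered (gate)",
    "9a": "preventative measures were not contraindicated",
    "10": "error in ADE diagnosis contributed to the event persisting or worsening",
    "11": "delay in ADE diagnosis contributed to the event persisting or worsening",
    "12": "failure to act on the result of monitoring or testing",
    "13": "error in transcription of the culprit drug order",
    "14": "error in dispensing of the culprit drug order",
    "15": "error in administration of the culprit drug",
    "16": "superior alternative treatment available without contraindication",
    "17": "failure in communication contributed to the ADE",
    "18": "equipment failure contributed to the ADE",
}


def _coerce_response(cid: str, value) -> Response:
    if isinstance(value, Response):
        return value
    try:
        return Response(str(value).strip().upper())
    except ValueError:
        raise FormValidationError(
            f"criterion {cid!r}: response {value!r} is not one of YES/NO/UNCERTAIN"
        ) from None


@dataclass(frozen=True)
class ResponseForm:
    """One rater's completed criterion-response form for one event.

    ``responses`` must cover all 18 top-level ids; the nested ids 1a/9a may
    be absent when their gate is not YES.
    """

    event_id: str
    rater_id: str
    responses: Mapping[str, Response]

    def __post_init__(self):
        clean: dict[str, Response] = {}
        for cid, value in self.responses.items():
            cid = str(cid)
            if cid not in ALL_IDS:
                raise FormValidationError(f"unknown criterion id {cid!r}")
            clean[cid] = _coerce_response(cid, value)
        missing = [cid for cid in TOP_LEVEL_IDS if cid not in clean]
        if missing:
            raise FormValidationError(
                f"event {self.event_id!r} rater {self.rater_id!r}: "
                f"missing top-level criteria {missing}"
            )
        for nested, gate in GATES.items():
            if clean[gate] is Response.YES and nested not in clean:
                raise FormValidationError(
                    f"event {self.event_id!r}: criterion {gate} is YES but "
                    f"follow-up {nested} is absent"
                )
        object.__setattr__(self, "responses", clean)

    def fired(self) -> list[tuple[str, Severity]]:
        """Triggers answered YES with their gate (if any) satisfied."""
        out = []
        for cid in ALL_IDS:
            sev = SEVERITY.get(cid)
            if sev is None:  # gate question
                continue
            if self.responses.get(cid) is not Response.YES:
                continue
            gate = GATES.get(cid)
            if gate is not None and self.responses[gate] is not Response.YES:
                continue
            out.append((cid, sev))
        return out


@dataclass(frozen=True)
class Attribution:
    """Which triggers fired for one event, with their severities."""

    event_id: str
    fired: tuple = field(default_factory=tuple)

    @property
    def rating(self) -> Rating:
        if not self.fired:
            return Rating.NOT_PREVENTABLE
        return max(sev.rating for _, sev in self.fired)


def classify(form: ResponseForm) -> Rating:
    """Rate one event from its criterion responses.

    DEFINITELY if any definite trigger fires, else PROBABLY if any probable
    trigger fires, else NOT_PREVENTABLE.
    """
    return attribute(form).rating


def attribute(form: ResponseForm) -> Attribution:
    """Return every fired trigger; ``Attribution.rating`` recovers classify."""
    return Attribution(event_id=form.event_id, fired=tuple(form.fired()))


def classify_table(forms: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify` over a forms table.

    ``forms`` has one column per criterion id (values YES/NO/UNCERTAIN,
    case-insensitive); any other columns (event_id, rater_id, ...) are
    carried through untouched. Returns a Series of :class:`Rating` aligned
    with the input index.
    """
    missing = [cid for cid in TOP_LEVEL_IDS if cid not in forms.columns]
    if missing:
        raise FormValidationError(f"forms table missing criterion columns {missing}")

    def yes(cid: str) -> np.ndarray:
        if cid not in forms.columns:
            return np.zeros(len(forms), dtype=bool)
        col = forms[cid].astype(str).str.strip().str.upper()
        bad = ~col.isin([r.value for r in Response])
        if bad.any():
            row = forms.index[bad][0]
            raise FormValidationError(
                f"criterion {cid!r} row {row!r}: response "
                f"{forms[cid].loc[row]!r} is not one of YES/NO/UNCERTAIN"
            )
        return (col == Response.YES.value).to_numpy()

    def fires(cid: str) -> np.ndarray:
        hit = yes(cid)
        gate = GATES.get(cid)
        return hit & yes(gate) if gate else hit

    any_def = np.logical_or.reduce([fires(c) for c in DEFINITE_TRIGGERS])
    any_prob = np.logical_or.reduce([fires(c) for c in PROBABLE_TRIGGERS])
    codes = np.where(any_def, Rating.DEFINITELY, np.where(any_prob, Rating.PROBABLY, Rating.NOT_PREVENTABLE))
    # dtype=object keeps the Rating enums (IntEnum would coerce to int64)
    return pd.Series(
        [Rating(int(c)) for c in codes], index=forms.index, name="rating", dtype=object
    )


def criterion_frequency(
    attributions: Iterable[Attribution],
    denominator_policy: str = "all_events",
) -> pd.DataFrame:
    """Count, per criterion, the events in which it fired.

    ``denominator_policy`` selects the percent denominator: ``"all_events"``
    uses every attribution supplied; ``"definite_events"`` uses only events
    whose overall rating is DEFINITELY (the subset a definitely-preventable
    frequency table is naturally reported over). Counts are always over all
    supplied attributions.

    Returns a DataFrame indexed by trigger id with columns ``label``,
    ``severity``, ``count``, ``pct`` (half-up, one decimal) and ``denominator``.
    """
    if denominator_policy not in ("all_events", "definite_events"):
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    attributions = list(attributions)
    counts = {cid: 0 for cid in SEVERITY}
    n_definite = 0
    for attr in attributions:
        if attr.rating is Rating.DEFINITELY:
            n_definite += 1
        for cid, _ in attr.fired:
            counts[cid] += 1
    denom = len(attributions) if denominator_policy == "all_events" else n_definite
    rows = []
    for cid in ALL_IDS:
        if cid not in SEVERITY:
            continue
        pct = round_percent(100.0 * counts[cid] / denom) if denom else 0.0
        rows.append(
            {
                "criterion": cid,
                "label": CRITERION_LABELS[cid],
                "severity": SEVERITY[cid].name,
                "count": counts[cid],
                "pct": pct,
                "denominator": denom,
            }
        )
    return pd.DataFrame(rows).set_index("criterion")


def severity_table() -> pd.DataFrame:
    """Machine-readable trigger/severity map (one row per criterion id)."""
    rows = []
    for cid in ALL_IDS:
        sev = SEVERITY.get(cid)
        rows.append(
            {
                "criterion": cid,
                "label": CRITERION_LABELS[cid],
                "role": "gate" if cid in GATES.values() else "trigger",
                "severity": sev.name if sev else "",
                "forces_rating": sev.rating.name if sev else "",
                "gate": GATES.get(cid, ""),
            }
        )
    return pd.DataFrame(rows).set_index("criterion")
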