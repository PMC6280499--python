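from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adeprev.algorithm import ALL_IDS, ResponseForm


def make_form(yes=(), uncertain=(), event_id="E1", rater_id="R1") -> ResponseForm:
    """Form with every criterion NO except the listed ids."""
    responses = {cid: "NO" for cid in ALL_IDS}
    for cid in yes:
        responses[str(cid)] = "YES"
    for cid in uncertain:
        responses[str(cid)] = "UNCERTAIN"
    return ResponseForm(event_id=event_id, rater_id=rater_id, responses=responses)


def random_forms(n: int, seed: int = 0) -> list[ResponseForm]:
    rng = np.random.default_rng(seed)
    picks = rng.choice(["YES", "NO", "UNCERTAIN"], size=(n, len(ALL_IDS)))
    return [
        ResponseForm(f"E{i}", "R1", dict(zip(ALL_IDS, picks[i])))
        for i in range(n)
    ]


@pytest.fixture
def tiny_cohort():
    """Twelve events, one method, with a hand-designed binary cross-tab.

    Binary collapse of (pharmacist, physician) gives the 2x2 table
    [[4, 2], [1, 5]] (rows pharmacist NOT/PREV): po = 9/12, pe = 1/2,
    kappa = 0.5, se = 0.25.
    """
    pairs = (
        [("NOT_PREVENTABLE", "NOT_PREVENTABLE")] * 4
        + [("NOT_PREVENTABLE", "PROBABLY")] * 2
        + [("PROBABLY", "NOT_PREVENTABLE")] * 1
        + [("PROBABLY", "PROBABLY")] * 3
        + [("DEFINITELY", "DEFINITELY")] * 1
        + [("PROBABLY", "DEFINITELY")] * 1
    )
    rows, resolutions = [], []
    for i, (a, b) in enumerate(pairs, start=1):
        event = f"E{i:02d}"
        rows.append([event, "pharm-1", "PHARMACIST", "BEST_PRACTICE", a])
        rows.append([event, "md-1", "PHYSICIAN", "BEST_PRACTICE", b])
        if a != b:
            resolutions.append([event, "BEST_PRACTICE", a, ""])
    assessments = pd.DataFrame(
        rows, columns=["event_id", "rater_id", "rater_role", "method", "rating"]
    )
    resolutions = pd.DataFrame(
        resolutions,
        columns=["event_id", "method", "discussion_rating", "adjudication_rating"],
    )
    return assessments, resolutions
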