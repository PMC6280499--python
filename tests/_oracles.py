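"""Independent brute-force oracles used by the tests.

Deliberately written from the instrument's published rules, not from the
package implementation: the rule table below is a literal transcription of
which questions force which rating, and the kappa oracle spells out the
agreement formulas with plain loops. Keep these free of adeprev imports
other than enums/types.
"""

from __future__ import annotations

import math

# question id -> rating it forces when answered YES (gate satisfied);
# "definitely" beats "probably"; everything else -> not preventable.
FORCES_DEFINITELY = {"1a", "2", "3", "4", "5", "10", "12", "13", "14", "15", "17", "18"}
FORCES_PROBABLY = {"6", "7", "8", "9a", "11", "16"}
GATE_OF = {"1a": "1", "9a": "9"}


def oracle_classify(responses: dict[str, str]) -> str:
    """Rate a form by direct rule lookup. Responses: id -> YES/NO/UNCERTAIN."""

    def fires(qid: str) -> bool:
        if responses.get(qid) != "YES":
            return False
        gate = GATE_OF.get(qid)
        return gate is None or responses.get(gate) == "YES"

    if any(fires(q) for q in FORCES_DEFINITELY):
        return "DEFINITELY"
    if any(fires(q) for q in FORCES_PROBABLY):
        return "PROBABLY"
    return "NOT_PREVENTABLE"


def oracle_kappa(counts) -> tuple[float, float, float]:
    """(kappa, po, se) from first principles with explicit loops."""
    k = len(counts)
    n = sum(sum(row) for row in counts)
    po = sum(counts[i][i] for i in range(k)) / n
    pe = 0.0
    for i in range(k):
        row_i = sum(counts[i][j] for j in range(k)) / n
        col_i = sum(counts[j][i] for j in range(k)) / n
        pe += row_i * col_i
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    return kappa, po, se
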