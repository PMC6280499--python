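"""Agreement statistics: Cohen's kappa with 95% CI, binary collapse of the
three-level preventability scale, and binomial proportions with Wald CIs.

Cohen's kappa corrects raw agreement for chance: kappa = (po - pe)/(1 - pe)
with po the observed agreement proportion (trace of the contingency table
over n) and pe the chance agreement implied by the margins. The confidence
interval uses the standard asymptotic standard error
``sqrt(po * (1 - po) / (n * (1 - pe)**2))`` and a normal quantile at the
configured confidence level, truncated to [-1, 1].
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from ._formatting import fmt_ci, fmt_percent
from .algorithm import Rating
from .consensus import Method, RaterRole
from .errors import EmptySubsetError, RecordValidationError, UndefinedKappaError

__all__ = [
    "BinaryRating",
    "ContingencyTable",
    "KappaResult",
    "ProportionResult",
    "cohens_kappa",
    "collapse_binary",
    "wald_proportion_ci",
    "interrater_agreement",
    "intermethod_agreement",
]

log = logging.getLogger(__name__)


class BinaryRating(str, enum.Enum):
    NOT_PREVENTABLE = "NOT_PREVENTABLE"
    PREVENTABLE = "PREVENTABLE"


def collapse_binary(rating: Rating) -> BinaryRating:
    """Merge definitely + probably preventable into one preventable level."""
    if not isinstance(rating, Rating):
        rating = Rating[str(rating)]
    if rating is Rating.NOT_PREVENTABLE:
        return BinaryRating.NOT_PREVENTABLE
    return BinaryRating.PREVENTABLE


@dataclass(frozen=True)
class ContingencyTable:
    """k x k cross-tabulation of two raters (rows = A, columns = B)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} != ({k}, {k})")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if counts.sum() < 1:
            raise ValueError("empty contingency table")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_ratings(cls, a, b, labels: tuple[str, ...]) -> "ContingencyTable":
        """Cross-tabulate two aligned rating sequences over fixed labels."""
        a = pd.Categorical(list(a), categories=labels)
        b = pd.Categorical(list(b), categories=labels)
        tab = pd.crosstab(a, b, dropna=False).reindex(
            index=labels, columns=labels, fill_value=0
        )
        return cls(labels=tuple(labels), counts=tab.to_numpy())


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    po: float
    pe: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    confidence: float = 0.95

    def __str__(self):
        return f"{self.kappa:.2f} ({self.ci_low:.2f}–{self.ci_high:.2f}), n={self.n}"


@dataclass(frozen=True)
class ProportionResult:
    count: int
    n: int
    pct: float  # full precision, percent scale
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def __str__(self):
        return f"{self.count} ({fmt_percent(self.pct)}, {fmt_ci(self.ci_low, self.ci_high)})"


def cohens_kappa(table: ContingencyTable, confidence: float = 0.95) -> KappaResult:
    """Cohen's kappa with asymptotic CI on a square contingency table."""
    counts = table.counts
    n = counts.sum()
    po = float(np.trace(counts) / n)
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            # all mass in one diagonal cell: perfect, degenerate agreement
            return KappaResult(1.0, 1.0, 1.0, 0.0, 1.0, 1.0, int(n), confidence)
        raise UndefinedKappaError(
            f"chance agreement is 1 with observed agreement {po:.4f}; "
            "kappa is undefined"
        )
    kappa = (po - pe) / (1 - pe)
    se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    z = float(norm.ppf(0.5 + confidence / 2))
    lo = max(-1.0, kappa - z * se)
    hi = min(1.0, kappa + z * se)
    return KappaResult(kappa, po, pe, se, lo, hi, int(n), confidence)


def wald_proportion_ci(
    count: int, n: int, confidence: float = 0.95, method: str = "wald"
) -> ProportionResult:
    """Binomial proportion with a normal-approximation (Wald) CI.

    ``method="wilson"`` selects the Wilson score interval instead. Bounds
    are clipped to [0, 1] and reported on the percent scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    sm_method = {"wald": "normal", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(count, n, alpha=1 - confidence, method=sm_method)
    lo, hi = max(0.0, float(lo)), min(1.0, float(hi))
    return ProportionResult(count, n, 100.0 * count / n, 100.0 * lo, 100.0 * hi, confidence)


_THREE_LABELS = tuple(r.name for r in Rating)
_BINARY_LABELS = (BinaryRating.NOT_PREVENTABLE.value, BinaryRating.PREVENTABLE.value)
_DEF_PROB_LABELS = (Rating.PROBABLY.name, Rating.DEFINITELY.name)


def _rater_pivot(assessments: pd.DataFrame, method: Method | str) -> pd.DataFrame:
    method = Method(method).value
    sub = assessments[
        (assessments["method"] == method)
        & (assessments["rater_role"] != RaterRole.ADJUDICATOR.value)
    ]
    if sub.empty:
        raise EmptySubsetError(f"no primary ratings for method {method}")
    wide = sub.pivot_table(
        index="event_id", columns="rater_role", values="rating", aggfunc="first"
    )
    for role in (RaterRole.PHARMACIST.value, RaterRole.PHYSICIAN.value):
        if role not in wide.columns or wide[role].isna().any():
            missing = (
                wide.index[wide[role].isna()].tolist() if role in wide.columns else "all"
            )
            raise RecordValidationError(
                f"method {method}: events missing a {role} rating: {missing}"
            )
    return wide


def interrater_agreement(
    assessments: pd.DataFrame,
    method: Method | str,
    scale: str = "binary",
    subset_policy: str = "consensus_preventable",
    consensus: pd.DataFrame | None = None,
    confidence: float = 0.95,
) -> KappaResult:
    """Pharmacist-vs-physician kappa for one method.

    ``scale="binary"`` collapses ratings to preventable vs not and uses all
    events. ``scale="def_vs_prob"`` cross-tabulates DEFINITELY vs PROBABLY
    on a preventable subset chosen by ``subset_policy``:

    - ``"consensus_preventable"``: events whose consensus rating under the
      method is preventable (requires ``consensus``); events where either
      original rating is NOT_PREVENTABLE are then dropped (and logged),
      since the two-level cross-tab cannot hold them.
    - ``"both_raters_preventable"``: events where both original ratings are
      preventable (pre-consensus reading; needs no consensus table).
    """
    wide = _rater_pivot(assessments, method)
    a = wide[RaterRole.PHARMACIST.value]
    b = wide[RaterRole.PHYSICIAN.value]
    if scale == "binary":
        a = a.map(lambda r: collapse_binary(r).value)
        b = b.map(lambda r: collapse_binary(r).value)
        table = ContingencyTable.from_ratings(a, b, _BINARY_LABELS)
        return cohens_kappa(table, confidence)
    if scale != "def_vs_prob":
        raise ValueError(f"unknown scale {scale!r}")

    not_name = Rating.NOT_PREVENTABLE.name
    if subset_policy == "consensus_preventable":
        if consensus is None:
            raise ValueError("subset_policy 'consensus_preventable' needs a consensus table")
        keep = consensus[
            (consensus["method"] == Method(method).value)
            & (consensus["final_rating"] != not_name)
        ]["event_id"]
        sel = wide.loc[wide.index.intersection(keep)]
        usable = sel[(sel != not_name).all(axis=1)]
        if len(usable) < len(sel):
            log.info(
                "def_vs_prob: dropped %d consensus-preventable events with a "
                "NOT_PREVENTABLE original rating",
                len(sel) - len(usable),
            )
    elif subset_policy == "both_raters_preventable":
        usable = wide[(wide != not_name).all(axis=1)]
    else:
        raise ValueError(f"unknown subset_policy {subset_policy!r}")
    if usable.empty:
        raise EmptySubsetError(
            f"method {Method(method).value}: no events in the definitely-vs-probably subset"
        )
    table = ContingencyTable.from_ratings(
        usable[RaterRole.PHARMACIST.value],
        usable[RaterRole.PHYSICIAN.value],
        _DEF_PROB_LABELS,
    )
    return cohens_kappa(table, confidence)


def intermethod_agreement(
    consensus: pd.DataFrame,
    method_a: Method | str,
    method_b: Method | str,
    confidence: float = 0.95,
) -> KappaResult:
    """Kappa between two methods' binary-collapsed consensus ratings."""
    ma, mb = Method(method_a).value, Method(method_b).value
    a = consensus[consensus["method"] == ma].set_index("event_id")["final_rating"]
    b = consensus[consensus["method"] == mb].set_index("event_id")["final_rating"]
    common = a.index.intersection(b.index)
    excluded = (len(a) - len(common)) + (len(b) - len(common))
    if excluded:
        log.info("intermethod %s vs %s: excluded %d non-overlapping events", ma, mb, excluded)
    if len(common) == 0:
        raise EmptySubsetError(f"methods {ma} and {mb} share no events")
    a = a.loc[common].map(lambda r: collapse_binary(r).value)
    b = b.loc[common].map(lambda r: collapse_binary(r).value)
    table = ContingencyTable.from_ratings(a, b, _BINARY_LABELS)
    return cohens_kappa(table, confidence)
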