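"""End-to-end orchestration: inputs -> classification -> consensus ->
agreement statistics -> report tables.

A run produces five tables mirroring the standard reporting layout for a
dual-reviewer preventability study: consensus rating proportions by method
(with CIs), binary inter-rater kappas, definitely-vs-probably inter-rater
kappas, inter-method kappas on consensus ratings, and the definite-trigger
criterion frequency table. Every cell is kept at full precision alongside
its formatted string; reports are deterministic functions of their inputs
(plus the seed in simulate mode) and contain no timestamps, so repeat runs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as adeio
from ._formatting import fmt_ci, fmt_percent
from .agreement import (
    EmptySubsetError,
    interrater_agreement,
    intermethod_agreement,
    wald_proportion_ci,
)
from .algorithm import (
    ALL_IDS,
    Rating,
    Response,
    classify_table,
    criterion_frequency,
)
from .algorithm import Attribution, SEVERITY, GATES
from .consensus import Method, RaterRole, consensus_dataset
from .errors import RecordValidationError
from .simulate import SimulationConfig, simulate

__all__ = ["RunConfig", "StudyReport", "run", "validate_inputs", "regenerate_tables"]

log = logging.getLogger(__name__)

_METHODS = [m.value for m in (Method.BEST_PRACTICE, Method.ERROR_BASED, Method.ALGORITHM)]
_TABLE_NAMES = ("table2", "table3", "table4", "table5", "table6")


@dataclass
class RunConfig:
    """Either file-mode (all three paths set) or simulate-mode (sim set)."""

    ratings_path: str | Path | None = None
    forms_path: str | Path | None = None
    resolutions_path: str | Path | None = None
    sim: SimulationConfig | None = None
    confidence: float = 0.95
    denominator_policy: str = "all_events"
    subset_policy: str = "consensus_preventable"
    invert_criteria: tuple[str, ...] = ()

    def __post_init__(self):
        file_mode = self.ratings_path is not None
        if file_mode == (self.sim is not None):
            raise ValueError("exactly one of file-mode (paths) or simulate-mode (sim) must be set")


def _jsonable_records(frame: pd.DataFrame) -> list[dict]:
    """Records with native Python scalars so floats round-trip exactly
    (pandas' own JSON writer caps doubles at 15 digits)."""
    def conv(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or v is pd.NA:
            return None
        if hasattr(v, "item"):
            return v.item()
        return v

    return [
        {col: conv(val) for col, val in row.items()}
        for row in frame.to_dict(orient="records")
    ]


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame]
    meta: dict = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in _TABLE_NAMES:
            paths[name] = outdir / f"{name}.csv"
            self.tables[name].to_csv(paths[name], index=False)
        summary = {
            "meta": self.meta,
            **{
                name: {
                    "columns": list(self.tables[name].columns),
                    "rows": _jsonable_records(self.tables[name]),
                }
                for name in _TABLE_NAMES
            },
        }
        paths["summary"] = outdir / "summary.json"
        paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
        return paths

    @classmethod
    def from_summary(cls, path: str | Path) -> "StudyReport":
        doc = json.loads(Path(path).read_text())
        tables = {
            name: pd.DataFrame(doc[name]["rows"], columns=doc[name]["columns"])
            for name in _TABLE_NAMES
        }
        return cls(tables=tables, meta=doc.get("meta", {}))


def regenerate_tables(summary_path: str | Path, outdir: str | Path) -> dict[str, Path]:
    """Rewrite the formatted CSV tables from a machine-readable summary."""
    return StudyReport.from_summary(summary_path).to_dir(outdir)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _attributions_from_forms(forms: pd.DataFrame) -> list[Attribution]:
    out = []
    for _, row in forms.iterrows():
        fired = []
        for cid, sev in SEVERITY.items():
            if row[cid] != Response.YES.value:
                continue
            gate = GATES.get(cid)
            if gate is not None and row[gate] != Response.YES.value:
                continue
            fired.append((cid, sev))
        out.append(Attribution(event_id=row["event_id"], fired=tuple(sorted(fired))))
    return out


def _derive_algorithm_ratings(
    assessments: pd.DataFrame, forms: pd.DataFrame
) -> pd.DataFrame:
    """Fill in ALGORITHM assessment rows from the forms via the engine."""
    roles = (
        assessments[["rater_id", "rater_role"]]
        .drop_duplicates()
        .set_index("rater_id")["rater_role"]
    )
    unknown = set(forms["rater_id"]) - set(roles.index)
    if unknown:
        raise RecordValidationError(
            f"forms reference rater ids with no role in the ratings file: {sorted(unknown)}"
        )
    derived = pd.DataFrame(
        {
            "event_id": forms["event_id"],
            "rater_id": forms["rater_id"],
            "rater_role": forms["rater_id"].map(roles).to_numpy(),
            "method": Method.ALGORITHM.value,
            "rating": [r.name for r in classify_table(forms)],
        }
    )
    return pd.concat([assessments, derived], ignore_index=True)


def _table2(consensus: pd.DataFrame, confidence: float) -> pd.DataFrame:
    rows = []
    for method in _METHODS:
        ratings = consensus.loc[consensus["method"] == method, "final_rating"]
        n = len(ratings)
        counts = ratings.value_counts()
        cells = [
            ("DEFINITELY_OR_PROBABLY",
             int(counts.get(Rating.DEFINITELY.name, 0) + counts.get(Rating.PROBABLY.name, 0))),
            ("DEFINITELY", int(counts.get(Rating.DEFINITELY.name, 0))),
            ("PROBABLY", int(counts.get(Rating.PROBABLY.name, 0))),
            ("NOT_PREVENTABLE", int(counts.get(Rating.NOT_PREVENTABLE.name, 0))),
        ]
        for label, count in cells:
            res = wald_proportion_ci(count, n, confidence)
            rows.append(
                {
                    "method": method,
                    "rating": label,
                    "count": count,
                    "n": n,
                    "pct": res.pct,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "formatted": f"{count} ({fmt_percent(res.pct)}, {fmt_ci(res.ci_low, res.ci_high)})",
                }
            )
    return pd.DataFrame(rows)


def _kappa_row(result, **front) -> dict:
    return {
        **front,
        "n": result.n,
        "kappa": result.kappa,
        "se": result.se,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "formatted": f"{result.kappa:.2f} ({result.ci_low:.2f}–{result.ci_high:.2f})",
    }


def run(config: RunConfig) -> StudyReport:
    """Execute one full analysis and return the report."""
    meta: dict = {
        "confidence": config.confidence,
        "denominator_policy": config.denominator_policy,
        "subset_policy": config.subset_policy,
    }
    if config.sim is not None:
        dataset = simulate(config.sim)
        assessments, forms, resolutions = (
            dataset.assessments, dataset.forms, dataset.resolutions,
        )
        meta["mode"] = "simulate"
        meta["seed"] = config.sim.seed
        meta["n_events"] = config.sim.n_events
    else:
        assessments = adeio.read_ratings(config.ratings_path)
        forms = adeio.read_forms(config.forms_path, invert=config.invert_criteria)
        resolutions = adeio.read_resolutions(config.resolutions_path)
        meta["mode"] = "file"
        meta["inputs"] = {
            "ratings": {"path": str(config.ratings_path), "sha256": _sha256(config.ratings_path)},
            "forms": {"path": str(config.forms_path), "sha256": _sha256(config.forms_path)},
            "resolutions": {
                "path": str(config.resolutions_path),
                "sha256": _sha256(config.resolutions_path),
            },
        }
        if not (assessments["method"] == Method.ALGORITHM.value).any():
            assessments = _derive_algorithm_ratings(assessments, forms)

    consensus = consensus_dataset(assessments, resolutions)
    meta["path_counts"] = {
        k: int(v) for k, v in sorted(consensus["path"].value_counts().items())
    }

    table3_rows, table4_rows = [], []
    for method in _METHODS:
        table3_rows.append(
            _kappa_row(
                interrater_agreement(assessments, method, "binary", confidence=config.confidence),
                method=method,
            )
        )
        try:
            table4_rows.append(
                _kappa_row(
                    interrater_agreement(
                        assessments, method, "def_vs_prob",
                        subset_policy=config.subset_policy,
                        consensus=consensus, confidence=config.confidence,
                    ),
                    method=method,
                )
            )
        except EmptySubsetError as err:
            log.warning("table4 %s: %s", method, err)
            table4_rows.append(
                {"method": method, "n": 0, "kappa": None, "se": None,
                 "ci_low": None, "ci_high": None, "formatted": ""}
            )

    table5_rows = [
        _kappa_row(
            intermethod_agreement(consensus, ma, mb, confidence=config.confidence),
            method_a=ma, method_b=mb,
        )
        for ma, mb in (
            (Method.BEST_PRACTICE.value, Method.ALGORITHM.value),
            (Method.ALGORITHM.value, Method.ERROR_BASED.value),
            (Method.BEST_PRACTICE.value, Method.ERROR_BASED.value),
        )
    ]

    # criterion attribution uses the pharmacist's forms
    pharm_ids = set(
        assessments.loc[
            assessments["rater_role"] == RaterRole.PHARMACIST.value, "rater_id"
        ]
    )
    pharm_forms = forms[forms["rater_id"].isin(pharm_ids)]
    table6 = criterion_frequency(
        _attributions_from_forms(pharm_forms), config.denominator_policy
    ).reset_index()
    table6["formatted"] = [
        f"{c} ({fmt_percent(p)})" for c, p in zip(table6["count"], table6["pct"])
    ]

    tables = {
        "table2": _table2(consensus, config.confidence),
        "table3": pd.DataFrame(table3_rows),
        "table4": pd.DataFrame(table4_rows),
        "table5": pd.DataFrame(table5_rows),
        "table6": table6,
    }
    return StudyReport(tables=tables, meta=meta)


def validate_inputs(
    ratings_path: str | Path,
    forms_path: str | Path | None = None,
    resolutions_path: str | Path | None = None,
) -> pd.DataFrame:
    """Lenient validation pass; never mutates inputs.

    Returns one row per finding with columns file, line, kind, message.
    Checks: duplicate (event, rater, method) keys, events missing one of
    the two primary raters, out-of-scale ratings, unknown criterion
    columns/responses, and recorded ALGORITHM ratings that contradict the
    engine's classification of the corresponding form.
    """
    findings: list[dict] = []

    def add(file, line, kind, message):
        findings.append({"file": str(file), "line": line, "kind": kind, "message": message})

    ratings = pd.read_csv(ratings_path, dtype=str).fillna("")
    missing_cols = [c for c in adeio.RATINGS_COLUMNS if c not in ratings.columns]
    for col in missing_cols:
        add(ratings_path, 1, "missing_column", f"column {col!r} absent")
    if not missing_cols:
        for col in ("rater_role", "method", "rating"):
            ratings[col] = ratings[col].str.strip().str.upper()
        dup = ratings.duplicated(["event_id", "rater_id", "method"], keep=False)
        for idx in ratings.index[dup & ~ratings.duplicated(["event_id", "rater_id", "method"])]:
            row = ratings.loc[idx]
            add(ratings_path, int(idx) + 2, "duplicate_key",
                f"duplicated (event, rater, method) = "
                f"({row['event_id']}, {row['rater_id']}, {row['method']})")
        valid_names = {r.name for r in Rating}
        for idx in ratings.index[~ratings["rating"].isin(valid_names)]:
            add(ratings_path, int(idx) + 2, "out_of_scale",
                f"rating {ratings.loc[idx, 'rating']!r} not in {sorted(valid_names)}")
        primary = ratings[ratings["rater_role"] != RaterRole.ADJUDICATOR.value]
        n_raters = primary.groupby(["event_id", "method"])["rater_id"].nunique()
        for (event, method), k in n_raters[n_raters != 2].items():
            add(ratings_path, None, "missing_rater",
                f"event {event} method {method} has {k} primary rater(s), expected 2")

    forms = None
    if forms_path is not None:
        raw = pd.read_csv(forms_path, dtype=str).fillna("")
        known, unknown = {}, []
        for col in raw.columns:
            if col in ("event_id", "rater_id"):
                continue
            cid = adeio._canonical_criterion(col)
            (unknown.append(col) if cid is None else known.update({col: cid}))
        for col in unknown:
            add(forms_path, 1, "unknown_criterion", f"unknown criterion column {col!r}")
        raw = raw.rename(columns=known)
        ok_cols = [cid for cid in ALL_IDS if cid in raw.columns]
        valid_resp = {r.value for r in Response}
        clean_rows = pd.Series(True, index=raw.index)
        for cid in ok_cols:
            raw[cid] = raw[cid].str.strip().str.upper()
            bad = ~raw[cid].isin(valid_resp)
            clean_rows &= ~bad
            for idx in raw.index[bad]:
                add(forms_path, int(idx) + 2, "out_of_scale",
                    f"criterion {cid}: response {raw.loc[idx, cid]!r} invalid")
        if len(ok_cols) == len(ALL_IDS) and not missing_cols:
            forms = raw[clean_rows]

    if forms is not None and len(forms):
        algo = ratings[
            (ratings["method"] == Method.ALGORITHM.value)
            & (ratings["rater_role"] != RaterRole.ADJUDICATOR.value)
        ].set_index(["event_id", "rater_id"])["rating"]
        predicted = classify_table(forms)
        for (idx, row), rating in zip(forms.iterrows(), predicted):
            key = (row["event_id"], row["rater_id"])
            if key in algo.index and algo.loc[key] != rating.name:
                add(forms_path, int(idx) + 2, "classify_mismatch",
                    f"event {key[0]} rater {key[1]}: recorded {algo.loc[key]}, "
                    f"engine classifies {rating.name}")

    if resolutions_path is not None:
        res = pd.read_csv(resolutions_path, dtype=str).fillna("")
        for col in adeio.RESOLUTIONS_COLUMNS:
            if col not in res.columns:
                add(resolutions_path, 1, "missing_column", f"column {col!r} absent")
        valid = {r.name for r in Rating} | {""}
        for col in ("discussion_rating", "adjudication_rating"):
            if col in res.columns:
                vals = res[col].str.strip().str.upper()
                for idx in res.index[~vals.isin(valid)]:
                    add(resolutions_path, int(idx) + 2, "out_of_scale",
                        f"{col} {res.loc[idx, col]!r} invalid")

    return pd.DataFrame(findings, columns=["file", "line", "kind", "message"])
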