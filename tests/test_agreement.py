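"""Agreement-statistics tests: kappa vs an independent oracle, binary
collapse, Wald proportions against published-style tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from adeprev._formatting import round_percent
from adeprev.agreement import (
    BinaryRating,
    ContingencyTable,
    cohens_kappa,
    collapse_binary,
    intermethod_agreement,
    interrater_agreement,
    wald_proportion_ci,
)
from adeprev.algorithm import Rating
from adeprev.errors import EmptySubsetError, RecordValidationError

from _oracles import oracle_kappa


def random_tables(n, seed, kmin=2, kmax=4):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        k = int(rng.integers(kmin, kmax + 1))
        counts = rng.integers(0, 40, size=(k, k))
        if counts.sum() == 0:
            counts[0, 0] = 1
        yield ContingencyTable(tuple(f"c{i}" for i in range(k)), counts)


class TestCohensKappa:
    def test_perfect_agreement(self):
        t = ContingencyTable(("a", "b"), [[10, 0], [0, 10]])
        assert cohens_kappa(t).kappa == 1.0

    def test_independence_limit(self):
        t = ContingencyTable(("a", "b"), [[25, 25], [25, 25]])
        assert cohens_kappa(t).kappa == 0.0

    def test_worked_2x2_against_oracle(self):
        t = ContingencyTable(("a", "b"), [[10, 5], [3, 12]])
        res = cohens_kappa(t)
        kappa, po, se = oracle_kappa([[10, 5], [3, 12]])
        assert res.kappa == pytest.approx(kappa, rel=1e-12)
        assert res.po == pytest.approx(po, rel=1e-12)
        assert res.se == pytest.approx(se, rel=1e-12)
        assert res.ci_low == pytest.approx(kappa - 1.959963984540054 * se, rel=1e-9)

    def test_many_random_tables_match_oracle(self):
        for t in random_tables(300, seed=42):
            res = cohens_kappa(t)
            kappa, po, se = oracle_kappa(t.counts.tolist())
            assert res.kappa == pytest.approx(kappa, rel=1e-12, abs=1e-12)
            assert res.se == pytest.approx(se, rel=1e-12, abs=1e-12)
            assert -1 <= res.ci_low <= res.kappa <= res.ci_high <= 1

    def test_point_estimate_matches_sklearn(self):
        """Cross-check against an established implementation by expanding
        the table back to label pairs."""
        for t in random_tables(50, seed=7):
            a, b = [], []
            for i in range(len(t.labels)):
                for j in range(len(t.labels)):
                    a += [t.labels[i]] * int(t.counts[i, j])
                    b += [t.labels[j]] * int(t.counts[i, j])
            expected = cohen_kappa_score(a, b, labels=list(t.labels))
            if np.isnan(expected):  # degenerate single-cell table
                continue
            assert cohens_kappa(t).kappa == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        for t in random_tables(50, seed=13, kmin=3, kmax=3):
            perm = rng.permutation(3)
            shuffled = ContingencyTable(
                tuple(t.labels[i] for i in perm), t.counts[np.ix_(perm, perm)]
            )
            assert cohens_kappa(shuffled).kappa == pytest.approx(
                cohens_kappa(t).kappa, rel=1e-12, abs=1e-12
            )

    def test_degenerate_single_cell_is_perfect(self):
        t = ContingencyTable(("a", "b"), [[7, 0], [0, 0]])
        res = cohens_kappa(t)
        assert (res.kappa, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a", "b"), [[0, 0], [0, 0]])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4).filter(lambda c: sum(c) > 0))
    def test_kappa_bounded_and_consistent(self, cells):
        """For any non-empty 2x2 table, kappa lies in [-1, 1], satisfies its
        defining identity, and the CI brackets the estimate."""
        t = ContingencyTable(("a", "b"), [cells[:2], cells[2:]])
        try:
            res = cohens_kappa(t)
        except ZeroDivisionError:
            return
        assert -1.0 <= res.kappa <= 1.0
        if res.pe < 1:
            assert res.kappa == pytest.approx((res.po - res.pe) / (1 - res.pe), rel=1e-12, abs=1e-12)
        assert res.ci_low <= res.kappa <= res.ci_high


class TestCollapseBinary:
    @pytest.mark.parametrize(
        "rating,expected",
        [
            (Rating.DEFINITELY, BinaryRating.PREVENTABLE),
            (Rating.PROBABLY, BinaryRating.PREVENTABLE),
            (Rating.NOT_PREVENTABLE, BinaryRating.NOT_PREVENTABLE),
        ],
    )
    def test_mapping(self, rating, expected):
        assert collapse_binary(rating) is expected

    def test_accepts_names(self):
        assert collapse_binary("PROBABLY") is BinaryRating.PREVENTABLE


class TestWaldProportion:
    @pytest.mark.parametrize(
        "count,n,pct,lo,hi",
        [
            (869, 1356, 64.1, 61.5, 66.6),
            (87, 1356, 6.4, 5.1, 7.7),
            (0, 100, 0.0, 0.0, 0.0),
        ],
    )
    def test_formatted_values(self, count, n, pct, lo, hi):
        res = wald_proportion_ci(count, n)
        assert round_percent(res.pct) == pct
        assert round_percent(res.ci_low) == lo
        assert round_percent(res.ci_high) == hi

    def test_against_closed_form(self):
        res = wald_proportion_ci(148, 508)
        p = 148 / 508
        se = (p * (1 - p) / 508) ** 0.5
        z = 1.959963984540054
        assert res.pct == pytest.approx(100 * p, rel=1e-12)
        assert res.ci_low == pytest.approx(100 * (p - z * se), rel=1e-9)
        assert res.ci_high == pytest.approx(100 * (p + z * se), rel=1e-9)
        assert round_percent(res.pct) == 29.1

    def test_ci_width_shrinks_with_n(self):
        widths = [
            wald_proportion_ci(n // 4, n).ci_high - wald_proportion_ci(n // 4, n).ci_low
            for n in (40, 400, 4000, 40000)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_wilson_option_stays_off_boundary(self):
        wald = wald_proportion_ci(1, 50)
        wilson = wald_proportion_ci(1, 50, method="wilson")
        assert wald.ci_low == 0.0  # Wald lower bound clipped at 0
        assert wilson.ci_low > 0.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            wald_proportion_ci(5, 0)
        with pytest.raises(ValueError):
            wald_proportion_ci(7, 5)


class TestInterRater:
    def test_identical_columns_kappa_one(self, tiny_cohort):
        assessments, _ = tiny_cohort
        copied = assessments.copy()
        pharm = copied[copied["rater_role"] == "PHARMACIST"]
        md = pharm.assign(rater_id="md-1", rater_role="PHYSICIAN")
        res = interrater_agreement(pd.concat([pharm, md]), "BEST_PRACTICE", "binary")
        assert res.kappa == 1.0

    def test_binary_kappa_matches_hand_crosstab(self, tiny_cohort):
        """The 12-event fixture collapses to [[4,2],[1,5]]: kappa 0.5."""
        assessments, _ = tiny_cohort
        res = interrater_agreement(assessments, "BEST_PRACTICE", "binary")
        direct = cohens_kappa(ContingencyTable(("n", "p"), [[4, 2], [1, 5]]))
        assert res.kappa == pytest.approx(direct.kappa, rel=1e-12)
        assert res.kappa == pytest.approx(0.5, rel=1e-12)
        assert res.se == pytest.approx(0.25, rel=1e-12)
        assert res.n == 12

    def test_def_vs_prob_policies(self, tiny_cohort):
        assessments, resolutions = tiny_cohort
        from adeprev.consensus import consensus_dataset

        consensus = consensus_dataset(assessments, resolutions)
        pre = interrater_agreement(
            assessments, "BEST_PRACTICE", "def_vs_prob",
            subset_policy="both_raters_preventable",
        )
        # both-preventable events: E08-E10 (P,P), E11 (D,D), E12 (P,D)
        direct = cohens_kappa(ContingencyTable(("P", "D"), [[3, 1], [0, 1]]))
        assert pre.n == 5 and pre.kappa == pytest.approx(direct.kappa, rel=1e-12)
        post = interrater_agreement(
            assessments, "BEST_PRACTICE", "def_vs_prob",
            subset_policy="consensus_preventable", consensus=consensus,
        )
        # consensus-preventable adds E07 (discussion->PROBABLY) but E07's
        # physician rating is NOT_PREVENTABLE, so it is dropped again
        assert post.n == 5

    def test_all_not_preventable_subset_errors(self):
        assessments = pd.DataFrame(
            [
                ["E1", "pharm-1", "PHARMACIST", "BEST_PRACTICE", "NOT_PREVENTABLE"],
                ["E1", "md-1", "PHYSICIAN", "BEST_PRACTICE", "NOT_PREVENTABLE"],
            ],
            columns=["event_id", "rater_id", "rater_role", "method", "rating"],
        )
        with pytest.raises(EmptySubsetError):
            interrater_agreement(
                assessments, "BEST_PRACTICE", "def_vs_prob",
                subset_policy="both_raters_preventable",
            )

    def test_missing_rater_errors(self, tiny_cohort):
        assessments, _ = tiny_cohort
        with pytest.raises(RecordValidationError):
            interrater_agreement(assessments.iloc[:-1], "BEST_PRACTICE", "binary")


class TestInterMethod:
    @staticmethod
    def consensus_frame(pairs):
        rows = []
        for i, (a, b) in enumerate(pairs):
            rows.append([f"E{i}", "BEST_PRACTICE", a, "CONCORDANT"])
            rows.append([f"E{i}", "ALGORITHM", b, "CONCORDANT"])
        return pd.DataFrame(rows, columns=["event_id", "method", "final_rating", "path"])

    def test_identical_columns(self):
        frame = self.consensus_frame([("PROBABLY", "PROBABLY")] * 5 + [("NOT_PREVENTABLE", "NOT_PREVENTABLE")] * 5)
        assert intermethod_agreement(frame, "BEST_PRACTICE", "ALGORITHM").kappa == 1.0

    def test_matches_specified_crosstab(self):
        pairs = (
            [("NOT_PREVENTABLE", "NOT_PREVENTABLE")] * 6
            + [("NOT_PREVENTABLE", "PROBABLY")] * 2
            + [("DEFINITELY", "NOT_PREVENTABLE")] * 1
            + [("PROBABLY", "DEFINITELY")] * 11
        )
        res = intermethod_agreement(self.consensus_frame(pairs), "BEST_PRACTICE", "ALGORITHM")
        direct = cohens_kappa(ContingencyTable(("n", "p"), [[6, 2], [1, 11]]))
        assert res.kappa == pytest.approx(direct.kappa, rel=1e-12)

    def test_disjoint_events_error(self):
        rows = [["E1", "BEST_PRACTICE", "PROBABLY", "CONCORDANT"],
                ["E2", "ALGORITHM", "PROBABLY", "CONCORDANT"]]
        frame = pd.DataFrame(rows, columns=["event_id", "method", "final_rating", "path"])
        with pytest.raises(EmptySubsetError):
            intermethod_agreement(frame, "BEST_PRACTICE", "ALGORITHM")
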