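"""Rankings, rank-sum tests, Spearman correlation, group profiles."""

import numpy as np
import pytest

import fpikit as fp
from tests._oracles import ranksum_p_by_enumeration


def table_from_scores(scores):
    """Minimal one-node ScoreTable from {case_id: score or None}."""
    import pandas as pd

    rows = [
        (cid, "tbl", "indicator", "node", float("nan") if s is None else float(s), 1.0, False, "")
        for cid, s in scores.items()
    ]
    frame = pd.DataFrame(
        rows,
        columns=["case_id", "partitioning", "node_level", "node_id", "score", "coverage", "flag", "color"],
    )
    return fp.ScoreTable(frame=frame, partitioning="tbl")


class TestRankCases:
    def test_descending_order_with_ranks(self):
        r = fp.rank_cases(table_from_scores({"A": 5, "B": 3, "C": 4}), "node")
        assert r.case_ids == ["A", "C", "B"]
        assert [e[2] for e in r.entries] == [1.0, 2.0, 3.0]

    def test_ties_get_average_ranks(self):
        r = fp.rank_cases(table_from_scores({"A": 4, "B": 4}), "node")
        assert [e[2] for e in r.entries] == [1.5, 1.5]
        assert r.case_ids == ["A", "B"]  # tie broken by case_id

    def test_rank_sum_identity(self):
        r = fp.rank_cases(table_from_scores({"A": 5, "B": 3, "C": 4, "D": 4}), "node")
        n = len(r.entries)
        assert sum(e[2] for e in r.entries) == pytest.approx(n * (n + 1) / 2)

    def test_missing_excluded_and_listed(self):
        r = fp.rank_cases(table_from_scores({"A": 5, "B": None, "C": 4}), "node")
        assert r.case_ids == ["A", "C"]
        assert r.excluded == ["B"]

    def test_all_missing(self):
        r = fp.rank_cases(table_from_scores({"A": None, "B": None}), "node")
        assert r.entries == []
        assert r.excluded == ["A", "B"]

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            fp.rank_cases(table_from_scores({"A": 5}), "other")


class TestRankSumTest:
    def test_separated_pairs(self):
        r = fp.rank_sum_test([1, 2], [3, 4])
        assert r.statistic_w == 3.0
        assert r.u == 0.0
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(1 / 3)

    def test_separated_triples(self):
        r = fp.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.u == 0.0
        assert r.p_two_sided == pytest.approx(0.1)

    def test_u_w_relation_and_bounds(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=5)
        r = fp.rank_sum_test(x, y)
        assert r.u == pytest.approx(r.statistic_w - r.n1 * (r.n1 + 1) / 2)
        assert 0 <= r.u <= r.n1 * r.n2
        assert 0 < r.p_two_sided <= 1

    def test_identical_samples_large_n(self):
        x = list(range(12))
        r = fp.rank_sum_test(x, x)
        assert r.method == "normal_approx"
        assert r.p_two_sided > 0.9

    def test_ties_fall_back_to_approximation(self):
        r = fp.rank_sum_test([1, 2, 2], [2, 3, 4])
        assert r.method == "normal_approx"

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            fp.rank_sum_test([], [1.0])

    def test_exact_matches_enumeration_exhaustively(self):
        """Exact branch equals complete enumeration for all n1, n2 <= 6."""
        rng = np.random.default_rng(42)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                for _ in range(4):
                    vals = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
                    x, y = list(vals[:n1]), list(vals[n1:])
                    r = fp.rank_sum_test(x, y)
                    assert r.method == "exact"
                    assert r.p_two_sided == pytest.approx(
                        ranksum_p_by_enumeration(x, y), abs=1e-12
                    )


class TestRankCorrelation:
    def _ranking(self, scores):
        return fp.rank_cases(table_from_scores(scores), "node")

    def test_identical_rankings(self):
        r = self._ranking({"A": 5, "B": 4, "C": 3})
        assert fp.rank_correlation(r, r) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        r1 = self._ranking({"A": 5, "B": 4, "C": 3, "D": 2})
        r2 = self._ranking({"A": 2, "B": 3, "C": 4, "D": 5})
        assert fp.rank_correlation(r1, r2) == pytest.approx(-1.0)

    def test_one_swap_of_four(self):
        # swapping two adjacent cases: rho = 1 - 6*2 / (4*15) = 0.8
        r1 = self._ranking({"A": 4, "B": 3, "C": 2, "D": 1})
        r2 = self._ranking({"A": 4, "B": 3, "C": 1, "D": 2})
        assert fp.rank_correlation(r1, r2) == pytest.approx(0.8)

    def test_invariant_to_monotone_transform(self):
        scores = {"A": 1.2, "B": 4.7, "C": 2.9, "D": 3.3, "E": 2.0}
        transformed = {k: v**3 + 2 for k, v in scores.items()}
        r1, r2 = self._ranking(scores), self._ranking(transformed)
        base = self._ranking({"A": 5, "B": 1, "C": 3, "D": 2, "E": 4})
        assert fp.rank_correlation(r1, base) == pytest.approx(
            fp.rank_correlation(r2, base)
        )

    def test_mismatched_case_sets_raise(self):
        with pytest.raises(ValueError):
            fp.rank_correlation(
                self._ranking({"A": 1, "B": 2}), self._ranking({"A": 1, "C": 2})
            )

    def test_too_few_cases_raise(self):
        with pytest.raises(ValueError):
            fp.rank_correlation(self._ranking({"A": 1}), self._ranking({"A": 2}))


class TestGroupTables:
    def test_identical_sheets_give_equal_columns(self, schema, uniform, make_case):
        levels = {m.metric_id: 3 for m in schema.output_metrics}
        a = make_case(levels, case_id="a", status="developed")
        b = make_case(levels, case_id="b", status="developing")
        means = fp.group_dimension_means([a, b], schema, uniform)
        assert np.allclose(means["developed"], means["developing"], equal_nan=True)

    def test_unlabeled_case_raises(self, schema, uniform, make_case):
        case = make_case({"crew_earnings": 3}, status="")
        with pytest.raises(ValueError):
            fp.group_dimension_means([case], schema, uniform)

    def test_grouping_mapping_supported(self, schema, uniform, make_case):
        a = make_case({"crew_earnings": 5}, case_id="a")
        b = make_case({"crew_earnings": 1}, case_id="b")
        means = fp.group_dimension_means(
            [a, b], schema, uniform, grouping={"a": "g1", "b": "g2"}
        )
        assert means.at["labor_returns", "g1"] == pytest.approx(5.0)
        assert means.at["labor_returns", "g2"] == pytest.approx(1.0)


class TestQualityProfile:
    def test_all_a_everywhere(self, schema, make_case):
        levels = {m.metric_id: 3 for m in schema.output_metrics}
        quality = {m.metric_id: "A" for m in schema.output_metrics}
        case = make_case(levels, quality=quality)
        prof = fp.quality_profile([case], schema, partitioning="sector")
        assert np.allclose(prof["developed"].dropna(), 3.0)

    def test_half_a_half_c_is_midpoint(self, schema, make_case):
        mids = schema.metric_ids_of("s_risk", "sector")[:4]
        case = make_case(
            {m: 3 for m in mids},
            quality={m: ("A" if i < 2 else "C") for i, m in enumerate(mids)},
        )
        prof = fp.quality_profile([case], schema, partitioning="sector")
        assert prof.at["s_risk", "developed"] == pytest.approx(2.0)

    def test_a_b_b_mean(self, schema, make_case):
        mids = schema.metric_ids_of("s_risk", "sector")[:3]
        case = make_case(
            {m: 3 for m in mids},
            quality=dict(zip(mids, ["A", "B", "B"])),
        )
        prof = fp.quality_profile([case], schema, partitioning="sector")
        assert prof.at["s_risk", "developed"] == pytest.approx(7 / 3)

    def test_custom_quality_map(self, schema, make_case):
        mids = schema.metric_ids_of("s_risk", "sector")[:2]
        case = make_case({m: 3 for m in mids}, quality={m: "C" for m in mids})
        prof = fp.quality_profile(
            [case], schema, partitioning="sector", quality_map={"A": 1, "B": 2, "C": 3}
        )
        assert prof.at["s_risk", "developed"] == pytest.approx(3.0)
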