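"""Dimension/indicator aggregation, quality weighting, color binning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fpikit as fp
from tests._oracles import flat_metric_mean


def levels_case(schema, dim_id, levels, quality=()):
    """Case scoring the first len(levels) metrics of one dimension."""
    part = schema.dimension(dim_id).partitioning
    mids = schema.metric_ids_of(dim_id, part)[: len(levels)]
    quality = dict(zip(mids, quality))
    scores = [fp.MetricScore(m, l, quality.get(m)) for m, l in zip(mids, levels)]
    return fp.CaseStudy("c", "f", "x", 2015, "developed", scores=scores)


class TestDimensionScore:
    def test_uniform_mean(self, schema, uniform):
        case = levels_case(schema, "risk", [3, 4, 5])
        assert fp.dimension_score(case, "risk", schema, uniform) == pytest.approx(4.0)

    def test_equal_levels_any_weights(self, schema):
        scheme = fp.WeightingScheme(quality_weights={"A": 2.0, "B": 0.5, "C": 0.1})
        case = levels_case(schema, "risk", [4, 4, 4], quality=["A", "B", "C"])
        assert fp.dimension_score(case, "risk", schema, scheme) == pytest.approx(4.0)

    def test_quality_weighted_mean(self, schema):
        scheme = fp.WeightingScheme(quality_weights={"A": 1.0, "B": 0.6, "C": 0.3})
        case = levels_case(schema, "risk", [2, 4], quality=["A", "C"])
        expected = (2 * 1.0 + 4 * 0.3) / 1.3
        assert fp.dimension_score(case, "risk", schema, scheme) == pytest.approx(expected)

    def test_unscored_dimension_is_missing(self, schema, uniform, make_case):
        case = make_case({"crew_earnings": 3})
        assert fp.dimension_score(case, "risk", schema, uniform) is fp.MISSING

    def test_unknown_dimension_raises(self, schema, uniform, make_case):
        with pytest.raises(KeyError):
            fp.dimension_score(make_case({}), "nope", schema, uniform)

    @given(levels=st.lists(st.integers(1, 5), min_size=1, max_size=5))
    def test_bounds_and_permutation_invariance(self, levels):
        schema = fp.default_schema()
        scheme = fp.WeightingScheme()  # default decreasing quality weights
        quality = ["A", "B", "C", "A", "B"][: len(levels)]
        case = levels_case(schema, "risk", levels, quality)
        s = fp.dimension_score(case, "risk", schema, scheme)
        assert min(levels) <= s <= max(levels)
        perm_case = fp.CaseStudy(
            "c", "f", "x", 2015, "developed", scores=list(reversed(case.scores))
        )
        assert fp.dimension_score(perm_case, "risk", schema, scheme) == pytest.approx(s)

    @given(levels=st.lists(st.integers(1, 5), min_size=1, max_size=5), w=st.floats(0.1, 3.0))
    def test_uniform_weight_value_is_irrelevant(self, levels, w):
        """Any uniform A=B=C weighting reproduces the unweighted mean."""
        schema = fp.default_schema()
        case = levels_case(schema, "risk", levels, ["A", "B", "C", "A", "B"][: len(levels)])
        s_u = fp.dimension_score(case, "risk", schema, fp.WeightingScheme.uniform())
        scheme = fp.WeightingScheme(quality_weights={"A": w, "B": w, "C": w})
        assert fp.dimension_score(case, "risk", schema, scheme) == pytest.approx(s_u)
        assert s_u == pytest.approx(float(np.mean(levels)))

    def test_removing_metric_at_the_mean_leaves_score(self, schema, uniform):
        case = levels_case(schema, "risk", [3, 4, 5])  # mean 4.0
        before = fp.dimension_score(case, "risk", schema, uniform)
        trimmed = fp.CaseStudy(
            "c", "f", "x", 2015, "developed",
            scores=[s for s in case.scores if s.level != 4],
        )
        assert fp.dimension_score(trimmed, "risk", schema, uniform) == pytest.approx(before)


class TestIndicatorScore:
    def test_dimension_mean(self, schema, uniform, full_case):
        dims = schema.dimension_ids_of_indicator("economics", "tbl")
        dim_scores = [fp.dimension_score(full_case, d, schema, uniform) for d in dims]
        expected = float(np.mean(dim_scores))
        got = fp.indicator_score(full_case, "economics", "tbl", schema, uniform)
        assert got == pytest.approx(expected)

    def test_two_dimension_example(self, schema, uniform):
        # harvest metrics all 3, risk metrics all 5 -> indicator mean over
        # scored dimensions is 4.0
        mids = schema.metric_ids_of("harvest", "tbl") + schema.metric_ids_of("risk", "tbl")
        levels = [3] * 6 + [5] * 5
        case = fp.CaseStudy(
            "c", "f", "x", 2015, "developed",
            scores=[fp.MetricScore(m, l) for m, l in zip(mids, levels)],
        )
        assert fp.indicator_score(case, "economics", "tbl", schema, uniform) == pytest.approx(4.0)

    def test_single_dimension_ecology_identity(self, schema, uniform, full_case):
        ind = fp.indicator_score(full_case, "ecology", "tbl", schema, uniform)
        dim = fp.dimension_score(full_case, "stock_health", schema, uniform)
        assert ind == pytest.approx(dim)

    def test_metric_mean_matches_flat_oracle(self, schema, full_case):
        scheme = fp.WeightingScheme.uniform(indicator_method="metric_mean")
        for ind in ("ecology", "economics", "community"):
            got = fp.indicator_score(full_case, ind, "tbl", schema, scheme)
            oracle = flat_metric_mean(full_case, schema.metric_ids_of(ind, "tbl"))
            assert got == pytest.approx(oracle)

    def test_methods_differ_when_dimension_sizes_differ(self, schema, full_case):
        flat = fp.WeightingScheme.uniform(indicator_method="metric_mean")
        nested = fp.WeightingScheme.uniform()
        a = fp.indicator_score(full_case, "economics", "tbl", schema, flat)
        b = fp.indicator_score(full_case, "economics", "tbl", schema, nested)
        assert a != pytest.approx(b, abs=1e-9)

    def test_unknown_indicator_raises(self, schema, uniform, full_case):
        with pytest.raises(KeyError):
            fp.indicator_score(full_case, "nope", "tbl", schema, uniform)


class TestColorBin:
    @pytest.mark.parametrize(
        "score,color",
        [(2.9, "red"), (3.0, "yellow"), (3.99, "yellow"), (4.0, "green"), (5.0, "green"), (1.0, "red")],
    )
    def test_default_bins(self, score, color):
        assert fp.color_bin(score) == color

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fp.color_bin(0.5)
        with pytest.raises(ValueError):
            fp.color_bin(5.5)

    def test_custom_bins(self):
        assert fp.color_bin(2.5, bins=(2.0, 3.0)) == "yellow"


class TestScoreAll:
    def test_one_full_case(self, schema, uniform, full_case):
        table = fp.score_all([full_case], schema, uniform, "tbl")
        assert len(table.frame) == 14 + 3  # dimensions + indicators
        scores = table.frame["score"]
        assert ((scores >= 1) & (scores <= 5)).all()
        assert (table.frame["coverage"] == 1.0).all()
        assert not table.frame["flag"].any()

    def test_empty_case_list(self, schema, uniform):
        table = fp.score_all([], schema, uniform, "tbl")
        assert table.frame.empty
        assert list(table.frame.columns) == [
            "case_id", "partitioning", "node_level", "node_id",
            "score", "coverage", "flag", "color",
        ]

    def test_low_coverage_flagged(self, schema, make_case):
        scheme = fp.WeightingScheme.uniform(min_coverage=0.5)
        case = make_case({"landings_volatility": 4})  # 1 of 5 risk metrics
        table = fp.score_all([case], schema, scheme, "tbl")
        row = table.frame[table.frame["node_id"] == "risk"].iloc[0]
        assert row["flag"]
        assert row["score"] == pytest.approx(4.0)

    def test_missing_rendered_as_nan_with_blank_color(self, schema, uniform, make_case):
        table = fp.score_all([make_case({"crew_earnings": 2})], schema, uniform, "tbl")
        risk = table.frame[table.frame["node_id"] == "risk"].iloc[0]
        assert np.isnan(risk["score"])
        assert risk["color"] == ""

    def test_row_order_deterministic(self, schema, uniform, full_case):
        t1 = fp.score_all([full_case], schema, uniform, "sector")
        t2 = fp.score_all([full_case], schema, uniform, "sector")
        assert t1.frame.equals(t2.frame)


class TestWeightingScheme:
    def test_rejects_all_zero_weights(self):
        with pytest.raises(ValueError):
            fp.WeightingScheme(quality_weights={"A": 0.0, "B": 0.0, "C": 0.0})

    def test_rejects_negative_weight(self):
        with pytest.raises(ValueError):
            fp.WeightingScheme(quality_weights={"A": 1.0, "B": -0.1, "C": 0.3})

    def test_rejects_unknown_indicator_method(self):
        with pytest.raises(ValueError):
            fp.WeightingScheme(indicator_method="median")
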