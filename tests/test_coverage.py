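"""Coverage statistics: printed-pair reproduction, rounding, properties."""

import random

import pytest
from hypothesis import given, strategies as st

from mitschema import (
    PlantSpec,
    compare_reports,
    coverage_report,
    crosswalk_fixture_from_counts,
    generate_vocabulary,
    auto_crosswalk,
    percent_half_up,
)
from mitschema.coverage import CoverageError

MODULES = [
    "general_information",
    "material_information",
    "biological_model_information",
    "exposure_information",
    "endpoint_readout_information",
    "analysis_statistics",
]
MODULE_SIZES = [22, 32, 69, 48, 98, 31]

# every published (percent, matched, total) pair of the two compatibility
# analyses, both mapping modes
PRINTED_PAIRS = [
    (34, 113, 333),
    (17, 55, 333),
    (24, 8, 33),
    (15, 5, 33),
    (35, 105, 300),
    (17, 50, 300),
    (77, 231, 300),
    (86, 257, 300),
    (91, 29, 32),
    (64, 14, 22),
    (23, 16, 69),
    (27, 13, 48),
    (22, 22, 98),
    (35, 11, 31),
    (59, 13, 22),
    (81, 26, 32),
    (84, 58, 69),
    (94, 45, 48),
    (15, 15, 98),
    (84, 26, 31),
]

ENM_ONE_TO_ONE_MODULE_COUNTS = [14, 29, 16, 13, 22, 11]


class TestPercentArithmetic:
    @pytest.mark.parametrize("percent,matched,total", PRINTED_PAIRS)
    def test_half_up_reproduces_every_printed_pair(self, percent, matched, total):
        assert percent_half_up(matched, total) == percent

    def test_half_up_has_no_float_artifacts(self):
        # 0.5 boundary cases round up
        assert percent_half_up(1, 200) == 1
        assert percent_half_up(1, 8) == 13
        assert percent_half_up(0, 0) == 0


@pytest.fixture(scope="module")
def one_to_one(reference):
    counts = {"grouping": (8, 0)}
    counts.update(
        (mid, (n, 0)) for mid, n in zip(MODULES, ENM_ONE_TO_ONE_MODULE_COUNTS)
    )
    xw = crosswalk_fixture_from_counts(reference, counts)
    return coverage_report(xw, "one_to_one")


class TestEnmCoverage:

    def test_overall_113_of_333_is_34pct(self, one_to_one):
        row = one_to_one.by_stratum["overall"]
        assert (row.matched, row.total, row.percent) == (113, 333, 34)

    def test_grouping_8_of_33_is_24pct(self, one_to_one):
        row = one_to_one.by_stratum["grouping"]
        assert (row.matched, row.total, row.percent) == (8, 33, 24)

    def test_module_counts_aggregate_to_105_of_300(self, one_to_one):
        assert sum(ENM_ONE_TO_ONE_MODULE_COUNTS) == 105
        row = one_to_one.by_stratum["content_bearing"]
        assert (row.matched, row.total, row.percent) == (105, 300, 35)

    @pytest.mark.parametrize(
        "module_id,matched,total,percent",
        [
            ("general_information", 14, 22, 64),
            ("material_information", 29, 32, 91),
            ("biological_model_information", 16, 69, 23),
            ("exposure_information", 13, 48, 27),
            ("endpoint_readout_information", 22, 98, 22),
            ("analysis_statistics", 11, 31, 35),
        ],
    )
    def test_per_module_rows(self, one_to_one, module_id, matched, total, percent):
        row = one_to_one.by_stratum[module_id]
        assert (row.matched, row.total, row.percent) == (matched, total, percent)

    def test_partial_mode_reaches_231_of_300(self, reference):
        extra_partial = [8, 3, 53, 35, 7, 20]  # 126 more within module capacity
        assert sum(extra_partial) == 231 - 105
        counts = {"grouping": (8, 0)}
        counts.update(
            (mid, (e, p))
            for mid, e, p in zip(
                MODULES, ENM_ONE_TO_ONE_MODULE_COUNTS, extra_partial
            )
        )
        xw = crosswalk_fixture_from_counts(reference, counts)
        row = coverage_report(xw, "partial").by_stratum["content_bearing"]
        assert (row.matched, row.total, row.percent) == (231, 300, 77)

    def test_partial_gain_over_one_to_one_is_42_points(self, reference):
        extra_partial = [8, 3, 53, 35, 7, 20]
        counts = {"grouping": (8, 0)}
        counts.update(
            (mid, (e, p))
            for mid, e, p in zip(
                MODULES, ENM_ONE_TO_ONE_MODULE_COUNTS, extra_partial
            )
        )
        xw = crosswalk_fixture_from_counts(reference, counts)
        delta = compare_reports(
            coverage_report(xw, "one_to_one"), coverage_report(xw, "partial")
        )
        content = delta[delta.stratum == "content_bearing"].iloc[0]
        assert content.delta == 77 - 35 == 42


class TestIsaTabCoverage:
    def test_one_to_one_overall_55_of_333(self, reference):
        exact = [5, 5, 12, 8, 15, 5]  # content split summing to the printed 50
        assert sum(exact) == 50
        counts = {"grouping": (5, 0)}
        counts.update((mid, (e, 0)) for mid, e in zip(MODULES, exact))
        report = coverage_report(
            crosswalk_fixture_from_counts(reference, counts), "one_to_one"
        )
        assert report.by_stratum["grouping"].percent == 15
        row = report.by_stratum["overall"]
        assert (row.matched, row.total, row.percent) == (55, 333, 17)
        content = report.by_stratum["content_bearing"]
        assert (content.matched, content.percent) == (50, 17)

    @pytest.mark.parametrize(
        "module_id,matched,total,percent",
        [
            ("general_information", 13, 22, 59),
            ("material_information", 26, 32, 81),
            ("biological_model_information", 58, 69, 84),
            ("exposure_information", 45, 48, 94),
            ("endpoint_readout_information", 15, 98, 15),
            ("analysis_statistics", 26, 31, 84),
        ],
    )
    def test_partial_per_module_pairs(self, reference, module_id, matched, total, percent):
        # checked pair by pair: the published per-module partial counts do
        # not aggregate to the published overall partial count, so no
        # cross-consistency is asserted for this target
        counts = {module_id: (0, matched)}
        report = coverage_report(
            crosswalk_fixture_from_counts(reference, counts), "partial"
        )
        row = report.by_stratum[module_id]
        assert (row.matched, row.total, row.percent) == (matched, total, percent)

    def test_partial_content_total_257_of_300(self, reference):
        partial = [22, 32, 69, 48, 55, 31]
        assert sum(partial) == 257
        counts = dict(zip(MODULES, ((0, p) for p in partial)))
        report = coverage_report(
            crosswalk_fixture_from_counts(reference, counts), "partial"
        )
        row = report.by_stratum["content_bearing"]
        assert (row.matched, row.total, row.percent) == (257, 300, 86)


class TestProperties:
    def test_all_exact_crosswalk_all_strata_100(self, reference):
        counts = {"grouping": (33, 0)}
        counts.update((mid, (n, 0)) for mid, n in zip(MODULES, MODULE_SIZES))
        report = coverage_report(
            crosswalk_fixture_from_counts(reference, counts), "one_to_one"
        )
        assert all(r.percent == 100 for r in report.rows)

    def test_all_zero_spec_gives_0_everywhere(self, reference):
        report = coverage_report(
            crosswalk_fixture_from_counts(reference, {}), "partial"
        )
        assert all(r.matched == 0 and r.percent == 0 for r in report.rows)

    def test_count_exceeding_stratum_is_a_bounds_error(self, reference):
        with pytest.raises(CoverageError, match="exceed"):
            crosswalk_fixture_from_counts(reference, {"general_information": (23, 0)})

    @given(seed=st.integers(0, 2**20))
    def test_spec_round_trips_through_fixture_and_report(self, reference, seed):
        rng = random.Random(seed)
        spec = {}
        for mid, size in zip(MODULES, MODULE_SIZES):
            e = rng.randint(0, size)
            spec[mid] = (e, rng.randint(0, size - e))
        g = rng.randint(0, 33)
        spec["grouping"] = (g, rng.randint(0, 33 - g))
        xw = crosswalk_fixture_from_counts(reference, spec)
        one = coverage_report(xw, "one_to_one").by_stratum
        both = coverage_report(xw, "partial").by_stratum
        for stratum, (n_exact, n_partial) in spec.items():
            assert one[stratum].matched == n_exact
            assert both[stratum].matched == n_exact + n_partial

    @given(seed=st.integers(0, 2**20))
    def test_partial_mode_dominates_one_to_one_in_every_stratum(self, reference, seed):
        vocab, _ = generate_vocabulary(reference, PlantSpec(0.3, 0.3, 0.4, seed=seed))
        xw = auto_crosswalk(reference, vocab)
        one = coverage_report(xw, "one_to_one")
        both = coverage_report(xw, "partial")
        for a, b in zip(one.rows, both.rows):
            assert b.percent >= a.percent
            assert b.matched >= a.matched

    def test_counts_match_brute_force_recount(self, reference):
        vocab, _ = generate_vocabulary(reference, PlantSpec(0.4, 0.2, 0.4, seed=13))
        xw = auto_crosswalk(reference, vocab)
        report = coverage_report(xw, "one_to_one")
        by_field = {d.field_id: d for d in xw.decisions}
        for module in reference.modules:
            expected = sum(
                1
                for f in module.content_fields()
                if by_field[f.field_id].match_type == "exact"
            )
            assert report.by_stratum[module.module_id].matched == expected

    def test_reports_over_different_strata_not_comparable(self, reference):
        r = coverage_report(crosswalk_fixture_from_counts(reference, {}), "partial")
        import copy

        other = copy.deepcopy(r)
        other.rows = other.rows[:-1]
        with pytest.raises(CoverageError, match="comparable"):
            compare_reports(r, other)

    def test_report_vs_itself_all_deltas_zero(self, reference):
        r = coverage_report(crosswalk_fixture_from_counts(reference, {}), "partial")
        assert (compare_reports(r, r).delta == 0).all()
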