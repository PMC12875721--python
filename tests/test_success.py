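import pytest

from axenet.master_table import MasterTable
from axenet.success import (
    FILTER_LIMIT,
    division_summary,
    method_success_rates,
    success_rate_frame,
)

from conftest import record, table


def uses_table(n_uses, n_success, method="Mkpk", division="diatoms"):
    recs = [
        record(
            pub=f"p{i}",
            species="sp",
            division=division,
            methods=(method,),
            outcome="success" if i < n_success else "failure",
        )
        for i in range(n_uses)
    ]
    return table(*recs)


def entry(entries, method):
    return next(e for e in entries if e.method == method)


class TestMethodSuccessRates:
    def test_rate_is_successes_over_uses(self):
        entries = method_success_rates(uses_table(10, 7), "diatoms")
        e = entry(entries, "Mkpk")
        assert (e.n_uses, e.n_success, e.rate) == (10, 7, 0.7)

    def test_zero_successes_give_zero_rate(self):
        e = entry(method_success_rates(uses_table(7, 0), "diatoms"), "Mkpk")
        assert e.rate == 0.0

    def test_exactly_six_uses_is_below_filter_limit(self):
        e = entry(method_success_rates(uses_table(FILTER_LIMIT, 6), "diatoms"), "Mkpk")
        assert e.below_filter_limit and e.rate is None

    def test_seven_uses_is_above_filter_limit(self):
        e = entry(method_success_rates(uses_table(FILTER_LIMIT + 1, 7), "diatoms"), "Mkpk")
        assert not e.below_filter_limit and e.rate == 1.0

    def test_repeated_method_in_one_workflow_counts_once(self):
        tbl = table(record(methods=("Wash", "Wash", "Wash")))
        e = entry(method_success_rates(tbl, "diatoms"), "Wash")
        assert e.n_uses == 1

    def test_partial_counts_toward_uses_not_successes(self):
        recs = [
            record(pub=f"p{i}", methods=("Fltr",), outcome="partial")
            for i in range(8)
        ]
        e = entry(method_success_rates(table(*recs), "diatoms"), "Fltr")
        assert (e.n_uses, e.n_success, e.rate) == (8, 0, 0.0)

    def test_duplicating_records_preserves_rate_but_can_clear_bfl(self):
        tbl = uses_table(4, 3)
        before = entry(method_success_rates(tbl, "diatoms"), "Mkpk")
        doubled = table(
            *tbl.records,
            *(
                record(
                    pub=f"{r.publication_id}x",
                    species=r.species,
                    division=r.division,
                    methods=r.methods,
                    outcome=r.outcome,
                )
                for r in tbl.records
            ),
        )
        after = entry(method_success_rates(doubled, "diatoms"), "Mkpk")
        assert before.below_filter_limit and not after.below_filter_limit
        assert after.rate == pytest.approx(before.n_success / before.n_uses)

    def test_total_uses_at_least_record_count(self, synthetic_default):
        tbl, _ = synthetic_default
        entries = method_success_rates(tbl, "green_algae")
        n_records = sum(1 for r in tbl.records if r.division == "green_algae")
        assert sum(e.n_uses for e in entries) >= n_records

    def test_frame_formats_bfl_and_two_decimals(self):
        frame = success_rate_frame(method_success_rates(uses_table(9, 6), "diatoms"))
        assert frame.loc[0, "rate"] == "0.67"
        frame_bfl = success_rate_frame(method_success_rates(uses_table(3, 1), "diatoms"))
        assert frame_bfl.loc[0, "rate"] == "BFL"

    def test_empty_division_rejected(self):
        with pytest.raises(ValueError):
            method_success_rates(uses_table(3, 1), "other")


class TestDivisionSummary:
    def test_outcome_tally_at_publication_level(self):
        tbl = table(
            record(pub="p1", species="a", outcome="success"),
            record(pub="p1", species="b", outcome="success"),
            record(pub="p2", species="a", outcome="failure"),
            record(pub="p3", species="a", outcome="success"),
            record(pub="p3", species="b", outcome="failure"),
        )
        summary = division_summary(tbl)["diatoms"]
        assert summary.outcome_tally == {"Yes": 1, "No": 1, "Multi/Part": 1}
        assert summary.n_publications == 3

    def test_tallies_sum_to_publication_count(self, synthetic_default):
        tbl, _ = synthetic_default
        for div, summary in division_summary(tbl).items():
            assert sum(summary.outcome_tally.values()) == summary.n_publications

    def test_partial_outcome_maps_to_multi_part(self):
        tbl = table(record(pub="p1", outcome="partial"))
        assert division_summary(tbl)["diatoms"].outcome_tally["Multi/Part"] == 1

    def test_empty_table_gives_all_zero_summary(self):
        summary = division_summary(MasterTable(()))
        for div in summary.values():
            assert div.n_publications == 0
            assert sum(div.outcome_tally.values()) == 0

    def test_method_type_counts_unique_methods(self):
        tbl = table(
            record(pub="p1", species="a", methods=("AntB", "Fltr")),
            record(pub="p2", species="a", methods=("AntB", "Wash", "CoCu")),
        )
        counts = division_summary(tbl)["diatoms"].method_type_counts
        assert counts == {"Biological": 1, "Chemical": 1, "Physical": 2}

    def test_genera_counted_from_species_binomials(self):
        tbl = table(
            record(pub="p1", species="Navicula alpha"),
            record(pub="p1", species="Navicula beta"),
            record(pub="p2", species="Nitzschia gamma"),
        )
        assert division_summary(tbl)["diatoms"].n_genera == 2
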