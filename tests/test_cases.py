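"""Case-level merge, drug matching, pair expansion, and ICSR counting."""

import numpy as np
import pytest

from srsignal.cases import (
    count_unique_icsrs,
    expand_pairs,
    filter_primary_suspect,
    merge_case_level,
)
from srsignal.dates import PartialDate
from srsignal.io import read_jader_tables, write_jader_tables
from srsignal.lexicon import DEFAULT_LEXICON, compile_lexicon, match_drug
from srsignal.model import CaseRecord, DrugEntry, DrugEventPair, EventEntry, Role, Sex

LEX = compile_lexicon(DEFAULT_LEXICON)


class TestMatchDrug:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("  fenofibric acid ", "fenofibrate"),
            ("CHOLINE  FENOFIBRATE", "fenofibrate"),
            ("PEMAFIBRATE", "pemafibrate"),
            ("ペマフィブラート", "pemafibrate"),
            ("bezafibrate", "bezafibrate"),
            ("ASPIRIN", None),
        ],
    )
    def test_normalized_exact_matching(self, raw, expected):
        assert match_drug(raw, LEX) == expected


class TestMergeJader:
    def test_left_merge_semantics(self, jader_tables):
        cases = merge_case_level(jader_tables, "jader")
        assert len(cases) == 3
        by_id = {c.case_id: c for c in cases}
        assert len(by_id["JP1"].drugs) == 2
        assert len(by_id["JP1"].events) == 2
        assert len(by_id["JP3"].drugs) == 0 and len(by_id["JP3"].events) == 0

    def test_demographics_parsed(self, jader_tables):
        by_id = {c.case_id: c for c in merge_case_level(jader_tables, "jader")}
        c1 = by_id["JP1"]
        assert c1.sex is Sex.MALE
        assert c1.age_band == "60s"
        assert c1.height_band_cm == (160, 170)
        assert c1.weight_band_kg == (60, 70)
        assert c1.report_year == 2022
        assert by_id["JP3"].sex is Sex.UNKNOWN
        assert by_id["JP3"].age_band is None

    def test_suspect_role_maps_to_primary_suspect(self, jader_tables):
        by_id = {c.case_id: c for c in merge_case_level(jader_tables, "jader")}
        roles = [d.role for d in by_id["JP1"].drugs]
        assert roles == [Role.PRIMARY_SUSPECT, Role.CONCOMITANT]

    def test_partial_therapy_date_kept_incomplete(self, jader_tables):
        by_id = {c.case_id: c for c in merge_case_level(jader_tables, "jader")}
        aspirin = by_id["JP1"].drugs[1]
        assert aspirin.therapy_start == PartialDate(2022, 1)
        assert not aspirin.therapy_start.is_complete

    def test_orphan_event_rows_dropped_with_warning(self, jader_tables, caplog):
        tables = dict(jader_tables)
        reac = tables["reac"].copy()
        reac.loc[len(reac)] = ["JP99", "Nausea", "10028813", ""]
        tables["reac"] = reac
        with caplog.at_level("WARNING"):
            cases = merge_case_level(tables, "jader")
        assert len(cases) == 3
        assert sum(len(c.events) for c in cases) == 3
        assert any("orphan" in r.message for r in caplog.records)

    def test_roundtrip_through_files(self, jader_tables, tmp_path):
        paths = write_jader_tables(jader_tables, tmp_path)
        reread = read_jader_tables(paths)
        a = merge_case_level(jader_tables, "jader")
        b = merge_case_level(reread, "jader")
        assert a == b


class TestMergeFaers:
    def test_dedup_then_merge(self, faers_tables):
        cases = merge_case_level(faers_tables, "faers")
        assert len(cases) == 2
        by_id = {c.case_id: c for c in cases}
        # case 100 resolves to version 2, whose children attach
        assert by_id["100"].case_version == 2
        assert [d.raw_name for d in by_id["100"].drugs] == ["PEMAFIBRATE", "ASPIRIN"]
        assert by_id["100"].drugs[0].role is Role.PRIMARY_SUSPECT
        assert by_id["100"].drugs[1].role is Role.CONCOMITANT
        assert by_id["200"].drugs[0].role is Role.SECONDARY_SUSPECT

    def test_therapy_start_linked_by_drug_seq(self, faers_tables):
        by_id = {c.case_id: c for c in merge_case_level(faers_tables, "faers")}
        assert by_id["100"].drugs[0].therapy_start == PartialDate(2023, 1, 5)
        assert by_id["100"].drugs[1].therapy_start is None

    def test_event_date_from_demo_applied_to_reactions(self, faers_tables):
        by_id = {c.case_id: c for c in merge_case_level(faers_tables, "faers")}
        assert all(
            e.onset == PartialDate(2023, 3, 10) for e in by_id["100"].events
        )
        # month-only event date stays incomplete
        assert by_id["200"].events[0].onset == PartialDate(2023, 2)

    def test_weight_band_from_kg_value(self, faers_tables):
        by_id = {c.case_id: c for c in merge_case_level(faers_tables, "faers")}
        assert by_id["100"].weight_band_kg == (70, 80)
        assert by_id["200"].weight_band_kg is None


def _case(case_id, drugs, events, **kw):
    return CaseRecord(
        case_id=case_id,
        drugs=[
            DrugEntry(raw_name=n, canonical_drug=match_drug(n, LEX), role=r)
            for n, r in drugs
        ],
        events=[EventEntry(pt_code=e) for e in events],
        **kw,
    )


class TestExpandPairs:
    def test_cross_product_counts(self):
        case = _case(
            "X",
            [("PEMAFIBRATE", Role.PRIMARY_SUSPECT), ("ASPIRIN", Role.CONCOMITANT)],
            ["a", "b", "c"],
        )
        pairs = expand_pairs([case])
        assert len(pairs) == 6
        assert {p.drug for p in pairs} == {"pemafibrate", "ASPIRIN"}

    def test_no_events_no_pairs(self):
        case = _case("X", [("PEMAFIBRATE", Role.PRIMARY_SUSPECT)], [])
        assert expand_pairs([case]) == []

    def test_two_singleton_cases(self):
        cases = [
            _case("X", [("PEMAFIBRATE", Role.PRIMARY_SUSPECT)], ["a"]),
            _case("Y", [("ASPIRIN", Role.CONCOMITANT)], ["b"]),
        ]
        assert len(expand_pairs(cases)) == 2

    def test_pair_count_identity_randomized(self):
        rng = np.random.default_rng(0)
        cases = [
            _case(
                f"C{i}",
                [("ASPIRIN", Role.CONCOMITANT)] * int(rng.integers(0, 5)),
                [f"e{j}" for j in range(int(rng.integers(0, 4)))],
            )
            for i in range(200)
        ]
        pairs = expand_pairs(cases)
        assert len(pairs) == sum(len(c.drugs) * len(c.events) for c in cases)

    def test_duplicate_drug_listings_kept_unless_collapsed(self):
        case = _case(
            "X",
            [("PEMAFIBRATE", Role.PRIMARY_SUSPECT)] * 2,
            ["a"],
        )
        assert len(expand_pairs([case])) == 2
        assert len(expand_pairs([case], collapse_duplicates=True)) == 1


class TestRoleFilterAndCounting:
    def test_only_primary_suspect_kept(self):
        pairs = [
            DrugEventPair("A", "d", "e", Role.PRIMARY_SUSPECT),
            DrugEventPair("A", "d", "e", Role.CONCOMITANT),
            DrugEventPair("B", "d", "e", Role.INTERACTING),
        ]
        kept = filter_primary_suspect(pairs)
        assert len(kept) == 1 and kept[0].case_id == "A"
        assert filter_primary_suspect([]) == []
        assert (
            filter_primary_suspect(
                [DrugEventPair("A", "d", "e", Role.CONCOMITANT)]
            )
            == []
        )

    def test_multi_fibrate_case_counts_once(self):
        case = _case(
            "X",
            [
                ("PEMAFIBRATE", Role.PRIMARY_SUSPECT),
                ("FENOFIBRATE", Role.CONCOMITANT),
            ],
            ["10008629"],
        )
        pairs = expand_pairs([case])
        n = count_unique_icsrs(
            pairs, {"pemafibrate", "fenofibrate"}, {"10008629"}
        )
        assert n == 1 and len(pairs) == 2

    def test_counts_against_brute_force(self):
        rng = np.random.default_rng(7)
        drugs = ["d1", "d2", "d3"]
        events = ["e1", "e2"]
        pairs = [
            DrugEventPair(
                f"C{rng.integers(0, 10)}",
                str(rng.choice(drugs)),
                str(rng.choice(events)),
                Role.CONCOMITANT,
            )
            for _ in range(60)
        ]
        dset, eset = {"d1", "d3"}, {"e2"}
        brute = {p.case_id for p in pairs if p.drug in dset and p.pt_code in eset}
        assert count_unique_icsrs(pairs, dset, eset) == len(brute)
        n_pairs = sum(1 for p in pairs if p.drug in dset and p.pt_code in eset)
        assert count_unique_icsrs(pairs, dset, eset) <= n_pairs

    def test_no_qualifying_pairs(self):
        pairs = [DrugEventPair("A", "d", "e", Role.CONCOMITANT)]
        assert count_unique_icsrs(pairs, {"x"}, {"e"}) == 0
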