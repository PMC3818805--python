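"""Flatfile parsing, query construction, phylum assignment and tallying."""

from __future__ import annotations

import io
from datetime import date

import pytest

from bactgeo import ncbi_filter, taxa
from bactgeo.ncbi_filter import (
    FetchConfig,
    NetworkDisabled,
    ParseLedger,
    SeqRecordMeta,
    assign_phylum,
    build_query,
    fetch_remote,
    flag_environmental,
    parse_genbank,
    tally_ncbi,
)

PHYLA = taxa.default_phyla()


class TestBuildQuery:
    def test_term_contains_four_and_joined_clauses(self):
        term = build_query("France", date(1986, 1, 1), date(2012, 11, 25))
        clauses = term.split(" AND ")
        assert clauses[0] == "country"
        assert clauses[1] == '"France"'
        assert clauses[2] == "Bacteria[Organism]"
        assert "1986/01/01" in clauses[3] and "2012/11/25" in clauses[3]
        assert "[Publication Date]" in clauses[3]

    def test_single_day_window(self):
        d = date(2010, 5, 5)
        term = build_query("USA", d, d)
        assert term.count("2010/05/05") == 2

    def test_multiword_area_is_one_quoted_phrase(self):
        term = build_query("New Zealand", date(2000, 1, 1), date(2001, 1, 1))
        clauses = term.split(" AND ")
        assert len(clauses) == 4
        assert clauses[1] == '"New Zealand"'

    def test_reversed_dates_rejected(self):
        with pytest.raises(ValueError):
            build_query("USA", date(2012, 1, 1), date(1986, 1, 1))


class TestParseGenbank:
    def test_presence_and_absence_of_country_qualifier(self, flatfile_builder):
        text = flatfile_builder(
            [
                {"accession": "A1", "country": "USA"},
                {"accession": "A2", "country": None},
                {"accession": "A3", "country": "France: Alsace"},
            ]
        )
        metas = list(parse_genbank(io.StringIO(text)))
        assert [m.country_qualifier for m in metas] == ["USA", None, "France: Alsace"]

    def test_definition_mentions_are_not_the_qualifier(self, flatfile_builder):
        text = flatfile_builder(
            [
                {
                    "accession": "A1",
                    "country": "France: Alsace",
                    "description": "strain isolated with colleagues from Italy",
                }
            ]
        )
        (meta,) = parse_genbank(io.StringIO(text))
        assert meta.country_qualifier == "France: Alsace"
        assert "Italy" in meta.description

    def test_roundtrip_recovers_all_fields(self, flatfile_builder):
        entries = [
            {
                "accession": f"RT{i:03d}",
                "organism": f"Firmicutes bacterium {i}",
                "lineage": ("Bacteria", "Firmicutes", "Bacilli"),
                "country": f"USA: site {i}" if i % 3 else None,
                "date": "05-MAR-2011",
                "description": f"record {i}",
            }
            for i in range(100)
        ]
        metas = list(parse_genbank(io.StringIO(flatfile_builder(entries))))
        assert len(metas) == 100
        for e, m in zip(entries, metas):
            assert m.accession.startswith(e["accession"])
            assert m.organism == e["organism"]
            assert m.lineage == e["lineage"]
            assert m.country_qualifier == e["country"]
            assert m.publication_date == date(2011, 3, 5)

    def test_malformed_entry_skipped_and_counted(self, flatfile_builder):
        good = flatfile_builder([{"accession": "OK1", "country": "USA"}])
        broken = "ACCESSION   BROKEN1\nnot a flatfile entry\n//\n"
        ledger = ParseLedger()
        metas = list(parse_genbank(io.StringIO(broken + good), ledger=ledger))
        assert [m.accession.startswith("OK1") for m in metas] == [True]
        assert ledger.skipped_truncated == 1
        assert ledger.parsed == 1

    def test_zero_entries_gives_empty_iterator(self):
        assert list(parse_genbank(io.StringIO(""))) == []

    def test_date_window_guard_drops_out_of_window_records(self, flatfile_builder):
        text = flatfile_builder(
            [
                {"accession": "IN1", "date": "01-JUN-2000", "country": "USA"},
                {"accession": "OUT1", "date": "01-JUN-2013", "country": "USA"},
            ]
        )
        ledger = ParseLedger()
        metas = list(
            parse_genbank(
                io.StringIO(text),
                date_window=(date(1986, 1, 1), date(2012, 11, 25)),
                ledger=ledger,
            )
        )
        assert len(metas) == 1 and ledger.skipped_date == 1


class TestAssignPhylum:
    @pytest.mark.parametrize(
        "lineage, expected",
        [
            (["Bacteria", "Proteobacteria", "Gammaproteobacteria"], "Proteobacteria"),
            (["Bacteria", "Deinococcus-Thermus", "Deinococci"], "Deinococcus-Thermus"),
            (["Bacteria", "deinococcus-thermus"], "Deinococcus-Thermus"),
            (["Bacteria", "Tenericutes", "Mollicutes"], "unassigned"),
            (["Bacteria", "Nitrospinae"], "unassigned"),
            (["Bacteria", "environmental samples"], "unassigned"),
            ([], "unassigned"),
        ],
    )
    def test_first_frame_member_or_unassigned(self, lineage, expected):
        assert assign_phylum(lineage, PHYLA) == expected

    def test_result_is_always_frame_member_or_unassigned(self):
        frame = set(PHYLA) | {"unassigned"}
        for lineage in (["Bacteria"], ["Bacteria", "Spirochaetes"], ["X", "Y"]):
            assert assign_phylum(lineage, PHYLA) in frame


class TestFlagEnvironmental:
    def test_environmental_lineage_flags_true(self):
        m = SeqRecordMeta("A", "uncultured bacterium", ("Bacteria", "environmental samples"))
        assert flag_environmental(m)

    def test_plain_lineage_flags_false(self):
        m = SeqRecordMeta("A", "Bacillus sp.", ("Bacteria", "Firmicutes", "Bacilli"))
        assert not flag_environmental(m)

    def test_assigned_and_environmental_both_recorded(self, mini_areas):
        m = SeqRecordMeta(
            "A",
            "uncultured Firmicutes bacterium",
            ("Bacteria", "Firmicutes", "environmental samples"),
            country_qualifier="USA",
        )
        assert flag_environmental(m)
        tally = tally_ncbi([m], mini_areas, PHYLA)
        assert tally.counts.loc["USA", "Firmicutes"] == 1
        assert tally.environmental.loc["USA"] == 1


class TestTallyNcbi:
    def test_uniform_fixture(self, mini_areas):
        metas = [
            SeqRecordMeta(f"A{i}", "x", ("Bacteria", "Proteobacteria"), "USA")
            for i in range(10)
        ]
        m = tally_ncbi(metas, mini_areas, PHYLA)
        assert m.matched.loc["USA"] == 10
        assert m.counts.loc["USA", "Proteobacteria"] == 10

    def test_free_text_country_mention_does_not_count(self, mini_areas):
        metas = [
            SeqRecordMeta(
                "A1",
                "x",
                ("Bacteria", "Proteobacteria"),
                "France",
                description="joint work with Italy",
            )
        ]
        m = tally_ncbi(metas, mini_areas, PHYLA)
        assert m.matched.loc["France"] == 1
        assert m.matched.loc["Italy"] == 0

    def test_conservation_over_mixed_fixture(self, mini_areas):
        metas = [
            SeqRecordMeta("A1", "x", ("Bacteria", "Proteobacteria"), "USA"),
            SeqRecordMeta("A2", "x", ("Bacteria", "Tenericutes"), "France"),
            SeqRecordMeta("A3", "x", ("Bacteria", "Firmicutes"), None),
            SeqRecordMeta("A4", "x", ("Bacteria", "Firmicutes"), "Atlantis"),
        ]
        m = tally_ncbi(metas, mini_areas, PHYLA)
        # per-area: matched = sum of phyla + unassigned, by construction
        assert (m.matched == m.counts.sum(axis=1)).all()
        assert m.total_matched + m.unlocated + m.ambiguous == len(metas)
        assert m.unlocated == 2
        assert m.counts.loc["France", "unassigned"] == 1


class TestFetchRemote:
    def test_disabled_by_default(self, tmp_path):
        with pytest.raises(NetworkDisabled):
            fetch_remote("country AND x", cache_dir=tmp_path)

    def test_mocked_transport_two_record_page(self, tmp_path, flatfile_builder):
        page = flatfile_builder(
            [{"accession": "M1", "country": "USA"}, {"accession": "M2", "country": "USA"}]
        )

        class Stub:
            def __init__(self):
                self.calls = 0

            def search(self, term, retstart, retmax):
                self.calls += 1
                return ["1", "2"] if retstart == 0 else []

            def fetch(self, ids):
                return page

        out = fetch_remote(
            "country AND x",
            batch_size=2,
            cache_dir=tmp_path,
            config=FetchConfig(allow_network=True),
            transport=Stub(),
            _sleep=lambda s: None,
        )
        metas = list(parse_genbank(out))
        assert len(metas) == 2

    def test_empty_result_set_gives_empty_cache(self, tmp_path):
        class Stub:
            def search(self, term, retstart, retmax):
                return []

            def fetch(self, ids):  # pragma: no cover - never reached
                raise AssertionError

        out = fetch_remote(
            "country AND x",
            cache_dir=tmp_path,
            config=FetchConfig(allow_network=True),
            transport=Stub(),
            _sleep=lambda s: None,
        )
        assert out.read_text() == ""
        assert list(parse_genbank(out)) == []

    def test_transport_failure_aborts_with_resumable_cursor(self, tmp_path):
        class Flaky:
            def search(self, term, retstart, retmax):
                raise OSError("boom")

            def fetch(self, ids):
                raise OSError("boom")

        with pytest.raises(RuntimeError, match="resume cursor"):
            fetch_remote(
                "q",
                cache_dir=tmp_path,
                config=FetchConfig(allow_network=True),
                transport=Flaky(),
                _sleep=lambda s: None,
            )
        assert (tmp_path / "fetch.cursor").read_text() == "0"
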