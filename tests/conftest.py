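"""Shared fixtures: a small area frame, flatfile builders, corpora."""

from __future__ import annotations

import io

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from bactgeo.geography import GeoArea, default_area_list


@pytest.fixture(scope="session")
def areas208():
    return default_area_list()


@pytest.fixture()
def mini_areas():
    """A six-area frame including the Congo exception pair."""
    from bactgeo.geography import _derive_ambiguity

    raw = [
        GeoArea("USA", "AMERICA"),
        GeoArea("France", "EUROPE"),
        GeoArea("Italy", "EUROPE"),
        GeoArea("Republic of the Congo", "AFRICA"),
        GeoArea("Democratic Republic of Congo", "AFRICA"),
        GeoArea("New Zealand", "AUSTRALIA-OCEANIA"),
    ]
    return _derive_ambiguity(raw)


def make_flatfile(entries) -> str:
    """Build flatfile text from simple dicts (accession, organism,
    lineage, country, date, description)."""
    records = []
    for e in entries:
        rec = SeqRecord(
            Seq(e.get("seq", "ACGTACGTACGT")),
            id=e["accession"],
            name=e["accession"],
            description=e.get("description", "synthetic test record"),
            annotations={
                "molecule_type": "DNA",
                "organism": e.get("organism", "Proteobacteria bacterium"),
                "source": e.get("organism", "Proteobacteria bacterium"),
                "taxonomy": list(e.get("lineage", ("Bacteria", "Proteobacteria"))),
                "date": e.get("date", "01-JAN-2000"),
            },
        )
        qualifiers = {"organism": [rec.annotations["organism"]]}
        if e.get("country") is not None:
            qualifiers["country"] = [e["country"]]
        rec.features.append(
            SeqFeature(FeatureLocation(0, len(rec.seq)), type="source", qualifiers=qualifiers)
        )
        records.append(rec)
    buf = io.StringIO()
    SeqIO.write(records, buf, "genbank")
    return buf.getvalue()


@pytest.fixture()
def flatfile_builder():
    return make_flatfile
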