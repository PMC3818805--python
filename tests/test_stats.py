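"""Summary statistics: abundance, occurrence, rollups, rankings, shares.

The frozen expected percentages come from the December-2012 snapshot
tables packaged with the library; each is recomputed from the packaged
counts and compared at the tables' 3-decimal precision.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import pytest

from bactgeo import stats, taxa
from bactgeo.geography import GeoArea
from bactgeo.stats import (
    TallyMatrix,
    abundance_percentages,
    continent_rollup,
    geographic_occurrence,
    kingdom_shares,
    occurrence_pct,
    relative_abundance,
    round_pct,
    summarize_continents,
    top_countries,
)

PHYLA = taxa.default_phyla()
TOL = 0.001


def snapshot(name: str) -> pd.DataFrame:
    ref = resources.files("bactgeo.data") / "snapshot2012" / name
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def one_row_matrix(ab: dict[str, int], area: str = "ALL") -> TallyMatrix:
    m = TallyMatrix.empty("NCBI", [GeoArea(area, "AMERICA")], PHYLA)
    for p, v in ab.items():
        m.counts.loc[area, p] = v
    return m


@pytest.fixture(scope="module")
def ncbi_ab() -> dict[str, int]:
    df = snapshot("ncbi_phylum_abundance.tsv")
    return dict(zip(df["phylum"], df["ab"]))


class TestRelativeAbundance:
    def test_snapshot_proteobacteria_share(self, ncbi_ab):
        summaries = {s.phylum: s for s in relative_abundance(one_row_matrix(ncbi_ab))}
        assert summaries["Proteobacteria"].Ab == 841254
        assert abs(summaries["Proteobacteria"].Ab_pct - 64.166) <= TOL

    def test_snapshot_firmicutes_share(self, ncbi_ab):
        summaries = {s.phylum: s for s in relative_abundance(one_row_matrix(ncbi_ab))}
        assert abs(summaries["Firmicutes"].Ab_pct - 12.785) <= TOL

    def test_single_phylum_normalizes_to_100(self):
        m = one_row_matrix({"Firmicutes": 7})
        (only,) = [s for s in relative_abundance(m) if s.Ab]
        assert only.Ab_pct == 100.0

    def test_shares_sum_to_100(self, ncbi_ab):
        total = sum(s.Ab_pct for s in relative_abundance(one_row_matrix(ncbi_ab)))
        assert abs(total - 100.0) <= 0.01

    def test_all_zero_matrix_is_an_error(self, mini_areas):
        m = TallyMatrix.empty("NCBI", mini_areas, PHYLA)
        with pytest.raises(ValueError, match="no assigned records"):
            relative_abundance(m)


class TestGeographicOccurrence:
    def test_snapshot_oc_percentages(self):
        # Oc counts over the 208-area frame
        assert occurrence_pct(144, 208) == 69.231  # NCBI Actinobacteria
        assert occurrence_pct(177, 208) == 85.096  # GBIF Cyanobacteria

    def test_everywhere_present_phylum_is_100(self, mini_areas):
        m = TallyMatrix.empty("NCBI", mini_areas, PHYLA)
        m.counts["Proteobacteria"] = 3
        (proteo,) = [s for s in geographic_occurrence(m) if s.phylum == "Proteobacteria"]
        assert proteo.Oc == len(mini_areas) and proteo.Oc_pct == 100.0

    def test_oc_monotone_under_record_addition(self, mini_areas):
        rng = np.random.default_rng(3)
        m = TallyMatrix.empty("NCBI", mini_areas, PHYLA)
        m.counts.iloc[:, :] = rng.integers(0, 3, m.counts.shape)
        before = {s.phylum: s.Oc for s in geographic_occurrence(m)}
        m2 = TallyMatrix("NCBI", m.counts + rng.integers(0, 2, m.counts.shape), m.environmental)
        after = {s.phylum: s.Oc for s in geographic_occurrence(m2)}
        assert all(after[p] >= before[p] for p in before)


class TestContinents:
    def test_snapshot_rollup_percentages(self):
        df = snapshot("continent_counts.tsv").set_index("continent")
        gbif = summarize_continents(
            df.rename(columns={"gbif_records": "records", "gbif_assigned": "assigned"})
        )
        america = next(c for c in gbif if c.continent == "AMERICA")
        assert abs(america.pct_of_total - 39.435) <= TOL
        assert abs(america.pct_assigned - 87.458) <= TOL
        ncbi = summarize_continents(
            df.rename(columns={"ncbi_records": "records", "ncbi_assigned": "assigned"})
        )
        antarctica = next(c for c in ncbi if c.continent == "ANTARCTICA")
        assert abs(antarctica.pct_assigned - 8.885) <= TOL
        assert abs(sum(c.pct_of_total for c in gbif) - 100.0) <= 0.01

    def test_single_continent_matrix_is_100(self):
        areas = [GeoArea("USA", "AMERICA"), GeoArea("Canada", "AMERICA")]
        m = TallyMatrix.empty("NCBI", areas, PHYLA)
        m.counts.loc["USA", "Firmicutes"] = 4
        (only,) = continent_rollup(m, areas)
        assert only.pct_of_total == 100.0

    def test_unknown_continent_area_is_an_error(self, mini_areas):
        ghost = GeoArea("Ghostland", "ASIA")
        m = TallyMatrix.empty("NCBI", list(mini_areas) + [ghost], PHYLA)
        with pytest.raises(ValueError, match="Ghostland"):
            continent_rollup(m, mini_areas)


class TestTopCountries:
    def _matrix(self, counts: dict[str, int], areas) -> TallyMatrix:
        m = TallyMatrix.empty("NCBI", areas, PHYLA)
        for name, v in counts.items():
            m.counts.loc[name, "Proteobacteria"] = v
        return m

    def test_largest_contributor_first(self, mini_areas):
        m = self._matrix({"USA": 50, "France": 20, "Italy": 5}, mini_areas)
        assert top_countries(m, 3)[0][0] == "USA"

    def test_n_larger_than_frame_returns_all(self, mini_areas):
        m = self._matrix({"USA": 1}, mini_areas)
        assert len(top_countries(m, 100)) == len(mini_areas)

    def test_ties_alphabetical_and_permutation_invariant(self, mini_areas):
        m = self._matrix({"USA": 10, "France": 10, "Italy": 3}, mini_areas)
        ranked = top_countries(m, 2)
        assert [r[0] for r in ranked] == ["France", "USA"]
        shuffled = TallyMatrix(
            "NCBI", m.counts.iloc[::-1], m.environmental.iloc[::-1]
        )
        assert top_countries(shuffled, 2) == ranked


class TestKingdomShares:
    def test_snapshot_shares(self):
        df = snapshot("gbif_kingdom_counts.tsv")
        shares = kingdom_shares(dict(zip(df["kingdom"], df["records"])))
        assert shares["Bacteria"] == 0.479
        assert shares["Animalia"] == 71.785
        assert abs(sum(shares.values()) - 100.0) <= 0.01

    def test_single_kingdom_is_100(self):
        assert kingdom_shares({"Bacteria": 5}) == {"Bacteria": 100.0}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            kingdom_shares({})


class TestInvariants:
    def test_rounding_is_half_up(self):
        assert round_pct(12.3455) == 12.346
        assert round_pct(0.0005) == 0.001

    def test_permutation_invariance_of_all_summaries(self, mini_areas):
        rng = np.random.default_rng(9)
        m = TallyMatrix.empty("NCBI", mini_areas, PHYLA)
        m.counts.iloc[:, :] = rng.integers(0, 20, m.counts.shape)
        perm = rng.permutation(len(m.counts))
        m2 = TallyMatrix("NCBI", m.counts.iloc[perm], m.environmental.iloc[perm])
        ab1 = {s.phylum: (s.Ab, s.Ab_pct) for s in relative_abundance(m)}
        ab2 = {s.phylum: (s.Ab, s.Ab_pct) for s in relative_abundance(m2)}
        assert ab1 == ab2
        oc1 = {s.phylum: s.Oc for s in geographic_occurrence(m)}
        oc2 = {s.phylum: s.Oc for s in geographic_occurrence(m2)}
        assert oc1 == oc2
        r1 = {c.continent: vars(c) for c in continent_rollup(m, mini_areas)}
        r2 = {c.continent: vars(c) for c in continent_rollup(m2, mini_areas)}
        assert r1 == r2
        assert top_countries(m) == top_countries(m2)

    def test_matched_column_consistency_roundtrip(self, tmp_path, mini_areas):
        rng = np.random.default_rng(2)
        m = TallyMatrix.empty("NCBI", mini_areas, PHYLA)
        m.counts.iloc[:, :] = rng.integers(0, 5, m.counts.shape)
        m.to_tsv(tmp_path / "t.tsv")
        back = TallyMatrix.from_tsv(tmp_path / "t.tsv")
        assert (back.counts == m.counts).all().all()

    def test_negative_counts_rejected(self, mini_areas):
        m = TallyMatrix.empty("NCBI", mini_areas, PHYLA)
        bad = m.counts.copy()
        bad.iloc[0, 0] = -1
        with pytest.raises(ValueError):
            TallyMatrix("NCBI", bad, m.environmental)
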