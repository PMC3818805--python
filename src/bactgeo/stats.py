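"""Summary statistics over per-area, per-phylum tally matrices.

The quantities mirror the standard biogeography summaries for database
record tallies:

* relative abundance ``Ab`` — records assigned to a phylum, summed over
  areas, and ``Ab% = 100·Ab/ΣAb`` over the harmonized phylum frame;
* geographic occurrence ``Oc`` — the number of study-frame areas with at
  least one record of the phylum, and ``Oc% = 100·Oc/n_areas``;
* continent rollups — records and phylum-assigned records per continent,
  as counts and percentages;
* top-N contributing countries and kingdom shares.

Percentages are rounded half-up to three decimals for table export.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .geography import GeoArea

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


def round_pct(value: float, ndigits: int = 3) -> float:
    """Round half-up (not banker's) to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: float, denominator: float) -> float:
    if denominator == 0:
        return 0.0
    return round_pct(100.0 * numerator / denominator)


@dataclass
class TallyMatrix:
    """Areas × (phyla + unassigned) count matrix for one source database.

    ``counts`` is indexed by area name with one integer column per phylum
    of the frame plus ``unassigned``; ``environmental`` counts records
    whose lineage carries the "environmental samples" taxon (orthogonal
    to phylum assignment).  Per-row, matched = Σ phyla + unassigned by
    construction.  Records that could not be placed are in the scalar
    ledger fields, so the global conservation law is
    ``total input = Σ matched + unlocated + ambiguous + parse_skipped``.
    """

    source: str
    counts: pd.DataFrame
    environmental: pd.Series
    unlocated: int = 0
    ambiguous: int = 0
    parse_skipped: int = 0
    excluded_other: int = 0

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("tally counts must be non-negative")
        self.counts = self.counts.astype(int)
        self.environmental = self.environmental.reindex(self.counts.index).fillna(0).astype(int)

    @property
    def phyla(self) -> list[str]:
        return [c for c in self.counts.columns if c != UNASSIGNED]

    @property
    def matched(self) -> pd.Series:
        """Per-area matched record count (= Σ phyla + unassigned)."""
        return self.counts.sum(axis=1)

    @property
    def n_areas(self) -> int:
        return len(self.counts.index)

    @property
    def total_matched(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def empty(cls, source: str, areas: Sequence[GeoArea], phyla: Sequence[str]) -> "TallyMatrix":
        names = [a.name for a in areas]
        cols = list(phyla) + [UNASSIGNED]
        counts = pd.DataFrame(0, index=pd.Index(names, name="area"), columns=cols)
        env = pd.Series(0, index=counts.index, name="environmental")
        return cls(source=source, counts=counts, environmental=env)

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write one row per area: area, matched, phyla…, unassigned, environmental."""
        out = self.counts.copy()
        out.insert(0, "matched", self.matched)
        out["environmental"] = self.environmental
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], source: str = "NCBI") -> "TallyMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        env = df.pop("environmental")
        matched = df.pop("matched")
        m = cls(source=source, counts=df, environmental=env)
        if not (m.matched == matched).all():
            raise ValueError(f"{path}: matched column inconsistent with row sums")
        return m


@dataclass
class PhylumSummary:
    """Per-phylum abundance and occurrence summary (one table row)."""

    phylum: str
    Ab: Optional[int] = None
    Ab_pct: Optional[float] = None
    Oc: Optional[int] = None
    Oc_pct: Optional[float] = None


@dataclass
class ContinentSummary:
    continent: str
    records: int
    pct_of_total: float
    assigned: int
    pct_assigned: float


def abundance_percentages(ab: Mapping[str, int]) -> dict[str, float]:
    """``Ab% = 100·Ab/ΣAb`` over the given phylum counts, 3 decimals."""
    total = sum(ab.values())
    if total == 0:
        raise ValueError("no assigned records")
    return {p: _pct(v, total) for p, v in ab.items()}


def relative_abundance(m: TallyMatrix) -> list[PhylumSummary]:
    """Relative abundance of each phylum of the frame (Ab, Ab%)."""
    ab = {p: int(m.counts[p].sum()) for p in m.phyla}
    pcts = abundance_percentages(ab)
    return [PhylumSummary(phylum=p, Ab=ab[p], Ab_pct=pcts[p]) for p in m.phyla]


def occurrence_pct(oc: int, n_areas: int) -> float:
    """``Oc% = 100·Oc/n_areas``, 3 decimals."""
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    return _pct(oc, n_areas)


def geographic_occurrence(m: TallyMatrix) -> list[PhylumSummary]:
    """Geographic occurrence of each phylum: areas with ≥1 record (Oc, Oc%)."""
    out = []
    for p in m.phyla:
        oc = int((m.counts[p] >= 1).sum())
        out.append(PhylumSummary(phylum=p, Oc=oc, Oc_pct=occurrence_pct(oc, m.n_areas)))
    return out


def summarize_continents(per_continent: pd.DataFrame) -> list[ContinentSummary]:
    """Percentage columns for a continents × (records, assigned) table."""
    grand = int(per_continent["records"].sum())
    out = []
    for continent, row in per_continent.iterrows():
        rec, asn = int(row["records"]), int(row["assigned"])
        out.append(
            ContinentSummary(
                continent=str(continent),
                records=rec,
                pct_of_total=_pct(rec, grand),
                assigned=asn,
                pct_assigned=_pct(asn, rec),
            )
        )
    return out


def continent_rollup(m: TallyMatrix, areas: Sequence[GeoArea]) -> list[ContinentSummary]:
    """Records and assigned records summed per continent."""
    cont = {a.name: a.continent for a in areas}
    missing = [n for n in m.counts.index if n not in cont]
    if missing:
        raise ValueError(f"area(s) with unknown continent: {missing}")
    assigned = m.counts[m.phyla].sum(axis=1)
    df = pd.DataFrame({"records": m.matched, "assigned": assigned})
    df["continent"] = [cont[n] for n in df.index]
    agg = df.groupby("continent", sort=False)[["records", "assigned"]].sum()
    # keep a stable, conventional continent order
    order = [c for c in ("AMERICA", "AFRICA", "EUROPE", "ASIA", "AUSTRALIA-OCEANIA", "ANTARCTICA") if c in agg.index]
    return summarize_continents(agg.loc[order])


def top_countries(m: TallyMatrix, n: int = 10) -> list[tuple[str, int, float]]:
    """Top-``n`` areas by matched records.

    Sorted by record count descending, ties broken alphabetically so the
    ranking is stable under row-order permutation.  Returns
    ``(area, records, pct_assigned)`` tuples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    matched = m.matched
    assigned = m.counts[m.phyla].sum(axis=1)
    ranked = sorted(m.counts.index, key=lambda a: (-int(matched[a]), a))
    out = []
    for area in ranked[:n]:
        rec = int(matched[area])
        out.append((area, rec, _pct(int(assigned[area]), rec)))
    return out


def kingdom_shares(counts: Mapping[str, int]) -> dict[str, float]:
    """Each kingdom's share (%) of the total record count."""
    total = sum(counts.values())
    if not counts or total <= 0:
        raise ValueError("need at least one kingdom with records")
    return {k: _pct(v, total) for k, v in counts.items()}


def export_summary_json(
    path: Union[str, Path],
    *,
    abundance: Iterable[PhylumSummary] = (),
    occurrence: Iterable[PhylumSummary] = (),
    continents: Iterable[ContinentSummary] = (),
    top: Iterable[tuple[str, int, float]] = (),
    extra: Optional[Mapping] = None,
) -> None:
    """Machine-readable run summary."""
    payload = {
        "abundance": [vars(s) for s in abundance],
        "occurrence": [vars(s) for s in occurrence],
        "continents": [vars(s) for s in continents],
        "top_countries": [list(t) for t in top],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
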