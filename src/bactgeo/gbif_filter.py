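"""Occurrence-database side of the pipeline: parse GBIF-style occurrence
downloads, keep the bacterial kingdom, and tally per area and phylum.

Occurrence downloads are tab-separated Darwin-Core-style spreadsheets,
optionally zip-wrapped, retrieved one file per geographic area.  The
filter keeps rows whose kingdom is Bacteria, maps the phylum column onto
the harmonized 24-phylum frame through a classification-dialect synonym
table, and maintains a conservation ledger so that
``parsed = kept + excluded_kingdom + unlocated (+ foreign)`` per file.

Older download interfaces cap each file at 250,000 rows; a file hitting
exactly that count is parsed fully but a truncation warning is emitted,
since the area's true record count is then a lower bound.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings as _warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

from . import geography, taxa
from .geography import GeoArea, parse_qualifier, resolve_area_detailed
from .stats import UNASSIGNED, TallyMatrix

logger = logging.getLogger(__name__)

#: Maximum rows per download file in the capped portal interface.
DOWNLOAD_CAP = 250_000


class TruncationWarning(UserWarning):
    """A download file hit the per-file row cap and is likely truncated."""


@dataclass(frozen=True)
class OccurrenceRow:
    """One occurrence line: taxonomy plus locality."""

    scientific_name: str
    kingdom: str
    phylum: str
    area_name: str
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for one download flavour (Darwin-Core defaults)."""

    scientific_name: str = "scientificName"
    kingdom: str = "kingdom"
    phylum: str = "phylum"
    area: str = "country"
    latitude: str = "decimalLatitude"
    longitude: str = "decimalLongitude"
    delimiter: str = "\t"

    @property
    def required(self) -> tuple[str, ...]:
        return (self.scientific_name, self.kingdom, self.phylum, self.area)


DEFAULT_DIALECT = Dialect()


@dataclass
class ExclusionLedger:
    """Per-file conservation bookkeeping."""

    parsed: int = 0
    kept: int = 0
    excluded_kingdom: int = 0
    unlocated: int = 0
    foreign_area: int = 0
    ambiguous: int = 0


def _coord(raw: str, name: str, line: int) -> Optional[float]:
    raw = (raw or "").strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        logger.warning("line %d: malformed %s %r dropped, row kept", line, name, raw)
        return None


def _open_text(source: Union[str, Path, TextIO]) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() == ".zip":
            zf = zipfile.ZipFile(path)
            members = [n for n in zf.namelist() if not n.endswith("/")]
            if not members:
                raise ValueError(f"{path}: zip archive contains no files")
            return io.TextIOWrapper(zf.open(members[0]), encoding="utf-8"), True
        return open(path, encoding="utf-8"), True
    return source, False


def parse_occurrences(
    stream: Union[str, Path, TextIO],
    dialect: Dialect = DEFAULT_DIALECT,
    ledger: Optional[ExclusionLedger] = None,
) -> Iterator[OccurrenceRow]:
    """Yield one :class:`OccurrenceRow` per data line.

    Accepts plain or zip-wrapped tab-separated text with a header row.
    Missing optional fields become absent; a malformed coordinate is
    dropped with a warning but the row is kept.  A missing required
    column raises ``ValueError`` naming it.  A file of exactly
    :data:`DOWNLOAD_CAP` rows is parsed fully and a
    :class:`TruncationWarning` is emitted.
    """
    fh, close = _open_text(stream)
    ledger = ledger if ledger is not None else ExclusionLedger()
    try:
        lines = (ln for ln in fh if not ln.startswith("#"))  # seed/provenance comments
        reader = csv.DictReader(lines, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        missing = [c for c in dialect.required if c not in header]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        n = 0
        for lineno, rec in enumerate(reader, start=2):
            n += 1
            ledger.parsed += 1
            lat = _coord(rec.get(dialect.latitude, ""), "latitude", lineno)
            lon = _coord(rec.get(dialect.longitude, ""), "longitude", lineno)
            if lat is not None and not -90 <= lat <= 90:
                logger.warning("line %d: latitude %s out of range, dropped", lineno, lat)
                lat = None
            if lon is not None and not -180 <= lon <= 180:
                logger.warning("line %d: longitude %s out of range, dropped", lineno, lon)
                lon = None
            yield OccurrenceRow(
                scientific_name=(rec.get(dialect.scientific_name) or "").strip(),
                kingdom=(rec.get(dialect.kingdom) or "").strip(),
                phylum=(rec.get(dialect.phylum) or "").strip(),
                area_name=(rec.get(dialect.area) or "").strip(),
                latitude=lat,
                longitude=lon,
            )
        if n >= DOWNLOAD_CAP:
            _warnings.warn(
                f"file contains {n} rows (download cap {DOWNLOAD_CAP}); "
                "the source likely holds more records",
                TruncationWarning,
                stacklevel=2,
            )
    finally:
        if close:
            fh.close()


def filter_bacteria(
    rows: Iterable[OccurrenceRow], ledger: Optional[ExclusionLedger] = None
) -> Iterator[OccurrenceRow]:
    """Keep rows whose kingdom equals "Bacteria" (case-insensitive).

    Rows with another or an empty kingdom are dropped and counted in the
    ledger.  Idempotent: applying it twice changes nothing.
    """
    for row in rows:
        if row.kingdom.strip().lower() == "bacteria":
            if ledger is not None:
                ledger.kept += 1
            yield row
        elif ledger is not None:
            ledger.excluded_kingdom += 1


def assign_phylum_gbif(
    row: OccurrenceRow,
    phylum_list: Sequence[str],
    synonyms: Optional[dict[str, str]] = None,
) -> str:
    """Canonicalize the row's phylum onto the frame, else "unassigned".

    The classification-dialect synonym table is applied first (so e.g. a
    source writing "Pseudomonadota" still lands on Proteobacteria), then
    a case-insensitive frame lookup.
    """
    name = row.phylum.strip()
    if not name:
        return UNASSIGNED
    if synonyms:
        name = synonyms.get(name.lower(), name)
    return taxa.canonical_lookup(phylum_list).get(name.lower(), UNASSIGNED)


def tally_gbif(
    rows: Iterable[OccurrenceRow],
    areas: Sequence[GeoArea],
    phylum_list: Optional[Sequence[str]] = None,
    synonyms: Optional[dict[str, str]] = None,
    file_area: Optional[GeoArea] = None,
    ledger: Optional[ExclusionLedger] = None,
) -> TallyMatrix:
    """Tally occurrence rows into an areas × phyla matrix.

    The kingdom filter is applied here as well (it is idempotent), so a
    caller may pass raw parsed rows.  With ``file_area`` set (the
    one-download-per-area layout), a row naming a *different* area is
    excluded and logged as foreign; rows with a blank area inherit the
    file's area.  Without ``file_area``, each row's area name is resolved
    through the strict qualifier matcher; unresolvable rows count as
    unlocated.
    """
    phylum_list = list(phylum_list) if phylum_list is not None else taxa.default_phyla()
    synonyms = synonyms if synonyms is not None else taxa.default_synonyms()
    ledger = ledger if ledger is not None else ExclusionLedger()
    m = TallyMatrix.empty("GBIF", areas, phylum_list)
    counts = m.counts
    for row in filter_bacteria(rows, ledger=ledger):
        area: Optional[GeoArea]
        if not row.area_name:
            area = file_area
            status = geography.EXACT if file_area else geography.NO_MATCH
        else:
            area, status = resolve_area_detailed(parse_qualifier(row.area_name), areas)
        if status == geography.AMBIGUOUS:
            m.ambiguous += 1
            ledger.ambiguous += 1
            ledger.kept -= 1
            continue
        if area is None:
            m.unlocated += 1
            ledger.unlocated += 1
            ledger.kept -= 1
            continue
        if file_area is not None and area.name != file_area.name:
            logger.warning(
                "row for area %r found in file for %r; excluded", area.name, file_area.name
            )
            m.excluded_other += 1
            ledger.foreign_area += 1
            ledger.kept -= 1
            continue
        counts.loc[area.name, assign_phylum_gbif(row, phylum_list, synonyms)] += 1
    return m
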