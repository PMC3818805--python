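"""Sequence-database side of the pipeline: GenBank-flatfile parsing,
query construction, phylum assignment and per-area tallying.

A record contributes to an area's tally only when its source feature's
``/country`` qualifier resolves to that area — a record whose DEFINITION
line mentions a second country (a collaborator's address, a comparison
site) is never counted for that country.  Taxonomy is read from the
structured lineage of the ORGANISM block and mapped onto the harmonized
phylum frame; records carrying the "environmental samples" taxon are
flagged orthogonally to phylum assignment.
"""

from __future__ import annotations

import io
import logging
import time
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio import SeqIO

from . import geography, taxa
from .geography import GeoArea, MissingQualifier, parse_qualifier, resolve_area_detailed
from .stats import UNASSIGNED, TallyMatrix

logger = logging.getLogger(__name__)

ENVIRONMENTAL_PHRASE = "environmental samples"
_MONTHS = "JAN FEB MAR APR MAY JUN JUL AUG SEP OCT NOV DEC".split()


@dataclass(frozen=True)
class SeqRecordMeta:
    """Per-record metadata extracted from one flatfile entry."""

    accession: str
    organism: str
    lineage: tuple[str, ...]
    country_qualifier: Optional[str] = None
    publication_date: Optional[date] = None
    description: str = ""


@dataclass
class ParseLedger:
    """Bookkeeping for one parse pass (conservation checks)."""

    parsed: int = 0
    skipped_truncated: int = 0
    skipped_date: int = 0
    skipped_duplicate_accession: int = 0


def build_query(area_name: str, date_start: date, date_end: date) -> str:
    """Entrez-style search term restricting to the qualifier-bearing subset.

    ``country`` narrows to records that may carry the ``/country``
    qualifier, the quoted area name pins the geography, and
    ``Bacteria[Organism]`` plus the publication-date window bound the
    taxon and time period.
    """
    if not area_name.strip():
        raise ValueError("area_name must be non-empty")
    if date_start > date_end:
        raise ValueError("date_start must not be after date_end")
    window = (
        f'("{date_start:%Y/%m/%d}"[Publication Date] : '
        f'"{date_end:%Y/%m/%d}"[Publication Date])'
    )
    return f'country AND "{area_name}" AND Bacteria[Organism] AND {window}'


def _parse_flatfile_date(raw: Optional[str]) -> Optional[date]:
    """Parse a DD-MON-YYYY flatfile date without locale dependence."""
    if not raw:
        return None
    try:
        d, mon, y = raw.strip().split("-")
        return date(int(y), _MONTHS.index(mon.upper()) + 1, int(d))
    except (ValueError, IndexError):
        logger.warning("unparseable flatfile date %r", raw)
        return None


def _entry_to_meta(chunk: str) -> SeqRecordMeta:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = SeqIO.read(io.StringIO(chunk), "genbank")
    country = None
    for feat in rec.features:
        if feat.type != "source":
            continue
        values = feat.qualifiers.get("country", [])
        if values:
            if country is None:
                country = values[0]
            if len(values) > 1:
                logger.info(
                    "%s: %d extra /country qualifiers ignored", rec.id, len(values) - 1
                )
    return SeqRecordMeta(
        accession=rec.id,
        organism=rec.annotations.get("organism", ""),
        lineage=tuple(rec.annotations.get("taxonomy", ())),
        country_qualifier=country,
        publication_date=_parse_flatfile_date(rec.annotations.get("date")),
        description=rec.description,
    )


def parse_genbank(
    stream: Union[str, Path, TextIO],
    date_window: Optional[tuple[date, date]] = None,
    ledger: Optional[ParseLedger] = None,
) -> Iterator[SeqRecordMeta]:
    """Yield one :class:`SeqRecordMeta` per flatfile entry.

    Entries are delimited by the ``//`` separator line; a truncated or
    malformed entry is logged (naming the accession when recoverable, or
    the byte offset) and skipped, and parsing resumes at the next
    separator.  When ``date_window`` is given, entries whose publication
    date falls outside it are dropped here — a redundant guard on top of
    any date clause already in the retrieval query, so offline fixture
    files honor the study cut-off too.  Duplicate accessions within one
    input are skipped (accessions must be unique per file).
    """
    if isinstance(stream, (str, Path)):
        fh: TextIO = open(stream, encoding="utf-8")
        close = True
    else:
        fh, close = stream, False
    ledger = ledger if ledger is not None else ParseLedger()
    seen: set[str] = set()
    try:
        buf: list[str] = []
        offset = 0
        entry_offset = 0
        while True:
            line = fh.readline()
            at_eof = line == ""
            if not at_eof:
                if not buf:
                    entry_offset = offset
                buf.append(line)
                offset += len(line)
            if buf and (at_eof or line.rstrip() == "//"):
                chunk = "".join(buf)
                buf = []
                if at_eof and not chunk.strip():
                    pass
                else:
                    try:
                        meta = _entry_to_meta(chunk)
                    except Exception as exc:  # malformed/truncated entry
                        acc = _guess_accession(chunk)
                        where = acc if acc else f"byte offset {entry_offset}"
                        logger.error("skipping malformed entry at %s: %s", where, exc)
                        ledger.skipped_truncated += 1
                    else:
                        if meta.accession in seen:
                            logger.warning("duplicate accession %s skipped", meta.accession)
                            ledger.skipped_duplicate_accession += 1
                        elif date_window is not None and meta.publication_date is not None and not (
                            date_window[0] <= meta.publication_date <= date_window[1]
                        ):
                            ledger.skipped_date += 1
                        else:
                            seen.add(meta.accession)
                            ledger.parsed += 1
                            yield meta
            if at_eof:
                break
    finally:
        if close:
            fh.close()


def _guess_accession(chunk: str) -> Optional[str]:
    for line in chunk.splitlines():
        if line.startswith("ACCESSION"):
            parts = line.split()
            if len(parts) > 1:
                return parts[1]
        if line.startswith("LOCUS"):
            parts = line.split()
            if len(parts) > 1:
                return parts[1]
    return None


def assign_phylum(lineage: Sequence[str], phylum_list: Sequence[str]) -> str:
    """Map a structured lineage onto the phylum frame.

    Returns the first lineage element equal (case-insensitive,
    hyphen-preserving) to a frame phylum, else ``"unassigned"`` — which
    covers lineages naming phyla outside the harmonized frame as well as
    unranked or environmental lineages.
    """
    if not lineage:
        logger.info("empty lineage -> unassigned")
        return UNASSIGNED
    lookup = taxa.canonical_lookup(phylum_list)
    for taxon in lineage:
        hit = lookup.get(taxon.strip().lower())
        if hit is not None:
            return hit
    return UNASSIGNED


def flag_environmental(meta: SeqRecordMeta) -> bool:
    """True when the organism or lineage carries the environmental-samples taxon."""
    if ENVIRONMENTAL_PHRASE in meta.organism.lower():
        return True
    return any(ENVIRONMENTAL_PHRASE in taxon.lower() for taxon in meta.lineage)


def tally_ncbi(
    records: Iterable[SeqRecordMeta],
    areas: Sequence[GeoArea],
    phylum_list: Optional[Sequence[str]] = None,
) -> TallyMatrix:
    """Tally records into an areas × phyla matrix under strict matching.

    Per matched record: its area's matched count and its phylum (or
    unassigned) column gain one, and the environmental flag is tallied.
    Records with a missing or unresolvable qualifier go to the global
    ``unlocated`` bucket; qualifiers matching two equal-length areas are
    excluded as ``ambiguous`` and logged.
    """
    phylum_list = list(phylum_list) if phylum_list is not None else taxa.default_phyla()
    m = TallyMatrix.empty("NCBI", areas, phylum_list)
    counts, env = m.counts, m.environmental
    for meta in records:
        if not meta.country_qualifier or not meta.country_qualifier.strip():
            m.unlocated += 1
            continue
        q = parse_qualifier(meta.country_qualifier)
        area, status = resolve_area_detailed(q, areas)
        if status == geography.AMBIGUOUS:
            m.ambiguous += 1
            continue
        if area is None:
            m.unlocated += 1
            continue
        phylum = assign_phylum(meta.lineage, phylum_list)
        counts.loc[area.name, phylum] += 1
        if flag_environmental(meta):
            env.loc[area.name] += 1
    return m


# ---------------------------------------------------------------------------
# Optional remote retrieval (off by default; the pipeline runs on cached
# flatfiles identically whether they came from disk or from a fetch).
# ---------------------------------------------------------------------------


class NetworkDisabled(RuntimeError):
    """Raised when remote retrieval is attempted without the explicit flag."""


@dataclass
class FetchConfig:
    allow_network: bool = False
    contact: str = ""
    max_rate_per_s: float = 3.0
    max_retries: int = 3


class EntrezTransport:
    """Two-step E-utilities transport: search for ids, fetch flatfile text."""

    ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
    EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

    def __init__(self, contact: str = "") -> None:
        self.contact = contact

    def search(self, term: str, retstart: int, retmax: int) -> list[str]:
        import re
        import urllib.parse
        import urllib.request

        url = self.ESEARCH + "?" + urllib.parse.urlencode(
            {
                "db": "nucleotide",
                "term": term,
                "retstart": retstart,
                "retmax": retmax,
                "tool": "bactgeo",
                "email": self.contact,
            }
        )
        with urllib.request.urlopen(url) as resp:
            body = resp.read().decode()
        return re.findall(r"<Id>(\d+)</Id>", body)

    def fetch(self, ids: Sequence[str]) -> str:
        import urllib.parse
        import urllib.request

        url = self.EFETCH + "?" + urllib.parse.urlencode(
            {
                "db": "nucleotide",
                "id": ",".join(ids),
                "rettype": "gb",
                "retmode": "text",
                "tool": "bactgeo",
                "email": self.contact,
            }
        )
        with urllib.request.urlopen(url) as resp:
            return resp.read().decode()


def fetch_remote(
    query: str,
    batch_size: int = 500,
    *,
    cache_dir: Union[str, Path],
    config: Optional[FetchConfig] = None,
    transport=None,
    _sleep: Callable[[float], None] = time.sleep,
) -> Path:
    """Retrieve flatfile text for ``query`` into a cache file.

    Disabled unless ``config.allow_network`` is set.  Pages through the
    result set ``batch_size`` ids at a time at a polite rate, retrying
    each page up to ``max_retries`` times with exponential backoff; on
    final failure the cache file written so far is kept together with a
    ``.cursor`` file holding the next offset, so a rerun can resume.
    """
    config = config or FetchConfig()
    if not config.allow_network:
        raise NetworkDisabled("network disabled: set allow_network to fetch remotely")
    transport = transport or EntrezTransport(config.contact)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    out = cache_dir / "fetch.gb"
    cursor_file = cache_dir / "fetch.cursor"
    retstart = int(cursor_file.read_text()) if cursor_file.exists() else 0
    min_interval = 1.0 / config.max_rate_per_s
    mode = "a" if retstart else "w"
    with open(out, mode, encoding="utf-8") as fh:
        while True:
            ids = _with_retries(
                lambda: transport.search(query, retstart, batch_size),
                config.max_retries,
                _sleep,
                cursor_file,
                retstart,
            )
            if not ids:
                break
            text = _with_retries(
                lambda: transport.fetch(ids),
                config.max_retries,
                _sleep,
                cursor_file,
                retstart,
            )
            fh.write(text)
            retstart += len(ids)
            if len(ids) < batch_size:
                break
            _sleep(min_interval)
    if cursor_file.exists():
        cursor_file.unlink()
    return out


def _with_retries(fn, max_retries: int, _sleep, cursor_file: Path, retstart: int):
    for attempt in range(max_retries):
        try:
            return fn()
        except Exception as exc:
            if attempt == max_retries - 1:
                cursor_file.write_text(str(retstart))
                raise RuntimeError(
                    f"fetch aborted after {max_retries} attempts; resume cursor saved"
                ) from exc
            _sleep(2.0**attempt)
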