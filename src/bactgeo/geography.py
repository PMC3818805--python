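"""Controlled-vocabulary geography: area list handling and strict
``/country``-qualifier matching.

Sequence records carry their geographic origin in the source feature's
``/country`` qualifier, formatted ``Country[:Region]`` against the INSDC
controlled vocabulary.  Free-text search over whole records overestimates
per-country tallies (a collaborator's address matches just as well as the
sampling site), so attribution here is *strict*: a record counts for an
area only when the qualifier's country part names that area.

The one wrinkle is exception pairs — distinct areas whose canonical names
nearly contain one another, such as "Republic of the Congo" and
"Democratic Republic of Congo".  Containment is therefore defined on
normalized token sequences (lowercase, alphanumeric tokens, the article
"the" dropped), and a qualifier that matches no name exactly resolves to
the *longest* canonical name contained in it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

logger = logging.getLogger(__name__)

#: The six continents of the study frame.
CONTINENTS = frozenset(
    {"AMERICA", "AFRICA", "EUROPE", "ASIA", "AUSTRALIA-OCEANIA", "ANTARCTICA"}
)

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def _tokens(name: str) -> tuple[str, ...]:
    """Normalized token sequence of an area name.

    Lowercase, split on any non-alphanumeric run, article "the" removed —
    so "Republic of the Congo" and "Democratic Republic of Congo" share
    the token run ("republic", "of", "congo").
    """
    return tuple(t for t in _TOKEN_RE.split(name.lower()) if t and t != "the")


def _contains(outer: Sequence[str], inner: Sequence[str]) -> bool:
    """True when ``inner`` occurs as a contiguous sub-sequence of ``outer``."""
    if not inner or len(inner) > len(outer):
        return False
    n = len(inner)
    return any(tuple(outer[i : i + n]) == tuple(inner) for i in range(len(outer) - n + 1))


@dataclass(frozen=True)
class GeoArea:
    """One controlled-vocabulary geographic area.

    Parameters
    ----------
    name
        Canonical INSDC area string.
    continent
        One of the six study continents (see :data:`CONTINENTS`).
    ambiguous_with
        Names of other areas whose normalized name contains, or is
        contained by, this one (the exception set).  Symmetric.
    historical
        True for superseded country names kept for old records; such
        entries are excluded from the default study frame.
    """

    name: str
    continent: str
    ambiguous_with: tuple[str, ...] = field(default=())
    historical: bool = False

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("GeoArea name must be non-empty")
        if self.continent not in CONTINENTS:
            raise ValueError(
                f"unknown continent {self.continent!r} for area {self.name!r}; "
                f"expected one of {sorted(CONTINENTS)}"
            )

    @property
    def tokens(self) -> tuple[str, ...]:
        return _tokens(self.name)


@dataclass(frozen=True)
class QualifierValue:
    """A parsed ``/country`` qualifier: ``Country[:Region]``."""

    raw: str
    country_part: str
    region_part: str


class AreaListError(ValueError):
    """Raised for an invalid area-list file (duplicate name, bad continent)."""


class MissingQualifier(ValueError):
    """Raised when a ``/country`` value is empty or whitespace."""


def parse_qualifier(raw: str) -> QualifierValue:
    """Split a raw ``/country`` value on its first colon only.

    >>> parse_qualifier("Chile: Atacama: site 3").region_part
    'Atacama: site 3'
    """
    if raw is None or not raw.strip():
        raise MissingQualifier("empty /country qualifier")
    country, sep, region = raw.strip().partition(":")
    return QualifierValue(raw=raw, country_part=country.strip(), region_part=region.strip())


def _derive_ambiguity(areas: list[GeoArea]) -> list[GeoArea]:
    """Populate symmetric ambiguity sets by pairwise containment."""
    toks = [a.tokens for a in areas]
    amb: list[set[str]] = [set() for _ in areas]
    for i, a in enumerate(areas):
        for j in range(i + 1, len(areas)):
            if _contains(toks[i], toks[j]) or _contains(toks[j], toks[i]):
                amb[i].add(areas[j].name)
                amb[j].add(a.name)
    return [
        GeoArea(a.name, a.continent, tuple(sorted(amb[i])), a.historical)
        for i, a in enumerate(areas)
    ]


def load_area_list(
    source: Union[str, Path], include_historical: bool = False
) -> list[GeoArea]:
    """Load a controlled-vocabulary area list from a TSV file.

    The file is UTF-8, ``#`` comment lines allowed, header row
    ``name<TAB>continent`` with an optional third ``historical`` column
    (truthy values: 1/true/yes).  Areas are returned in file order with
    ambiguity sets auto-derived by pairwise name containment.

    Raises
    ------
    AreaListError
        On a duplicate name or an unknown continent (with line number).
    """
    path = Path(source)
    areas: list[GeoArea] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header_done = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_done:
                header_done = True  # first non-comment line is the header
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AreaListError(f"line {lineno}: expected name<TAB>continent")
            name = parts[0].strip()
            continent = parts[1].strip()
            historical = len(parts) > 2 and parts[2].strip().lower() in {"1", "true", "yes"}
            if name in seen:
                raise AreaListError(
                    f"line {lineno}: duplicate area name {name!r} "
                    f"(first seen line {seen[name]})"
                )
            if continent not in CONTINENTS:
                raise AreaListError(f"line {lineno}: unknown continent {continent!r}")
            seen[name] = lineno
            if historical and not include_historical:
                logger.info("skipping historical area name %r", name)
                continue
            areas.append(GeoArea(name, continent, historical=historical))
    if not areas:
        logger.warning("area list %s contains no areas", path)
    return _derive_ambiguity(areas)


def default_area_list() -> list[GeoArea]:
    """The packaged 208-area study frame."""
    ref = resources.files("bactgeo.data") / "areas_insdc_2012.tsv"
    with resources.as_file(ref) as p:
        return load_area_list(p)


# resolution statuses
EXACT = "exact"
CONTAINMENT = "containment"
AMBIGUOUS = "ambiguous"
NO_MATCH = "none"


def resolve_area_detailed(
    q: QualifierValue, areas: Sequence[GeoArea]
) -> tuple[Optional[GeoArea], str]:
    """Resolve a qualifier to an area, reporting how.

    Returns ``(area, status)`` where status is one of ``"exact"``,
    ``"containment"``, ``"ambiguous"`` or ``"none"``; area is None for
    the last two.  Matching order:

    1. case-insensitive exact equality of the country part with a
       canonical name;
    2. otherwise the longest canonical name (most tokens, then most
       characters) whose normalized tokens are contained in the country
       part's tokens — the exception-pair rule;
    3. two distinct same-length candidates → ambiguous, record excluded.
    """
    cp = q.country_part.strip()
    if not cp:
        return None, NO_MATCH
    cp_lower = cp.lower()
    exact = [a for a in areas if a.name.lower() == cp_lower]
    if len(exact) == 1:
        return exact[0], EXACT
    if len(exact) > 1:  # duplicate canonical names cannot load, but be safe
        logger.warning("ambiguous qualifier %r: duplicate canonical names", q.raw)
        return None, AMBIGUOUS

    cp_tokens = _tokens(cp)
    candidates = [a for a in areas if _contains(cp_tokens, a.tokens)]
    if not candidates:
        return None, NO_MATCH
    best_key = max((len(a.tokens), len(a.name)) for a in candidates)
    best = [a for a in candidates if (len(a.tokens), len(a.name)) == best_key]
    if len(best) > 1:
        logger.warning(
            "ambiguous qualifier %r: equal-length matches %s",
            q.raw,
            sorted(a.name for a in best),
        )
        return None, AMBIGUOUS
    return best[0], CONTAINMENT


def resolve_area(q: QualifierValue, areas: Sequence[GeoArea]) -> Optional[GeoArea]:
    """Resolve a qualifier's country part to its unique area, or None."""
    area, _ = resolve_area_detailed(q, areas)
    return area
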