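"""The harmonized phylum frame shared by both database filters.

The frame is the set of bacterial phyla present in both source
classifications (NCBI Taxonomy and Catalogue of Life); taxa outside it —
including phyla recognised by only one classification, such as
Tenericutes or Nitrospinae — tally as "unassigned".  A small editable
synonym table maps classification-dialect spellings onto canonical frame
names.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union


def load_phylum_list(source: Union[str, Path]) -> list[str]:
    """Read one phylum name per line; ``#`` comments and blanks ignored."""
    names: list[str] = []
    for line in Path(source).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    if len(names) != len(set(n.lower() for n in names)):
        raise ValueError("phylum list contains case-insensitive duplicates")
    return names


def default_phyla() -> list[str]:
    """The packaged 24-phylum frame."""
    ref = resources.files("bactgeo.data") / "phyla24.txt"
    with resources.as_file(ref) as p:
        return load_phylum_list(p)


def load_synonyms(source: Union[str, Path]) -> dict[str, str]:
    """Read a ``dialect_name<TAB>canonical`` synonym table (lowercased keys)."""
    table: dict[str, str] = {}
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    header_done = False
    for line in lines:
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if not header_done:
            header_done = True
            continue
        dialect, _, canonical = line.partition("\t")
        table[dialect.strip().lower()] = canonical.strip()
    return table


def default_synonyms() -> dict[str, str]:
    ref = resources.files("bactgeo.data") / "phylum_synonyms.tsv"
    with resources.as_file(ref) as p:
        return load_synonyms(p)


def canonical_lookup(phylum_list: Sequence[str]) -> Mapping[str, str]:
    """Case-insensitive lookup from spelling to canonical frame name."""
    return {p.lower(): p for p in phylum_list}
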