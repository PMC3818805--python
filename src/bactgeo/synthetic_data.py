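"""Seedable synthetic corpora with exact ground truth.

Both database filters are exercised offline against generated inputs
whose expected tallies are known to the record: a flatfile corpus in the
sequence-database dialect and per-area occurrence downloads in the
Darwin-Core dialect.  The generator reproduces the statistical structure
that matters to the pipeline —

* per-area multinomial mixtures over the 24-phylum frame plus an
  unassigned component (default proportions follow the December-2012
  sequence-database snapshot: assigned fraction 0.565, phylum shares
  proportional to the snapshot abundances);
* records lacking the ``/country`` qualifier (default fraction 0.28,
  the snapshot's unmatched share);
* "confounder" records whose DEFINITION line names a second country —
  the overestimation trap a strict matcher must ignore;
* exception-pair qualifiers (article variants of the two Congo names)
  that only longest-containment matching resolves correctly;
* environmental-sample lineages (default fraction 0.38), orthogonal to
  phylum assignment;
* non-bacterial contaminant rows and a download-cap mode on the
  occurrence side.

Every generated file records its seed in a leading comment, and the
expected tally is returned as a :class:`GroundTruth` that the end-to-end
tests compare against integer-exactly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .geography import GeoArea, default_area_list
from .stats import UNASSIGNED, TallyMatrix
from .taxa import default_phyla

_MONTHS = "JAN FEB MAR APR MAY JUN JUL AUG SEP OCT NOV DEC".split()

#: Phyla recognised by only one of the two source classifications; their
#: lineages must tally as unassigned.
NON_FRAME_PHYLA = (
    "Synergistetes",
    "Caldiserica",
    "Elusimicrobia",
    "Armatimonadetes",
    "Ignavibacteria",
    "Tenericutes",
    "Thermomicrobia",
    "Nitrospinae",
)

CONTAMINANT_KINGDOMS = ("Animalia", "Plantae", "Fungi", "Chromista")

#: Study window: first flatfile date to the query submission date.
DATE_WINDOW = (date(1986, 1, 1), date(2012, 11, 25))

#: Article variants of the exception-pair names, exercising the
#: longest-containment resolution path (truth: the full canonical name).
CONGO_VARIANTS = {
    "Democratic Republic of Congo": "Democratic Republic of the Congo",
    "Republic of the Congo": "The Republic of Congo",
}


def _snapshot_abundance() -> pd.Series:
    ref = resources.files("bactgeo.data") / "snapshot2012" / "ncbi_phylum_abundance.tsv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return df.set_index("phylum")["ab"]


def default_ncbi_mixture() -> dict[str, float]:
    """Snapshot phylum shares scaled to a 0.565 assigned fraction."""
    ab = _snapshot_abundance()
    probs = 0.565 * ab / ab.sum()
    mix = {p: float(v) for p, v in probs.items()}
    mix[UNASSIGNED] = 1.0 - sum(mix.values())
    return mix


def default_gbif_mixture() -> dict[str, float]:
    """Same phylum shares at the occurrence database's 0.89 assigned fraction."""
    ab = _snapshot_abundance()
    probs = 0.89 * ab / ab.sum()
    mix = {p: float(v) for p, v in probs.items()}
    mix[UNASSIGNED] = 1.0 - sum(mix.values())
    return mix


@dataclass
class SimConfig:
    """Conditions for one synthetic corpus.

    ``phylum_mixture`` is either one multinomial over the 24 phyla plus
    ``"unassigned"`` applied to every area, or a per-area mapping of such
    multinomials.  Fractions are probabilities in [0, 1].
    """

    seed: int = 0
    areas: Optional[Sequence[GeoArea]] = None
    per_area_n: int = 240
    phylum_mixture: Optional[Mapping] = None
    missing_qualifier_frac: float = 0.28
    confounder_frac: float = 0.10
    environmental_frac: float = 0.38
    contaminant_frac: float = 0.05
    synonym_frac: float = 0.20
    variant_qualifier_frac: float = 0.25
    exception_pairs: tuple[tuple[str, str], ...] = (
        ("Republic of the Congo", "Democratic Republic of Congo"),
    )

    def resolved_areas(self) -> list[GeoArea]:
        return list(self.areas) if self.areas is not None else default_area_list()

    def mixture_for(self, area_name: str, fallback: Mapping[str, float]) -> Mapping[str, float]:
        mix = self.phylum_mixture
        if mix is None:
            mix = fallback
        elif mix and isinstance(next(iter(mix.values())), Mapping):
            mix = mix[area_name]
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture for {area_name!r} sums to {total}, not 1")
        return mix

    def validate(self) -> None:
        for name in (
            "missing_qualifier_frac",
            "confounder_frac",
            "environmental_frac",
            "contaminant_frac",
            "synonym_frac",
            "variant_qualifier_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.per_area_n < 0:
            raise ValueError("per_area_n must be >= 0")


@dataclass
class GroundTruth:
    """Exact expected pipeline output for a generated corpus."""

    source: str
    counts: pd.DataFrame
    environmental: pd.Series
    unlocated: int = 0
    contaminants: int = 0
    total_records: int = 0
    seed: int = 0

    def expected_tally(self) -> TallyMatrix:
        return TallyMatrix(
            source=self.source,
            counts=self.counts.copy(),
            environmental=self.environmental.copy(),
            unlocated=self.unlocated,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "seed": self.seed,
                "unlocated": self.unlocated,
                "contaminants": self.contaminants,
                "total_records": self.total_records,
                "environmental": {k: int(v) for k, v in self.environmental.items()},
                "counts": {a: {c: int(v) for c, v in row.items()} for a, row in self.counts.iterrows()},
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        counts = pd.DataFrame.from_dict(d["counts"], orient="index")
        counts.index.name = "area"
        env = pd.Series(d["environmental"], name="environmental").reindex(counts.index).fillna(0)
        return cls(
            source=d["source"],
            counts=counts,
            environmental=env,
            unlocated=d["unlocated"],
            contaminants=d["contaminants"],
            total_records=d["total_records"],
            seed=d["seed"],
        )


def _empty_truth(source: str, areas: Sequence[GeoArea], phyla: Sequence[str], seed: int) -> GroundTruth:
    idx = pd.Index([a.name for a in areas], name="area")
    cols = list(phyla) + [UNASSIGNED]
    return GroundTruth(
        source=source,
        counts=pd.DataFrame(0, index=idx, columns=cols),
        environmental=pd.Series(0, index=idx, name="environmental"),
        seed=seed,
    )


def _flatfile_date(rng: np.random.Generator) -> str:
    lo, hi = DATE_WINDOW[0].toordinal(), DATE_WINDOW[1].toordinal()
    d = date.fromordinal(int(rng.integers(lo, hi + 1)))
    return f"{d.day:02d}-{_MONTHS[d.month - 1]}-{d.year}"


def _lineage_and_organism(
    phylum: str, environmental: bool, rng: np.random.Generator
) -> tuple[tuple[str, ...], str]:
    if phylum == UNASSIGNED:
        if environmental:
            return ("Bacteria", "environmental samples"), "uncultured bacterium"
        off_frame = NON_FRAME_PHYLA[int(rng.integers(len(NON_FRAME_PHYLA)))]
        return ("Bacteria", off_frame), f"{off_frame} bacterium"
    lineage = ["Bacteria", phylum, f"{phylum} classis incertae sedis"]
    organism = f"{phylum} bacterium"
    if environmental:
        lineage.append("environmental samples")
        organism = f"uncultured {phylum} bacterium"
    return tuple(lineage), organism


def generate_genbank_corpus(cfg: SimConfig) -> tuple[str, GroundTruth]:
    """Emit a flatfile corpus and its exact expected tally.

    Deterministic for a fixed seed (byte-identical output).  Confounder
    records name a second country in their DEFINITION line only, so the
    expected tally is identical whatever ``confounder_frac`` is; records
    drawn as qualifier-missing carry no ``/country`` and are expected in
    the unlocated bucket.
    """
    cfg.validate()
    areas = cfg.resolved_areas()
    phyla = default_phyla()
    truth = _empty_truth("NCBI", areas, phyla, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    fallback = default_ncbi_mixture()
    variant_areas = {n for pair in cfg.exception_pairs for n in pair}
    names = [a.name for a in areas]

    records: list[SeqRecord] = []
    acc = 0
    for area in areas:
        n = cfg.per_area_n
        if n == 0:
            continue
        mix = cfg.mixture_for(area.name, fallback)
        cats = list(mix.keys())
        draws = rng.choice(len(cats), size=n, p=list(mix.values()))
        missing = rng.random(n) < cfg.missing_qualifier_frac
        env = rng.random(n) < cfg.environmental_frac
        confound = rng.random(n) < cfg.confounder_frac
        partners = rng.integers(0, len(names), size=n)
        variants = rng.random(n) < cfg.variant_qualifier_frac
        regions = rng.random(n) < 0.3
        for i in range(n):
            acc += 1
            phylum = cats[draws[i]]
            lineage, organism = _lineage_and_organism(phylum, bool(env[i]), rng)
            desc = f"{organism} 16S ribosomal RNA gene, partial sequence"
            if confound[i]:
                other = names[partners[i] % len(names)]
                if other == area.name:
                    other = names[(partners[i] + 1) % len(names)]
                desc += f", sequenced in collaboration with a laboratory in {other}"
            rec = SeqRecord(
                Seq("ACGTACGTACGTACGTACGT"),
                id=f"SYN{acc:08d}",
                name=f"SYN{acc:08d}",
                description=desc,
                annotations={
                    "molecule_type": "DNA",
                    "organism": organism,
                    "source": organism,
                    "taxonomy": list(lineage),
                    "date": _flatfile_date(rng),
                    "accessions": [f"SYN{acc:08d}"],
                },
            )
            qualifiers: dict[str, list[str]] = {"organism": [organism]}
            if not missing[i]:
                qname = area.name
                if area.name in variant_areas and variants[i]:
                    qname = CONGO_VARIANTS.get(area.name, area.name)
                value = qname if not regions[i] else f"{qname}: Region {int(draws[i]) + 1}"
                qualifiers["country"] = [value]
            rec.features.append(
                SeqFeature(FeatureLocation(0, len(rec.seq)), type="source", qualifiers=qualifiers)
            )
            records.append(rec)

            truth.total_records += 1
            if missing[i]:
                truth.unlocated += 1
            else:
                truth.counts.loc[area.name, phylum] += 1
                if env[i]:
                    truth.environmental.loc[area.name] += 1

    buf = io.StringIO()
    buf.write(f"# synthetic flatfile corpus; seed: {cfg.seed}\n")
    SeqIO.write(records, buf, "genbank")
    return buf.getvalue(), truth


def generate_gbif_corpus(
    cfg: SimConfig, cap_test_area: Optional[str] = None
) -> tuple[dict[str, str], GroundTruth]:
    """Emit per-area occurrence download files and their expected tally.

    Returns ``{area name: TSV text}``.  A ``contaminant_frac`` share of
    rows belongs to non-bacterial kingdoms (expected to be excluded by
    the kingdom filter and counted in ``contaminants``), and a
    ``synonym_frac`` share of assigned rows spells its phylum in a
    classification-dialect synonym.  With ``cap_test_area`` set, that
    area's file holds exactly the download-cap row count so the
    truncation-warning path can be exercised.
    """
    cfg.validate()
    from .gbif_filter import DOWNLOAD_CAP, DEFAULT_DIALECT

    areas = cfg.resolved_areas()
    phyla = default_phyla()
    truth = _empty_truth("GBIF", areas, phyla, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    fallback = default_gbif_mixture()
    # reverse synonym map: canonical -> one dialect spelling
    from .taxa import default_synonyms

    reverse_syn: dict[str, str] = {}
    for dialect_name, canonical in default_synonyms().items():
        reverse_syn.setdefault(canonical, dialect_name.capitalize())

    header = "\t".join(
        [
            DEFAULT_DIALECT.scientific_name,
            DEFAULT_DIALECT.kingdom,
            DEFAULT_DIALECT.phylum,
            DEFAULT_DIALECT.area,
            DEFAULT_DIALECT.latitude,
            DEFAULT_DIALECT.longitude,
        ]
    )
    files: dict[str, str] = {}
    for area in areas:
        n = DOWNLOAD_CAP if area.name == cap_test_area else cfg.per_area_n
        lines = [f"# synthetic occurrence download; seed: {cfg.seed}", header]
        if n:
            mix = cfg.mixture_for(area.name, fallback)
            cats = list(mix.keys())
            draws = rng.choice(len(cats), size=n, p=list(mix.values()))
            contam = rng.random(n) < cfg.contaminant_frac
            syn = rng.random(n) < cfg.synonym_frac
            has_coord = rng.random(n) < 0.8
            lats = rng.uniform(-90, 90, size=n)
            lons = rng.uniform(-180, 180, size=n)
            kingdoms = rng.integers(0, len(CONTAMINANT_KINGDOMS), size=n)
            for i in range(n):
                truth.total_records += 1
                if contam[i]:
                    kingdom = CONTAMINANT_KINGDOMS[kingdoms[i]]
                    name, phylum_txt = f"{kingdom} sp.", "Chordata"
                    truth.contaminants += 1
                else:
                    kingdom = "Bacteria"
                    phylum = cats[draws[i]]
                    if phylum == UNASSIGNED:
                        off = NON_FRAME_PHYLA[int(rng.integers(len(NON_FRAME_PHYLA)))]
                        name, phylum_txt = f"{off} bacterium", off
                    else:
                        name = f"{phylum} bacterium"
                        phylum_txt = phylum
                        if syn[i] and phylum in reverse_syn:
                            phylum_txt = reverse_syn[phylum]
                    truth.counts.loc[area.name, phylum] += 1
                lat = f"{lats[i]:.4f}" if has_coord[i] else ""
                lon = f"{lons[i]:.4f}" if has_coord[i] else ""
                lines.append("\t".join([name, kingdom, phylum_txt, area.name, lat, lon]))
        files[area.name] = "\n".join(lines) + "\n"
    return files, truth
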