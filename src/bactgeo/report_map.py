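"""World choropleths and pipeline orchestration.

Maps are schematic: the package ships a coarse continent-outline table,
not survey-grade boundaries.  Continent-level summaries fill the six
outlines; country-level summaries are drawn as a tile grid laid out
inside each continent's silhouette.  The colour scale is quantile-binned
record counts with a designated no-data fill, and the test surface is
the plotted data table (written alongside the image), never pixels.

``run_pipeline`` drives a full run — generate or load inputs, tally,
summarize, map — into a deterministic directory layout with every
stage's exclusion ledger logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__, gbif_filter, ncbi_filter, stats, synthetic_data, taxa
from .geography import GeoArea, default_area_list, load_area_list
from .stats import TallyMatrix

logger = logging.getLogger(__name__)

NO_DATA_COLOR = "#d9d9d9"
N_BINS = 5


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_outlines() -> dict[str, list[tuple[float, float]]]:
    ref = resources.files("bactgeo.data") / "continent_outlines.tsv"
    out: dict[str, list[tuple[float, float]]] = {}
    for line in ref.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("continent\t"):
            continue
        name, verts = line.split("\t")
        out[name] = [
            (float(lon), float(lat)) for lon, lat in (v.split(",") for v in verts.split(";"))
        ]
    return out


def load_aliases() -> dict[str, str]:
    """Packaged join-alias table: external spelling -> canonical area name."""
    ref = resources.files("bactgeo.data") / "map_aliases.tsv"
    table: dict[str, str] = {}
    header_done = False
    for line in ref.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_done:
            header_done = True
            continue
        alias, _, canonical = line.partition("\t")
        table[alias.strip().lower()] = canonical.strip()
    return table


def _quantile_bins(values: pd.Series, n_bins: int = N_BINS) -> pd.Series:
    """Bin positive counts into quantile classes 1..n (0 = no data)."""
    bins = pd.Series(0, index=values.index, dtype=int)
    pos = values[values > 0]
    if pos.empty:
        return bins
    ranks = pos.rank(method="average", pct=True)
    bins.loc[pos.index] = np.minimum((ranks * n_bins).apply(np.ceil).astype(int), n_bins)
    return bins


def _tile_layout(areas: Sequence[GeoArea], outlines) -> dict[str, tuple[float, float]]:
    """Deterministic tile positions: an alphabetical grid per continent."""
    pos: dict[str, tuple[float, float]] = {}
    by_continent: dict[str, list[str]] = {}
    for a in areas:
        by_continent.setdefault(a.continent, []).append(a.name)
    for continent, names in by_continent.items():
        names.sort()
        verts = outlines[continent]
        lons = [v[0] for v in verts]
        lats = [v[1] for v in verts]
        x0, x1 = min(lons), max(lons)
        y0, y1 = min(lats), max(lats)
        ncol = max(1, int(np.ceil(np.sqrt(len(names) * (x1 - x0) / max(y1 - y0, 1)))))
        nrow = int(np.ceil(len(names) / ncol))
        for k, name in enumerate(names):
            r, c = divmod(k, ncol)
            x = x0 + (c + 0.5) * (x1 - x0) / ncol
            y = y1 - (r + 0.5) * (y1 - y0) / max(nrow, 1)
            pos[name] = (x, y)
    return pos


def render_choropleth(
    summary: Union[Mapping[str, int], pd.Series],
    level: str,
    out: Union[str, Path],
    areas: Optional[Sequence[GeoArea]] = None,
) -> pd.DataFrame:
    """Render a record-count choropleth and return the plotted data table.

    ``level`` is ``"country"`` or ``"continent"``.  Summary keys are
    joined to the packaged frame through the alias table; a key that
    still does not join is logged and listed as unjoinable (never
    silently dropped), and frame members without data get the no-data
    fill.  The data table (name, count, bin, status) is also written
    next to the image as ``<out>.data.tsv`` — that table, not pixels, is
    the reproducible surface.
    """
    if level not in {"country", "continent"}:
        raise ValueError("level must be 'country' or 'continent'")
    summary = pd.Series(dict(summary), dtype=float)
    if summary.empty:
        raise ValueError("summary is empty")
    outlines = _load_outlines()
    areas = list(areas) if areas is not None else default_area_list()
    aliases = load_aliases()

    frame = list(outlines) if level == "continent" else [a.name for a in areas]
    canonical: dict[str, float] = {}
    unjoinable: list[str] = []
    frame_lower = {n.lower(): n for n in frame}
    for key, value in summary.items():
        name = frame_lower.get(str(key).lower()) or frame_lower.get(
            aliases.get(str(key).lower(), "").lower()
        )
        if name is None:
            logger.warning("summary key %r does not join the boundaries frame", key)
            unjoinable.append(str(key))
            continue
        canonical[name] = canonical.get(name, 0) + float(value)

    counts = pd.Series({n: canonical.get(n, 0.0) for n in frame})
    bins = _quantile_bins(counts)
    cmap = plt.get_cmap("YlGnBu")

    fig, ax = plt.subplots(figsize=(10, 5.5))
    ax.set_xlim(-185, 185)
    ax.set_ylim(-90, 85)
    ax.set_axis_off()
    for continent, verts in outlines.items():
        if level == "continent":
            b = int(bins[continent])
            color = NO_DATA_COLOR if b == 0 else cmap(0.25 + 0.75 * (b - 0.5) / N_BINS)
            ax.fill(*zip(*verts), facecolor=color, edgecolor="#555555", linewidth=0.6)
        else:
            ax.fill(*zip(*verts), facecolor="#f2f2f2", edgecolor="#bbbbbb", linewidth=0.5)
    if level == "country":
        layout = _tile_layout(areas, outlines)
        for name in frame:
            b = int(bins[name])
            color = NO_DATA_COLOR if b == 0 else cmap(0.25 + 0.75 * (b - 0.5) / N_BINS)
            x, y = layout[name]
            ax.add_patch(
                plt.Rectangle((x - 1.6, y - 1.6), 3.2, 3.2, facecolor=color, edgecolor="#444444", linewidth=0.3)
            )
    # quantile legend: the count ranges in each bin
    handles = [plt.Rectangle((0, 0), 1, 1, facecolor=NO_DATA_COLOR, edgecolor="#555555")]
    labels = ["no data"]
    for b in range(1, N_BINS + 1):
        members = counts[bins == b]
        if members.empty:
            continue
        handles.append(
            plt.Rectangle((0, 0), 1, 1, facecolor=cmap(0.25 + 0.75 * (b - 0.5) / N_BINS))
        )
        labels.append(f"{int(members.min()):,}–{int(members.max()):,}")
    ax.legend(handles, labels, loc="lower left", fontsize=7, title="records", title_fontsize=8)
    ax.set_title(f"Bacterial records by {level}")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, format=out.suffix.lstrip(".") or "svg")
    plt.close(fig)

    table = pd.DataFrame(
        {
            "name": list(counts.index) + unjoinable,
            "records": [int(v) for v in counts] + [0] * len(unjoinable),
            "bin": [int(bins[n]) for n in counts.index] + [0] * len(unjoinable),
            "status": ["data" if counts[n] > 0 else "no-data" for n in counts.index]
            + ["unjoinable"] * len(unjoinable),
        }
    )
    table.to_csv(out.with_suffix(out.suffix + ".data.tsv"), sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Declarative configuration for one run."""

    mode: str = "simulate"  # simulate | offline | fetch
    outdir: str = "bactgeo_run"
    seed: int = 0
    per_area_n: int = 240
    areas_path: Optional[str] = None
    phyla_path: Optional[str] = None
    allow_network: bool = False
    date_start: str = "1986-01-01"
    date_end: str = "2012-11-25"
    ncbi_files: list = field(default_factory=list)
    gbif_files: dict = field(default_factory=dict)  # area name -> path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def _summarize(m: TallyMatrix, areas: Sequence[GeoArea], outdir: Path, tag: str) -> dict:
    ab = stats.relative_abundance(m)
    oc = stats.geographic_occurrence(m)
    cont = stats.continent_rollup(m, areas)
    top = stats.top_countries(m, 10)
    sdir = outdir / "summaries"
    sdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(s) for s in ab]).to_csv(sdir / f"{tag}_abundance.tsv", sep="\t", index=False)
    pd.DataFrame([vars(s) for s in oc]).to_csv(sdir / f"{tag}_occurrence.tsv", sep="\t", index=False)
    pd.DataFrame([vars(s) for s in cont]).to_csv(sdir / f"{tag}_continents.tsv", sep="\t", index=False)
    pd.DataFrame(top, columns=["area", "records", "pct_assigned"]).to_csv(
        sdir / f"{tag}_top10.tsv", sep="\t", index=False
    )
    stats.export_summary_json(
        sdir / f"{tag}_summary.json", abundance=ab, occurrence=oc, continents=cont, top=top
    )
    return {
        "total_matched": m.total_matched,
        "unlocated": m.unlocated,
        "ambiguous": m.ambiguous,
        "parse_skipped": m.parse_skipped,
        "excluded_other": m.excluded_other,
        "continent_records": {c.continent: c.records for c in cont},
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute a full run into ``config.outdir`` and return that path.

    Modes: ``simulate`` generates both corpora with ground truth and
    verifies integer-exact recovery; ``offline`` runs on user-supplied
    flatfile / occurrence-download files; ``fetch`` is refused unless
    ``allow_network`` is set.  Any stage error aborts with the stage
    name; outputs written so far are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=outdir / "run.log", level=logging.INFO, force=False)

    areas = (
        load_area_list(config.areas_path) if config.areas_path else default_area_list()
    )
    phyla = taxa.load_phylum_list(config.phyla_path) if config.phyla_path else taxa.default_phyla()
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "seed": config.seed,
    }

    if config.mode == "fetch" and not config.allow_network:
        raise ncbi_filter.NetworkDisabled(
            "fetch mode requires allow_network: true in the config"
        )
    if config.mode not in {"simulate", "offline", "fetch"}:
        raise ValueError(f"unknown mode {config.mode!r}")

    truth_n = truth_g = None
    if config.mode == "simulate":
        cfg = synthetic_data.SimConfig(
            seed=config.seed, areas=areas, per_area_n=config.per_area_n
        )
        ncbi_text, truth_n = _gen_ncbi(cfg, outdir)
        gbif_files, truth_g = _gen_gbif(cfg, outdir)
        ncbi_sources = [outdir / "inputs" / "ncbi_corpus.gb"]
        gbif_sources = {
            name: outdir / "inputs" / "gbif" / f"{name}.tsv" for name in gbif_files
        }
    else:
        ncbi_sources = [Path(p) for p in config.ncbi_files]
        gbif_sources = {a: Path(p) for a, p in config.gbif_files.items()}

    m_ncbi = _run_ncbi(ncbi_sources, areas, phyla, config, outdir)
    m_gbif = _run_gbif(gbif_sources, areas, phyla, outdir)

    summary["ncbi"] = _summarize(m_ncbi, areas, outdir, "ncbi")
    summary["gbif"] = _summarize(m_gbif, areas, outdir, "gbif")

    if truth_n is not None:
        summary["exact_recovery"] = {
            "ncbi_count_mismatches": int(
                (m_ncbi.counts != truth_n.counts).to_numpy().sum()
            ),
            "ncbi_unlocated_match": m_ncbi.unlocated == truth_n.unlocated,
            "gbif_count_mismatches": int(
                (m_gbif.counts != truth_g.counts).to_numpy().sum()
            ),
        }

    _render_maps(m_ncbi, m_gbif, areas, outdir)

    summary_path = outdir / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return outdir


@_stage("generate-ncbi")
def _gen_ncbi(cfg, outdir: Path):
    text, truth = synthetic_data.generate_genbank_corpus(cfg)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    (inputs / "ncbi_corpus.gb").write_text(text)
    (inputs / "ncbi_ground_truth.json").write_text(truth.to_json())
    return text, truth


@_stage("generate-gbif")
def _gen_gbif(cfg, outdir: Path):
    files, truth = synthetic_data.generate_gbif_corpus(cfg)
    gdir = outdir / "inputs" / "gbif"
    gdir.mkdir(parents=True, exist_ok=True)
    for name, text in files.items():
        (gdir / f"{name}.tsv").write_text(text)
    (outdir / "inputs" / "gbif_ground_truth.json").write_text(truth.to_json())
    return files, truth


@_stage("filter-ncbi")
def _run_ncbi(sources, areas, phyla, config: PipelineConfig, outdir: Path) -> TallyMatrix:
    from datetime import date

    window = (
        date.fromisoformat(config.date_start),
        date.fromisoformat(config.date_end),
    )
    ledger = ncbi_filter.ParseLedger()

    def records():
        for path in sources:
            yield from ncbi_filter.parse_genbank(path, date_window=window, ledger=ledger)

    m = ncbi_filter.tally_ncbi(records(), areas, phyla)
    m.parse_skipped = ledger.skipped_truncated + ledger.skipped_date
    tdir = outdir / "tallies"
    tdir.mkdir(parents=True, exist_ok=True)
    m.to_tsv(tdir / "ncbi.tsv")
    (tdir / "ncbi_ledger.json").write_text(json.dumps(dataclasses.asdict(ledger)))
    return m


@_stage("filter-gbif")
def _run_gbif(sources: Mapping[str, Path], areas, phyla, outdir: Path) -> TallyMatrix:
    by_name = {a.name: a for a in areas}
    total = TallyMatrix.empty("GBIF", areas, phyla)
    ledgers = {}
    for area_name, path in sources.items():
        ledger = gbif_filter.ExclusionLedger()
        rows = gbif_filter.parse_occurrences(path, ledger=ledger)
        m = gbif_filter.tally_gbif(
            rows, areas, phyla, file_area=by_name.get(area_name), ledger=ledger
        )
        total.counts += m.counts
        total.unlocated += m.unlocated
        total.ambiguous += m.ambiguous
        total.excluded_other += m.excluded_other
        ledgers[area_name] = dataclasses.asdict(ledger)
    tdir = outdir / "tallies"
    tdir.mkdir(parents=True, exist_ok=True)
    total.to_tsv(tdir / "gbif.tsv")
    (tdir / "gbif_ledger.json").write_text(json.dumps(ledgers, sort_keys=True))
    return total


@_stage("map")
def _render_maps(m_ncbi: TallyMatrix, m_gbif: TallyMatrix, areas, outdir: Path) -> None:
    cont = {a.name: a.continent for a in areas}
    mdir = outdir / "maps"
    for tag, m in (("ncbi", m_ncbi), ("gbif", m_gbif)):
        matched = m.matched
        render_choropleth(matched, "country", mdir / f"{tag}_country.svg", areas)
        by_cont = matched.groupby(lambda n: cont[n]).sum()
        render_choropleth(by_cont, "continent", mdir / f"{tag}_continent.svg", areas)
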