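# Methods

## Problem and data model

The pipeline estimates where bacterial records in public databases come
from, at phylum resolution, over a fixed frame of 208 geographic areas
grouped into six continents (AMERICA, AFRICA, EUROPE, ASIA,
AUSTRALIA-OCEANIA, ANTARCTICA). Two record dialects are supported:

* **Sequence records** (GenBank/INSDC flatfile entries). The fields
  consulted are LOCUS/ACCESSION, DEFINITION, the ORGANISM block's
  structured lineage, the source feature's `/country` qualifier, and the
  flatfile date. Sequence content is never analysed.
* **Occurrence records** (Darwin-Core-style tab-separated downloads,
  optionally zip-wrapped, one file per area). The columns consulted are
  scientific name, kingdom, phylum, country and the decimal coordinates;
  column names are configurable per dialect.

Records are *not* deduplicated: many sequences can belong to one strain
(whole-genome shotgun submissions especially), and the tallies are
deliberately record tallies, not strain tallies.

## Strict geographic attribution

A record is attributed to an area only through its `/country` qualifier,
parsed as `Country[:Region]` by splitting on the first colon. Matching
proceeds in two steps:

1. **Exact**: case-insensitive equality of the country part with a
   canonical area name.
2. **Longest containment** (the exception-pair rule): otherwise, the
   candidate set is every area whose *normalized token sequence* occurs
   contiguously inside the country part's tokens, and the longest
   candidate (most tokens, then most characters) wins. Normalization
   lowercases, splits on non-alphanumeric runs and drops the article
   "the", so "Democratic Republic of the Congo" resolves to *Democratic
   Republic of Congo* rather than to the other Congo or to nothing.
   Two distinct candidates of identical length make the qualifier
   *ambiguous*; the record is excluded from area tallies and logged.

Token-level (rather than raw substring) containment is also what derives
each area's ambiguity set at load time; it links the Congo pair while
avoiding accidental pairs that character substrings create (e.g. "Oman"
inside "Romania"). Free-text mentions of countries anywhere else in the
record are ignored by construction — this is the design's entire point,
since full-text search counts collaborator addresses as sampling sites
and overestimates per-country tallies. Records with no or unresolvable
qualifiers accumulate in an explicit *unlocated* bucket so that every
input record is accounted for.

Multiple `/country` qualifiers on one record: the first is used, the
rest are logged. Region text after the colon is preserved but never
consulted for matching; the vocabulary's historical country names are
accepted in list files but flagged and excluded from the default frame.
Whether the original portal matching was case-sensitive, and whether
region text was consulted, is unknowable from the outside; both choices
here (case-insensitive, region ignored) are this package's decisions.

## Taxonomy harmonization

The phylum frame is the 24 bacterial phyla shared by the NCBI Taxonomy
and Catalogue of Life classifications (packaged in `data/phyla24.txt`).
On the sequence side, the first lineage element equal (case-insensitive)
to a frame phylum is taken; on the occurrence side, the phylum column is
first passed through an editable synonym table
(`data/phylum_synonyms.tsv`, dialect spelling → canonical name) and then
looked up in the frame. Everything else — including the eight phyla
recognised by only one classification (Synergistetes, Caldiserica,
Elusimicrobia, Armatimonadetes, Ignavibacteria, Tenericutes,
Thermomicrobia, Nitrospinae) — is *unassigned*. The `environmental
samples` taxon flags a record as environmental independently of phylum
assignment, because assigned lineages can also be environmental.

## Tally semantics and conservation

A tally matrix holds one row per frame area and one integer column per
phylum plus `unassigned`; per row, matched = Σ phyla + unassigned by
construction. Every stage maintains an exclusion ledger so the global
law holds exactly:

* sequence side: input = matched + unlocated + ambiguous + parse-skipped
  (malformed entries and out-of-window dates);
* occurrence side, per file: parsed = kept + excluded-by-kingdom +
  unlocated + foreign-area + ambiguous.

Date filtering (default window 1986-01-01 to 2012-11-25, the frame's
snapshot window) is applied at parse time even though a retrieval query
would already bound dates, so offline fixture files honor the cut-off.
A 250,000-row occurrence file is parsed fully but flagged with a
truncation warning, since capped download interfaces make such a file's
count a lower bound.

## Summary statistics

For phylum *p*: `Ab(p)` is the column sum over areas and
`Ab%(p) = 100·Ab(p)/Σ_q Ab(q)` over the 24-phylum frame; `Oc(p)` is the
number of areas with at least one record of *p* and
`Oc%(p) = 100·Oc(p)/n_areas`. Continent rollups report records, share of
the grand total, assigned records and the assignment rate
(assigned/records). Top-N rankings sort by records descending with
alphabetical tie-break, making them invariant to row order. All
percentages are rounded half-up (not banker's) to 3 decimals, matching
the precision of the snapshot tables; tests compare at 0.001.

The packaged December-2012 snapshot tables (`data/snapshot2012/`) serve
as worked-example inputs. One caveat is shipped with them: the
occurrence-side per-phylum abundance counts are not internally
consistent with any printed denominator (they sum to 1,735,822), so the
package only ever computes self-consistent percentages from whatever
counts it is given and makes no attempt to reproduce that column.

## Synthetic data generator

The generator emulates the statistical structure the pipeline is
sensitive to, with exact ground truth:

* per-area multinomial mixtures over the 24 phyla + unassigned. Defaults
  follow the snapshot marginals: phylum shares proportional to the
  snapshot abundances, assigned fraction 0.565 on the sequence side
  (1,311,049/2,322,339) and 0.89 on the occurrence side;
* missing-qualifier fraction 0.28 (the snapshot's unmatched share) — such
  records must land in the unlocated bucket;
* environmental-lineage fraction 0.38 (1,233,118/3,232,147), drawn
  independently of phylum so the both-assigned-and-environmental case
  occurs;
* confounder fraction 0.10 by default: the DEFINITION line names a second
  country. No rate is documented for real archives; 0.10 is this
  package's choice of a visible-but-minority contamination level, and the
  immunity tests sweep it to 1.0 anyway (the expected tally is identical
  by construction);
* Congo-pair article-variant qualifiers (fraction 0.25 of the pair's
  records) exercising the longest-containment path;
* non-bacterial contaminant rows (fraction 0.05, occurrence side) and a
  download-cap mode emitting exactly 250,000 rows;
* default 241 records per area over the full 208-area frame ≈ a
  50,128-record corpus, the scale at which end-to-end exactness is
  verified.

Output is deterministic and byte-identical per seed (one named
`numpy.random.default_rng` stream; every file records its seed in a
header comment). What the generator does **not** emulate: real lineage
depth and nomenclature noise, submission-date clustering, per-strain
sequence duplication structure, coordinate/locality inconsistencies, and
cross-dataset duplicates on the occurrence side. Passing tests therefore
demonstrate that the bookkeeping, matching and statistics are correct —
not that real-archive parsing covers every flatfile corner case, though
the parser is the standard Biopython reader and malformed entries are
skipped with named errors rather than trusted.

## Maps

Choropleths are schematic by design: the package ships a coarse
continent-outline table, not survey-grade boundaries. Continent-level
summaries fill the six silhouettes; country-level summaries are drawn as
an alphabetical tile grid inside each continent's bounding box. Counts
are binned into five quantile classes (the binning scheme is a package
decision) with a designated no-data fill; names join through a packaged
alias table, and unjoinable names are logged and listed, never silently
dropped. Images default to SVG, and the reproducible surface is the
plotted data table written next to each image — tests hash/compare that
table, never pixels, so the legend counts can be checked against the
statistics module without recomputation drift.

## Remote retrieval

Fetching from the live sequence archive is optional and off by default;
enabling it requires an explicit config flag. The client pages through
an id search + flatfile fetch at ≤ 3 requests/second with exponential
backoff (3 attempts) and a resumable cursor; the pipeline then runs on
the cached flatfile identically to any offline file. Live services
change continuously, so no test or shipped number depends on them.

## Numerical and degenerate-input choices

* Rounding: half-up, 3 decimals, applied only at reporting boundaries;
  internal arithmetic is exact integers / double precision.
* Empty area list: warning + empty frame. All-zero tally: abundance
  summaries raise "no assigned records" rather than emitting NaNs.
* Malformed coordinates: coordinate dropped, row kept, warning logged;
  out-of-range coordinates treated the same.
* Duplicate accessions within one input file: first wins, rest skipped
  and counted.
* Equal-length ambiguous qualifier matches: excluded, never arbitrarily
  assigned.

## Problem sizes used by the test suite

End-to-end exactness runs on the ~50k-record full-frame corpus;
parameter recovery uses 5,000 records/area over four areas with an exact
binomial per-cell test at Bonferroni-adjusted level for 99% joint
coverage; oracle equivalence uses 1,000 qualifier fixtures. These sizes
give the property checks real statistical bite while keeping a full test
run under a minute on one core.

## Known limitations

* The 208-area frame is a reconstruction of the vocabulary in use at the
  snapshot date; area lists drift over time and user-supplied lists are
  first-class inputs for that reason.
* Attribution ignores `/lat_lon`; records georeferenced only by
  coordinates are unlocated here.
* Phylum-level resolution hides all finer biogeographic structure.
* Tallies measure sampling/submission effort, not biodiversity; the
  statistics inherit every collection bias of the source archives.
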