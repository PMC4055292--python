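# Methods

## Problem and model

Multi-omics experiments report their measurements against incompatible
coordinate vocabularies: a microarray file keys rows by gene symbol, an
RNA-Seq quantification by gene identifier, a CNV segmentation or a
methylation track by raw chromosomal spans. `regionamalgam` translates K
such annotation-level files onto one shared vocabulary and merges them,
placing equal weight on each dataset.

The vocabulary element is the **regional unit**: per chromosome, all
translated entries are partitioned into connected components under the
relation "spans share at least one base pair" (transitive closure on
1-based inclusive coordinates). Each component becomes one unit whose
envelope `[StartFlag, StopFlag]` is the min start / max end of its
members; the widest member is the unit's *defining entity* and its
dataset the unit's *origin*; the remaining members are *subregions*
(`[Start, Stop]` within the unit). By construction units on one
chromosome are pairwise non-overlapping and every mapped entry belongs to
exactly one unit. An entry overlapping nothing still forms a singleton
unit: the vocabulary must include every supplied entity.

Two interpretation points are deliberate design choices:

* **"Widest non-overlapping units"** is read as: units are
  overlap-closure envelopes, and the widest member entry is the unit's
  origin. This is the single most consequential interpretation in the
  package — it reconciles non-overlapping envelopes with units that
  "originate" from one dataset while containing subregions from others.
* **Overlap requires ≥ 1 shared base**; abutting intervals
  (`end + 1 == start`) do not merge, so "non-overlapping" has a sharp
  complement.

## Translation routes

Entries are placed in this order of precedence:

1. **Coordinates supplied** (`given_coords`): the measured span always
   wins. A resolvable entity name contributes the gene assignment (with a
   mismatch note when the library span disagrees); otherwise the entry is
   reverse-annotated: every library gene intersecting the span is ranked
   by overlap length (ties by symbol), the best one assigned, the full
   list kept in the audit note. When the row *had* a name that the
   library does not know and a gene is recovered this way, the resolution
   is labelled `reverse_annotation`.
2. **Name only** (`name_lookup`): case-insensitive lookup over symbols
   and synonyms; canonical matches outrank synonym matches. A unique
   match contributes its library span. Ambiguous names (shared synonyms,
   multi-locus genes) follow the policy: `reject` (default — the entry is
   counted unmapped, keeping the vocabulary deterministic) or `all_loci`
   (one entry per matching locus, flagged in the note).
3. Otherwise **unmapped**, with reason `name_not_in_library`,
   `ambiguous_name`, `malformed`, or — only under the opt-in
   `require_gene` policy — `no_overlapping_gene_info` for coordinate
   spans that touch no library gene.

Unmapped entries can be retried against a *fallback library* (a second
library file applied only to them), mirroring a local-then-remote
annotation workflow without any network dependency.

## Determinism

The defining entity is chosen by the tie-break chain *longest span →
lowest dataset load order → lexicographically smallest entity label →
smallest start*; subregions sort by (start, end, load order, label);
chromosomes by browser order (1–22, X, Y, MT, others lexicographic).
Permuting dataset load order can therefore change only tie-broken
defining entities, never spans or membership. With `--deterministic` the
Txt sentinel omits its timestamp and all outputs are byte-identical
across reruns.

The sweep is a single left-to-right pass per chromosome tracking the
running maximum end over start-sorted entries — O(n log n) from the sort.
The quadratic fixpoint closure (repeated pairwise merging of components
with intersecting base-pair sets) exists only as the independent test
oracle and shares no code with the sweep.

## Coordinates and formats

All interfaces speak 1-based inclusive base pairs (genome-browser
display convention); inclusive lengths are `end − start + 1`, so a gene
at 100–200 queried with its own span overlaps by 101 bp. The interval
index stores half-open intervals internally (`intervaltree`), invisible
at every interface. Chromosome names are normalized (strip `chr`,
uppercase X/Y/MT, `M → MT`) before any comparison. BED export converts
to 0-based half-open (`start − 1`, `end`) — an exact bijection; FASTA
extraction takes the inclusive substring of the reference via `pyfaidx`.

The Txt export is the round-trip format: a `#regionamalgam` sentinel
line (format version, mode, assembly label, optional timestamp),
`#dataset` lines recording each source dataset's id, data type and
passthrough columns in load order, a header, then one row per member
entry — defining entry first within its unit — carrying the unit
envelope, the member span, entity name, data type, dataset id, gene
assignment with identifiers and library span, resolution and audit note,
plus the union of passthrough columns (empty cells where a dataset lacks
one). This is richer than the minimal seven-column table because the
file is reloadable: a later run detects the sentinel, reconstructs the
original datasets with their load order and pre-annotated placements,
and rebuilding from them reproduces the map exactly, byte for byte on
re-export. HTML output is one self-contained document (inline CSS only)
with unit header rows and per-entry links to NCBI (keyed on symbol) and
Ensembl/UCSC (keyed on region); URL templates are overridable.

Key-based merging (`--merge-mode key`) replaces the genomic interval
with a shared identifier column: case-insensitive identical keys form a
unit, defining entry chosen by load order (span length plays no role),
and a unit carries coordinates only when all members agree on one
chromosome (otherwise it is excluded from BED export).

## Synthetic data generator

`regionamalgam.fixtures` emulates the intended study setting — one gene
library plus K platform files (defaults: 3 datasets of 20/15/12 entries
over 2 chromosomes, half name-keyed and half span-keyed rows, 10 %
deliberately unmappable names of which half are fallback-recoverable) —
with the true vocabulary *planted*: disjoint unit spans are laid down
first, each occupied unit's first entry spans it entirely (guaranteeing
connectivity and a known envelope), genes live inside units (the first
gene of a unit spanning it, so name-keyed rows can anchor units), and
every further entry is drawn inside one unit. Ground truth is thus known
constructively, independent of both the sweep-line and the oracle; the
expected map is checked against the structural invariants at generation
time. Same seed, same fixture, byte for byte (per-chromosome substreams
are derived deterministically from the seed).

What the generator does **not** emulate: realistic expression/CNV value
distributions (passthrough cells are arbitrary tokens — the method never
interprets them), entries straddling two planted units, assembly
mismatches between library and data, or the scale and annotation noise
of real platform files. Passing tests therefore demonstrate the
correctness of translation, merging and serialization logic, not
robustness to database-version drift in real annotation sources.

## Problem sizes

The verification workloads are sized for quick, repeated desk runs: the
oracle-equivalence check uses 500 random instances of up to 60 intervals
across up to 3 datasets in a 10 kb coordinate space (the quadratic
oracle's explicit base-pair sets stay small); planted-truth recovery
uses 50 seeded studies of ~47 rows each. The sweep-line itself is
O(n log n) and handles genome-scale inputs; only the oracle is
deliberately tiny.

## Known limitations

* No arbitration between disagreeing annotation sources: whatever single
  library file the user supplies is the truth for a run.
* No assembly liftover; all inputs are assumed to share the library's
  assembly, echoed into outputs for audit.
* Strand is recorded but ignored in all overlap computations; annotation
  tracks here are strand-agnostic.
* No live database retrieval, no GUI browsers, no email/cloud transport;
  the fallback library and the programmatic summary/search/FASTA calls
  are the deliberate replacements.
* Genome-scale case studies (tens of thousands of units from real TCGA
  platform files) are outside the verification scope; nothing in the
  code limits input size, but correctness evidence comes from the
  synthetic studies above.
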