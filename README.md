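# regionamalgam

Merge heterogeneous genomic annotation files — microarray expression,
RNA-Seq quantifications, CNV segmentations, methylation tracks — onto a
single shared vocabulary of **widest non-overlapping regional units** of
the genome, and emit merged, linkable, reusable output files.

It is for anyone who has K annotation-level text files that key their
rows by gene name *or* by chromosomal span (plus arbitrary value/metadata
columns) and needs them expressed in one common coordinate vocabulary
before integrative analysis: every row is translated onto the genome via
a local gene library (forward lookup through symbols and synonyms, or
reverse annotation of raw spans against gene loci), and the translated
entries are partitioned, per chromosome, into connected components under
"spans share ≥ 1 bp" (transitive closure, 1-based inclusive
coordinates). Each component is one regional unit:

    StartFlag = min member start        StopFlag = max member end
    defining entity = the widest member (its dataset is the unit's origin)
    subregions      = every other member, [Start, Stop] inside the unit

Units on a chromosome are pairwise non-overlapping, every mapped entry
lands in exactly one unit, all datasets carry equal weight, and rows the
library cannot place are counted in an unmapped report (optionally
retried against a fallback library). An alternative key-based mode merges
on a shared identifier column instead of coordinates.

## Worked example

Three genes in a toy library; an expression file keyed by gene name and a
CNV file keyed by coordinates:

```
$ cat library.tsv                   $ cat expr.tsv          $ cat cnv.tsv
symbol synonyms chrom start end ... Gene   ExprValue        Chrom Start End  SegMean
GENEA  A1       chr1  100   300     GENEA  7.25             chr1  250   400  0.83
GENEB           chr1  250   400     GENEC  1.10
GENEC           chr1  500   600

$ regionamalgam merge --library library.tsv \
    --dataset expr.tsv:expr:microarray-expr --dataset cnv.tsv:cnv:cnv \
    --outdir out --formats txt,summary --deterministic
INFO merge: 2 regional units, 1 subregions, 0 unmapped
RUN ok units=2 subregions=1 unmapped=0 files=2
```

`out/merged.txt` (columns abridged):

```
Chrom  StartFlag  StopFlag  Start  Stop  EntityName  DataType         IsDefining  AssignedGene  Resolution    ExprValue  SegMean
1      100        400       100    300   GENEA       microarray-expr  1           GENEA         name_lookup   7.25
1      100        400       250    400               cnv              0           GENEB         given_coords             0.83
1      500        600       500    600   GENEC       microarray-expr  1           GENEC         name_lookup   1.10
```

Reading it: GENEA (expression, placed by name lookup at 100–300) and the
CNV segment 250–400 overlap by 51 bp, so they merge into one unit with
envelope 100–400; the 201 bp expression entry is wider than the 151 bp
segment, so it is the defining entity and the segment a subregion — whose
reverse annotation assigned GENEB (151 bp overlap beats GENEA's 51; the
full ranking is kept in the Note column). GENEC stands alone as a
singleton unit 500–600. The value columns of both input files ride
through untouched. `out/summary.txt`:

```
chrom  units  expr  cnv  covered_bp
    1      2     2    1         402
TOTAL      2     2    1         402
```

(402 = (400−100+1) + (600−500+1) base pairs covered.)

The Txt file is itself a valid input: a later `regionamalgam merge` run
detects its sentinel line, reconstructs the original datasets, and can
merge them with additional files — re-merging with nothing added
reproduces the file byte-for-byte under `--deterministic`. Other
subcommands: `fixtures` (synthetic studies with known ground truth),
`summarize`, `search`, `extract-fasta`; other formats: self-contained
HTML with NCBI/Ensembl/UCSC links per gene, BED6, FASTA of unit or gene
spans. Everything is equally available as library functions
(`regionamalgam.load_gene_library`, `annotate_dataset`,
`build_regional_units`, `write_txt`, ...).

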