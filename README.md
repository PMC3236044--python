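# annotqc

Quality control for annotated prokaryotic genome records.

Complete prokaryotic genomes are used as gold-standard references, yet the
archives contain genomes with no annotated RNAs, every protein named
"hypothetical protein", translated products on pseudogenes, or duplicated
locus_tags. `annotqc` measures, lints and judges an annotated genome
against the community minimal annotation standards for complete
prokaryotic genomes, and compares measure vectors across cohorts to flag
annotation outliers.

It is aimed at genome submitters and database curators who want a
submission-time sanity check, and at comparative genomicists who want to
know whether an odd measure reflects biology (endosymbiont genome
degradation, streamlining) or a mis-tuned annotation pipeline.

## What it computes

**Annotation-report measures** per genome: replicon count, length, GC%,
protein and RNA counts, amino acids covered by functional tRNAs,
hypothetical-protein count, coding density *d* = proteins/kbp, average and
minimum protein length, short-protein ratio (fraction of proteins < 150 aa)
and the standard start-codon percentage (fraction of 5'-complete CDS
starting ATG).

**Feature lint** against INSDC conventions, each outcome a `Finding` with
a rule id and severity (ERROR / FAIL / WARN / INFO): protein-naming rules
(only "hypothetical protein" and "uncharacterized protein" are acceptable
for unknown function), the structured `/inference` and `/experiment`
evidence grammar (`[CATEGORY:] type [(same species)] [:source[:version]]…`),
pseudogene strategies (no translated product on a `/pseudo` feature;
`LOW-QUALITY PROTEIN:` prefix with `/artificial_location`; evidence
required with the transcript/proteomic-data exception), locus_tag
uniqueness/prefix/syntax, and feature-table structure (gene/CDS pairing,
`/translation` consistency, reading-frame sanity, BioProject and
structured-comment metadata).

**Minimal-standards compliance**: a full rRNA set (5S, 16S, 23S), tRNAs
for all 20 standard amino acids, protein genes at expected density with
core conserved functions annotated (shipped 12-function catalog,
user-replaceable), plus the lint-derived checks. Genuine biological
exceptions documented on the record (`annotation-exception: CHECK_ID:
reason`) flip a FAIL to EXEMPT. The overall verdict is COMPLIANT /
COMPLIANT_WITH_EXEMPTIONS / NONCOMPLIANT.

**Cohort statistics**: z-scaling of a genomes × measures matrix, per-measure
OLS regression (slope, intercept, R², two-sided p for zero slope), PCA,
average-linkage hierarchical clustering for heatmap ordering, and |z| > 3
outlier flagging.

A deterministic synthetic-genome generator with exact declared truth
underpins the test suite and provides fixtures for every rule.

## Worked example

```sh
annotqc generate --seed 42 -o gold.gbk     # fully compliant synthetic genome
annotqc report gold.gbk
```

prints one measure row:

```
organism  replicon_count  total_length_mbp  gc_percent  protein_count  rna_count  trna_aa_count  hypothetical_count  coding_density  avg_protein_len_aa  min_protein_len_aa  short_protein_percent  standard_start_percent
Synthetica exemplaris  1  0.200  50.00  150  23  20  15  0.75  288  68  6.67  90.00
```

150 proteins on a 200 kb replicon give a coding density of 0.75
proteins/kbp (real complete genomes span roughly 0.49–1.19); 20 amino
acids are covered by tRNAs, 23 RNA features include the three rRNAs, 10%
of proteins are hypothetical and 90% start with ATG.

```sh
annotqc validate gold.gbk ; echo "exit $?"
```

reports every check PASS, `Overall: COMPLIANT`, exit 0. A variant missing
its 5S rRNA (`annotqc generate --case RRNA_SET`) validates NONCOMPLIANT
with exit 2; a reduced endosymbiont-like genome with a documented
`annotation-exception:` note exits 1 (COMPLIANT_WITH_EXEMPTIONS).

```sh
annotqc compare g1.gbk g2.gbk g3.gbk ... -o cmp/
```

writes the measure matrix, its scaled form, per-measure regression fits
against genome length, outlier findings and clustering leaf orders.

As a library:

```python
from annotqc import parse_genbank, compute_metrics, evaluate
record = parse_genbank(open("genome.gbk").read())
row = compute_metrics(record)          # MetricsRow
report = evaluate(record)              # ComplianceReport
print(report.overall, row.coding_density)
```

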