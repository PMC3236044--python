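# Methods

## Record model and coordinate conventions

A `GenomeRecord` is one or more replicons (named sequence, linear or
circular topology, feature list) plus organism, optional BioProject
identifier and an optional structured metadata comment block. A `Feature`
is a key (CDS, gene, tRNA, …), a `Location` and a qualifier multimap;
flag qualifiers such as `/pseudo` carry value `None`.

Internally all coordinates are 0-based half-open; GenBank, GFF3 and the
5-column feature table use 1-based inclusive coordinates, converted only
at the I/O boundary. Location segments are stored in written order with
strand-relative partial flags (`partial5` on the reverse strand is the `>`
marker on the highest coordinate). A multi-segment location whose first
segment starts after its last segment ends is treated as origin-spanning
on a circular replicon and rejected on a linear one. Reverse-strand
origin-spanning joins are not distinguishable from the reversed part order
some parsers emit for `complement(join(...))`; the toolkit normalises
reverse compound locations to ascending order, which is correct for all
non-wrapping cases, and the generator never emits reverse-strand wraps.

GenBank reading/writing goes through Biopython and GFF3 parsing through
gffutils; the GFF3 and `.tbl` writers are local. `source` features fold
into record metadata on parse and are regenerated on write, so
`parse(write(record)) == record` holds field-by-field. Record metadata
without a GFF3 home (organism, BioProject, structured comment, replicon
definition) travels in `#!`-prefixed pragma lines so the two formats are
mutually round-trippable.

Translation uses the bacterial/archaeal genetic code (table 11) unless a
`/transl_table` qualifier overrides it. A complete 5' end renders a valid
start codon (ATG/GTG/TTG/…) as M; the trailing stop is dropped; codons
containing ambiguity codes give X; an internal stop is an error carrying
the codon index, never a silent read-through. `/translation` values are
stored verbatim: disagreement with the computed translation is a lint
finding (STRUCT002), not a parse error, because archived records are
authoritative snapshots.

## Measures

Per genome: replicon count; pooled length; GC% over ACGT bases only
(ambiguity codes excluded from numerator and denominator); protein count =
non-pseudo CDS (features rescued via `/exception` or
`/artificial_location` still encode products and are counted); RNA count
over {tRNA, rRNA, ncRNA, tmRNA} (misc_RNA/precursor_RNA excluded by
default, configurable); amino acids with functional tRNA, parsed from
`tRNA-Xxx` products over the 20 standard tokens plus Sec, Pyl, fMet, Ile2
and OTHER, with pseudo-tRNA coverage tracked separately; hypothetical
count by normalized product name against a configurable name set (the
accepted pair plus legacy synonyms, so pre-standard records stay
measurable; missing `/product` counts as hypothetical with a WARN);
coding density = proteins per kbp; protein length from `/translation`
when present else span/3 − 1 (stop codon; no −1 at a 3'-partial end);
short-protein percentage below 150 aa; standard start-codon percentage
over 5'-complete non-pseudo CDS.

Report rounding is half-away-from-zero — two decimals for percentages and
density, nearest integer for average length — matching how annotation
reports print these values; raw values are retained on the row and used
by all downstream statistics.

## Lint rules and severities

Severities encode consequence: ERROR violates an INSDC prohibition (the
record is unsubmittable — e.g. a `/translation` on a pseudogene), FAIL
violates an accepted standard, WARN is outside guideline, INFO advisory.
The full registry lives in `annotqc.lint.RULE_CATALOG`; each rule has a
dedicated positive fixture in the generator and must stay silent on the
gold-standard fixture (a coverage-matrix test enforces both directions).

Naming: beyond the accepted-pair rule, stylistic checks (all-uppercase
names, "homolog"/"fragment" qualifiers) exist but default off — only the
community-mandated rules are on. `/pseudogene` with a value is accepted
as a synonym of `/pseudo` and noted INFO, since the proposal to split
`/pseudo` into `/pseudogene` + `/nonfunctional` is still pending. The
"potential pseudogene recorded only in a note" strategy is inherently
untrackable and is documented here rather than linted.

Evidence: the `/inference` grammar is an optional category token
(EXISTENCE / COORDINATES / DESCRIPTION), a type from the fixed vocabulary
("non-experimental", the "similar to …" family, profile, motif, ab initio
prediction, alignment), an optional "(same species)", and a
colon-separated basis list pairing source with version or
accession.version. `render(parse(x))` is the canonical form of `x` and
`parse(render(e)) == e`; unknown tokens are findings, never crashes.

Locus tags: duplicate values on distinct loci (a gene and its CDS/tRNA at
the same range legitimately share one tag), more than one prefix per
genome, registry syntax (letter start, alphanumeric, length ≥ 3, single
underscore), and missing tags on gene/CDS/tRNA/rRNA features.

## Minimal standards and compliance

Checks: RRNA_SET (one each 5S/16S/23S, classified from `/product` with
subunit synonyms; pseudo-only presence downgrades to WARN), TRNA_SET
(functional coverage of the 20 standard amino acids; pseudo coverage
downgrades), CORE_FUNCS, DENSITY, HYPOTHETICAL_RATIO, plus LOCUS_TAGS,
PSEUDO_FORMAT and VALIDATION_CLEAN derived from the lint findings.
Overall: NONCOMPLIANT iff any check FAILs or any ERROR finding exists;
EXEMPT checks give COMPLIANT_WITH_EXEMPTIONS.

The shipped core catalog is the 12 functions with a historical record of
having been restored to curated reference genomes (42 additions in
total), each with name patterns and an expected length ± sd; the larger
curated core sets behind that effort are not published, so the default
catalog is deliberately small and honest, with a non-normative extension
(`core_functions_extended.tsv`) and full user replaceability. Matching is
word-bounded case-insensitive substring ("ribosomal protein L2" must not
match L23); a match only on a pseudogene note downgrades to WARN; a
matched protein whose length is outside expected ± 4 sd is an INFO
(CORE001). Name-pattern matching is a deliberate simplification — an
HMM/profile search would be stronger evidence; the catalog loader is the
hook for user-supplied match results.

"Expected density" has no published numeric definition; the default WARN
band [0.5, 1.25] proteins/kbp brackets the extremes observed in real
complete genomes (0.49 in a degraded obligate pathogen, 1.19 at the dense
end) with margin, and is WARN rather than FAIL because real biology
produces both ends. The hypothetical-ratio check FAILs at ≥ 0.95
(essentially every protein unannotated) and WARNs at ≥ 0.8; both
thresholds are configuration.

Exceptions: the standards require documented exceptions but fix no
syntax, so this package greps for `annotation-exception: <CHECK_ID>:
<free text>` in structured-comment values and feature `/note`s — explicit
and machine-checkable.

## Cohort statistics

Column scaling subtracts the column mean and divides by the sample (n−1)
standard deviation — the convention is not fixed by the published
heatmap description, so the common statistical one is used and tested
explicitly; missing entries are ignored in moments (pairwise-complete)
and preserved. OLS fits report slope, intercept, R² = 1 − SSres/SStot and
the two-sided zero-slope t-test on n−2 degrees of freedom; the test-suite
oracle is the closed form via the normal equations and the regularized
incomplete beta function, independent of the scipy routine used in the
implementation. PCA is an SVD of the (re-centred) scaled matrix with
missing cells imputed at the column mean (0 after scaling) and a
largest-loading-nonnegative sign convention. Clustering is agglomerative
with Euclidean distance and average linkage, leaf order taken from the
linkage for heatmap rendering. Outlier flagging reports every
(genome, measure) cell with |z| > 3 (configurable) as a WARN finding.

## Synthetic-genome generator

The generator is first-class, tested code: it builds an annotated
replicon whose measures are known by construction. Counts are constructed
exactly, not sampled — the hypothetical, standard-start and evidence
assignments are integer counts rounded from the requested fractions, so
truth assertions are equalities, not tolerance bands. CDS bodies are
built backwards from the amino-acid length (start codon + L−1 random
sense codons + stop), placed on a random strand, with the consistent
`/translation` attached. GC is realised by exact base-count construction
of the non-coding pool (gaps, RNA bodies): the pool receives exactly the
number of G+C bases that brings the whole replicon to the target, so the
realised GC equals the target to integer-count rounding and is recorded
as truth. Infeasible requests (payload too large, unreachable GC,
too few proteins to host the core functions) fail before any output.

Defaults — the study conditions — are ratio-realistic and length-scaled:
200 kb, 150 proteins (density 0.75/kbp, inside the real-genome range),
length ~N(300, 80) aa truncated at 50, GC 50%, 10% hypothetical, 90%
ATG starts, full tRNA/rRNA complements, the 12 core functions named on
the first 12 proteins at their expected lengths, 20% of CDS carrying
structured evidence. The absolute genome size is scaled down by roughly
20× relative to a typical chromosome to keep fixtures fast; every
*measure* the toolkit checks is in the realistic range, which is what the
tests exercise.

What passing tests do and do not show: the generator has no operon
structure, no codon-usage bias, no overlapping genes, no realistic
intergenic grammar and no sequencing error, so green tests demonstrate
correctness of measure arithmetic, rule logic and I/O on well-formed
records — not robustness to the full messiness of archival submissions
(e.g. records predating locus_tags, nonstandard product formats beyond
the lint vocabulary).

Violations are planted exactly once each from a registry covering the
whole rule catalog: most are post-construction mutations of a generic
(non-core, non-hypothetical, forward-strand) protein; rules that are
properties of the whole record (missing metadata, bad prefix syntax,
missing RNA classes) are generated from spec overrides. `gold_standard()`
passes every check; `case_fixture(rule_id)` violates exactly its rule and
no other FAIL/ERROR rule.

## Numerical choices and degenerate inputs

Half-away-from-zero report rounding via decimal arithmetic on the float
repr; comparisons in tests are on raw values at 1e−9. Constant measure
columns are an error naming the measure (a z-score is undefined);
regression requires n ≥ 3 and non-constant x; clustering requires ≥ 2
items, with scipy's deterministic tie-breaking on fixed input order. A
record without sequence (GFF3 without FASTA) computes every
sequence-independent measure and reports the rest as absent with a WARN —
the error surfaces at the sequence-dependent operation, not at parse.
Zero-protein records report absent length statistics with a WARN rather
than raising.

## Problem sizes

The default test suite and the acceptance script generate genomes of
120–500 kb with 80–400 proteins; the generator-truth sweep uses 50 specs
varying length, GC, hypothetical and start-codon fractions and pseudogene
cases. These sizes exercise every code path while keeping the whole suite
in tens of seconds on one CPU.

## Known limitations

- GenBank dialect support is Biopython's; EMBL flat files and ASN.1 are
  out of scope, as are alignment- or HMM-based analyses (frameshift
  detection, profile core-function search).
- The cross-genome layer operates on measure tables; it does not attempt
  phylogeny-aware comparison or reproduce any specific historical cohort.
- Reverse-strand origin-wrapping join locations are not round-trippable
  (see coordinate conventions above).
- The core catalog is a seed, not a complete essential-gene set; absence
  of a FAIL from CORE_FUNCS says little for genomes annotated with
  nonstandard product vocabularies.
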