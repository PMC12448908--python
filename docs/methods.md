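# Methods

## Data model

IGD stores a hard-call genotype matrix: every call is a definite allele
assignment (0, 1, …, k, or missing); dosages and genotype likelihoods
are out of scope and dropped with a warning during VCF conversion. A
file holds exactly one contig, one ploidy (1..255), and one phasedness.

Sites are expanded to biallelic rows. For a site with k alternate
alleles:

* **phased**: k rows, each listing the haploid carriers of one
  alternate allele; haploid index = individual × ploidy + call slot, so
  columns are the NH = N × ploidy chromosome copies.
* **unphased**: one row per (alternate allele, copy count c) pair that
  has at least one carrier, listing individual indexes with
  `numCopies = c`; columns are the N individuals. An alternate allele
  with no carriers at all still gets one empty row with `numCopies = 1`,
  so monomorphic variants are never silently dropped and row counts are
  stable across phasedness.
* **missing data**: at most one IS_MISSING row per site (not per
  expanded variant), listing haploid samples (phased) or individuals
  (unphased) lacking a call. Its allele-strings entry is (ref, "") and
  its variant ID is empty. Q counts these rows.

Rows for one site are emitted variants-first (alternate alleles in input
order, copy counts ascending), then the missing row. Sites must arrive
in ascending position order; equal positions are allowed and are how
multiallelic sites exist on disk at all.

### Half-calls and unphased missingness

An unphased genotype with some calls known and some missing (e.g.
`./1`) cannot be represented by per-copy-count rows. The individual is
placed in the missing row and excluded from every copy count. This is
the one **lossy** corner of conversion: reading back yields a fully
missing genotype for that individual. Phased half-calls are lossless
(the known slot keeps its call; only the missing slot joins the missing
row). The unphased missing row's `numCopies` is written as 1 — a value
the format requires to be in 1..ploidy but to which it assigns no
meaning — and is read back verbatim.

## Encoding rules and numerical choices

* All multi-byte integers are **little-endian** (the format's prose
  never fixes byte order; this matches the dominant platforms and
  typical genomics binary formats).
* Version constant: 1. Readers reject other versions outright rather
  than guessing.
* **Sparse/dense rule**: sparse iff
  `carrier_count × threshold < column_count`, threshold from the header
  (default 32). The tie goes dense: at equality the serialized sizes are
  equal too (for byte-aligned widths), and dense decodes with less
  indirection. The rule provably picks the strictly smaller encoding
  whenever sizes differ, for byte-aligned widths ≥ 160 (verified
  exhaustively in the tests up to width 4096; below 160 the 4-byte
  length prefix makes tiny rows a wash either way).
* **Canonical rows**: sparse sample lists are strictly ascending with no
  duplicates; the writer enforces this and the reader rejects
  non-canonical rows. Ascending order makes rows diff-able and
  binary-searchable and makes sparse↔dense conversion an identity on
  carrier sets.
* Positions must fit in 48 bits and NH in 32 bits; both are hard errors
  at write time, not silent truncation.
* Reserved header bytes and unknown flag bits are written as zero and
  ignored on read, for forward compatibility.
* The one-pass writer streams genotype rows to disk while buffering
  index entries (16 bytes/row) and allele strings in memory, then writes
  the trailing sections and patches the four header offsets in place. A
  zero-offset header is therefore the recognizable "under construction"
  state, and the reader refuses it.
* An empty file (zero sites) is valid: the index begins immediately
  after the description strings and the index and allele offsets
  coincide.

## Reader behavior

Random access to row *i* costs one seek into the index and one seek to
the genotype row. Allele strings are variable-length, so traversal
streams them with a cursor while the first random access loads the whole
table into memory (it is small: two short strings per row). Range
queries are half-open `[start, end)` in base pairs, with positions
stored verbatim from VCF (1-based) — this avoids off-by-one mismatches
against VCF tooling. `lower_bound` is a textbook binary search over the
index. Site traversal groups consecutive equal-position rows in linear
time. IS_MISSING rows are yielded by default so M+Q accounting stays
visible; a flag filters them.

Allele frequency always recounts the full carrier list — phased:
|samples| / NH; unphased: |samples| × numCopies / NH — never a cached
count, so the computation doubles as a traversal exercise of every byte
of genotype data.

## VCF conversion

Parsing goes through pysam/htslib, reading plain, BGZF, and gzip VCF
(plain gzip is transparently decompressed to a temporary file because
htslib cannot seek in it). Phasedness is taken from the first
genotype's separator; later conflicts are errors, not coercions.
Haploid calls carry no separator, so ploidy-1 input defaults to phased
with an explicit override. Mixed ploidy and multi-contig input are
errors; a `contig=` option selects one contig from a multi-contig file
(other records are counted as skipped). Star and symbolic alleles pass
through as opaque strings. Note that htslib masks out-of-range GT
allele indexes to missing before the library sees them, so that
validation only fires for programmatically built sites. Duplicate
(position, alt) pairs are written as-is; uniqueness is a convention of
well-formed input, not enforced, keeping conversion one-pass.

Export produces a minimal GT-only VCFv4.2: consecutive same-position
rows re-merge into one multiallelic record, missing rows become `.`
calls, and unphased genotypes print ref copies first with alternate
alleles in ascending order (only copy counts are meaningful). The
sidecar metadata TSV (CHROM, POS, REF, ALT, ID, QUAL, FILTER, INFO; one
row per expanded non-missing variant) is this package's local schema
for keeping VCF metadata in easily manipulated plaintext.

## Synthetic fixtures

`igdkit.fixtures.make_matrix` generates small genotype matrices with a
single integer seed controlling all randomness. Defaults: 30 diploid
individuals, 25 sites, phased, no missing data, alternate-allele count
distribution (0.85, 0.09, 0.04, 0.02) for k = 1..4, and a discretized
neutral-like spectrum P(carrier count = c) ∝ 1/c — a desk-scale stand-in
for the rare-variant-rich composition of large sequencing cohorts. Two
extreme spectra force the all-sparse regime ("rare": every variant below
the 1/32 break-even) and the all-dense regime ("common": frequencies
around one half). Missingness is applied per haploid slot for phased
data and per whole individual for unphased data, matching what
per-copy-count storage represents losslessly.

The ground-truth matrix is materialized before any codec call, and test
oracles recount it with plain numpy operations — a code path independent
of the writer. The fixtures emulate matrix structure only: positions are
arbitrary increments, alleles are unlinked (no linkage disequilibrium),
and sample sizes are in the tens, so passing tests demonstrate format
correctness — byte layout, expansion, round trips, accounting — not
performance or compression behavior at biobank scale. Test problem
sizes (N ≤ 200, ≤ 60 sites) keep the whole suite in a few seconds while
still exercising every format feature: ploidy 1/2/3, both phasednesses,
k up to 4, missing data, and both frequency regimes.

## Known limitations

* No compression, memory-mapped access contract, append mode, or
  concurrent writers.
* Samples and metadata are not indexed; only positions can be queried
  efficiently.
* Unphased half-calls degrade to fully missing genotypes (documented
  above).
* Byte compatibility with other IGD implementations' current version
  numbers is not claimed; this library writes version 1 and rejects
  others.
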