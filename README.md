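# igdkit

Read, write, and convert **IGD** (Indexable Genotype Data) files — a
simple, uncompressed binary format for hard-call genotype matrices that
supports random access by row, binary search by base-pair position, and
fast full-file traversal, without external compression libraries or
sidecar index files.

## The format in brief

A dataset with *N* individuals of a given ploidy has
NH = N × ploidy haploid samples. IGD stores one row per **variant** — a
unique (position, alternate allele) pair — so a (k+1)-allelic site is
expanded into k rows sharing one position and reference allele. With *M*
variants and *Q* sites carrying missing data, the file holds an
(M+Q) × NH matrix: missing data is one extra row per site listing the
samples that *lack* a call.

Each genotype row is stored one of two ways, chosen per row:

* **sparse** (`list32`): a uint32 count followed by that many uint32
  sample indexes — 4 + 4k bytes;
* **dense** (bit-vector): one bit per sample, MSB-first within each byte
  (sample *b* sets bit 7 − (b mod 8) of byte ⌊b/8⌋) — ⌈w/8⌉ bytes.

Because a sparse entry costs 32 bits and a dense sample costs 1 bit,
sparse wins exactly when the carrier count times the sparsity threshold
(default 32) is below the column count — i.e. allele frequency < 1/32.
Rare-variant-rich cohorts therefore compress well with no compression
algorithm at all.

A fixed 128-byte header (magic `0x3a0c6fd7945a3481`, version, ploidy,
counts, flags, section offsets) is followed by two description strings,
the genotype rows, a 16-byte-per-row index (48-bit position, 8-bit
`numCopies`, 8-bit flags, 64-bit row offset), the allele strings, and
optional individual-ID and variant-ID string tables. All integers are
little-endian. Phased files list haploid carriers (`numCopies` = 0);
unphased files list individuals, one row per (alternate allele, copy
count) pair with `numCopies` ∈ 1..ploidy.

## Worked example

Generate a small synthetic cohort (50 diploid individuals, 6 sites, 5%
missing calls), convert it to IGD, and inspect it:

```sh
$ igdkit make-fixture cohort.vcf --seed 7 --individuals 50 --sites 6 --missing-rate 0.05
$ igdkit convert cohort.vcf cohort.igd
sites_read      6
variants_written        7
missing_rows    6
skipped_records 0
```

Six sites became 7 variant rows (one site is multiallelic) plus 6
missing-data rows. `info` shows the layout:

```sh
$ igdkit info cohort.igd
version 1
ploidy  2
phased  true
individuals     50
haploid_samples 100
rows    13
rows_sparse     3
rows_dense      10
sparsity_threshold      32
...
```

Three rows went sparse (their carrier count × 32 < 100). Allele
frequencies are recounted from the full rows, never a stored count:

```sh
$ igdkit freq cohort.igd
position        ref     alt     num_copies      count   frequency
48      A       C       0       10      0.1
79      T       A       0       17      0.17
113     G       A       0       9       0.09
113     G       C       0       29      0.29
157     T       A       0       75      0.75
186     A       C       0       5       0.05
225     A       C       0       3       0.03
```

Position 113 prints two lines — the two alternate alleles of the
multiallelic site. The same data is reachable from Python:

```python
from igdkit import open_igd

with open_igd("cohort.igd") as f:
    i = f.lower_bound(113)            # binary search on the internal index
    v = f.get_variant(i)              # one index seek + one row seek
    print(v.position, v.ref, v.alt, len(v.samples), f.allele_frequency(v))
    # 113 G A 9 0.09
```

`igdkit query --range START-END` filters by half-open position range,
and `igdkit export-vcf` converts back to a minimal GT-only VCF,
re-merging expanded rows into multiallelic records.

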