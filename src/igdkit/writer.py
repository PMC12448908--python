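"""One-pass construction of IGD files from an in-memory site stream.

A *site* is one polymorphic position with a reference allele, ``k``
alternate alleles, and a hard-call genotype vector per individual.  The
writer expands each site into IGD variant rows:

* phased files get one row per alternate allele listing the haploid
  carriers (haploid index = individual * ploidy + call slot);
* unphased files get one row per (alternate allele, copy count c) pair
  with at least one carrier, listing individual indexes with
  ``numCopies = c``;
* a site with any missing call additionally gets one IS_MISSING row
  listing the haploid samples (phased) or individuals (unphased) that
  lack a call.

Genotype rows stream to disk as they are produced; index entries and
allele strings buffer in memory (16 bytes and two short strings per row)
and are written after the last row, after which the header offsets are
patched in place.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Iterator, Literal, Sequence

from .codec import (
    DEFAULT_SPARSITY_THRESHOLD,
    HEADER_SIZE,
    INDEX_ENTRY_SIZE,
    IS_MISSING,
    SPARSE,
    CapacityError,
    Header,
    IgdError,
    IndexEntry,
    InvalidCallError,
    RowKind,
    SortOrderError,
    choose_representation,
    encode_dense_row,
    encode_header,
    encode_sparse_row,
    encode_string,
    encode_string_table,
    pack_index_entry,
)

MISSING = -1
"""Sentinel call value for a missing allele in a genotype vector."""

Representation = Literal["optimal", "sparse", "dense"]


@dataclass
class SiteInput:
    """One polymorphic site before biallelic expansion.

    ``genotypes`` holds one call vector of length ``ploidy`` per
    individual; call values are 0 (reference), 1..k (alternate allele
    number), or :data:`MISSING`.  ``variant_ids`` optionally names the k
    expanded variants (a single entry is replicated across all k).
    """

    position: int
    ref: str
    alt_alleles: Sequence[str]
    genotypes: Sequence[Sequence[int]]
    variant_ids: Sequence[str] | None = None


@dataclass(frozen=True)
class ExpandedVariant:
    """One IGD row produced by expanding a site."""

    position: int
    ref: str
    alt: str
    num_copies: int
    is_missing: bool
    samples: list[int]
    variant_id: str = ""


def expand_site(
    site: SiteInput, phased: bool, ploidy: int, num_individuals: int
) -> list[ExpandedVariant]:
    """Expand one site into IGD rows: variant rows first, then at most one
    IS_MISSING row; alternate alleles in input order, copy counts ascending.

    For unphased data an individual with a partially missing genotype
    (some calls known, some missing) is placed in the missing row and
    excluded from all copy counts: per-copy rows cannot represent a
    half-called genotype, so the whole individual is treated as missing.
    """
    k = len(site.alt_alleles)
    ids = list(site.variant_ids) if site.variant_ids else []
    if len(ids) == 1 and k > 1:
        ids = ids * k
    if ids and len(ids) != k:
        raise IgdError(
            f"site at {site.position} has {k} alt alleles but {len(ids)} variant IDs"
        )

    def vid(j: int) -> str:
        return ids[j] if ids else ""

    if len(site.genotypes) != num_individuals:
        raise IgdError(
            f"site at {site.position}: expected {num_individuals} genotype "
            f"vectors, got {len(site.genotypes)}"
        )

    rows: list[ExpandedVariant] = []
    missing: list[int] = []

    if phased:
        carriers: list[list[int]] = [[] for _ in range(k)]
        for n, calls in enumerate(site.genotypes):
            if len(calls) != ploidy:
                raise IgdError(
                    f"site at {site.position}: genotype of individual {n} "
                    f"has {len(calls)} calls, expected ploidy {ploidy}"
                )
            for p, call in enumerate(calls):
                if call == MISSING:
                    missing.append(n * ploidy + p)
                elif call == 0:
                    continue
                elif 1 <= call <= k:
                    carriers[call - 1].append(n * ploidy + p)
                else:
                    raise InvalidCallError(
                        f"call value {call} exceeds k={k} at position {site.position}"
                    )
        for j in range(k):
            rows.append(
                ExpandedVariant(
                    site.position, site.ref, site.alt_alleles[j], 0, False,
                    carriers[j], vid(j),
                )
            )
    else:
        # per (alt, copy count) individual lists
        by_copies: dict[tuple[int, int], list[int]] = {}
        for n, calls in enumerate(site.genotypes):
            if len(calls) != ploidy:
                raise IgdError(
                    f"site at {site.position}: genotype of individual {n} "
                    f"has {len(calls)} calls, expected ploidy {ploidy}"
                )
            bad = [c for c in calls if c != MISSING and not 0 <= c <= k]
            if bad:
                raise InvalidCallError(
                    f"call value {bad[0]} exceeds k={k} at position {site.position}"
                )
            if any(c == MISSING for c in calls):
                missing.append(n)
                continue
            for j in range(k):
                c = sum(1 for call in calls if call == j + 1)
                if c:
                    by_copies.setdefault((j, c), []).append(n)
        for j in range(k):
            copy_counts = sorted(c for (jj, c) in by_copies if jj == j)
            if not copy_counts:
                # monomorphic alt: keep the variant as a single empty row
                rows.append(
                    ExpandedVariant(
                        site.position, site.ref, site.alt_alleles[j], 1, False,
                        [], vid(j),
                    )
                )
                continue
            for c in copy_counts:
                rows.append(
                    ExpandedVariant(
                        site.position, site.ref, site.alt_alleles[j], c, False,
                        by_copies[(j, c)], vid(j),
                    )
                )

    if missing:
        # one missing row per site; numCopies is 0 for phased files and 1
        # for unphased files (the per-individual number of missing copies
        # is not representable in a single row and is not recorded)
        rows.append(
            ExpandedVariant(
                site.position, site.ref, "", 0 if phased else 1, True, missing, ""
            )
        )
    return rows


def encode_row(
    samples: Sequence[int],
    width: int,
    threshold: int = DEFAULT_SPARSITY_THRESHOLD,
    representation: Representation = "optimal",
) -> tuple[RowKind, bytes]:
    """Encode a carrier set, choosing sparse vs dense per the threshold
    rule unless a representation is forced."""
    if representation == "optimal":
        kind = choose_representation(len(samples), width, threshold)
    else:
        kind = representation
    if kind == "sparse":
        return "sparse", encode_sparse_row(samples)
    return "dense", encode_dense_row(samples, width)


@dataclass
class WriteReport:
    """Summary returned by :func:`write_igd`."""

    header: Header
    num_sites: int = 0
    num_variant_rows: int = 0  # M
    num_missing_rows: int = 0  # Q
    rows_sparse: int = 0
    rows_dense: int = 0
    bytes_written: int = 0

    @property
    def num_rows(self) -> int:
        return self.num_variant_rows + self.num_missing_rows


def write_igd(
    sink: str | os.PathLike | BinaryIO,
    sites: Iterable[SiteInput],
    *,
    num_individuals: int,
    ploidy: int,
    phased: bool,
    individual_ids: Sequence[str] | None = None,
    sparsity_threshold: int = DEFAULT_SPARSITY_THRESHOLD,
    representation: Representation = "optimal",
    source_description: str = "",
    description: str = "",
) -> WriteReport:
    """Write an IGD file in one pass over ``sites``.

    Sites must arrive in ascending position order.  A variant-IDs section
    is written iff any site supplies ``variant_ids``; an individual-IDs
    section iff ``individual_ids`` is given (its length must equal the
    number of individuals).  Returns a report whose ``header`` matches
    the one patched into the file.
    """
    if individual_ids is not None and len(individual_ids) != num_individuals:
        raise IgdError(
            f"{len(individual_ids)} individual IDs for {num_individuals} individuals"
        )
    header = Header(
        ploidy=ploidy,
        num_individuals=num_individuals,
        sparsity_threshold=sparsity_threshold,
    )
    header.phased = phased
    header.validate()  # ploidy / NH capacity checks up front
    width = header.row_width

    own = isinstance(sink, (str, os.PathLike))
    fh: BinaryIO = open(sink, "w+b") if own else sink
    report = WriteReport(header=header)
    try:
        fh.write(encode_header(header))  # placeholder: offsets still zero
        fh.write(encode_string(source_description))
        fh.write(encode_string(description))

        index: list[IndexEntry] = []
        alleles: list[tuple[str, str]] = []
        variant_ids: list[str] = []
        any_ids = False
        last_position = -1

        for site in sites:
            report.num_sites += 1
            if site.position < last_position:
                raise SortOrderError(
                    f"site at {site.position} arrived after position {last_position}"
                )
            last_position = site.position
            if site.variant_ids:
                any_ids = True
            for row in expand_site(site, phased, ploidy, num_individuals):
                kind, data = encode_row(
                    row.samples, width, sparsity_threshold, representation
                )
                flags = (SPARSE if kind == "sparse" else 0) | (
                    IS_MISSING if row.is_missing else 0
                )
                index.append(
                    IndexEntry(row.position, row.num_copies, flags, fh.tell())
                )
                fh.write(data)
                alleles.append((row.ref, row.alt))
                variant_ids.append(row.variant_id)
                if row.is_missing:
                    report.num_missing_rows += 1
                else:
                    report.num_variant_rows += 1
                if kind == "sparse":
                    report.rows_sparse += 1
                else:
                    report.rows_dense += 1

        header.num_variants = len(index)
        header.index_offset = fh.tell()
        for entry in index:
            fh.write(pack_index_entry(entry))
        header.allele_offset = fh.tell()
        for ref, alt in alleles:
            fh.write(encode_string(ref))
            fh.write(encode_string(alt))
        if individual_ids is not None:
            header.individual_ids_offset = fh.tell()
            fh.write(encode_string_table(individual_ids))
        if any_ids:
            header.variant_ids_offset = fh.tell()
            fh.write(encode_string_table(variant_ids))
        report.bytes_written = fh.tell()

        fh.seek(0)
        fh.write(encode_header(header))  # patch counts and section offsets
        fh.flush()
    finally:
        if own:
            fh.close()
    return report
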