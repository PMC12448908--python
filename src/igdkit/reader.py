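"""Random access, range query, and traversal over IGD files.

The internal index (16 bytes per row) makes three access patterns cheap:

* random access to row ``i`` — one seek into the index, one seek to the
  genotype row;
* binary search by base-pair position (`lower_bound`), since rows are
  stored in ascending position order;
* full traversal, reading the index sequentially and grouping
  consecutive equal-position rows back into multiallelic sites.

Samples and metadata are not indexed and cannot be queried efficiently;
the format trades that away for simplicity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import BinaryIO, Iterator

from .codec import (
    HEADER_SIZE,
    INDEX_ENTRY_SIZE,
    CorruptSectionError,
    Header,
    IgdError,
    IndexEntry,
    TruncatedFileError,
    decode_header,
    decode_row,
    decode_string,
    decode_string_table,
    dense_row_nbytes,
    unpack_index_entry,
)


@dataclass(frozen=True)
class VariantRecord:
    """One decoded IGD row.

    ``samples`` are haploid sample indexes for phased files and
    individual indexes for unphased files, strictly ascending.  For an
    IS_MISSING row they identify the samples *lacking* a call at the
    site rather than alternate-allele carriers, and ``alt`` is empty.
    """

    index: int
    position: int
    ref: str
    alt: str
    num_copies: int
    is_missing: bool
    samples: list[int]


@dataclass
class SiteGroup:
    """Consecutive variants sharing a position: one multiallelic site.

    ``num_alt_alleles`` counts distinct alternate alleles among the
    non-missing member variants (collapsing the per-copy-count rows of
    unphased files), i.e. the k of the original (k+1)-allelic site.
    """

    position: int
    ref: str
    variants: list[VariantRecord] = field(default_factory=list)

    @property
    def num_alt_alleles(self) -> int:
        return len({v.alt for v in self.variants if not v.is_missing})

    @property
    def missing(self) -> VariantRecord | None:
        for v in self.variants:
            if v.is_missing:
                return v
        return None


def allele_frequency(record: VariantRecord, header: Header) -> float:
    """Alternate-allele frequency of a variant row, recomputed from the
    full carrier list (never a stored count).

    Phased: ``|samples| / NH``.  Unphased: each listed individual holds
    ``numCopies`` copies, so ``|samples| * numCopies / (N * ploidy)``.
    """
    if record.is_missing:
        raise IgdError("allele frequency is undefined for an IS_MISSING row")
    nh = header.num_samples
    if nh == 0:
        return 0.0
    if header.phased:
        return len(record.samples) / nh
    return len(record.samples) * record.num_copies / nh


class IgdFile:
    """Handle on an open IGD file.

    The header and the two description strings are decoded eagerly;
    genotype rows are read on demand.  Allele strings are streamed with
    a cursor during traversal and loaded into memory in full the first
    time a random access needs them.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._fh: BinaryIO = open(self.path, "rb")
        try:
            self.header = decode_header(self._fh.read(HEADER_SIZE))
            self.source_description, self.description = self._read_descriptions()
        except Exception:
            self._fh.close()
            raise
        self._alleles: list[tuple[str, str]] | None = None
        self._individual_ids: list[str] | None = None
        self._variant_ids: list[str] | None = None

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "IgdFile":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- basic properties --------------------------------------------------

    @property
    def num_variants(self) -> int:
        """Number of stored rows, M + Q."""
        return self.header.num_variants

    @property
    def num_individuals(self) -> int:
        return self.header.num_individuals

    @property
    def ploidy(self) -> int:
        return self.header.ploidy

    @property
    def phased(self) -> bool:
        return self.header.phased

    @property
    def num_samples(self) -> int:
        return self.header.num_samples

    # -- low-level reads ---------------------------------------------------

    def _read_descriptions(self) -> tuple[str, str]:
        # two length-prefixed strings immediately after the header
        buf = b""
        out = []
        pos = HEADER_SIZE
        for _ in range(2):
            self._fh.seek(pos)
            head = self._fh.read(4)
            if len(head) < 4:
                raise TruncatedFileError("description strings are truncated")
            length = int.from_bytes(head, "little")
            data = self._fh.read(length)
            if len(data) < length:
                raise TruncatedFileError("description strings are truncated")
            out.append(data.decode("utf-8", errors="replace"))
            pos += 4 + length
        return out[0], out[1]

    def _index_entry(self, i: int) -> IndexEntry:
        if not 0 <= i < self.num_variants:
            raise IndexError(
                f"variant index {i} out of range [0, {self.num_variants})"
            )
        self._fh.seek(self.header.index_offset + INDEX_ENTRY_SIZE * i)
        return unpack_index_entry(self._fh.read(INDEX_ENTRY_SIZE))

    def _read_samples(self, entry: IndexEntry) -> list[int]:
        width = self.header.row_width
        self._fh.seek(entry.row_offset)
        if entry.is_sparse:
            head = self._fh.read(4)
            if len(head) < 4:
                raise TruncatedFileError("sparse row truncated at length prefix")
            count = int.from_bytes(head, "little")
            return decode_row(head + self._fh.read(4 * count), True, width)
        return decode_row(self._fh.read(dense_row_nbytes(width)), False, width)

    def _load_alleles(self) -> list[tuple[str, str]]:
        if self._alleles is None:
            self._fh.seek(self.header.allele_offset)
            data = self._fh.read()
            out: list[tuple[str, str]] = []
            pos = 0
            for _ in range(self.num_variants):
                ref, pos = decode_string(data, pos)
                alt, pos = decode_string(data, pos)
                out.append((ref.decode("utf-8"), alt.decode("utf-8")))
            self._alleles = out
        return self._alleles

    # -- public API --------------------------------------------------------

    def get_variant(self, i: int) -> VariantRecord:
        """Random access to row ``i`` (one index seek + one row seek)."""
        entry = self._index_entry(i)
        samples = self._read_samples(entry)
        ref, alt = self._load_alleles()[i]
        return VariantRecord(
            index=i,
            position=entry.position,
            ref=ref,
            alt=alt,
            num_copies=entry.num_copies,
            is_missing=entry.is_missing,
            samples=samples,
        )

    def position(self, i: int) -> int:
        """Base-pair position of row ``i`` without reading the genotype row."""
        return self._index_entry(i).position

    def lower_bound(self, position: int) -> int:
        """Smallest row index whose position is >= ``position``; returns
        ``num_variants`` when every stored position is smaller."""
        lo, hi = 0, self.num_variants
        while lo < hi:
            mid = (lo + hi) // 2
            if self._index_entry(mid).position < position:
                lo = mid + 1
            else:
                hi = mid
        return lo

    def iterate_variants(
        self,
        start: int | None = None,
        end: int | None = None,
        *,
        include_missing: bool = True,
    ) -> Iterator[VariantRecord]:
        """Yield rows in file order, optionally restricted to base-pair
        positions in the half-open range ``[start, end)``.

        IS_MISSING rows are yielded by default so that M+Q accounting is
        visible; pass ``include_missing=False`` to filter them out.
        """
        i = self.lower_bound(start) if start is not None else 0
        alleles = self._load_alleles()
        while i < self.num_variants:
            entry = self._index_entry(i)
            if end is not None and entry.position >= end:
                return
            if include_missing or not entry.flags & 0x02:
                samples = self._read_samples(entry)
                ref, alt = alleles[i]
                yield VariantRecord(
                    index=i,
                    position=entry.position,
                    ref=ref,
                    alt=alt,
                    num_copies=entry.num_copies,
                    is_missing=entry.is_missing,
                    samples=samples,
                )
            i += 1

    def iterate_sites(
        self, start: int | None = None, end: int | None = None
    ) -> Iterator[SiteGroup]:
        """Group consecutive equal-position rows back into sites.

        The concatenation of the emitted groups reproduces the variant
        traversal order; runs in linear time over the rows visited.
        """
        group: SiteGroup | None = None
        for record in self.iterate_variants(start, end):
            if group is None or record.position != group.position:
                if group is not None:
                    yield group
                ref = record.ref
                group = SiteGroup(position=record.position, ref=ref)
            if not record.is_missing and not group.variants:
                group.ref = record.ref
            group.variants.append(record)
        if group is not None:
            yield group

    def allele_frequency(self, record: VariantRecord) -> float:
        return allele_frequency(record, self.header)

    def get_individual_ids(self) -> list[str]:
        """Individual identifiers, or ``[]`` when the section is absent.

        The stored count must equal N or the section is corrupt.
        """
        if self._individual_ids is None:
            self._individual_ids = self._read_id_section(
                self.header.individual_ids_offset, self.num_individuals, "individual"
            )
        return self._individual_ids

    def get_variant_ids(self) -> list[str]:
        """Variant identifiers (one per stored row, IS_MISSING rows have
        empty IDs), or ``[]`` when the section is absent."""
        if self._variant_ids is None:
            self._variant_ids = self._read_id_section(
                self.header.variant_ids_offset, self.num_variants, "variant"
            )
        return self._variant_ids

    def _read_id_section(self, offset: int, expected: int, what: str) -> list[str]:
        if offset == 0:
            return []
        self._fh.seek(offset)
        data = self._fh.read()
        try:
            entries, _ = decode_string_table(data)
        except TruncatedFileError as exc:
            raise CorruptSectionError(f"{what}-IDs section is corrupt: {exc}") from exc
        if len(entries) != expected:
            raise CorruptSectionError(
                f"{what}-IDs section holds {len(entries)} strings, expected {expected}"
            )
        return [e.decode("utf-8") for e in entries]


def open_igd(path: str | os.PathLike) -> IgdFile:
    """Open an IGD file, validating its header."""
    return IgdFile(path)
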