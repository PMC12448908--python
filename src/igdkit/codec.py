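"""Bit-exact encoding/decoding of the IGD on-disk structures.

The Indexable Genotype Data (IGD) format stores a hard-call genotype
matrix as one row per variant, where a "variant" is a unique
(base-pair position, alternate allele) pair.  The file consists of a
fixed 128-byte header, two description strings, the genotype rows, a
16-byte-per-row index, the allele strings, and two optional string
tables (individual IDs and variant IDs).

Every multi-byte integer is little-endian.  Rows are encoded either
sparsely (``list32``: a uint32 count followed by that many uint32
sample indexes) or densely (a bit-vector of ``w`` bits at byte
granularity, MSB-first within each byte).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Format constants
# --------------------------------------------------------------------------

MAGIC = 0x3A0C6FD7945A3481
"""Magic number in the first 8 bytes of every IGD file."""

VERSION = 1
"""On-disk format version written by this library."""

HEADER_SIZE = 128
INDEX_ENTRY_SIZE = 16

MAX_PLOIDY = 255
MAX_POSITION = (1 << 48) - 1  # positions live in the low 48 bits of an index word

DEFAULT_SPARSITY_THRESHOLD = 32
"""Default divisor for the sparse/dense decision: a row goes sparse when
``carrier_count * threshold < w`` (w = number of matrix columns), i.e. when
a 32-bit index list is smaller than a w-bit vector."""

# Header flag bits (64-bit field at byte offset 40).
FLAG_PHASED = 0x1

# Per-row index flag bits (most significant byte of the first index word).
SPARSE = 0x01
IS_MISSING = 0x02

RowKind = Literal["sparse", "dense"]

_HEADER_STRUCT = struct.Struct("<QQIIQIIQQQQQ48x")
assert _HEADER_STRUCT.size == HEADER_SIZE

_U32 = struct.Struct("<I")
_U64 = struct.Struct("<Q")
_INDEX_STRUCT = struct.Struct("<QQ")


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class IgdError(Exception):
    """Base class for all IGD format errors."""


class InvalidHeaderError(IgdError):
    """A header field violates the format's invariants."""


class NotAnIgdFileError(IgdError):
    """The magic number does not match; the input is not an IGD file."""


class UnsupportedVersionError(IgdError):
    """The file's format version is not supported by this reader."""


class TruncatedFileError(IgdError):
    """The file ended in the middle of a structure."""


class PositionOverflowError(IgdError):
    """A base-pair position does not fit in 48 bits."""


class InvalidRowError(IgdError):
    """A genotype row is not in canonical form."""


class CorruptSectionError(IgdError):
    """A string-table section is inconsistent with the header counts."""


class InvalidCallError(IgdError):
    """A genotype call value is outside 0..k / MISSING."""


class PhasednessError(IgdError):
    """Input data mixes phased and unphased genotypes."""


class CapacityError(IgdError):
    """A count exceeds what the format can address (e.g. NH >= 2**32)."""


class SortOrderError(IgdError):
    """Variants were supplied out of ascending position order."""


# --------------------------------------------------------------------------
# Header
# --------------------------------------------------------------------------

@dataclass
class Header:
    """The fixed 128-byte header at the start of every IGD file.

    Section byte offsets are measured from the start of the file.  The
    individual-ID and variant-ID offsets are 0 when the section is absent.
    An all-zero offset block is the legal under-construction state used by
    the one-pass writer before it patches the offsets in place.
    """

    ploidy: int
    num_individuals: int
    num_variants: int = 0  # M + Q rows stored in the file
    sparsity_threshold: int = DEFAULT_SPARSITY_THRESHOLD
    flags: int = 0
    index_offset: int = 0
    allele_offset: int = 0
    individual_ids_offset: int = 0
    variant_ids_offset: int = 0
    version: int = VERSION
    magic: int = field(default=MAGIC, repr=False)

    @property
    def phased(self) -> bool:
        return bool(self.flags & FLAG_PHASED)

    @phased.setter
    def phased(self, value: bool) -> None:
        self.flags = (self.flags | FLAG_PHASED) if value else (self.flags & ~FLAG_PHASED)

    @property
    def num_samples(self) -> int:
        """NH = N * ploidy, the number of haploid samples."""
        return self.num_individuals * self.ploidy

    @property
    def row_width(self) -> int:
        """Number of matrix columns: NH for phased files, N for unphased."""
        return self.num_samples if self.phased else self.num_individuals

    def validate(self, *, require_offsets: bool = False) -> None:
        if self.magic != MAGIC:
            raise NotAnIgdFileError(
                f"bad magic number 0x{self.magic:016x} (expected 0x{MAGIC:016x})"
            )
        if self.version != VERSION:
            raise UnsupportedVersionError(
                f"unsupported IGD version {self.version} (this library reads version {VERSION})"
            )
        if not 1 <= self.ploidy <= MAX_PLOIDY:
            raise InvalidHeaderError(f"ploidy must be in 1..{MAX_PLOIDY}, got {self.ploidy}")
        if self.sparsity_threshold < 1:
            raise InvalidHeaderError("sparsity threshold must be >= 1")
        if not 0 <= self.num_individuals < 1 << 32:
            raise InvalidHeaderError("number of individuals must fit in a uint32")
        if self.num_samples >= 1 << 32:
            raise CapacityError("NH = N * ploidy must be < 2**32")

        offsets_set = self.index_offset or self.allele_offset
        if require_offsets and not offsets_set:
            raise InvalidHeaderError("section offsets are zero (incomplete file)")
        if offsets_set:
            if self.index_offset <= HEADER_SIZE:
                raise InvalidHeaderError(
                    f"index offset {self.index_offset} must lie past the header"
                )
            if self.allele_offset < self.index_offset + INDEX_ENTRY_SIZE * self.num_variants:
                raise InvalidHeaderError(
                    "allele-strings offset overlaps the index section"
                )
            for name, off in (
                ("individual-IDs", self.individual_ids_offset),
                ("variant-IDs", self.variant_ids_offset),
            ):
                if off and off < self.allele_offset:
                    raise InvalidHeaderError(f"{name} offset precedes the allele strings")
        elif self.individual_ids_offset or self.variant_ids_offset:
            raise InvalidHeaderError("ID section offsets set while index offset is zero")


def encode_header(header: Header) -> bytes:
    """Serialize a :class:`Header` to exactly 128 bytes.

    Bytes 36..39 and 80..127 are reserved and written as zero.
    """
    header.validate()
    return _HEADER_STRUCT.pack(
        header.magic,
        header.version,
        header.ploidy,
        header.sparsity_threshold,
        header.num_variants,
        header.num_individuals,
        0,  # reserved
        header.flags,
        header.index_offset,
        header.allele_offset,
        header.individual_ids_offset,
        header.variant_ids_offset,
    )


def decode_header(data: bytes, *, require_offsets: bool = True) -> Header:
    """Decode the first 128 bytes of an IGD file.

    Raises :class:`NotAnIgdFileError` on a magic mismatch,
    :class:`UnsupportedVersionError` on an unknown version, and
    :class:`TruncatedFileError` when fewer than 128 bytes are supplied.
    Reserved bytes and unknown flag bits are ignored for forward
    compatibility.
    """
    # check the magic first so that a short non-IGD input (e.g. a small
    # gzip file) reports "not an IGD file" rather than truncation
    if len(data) >= 8 and _U64.unpack_from(data, 0)[0] != MAGIC:
        raise NotAnIgdFileError(
            f"bad magic number 0x{_U64.unpack_from(data, 0)[0]:016x} "
            f"(expected 0x{MAGIC:016x})"
        )
    if len(data) < HEADER_SIZE:
        raise TruncatedFileError(
            f"need {HEADER_SIZE} header bytes, got {len(data)}"
        )
    (
        magic,
        version,
        ploidy,
        threshold,
        num_variants,
        num_individuals,
        _reserved,
        flags,
        index_offset,
        allele_offset,
        individual_ids_offset,
        variant_ids_offset,
    ) = _HEADER_STRUCT.unpack(data[:HEADER_SIZE])
    header = Header(
        ploidy=ploidy,
        num_individuals=num_individuals,
        num_variants=num_variants,
        sparsity_threshold=threshold,
        flags=flags,
        index_offset=index_offset,
        allele_offset=allele_offset,
        individual_ids_offset=individual_ids_offset,
        variant_ids_offset=variant_ids_offset,
        version=version,
        magic=magic,
    )
    header.validate(require_offsets=require_offsets)
    return header


# --------------------------------------------------------------------------
# Index entries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexEntry:
    """One 16-byte index row: two uint64 words.

    Word 1 packs the base-pair position into the least significant 48
    bits, ``numCopies`` into bits 48..55, and the row flags (SPARSE,
    IS_MISSING) into the most significant 8 bits.  Word 2 is the file
    offset of the genotype row.
    """

    position: int
    num_copies: int
    flags: int
    row_offset: int

    @property
    def is_sparse(self) -> bool:
        return bool(self.flags & SPARSE)

    @property
    def is_missing(self) -> bool:
        return bool(self.flags & IS_MISSING)

    @property
    def word1(self) -> int:
        return self.position | (self.num_copies << 48) | (self.flags << 56)


def pack_index_entry(entry: IndexEntry) -> bytes:
    """Serialize an index entry to exactly 16 bytes."""
    if not 0 <= entry.position <= MAX_POSITION:
        raise PositionOverflowError(
            f"position {entry.position} does not fit in 48 bits"
        )
    if not 0 <= entry.num_copies <= 0xFF:
        raise IgdError(f"numCopies {entry.num_copies} does not fit in 8 bits")
    if not 0 <= entry.flags <= 0xFF:
        raise IgdError(f"flags 0x{entry.flags:x} do not fit in 8 bits")
    return _INDEX_STRUCT.pack(entry.word1, entry.row_offset)


def unpack_index_entry(data: bytes) -> IndexEntry:
    """Exact inverse of :func:`pack_index_entry`."""
    if len(data) < INDEX_ENTRY_SIZE:
        raise TruncatedFileError(
            f"need {INDEX_ENTRY_SIZE} index bytes, got {len(data)}"
        )
    word1, row_offset = _INDEX_STRUCT.unpack(data[:INDEX_ENTRY_SIZE])
    return IndexEntry(
        position=word1 & MAX_POSITION,
        num_copies=(word1 >> 48) & 0xFF,
        flags=(word1 >> 56) & 0xFF,
        row_offset=row_offset,
    )


# --------------------------------------------------------------------------
# Genotype rows
# --------------------------------------------------------------------------

def _check_samples(samples: Sequence[int]) -> np.ndarray:
    arr = np.asarray(samples, dtype=np.int64)
    if arr.ndim != 1:
        raise InvalidRowError("sample list must be one-dimensional")
    if arr.size and (arr[0] < 0 or arr[-1] >= 1 << 32):
        raise InvalidRowError("sample indexes must fit in a uint32")
    if arr.size > 1 and not (np.diff(arr) > 0).all():
        raise InvalidRowError("sample indexes must be strictly ascending")
    return arr


def encode_sparse_row(samples: Sequence[int]) -> bytes:
    """Encode a carrier set as a ``list32``: uint32 count + count uint32s.

    ``samples`` must be strictly ascending (canonical form); duplicates or
    unsorted input raise :class:`InvalidRowError`.
    """
    arr = _check_samples(samples)
    return _U32.pack(arr.size) + arr.astype("<u4").tobytes()


def encode_dense_row(samples: Sequence[int], width: int) -> bytes:
    """Encode a carrier set as a bit-vector of ``width`` bits.

    Sample index ``b`` is stored in byte ``b // 8`` at the
    ``7 - (b % 8)``-th least significant bit, i.e. MSB-first within each
    byte.  The output is exactly ``ceil(width / 8)`` bytes.
    """
    arr = _check_samples(samples)
    if arr.size and arr[-1] >= width:
        raise InvalidRowError(
            f"sample index {int(arr[-1])} out of range for width {width}"
        )
    bits = np.zeros(-(-width // 8) * 8, dtype=np.uint8)
    bits[arr] = 1
    return np.packbits(bits).tobytes()  # packbits is MSB-first, as required


def decode_row(data: bytes, is_sparse: bool, width: int) -> list[int]:
    """Decode a genotype row into its strictly ascending carrier set.

    ``is_sparse`` comes from the row's index-entry flag; ``width`` is NH
    for phased files and N for unphased files (only used for dense rows).
    """
    if is_sparse:
        if len(data) < 4:
            raise TruncatedFileError("sparse row shorter than its length prefix")
        (count,) = _U32.unpack(data[:4])
        if len(data) < 4 + 4 * count:
            raise TruncatedFileError(
                f"sparse row claims {count} samples but only "
                f"{(len(data) - 4) // 4} are present"
            )
        arr = np.frombuffer(data, dtype="<u4", count=count, offset=4).astype(np.int64)
        if arr.size > 1 and not (np.diff(arr) > 0).all():
            raise InvalidRowError("sparse row is not strictly ascending")
        return arr.tolist()
    nbytes = -(-width // 8)
    if len(data) < nbytes:
        raise TruncatedFileError(
            f"dense row needs {nbytes} bytes for width {width}, got {len(data)}"
        )
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8, count=nbytes))[:width]
    return np.flatnonzero(bits).tolist()


def sparse_row_nbytes(count: int) -> int:
    return 4 + 4 * count


def dense_row_nbytes(width: int) -> int:
    return -(-width // 8)


def choose_representation(
    count: int, width: int, threshold: int = DEFAULT_SPARSITY_THRESHOLD
) -> RowKind:
    """Pick the smaller encoding for a row of ``count`` carriers.

    Sparse wins when ``count * threshold < width`` (with the default
    threshold of 32 this is carrier frequency < 1/32, exactly when a
    4-byte-per-sample list beats a width-bit vector).  Ties go dense.
    """
    if threshold < 1:
        raise IgdError("sparsity threshold must be >= 1")
    return "sparse" if count * threshold < width else "dense"


# --------------------------------------------------------------------------
# Strings and string tables
# --------------------------------------------------------------------------

def encode_string(value: bytes | str) -> bytes:
    """Length-prefixed string: uint32 byte count + contents."""
    raw = value.encode("utf-8") if isinstance(value, str) else bytes(value)
    return _U32.pack(len(raw)) + raw


def decode_string(data: bytes, offset: int = 0) -> tuple[bytes, int]:
    """Decode one length-prefixed string; returns (contents, next offset)."""
    if len(data) < offset + 4:
        raise TruncatedFileError("string length prefix is truncated")
    (length,) = _U32.unpack_from(data, offset)
    end = offset + 4 + length
    if len(data) < end:
        raise TruncatedFileError("string contents are truncated")
    return data[offset + 4 : end], end


def encode_string_table(entries: Iterable[bytes | str]) -> bytes:
    """String table: uint64 count followed by that many strings."""
    entries = list(entries)
    return _U64.pack(len(entries)) + b"".join(encode_string(e) for e in entries)


def decode_string_table(data: bytes, offset: int = 0) -> tuple[list[bytes], int]:
    """Decode a string table; returns (entries, next offset)."""
    if len(data) < offset + 8:
        raise TruncatedFileError("string-table count is truncated")
    (count,) = _U64.unpack_from(data, offset)
    pos = offset + 8
    out: list[bytes] = []
    for _ in range(count):
        s, pos = decode_string(data, pos)
        out.append(s)
    return out, pos
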