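"""VCF <-> IGD conversion (hard calls only).

``vcf_to_igd`` streams a VCF (plain or gzip) through pysam, builds one
:class:`~igdkit.writer.SiteInput` per record, and writes the IGD in a
single pass.  Genotype positions are copied verbatim (1-based); sample
IDs from the VCF header populate the individual-IDs section and the VCF
ID column populates the variant IDs.  Dosages and likelihoods (GL/PL/GP)
are ignored: the format stores hard calls.  QUAL/FILTER/INFO can be
exported to a sidecar plaintext TSV; otherwise they are dropped.

``igd_to_vcf`` exports a minimal VCFv4.2: consecutive same-position rows
are re-merged into one multiallelic record and IS_MISSING rows are
restored as ``.`` calls.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from itertools import chain
from typing import Iterator, TextIO

import pysam

from .codec import IgdError, PhasednessError
from .reader import IgdFile, SiteGroup, open_igd
from .writer import MISSING, SiteInput, WriteReport, write_igd

METADATA_COLUMNS = ("CHROM", "POS", "REF", "ALT", "ID", "QUAL", "FILTER", "INFO")

_DOSAGE_KEYS = {"GL", "PL", "GP", "DS"}


def _is_bgzf(path: str) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(18)
    # BGZF: gzip magic, FEXTRA set, and a 'BC' extra subfield
    return (
        len(head) >= 18
        and head[:2] == b"\x1f\x8b"
        and head[3] & 0x04
        and head[12:14] == b"BC"
    )


def _open_variant_file(path: str) -> pysam.VariantFile:
    """Open a VCF for streaming; plain (non-BGZF) gzip is decompressed to a
    temporary file first because htslib cannot seek in it."""
    if path.endswith(".gz") and not _is_bgzf(path):
        import gzip
        import tempfile

        tmp = tempfile.NamedTemporaryFile(
            mode="wb", suffix=".vcf", delete=False
        )
        try:
            with gzip.open(path, "rb") as src:
                while chunk := src.read(1 << 20):
                    tmp.write(chunk)
            tmp.close()
            vf = pysam.VariantFile(tmp.name)
        except Exception:
            tmp.close()
            os.unlink(tmp.name)
            raise
        os.unlink(tmp.name)  # already open; unlink keeps the fs clean
        return vf
    return pysam.VariantFile(path)


class FormatError(IgdError):
    """The VCF lacks data the conversion requires (e.g. no GT field)."""


class PloidyError(IgdError):
    """The VCF mixes ploidies; IGD requires one ploidy per file."""


class ContigError(IgdError):
    """The VCF spans several contigs and no contig was selected."""


@dataclass
class ConversionReport:
    """Counts accumulated while converting a VCF to IGD."""

    sites_read: int = 0
    variants_written: int = 0  # M (non-missing expanded rows)
    missing_rows: int = 0  # Q
    skipped_records: int = 0  # records on non-selected contigs
    num_individuals: int = 0
    ploidy: int = 0
    phased: bool = True
    contig: str = ""


def _record_sites(
    vcf: pysam.VariantFile,
    report: ConversionReport,
    contig: str | None,
    phased_override: bool | None,
    meta_out: TextIO | None,
    state: dict,
) -> Iterator[SiteInput]:
    """Yield one SiteInput per kept VCF record, validating uniformity."""
    warned_dosage = False
    for rec in vcf:
        if "GT" not in rec.format:
            raise FormatError(f"record at {rec.chrom}:{rec.pos} has no GT field")
        if not warned_dosage and _DOSAGE_KEYS & set(rec.format.keys()):
            warnings.warn(
                "ignoring dosage/likelihood FORMAT fields; IGD stores hard calls only",
                stacklevel=3,
            )
            warned_dosage = True
        if report.contig == "":
            report.contig = contig if contig is not None else rec.chrom
        if rec.chrom != report.contig:
            if contig is None:
                raise ContigError(
                    f"records span contigs {report.contig!r} and {rec.chrom!r}; "
                    "select one with the contig option"
                )
            report.skipped_records += 1
            continue

        calls = [s.allele_indices for s in rec.samples.values()]
        ploidies = {len(c) for c in calls}
        if len(ploidies) > 1:
            raise PloidyError(
                f"mixed ploidy {sorted(ploidies)} at {rec.chrom}:{rec.pos}"
            )
        ploidy = ploidies.pop() if ploidies else 1
        if report.ploidy == 0:
            report.ploidy = ploidy
            if phased_override is not None:
                report.phased = phased_override
            elif ploidy == 1:
                report.phased = True  # haploid calls carry no separator
            else:
                report.phased = next(iter(rec.samples.values())).phased
            state["ploidy"] = report.ploidy
            state["phased"] = report.phased
        elif ploidy != report.ploidy:
            raise PloidyError(
                f"ploidy changes from {report.ploidy} to {ploidy} "
                f"at {rec.chrom}:{rec.pos}"
            )
        if ploidy > 1:
            for s in rec.samples.values():
                # fully missing genotypes carry no phase information
                if s.phased != report.phased and any(
                    a is not None for a in s.allele_indices
                ):
                    raise PhasednessError(
                        f"mixed phasedness at {rec.chrom}:{rec.pos} "
                        f"(file is {'phased' if report.phased else 'unphased'})"
                    )

        alts = [a for a in (rec.alts or ())]
        genotypes = [
            tuple(MISSING if a is None else int(a) for a in c) for c in calls
        ]
        vid = rec.id or ""
        report.sites_read += 1
        if meta_out is not None:
            fields = str(rec).rstrip("\n").split("\t")
            qual, filt, info = fields[5], fields[6], fields[7]
            for alt in alts:
                meta_out.write(
                    "\t".join(
                        [rec.chrom, str(rec.pos), rec.ref or "", alt,
                         vid or ".", qual, filt, info]
                    )
                    + "\n"
                )
        yield SiteInput(
            position=rec.pos,
            ref=rec.ref or "",
            alt_alleles=alts,
            genotypes=genotypes,
            variant_ids=[vid] * len(alts) if vid else None,
        )


def vcf_to_igd(
    vcf_path: str | os.PathLike,
    igd_path: str | os.PathLike,
    *,
    contig: str | None = None,
    phased: bool | None = None,
    representation: str = "optimal",
    include_ids: bool = True,
    metadata_tsv: str | os.PathLike | None = None,
    description: str = "",
) -> ConversionReport:
    """Convert a VCF/vcf.gz with hard-call GT fields to IGD.

    All kept records must share one contig (pass ``contig=`` to select
    one from a multi-contig file), one ploidy, and one phasedness;
    violations raise.  ``phased`` overrides separator-based detection,
    which is only ambiguous for haploid data.  When ``metadata_tsv`` is
    given, CHROM/POS/REF/ALT/ID/QUAL/FILTER/INFO are written there, one
    row per expanded (position, alternate allele) variant.
    """
    vcf_path = os.fspath(vcf_path)
    report = ConversionReport()
    state: dict = {}
    with _open_variant_file(vcf_path) as vcf:
        sample_names = list(vcf.header.samples)
        report.num_individuals = len(sample_names)

        meta_out: TextIO | None = None
        if metadata_tsv is not None:
            meta_out = open(metadata_tsv, "w", encoding="utf-8")
            meta_out.write("\t".join(METADATA_COLUMNS) + "\n")
        try:
            # peek one site so ploidy/phasedness are known, then stream the
            # rest straight into the one-pass writer
            site_iter = _record_sites(vcf, report, contig, phased, meta_out, state)
            first = next(site_iter, None)
            sites = chain([first], site_iter) if first is not None else iter(())

            ploidy = state.get("ploidy", 1)
            file_phased = state.get("phased", True if phased is None else phased)
            wreport = write_igd(
                igd_path,
                sites,
                num_individuals=report.num_individuals,
                ploidy=ploidy,
                phased=file_phased,
                individual_ids=sample_names if include_ids else None,
                representation=representation,  # type: ignore[arg-type]
                source_description=f"converted from {os.path.basename(vcf_path)}",
                description=description or report.contig,
            )
        finally:
            if meta_out is not None:
                meta_out.close()
    report.ploidy = ploidy
    report.phased = file_phased
    report.variants_written = wreport.num_variant_rows
    report.missing_rows = wreport.num_missing_rows
    return report


@dataclass
class ExportReport:
    """Counts accumulated while exporting an IGD back to VCF."""

    records_written: int = 0
    rows_read: int = 0


def _site_genotypes(group: SiteGroup, igd: IgdFile) -> tuple[list[str], list[str]]:
    """Reconstruct (alts, per-individual GT strings) for one site."""
    ploidy = igd.ploidy
    n = igd.num_individuals
    alts: list[str] = []
    for v in group.variants:
        if not v.is_missing and v.alt not in alts:
            alts.append(v.alt)
    if igd.phased:
        slots = [0] * (n * ploidy)
        for v in group.variants:
            if v.is_missing:
                for s in v.samples:
                    slots[s] = MISSING
            else:
                a = alts.index(v.alt) + 1
                for s in v.samples:
                    slots[s] = a
        gts = [
            "|".join(
                "." if c == MISSING else str(c)
                for c in slots[i * ploidy : (i + 1) * ploidy]
            )
            for i in range(n)
        ]
        return alts, gts

    counts = [[0] * len(alts) for _ in range(n)]
    missing_individuals: set[int] = set()
    for v in group.variants:
        if v.is_missing:
            missing_individuals.update(v.samples)
            continue
        a = alts.index(v.alt)
        for ind in v.samples:
            counts[ind][a] += v.num_copies
    gts = []
    for ind in range(n):
        if ind in missing_individuals:
            gts.append("/".join(["."] * ploidy))
            continue
        total = sum(counts[ind])
        if total > ploidy:
            raise IgdError(
                f"individual {ind} at position {group.position} carries "
                f"{total} alternate copies but ploidy is {ploidy}"
            )
        calls = [0] * (ploidy - total)
        for a, c in enumerate(counts[ind]):
            calls.extend([a + 1] * c)
        gts.append("/".join(str(c) for c in sorted(calls)))
    return alts, gts


def igd_to_vcf(
    igd_path: str | os.PathLike, vcf_path: str | os.PathLike
) -> ExportReport:
    """Export an IGD to a minimal GT-only VCFv4.2.

    CHROM comes from the file's second description string (the source
    contig), falling back to ``"chr1"``.  Consecutive same-position rows
    are merged back into one multiallelic record; variants whose alt
    allele has no carriers are preserved in the ALT column.
    """
    report = ExportReport()
    with open_igd(igd_path) as igd:
        contig = igd.description or "chr1"
        individual_ids = igd.get_individual_ids() or [
            f"ind{n:04d}" for n in range(igd.num_individuals)
        ]
        variant_ids = igd.get_variant_ids()
        with open(vcf_path, "w", encoding="utf-8") as out:
            out.write("##fileformat=VCFv4.2\n")
            out.write(f"##contig=<ID={contig}>\n")
            out.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            out.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(individual_ids)
                + "\n"
            )
            for group in igd.iterate_sites():
                report.rows_read += len(group.variants)
                alts, gts = _site_genotypes(group, igd)
                ids = []
                for v in group.variants:
                    if variant_ids and not v.is_missing:
                        vid = variant_ids[v.index]
                        if vid and vid not in ids:
                            ids.append(vid)
                out.write(
                    "\t".join(
                        [
                            contig,
                            str(group.position),
                            ";".join(ids) if ids else ".",
                            group.ref,
                            ",".join(alts) if alts else ".",
                            ".",
                            ".",
                            ".",
                            "GT",
                        ]
                        + gts
                    )
                    + "\n"
                )
                report.records_written += 1
    return report
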