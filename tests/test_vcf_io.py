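"""VCF <-> IGD conversion tests.

The normalized-matrix helper reads both VCFs through pysam and compares
hard calls site by site: exact slots for phased data, allele multisets
for unphased data, with a partially missing unphased genotype normalized
to fully missing (the lossy case the per-copy-count storage documents).
"""

import gzip

import pysam
import pytest

from igdkit import (
    ContigError,
    FormatError,
    PhasednessError,
    PloidyError,
    make_matrix,
    make_vcf,
    igd_to_vcf,
    open_igd,
    vcf_to_igd,
)

from conftest import oracle_rows


def write_vcf(tmp_path, text, name="in.vcf", compress=False):
    path = tmp_path / (name + (".gz" if compress else ""))
    if compress:
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)
    return path


def vcf_text(records, samples=("s1", "s2"), contig="chr1"):
    head = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={contig}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    return head + "".join("\t".join(r) + "\n" for r in records)


def normalized_matrix(vcf_path, phased):
    """{(pos, ref): [per-sample genotype]} with unphased order collapsed."""
    out = {}
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            gts = []
            for s in rec.samples.values():
                alleles = [
                    rec.alleles[a] if a is not None else None
                    for a in s.allele_indices
                ]
                if phased:
                    gts.append(tuple(alleles))
                else:
                    if any(a is None for a in alleles):
                        alleles = [None] * len(alleles)
                    gts.append(tuple(sorted(a or "" for a in alleles)))
            out[(rec.pos, rec.ref)] = gts
    return out


class TestVcfToIgd:
    def test_biallelic_phased_expansion(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".", "GT",
                                 "0|1", "1|1")])
        )
        igd = tmp_path / "out.igd"
        report = vcf_to_igd(vcf, igd)
        assert (report.sites_read, report.variants_written) == (1, 1)
        with open_igd(igd) as f:
            assert f.num_samples == 4
            v = f.get_variant(0)
            assert v.samples == [1, 2, 3]
            assert (v.position, v.ref, v.alt) == (5, "A", "C")

    def test_multiallelic_record_expands_to_two_rows(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", "rs9", "A", "C,G", ".", ".", ".",
                                 "GT", "0|1", "2|0")])
        )
        igd = tmp_path / "out.igd"
        vcf_to_igd(vcf, igd)
        with open_igd(igd) as f:
            alts = [f.get_variant(i).alt for i in range(f.num_variants)]
            assert alts == ["C", "G"]
            assert {f.position(i) for i in range(2)} == {5}
            assert f.get_variant_ids() == ["rs9", "rs9"]

    def test_fully_missing_genotype_lands_in_missing_row(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", "./.", "0/1")])
        )
        igd = tmp_path / "out.igd"
        report = vcf_to_igd(vcf, igd)
        assert report.missing_rows == 1
        with open_igd(igd) as f:
            missing = next(v for v in f.iterate_variants() if v.is_missing)
            assert missing.samples == [0]  # individual index, unphased file

    def test_phased_half_call_marks_one_haploid_slot(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", ".|1", "0|0")])
        )
        igd = tmp_path / "out.igd"
        vcf_to_igd(vcf, igd)
        with open_igd(igd) as f:
            rows = list(f.iterate_variants())
            assert [v.samples for v in rows] == [[1], [0]]
            assert rows[1].is_missing

    def test_sample_ids_come_from_vcf_header(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", "0|1", "0|0")], samples=("alice", "bob"))
        )
        igd = tmp_path / "out.igd"
        vcf_to_igd(vcf, igd)
        with open_igd(igd) as f:
            assert f.get_individual_ids() == ["alice", "bob"]
            assert f.description == "chr1"
            assert "in.vcf" in f.source_description

    def test_gzip_input_accepted(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", "0|1", "1|1")]), compress=True
        )
        igd = tmp_path / "out.igd"
        report = vcf_to_igd(vcf, igd)
        assert report.variants_written == 1

    def test_mixed_phasedness_rejected(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", "0|1", "0/1")])
        )
        with pytest.raises(PhasednessError):
            vcf_to_igd(vcf, tmp_path / "out.igd")

    def test_mixed_ploidy_rejected(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", "0|1", "1")])
        )
        with pytest.raises(PloidyError):
            vcf_to_igd(vcf, tmp_path / "out.igd")

    def test_multi_contig_without_selection_rejected(self, tmp_path):
        records = [
            ("chr1", "5", ".", "A", "C", ".", ".", ".", "GT", "0|1", "0|0"),
            ("chr2", "7", ".", "T", "G", ".", ".", ".", "GT", "0|0", "0|1"),
        ]
        text = vcf_text(records).replace(
            "##contig=<ID=chr1>\n", "##contig=<ID=chr1>\n##contig=<ID=chr2>\n"
        )
        vcf = write_vcf(tmp_path, text)
        with pytest.raises(ContigError):
            vcf_to_igd(vcf, tmp_path / "out.igd")
        report = vcf_to_igd(vcf, tmp_path / "out.igd", contig="chr2")
        assert report.skipped_records == 1
        assert report.sites_read == 1

    def test_record_without_gt_rejected(self, tmp_path):
        text = vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".", "DP",
                          "3", "4")])
        text = text.replace(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n',
        )
        vcf = write_vcf(tmp_path, text)
        with pytest.raises(FormatError):
            vcf_to_igd(vcf, tmp_path / "out.igd")

    def test_symbolic_and_star_alleles_pass_through(self, tmp_path):
        vcf = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "*,<DEL>", ".", ".",
                                 ".", "GT", "0|1", "2|0")])
        )
        igd = tmp_path / "out.igd"
        vcf_to_igd(vcf, igd)
        with open_igd(igd) as f:
            assert [f.get_variant(i).alt for i in range(2)] == ["*", "<DEL>"]

    def test_metadata_sidecar_schema(self, tmp_path):
        vcf = write_vcf(
            tmp_path,
            vcf_text([("chr1", "5", "rs1", "A", "C,G", "30", "PASS",
                       "DP=10", "GT", "0|1", "2|0")]),
        )
        tsv = tmp_path / "meta.tsv"
        vcf_to_igd(vcf, tmp_path / "out.igd", metadata_tsv=tsv)
        lines = [l.split("\t") for l in tsv.read_text().splitlines()]
        assert lines[0] == ["CHROM", "POS", "REF", "ALT", "ID", "QUAL",
                            "FILTER", "INFO"]
        assert len(lines) == 3  # header + one row per expanded variant
        assert lines[1][:5] == ["chr1", "5", "A", "C", "rs1"]
        assert lines[2][3] == "G"
        assert lines[1][7] == "DP=10"


class TestRoundTrip:
    def test_matrix_preserved_through_vcf_igd_vcf(self, family_fixture, tmp_path):
        fx = family_fixture
        vcf1 = write_vcf(tmp_path, make_vcf(fx), "a.vcf")
        igd = tmp_path / "a.igd"
        vcf_to_igd(vcf1, igd, phased=fx.phased)
        vcf2 = tmp_path / "b.vcf"
        igd_to_vcf(igd, vcf2)
        m1 = normalized_matrix(vcf1, fx.phased)
        m2 = normalized_matrix(vcf2, fx.phased)
        assert m1 == m2

    def test_expanded_row_count_matches_oracle(self, family_fixture, tmp_path):
        fx = family_fixture
        vcf1 = write_vcf(tmp_path, make_vcf(fx), "a.vcf")
        igd = tmp_path / "a.igd"
        report = vcf_to_igd(vcf1, igd, phased=fx.phased)
        expected = oracle_rows(fx)
        assert report.variants_written == sum(1 for r in expected if not r[3])
        assert report.missing_rows == sum(1 for r in expected if r[3])

    def test_frequencies_agree_between_vcf_and_igd(self, family_fixture, tmp_path):
        fx = family_fixture
        vcf1 = write_vcf(tmp_path, make_vcf(fx), "a.vcf")
        igd = tmp_path / "a.igd"
        vcf_to_igd(vcf1, igd, phased=fx.phased)
        nh = fx.num_individuals * fx.ploidy
        # recount from the VCF text via pysam, independent of the fixture
        vcf_counts = {}
        with pysam.VariantFile(str(vcf1)) as vf:
            for rec in vf:
                for s in rec.samples.values():
                    idx = s.allele_indices
                    dropped = not fx.phased and any(a is None for a in idx)
                    for a in idx:
                        if a and not dropped:
                            key = (rec.pos, rec.alleles[a])
                            vcf_counts[key] = vcf_counts.get(key, 0) + 1
        with open_igd(igd) as f:
            igd_counts = {}
            for v in f.iterate_variants(include_missing=False):
                key = (v.position, v.alt)
                copies = len(v.samples) * (1 if fx.phased else v.num_copies)
                igd_counts[key] = igd_counts.get(key, 0) + copies
        for key, count in vcf_counts.items():
            assert igd_counts.get(key, 0) == count, key
        for key, count in igd_counts.items():
            if count:
                assert vcf_counts.get(key, 0) == count, key

    def test_unphased_export_uses_slash_and_copy_counts(self, tmp_path):
        vcf1 = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", "0/1", "1/1")])
        )
        igd = tmp_path / "a.igd"
        vcf_to_igd(vcf1, igd)
        vcf2 = tmp_path / "b.vcf"
        igd_to_vcf(igd, vcf2)
        line = vcf2.read_text().splitlines()[-1].split("\t")
        assert line[9:] == ["0/1", "1/1"]

    def test_export_without_variant_ids_writes_dot(self, tmp_path):
        vcf1 = write_vcf(
            tmp_path, vcf_text([("chr1", "5", ".", "A", "C", ".", ".", ".",
                                 "GT", "0|1", "1|1")])
        )
        igd = tmp_path / "a.igd"
        vcf_to_igd(vcf1, igd)
        vcf2 = tmp_path / "b.vcf"
        igd_to_vcf(igd, vcf2)
        assert vcf2.read_text().splitlines()[-1].split("\t")[2] == "."
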