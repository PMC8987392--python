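"""File-dialect readers/writers: round trips, coordinate conventions, errors."""

import numpy as np
import pytest

from gvpipe import formats
from gvpipe.formats import (
    HET,
    HOM_ALT,
    DepthRecord,
    FormatError,
    GenotypeRecord,
    VariantKey,
    VcfVariant,
)


def make_records(rng, n=20, sample="S1"):
    recs = []
    used = set()
    while len(recs) < n:
        pos = int(rng.integers(100, 10_000_000))
        chrom = f"chr{int(rng.integers(1, 23))}"
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        dp = int(rng.integers(10, 100))
        vd = int(rng.integers(1, dp + 1))
        call = HOM_ALT if vd / dp >= 0.75 else HET
        key = VariantKey.make(chrom, pos, str(ref), str(alt))
        recs.append(VcfVariant(key, "PASS", GenotypeRecord(sample, key, call, dp, vd)))
    return recs


class TestVariantKey:
    def test_validation_rejects_indels_and_bad_positions(self):
        with pytest.raises(ValueError):
            VariantKey.make("chr1", 100, "GA", "G")
        with pytest.raises(ValueError):
            VariantKey.make("chr1", 100, "G", "G")
        with pytest.raises(ValueError):
            VariantKey.make("chr1", 0, "G", "C")
        with pytest.raises(ValueError):
            VariantKey.make("chr1", 5, "G", "N")

    def test_natural_chromosome_ordering(self):
        keys = [
            VariantKey.make(c, 5, "A", "C")
            for c in ["chrX", "chr10", "chr2", "chr1", "chrY", "chr22"]
        ]
        ordered = [k.chrom for k in formats.sort_variant_keys(keys)]
        assert ordered == ["chr1", "chr2", "chr10", "chr22", "chrX", "chrY"]

    def test_ordering_is_total_within_chromosome(self):
        a = VariantKey.make("chr1", 100, "A", "C")
        b = VariantKey.make("chr1", 100, "A", "G")
        c = VariantKey.make("chr1", 99, "T", "A")
        assert formats.sort_variant_keys([b, a, c]) == [c, a, b]


class TestVcf:
    def test_parse_single_line(self, tmp_path):
        path = tmp_path / "one.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=PASS,Description="ok">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=VD,Number=1,Type=Integer,Description="v">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tG\tC\t.\tPASS\t.\tGT:DP:VD\t0/1:40:20\n"
        )
        (rec,) = formats.read_vcf(str(path))
        assert rec.key == VariantKey("chr1", 100, "G", "C")
        assert rec.filter == "PASS"
        assert rec.genotype == GenotypeRecord("S1", rec.key, HET, 40, 20)

    def test_variant_depth_falls_back_to_ad(self, tmp_path):
        path = tmp_path / "ad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "##contig=<ID=chr2>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS9\n"
            "chr2\t55\t.\tA\tT\t.\tPASS\t.\tGT:DP:AD\t1/1:30:1,29\n"
        )
        (rec,) = formats.read_vcf(str(path))
        assert rec.genotype.call == HOM_ALT
        assert rec.genotype.variant_depth == 29

    def test_header_only_file_is_empty(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        assert formats.read_vcf(str(path)) == []

    def test_malformed_header_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("chrom pos stuff\nnot a vcf\n")
        with pytest.raises(FormatError):
            formats.read_vcf(str(path))

    def test_round_trip(self, tmp_path, rng):
        records = make_records(rng)
        path = tmp_path / "rt.vcf"
        formats.write_vcf(records, str(path))
        again = formats.read_vcf(str(path))
        assert again == records
        # second round trip is byte-stable
        path2 = tmp_path / "rt2.vcf"
        formats.write_vcf(again, str(path2))
        assert path.read_bytes() == path2.read_bytes()


class TestFilterPass:
    def test_label_match(self, rng):
        recs = make_records(rng, n=3)
        recs[1] = recs[1]._replace(filter="q25")
        assert formats.filter_pass(recs) == [recs[0], recs[2]]
        assert formats.filter_pass([]) == []
        assert formats.filter_pass(recs[:1]) == recs[:1]


class TestDepthTsv:
    def test_round_trip_and_parse(self, tmp_path, rng):
        records = [
            DepthRecord(f"chr{int(rng.integers(1, 23))}", int(rng.integers(1, 1e6)), int(d))
            for d in rng.integers(0, 200, size=50)
        ]
        path = tmp_path / "d.tsv"
        formats.write_depth_tsv(records, str(path))
        assert formats.read_depth_tsv(str(path)) == records

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("")
        assert formats.read_depth_tsv(str(path)) == []

    def test_non_integer_depth_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr1\t100\thigh\n")
        with pytest.raises(FormatError):
            formats.read_depth_tsv(str(path))


class TestBed:
    def test_coordinate_shift_and_position_dedup(self, tmp_path):
        keys = [
            VariantKey.make("chr1", 100, "G", "C"),
            VariantKey.make("chr1", 100, "G", "T"),
            VariantKey.make("chr2", 7, "A", "G"),
        ]
        path = tmp_path / "u.bed"
        formats.write_bed(keys, str(path))
        assert path.read_text() == "chr1\t99\t100\nchr2\t6\t7\n"

    def test_round_trip_has_no_off_by_one(self, tmp_path, rng):
        positions = sorted(set(int(p) for p in rng.integers(1, 10**8, size=1000)))
        keys = [VariantKey.make("chr3", p, "A", "C") for p in positions]
        path = tmp_path / "r.bed"
        formats.write_bed(keys, str(path))
        back = formats.read_bed_positions(str(path))
        assert back == [("chr3", p) for p in positions]


class TestAnnovar:
    def test_snv_convention_and_round_trip(self, tmp_path, rng):
        from gvpipe.status_matrix import matrix_from_statuses

        keys = [k.key for k in make_records(rng, n=10)]
        keys = formats.sort_variant_keys(keys)
        matrix = matrix_from_statuses({"S1": {k: HET for k in keys}}, keys)
        path = tmp_path / "av.txt"
        formats.write_annovar_input(matrix, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == len(keys) + 1
        first = lines[1].split("\t")
        assert first[1] == first[2] == str(keys[0].pos)
        assert formats.read_annovar_keys(str(path)) == keys


class TestPatientMap:
    def write_list(self, path, col, rows):
        path.write_text("Case_ID\t" + col + "\n" + "".join(f"{a}\t{b}\n" for a, b in rows))

    def test_outer_join(self, tmp_path):
        self.write_list(tmp_path / "n.tsv", "normal", [("P1", "P1-N"), ("P2", "P2-N")])
        self.write_list(tmp_path / "t.tsv", "tumor", [("P1", "P1-T"), ("P3", "P3-T")])
        self.write_list(tmp_path / "r.tsv", "rnaseq", [("P1", "P1-R")])
        pmap = formats.read_patient_map(
            str(tmp_path / "n.tsv"), str(tmp_path / "t.tsv"), str(tmp_path / "r.tsv")
        )
        assert list(pmap.columns) == ["normal", "tumor", "rnaseq"]
        assert pmap.loc["P1"].tolist() == ["P1-N", "P1-T", "P1-R"]
        assert pmap.loc["P2", "normal"] == "P2-N" and pmap.loc["P2"].isna().sum() == 2
        assert pmap.loc["P3", "tumor"] == "P3-T"

    def test_duplicate_case_id_raises(self, tmp_path):
        self.write_list(tmp_path / "n.tsv", "normal", [("P1", "a"), ("P1", "b")])
        with pytest.raises(FormatError, match="duplicate"):
            formats.read_patient_map(normal_path=str(tmp_path / "n.tsv"))

    def test_wrong_header_names_error(self, tmp_path):
        self.write_list(tmp_path / "n.tsv", "Sample_Barcode", [("P1", "a")])
        with pytest.raises(FormatError, match="normal"):
            formats.read_patient_map(normal_path=str(tmp_path / "n.tsv"))


class TestStatusTable:
    def test_round_trip(self, tmp_path, rng):
        from gvpipe.status_matrix import matrix_from_statuses

        keys = formats.sort_variant_keys([r.key for r in make_records(rng, n=15)])
        statuses = {
            s: {k: str(rng.choice(formats.STATUSES)) for k in keys} for s in ["A", "B"]
        }
        matrix = matrix_from_statuses(statuses, keys)
        path = tmp_path / "s.tsv"
        formats.write_status_table(matrix, str(path))
        again = formats.read_status_table(str(path))
        assert again.equals(matrix)

    def test_invalid_status_value_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("CHROM\tPOS\tREF\tALT\tS1\nchr1\t5\tA\tC\tmaybe\n")
        with pytest.raises(FormatError, match="maybe"):
            formats.read_status_table(str(path))
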