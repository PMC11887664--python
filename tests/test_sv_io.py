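"""I/O: VCF coordinate conventions, round trips, gene models, tables."""

import pytest

from bdcnv import sv_io
from bdcnv.types import Biotype, Caller, Cohort, SvType

from conftest import make_call

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##ALT=<ID=DEL,Description="Deletion">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadCallerVcf:
    def test_coordinates_are_converted_to_zero_based_half_open(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t100001\t.\tN\t<DEL>\t312\t.\tEND=150000;SVTYPE=DEL\n")
        res = sv_io.read_caller_vcf(p, Caller.MANTA, sample_id="S1")
        (call,) = res.calls
        assert (call.start, call.end) == (100_000, 150_000)
        assert call.svtype == SvType.DEL
        assert call.quality == 312
        assert call.sample_id == "S1"

    def test_non_cnv_svtypes_are_skipped_and_counted(self, tmp_path):
        body = (
            "chr1\t1001\t.\tN\t<INV>\t50\t.\tEND=5000;SVTYPE=INV\n"
            "chr1\t100001\t.\tN\t<DEL>\t90\t.\tEND=150000;SVTYPE=DEL\n"
        )
        res = sv_io.read_caller_vcf(write_vcf(tmp_path, body), Caller.DELLY)
        assert len(res.calls) == 1
        assert res.n_skipped_svtype == 1

    def test_symbolic_record_without_end_is_rejected_and_counted(self, tmp_path):
        body = "chr1\t100001\t.\tN\t<DEL>\t90\t.\tSVTYPE=DEL\n"
        res = sv_io.read_caller_vcf(write_vcf(tmp_path, body), Caller.MANTA)
        assert res.calls == []
        assert res.n_missing_end == 1

    def test_malformed_vcf_names_a_line(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(sv_io.VcfParseError):
            sv_io.read_caller_vcf(p, Caller.MANTA)


class TestWriteCallerVcf:
    def test_round_trip_is_identity(self, tmp_path):
        calls = [
            make_call(start=0, end=10_000, quality=100.0),
            make_call(chrom="chr2", start=5_000, end=40_000, svtype=SvType.DUP, quality=55.5),
            make_call(start=200_000, end=260_000, quality=12.0),
        ]
        p = tmp_path / "rt.vcf"
        sv_io.write_caller_vcf(calls, p, contig_lengths={"chr1": 10**7, "chr2": 10**7})
        back = sv_io.read_caller_vcf(p, Caller.MANTA).calls
        key = lambda c: (c.chrom, c.start, c.end, c.svtype.value, c.quality)
        assert sorted(map(key, back)) == sorted(map(key, calls))
        assert {c.sample_id for c in back} == {"S1"}

    def test_rows_are_sorted_and_pos_is_one_based(self, tmp_path):
        calls = [
            make_call(chrom="chr2", start=0, end=10_000),
            make_call(chrom="chr1", start=50_000, end=70_000),
            make_call(chrom="chr1", start=10_000, end=30_000),
        ]
        p = tmp_path / "s.vcf"
        sv_io.write_caller_vcf(calls, p)
        rows = [l.split("\t") for l in p.read_text().splitlines() if not l.startswith("#")]
        assert [(r[0], int(r[1])) for r in rows] == [
            ("chr1", 10_001), ("chr1", 50_001), ("chr2", 1)
        ]

    def test_generator_output_round_trips(self, small_sim, tmp_path):
        sid = small_sim.samples[0].sample_id
        calls = [c for c in small_sim.calls_by_sample[sid] if c.caller_id == Caller.LUMPY]
        p = tmp_path / "gen.vcf"
        sv_io.write_caller_vcf(calls, p)
        back = sv_io.read_caller_vcf(p, Caller.LUMPY, sample_id=sid).calls
        key = lambda c: (c.chrom, c.start, c.end, c.svtype.value, round(c.quality, 6))
        assert sorted(map(key, back)) == sorted(map(key, calls))

    def test_empty_call_set_gives_header_only_file(self, tmp_path):
        p = tmp_path / "empty.vcf"
        sv_io.write_caller_vcf([], p)
        assert all(l.startswith("#") for l in p.read_text().splitlines())

    def test_mixed_samples_rejected(self, tmp_path):
        calls = [make_call(sample="A"), make_call(sample="B", start=1, end=20_000)]
        with pytest.raises(ValueError):
            sv_io.write_caller_vcf(calls, tmp_path / "x.vcf")


class TestGeneModels:
    def test_bed_is_taken_as_half_open(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t999\t2000\tGENE1\t.\t+\tprotein_coding\n")
        (g,) = sv_io.read_gene_models(p)
        assert (g.start, g.end, g.biotype) == (999, 2000, Biotype.protein_coding)

    def test_gff3_converted_from_one_based_inclusive(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=GENE1;gene_id=GENE1;gene_type=protein_coding\n"
        )
        (g,) = sv_io.read_gene_models(p)
        assert (g.start, g.end) == (999, 2000)

    def test_bed_and_gff3_agree_on_shared_genes(self, tmp_path):
        genes = [("G1", 999, 2000, "protein_coding"), ("G2", 5000, 9000, "lncRNA"),
                 ("G3", 12_000, 30_000, "miRNA")]
        bed = tmp_path / "g.bed"
        bed.write_text("".join(
            f"chr1\t{s}\t{e}\t{n}\t.\t+\t{b}\n" for n, s, e, b in genes
        ))
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n" + "".join(
            f"chr1\tsrc\tgene\t{s + 1}\t{e}\t.\t+\t.\tID={n};gene_id={n};gene_type={b}\n"
            for n, s, e, b in genes
        ))
        from_bed = sv_io.read_gene_models(bed)
        from_gff = sv_io.read_gene_models(gff)
        key = lambda g: (g.gene_id, g.chrom, g.start, g.end, g.biotype)
        assert sorted(map(key, from_bed)) == sorted(map(key, from_gff))

    def test_biotype_partition_and_unknown_fallback(self, tmp_path):
        rows = [("A", "protein_coding"), ("B", "lncRNA"), ("C", "snoRNA"),
                ("D", "weird_biotype"), ("E", "protein_coding")]
        p = tmp_path / "g.bed"
        p.write_text("".join(
            f"chr1\t{i * 1000}\t{i * 1000 + 500}\t{n}\t.\t+\t{b}\n"
            for i, (n, b) in enumerate(rows)
        ))
        models = sv_io.read_gene_models(p)
        by_type = {b: sum(1 for g in models if g.biotype == b) for b in Biotype}
        assert by_type == {Biotype.protein_coding: 2, Biotype.lncRNA: 1,
                           Biotype.other_ncRNA: 2}

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t100\tG\t.\t+\tprotein_coding\n"
                     "chr1\t500\t900\tG\t.\t+\tprotein_coding\n")
        with pytest.raises(ValueError, match="duplicate"):
            sv_io.read_gene_models(p)


class TestCohortTable:
    def test_diagnoses_are_split_on_semicolons(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("S1\tBD_CANCER\t191.9;742.4\n")
        (rec,) = sv_io.read_cohort_table(p)
        assert rec.cohort == Cohort.BD_CANCER
        assert rec.diagnoses == {"191.9", "742.4"}

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("S1\tBD_ONLY\t\nS1\tCONTROL\t\n")
        with pytest.raises(ValueError, match="duplicate"):
            sv_io.read_cohort_table(p)

    def test_unknown_cohort_label_lists_allowed(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("S1\tPATIENT\t\n")
        with pytest.raises(ValueError, match="BD_CANCER"):
            sv_io.read_cohort_table(p)

    def test_round_trip(self, small_sim, tmp_path):
        p = tmp_path / "c.tsv"
        sv_io.write_cohort_table(small_sim.samples, p)
        back = sv_io.read_cohort_table(p)
        assert back == small_sim.samples


class TestGeneSetsAndTargets:
    def test_gmt_line_parses_to_member_set(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("TERM1\tdesc\tG1\tG2\tG3\n")
        coll = sv_io.read_gene_sets(p)
        assert coll.sets["TERM1"] == {"G1", "G2", "G3"}
        assert coll.descriptions["TERM1"] == "desc"

    def test_short_gmt_line_rejected(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("TERM1\tonlydesc\n")
        with pytest.raises(ValueError):
            sv_io.read_gene_sets(p)

    def test_gmt_round_trip(self, small_sim, tmp_path):
        coll = small_sim.collections[0]
        p = tmp_path / "rt.gmt"
        sv_io.write_gene_sets(coll, p)
        back = sv_io.read_gene_sets(p, name=coll.name)
        assert back.sets == coll.sets

    def test_target_db_requires_schema(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("foo\tbar\nx\ty\n")
        with pytest.raises(ValueError):
            sv_io.read_target_db(p)

    def test_target_type_prefix_heuristic(self):
        assert sv_io.infer_target_type("miR-155-5p") == "miRNA"
        assert sv_io.infer_target_type("LINC00115") == "lncRNA"
        assert sv_io.infer_target_type("TP53") == "protein_coding"
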