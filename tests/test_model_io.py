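import textwrap

import numpy as np
import pytest

from declone.io import (compute_vaf, filter_by_depth, read_paired_vcf,
                        read_variant_table, write_variant_table)
from declone.model import (SampleInfo, VariantRecord, VariantTable,
                           parse_composition)


def test_parse_composition():
    assert parse_composition("1+1") == (1, 1)
    assert parse_composition("3+1") == (3, 1)
    assert parse_composition("2+0") == (2, 0)
    # order is preserved: 1+3 and 3+1 are different states
    assert parse_composition("1+3") != parse_composition("3+1")
    for bad in ("x+1", "1", "0+0", "-1+2", ""):
        with pytest.raises(ValueError):
            parse_composition(bad)


def test_compute_vaf():
    assert compute_vaf(75, 25) == 0.25
    assert compute_vaf(0, 10) == 1.0
    with pytest.raises(ValueError):
        compute_vaf(0, 0)


def test_variant_record_validation():
    with pytest.raises(ValueError):
        VariantRecord("S1", "chr1:1:A:T", vaf=1.5)
    with pytest.raises(ValueError):
        VariantRecord("S1", "chr1:1:A:T", ref_depth=-1)
    r = VariantRecord("S1", "chr1:1:A:T", vaf=0.5, cn_mutant=1, cn_wildtype=3)
    assert r.composition == "1+3"


def test_table_rejects_duplicates():
    s = [SampleInfo("S1")]
    recs = [VariantRecord("S1", "chr1:1:A:T", vaf=0.5),
            VariantRecord("S1", "chr1:1:A:T", vaf=0.6)]
    with pytest.raises(ValueError):
        VariantTable(records=recs, samples=s)
    with pytest.raises(ValueError):
        VariantTable(records=[VariantRecord("S2", "chr1:1:A:T", vaf=0.5)],
                     samples=s)


def test_table_round_trip(tmp_path, fixture_table):
    table, _ = fixture_table
    path = tmp_path / "t.tsv"
    write_variant_table(table, path)
    back = read_variant_table(path)
    assert len(back.records) == len(table.records)
    assert {s.sample_id for s in back.samples} == {s.sample_id for s in table.samples}
    orig = {(r.sample_id, r.variant_id): r.vaf for r in table.records}
    for r in back.records:
        assert r.vaf == pytest.approx(orig[(r.sample_id, r.variant_id)], abs=1e-12)


def test_depth_wins_over_vaf_column(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample_id\tvariant_id\tref_depth\talt_depth\tvaf\n"
                    "S1\tchr1:1:A:T\t75\t25\t0.9\n")
    with pytest.warns(UserWarning, match="inconsistent"):
        table = read_variant_table(path)
    assert table.records[0].vaf == 0.25


def test_vaf_only_rows_kept_as_is(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample_id\tvariant_id\tvaf\nS1\tchr1:1:A:T\t0.37\n")
    table = read_variant_table(path)
    assert table.records[0].vaf == 0.37
    assert table.records[0].ref_depth is None


def test_filter_by_depth_removes_variant_everywhere():
    samples = [SampleInfo("S1"), SampleInfo("S2")]
    recs = [VariantRecord("S1", "v1", ref_depth=50, alt_depth=50, vaf=0.5),
            VariantRecord("S2", "v1", ref_depth=3, alt_depth=2, vaf=0.4),
            VariantRecord("S1", "v2", ref_depth=60, alt_depth=40, vaf=0.4),
            VariantRecord("S2", "v2", ref_depth=55, alt_depth=45, vaf=0.45)]
    table = VariantTable(records=recs, samples=samples)
    out = filter_by_depth(table, min_depth=10)
    # v1 is under-covered in S2, so it is dropped from both samples
    assert {r.variant_id for r in out.records} == {"v2"}
    assert len(out.records) == 2


VCF_TEXT = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##FILTER=<ID=PASS,Description="pass">
    ##FILTER=<ID=REJECT,Description="reject">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allelic depths">
    ##contig=<ID=chr1,length=100000>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
    chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD\t0/1:30,30\t0/1:25,25
    chr1\t200\t.\tC\tG\t.\tREJECT\t.\tGT:AD\t0/1:40,20\t0/0:50,0
    chr1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT:AD\t1/2:10,20,30\t0/1:20,20,0
    """)


def test_read_paired_vcf(tmp_path):
    path = tmp_path / "pair.vcf"
    path.write_text(VCF_TEXT)
    sites = read_paired_vcf(path, tumor_sample="TUMOR")
    # multiallelic site splits into one record per ALT; REJECT is retained
    assert len(sites) == 4
    s0 = sites[0]
    assert (s0.chrom, s0.pos) == ("chr1", 100)
    assert s0.baf_tumor == pytest.approx(0.5)
    assert s0.is_het_germline
    rej = [s for s in sites if s.filter_status == "REJECT"]
    assert len(rej) == 1 and not rej[0].is_het_germline
    multi = [s for s in sites if s.pos == 300]
    assert len(multi) == 2
    assert multi[0].tumor_alt == 20 and multi[1].tumor_alt == 30
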