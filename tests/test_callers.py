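"""Dialect parsing, somatic verdicts, and canonicalization."""

import pytest

from varconsensus.callers import (CallerId, CallerRecord, DialectError,
                                  VariantClass, canonicalize, is_somatic_pass,
                                  parse_caller_vcf)

MNV_CAPABLE = {CallerId.MUTECT2, CallerId.VARDICT}


def make_record(caller=CallerId.MUTECT2, **kw):
    base = dict(
        sample_id="S1", chrom="chr1", pos=100, ref="A", alts=["T"],
        filter_field="PASS", info_field={}, caller=caller,
        t_alt=10, t_ref=30, n_alt=0, n_ref=40,
    )
    base.update(kw)
    return CallerRecord(**base)


class TestSomaticPass:
    @pytest.mark.parametrize("caller,kw,expected", [
        (CallerId.MUTECT2, {"filter_field": "PASS"}, True),
        (CallerId.MUTECT2, {"filter_field": "germline"}, False),
        (CallerId.MUSE, {"filter_field": "PASS"}, True),
        (CallerId.SOMATICSNIPER, {"filter_field": "LowQual"}, False),
        (CallerId.STRELKA2, {"filter_field": "LowEVS"}, False),
        (CallerId.STRELKA2, {"filter_field": "PASS"}, True),
        (CallerId.VARSCAN2, {"somatic_status_field": "Somatic"}, True),
        (CallerId.VARSCAN2, {"somatic_status_field": "Germline"}, False),
        (CallerId.VARDICT, {"somatic_status_field": "StrongSomatic"}, True),
        (CallerId.VARDICT, {"somatic_status_field": "LikelySomatic"}, False),
    ])
    def test_caller_specific_verdicts(self, caller, kw, expected):
        assert is_somatic_pass(make_record(caller=caller, **kw)) is expected

    @pytest.mark.parametrize("caller", [CallerId.VARSCAN2, CallerId.VARDICT])
    def test_missing_status_field_raises(self, caller):
        rec = make_record(caller=caller, somatic_status_field=None)
        with pytest.raises(DialectError, match="STATUS|SS"):
            is_somatic_pass(rec)

    def test_verdict_ignores_unrelated_info_keys(self):
        rec = make_record(caller=CallerId.VARDICT,
                          somatic_status_field="StrongSomatic",
                          info_field={"A": 1, "B": 2})
        perm = make_record(caller=CallerId.VARDICT,
                           somatic_status_field="StrongSomatic",
                           info_field={"B": 2, "A": 1, "ZZZ": "x"})
        assert is_somatic_pass(rec) == is_somatic_pass(perm) is True


class TestCanonicalize:
    def test_dinucleotide_substitution_is_mnv(self):
        v, = canonicalize(make_record(ref="AT", alts=["GC"]))
        assert v.variant_class is VariantClass.MNV
        assert (v.ref, v.alt) == ("AT", "GC")

    def test_shared_prefix_trimmed_to_snv(self):
        v, = canonicalize(make_record(pos=100, ref="CA", alts=["CT"]))
        assert (v.pos, v.ref, v.alt) == (101, "A", "T")
        assert v.variant_class is VariantClass.SNV

    def test_maf_arithmetic(self):
        v, = canonicalize(make_record(t_alt=5, t_ref=15))
        assert v.maf == pytest.approx(0.25)

    def test_zero_denominator_yields_undefined_maf(self):
        v, = canonicalize(make_record(t_alt=0, t_ref=0))
        assert v.maf is None

    def test_multi_alt_split_marks_source(self):
        vs = canonicalize(make_record(alts=["T", "G"]))
        assert len(vs) == 2
        assert all(v.multiallelic_source for v in vs)
        assert {v.alt for v in vs} == {"T", "G"}

    def test_indel_classes(self):
        ins, = canonicalize(make_record(ref="A", alts=["ATG"]))
        dele, = canonicalize(make_record(ref="ATG", alts=["A"]))
        assert ins.variant_class is VariantClass.INSERTION
        assert dele.variant_class is VariantClass.DELETION

    @pytest.mark.parametrize("pos,ref,alt", [
        (10, "A", "T"), (10, "AT", "GC"), (10, "A", "ATT"), (10, "ATT", "A"),
    ])
    def test_idempotent_on_minimal_alleles(self, pos, ref, alt):
        v, = canonicalize(make_record(pos=pos, ref=ref, alts=[alt]))
        again, = canonicalize(make_record(pos=v.pos, ref=v.ref, alts=[v.alt]))
        assert (again.pos, again.ref, again.alt) == (v.pos, v.ref, v.alt)

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            make_record(pos=0)
        with pytest.raises(ValueError):
            make_record(t_alt=-1)


def expected_emissions(truth_df, sample, caller):
    """Truth-side oracle: the (chrom, pos, ref, alt) set a caller's
    somatic-PASS VCF lines should parse back to."""
    expected = set()
    sub = truth_df[(truth_df["sample"] == sample)
                   & (truth_df["somatic_pass"] == 1)]
    for row in sub.to_dict("records"):
        callers = row["callers"].split(",")
        if caller.value not in callers:
            continue
        if row["class"] == "MNV" and caller not in MNV_CAPABLE:
            for i in range(2):
                expected.add((row["chrom"], row["pos"] + i,
                              row["ref"][i], row["alt"][i]))
        else:
            expected.add((row["chrom"], row["pos"], row["ref"], row["alt"]))
            if row["extra_alt"]:
                expected.add((row["chrom"], row["pos"], row["ref"],
                              row["extra_alt"]))
    return expected


@pytest.mark.parametrize("caller", list(CallerId), ids=lambda c: c.value)
def test_round_trip_against_simulator(cohort, caller):
    """Dialect VCFs parse back to exactly the variant set emitted."""
    manifest = cohort["manifest"]
    truth = manifest["truth_frame"]
    sample = manifest["samples"][0]
    path = manifest["vcf_dir"] / f"{sample}.{caller.value}.vcf"
    records = parse_caller_vcf(path, caller)
    passed = [r for r in records if is_somatic_pass(r)]
    got = {(v.chrom, v.pos, v.ref, v.alt)
           for r in passed for v in canonicalize(r)}
    assert got == expected_emissions(truth, sample, caller)
    assert all(r.sample_id == sample for r in records)


def test_counts_round_trip(cohort):
    """Allele counts read back equal the counts the simulator wrote."""
    manifest = cohort["manifest"]
    truth = manifest["truth_frame"]
    sample = manifest["samples"][1]
    path = manifest["vcf_dir"] / f"{sample}.Mutect2.vcf"
    by_key = {(r.chrom, r.pos): r
              for r in parse_caller_vcf(path, CallerId.MUTECT2)}
    sub = truth[(truth["sample"] == sample)
                & truth.callers.str.split(",").apply(
                    lambda cs: "Mutect2" in cs)]
    checked = 0
    for row in sub.itertuples(index=False):
        rec = by_key[(row.chrom, row.pos)]
        assert rec.t_alt == row.t_alt
        assert rec.n_alt == row.n_alt
        checked += 1
    assert checked > 10


def test_varscan_somatic_status_round_trip(cohort):
    """VarScan2 lines carry the somatic-status field from INFO."""
    manifest = cohort["manifest"]
    sample = manifest["samples"][0]
    path = manifest["vcf_dir"] / f"{sample}.VarScan2.vcf"
    records = parse_caller_vcf(path, CallerId.VARSCAN2)
    assert records
    assert all(r.somatic_status_field in ("Somatic", "Germline")
               for r in records)


def test_empty_vcf_body(tmp_path):
    path = tmp_path / "empty.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS_T\tS_N\n"
    )
    assert parse_caller_vcf(path, CallerId.MUSE) == []


def test_missing_genotype_tag_names_line(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS_T\tS_N\n"
        "chr1\t5\t.\tA\tT\t.\tPASS\t.\tDP\t10\t10\n"
    )
    with pytest.raises(DialectError, match="line 1"):
        parse_caller_vcf(path, CallerId.MUSE)


def test_chromosome_naming_normalized(tmp_path):
    path = tmp_path / "nochr.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1,length=1000>\n"
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS_T\tS_N\n"
        "1\t5\t.\tA\tT\t.\tPASS\t.\tAD\t30,10\t40,0\n"
    )
    rec, = parse_caller_vcf(path, CallerId.MUSE)
    assert rec.chrom == "chr1"
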