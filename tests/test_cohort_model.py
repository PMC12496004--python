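"""Domain types, the packaged cohort table, and variant-table IO."""

import pytest

from conftest import make_patient, make_sample, make_variant
from lynchevo.io import (
    UnresolvableReferenceError,
    read_variant_table,
    resolve_reference_sample,
    write_variant_table,
)
from lynchevo.models import Histology, SampleRecord, SomaticVariant


class TestFixture:
    def test_row_counts_match_cohort_structure(self, cohort):
        assert len(cohort) == 64
        counts = cohort["group"].value_counts().to_dict()
        assert counts == {"EC": 27, "OC": 15, "AH": 22}

    def test_carcinoma_row_with_somatic_second_hit(self, cohort):
        row = cohort.set_index("sample_id").loc["LEC2_EEC"]
        assert row["gene"] == "MSH2"
        assert row["timepoint"] == 0
        assert row["mmr_status"] == "dMMR"
        assert row["loh"] == "No"
        (hit,) = row["second_hits"]
        assert (hit.effect, hit.vaf_pct, hit.sub_threshold) == ("splice", 24, False)
        assert row["tmb"] == 16.6 and row["hypermutated"]

    def test_carcinoma_row_without_second_hit(self, cohort):
        row = cohort.set_index("sample_id").loc["LEC24_EEC"]
        assert row["mmr_status"] == "dMMR"
        assert row["loh"] == "No"
        assert row["second_hits"] == ()
        assert row["tmb"] == 1.9 and not row["hypermutated"]

    def test_bracketed_vafs_are_flagged_sub_threshold(self, cohort):
        hits = dict(zip(cohort["sample_id"], cohort["second_hits"]))
        assert hits["LEC1_CAH"][0].sub_threshold and hits["LEC1_CAH"][0].vaf_pct == 2
        assert not hits["LEC1_EEC"][0].sub_threshold
        sub = [
            h for row in cohort["second_hits"] for h in row if h.sub_threshold
        ]
        assert all(h.vaf_pct < 5 for h in sub)
        assert all(
            h.vaf_pct >= 5
            for row in cohort["second_hits"] for h in row
            if not h.sub_threshold
        )

    def test_timepoints_never_positive(self, cohort):
        assert (cohort["timepoint"] <= 0).all()


class TestSampleRecord:
    def test_histology_tissue_consistency_enforced(self):
        with pytest.raises(ValueError, match="implies tissue"):
            SampleRecord(
                sample_id="X", patient_id="P", predisposing_gene="MLH1",
                histology=Histology.EEC, timepoint_years=0,
                tissue_class="blood",
            )

    def test_positive_timepoint_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            make_sample("X_EEC", "EEC", timepoint=1)

    @pytest.mark.parametrize(
        "histology,group",
        [("EEC", "EC"), ("CCEC", "EC"), ("CxEC", "EC"),
         ("EOC", "OC"), ("CCOC", "OC"), ("CAH", None)],
    )
    def test_carcinoma_group_assignment(self, histology, group):
        assert make_sample("S_" + histology, histology).carcinoma_group == group


class TestSomaticVariant:
    def test_vaf_read_count_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SomaticVariant(
                chrom="chr1", pos=1, ref="A", alt="T", vaf=0.5,
                alt_reads=10, ref_reads=90,
            )
        v = SomaticVariant(
            chrom="chr1", pos=1, ref="A", alt="T", vaf=0.1,
            alt_reads=10, ref_reads=90,
        )
        assert v.depth == 100


class TestVariantTableIO:
    def test_tsv_row_maps_directly(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\teffect\tvaf\talt_reads\tref_reads"
            "\tsomatic_p\tfilter\n"
            "chr3\t37038108\tC\tT\tMLH1\tnonsense\t0.24\t24\t76\t0.001\tPASS\n"
        )
        (v,) = read_variant_table(path)
        assert (v.chrom, v.pos, v.ref, v.alt) == ("chr3", 37038108, "C", "T")
        assert v.gene == "MLH1" and v.effect_class.value == "nonsense"
        assert v.vaf == 0.24 and v.somatic_p == 0.001

    def test_empty_table_with_header(self, tmp_path):
        path = tmp_path / "e.tsv"
        write_variant_table([], path)
        assert read_variant_table(path) == []

    def test_malformed_row_reports_index(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\teffect\tvaf\talt_reads\tref_reads"
            "\tsomatic_p\tfilter\nchr1\tnotanint\n"
        )
        with pytest.raises(Exception, match="row 2"):
            read_variant_table(path)

    def test_tsv_round_trip_is_bit_exact(self, tmp_path):
        variants = [
            make_variant(pos=11, vaf=1 / 3, somatic_p=0.0012345,
                         alt_reads=33, ref_reads=66),
            make_variant(pos=12, ref="AT", alt="A", effect="frameshift",
                         vaf=0.05),
            SomaticVariant(chrom="chr2", pos=13, ref="G", alt="C",
                           gene="", effect_class="other", vaf=0.9),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_variant_table(variants, p1)
        round_tripped = read_variant_table(p1)
        assert round_tripped == variants
        write_variant_table(round_tripped, p2)
        assert p1.read_text() == p2.read_text()

    def test_multiallelic_vcf_record_splits(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SOMATIC_P,Number=1,Type=Float,Description="p">\n'
            '##INFO=<ID=ANN,Number=1,Type=String,Description="gene|effect">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="depths">\n'
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="freqs">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            "chr1\t1000\t.\tG\tA,T\t.\tPASS\t"
            "SOMATIC_P=0.002;ANN=PTEN|missense_variant\tAD:AF\t"
            "60,25,15:0.25,0.15\n"
        )
        v1, v2 = read_variant_table(path)
        # hand-parsed expectation: one record per alternate allele
        assert (v1.chrom, v1.pos, v1.ref) == (v2.chrom, v2.pos, v2.ref)
        assert (v1.alt, v2.alt) == ("A", "T")
        assert (v1.alt_reads, v2.alt_reads) == (25, 15)
        assert (v1.ref_reads, v2.ref_reads) == (75, 85)
        assert (v1.vaf, v2.vaf) == pytest.approx((0.25, 0.15), abs=1e-6)
        assert v1.gene == "PTEN" and v1.effect_class.value == "missense"
        assert v1.somatic_p == pytest.approx(0.002)


class TestReferenceResolution:
    def test_blood_preferred_over_normals(self):
        patient = make_patient([
            make_sample("P1_B", "B"),
            make_sample("P1_NE", "NE", timepoint=0),
            make_sample("P1_EEC", "EEC"),
        ])
        assert resolve_reference_sample(patient).sample_id == "P1_B"

    def test_closest_normal_when_no_blood(self):
        patient = make_patient([
            make_sample("P1_NE", "NE", timepoint=-3),
            make_sample("P1_FT", "FT", timepoint=-1),
            make_sample("P1_EEC", "EEC", timepoint=0),
        ])
        assert resolve_reference_sample(patient).sample_id == "P1_FT"

    def test_equidistant_tie_prefers_endometrium(self):
        patient = make_patient([
            make_sample("P1_FT", "FT", timepoint=-1),
            make_sample("P1_NE", "NE", timepoint=-1),
            make_sample("P1_EEC", "EEC", timepoint=0),
        ])
        assert resolve_reference_sample(patient).sample_id == "P1_NE"

    def test_no_reference_available_errors(self):
        patient = make_patient([make_sample("P1_EEC", "EEC")])
        with pytest.raises(UnresolvableReferenceError):
            resolve_reference_sample(patient)
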