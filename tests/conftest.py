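import pytest

from lynchevo.fixture import load_cohort_fixture
from lynchevo.models import (
    Histology,
    MMRGene,
    PatientRecord,
    SampleRecord,
    SomaticVariant,
)


@pytest.fixture(scope="session")
def cohort():
    return load_cohort_fixture()


def make_variant(
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    gene="PTEN",
    effect="missense",
    vaf=0.30,
    somatic_p=0.001,
    caller_filter="PASS",
    alt_reads=None,
    ref_reads=None,
):
    return SomaticVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        effect_class=effect, vaf=vaf, somatic_p=somatic_p,
        caller_filter=caller_filter, alt_reads=alt_reads, ref_reads=ref_reads,
    )


def make_sample(sample_id, histology, timepoint=0, patient_id="P1",
                gene=MMRGene.MLH1, **kwargs):
    return SampleRecord(
        sample_id=sample_id, patient_id=patient_id, predisposing_gene=gene,
        histology=Histology(histology), timepoint_years=timepoint, **kwargs,
    )


def make_patient(samples, variant_tables=None, patient_id="P1",
                 gene=MMRGene.MLH1):
    return PatientRecord(
        patient_id=patient_id, predisposing_gene=gene,
        samples=list(samples), variant_tables=variant_tables or {},
    )
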