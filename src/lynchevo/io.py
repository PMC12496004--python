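"""Readers and writers for variant tables and sample sheets.

Two on-disk variant formats are supported: a plain TSV dialect with header
``chrom pos ref alt gene effect vaf alt_reads ref_reads somatic_p filter``
and VCF 4.2 (read via cyvcf2) carrying AD/AF in FORMAT or INFO, the caller's
somatic p-value in ``SOMATIC_P``, and a ``gene|effect`` annotation in ``ANN``.
Positions are 1-based internally (VCF convention); multi-allelic VCF records
are split into one variant per alternate allele.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional

from .models import (
    EffectClass,
    Histology,
    IHCStatus,
    MMRGene,
    PatientRecord,
    SampleRecord,
    SomaticVariant,
)

VARIANT_TSV_HEADER = [
    "chrom", "pos", "ref", "alt", "gene", "effect",
    "vaf", "alt_reads", "ref_reads", "somatic_p", "filter",
]

SAMPLE_SHEET_HEADER = [
    "sample_id", "patient_id", "gene", "tissue", "histology",
    "timepoint", "msi_bat25", "msi_bat26", "ihc",
]

MISSING = "."


class VariantTableError(ValueError):
    """Malformed variant table (the offending row index is reported)."""


class UnresolvableReferenceError(LookupError):
    """Patient has neither blood nor a histologically normal sample."""


#: SnpEff-style annotation terms mapped onto the effect classes used here.
_EFFECT_ALIASES = {
    "missense_variant": EffectClass.missense,
    "stop_gained": EffectClass.nonsense,
    "frameshift_variant": EffectClass.frameshift,
    "splice_donor_variant": EffectClass.splice,
    "splice_acceptor_variant": EffectClass.splice,
    "splice_region_variant": EffectClass.splice,
    "inframe_deletion": EffectClass.in_frame_indel,
    "inframe_insertion": EffectClass.in_frame_indel,
    "disruptive_inframe_deletion": EffectClass.in_frame_indel,
    "disruptive_inframe_insertion": EffectClass.in_frame_indel,
    "synonymous_variant": EffectClass.synonymous,
    "in_frame_deletion": EffectClass.in_frame_indel,
    "in_frame_insertion": EffectClass.in_frame_indel,
}


def effect_from_string(token: str) -> EffectClass:
    """Map an annotation term (native or SnpEff-style) to an effect class."""
    token = token.strip()
    try:
        return EffectClass(token)
    except ValueError:
        pass
    base = token.split("&")[0].split("+")[0]
    if base in _EFFECT_ALIASES:
        return _EFFECT_ALIASES[base]
    if token in _EFFECT_ALIASES:
        return _EFFECT_ALIASES[token]
    return EffectClass.other


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _opt_int(token: str) -> Optional[int]:
    return None if token == MISSING else int(token)


def _opt_float(token: str) -> Optional[float]:
    return None if token == MISSING else float(token)


def read_variant_table(path, format: Optional[str] = None) -> list[SomaticVariant]:
    """Read a variant table; ``format`` is 'tsv', 'vcf', or inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise VariantTableError(f"unknown variant-table format {format!r}")


def _read_tsv(path: Path) -> list[SomaticVariant]:
    variants: list[SomaticVariant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != VARIANT_TSV_HEADER:
            raise VariantTableError(f"{path}: unexpected header {header}")
        for i, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(VARIANT_TSV_HEADER):
                raise VariantTableError(
                    f"{path}: row {i}: expected {len(VARIANT_TSV_HEADER)} "
                    f"fields, found {len(fields)}"
                )
            try:
                variants.append(
                    SomaticVariant(
                        chrom=fields[0],
                        pos=int(fields[1]),
                        ref=fields[2],
                        alt=fields[3],
                        gene=fields[4],
                        effect_class=effect_from_string(fields[5]),
                        vaf=float(fields[6]),
                        alt_reads=_opt_int(fields[7]),
                        ref_reads=_opt_int(fields[8]),
                        somatic_p=_opt_float(fields[9]),
                        caller_filter=fields[10],
                    )
                )
            except (ValueError, TypeError) as exc:
                raise VariantTableError(f"{path}: row {i}: {exc}") from exc
    return variants


def write_variant_table(variants: Iterable[SomaticVariant], path) -> None:
    """Write the TSV dialect; round-trips all fields bit-exactly."""
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_TSV_HEADER) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene,
                        v.effect_class.value,
                        _fmt(v.vaf),
                        _fmt(v.alt_reads),
                        _fmt(v.ref_reads),
                        _fmt(v.somatic_p),
                        v.caller_filter.value,
                    ]
                )
                + "\n"
            )


def _read_vcf(path: Path) -> list[SomaticVariant]:
    from cyvcf2 import VCF

    variants: list[SomaticVariant] = []
    vcf = VCF(str(path))
    try:
        n_samples = len(vcf.samples)
        for record in vcf:
            ann = record.INFO.get("ANN")
            gene, effect = "", EffectClass.other
            if ann:
                first = str(ann).split(",")[0]
                parts = first.split("|")
                if len(parts) >= 2:
                    gene, effect = parts[0], effect_from_string(parts[1])
                else:
                    gene = parts[0]
            somatic_p = record.INFO.get("SOMATIC_P")
            if somatic_p is not None:
                somatic_p = float(somatic_p)
            caller_filter = "PASS" if record.FILTER is None else "other"

            ad = af = None
            if n_samples:
                fmt_ad = record.format("AD")
                if fmt_ad is not None:
                    ad = [int(x) for x in fmt_ad[0]]
                fmt_af = record.format("AF")
                if fmt_af is not None:
                    af = [float(x) for x in fmt_af[0]]
            if ad is None:
                info_ad = record.INFO.get("AD")
                if info_ad is not None:
                    ad = [int(x) for x in (
                        info_ad if isinstance(info_ad, tuple) else (info_ad,)
                    )]
            if af is None:
                info_af = record.INFO.get("AF")
                if info_af is not None:
                    af = [float(x) for x in (
                        info_af if isinstance(info_af, tuple) else (info_af,)
                    )]

            for alt_index, alt in enumerate(record.ALT):
                alt_reads = ref_reads = None
                if ad is not None and len(ad) >= 2 + alt_index:
                    alt_reads = ad[1 + alt_index]
                    # after allele splitting, every non-alt read counts as
                    # reference support, keeping vaf = alt/(alt+ref)
                    ref_reads = sum(ad) - alt_reads
                if af is not None and len(af) > alt_index:
                    vaf = af[alt_index]
                elif alt_reads is not None and ref_reads is not None:
                    total = alt_reads + ref_reads
                    vaf = alt_reads / total if total else 0.0
                else:
                    vaf = 0.0
                variants.append(
                    SomaticVariant(
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        gene=gene,
                        effect_class=effect,
                        vaf=vaf,
                        alt_reads=alt_reads,
                        ref_reads=ref_reads,
                        somatic_p=somatic_p,
                        caller_filter=caller_filter,
                    )
                )
    finally:
        vcf.close()
    return variants


def read_sample_sheet(path) -> list[SampleRecord]:
    """Read the TSV sample sheet into sample records (MSI markers optional)."""
    records: list[SampleRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SAMPLE_SHEET_HEADER:
            raise VariantTableError(f"{path}: unexpected sample-sheet header {header}")
        for i, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(SAMPLE_SHEET_HEADER):
                raise VariantTableError(f"{path}: row {i}: wrong field count")
            msi = {}
            if f[6] != MISSING:
                msi["BAT25"] = int(f[6])
            if f[7] != MISSING:
                msi["BAT26"] = int(f[7])
            records.append(
                SampleRecord(
                    sample_id=f[0],
                    patient_id=f[1],
                    predisposing_gene=MMRGene(f[2]),
                    histology=Histology(f[4]),
                    timepoint_years=int(f[5]),
                    msi_deviations=msi,
                    ihc_loss=IHCStatus(f[8]),
                )
            )
    return records


def write_sample_sheet(records: Iterable[SampleRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SAMPLE_SHEET_HEADER) + "\n")
        for s in records:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        s.patient_id,
                        s.predisposing_gene.value,
                        s.tissue_class.value,
                        s.histology.value,
                        str(s.timepoint_years),
                        _fmt(s.msi_deviations.get("BAT25")),
                        _fmt(s.msi_deviations.get("BAT26")),
                        s.ihc_loss.value,
                    ]
                )
                + "\n"
            )


def group_patients(samples: Iterable[SampleRecord]) -> dict[str, PatientRecord]:
    """Group sample records into patient records (insertion-ordered)."""
    patients: dict[str, PatientRecord] = {}
    for s in samples:
        if s.patient_id not in patients:
            patients[s.patient_id] = PatientRecord(
                patient_id=s.patient_id, predisposing_gene=s.predisposing_gene
            )
        patients[s.patient_id].samples.append(s)
    return patients


def resolve_reference_sample(patient: PatientRecord) -> SampleRecord:
    """Pick the somatic-calling reference: blood, else the closest normal.

    Blood is used whenever available.  Otherwise the histologically normal
    sample (endometrium or fallopian tube) minimizing the mean absolute
    timepoint distance to the patient's neoplastic samples is chosen;
    equidistant candidates prefer endometrium over fallopian tube, then the
    lexicographically smallest sample id.
    """
    if not patient.samples:
        raise UnresolvableReferenceError(f"{patient.patient_id}: no samples")
    for s in patient.samples:
        if s.tissue_class.value == "blood":
            return s
    normals = [s for s in patient.samples if s.is_normal_tissue]
    if not normals:
        raise UnresolvableReferenceError(
            f"{patient.patient_id}: no blood and no normal sample"
        )
    neoplastic_tps = [s.timepoint_years for s in patient.neoplastic_samples]
    if not neoplastic_tps:
        neoplastic_tps = [0]

    def sort_key(s: SampleRecord):
        dist = sum(abs(s.timepoint_years - tp) for tp in neoplastic_tps) / len(
            neoplastic_tps
        )
        tissue_rank = 0 if s.tissue_class.value == "normal_endometrium" else 1
        return (dist, tissue_rank, s.sample_id)

    best = min(normals, key=sort_key)
    if math.isinf(best.timepoint_years):  # pragma: no cover - defensive
        raise UnresolvableReferenceError(patient.patient_id)
    return best
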