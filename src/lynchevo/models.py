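"""Domain types for Lynch-syndrome tumor-series analysis.

The package analyses consecutive specimens (normal endometrium, hyperplasia,
carcinoma, plus a blood reference) from carriers of a pathogenic germline
variant in a mismatch-repair (MMR) gene.  Timepoints are expressed in years
relative to the carcinoma endpoint, so every timepoint is ``<= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class MMRGene(str, Enum):
    MLH1 = "MLH1"
    MSH2 = "MSH2"
    MSH6 = "MSH6"
    PMS2 = "PMS2"


class TissueClass(str, Enum):
    blood = "blood"
    normal_endometrium = "normal_endometrium"
    fallopian_tube = "fallopian_tube"
    SH = "SH"
    CH = "CH"
    CAH = "CAH"
    carcinoma = "carcinoma"


class Histology(str, Enum):
    EEC = "EEC"    # endometrioid endometrial carcinoma
    CCEC = "CCEC"  # clear cell endometrial carcinoma
    CxEC = "CxEC"  # cervical adenocarcinoma (grouped with EC)
    EOC = "EOC"    # endometrioid ovarian carcinoma
    CCOC = "CCOC"  # clear cell ovarian carcinoma
    CAH = "CAH"    # complex atypical hyperplasia
    CH = "CH"      # complex hyperplasia without atypia
    SH = "SH"      # simple hyperplasia
    NE = "NE"      # normal endometrium
    FT = "FT"      # normal fallopian tube
    B = "B"        # blood


#: Carcinoma group assignment.  CxEC is grouped with endometrial carcinoma:
#: this is forced by the cohort bookkeeping (the EC group counts 27 samples,
#: reachable only with CxEC included) and is verified by the EC mean-TMB
#: reconstruction.
CARCINOMA_GROUP = {
    Histology.EEC: "EC",
    Histology.CCEC: "EC",
    Histology.CxEC: "EC",
    Histology.EOC: "OC",
    Histology.CCOC: "OC",
}

CARCINOMA_HISTOLOGIES = frozenset(CARCINOMA_GROUP)
HYPERPLASIA_HISTOLOGIES = frozenset({Histology.CAH, Histology.CH, Histology.SH})

_HISTOLOGY_TISSUE = {
    Histology.B: TissueClass.blood,
    Histology.NE: TissueClass.normal_endometrium,
    Histology.FT: TissueClass.fallopian_tube,
    Histology.SH: TissueClass.SH,
    Histology.CH: TissueClass.CH,
    Histology.CAH: TissueClass.CAH,
}


def tissue_for_histology(histology: Histology) -> TissueClass:
    """Tissue class implied by a histology code (carcinoma subtypes collapse)."""
    if histology in CARCINOMA_HISTOLOGIES:
        return TissueClass.carcinoma
    return _HISTOLOGY_TISSUE[histology]


class IHCStatus(str, Enum):
    loss = "loss"
    retained = "retained"
    not_done = "not_done"


class EffectClass(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice = "splice"
    in_frame_indel = "in_frame_indel"
    synonymous = "synonymous"
    other = "other"


class Curation(str, Enum):
    uncurated = "uncurated"
    kept = "kept"
    removed_quality = "removed_quality"
    removed_misplaced_reads = "removed_misplaced_reads"
    removed_misinterpretation = "removed_misinterpretation"
    removed_blood_vaf = "removed_blood_vaf"


class CallerFilter(str, Enum):
    PASS = "PASS"
    other = "other"


@dataclass
class SampleRecord:
    """One tissue specimen of one patient.

    ``timepoint_years`` is 0 at the carcinoma endpoint and negative before it.
    ``msi_deviations`` maps marker name (BAT25, BAT26, ...) to the observed
    allele-length deviation in nucleotides; missing markers are absent from the
    map, never imputed.
    """

    sample_id: str
    patient_id: str
    predisposing_gene: MMRGene
    histology: Histology
    timepoint_years: int
    tissue_class: TissueClass = None  # type: ignore[assignment]
    msi_deviations: dict[str, int] = field(default_factory=dict)
    ihc_loss: IHCStatus = IHCStatus.not_done

    def __post_init__(self) -> None:
        if isinstance(self.predisposing_gene, str):
            self.predisposing_gene = MMRGene(self.predisposing_gene)
        if isinstance(self.histology, str):
            self.histology = Histology(self.histology)
        if isinstance(self.ihc_loss, str):
            self.ihc_loss = IHCStatus(self.ihc_loss)
        if self.tissue_class is None:
            self.tissue_class = tissue_for_histology(self.histology)
        elif isinstance(self.tissue_class, str):
            self.tissue_class = TissueClass(self.tissue_class)
        if self.timepoint_years > 0:
            raise ValueError(
                f"{self.sample_id}: timepoint_years must be <= 0 "
                f"(0 = carcinoma endpoint), got {self.timepoint_years}"
            )
        expected = tissue_for_histology(self.histology)
        if self.tissue_class != expected:
            raise ValueError(
                f"{self.sample_id}: histology {self.histology.value} implies "
                f"tissue {expected.value}, got {self.tissue_class.value}"
            )

    @property
    def is_neoplastic(self) -> bool:
        return self.tissue_class in (
            TissueClass.carcinoma,
            TissueClass.CAH,
            TissueClass.CH,
            TissueClass.SH,
        )

    @property
    def is_normal_tissue(self) -> bool:
        return self.tissue_class in (
            TissueClass.normal_endometrium,
            TissueClass.fallopian_tube,
        )

    @property
    def carcinoma_group(self) -> Optional[str]:
        """'EC' or 'OC' for carcinomas, None otherwise."""
        return CARCINOMA_GROUP.get(self.histology)


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic variant call (1-based position, VCF-style ref/alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect_class: EffectClass = EffectClass.other
    vaf: float = 0.0
    alt_reads: Optional[int] = None
    ref_reads: Optional[int] = None
    somatic_p: Optional[float] = None
    caller_filter: CallerFilter = CallerFilter.PASS
    curation: Curation = Curation.uncurated

    def __post_init__(self) -> None:
        if isinstance(self.effect_class, str):
            object.__setattr__(self, "effect_class", EffectClass(self.effect_class))
        if isinstance(self.caller_filter, str):
            cf = CallerFilter.PASS if self.caller_filter == "PASS" else CallerFilter.other
            object.__setattr__(self, "caller_filter", cf)
        if isinstance(self.curation, str):
            object.__setattr__(self, "curation", Curation(self.curation))
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in [0,1], got {self.vaf}")
        if self.somatic_p is not None and not 0.0 <= self.somatic_p <= 1.0:
            raise ValueError(f"somatic_p must lie in [0,1], got {self.somatic_p}")
        if self.alt_reads is not None and self.ref_reads is not None:
            total = self.alt_reads + self.ref_reads
            if total > 0 and abs(self.vaf - self.alt_reads / total) > 0.005:
                raise ValueError(
                    f"{self.chrom}:{self.pos} {self.ref}>{self.alt}: vaf "
                    f"{self.vaf} inconsistent with reads "
                    f"{self.alt_reads}/{total}"
                )

    @property
    def depth(self) -> Optional[int]:
        if self.alt_reads is None or self.ref_reads is None:
            return None
        return self.alt_reads + self.ref_reads


@dataclass
class PatientRecord:
    """A patient: her specimens plus per-sample somatic variant tables."""

    patient_id: str
    predisposing_gene: MMRGene
    samples: list[SampleRecord] = field(default_factory=list)
    variant_tables: dict[str, list[SomaticVariant]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.predisposing_gene, str):
            self.predisposing_gene = MMRGene(self.predisposing_gene)
        ids = {s.sample_id for s in self.samples}
        for sid in self.variant_tables:
            if sid not in ids:
                raise ValueError(
                    f"variant table for unknown sample {sid!r} "
                    f"(patient {self.patient_id})"
                )
        for s in self.samples:
            if s.patient_id != self.patient_id:
                raise ValueError(
                    f"sample {s.sample_id} belongs to {s.patient_id}, "
                    f"not {self.patient_id}"
                )

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def neoplastic_samples(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.is_neoplastic]


class SecondHitMechanism(str, Enum):
    LOH = "LOH"
    pLOH = "pLOH"
    somatic_variant = "somatic_variant"


@dataclass
class SecondHitVariant:
    variant: SomaticVariant
    vaf: float
    sub_threshold: bool


@dataclass
class SecondHitCall:
    """Per-sample evidence for somatic inactivation of the wild-type allele."""

    sample_id: str
    mechanisms: set[SecondHitMechanism] = field(default_factory=set)
    variants: list[SecondHitVariant] = field(default_factory=list)

    @property
    def any_hit(self) -> bool:
        return bool(self.mechanisms)


@dataclass
class SharingResult:
    """Variant-set overlap between two samples called under one policy.

    ``sharing_pct`` is shared / (shared + unique_1 + unique_2); the
    directional fractions divide the shared count by each sample's total.
    """

    sample_id_1: str
    sample_id_2: str
    n_shared: int
    n_unique_1: int
    n_unique_2: int
    shared_keys: frozenset = frozenset()
    degenerate: bool = False

    @property
    def sharing_pct(self) -> float:
        denom = self.n_shared + self.n_unique_1 + self.n_unique_2
        return self.n_shared / denom if denom else 0.0

    @property
    def directional_1(self) -> float:
        denom = self.n_shared + self.n_unique_1
        return self.n_shared / denom if denom else 0.0

    @property
    def directional_2(self) -> float:
        denom = self.n_shared + self.n_unique_2
        return self.n_shared / denom if denom else 0.0
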