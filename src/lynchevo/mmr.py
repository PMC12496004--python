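"""MMR-deficiency calling and MMR-gene second hits.

A sample has microsatellite instability (MSI) when at least one mononucleotide
marker (BAT25/BAT26 by default) deviates by 2 or more nucleotides from the
germline allele length.  MMR deficiency (dMMR) is MSI or immunohistochemical
loss of the relevant MMR protein, or both.

The "second hit" — somatic inactivation of the remaining wild-type MMR
allele — is called per sample from two mechanisms: loss of heterozygosity at
the constitutionally heterozygous pathogenic variant (tumor:normal allelic
ratio), and somatic variants of the predisposing MMR gene.  A variant below
the 5% VAF cut-off is still attached to a sample (flagged sub-threshold) when
the identical variant reaches 5% in another sample of the same patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

from .filtering import FilterPolicy, VariantKey, raw_key
from .models import (
    IHCStatus,
    PatientRecord,
    SecondHitCall,
    SecondHitMechanism,
    SecondHitVariant,
    SomaticVariant,
)

MSI_DEVIATION_NT = 2


@dataclass(frozen=True)
class MSIResult:
    deviations: tuple[tuple[str, int], ...]

    @property
    def msi(self) -> bool:
        return any(d >= MSI_DEVIATION_NT for _, d in self.deviations)


class NotEvaluableError(ValueError):
    """No marker measured / no evaluable MMR evidence."""


def call_msi(deviations: Mapping[str, Optional[int]]) -> MSIResult:
    """MSI iff any measured marker deviates by >= 2 nt; missing markers are
    ignored, all-missing is not evaluable."""
    measured = tuple(
        (marker, d) for marker, d in deviations.items() if d is not None
    )
    if not measured:
        raise NotEvaluableError("all MSI markers missing")
    return MSIResult(measured)


class MMRStatus(str, Enum):
    dMMR = "dMMR"
    pMMR = "pMMR"
    not_evaluable = "not_evaluable"


def classify_mmr(
    msi: Optional[MSIResult], ihc_loss: IHCStatus = IHCStatus.not_done
) -> MMRStatus:
    """dMMR = MSI or IHC protein loss or both; pMMR requires every evaluable
    line of evidence to be negative."""
    msi_known = msi is not None
    ihc_known = ihc_loss != IHCStatus.not_done
    if not msi_known and not ihc_known:
        return MMRStatus.not_evaluable
    if (msi_known and msi.msi) or ihc_loss == IHCStatus.loss:
        return MMRStatus.dMMR
    return MMRStatus.pMMR


class LOHCall(str, Enum):
    LOH = "LOH"
    pLOH = "pLOH"
    none = "none"
    not_informative = "not_informative"


@dataclass(frozen=True)
class LOHThresholds:
    """Allelic-ratio thresholds for strict / putative LOH.

    With the pathogenic (alt) allele gaining on wild-type loss, a ratio at or
    above ``strict_upper`` is strict LOH and the putative band sits between
    ``putative_upper`` and ``strict_upper``.  The reciprocal lower thresholds
    cover loss of the mutant allele; only wild-type loss is reported as a
    second hit.  Defaults encode the conventional two-fold allelic imbalance.
    """

    strict_upper: float = 2.0
    putative_upper: float = 1.5

    def __post_init__(self) -> None:
        if not 1.0 < self.putative_upper < self.strict_upper:
            raise ValueError(
                "thresholds must satisfy 1 < putative_upper < strict_upper, "
                f"got {self.putative_upper} / {self.strict_upper}"
            )

    @property
    def strict_lower(self) -> float:
        return 1.0 / self.strict_upper

    @property
    def putative_lower(self) -> float:
        return 1.0 / self.putative_upper


@dataclass(frozen=True)
class LOHResult:
    ratio: Optional[float]
    call: LOHCall
    wildtype_lost: bool


def loh_ratio(
    t_alt: int, t_ref: int, n_alt: int, n_ref: int
) -> Optional[float]:
    """Tumor:normal allelic ratio (alt:ref)_T / (alt:ref)_N.

    A Haldane-style 0.5 pseudocount is added to every count whenever any of
    them is zero, keeping the ratio finite and symmetric.  Returns None (not
    informative) when the normal sample is homozygous (no reads on either
    allele would make the ratio meaningless).
    """
    for c in (t_alt, t_ref, n_alt, n_ref):
        if c < 0:
            raise ValueError("read counts must be >= 0")
    if n_alt == 0 and n_ref == 0:
        return None
    if min(t_alt, t_ref, n_alt, n_ref) == 0:
        t_alt, t_ref, n_alt, n_ref = (
            t_alt + 0.5, t_ref + 0.5, n_alt + 0.5, n_ref + 0.5,
        )
    return (t_alt / t_ref) / (n_alt / n_ref)


def classify_loh(
    ratio: Optional[float], thresholds: LOHThresholds = LOHThresholds()
) -> LOHResult:
    """Classify a tumor:normal allelic ratio (pathogenic allele as alt).

    Ratios above 1 mean the pathogenic allele gained, i.e. the wild-type
    allele was lost; the reciprocal band flags loss of the mutant allele,
    which is recorded but never reported as a second hit.
    """
    if ratio is None:
        return LOHResult(None, LOHCall.not_informative, False)
    if ratio <= 0:
        raise ValueError(f"allelic ratio must be positive, got {ratio}")
    if ratio >= thresholds.strict_upper:
        return LOHResult(ratio, LOHCall.LOH, True)
    if ratio >= thresholds.putative_upper:
        return LOHResult(ratio, LOHCall.pLOH, True)
    if ratio <= thresholds.strict_lower:
        return LOHResult(ratio, LOHCall.LOH, False)
    if ratio <= thresholds.putative_lower:
        return LOHResult(ratio, LOHCall.pLOH, False)
    return LOHResult(ratio, LOHCall.none, False)


def call_second_hits(
    patient: PatientRecord,
    mmr_gene: Optional[str] = None,
    loh_results: Optional[Mapping[str, LOHResult]] = None,
    policy: FilterPolicy = FilterPolicy(),
    panel_genes: Optional[set[str]] = None,
) -> list[SecondHitCall]:
    """Per-sample second-hit calls for a patient's neoplastic samples.

    Somatic-variant mechanism: variants of the predisposing MMR gene passing
    the p-value/PASS screens with VAF >= ``policy.vaf_min``; a sub-threshold
    occurrence of a variant is rescued (kept, flagged ``sub_threshold``, exact
    VAF retained) when the identical variant reaches the cut-off in another
    sample of the same patient.  LOH/pLOH mechanism: wild-type-allele loss
    from ``loh_results`` (sample_id -> LOHResult).  The result is invariant
    to sample ordering within the patient.
    """
    gene = mmr_gene or patient.predisposing_gene.value
    if panel_genes is not None and gene not in panel_genes:
        raise ValueError(
            f"MMR gene {gene!r} absent from the panel annotation "
            f"(patient {patient.patient_id})"
        )

    def screened(variants: Iterable[SomaticVariant]) -> list[SomaticVariant]:
        # p-value / PASS / non-synonymous screens, but no VAF floor: the
        # cross-sample rescue needs sub-threshold occurrences.
        relaxed = FilterPolicy(
            p_max=policy.p_max,
            vaf_min=0.0,
            require_pass=policy.require_pass,
            nonsynonymous_only=policy.nonsynonymous_only,
            blood_vaf_max=policy.blood_vaf_max,
        )
        from .filtering import significant_somatic

        return [v for v in significant_somatic(variants, relaxed) if v.gene == gene]

    per_sample = {
        sid: screened(variants) for sid, variants in patient.variant_tables.items()
    }
    anchors: set[VariantKey] = {
        raw_key(v)
        for variants in per_sample.values()
        for v in variants
        if policy.vaf_passes(v.vaf)
    }

    calls: list[SecondHitCall] = []
    for sample in sorted(patient.neoplastic_samples, key=lambda s: s.sample_id):
        call = SecondHitCall(sample_id=sample.sample_id)
        loh = (loh_results or {}).get(sample.sample_id)
        if loh is not None and loh.wildtype_lost:
            call.mechanisms.add(
                SecondHitMechanism.LOH
                if loh.call == LOHCall.LOH
                else SecondHitMechanism.pLOH
            )
        for v in per_sample.get(sample.sample_id, []):
            passes = policy.vaf_passes(v.vaf)
            if passes or raw_key(v) in anchors:
                call.variants.append(
                    SecondHitVariant(variant=v, vaf=v.vaf, sub_threshold=not passes)
                )
        if call.variants:
            # every attached variant either passes the cut-off itself or was
            # rescued by an anchor occurrence elsewhere in the patient
            call.mechanisms.add(SecondHitMechanism.somatic_variant)
        calls.append(call)
    return calls


def mutual_exclusivity(
    calls: Iterable[tuple[bool, bool]]
) -> tuple[list[list[int]], float]:
    """2x2 table of (LOH or pLOH) x (somatic variant >= 5% VAF) with a
    two-sided Fisher exact p; input is (has_loh, has_variant) per sample."""
    from .stats import fisher_2x2

    a = b = c = d = 0
    for has_loh, has_variant in calls:
        if has_loh and has_variant:
            a += 1
        elif has_loh:
            b += 1
        elif has_variant:
            c += 1
        else:
            d += 1
    table = [[a, b], [c, d]]
    return table, fisher_2x2(table)
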