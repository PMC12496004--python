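"""Somatic-variant inclusion rules and low-level presence probing.

The default policy mirrors the study conditions for targeted-panel somatic
calls against a matched normal: caller somatic p-value < .01, VAF >= 5%,
caller PASS status, non-synonymous effects only.  A separate manual-curation
step (visual read inspection) is consumed as a decision table; variants whose
blood VAF exceeds 5% are removed to avoid confusing tumor variants with
clonal hematopoiesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .models import Curation, EffectClass, SomaticVariant

VariantKey = tuple[str, int, str, str]


def raw_key(v: SomaticVariant) -> VariantKey:
    return (v.chrom, v.pos, v.ref, v.alt)


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusion thresholds for significant somatic variants."""

    p_max: float = 0.01
    vaf_min: float = 0.05
    require_pass: bool = True
    nonsynonymous_only: bool = True
    blood_vaf_max: float = 0.05
    #: VAF comparison at the boundary: the study's tables treat the 5%
    #: cut-off inclusively (>=), the prose says "higher than"; inclusive is
    #: the default and the behavior is a flag.
    vaf_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise ValueError(f"p_max must lie in (0,1], got {self.p_max}")
        if not 0 <= self.vaf_min < 1:
            raise ValueError(f"vaf_min must lie in [0,1), got {self.vaf_min}")

    def vaf_passes(self, vaf: float) -> bool:
        return vaf >= self.vaf_min if self.vaf_inclusive else vaf > self.vaf_min


def significant_somatic(
    variants: Iterable[SomaticVariant], policy: FilterPolicy = FilterPolicy()
) -> list[SomaticVariant]:
    """Keep variants passing the policy; input order is preserved.

    Raises ``ValueError`` naming the variant if ``somatic_p`` is missing
    while p-value filtering is requested.
    """
    kept = []
    for v in variants:
        if v.somatic_p is None:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} lacks somatic_p "
                "required by the filter policy"
            )
        if v.somatic_p >= policy.p_max:
            continue
        if not policy.vaf_passes(v.vaf):
            continue
        if policy.require_pass and v.caller_filter.value != "PASS":
            continue
        if policy.nonsynonymous_only and v.effect_class == EffectClass.synonymous:
            continue
        kept.append(v)
    return kept


class CurationDecision(str, Enum):
    kept = "kept"
    quality = "quality"
    misplaced = "misplaced"
    misinterpretation = "misinterpretation"
    blood_vaf = "blood_vaf"


_DECISION_TO_CURATION = {
    CurationDecision.kept: Curation.kept,
    CurationDecision.quality: Curation.removed_quality,
    CurationDecision.misplaced: Curation.removed_misplaced_reads,
    CurationDecision.misinterpretation: Curation.removed_misinterpretation,
    CurationDecision.blood_vaf: Curation.removed_blood_vaf,
}


@dataclass
class CurationSummary:
    n_input: int = 0
    n_retained: int = 0
    removed_by_category: dict[str, int] = field(default_factory=dict)

    def removal_fractions(self) -> dict[str, float]:
        total = sum(self.removed_by_category.values())
        if not total:
            return {}
        return {k: n / total for k, n in self.removed_by_category.items()}


def read_curation_table(path) -> dict[VariantKey, CurationDecision]:
    """Curation TSV: ``chrom pos ref alt decision`` (header required)."""
    table: dict[VariantKey, CurationDecision] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "ref", "alt", "decision"]:
            raise ValueError(f"{path}: unexpected curation header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, pos, ref, alt, decision = line.split("\t")
            table[(chrom, int(pos), ref, alt)] = CurationDecision(decision)
    return table


def apply_curation(
    variants: Iterable[SomaticVariant],
    curation_table: Mapping[VariantKey, CurationDecision],
    blood_vafs: Optional[Mapping[VariantKey, float]] = None,
    blood_vaf_max: float = 0.05,
) -> tuple[list[SomaticVariant], CurationSummary]:
    """Apply a manual-curation decision table.

    Removed variants are excluded from the returned list (and re-tagged with
    their removal category); an entry referencing an absent variant elicits a
    warning, not an error.  Variants whose blood VAF (from ``blood_vafs``)
    exceeds ``blood_vaf_max`` are removed under the blood-VAF category even
    without an explicit table entry.
    """
    variants = list(variants)
    summary = CurationSummary(n_input=len(variants))
    present = {raw_key(v) for v in variants}
    for key in curation_table:
        if key not in present:
            warnings.warn(f"curation entry for absent variant {key}", stacklevel=2)

    retained: list[SomaticVariant] = []
    for v in variants:
        key = raw_key(v)
        decision = curation_table.get(key)
        if decision is None and blood_vafs is not None:
            if blood_vafs.get(key, 0.0) > blood_vaf_max:
                decision = CurationDecision.blood_vaf
        if decision is None or decision == CurationDecision.kept:
            retained.append(v)
            continue
        category = _DECISION_TO_CURATION[decision].value
        summary.removed_by_category[category] = (
            summary.removed_by_category.get(category, 0) + 1
        )
    summary.n_retained = len(retained)
    return retained, summary


class ProbeStatus(str, Enum):
    present = "present"
    absent = "absent"
    no_coverage = "no_coverage"


@dataclass(frozen=True)
class ProbeVerdict:
    status: ProbeStatus
    alt_reads: int
    total_reads: int

    @property
    def vaf(self) -> Optional[float]:
        if self.total_reads == 0:
            return None
        return self.alt_reads / self.total_reads


def probe_low_level(
    alt_reads: int, total_reads: int, min_reads: int = 5, min_vaf: float = 0.01
) -> ProbeVerdict:
    """Low-level presence call in a probed (normal) sample.

    Present iff supported by at least ``min_reads`` reads AND reaching
    ``min_vaf``; zero coverage yields a distinct no-coverage verdict.
    """
    if total_reads == 0:
        return ProbeVerdict(ProbeStatus.no_coverage, alt_reads, total_reads)
    if alt_reads >= min_reads and alt_reads / total_reads >= min_vaf:
        return ProbeVerdict(ProbeStatus.present, alt_reads, total_reads)
    return ProbeVerdict(ProbeStatus.absent, alt_reads, total_reads)
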